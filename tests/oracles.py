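"""Independent test oracles, kept free of the implementation paths they check.

- Gotoh local alignment (affine gaps) implemented directly as dynamic
  programming, for checking germline assignment scores.
- A numerical ODE integration of the 1:1 binding rate equation, for
  checking the closed-form sensorgram.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

NEG_INF = float("-inf")


def smith_waterman(
    a: str, b: str,
    match: float = 1.0, mismatch: float = -1.0,
    gap_open: float = -2.0, gap_extend: float = -1.0,
) -> float:
    """Local alignment score, affine gaps: a gap of length L costs
    gap_open + (L-1) * gap_extend."""
    n, m = len(a), len(b)
    h = np.zeros((n + 1, m + 1))        # best ending in a match/mismatch or 0
    e = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consume b)
    f = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] + gap_open, e[i][j - 1] + gap_extend)
            f[i][j] = max(h[i - 1][j] + gap_open, f[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            if h[i][j] > best:
                best = h[i][j]
    return best


def best_reference_by_sw(contig: str, segments) -> tuple[str, float]:
    """Exhaustive best-scoring segment (first in order wins ties)."""
    best_name, best_score = None, NEG_INF
    for seg in segments:
        score = smith_waterman(contig, seg.seq)
        if score > best_score:
            best_name, best_score = seg.name, score
    return best_name, best_score


def integrate_binding_ode(
    ka: float, kd: float, rmax: float, conc: float,
    t_assoc: np.ndarray, t_dissoc: np.ndarray, assoc_duration: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dR/dt = ka*C*(Rmax - R) - kd*R through both phases."""

    def rate(_t, r, c):
        return ka * c * (rmax - r[0]) - kd * r[0]

    sol_a = solve_ivp(rate, (0.0, float(assoc_duration)), [0.0], args=(conc,),
                      t_eval=t_assoc, rtol=1e-10, atol=1e-12, max_step=1.0)
    r_end = solve_ivp(rate, (0.0, float(assoc_duration)), [0.0], args=(conc,),
                      rtol=1e-10, atol=1e-12, max_step=1.0).y[0, -1]
    sol_d = solve_ivp(rate, (0.0, float(t_dissoc[-1]) if len(t_dissoc) else 0.0),
                      [r_end], args=(0.0,), t_eval=t_dissoc,
                      rtol=1e-10, atol=1e-12, max_step=1.0)
    return sol_a.y[0], sol_d.y[0]
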