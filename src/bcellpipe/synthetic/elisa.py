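"""ELISA titration simulator: saturating binding curve over a serial dilution."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..datatypes import ElisaCurve


@dataclass
class LogisticParams:
    """Four-parameter logistic on concentration: OD = bg + (top-bg)/(1+(ec50/C)^hill)."""

    od_max: float = 2.5
    od_background: float = 0.05
    ec50: float = 1.0       # in units of starting concentration
    hill: float = 1.0


def simulate_elisa(
    top_concentration: float = 1.0,
    dilution_factor: float = 2.0,
    points: int = 8,
    params: LogisticParams | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    group: str = "",
) -> ElisaCurve:
    """Simulate an OD450 titration (default: load plus 7 two-fold dilutions)."""
    if points < 2:
        raise ValueError("need at least 2 titration points")
    if dilution_factor <= 1.0:
        raise ValueError("dilution factor must exceed 1")
    if params is None:
        params = LogisticParams()
    rng = np.random.default_rng(seed)
    dilution = dilution_factor ** np.arange(points)
    conc = top_concentration / dilution
    od = params.od_background + (params.od_max - params.od_background) / (
        1.0 + (params.ec50 / conc) ** params.hill
    )
    if noise_sd:
        od = od + rng.normal(0.0, noise_sd, size=od.size)
    return ElisaCurve(dilution=dilution, od450=od, group=group)
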