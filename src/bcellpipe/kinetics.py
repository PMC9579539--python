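"""Binding quantification: SPR 1:1 Langmuir kinetic fitting and ELISA AUC.

The kinetic fit is global: one (ka, kd, Rmax) triple is fit by nonlinear
least squares across all concentration traces simultaneously, with
multi-start over log-spaced rate initializations.  A per-curve mode is
available for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .datatypes import ElisaCurve, KineticParameters, SensorgramSet

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    spike_window_s: float = 2.0   # dropped on each side of a phase boundary


def preprocess_sensorgram(
    raw: SensorgramSet, params: PreprocessParams | None = None
) -> SensorgramSet:
    """Baseline-subtract, re-zero time at injection, drop boundary spikes.

    The per-trace baseline is the mean response of the pre-injection
    samples; the first association sample defines the injection time.
    """
    if params is None:
        params = PreprocessParams()
    frames = []
    for conc, grp in raw.df.groupby("conc_M", sort=True):
        pre = grp[grp["phase"] == "baseline"]
        if pre.empty:
            raise ValueError(f"no pre-injection samples for C={conc}")
        baseline = pre["ru"].mean()
        work = grp[grp["phase"] != "baseline"].copy()
        t0 = work["time_s"].iloc[0]
        work["time_s"] = work["time_s"] - t0
        work["ru"] = work["ru"] - baseline

        t_assoc_end = raw.association_s
        keep = np.ones(len(work), dtype=bool)
        for boundary in (0.0, t_assoc_end):
            t = work["time_s"].to_numpy()
            keep &= ~((t >= boundary) & (t < boundary + params.spike_window_s))
        frames.append(work[keep])
    import pandas as pd

    return SensorgramSet(pd.concat(frames, ignore_index=True),
                         raw.association_s, raw.dissociation_s)


def langmuir_predict(
    params: KineticParameters, conc: float, t: np.ndarray, phase: str,
    t_assoc: float | None = None,
) -> np.ndarray:
    """Closed-form 1:1 Langmuir response.

    Association (t from injection): R = Req (1 - exp(-(ka C + kd) t)) with
    Req = Rmax ka C / (ka C + kd).  Dissociation (t absolute, past the
    association end ``t_assoc``): R = R0 exp(-kd (t - t_assoc)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    kobs = params.ka * conc + params.kd
    req = params.rmax * params.ka * conc / kobs
    if phase == "assoc":
        return req * (1.0 - np.exp(-kobs * t))
    if phase == "dissoc":
        if t_assoc is None:
            raise ValueError("dissociation prediction needs the association end time")
        r0 = req * (1.0 - np.exp(-kobs * t_assoc))
        return r0 * np.exp(-params.kd * (t - t_assoc))
    raise ValueError(f"unknown phase {phase!r}")


def _model_response(log_ka, log_kd, rmax, conc, t, is_assoc, t_assoc):
    ka, kd = 10.0 ** log_ka, 10.0 ** log_kd
    kobs = ka * conc + kd
    req = rmax * ka * conc / kobs
    r_assoc = req * (1.0 - np.exp(-kobs * t))
    r0 = req * (1.0 - np.exp(-kobs * t_assoc))
    r_dissoc = r0 * np.exp(-kd * (t - t_assoc))
    return np.where(is_assoc, r_assoc, r_dissoc)


@dataclass
class FitOptions:
    log_ka_starts: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0)
    log_kd_starts: tuple[float, ...] = (-4.0, -3.0, -2.0)
    per_curve: bool = False


def fit_langmuir(sgrams: SensorgramSet, options: FitOptions | None = None) -> KineticParameters:
    """Global nonlinear least-squares fit of (ka, kd, Rmax) to all traces."""
    if options is None:
        options = FitOptions()
    work = sgrams.df[sgrams.df["phase"].isin(["assoc", "dissoc"])]
    concs = np.sort(work["conc_M"].unique())
    if concs.size < 2:
        logger.warning("single concentration: reduced identifiability")
    if options.per_curve:
        fits = [
            fit_langmuir(
                SensorgramSet(work[work["conc_M"] == c].reset_index(drop=True),
                              sgrams.association_s, sgrams.dissociation_s),
                FitOptions(options.log_ka_starts, options.log_kd_starts, False),
            )
            for c in concs
        ]
        ka = float(np.exp(np.mean([np.log(f.ka) for f in fits])))
        kd = float(np.exp(np.mean([np.log(f.kd) for f in fits])))
        rmax = float(np.mean([f.rmax for f in fits]))
        return KineticParameters(ka=ka, kd=kd, rmax=rmax)

    t = work["time_s"].to_numpy(dtype=float)
    r = work["ru"].to_numpy(dtype=float)
    c = work["conc_M"].to_numpy(dtype=float)
    is_assoc = (work["phase"] == "assoc").to_numpy()
    t_assoc = sgrams.association_s

    def residuals(theta):
        return _model_response(theta[0], theta[1], theta[2], c, t, is_assoc, t_assoc) - r

    rmax0 = max(float(np.max(r)), 1e-6)
    best = None
    for lka in options.log_ka_starts:
        for lkd in options.log_kd_starts:
            try:
                sol = least_squares(
                    residuals, x0=[lka, lkd, rmax0],
                    bounds=([-2, -8, 1e-9], [9, 2, 1e6]),
                    method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:  # singular starts are simply skipped
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise RuntimeError("Langmuir fit failed to converge from every start")

    n, p = r.size, 3
    rms = float(np.sqrt(2 * best.cost / n))
    # standard errors from the Jacobian at the optimum
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * (2 * best.cost / max(n - p, 1))
        se_log_ka, se_log_kd, se_rmax = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se_log_ka = se_log_kd = se_rmax = float("nan")

    ka, kd, rmax = 10.0 ** best.x[0], 10.0 ** best.x[1], float(best.x[2])
    ln10 = np.log(10.0)
    return KineticParameters(
        ka=float(ka), kd=float(kd), rmax=rmax,
        ka_se=float(ka * ln10 * se_log_ka),
        kd_se=float(kd * ln10 * se_log_kd),
        rmax_se=float(se_rmax),
        residual_rms=rms,
    )


def elisa_auc(curve: ElisaCurve) -> float:
    """Trapezoidal area of OD over log10(dilution)."""
    x = np.log10(curve.dilution)
    return float(np.trapezoid(curve.od450, x))


def compare_groups(aucs_by_group: dict[str, list[float]]):
    """One-way ANOVA plus Tukey pairwise comparisons over per-group AUCs."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = {k: np.asarray(v, dtype=float) for k, v in aucs_by_group.items()}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    f_stat, p_value = stats.f_oneway(*groups.values())
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[k] * v.size for k, v in groups.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    return {"F": float(f_stat), "p": float(p_value), "tukey": tukey}
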