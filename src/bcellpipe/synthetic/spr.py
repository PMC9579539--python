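"""Sensorgram simulator for 1:1 Langmuir binding kinetics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datatypes import SensorgramSet

#: default six-point analyte concentration series (M)
DEFAULT_CONCENTRATIONS = (100e-6, 20e-6, 4e-6, 800e-9, 160e-9, 32e-9)


@dataclass
class SprConfig:
    ka: float = 1e5            # 1/(M*s)
    kd: float = 1e-3           # 1/s
    rmax: float = 100.0        # RU
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    association_s: float = 60.0
    dissociation_s: float = 900.0
    baseline_s: float = 10.0
    sampling_interval_s: float = 0.5
    noise_sd: float = 0.0      # RU
    baseline_offset: float = 0.0  # RU
    spike_amplitude: float = 0.0  # RU, injected at phase boundaries
    spike_width_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.ka, self.kd, self.rmax) <= 0:
            raise ValueError("ka, kd and Rmax must be positive")
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")


def association_response(ka: float, kd: float, rmax: float, conc: float,
                         t: np.ndarray) -> np.ndarray:
    """R(t) = Req * (1 - exp(-(ka*C + kd) t)), Req = Rmax*ka*C/(ka*C + kd)."""
    kobs = ka * conc + kd
    req = rmax * ka * conc / kobs
    return req * (1.0 - np.exp(-kobs * np.asarray(t, dtype=float)))


def dissociation_response(kd: float, r0: float, t: np.ndarray) -> np.ndarray:
    """R(t) = R0 * exp(-kd t) with t measured from dissociation start."""
    return r0 * np.exp(-kd * np.asarray(t, dtype=float))


def simulate_sensorgram(config: SprConfig, seed: int) -> SensorgramSet:
    """Simulate one trace per concentration with noise/baseline/spikes.

    Times are absolute instrument times: the baseline phase runs first and
    the analyte injection happens at ``t = baseline_s``.
    """
    rng = np.random.default_rng(seed)
    dt = config.sampling_interval_s
    frames = []
    for conc in config.concentrations:
        t_base = np.arange(0.0, config.baseline_s, dt)
        t_assoc = np.arange(0.0, config.association_s, dt)
        t_dissoc = np.arange(0.0, config.dissociation_s, dt)

        r_base = np.zeros_like(t_base)
        r_assoc = association_response(config.ka, config.kd, config.rmax, conc, t_assoc)
        r0 = association_response(
            config.ka, config.kd, config.rmax, conc,
            np.array([config.association_s]),
        )[0]
        r_dissoc = dissociation_response(config.kd, r0, t_dissoc)

        t = np.concatenate([
            t_base,
            t_assoc + config.baseline_s,
            t_dissoc + config.baseline_s + config.association_s,
        ])
        r = np.concatenate([r_base, r_assoc, r_dissoc])
        phase = np.concatenate([
            np.full(t_base.size, "baseline"),
            np.full(t_assoc.size, "assoc"),
            np.full(t_dissoc.size, "dissoc"),
        ])

        r = r + config.baseline_offset
        if config.spike_amplitude:
            for boundary in (config.baseline_s,
                             config.baseline_s + config.association_s):
                in_spike = (t >= boundary) & (t < boundary + config.spike_width_s)
                r[in_spike] += config.spike_amplitude
        if config.noise_sd:
            r = r + rng.normal(0.0, config.noise_sd, size=r.size)

        frames.append(pd.DataFrame(
            {"time_s": t, "ru": r, "conc_M": conc, "phase": phase}
        ))

    df = pd.concat(frames, ignore_index=True)
    return SensorgramSet(df, config.association_s, config.dissociation_s)
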