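"""Synthetic anesthesia-transition cohorts.

Clinical induction/emergence EEG is not publicly available, so this module
generates seeded surrogate cohorts whose statistical structure carries the
two features the pipeline is built to detect:

* the awake EEG is more irregular (alpha-band dominated, ~10 Hz resonance)
  than the anesthetized EEG (large, regular slow waves, ~1.5 Hz), so
  permutation entropy is higher while awake;
* a directed, lagged frontal -> parietal influence is present, stronger
  while awake, so symbolic transfer entropy is higher in the
  fronto-parietal than the parieto-frontal direction.

Each channel is a state-weighted mixture of two stationary AR(2) processes
with controllable spectral peaks (pole radius r and angle 2*pi*f_peak/fs).
A weight w(t) built from two logistic transitions falls from 1 (awake) to
0 (anesthetized) around LoR and back to 1 around RoR.  Parietal channels
additionally receive a lagged, state-gain-weighted copy of the mean
frontal signal.  White measurement noise at 5% of the awake signal SD
makes ordinal ties measure-zero.

Everything is deterministic given (config, patient_seed); cohort patient
seeds are ``config.seed + patient_index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ConfigurationError, EegRecording, EventAnnotations, REQUIRED_CHANNELS

_AR_BURN_IN = 2000  # samples discarded so the AR processes start stationary


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Event times: if ``lor_time_s`` / ``ror_time_s`` are None they are drawn
    uniformly per patient, LoR in [60, 120] s and RoR in
    [duration - 120, duration - 60] s.

    AR(2) regimes: the awake process has its spectral peak at
    ``awake_peak_hz`` with pole radius 0.95; the anesthetized process peaks
    at ``anesth_peak_hz`` with pole radius 0.98 and 3x innovation
    amplitude, giving the larger, more regular slow-wave signal.
    """

    n_patients: int = 20
    duration_s: float = 300.0
    fs: float = 250.0
    lor_time_s: float | None = None
    ror_time_s: float | None = None
    lor_range_s: tuple[float, float] = (60.0, 120.0)
    ror_margin_s: tuple[float, float] = (120.0, 60.0)  # from end of recording
    transition_width_s: float = 10.0
    awake_peak_hz: float = 10.0
    anesth_peak_hz: float = 1.5
    awake_pole_radius: float = 0.95
    anesth_pole_radius: float = 0.98
    anesth_gain: float = 3.0  # innovation amplitude multiplier, anesthetized
    awake_coupling: float = 0.4
    anesth_coupling: float = 0.05
    coupling_lag_samples: int = 10  # 40 ms at 250 Hz
    noise_sd: float = 1.0  # AR innovation SD (microvolt scale)
    measurement_noise_frac: float = 0.05  # of awake signal SD
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        if self.transition_width_s <= 0:
            raise ConfigurationError(
                f"transition_width_s must be > 0, got {self.transition_width_s}"
            )
        for name in ("awake_coupling", "anesth_coupling"):
            g = getattr(self, name)
            if not 0 <= g < 1:
                raise ConfigurationError(f"{name} must be in [0, 1), got {g}")
        if self.lor_time_s is not None and self.ror_time_s is not None:
            if not 0 < self.lor_time_s < self.ror_time_s < self.duration_s:
                raise ConfigurationError(
                    "event times must satisfy 0 < lor_time_s < ror_time_s "
                    f"< duration_s, got lor={self.lor_time_s}, "
                    f"ror={self.ror_time_s}, duration={self.duration_s}"
                )
        if self.n_patients < 1:
            raise ConfigurationError(
                f"n_patients must be >= 1, got {self.n_patients}"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")


def _ar2(rng: np.random.Generator, n: int, pole_radius: float,
         peak_hz: float, fs: float, innovation_sd: float) -> np.ndarray:
    """A stationary AR(2) realization with spectral peak near peak_hz."""
    theta = 2 * np.pi * peak_hz / fs
    a = [1.0, -2.0 * pole_radius * np.cos(theta), pole_radius ** 2]
    eps = rng.standard_normal(n + _AR_BURN_IN) * innovation_sd
    return sps.lfilter([1.0], a, eps)[_AR_BURN_IN:]


def _draw_events(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[float, float]:
    lor = (cfg.lor_time_s if cfg.lor_time_s is not None
           else rng.uniform(*cfg.lor_range_s))
    ror = (cfg.ror_time_s if cfg.ror_time_s is not None
           else rng.uniform(cfg.duration_s - cfg.ror_margin_s[0],
                            cfg.duration_s - cfg.ror_margin_s[1]))
    if not 0 < lor < ror < cfg.duration_s:
        raise ConfigurationError(
            f"drawn event times violate 0 < lor < ror < duration: "
            f"lor={lor:.1f}, ror={ror:.1f}, duration={cfg.duration_s}"
        )
    return float(lor), float(ror)


def awake_weight(t_s: np.ndarray, lor_s: float, ror_s: float,
                 width_s: float) -> np.ndarray:
    """State weight w(t): 1 awake, 0 anesthetized, logistic transitions.

    w = 1 - sigmoid((t - lor)/width) * sigmoid((ror - t)/width): the product
    of the two logistic edges carves the anesthetized trough between LoR
    and RoR.
    """
    t = np.asarray(t_s, dtype=float)
    down = 1.0 / (1.0 + np.exp(-(t - lor_s) / width_s))
    up = 1.0 / (1.0 + np.exp(-(ror_s - t) / width_s))
    return 1.0 - down * up


def generate_recording(
    config: SimulationConfig,
    patient_seed: int,
    patient_id: str | None = None,
) -> tuple[EegRecording, EventAnnotations]:
    """One synthetic 4-channel recording with its LoR/RoR annotations."""
    config.validate()
    rng = np.random.default_rng(patient_seed)
    lor, ror = _draw_events(config, rng)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    w = awake_weight(t, lor, ror, config.transition_width_s)

    awake = {}
    anesth = {}
    for lab in REQUIRED_CHANNELS:
        awake[lab] = _ar2(rng, n, config.awake_pole_radius,
                          config.awake_peak_hz, config.fs, config.noise_sd)
        anesth[lab] = _ar2(rng, n, config.anesth_pole_radius,
                           config.anesth_peak_hz, config.fs,
                           config.anesth_gain * config.noise_sd)

    base = {lab: w * awake[lab] + (1.0 - w) * anesth[lab]
            for lab in REQUIRED_CHANNELS}

    # directed frontal -> parietal input, lagged and state-gain weighted
    L = config.coupling_lag_samples
    frontal_mean = 0.5 * (base["Fp1"] + base["Fp2"])
    lagged = np.zeros(n)
    if L > 0:
        lagged[L:] = frontal_mean[:-L]
    else:
        lagged[:] = frontal_mean
    g = w * config.awake_coupling + (1.0 - w) * config.anesth_coupling
    base["P3"] = base["P3"] + g * lagged
    base["P4"] = base["P4"] + g * lagged

    awake_sd = float(np.std(np.stack(list(awake.values()))))
    meas_sd = config.measurement_noise_frac * awake_sd
    samples = np.stack([
        base[lab] + rng.standard_normal(n) * meas_sd for lab in REQUIRED_CHANNELS
    ])

    if patient_id is None:
        patient_id = f"S{patient_seed}"
    rec = EegRecording(channel_labels=list(REQUIRED_CHANNELS), fs=config.fs,
                       samples=samples)
    return rec, EventAnnotations(patient_id=patient_id, lor_s=lor, ror_s=ror)


def generate_cohort(
    config: SimulationConfig,
) -> list[tuple[EegRecording, EventAnnotations]]:
    """n_patients recordings; patient i uses seed ``config.seed + i``."""
    config.validate()
    return [
        generate_recording(config, config.seed + i, patient_id=f"P{i:03d}")
        for i in range(config.n_patients)
    ]
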