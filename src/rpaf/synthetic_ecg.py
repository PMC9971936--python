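"""Seeded synthetic multi-lead ECG generator for AF vs NSR experiments.

The generator is a statistical phantom, not a biophysical model: each beat
is a sum of Gaussian bumps (P, R, S, T) placed at R-peak times drawn from a
truncated log-normal RR-interval distribution.  The two classes differ in
exactly the features a cardiologist uses on a rhythm strip:

* NSR — near-regular RR intervals (small coefficient of variation) and a
  visible P wave before each QRS complex;
* AF — irregular RR intervals (large CV), no P waves, and a continuous
  fibrillatory (f-)wave oscillation whose per-lead amplitude peaks on the
  V1-analog channel, mirroring where f-waves dominate clinically.

Per-lead amplitude vectors make lead informativeness fully plantable, which
is what the lead-selection tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

STANDARD_12_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")
V1_INDEX = 6  # position of V1 in the standard ordering
II_INDEX = 1

LABELS = ("AF", "NSR")


def default_lead_names(n_leads: int) -> tuple[str, ...]:
    if n_leads == 12:
        return STANDARD_12_LEADS
    return tuple(f"L{i + 1}" for i in range(n_leads))


def _peaked_vector(n: int, peak_idx: int, base: float, peak: float, spread: float = 1.5) -> np.ndarray:
    """Amplitude profile: ``base`` everywhere, rising to ``peak`` at one lead."""
    i = np.arange(n, dtype=float)
    return base + (peak - base) * np.exp(-0.5 * ((i - peak_idx) / spread) ** 2)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic ECG phantom.

    Amplitudes are in mV-like units; the defaults give clearly separable but
    noisy classes (R wave ~1, P wave ~0.17 on the II-analog, f-wave ~0.22 on
    the V1-analog, white noise SD 0.05).
    """

    n_leads: int = 12
    fs: float = 500.0
    duration: float = 10.0
    rr_mean_nsr: float = 0.8
    rr_mean_af: float = 0.65
    rr_cv_nsr: float = 0.03
    rr_cv_af: float = 0.25
    f_wave_freq: float = 6.0  # Hz, within the physiological 4-9 band
    f_wave_am_depth: float = 0.5  # waxing/waning of f-wave amplitude (0 = constant)
    f_wave_am_freq: float = 0.5  # Hz, rate of the coarse/fine alternation
    # per-record multiplier range for the whole f-wave (coarse vs fine AF);
    # (1, 1) keeps the amplitude fixed at f_wave_amp_by_lead
    f_wave_amp_scale_range: tuple[float, float] = (1.0, 1.0)
    # Optional AF subtype mixture for planted lead-informativeness fixtures.
    # When set to a fraction p in [0, 1], an AF record is with probability p
    # a "fine-f" subtype (f-wave scaled by f_wave_amp_scale_range[0], RR from
    # the irregular rr_mean_af/rr_cv_af) and otherwise a "coarse-f" subtype
    # (full f-wave amplitude, near-sinus ventricular response using
    # rr_mean_nsr/rr_cv_nsr).  None (default) disables the mixture: every AF
    # record has irregular RR and the configured f-wave scale range.
    af_fine_fraction: Optional[float] = None
    f_wave_amp_by_lead: Optional[tuple[float, ...]] = None
    p_wave_amp_by_lead: Optional[tuple[float, ...]] = None
    qrs_amp_by_lead: Optional[tuple[float, ...]] = None
    t_wave_amp_by_lead: Optional[tuple[float, ...]] = None
    noise_sd: float = 0.05
    v1_index: int = V1_INDEX
    seed: int = 0
    lead_names: Optional[tuple[str, ...]] = None

    # -- resolved per-lead vectors ------------------------------------
    def leads(self) -> tuple[str, ...]:
        return self.lead_names if self.lead_names is not None else default_lead_names(self.n_leads)

    def f_amps(self) -> np.ndarray:
        if self.f_wave_amp_by_lead is not None:
            return np.asarray(self.f_wave_amp_by_lead, dtype=float)
        return _peaked_vector(self.n_leads, self.v1_index, base=0.04, peak=0.22)

    def p_amps(self) -> np.ndarray:
        if self.p_wave_amp_by_lead is not None:
            return np.asarray(self.p_wave_amp_by_lead, dtype=float)
        return _peaked_vector(self.n_leads, II_INDEX, base=0.08, peak=0.17, spread=2.5)

    def qrs_amps(self) -> np.ndarray:
        if self.qrs_amp_by_lead is not None:
            return np.asarray(self.qrs_amp_by_lead, dtype=float)
        return _peaked_vector(self.n_leads, II_INDEX, base=0.8, peak=1.1, spread=4.0)

    def t_amps(self) -> np.ndarray:
        if self.t_wave_amp_by_lead is not None:
            return np.asarray(self.t_wave_amp_by_lead, dtype=float)
        return 0.25 * self.qrs_amps() / self.qrs_amps().max()

    def validate(self) -> None:
        if self.n_leads < 1:
            raise ValueError("n_leads must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.rr_mean_nsr <= 0 or self.rr_mean_af <= 0:
            raise ValueError("RR means must be positive")
        if not (self.rr_cv_af > self.rr_cv_nsr > 0):
            raise ValueError("require rr_cv_af > rr_cv_nsr > 0")
        if not (0 < self.f_wave_freq):
            raise ValueError("f_wave_freq must be positive")
        if not (0 <= self.f_wave_am_depth <= 1) or self.f_wave_am_freq <= 0:
            raise ValueError("f-wave AM depth must lie in [0, 1] with positive AM rate")
        lo, hi = self.f_wave_amp_scale_range
        if not (0 <= lo <= hi):
            raise ValueError("f_wave_amp_scale_range must be 0 <= low <= high")
        if self.af_fine_fraction is not None and not (0 <= self.af_fine_fraction <= 1):
            raise ValueError("af_fine_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.v1_index < self.n_leads):
            raise ValueError("v1_index out of range")
        for name, vec in (
            ("f_wave_amp_by_lead", self.f_amps()),
            ("p_wave_amp_by_lead", self.p_amps()),
            ("qrs_amp_by_lead", self.qrs_amps()),
        ):
            if len(vec) != self.n_leads:
                raise ValueError(f"{name} must have n_leads entries")
            if np.any(vec < 0):
                raise ValueError(f"{name} entries must be >= 0")
        f = self.f_amps()
        if int(np.argmax(f)) != self.v1_index:
            raise ValueError("f-wave amplitude must attain its maximum on the V1-analog lead")

    def with_leads(self, n_leads: int) -> "SynthConfig":
        return replace(self, n_leads=n_leads, lead_names=None)


@dataclass
class EcgRecord:
    """Multi-lead ECG time series with sampling rate and rhythm label."""

    signals: np.ndarray  # (n_leads, n_samples)
    fs: float
    lead_names: tuple[str, ...]
    label: str  # "AF" | "NSR" (or "|"-joined multi-label from external data)
    record_id: str

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a (n_leads, n_samples) matrix")
        if self.signals.shape[0] != len(self.lead_names):
            raise ValueError("lead_names length must match signal rows")

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.signals[self.lead_names.index(name)]
        except ValueError as exc:
            raise KeyError(f"lead {name!r} not in record ({self.lead_names})") from exc

    def label_set(self) -> frozenset[str]:
        return frozenset(part for part in self.label.split("|") if part)


def _truncated_lognormal_rr(rng: np.random.Generator, mean: float, cv: float, count: int) -> np.ndarray:
    # log-normal parameterized so that E[RR]=mean, SD[RR]/E[RR]=cv,
    # truncated to the physiologically plausible [0.3 s, 2.0 s].
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    rr = rng.lognormal(mu, np.sqrt(sigma2), size=count)
    return np.clip(rr, 0.3, 2.0)


def generate_record(cfg: SynthConfig, label: str, seed: Optional[int] = None) -> EcgRecord:
    """Generate one multi-lead record; bit-identical for fixed (cfg, label, seed)."""
    cfg.validate()
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    n = int(round(cfg.fs * cfg.duration))
    t = np.arange(n) / cfg.fs
    is_af = label == "AF"
    # AF subtype draw (planted-fixture mode): fine-f AF keeps the irregular
    # ventricular response, coarse-f AF has a near-sinus one
    fine_af = bool(
        is_af and cfg.af_fine_fraction is not None and rng.random() < cfg.af_fine_fraction
    )
    if not is_af or (cfg.af_fine_fraction is not None and not fine_af):
        rr_mean, rr_cv = cfg.rr_mean_nsr, cfg.rr_cv_nsr
    else:
        rr_mean, rr_cv = cfg.rr_mean_af, cfg.rr_cv_af

    max_beats = int(np.ceil(cfg.duration / 0.3)) + 8
    rr = _truncated_lognormal_rr(rng, rr_mean, rr_cv, max_beats)
    beats = rng.uniform(0.1, 0.4) + np.concatenate([[0.0], np.cumsum(rr)])
    beats = beats[beats < cfg.duration + 0.3]

    qrs = cfg.qrs_amps()
    t_amp = cfg.t_amps()
    p_amp = np.zeros(cfg.n_leads) if is_af else cfg.p_amps()

    sig = np.zeros((cfg.n_leads, n))
    for tb in beats:
        r_bump = np.exp(-0.5 * ((t - tb) / 0.018) ** 2)
        s_dip = -0.25 * np.exp(-0.5 * ((t - tb - 0.045) / 0.016) ** 2)
        t_bump = np.exp(-0.5 * ((t - tb - 0.30) / 0.06) ** 2)
        p_bump = np.exp(-0.5 * ((t - tb + 0.17) / 0.03) ** 2)
        sig += qrs[:, None] * (r_bump + s_dip)[None, :]
        sig += t_amp[:, None] * t_bump[None, :]
        sig += p_amp[:, None] * p_bump[None, :]

    if is_af:
        # continuous fibrillatory wave: frequency-modulated sinusoid whose
        # amplitude waxes and wanes (f-waves alternate between coarse and
        # fine), one phase per record, per-lead amplitude peaking on the V1
        # analog
        phase = rng.uniform(0, 2 * np.pi)
        fm = 0.4 * np.sin(2 * np.pi * 0.35 * t + rng.uniform(0, 2 * np.pi))
        f_wave = np.sin(2 * np.pi * cfg.f_wave_freq * t + fm + phase)
        if cfg.f_wave_am_depth > 0:
            env = 1.0 - cfg.f_wave_am_depth * 0.5 * (
                1.0 + np.sin(2 * np.pi * cfg.f_wave_am_freq * t + rng.uniform(0, 2 * np.pi))
            )
            f_wave = env * f_wave
        lo, hi = cfg.f_wave_amp_scale_range
        if cfg.af_fine_fraction is not None:
            scale = lo if fine_af else hi
        else:
            scale = rng.uniform(lo, hi) if hi > lo else lo
        sig += scale * cfg.f_amps()[:, None] * f_wave[None, :]

    if cfg.noise_sd > 0:
        sig += rng.normal(0.0, cfg.noise_sd, size=sig.shape)

    return EcgRecord(
        signals=sig,
        fs=cfg.fs,
        lead_names=cfg.leads(),
        label=label,
        record_id=f"{label}-seed{seed}",
    )


def child_seed(master: int, index: int) -> int:
    """Deterministic per-record seed derived from a master seed (< 2**31)."""
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0] % (2**31))


def generate_dataset(cfg: SynthConfig, n_per_class: int, seed: Optional[int] = None) -> list[EcgRecord]:
    """Balanced list of AF and NSR records with unique ids.

    Child seeds derive deterministically from the master seed, so datasets
    of any size are reproducible and extendable.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if seed is None:
        seed = cfg.seed
    records = []
    idx = 0
    for i in range(n_per_class):
        for label in LABELS:
            rec = generate_record(cfg, label, seed=child_seed(seed, idx))
            rec.record_id = f"{label}-{i:04d}"
            records.append(rec)
            idx += 1
    return records


def planted_two_lead_config(
    fs: float = 50.0,
    duration: float = 3.2,
    f_wave_amp: float = 0.8,
    noise_sd: float = 0.1,
    af_fine_fraction: float = 0.4,
) -> SynthConfig:
    """Study conditions with lead informativeness planted on exactly two leads.

    Only the V1-analog carries f-waves and only the II-analog carries the
    cardiac waveform (hence clean RR information); every other lead is pure
    noise.  AF records split into two subtypes: coarse-f (prominent V1
    f-waves, near-sinus ventricular response) and fine-f (invisible f-waves,
    highly irregular RR).  Neither planted lead alone can therefore detect
    all AF, while the pair covers the whole population — the ground truth a
    forward stepwise search should recover as {V1, II}, V1 first, since the
    coarse-f subtype is the larger one.
    """
    qrs = [0.0] * 12
    qrs[II_INDEX] = 1.0
    p = [0.0] * 12
    p[II_INDEX] = 0.22
    f = [0.0] * 12
    f[V1_INDEX] = f_wave_amp
    return SynthConfig(
        fs=fs,
        duration=duration,
        f_wave_freq=4.0,
        noise_sd=noise_sd,
        rr_mean_nsr=0.8,
        rr_cv_nsr=0.04,
        rr_mean_af=0.6,
        rr_cv_af=0.35,
        f_wave_amp_scale_range=(0.06, 1.0),
        f_wave_am_depth=0.25,
        af_fine_fraction=af_fine_fraction,
        qrs_amp_by_lead=tuple(qrs),
        p_wave_amp_by_lead=tuple(p),
        f_wave_amp_by_lead=tuple(f),
    )


# -- simple rhythm utilities used for validation and baseline checks ----

def detect_r_peaks(samples: np.ndarray, fs: float) -> np.ndarray:
    """Indices of R peaks: prominent maxima at least 250 ms apart."""
    x = np.asarray(samples, dtype=float)
    height = 0.5 * float(x.max())
    peaks, _ = find_peaks(x, height=height, distance=max(1, int(round(0.25 * fs))))
    return peaks


def rr_interval_cv(samples: np.ndarray, fs: float) -> float:
    """Coefficient of variation of RR intervals from detected R peaks.

    Returns NaN when fewer than three peaks are found.
    """
    peaks = detect_r_peaks(samples, fs)
    if len(peaks) < 3:
        return float("nan")
    rr = np.diff(peaks) / fs
    return float(rr.std() / rr.mean())
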