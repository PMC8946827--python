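"""Physics-based synthetic generator for carotid IPG / cuff-BP trials.

The forward model has three layers:

1. An arterial pressure pulse ``P(t)`` (mmHg) built from a two-Gaussian
   beat template (systolic upstroke + dicrotic wave).  Each beat's maximum
   is exactly the beat's systolic pressure and its minimum the diastolic
   pressure.  The template *shape* (systolic peak timing/width, dicrotic
   notch position and relative amplitude) varies smoothly with SBP and DBP,
   so that pressure information survives per-beat amplitude normalization
   downstream.
2. The Bramwell–Hill coupling between pressure and arterial cross-sectional
   area, ``dP = rho * (D/PTT)^2 * dA/A``.  Treating blood density ``rho``,
   electrode distance ``D`` and pulse transit time ``PTT`` as subject
   constants and integrating gives the closed form
   ``A(P) = A0 * exp((P - P0) * PTT^2 / (rho * D^2))`` (pressures in Pa).
3. Ohm's law for a cylindrical artery segment, ``Z = L / (sigma * A)``,
   mapping area to the measured impedance (ohms).  Impedance therefore
   *decreases* when pressure rises.

On top of the noise-free impedance waveform the generator adds white
measurement noise at a configurable SNR and a sub-0.3 Hz baseline-wander
sinusoid (removed by the downstream band-pass), and emulates the cuff
protocol: ``n_trials`` trials, each holding one noisy cuff (SBP, DBP)
reference and a signal segment containing at least ``beats_per_trial``
beats around the cuff operating time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

MMHG_TO_PA = 133.322

__all__ = [
    "MMHG_TO_PA",
    "HemodynamicParams",
    "SubjectProfile",
    "TrialRecord",
    "SubjectConfig",
    "generate_subject",
    "beat_template",
    "pressure_pulse",
    "pressure_to_impedance",
    "area_from_pressure",
    "pressure_from_area",
    "add_measurement_noise",
    "emulate_protocol",
    "write_subject_dataset",
    "read_subject_dataset",
]


@dataclass(frozen=True)
class HemodynamicParams:
    """Subject constants of the pressure→area→impedance forward model.

    Parameters
    ----------
    rho : float
        Blood density, kg/m^3.
    D : float
        Distance between the two measurement locations, m.
    PTT : float
        Pulse transit time over ``D``, s (so pulse-wave velocity is D/PTT).
    L : float
        Length of the measured arterial segment, m.
    sigma : float
        Blood conductivity, S/m.
    A0 : float
        Arterial cross-sectional area, m^2, at the reference pressure.
    P0 : float
        Reference pressure, mmHg (converted to Pa inside the physics).
    """

    rho: float = 1060.0
    D: float = 0.2
    PTT: float = 0.035
    L: float = 0.02
    sigma: float = 0.6
    A0: float = 3.0e-5
    P0: float = 70.0

    def __post_init__(self) -> None:
        for name in ("rho", "D", "PTT", "L", "sigma", "A0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"hemodynamic parameter {name!r} must be strictly positive")

    @property
    def compliance(self) -> float:
        """PTT^2 / (rho * D^2), the area-compliance exponent per Pa."""
        return self.PTT**2 / (self.rho * self.D**2)

    @property
    def Z0(self) -> float:
        """Impedance at the reference state, L / (sigma * A0), ohms."""
        return self.L / (self.sigma * self.A0)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject simulation parameters."""

    subject_id: str
    baseline_SBP: float
    baseline_DBP: float
    trial_sd: float = 5.0
    heart_rate: float = 1.2
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    noise_snr: float = 20.0
    cuff_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_SBP > self.baseline_DBP:
            raise ValueError("baseline_SBP must exceed baseline_DBP")
        if not (0.67 <= self.heart_rate <= 3.33):
            raise ValueError("heart_rate must lie in the 0.67–3.33 Hz heart-rate band")


@dataclass
class TrialRecord:
    """One protocol trial: cuff reference + an IPG signal segment.

    ``true_SBP``/``true_DBP`` are the latent pressures the beats were built
    from (simulation-only ground truth); ``cuff_SBP``/``cuff_DBP`` add the
    cuff device's measurement noise.  ``beat_anchors`` holds the sample
    indices of the true systolic peaks, for segmentation oracles.
    """

    trial_index: int
    cuff_SBP: float
    cuff_DBP: float
    signal: np.ndarray
    fs: float
    cuff_time: float
    true_SBP: float
    true_DBP: float
    beat_anchors: np.ndarray | None = None


@dataclass(frozen=True)
class SubjectConfig:
    """Sampling ranges for :func:`generate_subject` (uniform draws)."""

    sbp_range: tuple[float, float] = (110.0, 130.0)
    dbp_range: tuple[float, float] = (56.0, 79.0)
    hr_range: tuple[float, float] = (0.9, 1.5)
    trial_sd: float = 5.0
    noise_snr: float = 20.0
    cuff_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("sbp_range", "dbp_range", "hr_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy min < max, got ({lo}, {hi})")
        if self.sbp_range[1] <= self.dbp_range[0]:
            raise ValueError("SBP range upper bound must exceed DBP range lower bound")


def generate_subject(seed: int, config: SubjectConfig | None = None) -> SubjectProfile:
    """Draw a random subject profile, deterministic in ``seed``."""
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    config = config or SubjectConfig()
    rng = np.random.default_rng(seed)
    sbp = rng.uniform(*config.sbp_range)
    dbp = rng.uniform(*config.dbp_range)
    hr = rng.uniform(*config.hr_range)
    return SubjectProfile(
        subject_id=f"S{seed:03d}",
        baseline_SBP=float(sbp),
        baseline_DBP=float(dbp),
        trial_sd=config.trial_sd,
        heart_rate=float(hr),
        noise_snr=config.noise_snr,
        cuff_noise_sd=config.cuff_noise_sd,
        seed=seed,
    )


def beat_template(tau: np.ndarray, sbp: float, dbp: float) -> np.ndarray:
    """Normalized pulse shape g(tau) in [0, 1] over one beat phase tau∈[0,1).

    Two Gaussians model the systolic peak and the dicrotic (reflected) wave.
    Their timing, width and relative amplitude shift smoothly with pressure:
    higher SBP delays and narrows the systolic peak (stiffer artery, later
    shoulder), higher DBP strengthens and delays the dicrotic wave.  These
    couplings are what lets shape-only features carry pressure information.
    """
    s_n = (sbp - 120.0) / 20.0
    d_n = (dbp - 70.0) / 15.0
    mu1 = 0.32 + 0.06 * s_n
    sig1 = 0.11 - 0.02 * np.clip(s_n, -1.5, 1.5)
    mu2 = 0.62 + 0.08 * d_n
    sig2 = 0.12
    r2 = 0.45 + 0.20 * np.clip(d_n, -1.0, 1.0)
    g = np.exp(-0.5 * ((tau - mu1) / sig1) ** 2) + r2 * np.exp(-0.5 * ((tau - mu2) / sig2) ** 2)
    g = g - g.min()
    return g / g.max()


def pressure_pulse(
    profile: SubjectProfile,
    n_beats: int,
    fs: float,
    rng: np.random.Generator | None = None,
    sbp: float | None = None,
    dbp: float | None = None,
    jitter: float = 0.02,
    return_anchors: bool = False,
):
    """Arterial pressure waveform P(t), mmHg, as ``n_beats`` concatenated beats.

    Each beat's maximum equals ``sbp`` and its minimum ``dbp`` exactly (up to
    float rounding).  Beat periods are 1/heart_rate with multiplicative
    Gaussian jitter; ``jitter=0`` makes all beats bit-identical.

    With ``return_anchors=True`` also returns the sample index of each
    beat's systolic peak (simulation ground truth for segmentation tests).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if fs < 50.0:
        raise ValueError("fs must be at least 50 Hz to resolve the pulse template")
    sbp = profile.baseline_SBP if sbp is None else float(sbp)
    dbp = profile.baseline_DBP if dbp is None else float(dbp)
    if sbp <= dbp:
        raise ValueError("systolic pressure must exceed diastolic pressure")
    rng = rng or np.random.default_rng(profile.seed)

    beats = []
    anchors = []
    offset = 0
    for _ in range(n_beats):
        period = (1.0 / profile.heart_rate) * (1.0 + jitter * rng.standard_normal()) if jitter > 0 else 1.0 / profile.heart_rate
        n_samp = max(int(round(period * fs)), 8)
        tau = np.arange(n_samp) / n_samp
        g = beat_template(tau, sbp, dbp)
        beats.append(dbp + (sbp - dbp) * g)
        anchors.append(offset + int(np.argmax(g)))
        offset += n_samp
    P = np.concatenate(beats)
    if return_anchors:
        return P, np.asarray(anchors)
    return P


def area_from_pressure(P_mmhg: np.ndarray, hemo: HemodynamicParams) -> np.ndarray:
    """Closed-form A(P): Bramwell–Hill integrated with constant rho, D, PTT."""
    dP_pa = (np.asarray(P_mmhg, dtype=float) - hemo.P0) * MMHG_TO_PA
    return hemo.A0 * np.exp(dP_pa * hemo.compliance)


def pressure_from_area(A: np.ndarray, hemo: HemodynamicParams) -> np.ndarray:
    """Inverse of :func:`area_from_pressure`; returns pressure in mmHg."""
    return hemo.P0 + np.log(np.asarray(A, dtype=float) / hemo.A0) / (hemo.compliance * MMHG_TO_PA)


def pressure_to_impedance(P: np.ndarray, hemo: HemodynamicParams, P0: float | None = None) -> np.ndarray:
    """Map a pressure waveform (mmHg) to segment impedance Z(t) (ohms).

    ``Z = L / (sigma * A(P))`` with the exponential closed-form area; Z is
    strictly decreasing in P.  ``P0`` optionally overrides the reference
    pressure stored in ``hemo``.
    """
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("pressure waveform must be finite")
    if P0 is not None:
        hemo = HemodynamicParams(hemo.rho, hemo.D, hemo.PTT, hemo.L, hemo.sigma, hemo.A0, P0)
    return hemo.L / (hemo.sigma * area_from_pressure(P, hemo))


def add_measurement_noise(
    Z: np.ndarray,
    snr_db: float,
    rng: np.random.Generator,
    fs: float = 500.0,
    wander_amp_rel: float = 1.0,
    wander_freq: float = 0.15,
) -> np.ndarray:
    """Add white noise at ``snr_db`` (vs the pulsatile AC power) plus baseline wander.

    SNR is defined against the AC component (signal minus its mean) because
    the large DC impedance carries no pulse information.  The wander is a
    sinusoid below the 0.3 Hz band edge with amplitude ``wander_amp_rel``
    times the AC standard deviation; the front-end band-pass removes it.
    ``snr_db=inf`` with ``wander_amp_rel=0`` returns the input unchanged.
    """
    Z = np.asarray(Z, dtype=float)
    if np.isnan(snr_db):
        raise ValueError("snr_db must not be NaN")
    out = Z.copy()
    ac = Z - Z.mean()
    ac_std = float(ac.std())
    if np.isfinite(snr_db):
        noise_std = ac_std * 10.0 ** (-snr_db / 20.0)
        out = out + noise_std * rng.standard_normal(Z.shape)
    if wander_amp_rel > 0:
        t = np.arange(Z.size) / fs
        phase = rng.uniform(0, 2 * np.pi)
        out = out + wander_amp_rel * ac_std * np.sin(2 * np.pi * wander_freq * t + phase)
    return out


def emulate_protocol(
    profile: SubjectProfile,
    n_trials: int = 30,
    beats_per_trial: int = 5,
    fs: float = 500.0,
    extra_beats: int = 4,
    jitter: float = 0.02,
) -> list[TrialRecord]:
    """Emulate the cuff-synchronized acquisition protocol.

    Each trial draws latent true (SBP, DBP) around the subject baseline with
    SD ``trial_sd``, renders ``beats_per_trial + extra_beats`` beats at that
    pressure, converts to impedance, adds measurement noise, and attaches a
    cuff reference equal to the true values plus Gaussian cuff noise.  The
    cuff operating time is the middle of the signal segment, so at least
    ``beats_per_trial`` clean beats surround it.
    """
    if n_trials < 1 or beats_per_trial < 1:
        raise ValueError("n_trials and beats_per_trial must be >= 1")
    rng = np.random.default_rng(profile.seed)
    records: list[TrialRecord] = []
    min_pp = 15.0  # keep a physiological pulse pressure under noisy draws
    for i in range(1, n_trials + 1):
        true_sbp = profile.baseline_SBP + profile.trial_sd * rng.standard_normal()
        true_dbp = profile.baseline_DBP + profile.trial_sd * rng.standard_normal()
        if true_sbp - true_dbp < min_pp:
            true_dbp = true_sbp - min_pp
        P, anchors = pressure_pulse(
            profile, beats_per_trial + extra_beats, fs, rng,
            sbp=true_sbp, dbp=true_dbp, jitter=jitter, return_anchors=True,
        )
        Z = pressure_to_impedance(P, profile.hemo)
        # infinite SNR selects the fully noise-free path (no wander either)
        wander = 0.0 if np.isinf(profile.noise_snr) else 1.0
        sig = add_measurement_noise(Z, profile.noise_snr, rng, fs=fs, wander_amp_rel=wander)
        cuff_sbp = true_sbp + profile.cuff_noise_sd * rng.standard_normal()
        cuff_dbp = true_dbp + profile.cuff_noise_sd * rng.standard_normal()
        records.append(
            TrialRecord(
                trial_index=i,
                cuff_SBP=float(cuff_sbp),
                cuff_DBP=float(cuff_dbp),
                signal=sig,
                fs=fs,
                cuff_time=sig.size / fs / 2.0,
                true_SBP=float(true_sbp),
                true_DBP=float(true_dbp),
                beat_anchors=anchors,
            )
        )
    return records


# ---------------------------------------------------------------------------
# on-disk interface


def write_subject_dataset(outdir: str | Path, profile: SubjectProfile, trials: list[TrialRecord]) -> dict:
    """Write one subject's dataset: signals CSV, references CSV, profile JSON.

    Returns a manifest dict mapping logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = profile.subject_id

    sig_rows = []
    for tr in trials:
        t = np.arange(tr.signal.size) / tr.fs
        sig_rows.append(pd.DataFrame({"trial_index": tr.trial_index, "t": t, "signal": tr.signal}))
    signals_path = outdir / f"{sid}_signals.csv"
    pd.concat(sig_rows, ignore_index=True).to_csv(signals_path, index=False, float_format="%.8g")

    refs_path = outdir / f"{sid}_references.csv"
    pd.DataFrame(
        {
            "trial_index": [tr.trial_index for tr in trials],
            "cuff_SBP": [tr.cuff_SBP for tr in trials],
            "cuff_DBP": [tr.cuff_DBP for tr in trials],
            "cuff_time": [tr.cuff_time for tr in trials],
            "true_SBP": [tr.true_SBP for tr in trials],
            "true_DBP": [tr.true_DBP for tr in trials],
            "fs": [tr.fs for tr in trials],
        }
    ).to_csv(refs_path, index=False, float_format="%.8g")

    profile_path = outdir / f"{sid}_profile.json"
    profile_path.write_text(json.dumps(asdict(profile), indent=2))
    return {"signals": str(signals_path), "references": str(refs_path), "profile": str(profile_path)}


def read_subject_dataset(outdir: str | Path, subject_id: str) -> tuple[SubjectProfile, list[TrialRecord]]:
    """Read back a dataset written by :func:`write_subject_dataset`."""
    outdir = Path(outdir)
    raw = json.loads((outdir / f"{subject_id}_profile.json").read_text())
    raw["hemo"] = HemodynamicParams(**raw["hemo"])
    profile = SubjectProfile(**raw)
    signals = pd.read_csv(outdir / f"{subject_id}_signals.csv")
    refs = pd.read_csv(outdir / f"{subject_id}_references.csv")
    trials = []
    for _, row in refs.iterrows():
        idx = int(row["trial_index"])
        sig = signals.loc[signals["trial_index"] == idx, "signal"].to_numpy()
        trials.append(
            TrialRecord(
                trial_index=idx,
                cuff_SBP=float(row["cuff_SBP"]),
                cuff_DBP=float(row["cuff_DBP"]),
                signal=sig,
                fs=float(row["fs"]),
                cuff_time=float(row["cuff_time"]),
                true_SBP=float(row["true_SBP"]),
                true_DBP=float(row["true_DBP"]),
            )
        )
    return profile, trials
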