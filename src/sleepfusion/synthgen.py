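"""Synthetic PSG cohorts for end-to-end testing without clinical data.

A cohort is simulated in three layers:

* **hypnograms** — first-order Markov chains over Wake/NREM/REM with
  strong self-transitions and a reduced REM self-transition, emulating
  the fragmented, transition-rich nights typical of RBD;
* **EEG** — each 30-s epoch is the sum of a 1/f background and
  band-limited Gaussian components whose amplitudes depend on the stage
  (Wake: alpha-dominant with an occipital emphasis; NREM: delta-dominant
  with central 11–15 Hz spindle bursts; REM: theta-dominant), plus, with
  configurable probability, 20–35 Hz bursts during REM emulating the
  high-frequency contamination caused by lost atonia, and optional
  large-amplitude artifacts;
* **clinical scales** — PSQI/ESS/RBDSQ-like integer scores generated as
  linear functions of each subject's REM% plus Gaussian noise, clipped
  and rounded to the instruments' ranges, with configurable slopes so a
  target rank correlation can be planted (negative for PSQI/RBDSQ, zero
  for ESS by default).

Everything derives deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CANONICAL_CHANNELS, DEFAULT_BANDS, EPOCH_SECONDS, SimConfig
from .io import Hypnogram, Recording

__all__ = [
    "ScaleEffect", "DEFAULT_SCALE_EFFECTS", "SyntheticCohort",
    "simulate_hypnogram", "simulate_epoch", "simulate_recording",
    "simulate_cohort", "simulate_scales", "slope_for_pearson",
    "pearson_for_spearman",
]

_OCCIPITAL = (4, 5)   # O1, O2
_CENTRAL = (2, 3)     # C3, C4


def _validate_transition_matrix(tm: np.ndarray) -> np.ndarray:
    tm = np.asarray(tm, dtype=float)
    if tm.shape != (3, 3) or (tm < 0).any() or not np.allclose(tm.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be 3x3 row-stochastic")
    return tm


def simulate_hypnogram(
    n_epochs: int,
    transition_matrix,
    initial_stage: int = 0,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
) -> Hypnogram:
    """First-order Markov hypnogram over {Wake, NREM, REM}."""
    tm = _validate_transition_matrix(transition_matrix)
    if initial_stage not in (0, 1, 2):
        raise ValueError("initial stage must be 0, 1 or 2")
    rng = rng or np.random.default_rng(0)
    labels = np.empty(n_epochs, dtype=int)
    state = initial_stage
    for i in range(n_epochs):
        labels[i] = state
        state = rng.choice(3, p=tm[state])
    return Hypnogram(subject_id=subject_id, labels=labels)


def stationary_distribution(transition_matrix) -> np.ndarray:
    """Stationary stage frequencies of the chain (left eigenvector)."""
    tm = _validate_transition_matrix(transition_matrix)
    w, v = np.linalg.eig(tm.T)
    idx = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _band_noise(
    rng: np.random.Generator, n: int, rate: float,
    low: float, high: float, rms: float,
) -> np.ndarray:
    """Gaussian noise with power confined to [low, high] Hz, scaled to rms."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= low) & (freqs <= high)
    spec = np.zeros(freqs.size, dtype=complex)
    m = int(mask.sum())
    if m == 0 or rms <= 0:
        return np.zeros(n)
    spec[mask] = rng.normal(size=m) + 1j * rng.normal(size=m)
    x = np.fft.irfft(spec, n=n)
    cur = np.sqrt(np.mean(x * x))
    return x * (rms / cur) if cur > 0 else x


def _pink_noise(
    rng: np.random.Generator, n: int, rate: float, exponent: float, rms: float
) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    x = np.fft.irfft(spec, n=n)
    cur = np.sqrt(np.mean(x * x))
    return x * (rms / cur) if cur > 0 else x


def _burst_envelope(
    rng: np.random.Generator, n: int, rate: float, duration_s: float
) -> np.ndarray:
    """Hann-windowed burst at a random position within the epoch."""
    width = min(int(duration_s * rate), n)
    start = int(rng.integers(0, n - width + 1))
    env = np.zeros(n)
    env[start : start + width] = np.hanning(width)
    return env


def simulate_epoch(
    stage: int, cfg: SimConfig | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """One synthetic 8-channel 30-s epoch for the given stage (microvolts)."""
    cfg = cfg or SimConfig()
    rng = rng or np.random.default_rng(0)
    if stage not in (0, 1, 2):
        raise ValueError(f"unknown stage {stage}")
    rate = cfg.native_rate
    n = int(round(EPOCH_SECONDS * rate))
    amps = cfg.stage_band_amplitudes[stage]
    epoch = np.empty((8, n))
    for ch in range(8):
        x = _pink_noise(rng, n, rate, cfg.background_exponent,
                        cfg.background_amplitude)
        for band, amp in zip(DEFAULT_BANDS, amps):
            gain = 1.0
            if stage == 0 and band.name == "alpha" and ch in _OCCIPITAL:
                gain = cfg.occipital_alpha_gain
            x += _band_noise(rng, n, rate, band.low, band.high, amp * gain)
        epoch[ch] = x

    if stage == 1 and rng.random() < cfg.spindle_prob:
        env = _burst_envelope(rng, n, rate, 1.0)
        for ch in _CENTRAL:
            epoch[ch] += env * _band_noise(rng, n, rate, 11.0, 15.0,
                                           cfg.spindle_amplitude)
    if stage == 2 and rng.random() < cfg.rem_contamination_prob:
        env = _burst_envelope(rng, n, rate, 5.0)
        for ch in range(8):
            epoch[ch] += env * _band_noise(
                rng, n, rate, 20.0, 35.0, cfg.rem_contamination_amplitude
            )
    if cfg.artifact_rate > 0 and rng.random() < cfg.artifact_rate:
        ch = int(rng.integers(0, 8))
        epoch[ch] += cfg.artifact_amplitude * _burst_envelope(rng, n, rate, 2.0)
    return epoch


def simulate_recording(
    subject_id: str,
    hypnogram: Hypnogram,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Full-night recording matching a hypnogram, at the native rate."""
    cfg = cfg or SimConfig()
    rng = rng or np.random.default_rng(0)
    blocks = [simulate_epoch(int(s), cfg, rng) for s in hypnogram.labels]
    signals = np.concatenate(blocks, axis=1)
    return Recording(
        subject_id=subject_id,
        signals=signals,
        rate=cfg.native_rate,
        channel_names=list(CANONICAL_CHANNELS),
    )


@dataclass
class ScaleEffect:
    """Linear-plus-noise generator for one clinical scale.

    score = intercept + slope * (REM% - rem_center) + N(0, noise_sd),
    rounded and clipped to [lo, hi].
    """

    name: str
    intercept: float
    slope: float
    noise_sd: float
    lo: int
    hi: int
    rem_center: float = 13.0


def pearson_for_spearman(rho_s: float) -> float:
    """Latent Pearson r giving Spearman rho_s for bivariate normal data."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def slope_for_pearson(r: float, sd_x: float, noise_sd: float) -> float:
    """Slope planting Pearson correlation r given predictor SD and noise SD."""
    if not -1 < r < 1:
        raise ValueError("r must be in (-1, 1)")
    return r * noise_sd / (sd_x * np.sqrt(1.0 - r * r))


def _default_effects(sd_rem: float = 5.0) -> tuple[ScaleEffect, ...]:
    """PSQI/RBDSQ planted negative (rho ~ -0.5 / -0.45), ESS null."""
    s_psqi = slope_for_pearson(pearson_for_spearman(-0.5), sd_rem, 2.5)
    s_rbdsq = slope_for_pearson(pearson_for_spearman(-0.45), sd_rem, 2.0)
    return (
        ScaleEffect("psqi", 7.0, s_psqi, 2.5, 0, 21),
        ScaleEffect("ess", 7.0, 0.0, 2.5, 0, 24),
        ScaleEffect("rbdsq", 7.0, s_rbdsq, 2.0, 0, 13),
    )


DEFAULT_SCALE_EFFECTS: tuple[ScaleEffect, ...] = _default_effects()


def simulate_scales(
    rem_pcts,
    effects: tuple[ScaleEffect, ...] = DEFAULT_SCALE_EFFECTS,
    rng: np.random.Generator | None = None,
    round_scores: bool = True,
) -> pd.DataFrame:
    """Clinical-scale table with a planted monotone dependence on REM%."""
    rng = rng or np.random.default_rng(0)
    rem = np.asarray(rem_pcts, dtype=float)
    out = {}
    for eff in effects:
        # a night with no sleep has undefined REM%; score at the REM% centre
        rem = np.where(np.isfinite(rem), rem, eff.rem_center)
        raw = (
            eff.intercept
            + eff.slope * (rem - eff.rem_center)
            + rng.normal(0.0, eff.noise_sd, size=rem.size)
        )
        if round_scores:
            raw = np.clip(np.round(raw), eff.lo, eff.hi).astype(int)
        out[eff.name] = raw
    return pd.DataFrame(out)


def simulate_demographics(
    n: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Age/sex/BMI/medication covariates for a cohort of n subjects."""
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(64.8, 8.9, size=n), 40, 90).round(1),
            "sex": rng.binomial(1, 27 / 44, size=n),
            "bmi": np.clip(rng.normal(23.4, 3.1, size=n), 15, 40).round(1),
            "medication": rng.binomial(1, 0.295, size=n),
        }
    )


@dataclass
class SyntheticCohort:
    """Recordings + ground-truth hypnograms + subject-level scale table."""

    recordings: list[Recording]
    hypnograms: list[Hypnogram]
    scales: pd.DataFrame  # indexed by subject_id
    config: SimConfig = field(default_factory=SimConfig)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.recordings]


def simulate_cohort(cfg: SimConfig | None = None) -> SyntheticCohort:
    """Simulate a full cohort deterministically from the master seed."""
    cfg = cfg or SimConfig()
    if cfg.n_subjects < 1:
        raise ValueError("need at least one subject")
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_subjects + 1)
    recordings, hypnograms, rem_pcts = [], [], []
    for i in range(cfg.n_subjects):
        rng = np.random.default_rng(children[i])
        sid = f"sub-{i:03d}"
        hyp = simulate_hypnogram(
            cfg.epochs_per_night, cfg.transition_matrix,
            cfg.initial_stage, rng, subject_id=sid,
        )
        rec = simulate_recording(sid, hyp, cfg, rng)
        n_sleep = int(np.isin(hyp.labels, (1, 2)).sum())
        rem_pcts.append(
            100.0 * (hyp.labels == 2).sum() / n_sleep if n_sleep else np.nan
        )
        recordings.append(rec)
        hypnograms.append(hyp)

    rng_scales = np.random.default_rng(children[-1])
    scales = simulate_scales(np.asarray(rem_pcts), rng=rng_scales)
    demo = simulate_demographics(cfg.n_subjects, rng_scales)
    table = pd.concat([scales, demo], axis=1)
    table.insert(0, "rem_pct_true", rem_pcts)
    table.index = pd.Index([r.subject_id for r in recordings], name="subject_id")
    return SyntheticCohort(
        recordings=recordings, hypnograms=hypnograms, scales=table, config=cfg
    )
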