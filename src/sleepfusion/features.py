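"""Per-epoch handcrafted EEG descriptors (the 65-dimensional vector).

Layout, fixed and versioned (``FEATURE_LAYOUT_VERSION``):

* 8 channels x 8 features = 64, channel-major, per-channel block
  ``[mean, sd, rms, rel_delta, rel_theta, rel_alpha, rel_beta, rel_lowgamma]``
  (mean/sd/rms in microvolts; relative powers dimensionless in [0, 1]);
* 1 global feature: channel-averaged 90% spectral edge frequency (Hz).

Relative band powers are used instead of absolute ones so the vector is
invariant to overall amplitude scaling across recordings; the five bands
partition 0.5–35 Hz, so they sum to one on any non-degenerate epoch.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .config import DEFAULT_BANDS, FeatureConfig, CANONICAL_CHANNELS

__all__ = [
    "FEATURE_LAYOUT_VERSION", "feature_names", "time_stats", "welch_psd",
    "relative_band_powers", "sef90", "extract_features", "extract_feature_matrix",
]

FEATURE_LAYOUT_VERSION = "65:8ch-x-[mean,sd,rms,5relband]+sef90:v1"

_PER_CHANNEL = ("mean", "sd", "rms") + tuple(
    f"rel_{b.name}" for b in DEFAULT_BANDS
)


def feature_names(channels=CANONICAL_CHANNELS) -> list[str]:
    """Column names matching the 65-d layout."""
    names = [f"{ch}_{feat}" for ch in channels for feat in _PER_CHANNEL]
    names.append("sef90_mean")
    return names


def time_stats(x: np.ndarray) -> tuple[float, float, float]:
    """(mean, sample SD, RMS) of one channel-epoch.

    SD uses the n-1 denominator; RMS is sqrt(mean of squares).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for time statistics")
    return (
        float(x.mean()),
        float(x.std(ddof=1)),
        float(np.sqrt(np.mean(x * x))),
    )


def welch_psd(
    x: np.ndarray, rate: float, cfg: FeatureConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of a 30-s channel-epoch.

    4-s Hann segments with 50% overlap by default, giving 0.25 Hz
    resolution — enough to resolve the 0.5 Hz delta edge.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    nperseg = int(round(cfg.welch_seg_seconds * rate))
    if x.shape[-1] != int(round(30 * rate)):
        raise ValueError(
            f"expected a 30-s epoch ({int(round(30 * rate))} samples), got {x.shape[-1]}"
        )
    freqs, psd = sps.welch(
        x,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * cfg.welch_overlap),
        average="mean",
        axis=-1,
    )
    return freqs, psd


def _band_mass(freqs: np.ndarray, psd: np.ndarray, low: float, high: float) -> np.ndarray:
    """Rectangle-rule power mass of psd bins whose centre lies in [low, high)."""
    sel = (freqs >= low) & (freqs < high)
    return psd[..., sel].sum(axis=-1)


def relative_band_powers(
    freqs: np.ndarray,
    psd: np.ndarray,
    cfg: FeatureConfig | None = None,
) -> np.ndarray:
    """Relative power in delta/theta/alpha/beta/low-gamma.

    Each value is the band's bin mass divided by the total mass over the
    analysis band [0.5, 35] Hz (the last band's upper edge is inclusive).
    Degenerate epochs (total below ``power_eps``) return all zeros.
    """
    cfg = cfg or FeatureConfig()
    psd = np.asarray(psd, dtype=float)
    out = []
    for i, band in enumerate(cfg.bands):
        high = band.high + 1e-9 if i == len(cfg.bands) - 1 else band.high
        out.append(_band_mass(freqs, psd, band.low, high))
    out = np.stack(out, axis=-1)
    total = out.sum(axis=-1, keepdims=True)
    safe = total > cfg.power_eps
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(safe, out / np.maximum(total, cfg.power_eps), 0.0)
    return rel


def sef90(
    freqs: np.ndarray,
    psd: np.ndarray,
    cfg: FeatureConfig | None = None,
) -> tuple[float, bool]:
    """90% spectral edge frequency over 0.5–35 Hz.

    Returns ``(frequency_hz, degenerate)``: the smallest PSD grid frequency
    f such that cumulative power in [0.5, f] reaches 90% of the power in
    [0.5, 35].  A degenerate (near-zero-power) spectrum returns the lower
    band edge with the flag set.
    """
    cfg = cfg or FeatureConfig()
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= cfg.total_low) & (freqs <= cfg.total_high)
    f = freqs[sel]
    p = psd[sel]
    total = p.sum()
    if total <= cfg.power_eps:
        return cfg.total_low, True
    cum = np.cumsum(p) / total
    idx = int(np.searchsorted(cum, 0.90 - 1e-12))
    idx = min(idx, f.size - 1)
    return float(f[idx]), False


def extract_features(
    epoch: np.ndarray, rate: float, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """65-d handcrafted vector for one 8-channel 30-s epoch."""
    cfg = cfg or FeatureConfig()
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] != 8:
        raise ValueError(f"expected an (8, samples) epoch, got {epoch.shape}")
    freqs, psd = welch_psd(epoch, rate, cfg)
    rel = relative_band_powers(freqs, psd, cfg)          # (8, 5)
    means = epoch.mean(axis=1)
    sds = epoch.std(axis=1, ddof=1)
    rmss = np.sqrt(np.mean(epoch * epoch, axis=1))
    blocks = np.concatenate(
        [means[:, None], sds[:, None], rmss[:, None], rel], axis=1
    )                                                    # (8, 8)
    edges = np.array([sef90(freqs, psd[ch], cfg)[0] for ch in range(8)])
    return np.concatenate([blocks.reshape(-1), [edges.mean()]])


def extract_feature_matrix(
    epochs: np.ndarray, rate: float, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """Vectorised feature extraction for an (n_epochs, 8, samples) array."""
    cfg = cfg or FeatureConfig()
    epochs = np.asarray(epochs, dtype=float)
    n = epochs.shape[0]
    if n == 0:
        return np.zeros((0, 65))
    freqs, psd = welch_psd(epochs, rate, cfg)            # psd: (n, 8, nf)
    rel = relative_band_powers(freqs, psd, cfg)          # (n, 8, 5)
    means = epochs.mean(axis=2)
    sds = epochs.std(axis=2, ddof=1)
    rmss = np.sqrt(np.mean(epochs * epochs, axis=2))
    blocks = np.concatenate(
        [means[..., None], sds[..., None], rmss[..., None], rel], axis=2
    )                                                    # (n, 8, 8)
    edges = np.empty((n, 8))
    for i in range(n):
        for ch in range(8):
            edges[i, ch] = sef90(freqs, psd[i, ch], cfg)[0]
    return np.concatenate([blocks.reshape(n, -1), edges.mean(axis=1)[:, None]], axis=1)
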