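"""Time–frequency input for the 2D stream.

Each channel of a 30-s epoch is turned into a log-power STFT spectrogram
restricted to 0.5–35 Hz, bilinearly resized to a 32 x 32 grid, z-normalised
per channel, and stacked into an (8, 32, 32) tensor.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .config import SpectrogramConfig

__all__ = ["stft_spectrogram", "resize_grid", "build_spectrogram_tensor"]


def stft_spectrogram(
    x: np.ndarray, rate: float, cfg: SpectrogramConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-power STFT of one channel-epoch.

    Returns ``(freqs, times, logpower)`` with rows restricted to
    [0.5, 35] Hz and values ``log10(|STFT|^2 + eps)``.
    """
    cfg = cfg or SpectrogramConfig()
    x = np.asarray(x, dtype=float)
    if cfg.window > x.shape[-1]:
        raise ValueError(
            f"STFT window ({cfg.window}) longer than the epoch ({x.shape[-1]})"
        )
    freqs, times, Z = sps.stft(
        x,
        fs=rate,
        window="hann",
        nperseg=cfg.window,
        noverlap=cfg.window - cfg.hop,
        boundary=None,
        padded=False,
    )
    power = np.abs(Z) ** 2
    sel = (freqs >= cfg.freq_low) & (freqs <= cfg.freq_high)
    return freqs[sel], times, np.log10(power[..., sel, :] + cfg.eps)


def resize_grid(m: np.ndarray, side: int = 32) -> np.ndarray:
    """Bilinear resize of a 2-D matrix to (side, side).

    Sample positions follow the align-corners convention, so a constant
    matrix stays constant and outputs never leave [min(m), max(m)].
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    h, w = m.shape
    if (h, w) == (side, side):
        return m.copy()

    def axis_coords(n_in: int, n_out: int) -> np.ndarray:
        if n_in == 1:
            return np.zeros(n_out)
        return np.linspace(0.0, n_in - 1.0, n_out)

    rows = axis_coords(h, side)
    cols = axis_coords(w, side)
    r0 = np.clip(np.floor(rows).astype(int), 0, h - 1)
    c0 = np.clip(np.floor(cols).astype(int), 0, w - 1)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    top = m[np.ix_(r0, c0)] * (1 - fc) + m[np.ix_(r0, c1)] * fc
    bot = m[np.ix_(r1, c0)] * (1 - fc) + m[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr


def build_spectrogram_tensor(
    epoch: np.ndarray, rate: float = 100.0, cfg: SpectrogramConfig | None = None
) -> np.ndarray:
    """(8, 32, 32) z-normalised spectrogram tensor for one epoch.

    Normalisation is per channel over the resized grid (mean 0, SD 1,
    eps-guarded), which also removes the additive log-shift induced by any
    overall amplitude scaling of the raw signal.
    """
    cfg = cfg or SpectrogramConfig()
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] != 8:
        raise ValueError(f"expected an (8, samples) epoch, got {epoch.shape}")
    _, _, logp = stft_spectrogram(epoch, rate, cfg)   # (8, n_freq, n_time)
    out = np.empty((8, cfg.side, cfg.side))
    for ch in range(8):
        grid = resize_grid(logp[ch], cfg.side)
        mu = grid.mean()
        sd = grid.std()
        out[ch] = (grid - mu) / sd if sd > 1e-12 else np.zeros_like(grid)
    return out
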