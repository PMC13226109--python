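"""Recording / hypnogram containers and on-disk formats.

Signals travel as EDF (read through :mod:`mne`, written by the minimal
writer in :func:`write_edf`); per-epoch stage labels travel as a
single-column CSV of integers with an optional ``stage`` header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import CANONICAL_CHANNELS, EPOCH_SECONDS

__all__ = [
    "Recording", "Hypnogram", "EpochArray", "FormatError",
    "read_edf", "write_edf", "select_montage", "epoch_signals",
    "read_hypnogram", "write_hypnogram",
]


class FormatError(ValueError):
    """Raised for malformed on-disk signal or label files."""


@dataclass
class Recording:
    """Multichannel EEG block in microvolts.

    signals has shape (n_channels, n_samples); channel_names matches the
    row order.
    """

    subject_id: str
    signals: np.ndarray
    rate: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows vs "
                f"{len(self.channel_names)} channel names"
            )
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Seconds of signal."""
        return self.n_samples / self.rate


@dataclass
class Hypnogram:
    """Per-30-s-epoch stage labels: 0 = Wake, 1 = NREM, 2 = REM."""

    subject_id: str
    labels: np.ndarray
    epoch_length: float = float(EPOCH_SECONDS)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D sequence")
        bad = np.where(~np.isin(self.labels, (0, 1, 2)))[0]
        if bad.size:
            raise ValueError(
                f"invalid stage label {self.labels[bad[0]]} at epoch {bad[0]}"
            )

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class EpochArray:
    """Signals cut into 30-s epochs: (n_epochs, n_channels, samples_per_epoch)."""

    subject_id: str
    data: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        expected = int(round(EPOCH_SECONDS * self.rate))
        if self.data.shape[0] and self.data.shape[2] != expected:
            raise ValueError(
                f"samples per epoch {self.data.shape[2]} != 30 s x rate = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def _check_edf_header(path: Path) -> None:
    """Reject empty, truncated or mixed-rate EDF files up front.

    mne silently upsamples mixed-rate channels, but the staging pipeline
    requires one native rate, so a mixed-rate file is a format error here.
    """
    blob = path.read_bytes()
    if len(blob) < 256:
        raise FormatError(f"{path}: empty or truncated EDF header")
    try:
        n_sig = int(blob[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header") from exc
    if n_sig < 1 or len(blob) < 256 * (1 + n_sig):
        raise FormatError(f"{path}: malformed EDF header (n_signals={n_sig})")
    sig_hdr = blob[256 : 256 * (1 + n_sig)]
    labels = [
        sig_hdr[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(n_sig)
    ]
    spr_off = n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [
        int(sig_hdr[spr_off + 8 * i : spr_off + 8 * (i + 1)].decode().strip())
        for i in range(n_sig)
    ]
    kept = [(lab, s) for lab, s in zip(labels, spr)
            if not lab.lower().startswith("edf annotations")]
    if kept and len({s for _, s in kept}) > 1:
        ref = kept[0][1]
        bad = next(lab for lab, s in kept if s != ref)
        raise FormatError(
            f"{path}: channels have differing sampling rates "
            f"(e.g. {bad!r} vs {kept[0][0]!r})"
        )


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a Recording (microvolts, native rate)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_edf_header(path)
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        subject_id=path.stem,
        signals=np.ascontiguousarray(data),
        rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a Recording as plain 16-bit EDF.

    One data record per second; requires an integer sampling rate.  Scaling
    uses a symmetric physical range per channel so the quantisation step is
    range/65535 (< 0.02 µV for typical EEG).
    """
    path = Path(path)
    rate = int(round(rec.rate))
    if abs(rate - rec.rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // rate
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    sig = rec.signals[:, : n_records * rate]
    n_sig = rec.n_channels

    phys_max = np.maximum(np.abs(sig).max(axis=1) * 1.001, 1.0)
    # round to the 8-char header representation first so the encoder and the
    # header state exactly the same physical range
    phys_max = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    # EDF affine convention: phys = (dig - dig_min) * range_p / range_d + phys_min
    slope = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.clip(
        np.round((sig - phys_min[:, None]) / slope[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad(rec.subject_id, 80),
            pad("sleepfusion synthetic", 80),
            pad("01.01.25", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_sig)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_sig), 4),
        ]
    )
    fields = [
        b"".join(pad(name, 16) for name in rec.channel_names),
        b"".join(pad("", 80) for _ in range(n_sig)),
        b"".join(pad("uV", 8) for _ in range(n_sig)),
        b"".join(pad(f"{m:.6g}"[:8], 8) for m in phys_min),
        b"".join(pad(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(pad(str(dig_min), 8) for _ in range(n_sig)),
        b"".join(pad(str(dig_max), 8) for _ in range(n_sig)),
        b"".join(pad("", 80) for _ in range(n_sig)),
        b"".join(pad(str(rate), 8) for _ in range(n_sig)),
        b"".join(pad("", 32) for _ in range(n_sig)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for blob in fields:
            fh.write(blob)
        for rec_i in range(n_records):
            chunk = digital[:, rec_i * rate : (rec_i + 1) * rate]
            fh.write(chunk.tobytes())


def select_montage(
    rec: Recording,
    wanted: list[str] | tuple[str, ...] = CANONICAL_CHANNELS,
    strip_reference: bool = True,
) -> Recording:
    """Select and reorder channels to the canonical clinical montage.

    Matching is case-insensitive; with ``strip_reference`` labels such as
    ``"EEG Fp1-A2"`` match ``"Fp1"`` (common EDF label dialects).
    """

    def keys(label: str) -> list[str]:
        out = [label.lower()]
        cleaned = label.lower().removeprefix("eeg").strip(" :")
        out.append(cleaned)
        if strip_reference and "-" in cleaned:
            out.append(cleaned.split("-")[0].strip())
        return out

    lookup: dict[str, int] = {}
    for idx, name in enumerate(rec.channel_names):
        for key in keys(name):
            lookup.setdefault(key, idx)

    rows, missing = [], []
    for want in wanted:
        idx = lookup.get(want.lower())
        if idx is None:
            missing.append(want)
        else:
            rows.append(idx)
    if missing:
        raise KeyError(f"channels absent from recording: {', '.join(missing)}")
    return Recording(
        subject_id=rec.subject_id,
        signals=rec.signals[rows],
        rate=rec.rate,
        channel_names=list(wanted),
    )


def epoch_signals(rec: Recording) -> EpochArray:
    """Cut a recording into consecutive 30-s epochs.

    Epoch k covers samples [k*30*rate, (k+1)*30*rate); a trailing partial
    window is discarded.  A recording shorter than 30 s yields zero epochs.
    """
    spe = EPOCH_SECONDS * rec.rate
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError(f"rate {rec.rate} Hz does not give integer 30-s epochs")
    spe = int(round(spe))
    n_epochs = rec.n_samples // spe
    data = rec.signals[:, : n_epochs * spe]
    data = data.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochArray(subject_id=rec.subject_id, data=np.ascontiguousarray(data),
                      rate=rec.rate)


def read_hypnogram(path: str | Path, subject_id: str | None = None) -> Hypnogram:
    """Read a single-column CSV of stage labels (optional ``stage`` header)."""
    path = Path(path)
    rows = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if rows and not rows[0].lstrip("-").isdigit():
        rows = rows[1:]  # header
    labels = []
    for i, row in enumerate(rows):
        try:
            value = int(row)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer label {row!r} at row {i}") from exc
        if value not in (0, 1, 2):
            raise FormatError(f"{path}: invalid stage label {value} at row {i}")
        labels.append(value)
    if not labels:
        raise FormatError(f"{path}: empty hypnogram")
    return Hypnogram(subject_id=subject_id or path.stem, labels=np.array(labels))


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    path = Path(path)
    path.write_text("stage\n" + "\n".join(str(int(v)) for v in h.labels) + "\n")
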