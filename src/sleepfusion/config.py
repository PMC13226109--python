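"""Configuration dataclasses for the staging pipeline.

Every tunable of the pipeline lives here so that a single YAML file can
reproduce a run end to end.  Defaults are the values the package was
developed and validated with; they are documented in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Canonical clinical EEG montage, in the fixed order used by every tensor
#: in the pipeline: prefrontal, central, occipital and mastoid pairs.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "C3", "C4", "O1", "O2", "A1", "A2",
)

#: Scoring-epoch duration in seconds (standard 30-s sleep scoring window).
EPOCH_SECONDS: int = 30

#: Stage codes: 0 = Wake, 1 = NREM, 2 = REM.
STAGE_NAMES: tuple[str, ...] = ("Wake", "NREM", "REM")


@dataclass
class PreprocessConfig:
    """Signal-conditioning parameters.

    The chain is band-pass filter -> wavelet denoise -> resample to the
    model rate -> epoch -> artifact QC, always in that order.
    """

    band_low: float = 0.5          # Hz, high-pass edge (removes drift)
    band_high: float = 35.0        # Hz, low-pass edge (removes EMG/line noise)
    filter_order: int = 4          # Butterworth order, applied forward-backward
    model_rate: float = 100.0      # Hz, rate the network consumes
    wavelet: str = "db4"
    dwt_level: int = 5
    amplitude_limit: float = 500.0         # µV, per-sample absolute limit
    flatline_variance_floor: float = 0.01  # µV², below this a channel is dead
    spectral_ratio_limit: float = 0.5      # power(>35 Hz) / power(0.5–35 Hz)
    artifact_action: str = "remove"        # only "remove" is implemented

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.model_rate / 2):
            raise ValueError(
                "require 0 < band_low < band_high < model_rate/2, got "
                f"{self.band_low}, {self.band_high}, {self.model_rate}"
            )
        if self.artifact_action not in ("remove",):
            raise ValueError(f"unsupported artifact_action {self.artifact_action!r}")


@dataclass
class BandDefinition:
    name: str
    low: float
    high: float


#: Canonical EEG bands partitioning [0.5, 35] Hz.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("lowgamma", 30.0, 35.0),
)


@dataclass
class FeatureConfig:
    """Handcrafted-feature parameters (Welch PSD and band layout)."""

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    welch_seg_seconds: float = 4.0   # Hann segments; 0.25 Hz resolution
    welch_overlap: float = 0.5
    total_low: float = 0.5           # Hz, analysis band lower edge
    total_high: float = 35.0         # Hz, analysis band upper edge
    power_eps: float = 1e-12         # µV², degenerate-epoch guard

    def __post_init__(self) -> None:
        lows = [b.low for b in self.bands]
        highs = [b.high for b in self.bands]
        if lows[0] != self.total_low or highs[-1] != self.total_high:
            raise ValueError("bands must span the full analysis band")
        for h, l in zip(highs[:-1], lows[1:]):
            if h != l:
                raise ValueError("bands must partition the analysis band")


@dataclass
class SpectrogramConfig:
    """STFT / resize parameters for the 2D stream input."""

    window: int = 128       # samples (1.28 s at 100 Hz), Hann
    hop: int = 32           # samples
    eps: float = 1e-10      # log-compression floor
    side: int = 32          # output grid size
    freq_low: float = 0.5   # Hz, rows kept
    freq_high: float = 35.0


@dataclass
class ModelConfig:
    """Architecture and optimisation settings for the fusion network.

    The dimension chain 64 (1D stream) + 64 (2D stream) + 65 (handcrafted)
    = 193 is asserted at model construction.
    """

    # 1D stream: three conv blocks (out_channels, kernel, stride, pool)
    conv1d_blocks: tuple = ((32, 7, 3, 4), (64, 5, 1, 4), (64, 3, 1, 4))
    # 2D stream: three conv blocks (out_channels, kernel, pool)
    conv2d_blocks: tuple = ((16, 3, 2), (32, 3, 2), (64, 3, 2))
    embed_1d: int = 64
    embed_2d: int = 64
    handcrafted_dim: int = 65
    gate_hidden: int = 96
    classifier_widths: tuple = (128, 64)
    dropout: tuple = (0.5, 0.3)
    n_classes: int = 3
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 30
    scheduler_factor: float = 0.5
    scheduler_patience: int = 2
    early_stop_patience: int = 4
    val_fraction: float = 0.2   # subject-wise inner validation split
    seed: int = 0

    @property
    def fused_dim(self) -> int:
        return self.embed_1d + self.embed_2d + self.handcrafted_dim

    def __post_init__(self) -> None:
        if self.fused_dim != 193:
            raise ValueError(
                f"fused dimension must be 193, got {self.fused_dim}"
            )


@dataclass
class SimConfig:
    """Synthetic-cohort parameters.

    Defaults emulate a fragmented RBD-like night: strong stage
    self-transitions with a reduced REM self-transition, stage-dependent
    band-amplitude profiles, occasional REM high-frequency contamination
    (the loss-of-atonia analogue) and rare large-amplitude artifacts.
    """

    n_subjects: int = 10
    epochs_per_night: int = 240
    transition_matrix: tuple = (
        (0.90, 0.09, 0.01),
        (0.04, 0.91, 0.05),
        (0.07, 0.08, 0.85),
    )
    initial_stage: int = 0
    native_rate: float = 100.0       # Hz; synthesis happens at the model rate
    background_exponent: float = 1.0  # 1/f^alpha background
    background_amplitude: float = 10.0  # µV RMS of broadband background
    # per-stage band RMS amplitudes in µV: (delta, theta, alpha, beta, lowgamma)
    stage_band_amplitudes: tuple = (
        (6.0, 5.0, 22.0, 8.0, 2.0),   # Wake: alpha-dominant
        (40.0, 10.0, 5.0, 3.0, 1.0),  # NREM: delta-dominant (+ spindles)
        (8.0, 20.0, 6.0, 5.0, 2.0),   # REM: theta-dominant
    )
    occipital_alpha_gain: float = 2.5   # Wake alpha boost on O1/O2
    spindle_amplitude: float = 12.0     # µV, 11–15 Hz bursts on C3/C4 in NREM
    spindle_prob: float = 0.7
    rem_contamination_prob: float = 0.3
    rem_contamination_amplitude: float = 10.0   # µV, 20–35 Hz bursts
    artifact_rate: float = 0.0          # per-epoch probability of an artifact
    artifact_amplitude: float = 2000.0  # µV
    seed: int = 0


@dataclass
class RunConfig:
    """Top-level run configuration (paths + per-stage sections)."""

    data_dir: str = "data"
    output_dir: str = "output"
    checkpoint: str = "checkpoint.npz"
    seed: int = 0
    folds: int = 5
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    sim: SimConfig = field(default_factory=SimConfig)


def _build(cls, data: dict, warn: list[str], prefix: str = ""):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            warn.append(prefix + key)
            continue
        f = fields[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "preprocess", "features", "spectrogram", "model", "sim",
        ):
            sub = {
                "preprocess": PreprocessConfig,
                "features": FeatureConfig,
                "spectrogram": SpectrogramConfig,
                "model": ModelConfig,
                "sim": SimConfig,
            }[f.name]
            kwargs[key] = _build(sub, value or {}, warn, prefix=f"{key}.")
        elif f.name == "bands" and isinstance(value, list):
            kwargs[key] = tuple(
                BandDefinition(**v) if isinstance(v, dict) else BandDefinition(*v)
                for v in value
            )
        elif isinstance(value, list):
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in value
            )
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[RunConfig, list[str]]:
    """Load a RunConfig from YAML.

    Returns the config together with a list of unknown keys encountered
    (callers warn about them rather than failing).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    warn: list[str] = []
    cfg = _build(RunConfig, data, warn)
    return cfg, warn


def config_to_dict(cfg) -> dict:
    """Dataclass tree -> plain dict (for logging / manifests)."""
    return dataclasses.asdict(cfg)
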