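"""The multi-stream gated-fusion sleep stager and its training loop.

Three parallel streams encode each 30-s epoch:

* a 1D CNN over the raw 8 x 3000 waveform -> 64-d embedding,
* a 2D CNN over the 8 x 32 x 32 spectrogram tensor -> 64-d embedding,
* the 65-d handcrafted feature vector (z-scored with statistics from the
  development folds only).

The 193-d concatenation is reweighted feature-wise by a sigmoid gate
(two-layer MLP) and classified by three dense layers with dropout into
Wake/NREM/REM probabilities.  Training uses class-weighted cross-entropy,
Adam, a reduce-on-plateau schedule and early stopping on an inner
subject-wise validation split; evaluation uses patient-wise k-fold
cross-validation with pooled out-of-fold predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score

from . import nn
from .config import FeatureConfig, ModelConfig, PreprocessConfig, SpectrogramConfig
from .features import extract_feature_matrix
from .io import EpochArray, Hypnogram, Recording
from .preprocess import preprocess_recording
from .spectrogram import build_spectrogram_tensor

__all__ = [
    "StagePrediction", "FoldAssignment", "EpochInputs", "MultiStreamSleepStager",
    "FittedModel", "class_weights", "build_inputs", "train", "patientwise_cv",
    "predict_recording",
]


@dataclass
class StagePrediction:
    """Per-epoch stage probabilities and argmax labels.

    Probabilities lie on the 3-simplex; ties in the argmax resolve to the
    lowest class index (Wake < NREM < REM).
    """

    probabilities: np.ndarray  # (n_epochs, 3)
    labels: np.ndarray         # (n_epochs,)

    @classmethod
    def from_probabilities(cls, probs: np.ndarray) -> "StagePrediction":
        probs = np.asarray(probs, dtype=float)
        return cls(probabilities=probs, labels=probs.argmax(axis=1))


@dataclass
class FoldAssignment:
    """Subject -> test-fold mapping plus per-fold subject lists."""

    fold_of: dict[str, int]
    dev_subjects: list[list[str]]
    val_subjects: list[list[str]]
    test_subjects: list[list[str]]

    def validate(self) -> None:
        seen: dict[str, int] = {}
        for k, test in enumerate(self.test_subjects):
            for s in test:
                if s in seen:
                    raise AssertionError(f"subject {s} tested in folds {seen[s]} and {k}")
                seen[s] = k
            overlap = set(self.dev_subjects[k]) & set(test)
            if overlap:
                raise AssertionError(f"leakage in fold {k}: {sorted(overlap)}")
            if not set(self.val_subjects[k]) <= set(self.dev_subjects[k]):
                raise AssertionError(f"fold {k}: validation subjects outside development")


@dataclass
class EpochInputs:
    """Model-ready triplet for a block of epochs."""

    raw: np.ndarray   # (n, 8, 3000) per-epoch/channel standardized waveform
    spec: np.ndarray  # (n, 8, 32, 32)
    feat: np.ndarray  # (n, 65) unscaled handcrafted features

    def __len__(self) -> int:
        return self.raw.shape[0]


def build_inputs(
    epochs: EpochArray,
    feat_cfg: FeatureConfig | None = None,
    spec_cfg: SpectrogramConfig | None = None,
) -> EpochInputs:
    """Prepare the three per-epoch representations from conditioned epochs."""
    data = epochs.data
    mu = data.mean(axis=2, keepdims=True)
    sd = data.std(axis=2, keepdims=True)
    raw = (data - mu) / np.maximum(sd, 1e-12)
    spec = np.stack(
        [build_spectrogram_tensor(e, epochs.rate, spec_cfg) for e in data]
    ) if len(data) else np.zeros((0, 8, 32, 32))
    feat = extract_feature_matrix(data, epochs.rate, feat_cfg)
    return EpochInputs(raw=raw, spec=spec, feat=feat)


class _FusionGate(nn.Module):
    """Feature-wise sigmoid gating: out = sigmoid(MLP2(z)) * z."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator) -> None:
        self.net = nn.Sequential(
            nn.Dense(dim, hidden, rng), nn.ReLU(),
            nn.Dense(hidden, dim, rng), nn.Sigmoid(),
        )

    def params(self):
        return self.net.params()

    def forward(self, z, train=False):
        self._z = z
        self._g = self.net.forward(z, train=train)
        return self._g * z

    def backward(self, dy):
        dz_gate = self.net.backward(dy * self._z)
        return dy * self._g + dz_gate

    @property
    def last_gate(self) -> np.ndarray:
        return self._g


class MultiStreamSleepStager:
    """The full three-stream network (numpy implementation)."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int | None = None) -> None:
        self.cfg = cfg or ModelConfig()
        if self.cfg.fused_dim != 193:
            raise ValueError("fused dimension must equal 64 + 64 + 65 = 193")
        rng = np.random.default_rng(self.cfg.seed if seed is None else seed)

        layers1 = []
        cin = 8
        for cout, kernel, stride, pool in self.cfg.conv1d_blocks:
            layers1 += [
                nn.Conv1d(cin, cout, kernel, stride, rng),
                nn.BatchNorm(cout), nn.ReLU(), nn.MaxPool1d(pool),
            ]
            cin = cout
        if cin != self.cfg.embed_1d:
            raise ValueError("last 1D block must output embed_1d channels")
        layers1.append(nn.GlobalAvgPool())
        self.stream1d = nn.Sequential(*layers1)

        layers2 = []
        cin = 8
        for cout, kernel, pool in self.cfg.conv2d_blocks:
            layers2 += [
                nn.Conv2d(cin, cout, kernel, rng),
                nn.BatchNorm(cout), nn.ReLU(), nn.MaxPool2d(pool),
            ]
            cin = cout
        if cin != self.cfg.embed_2d:
            raise ValueError("last 2D block must output embed_2d channels")
        layers2.append(nn.GlobalAvgPool())
        self.stream2d = nn.Sequential(*layers2)

        self.gate = _FusionGate(self.cfg.fused_dim, self.cfg.gate_hidden, rng)

        clf = []
        din = self.cfg.fused_dim
        for width, drop in zip(self.cfg.classifier_widths, self.cfg.dropout):
            clf += [nn.Dense(din, width, rng), nn.ReLU(), nn.Dropout(drop, rng)]
            din = width
        clf.append(nn.Dense(din, self.cfg.n_classes, rng))
        self.classifier = nn.Sequential(*clf)

        self._parts = {
            "stream1d": self.stream1d, "stream2d": self.stream2d,
            "gate": self.gate.net, "classifier": self.classifier,
        }

    # ---- stream-level API -------------------------------------------------
    def forward_1d(self, raw: np.ndarray, train: bool = False) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        single = raw.ndim == 2
        if single:
            raw = raw[None]
        if raw.shape[1:] != (8, 3000):
            raise ValueError(f"expected (*, 8, 3000) raw input, got {raw.shape}")
        out = self.stream1d.forward(raw, train=train)
        return out[0] if single else out

    def forward_2d(self, spec: np.ndarray, train: bool = False) -> np.ndarray:
        spec = np.asarray(spec, dtype=float)
        single = spec.ndim == 3
        if single:
            spec = spec[None]
        if spec.shape[1:] != (8, 32, 32):
            raise ValueError(f"expected (*, 8, 32, 32) spectrogram input, got {spec.shape}")
        out = self.stream2d.forward(spec, train=train)
        return out[0] if single else out

    def fuse(self, e1: np.ndarray, e2: np.ndarray, h: np.ndarray,
             train: bool = False) -> np.ndarray:
        single = np.asarray(e1).ndim == 1
        e1, e2, h = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (e1, e2, h))
        if e1.shape[1] != 64 or e2.shape[1] != 64 or h.shape[1] != 65:
            raise ValueError(
                f"fusion dims must be 64/64/65, got {e1.shape[1]}/{e2.shape[1]}/{h.shape[1]}"
            )
        z = np.concatenate([e1, e2, h], axis=1)
        out = self.gate.forward(z, train=train)
        return out[0] if single else out

    def classify(self, fused: np.ndarray, train: bool = False) -> StagePrediction:
        fused = np.atleast_2d(np.asarray(fused, dtype=float))
        if fused.shape[1] != self.cfg.fused_dim:
            raise ValueError(f"expected {self.cfg.fused_dim}-d fused input")
        logits = self.classifier.forward(fused, train=train)
        return StagePrediction.from_probabilities(nn.softmax(logits))

    # ---- end-to-end -------------------------------------------------------
    def forward(self, raw, spec, feat, train: bool = False) -> np.ndarray:
        """Logits for a batch; caches activations for :meth:`backward`."""
        e1 = self.stream1d.forward(np.asarray(raw, dtype=float), train=train)
        e2 = self.stream2d.forward(np.asarray(spec, dtype=float), train=train)
        z = np.concatenate([e1, e2, np.asarray(feat, dtype=float)], axis=1)
        fused = self.gate.forward(z, train=train)
        return self.classifier.forward(fused, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.classifier.backward(dlogits)
        dz = self.gate.backward(dfused)
        self.stream1d.backward(dz[:, :64])
        self.stream2d.backward(dz[:, 64:128])
        # the handcrafted slice is an input, not a module: gradient stops here

    def params(self) -> list[nn.Param]:
        return (
            self.stream1d.params() + self.stream2d.params()
            + self.gate.params() + self.classifier.params()
        )

    def predict_proba(self, inputs: EpochInputs, feat_mean, feat_sd,
                      batch: int = 256) -> np.ndarray:
        feat = (inputs.feat - feat_mean) / feat_sd
        out = []
        for i in range(0, len(inputs), batch):
            logits = self.forward(
                inputs.raw[i : i + batch], inputs.spec[i : i + batch],
                feat[i : i + batch], train=False,
            )
            out.append(nn.softmax(logits))
        return np.concatenate(out) if out else np.zeros((0, 3))

    # ---- checkpointing ----------------------------------------------------
    def get_state(self) -> dict:
        state = {}
        for name, part in self._parts.items():
            for i, p in enumerate(part.params()):
                state[f"{name}.p{i}"] = p.value.copy()
            for key, extra in part.state_extra().items():
                for ek, ev in extra.items():
                    state[f"{name}.x{key}.{ek}"] = np.asarray(ev).copy()
        return state

    def set_state(self, state: dict) -> None:
        for name, part in self._parts.items():
            for i, p in enumerate(part.params()):
                p.value[...] = state[f"{name}.p{i}"]
            extras = {}
            for full, value in state.items():
                if full.startswith(f"{name}.x"):
                    key, ek = full[len(name) + 2 :].split(".", 1)
                    extras.setdefault(key, {})[ek] = value
            part.load_extra(extras)


def class_weights(label_counts) -> np.ndarray:
    """Inverse-frequency weights w_c = N_total / (3 * N_c)."""
    counts = np.asarray(label_counts, dtype=float)
    if counts.shape != (3,):
        raise ValueError("expected three class counts")
    if (counts <= 0).any():
        missing = int(np.where(counts <= 0)[0][0])
        raise ValueError(f"class {missing} absent from the development data")
    return counts.sum() / (3.0 * counts)


@dataclass
class FittedModel:
    """A trained network plus the normalisation statistics it requires."""

    network: MultiStreamSleepStager
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    history: list[dict] = field(default_factory=list)

    def predict(self, inputs: EpochInputs) -> StagePrediction:
        probs = self.network.predict_proba(inputs, self.feat_mean, self.feat_sd)
        return StagePrediction.from_probabilities(probs)

    def save(self, path) -> None:
        state = self.network.get_state()
        state["__feat_mean"] = self.feat_mean
        state["__feat_sd"] = self.feat_sd
        state["__config"] = np.frombuffer(
            json.dumps(_config_dict(self.network.cfg)).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "FittedModel":
        blob = np.load(path, allow_pickle=False)
        cfg_json = json.loads(bytes(blob["__config"]).decode())
        cfg = ModelConfig(**{
            k: tuple(tuple(v) if isinstance(v, list) else v for v in val)
            if isinstance(val, list) else val
            for k, val in cfg_json.items()
        })
        net = MultiStreamSleepStager(cfg)
        net.set_state({k: blob[k] for k in blob.files if not k.startswith("__")})
        return cls(
            network=net,
            feat_mean=np.asarray(blob["__feat_mean"]),
            feat_sd=np.asarray(blob["__feat_sd"]),
        )


def _config_dict(cfg: ModelConfig) -> dict:
    import dataclasses

    out = dataclasses.asdict(cfg)
    return out


def train(
    inputs: EpochInputs,
    labels: np.ndarray,
    subjects: np.ndarray,
    cfg: ModelConfig | None = None,
    val_subjects: list | None = None,
    seed: int | None = None,
) -> FittedModel:
    """Fit the stager on development data with an inner validation split.

    ``subjects`` assigns each epoch to a participant; when ``val_subjects``
    is not given, a subject-wise 20% split (at least one subject) is drawn
    for early stopping, scheduling and model selection.  The checkpoint
    with the best validation macro-F1 is returned.
    """
    cfg = cfg or ModelConfig()
    labels = np.asarray(labels, dtype=int)
    subjects = np.asarray(subjects)
    if not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("labels must be in {0, 1, 2}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    unique = np.unique(subjects)
    if val_subjects is None:
        order = rng.permutation(unique)
        n_val = max(1, int(round(cfg.val_fraction * unique.size)))
        if n_val >= unique.size:
            raise ValueError("not enough subjects for an inner validation split")
        val_subjects = list(order[:n_val])
    val_subjects = list(val_subjects)
    if not val_subjects:
        raise ValueError("empty validation set")
    val_mask = np.isin(subjects, val_subjects)
    if val_mask.all() or not val_mask.any():
        raise ValueError("validation split must be a proper, non-empty subset")

    tr_idx = np.where(~val_mask)[0]
    va_idx = np.where(val_mask)[0]
    counts = np.bincount(labels[tr_idx], minlength=3)
    weights = class_weights(counts)

    feat_mean = inputs.feat[tr_idx].mean(axis=0)
    feat_sd = np.maximum(inputs.feat[tr_idx].std(axis=0), 1e-8)
    feat = (inputs.feat - feat_mean) / feat_sd

    net = MultiStreamSleepStager(cfg, seed=rng.integers(2**31))
    opt = nn.Adam(net.params(), lr=cfg.learning_rate)

    best = {"f1": -np.inf, "state": None, "epoch": -1}
    plateau_wait = 0
    stop_wait = 0
    prev_val_loss = np.inf
    history: list[dict] = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(tr_idx)
        train_loss = 0.0
        n_batches = 0
        for i in range(0, order.size, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            if idx.size < 2:
                continue  # batch-norm needs more than one sample
            opt.zero_grad()
            logits = net.forward(
                inputs.raw[idx], inputs.spec[idx], feat[idx], train=True
            )
            loss, dlogits = nn.weighted_cross_entropy(logits, labels[idx], weights)
            net.backward(dlogits)
            opt.step()
            train_loss += loss
            n_batches += 1

        val_logits = []
        for i in range(0, va_idx.size, 256):
            idx = va_idx[i : i + 256]
            val_logits.append(net.forward(
                inputs.raw[idx], inputs.spec[idx], feat[idx], train=False
            ))
        val_logits = np.concatenate(val_logits)
        val_loss, _ = nn.weighted_cross_entropy(val_logits, labels[va_idx], weights)
        val_pred = val_logits.argmax(axis=1)
        val_f1 = f1_score(labels[va_idx], val_pred, average="macro", zero_division=0)

        history.append({
            "epoch": epoch,
            "train_loss": train_loss / max(n_batches, 1),
            "val_loss": val_loss,
            "val_macro_f1": float(val_f1),
            "lr": opt.lr,
        })

        if val_f1 > best["f1"]:
            best = {"f1": float(val_f1), "state": net.get_state(), "epoch": epoch}
            stop_wait = 0
        else:
            stop_wait += 1

        if val_loss < prev_val_loss - 1e-6:
            plateau_wait = 0
            prev_val_loss = val_loss
        else:
            plateau_wait += 1
            if plateau_wait >= cfg.scheduler_patience:
                opt.lr *= cfg.scheduler_factor
                plateau_wait = 0

        if stop_wait >= cfg.early_stop_patience:
            break

    if best["state"] is not None:
        net.set_state(best["state"])
    return FittedModel(
        network=net, feat_mean=feat_mean, feat_sd=feat_sd, history=history
    )


def patientwise_cv(
    dataset: dict,
    k: int = 5,
    cfg: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[dict, FoldAssignment]:
    """Patient-wise k-fold cross-validation with pooled out-of-fold predictions.

    ``dataset`` maps subject_id -> ``(EpochInputs, labels)``.  Every subject
    is predicted exactly once, by the fold model that never saw it during
    training, early stopping or model selection.  Returns
    ``(pooled, assignment)`` where ``pooled`` holds concatenated reference
    labels, predicted labels, probabilities, subject ids and epoch indices.
    """
    cfg = cfg or ModelConfig()
    subjects = sorted(dataset.keys())
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects for {k}-fold CV, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    folds = [list(part) for part in np.array_split(order, k)]

    fold_of = {s: i for i, part in enumerate(folds) for s in part}
    dev_lists, val_lists, test_lists = [], [], []
    pooled = {"subject": [], "epoch_index": [], "reference": [],
              "predicted": [], "probabilities": []}

    for i in range(k):
        test = folds[i]
        dev = [s for s in subjects if s not in test]
        n_val = max(1, int(round(cfg.val_fraction * len(dev))))
        val = list(rng.permutation(dev)[:n_val])
        dev_lists.append(dev)
        val_lists.append(val)
        test_lists.append(list(test))

        assert not (set(dev) & set(test)), "subject leakage between dev and test"

        tr_inputs = _concat_inputs([dataset[s][0] for s in dev])
        tr_labels = np.concatenate([dataset[s][1] for s in dev])
        tr_subj = np.concatenate(
            [np.repeat(s, len(dataset[s][1])) for s in dev]
        )
        fitted = train(
            tr_inputs, tr_labels, tr_subj, cfg,
            val_subjects=val, seed=int(rng.integers(2**31)),
        )
        for s in test:
            pred = fitted.predict(dataset[s][0])
            n = len(dataset[s][1])
            pooled["subject"].append(np.repeat(s, n))
            pooled["epoch_index"].append(np.arange(n))
            pooled["reference"].append(np.asarray(dataset[s][1], dtype=int))
            pooled["predicted"].append(pred.labels)
            pooled["probabilities"].append(pred.probabilities)

    assignment = FoldAssignment(
        fold_of=fold_of, dev_subjects=dev_lists,
        val_subjects=val_lists, test_subjects=test_lists,
    )
    assignment.validate()
    pooled = {key: np.concatenate(vals) for key, vals in pooled.items()}
    return pooled, assignment


def _concat_inputs(blocks: list[EpochInputs]) -> EpochInputs:
    return EpochInputs(
        raw=np.concatenate([b.raw for b in blocks]),
        spec=np.concatenate([b.spec for b in blocks]),
        feat=np.concatenate([b.feat for b in blocks]),
    )


def predict_recording(
    model: FittedModel,
    rec: Recording,
    pre_cfg: PreprocessConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
    spec_cfg: SpectrogramConfig | None = None,
) -> tuple[Hypnogram, StagePrediction]:
    """Stage a whole recording with a frozen model.

    The recording passes through the standard conditioning chain; every
    full 30-s epoch receives a label.  Epochs failing QC are still staged
    (a warning is emitted) so the hypnogram stays gap-free.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    epochs, mask = preprocess_recording(rec, pre_cfg)
    if epochs.n_epochs == 0:
        raise ValueError(
            f"recording {rec.subject_id} shorter than one 30-s epoch"
        )
    if mask.n_usable < epochs.n_epochs:
        warnings.warn(
            f"{rec.subject_id}: {epochs.n_epochs - mask.n_usable} epoch(s) "
            "failed QC; they are staged anyway", stacklevel=2,
        )
    inputs = build_inputs(epochs, feat_cfg, spec_cfg)
    pred = model.predict(inputs)
    hyp = Hypnogram(subject_id=rec.subject_id, labels=pred.labels)
    return hyp, pred
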