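"""Epoch-level metrics and night-level agreement statistics.

Stage-1 evaluation works on pooled out-of-fold epoch predictions
(per-class precision/recall/F1, confusion matrix, class-balanced
visualization subset).  Stage-2 evaluation summarises whole nights as
TST and REM%/NREM% of TST and quantifies automated-vs-manual agreement
with Bland–Altman statistics, MAE and ICC(A,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import STAGE_NAMES
from .io import Hypnogram

__all__ = [
    "EpochMetrics", "NightSummary", "AgreementReport",
    "epoch_metrics", "balanced_subset", "night_summary",
    "bland_altman", "icc_a1", "agreement_report",
]


@dataclass
class EpochMetrics:
    """Per-class precision/recall/F1 with the 3x3 confusion matrix.

    Confusion rows are the reference stage, columns the predicted stage.
    A zero denominator yields metric 0 and sets the class in
    ``undefined``.
    """

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray
    support: np.ndarray
    undefined: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": list(STAGE_NAMES),
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            }
        )


def epoch_metrics(reference, predicted) -> EpochMetrics:
    """Three-class precision/recall/F1 against adjudicated reference labels."""
    reference = np.asarray(reference, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if reference.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {reference.shape} reference vs {predicted.shape} predicted"
        )
    if not (np.isin(reference, (0, 1, 2)).all() and np.isin(predicted, (0, 1, 2)).all()):
        raise ValueError("labels must be in {0, 1, 2}")
    confusion = np.zeros((3, 3), dtype=int)
    np.add.at(confusion, (reference, predicted), 1)

    tp = np.diag(confusion).astype(float)
    pred_tot = confusion.sum(axis=0).astype(float)
    ref_tot = confusion.sum(axis=1).astype(float)
    undefined = []
    precision = np.zeros(3)
    recall = np.zeros(3)
    for c in range(3):
        if pred_tot[c] > 0:
            precision[c] = tp[c] / pred_tot[c]
        else:
            undefined.append(f"precision:{STAGE_NAMES[c]}")
        if ref_tot[c] > 0:
            recall[c] = tp[c] / ref_tot[c]
        else:
            undefined.append(f"recall:{STAGE_NAMES[c]}")
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    return EpochMetrics(
        precision=precision, recall=recall, f1=f1,
        confusion=confusion, support=ref_tot.astype(int), undefined=undefined,
    )


def balanced_subset(
    reference: np.ndarray,
    per_class: int,
    seed: int = 0,
    **aligned_arrays: np.ndarray,
) -> dict:
    """Uniform class-balanced subsample of pooled predictions.

    Draws exactly ``per_class`` epochs per reference class without
    replacement (seeded).  Any keyword arrays aligned with ``reference``
    (predicted labels, probabilities, subject ids, ...) are subsampled
    with the same indices, so each epoch keeps its (reference, predicted)
    pair.
    """
    reference = np.asarray(reference, dtype=int)
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(3):
        pool = np.where(reference == c)[0]
        if pool.size < per_class:
            raise ValueError(
                f"class {STAGE_NAMES[c]} has only {pool.size} pooled epochs, "
                f"need {per_class}"
            )
        chosen.append(rng.choice(pool, size=per_class, replace=False))
    idx = np.sort(np.concatenate(chosen))
    out = {"index": idx, "reference": reference[idx]}
    for name, arr in aligned_arrays.items():
        arr = np.asarray(arr)
        if arr.shape[0] != reference.shape[0]:
            raise ValueError(f"array {name!r} not aligned with reference")
        out[name] = arr[idx]
    return out


@dataclass
class NightSummary:
    """Whole-night totals: TST (min) and REM%/NREM% of TST.

    TST counts non-wake epochs at 0.5 min each.  When TST is zero the
    percentages are undefined: they are reported as NaN with
    ``undefined_percent`` set, never as silent NaN from a 0/0.
    """

    subject_id: str
    tst_minutes: float
    rem_pct: float
    nrem_pct: float
    undefined_percent: bool = False


def night_summary(h: Hypnogram) -> NightSummary:
    labels = h.labels
    n_nrem = int((labels == 1).sum())
    n_rem = int((labels == 2).sum())
    tst = 0.5 * (n_nrem + n_rem)
    if n_nrem + n_rem == 0:
        return NightSummary(h.subject_id, 0.0, float("nan"), float("nan"),
                            undefined_percent=True)
    rem_pct = 100.0 * n_rem / (n_nrem + n_rem)
    return NightSummary(h.subject_id, tst, rem_pct, 100.0 - rem_pct)


def bland_altman(auto, manual) -> tuple[float, float, float, float]:
    """Bland–Altman agreement for paired per-subject values.

    Differences are automated - manual.  Returns
    ``(bias, loa_low, loa_high, mae)`` with limits of agreement
    bias +/- 1.96 * SD(d) (sample SD, n-1) and MAE the mean absolute
    difference.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("auto and manual must be 1-D and paired")
    if auto.size < 3:
        raise ValueError("need at least 3 paired values")
    d = auto - manual
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, float(np.abs(d).mean())


def icc_a1(auto, manual) -> tuple[float, float, float]:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    Computed from the two-way ANOVA mean squares with k = 2 raters
    (automated, manual) and n subjects:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with the 95% CI from the F-distribution interval of McGraw & Wong.
    Returns ``(icc, ci_low, ci_high)``; a degenerate table (zero
    between-subject variance) raises.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("auto and manual must be 1-D and paired")
    n = auto.size
    if n < 5:
        raise ValueError("need at least 5 paired values for ICC")
    k = 2
    data = np.stack([auto, manual], axis=1)  # rows: subjects, cols: raters

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 1e-300 * max(1.0, abs(grand)):
        raise ValueError("degenerate table: no between-subject variance")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(A,1)
    alpha = 0.05
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isinf(a) or np.isinf(b):
        return float(icc), 1.0, 1.0
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_upper = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    ci_low = (n * (msr - f_upper * mse)) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = (n * (f_lower * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    return float(icc), float(ci_low), float(ci_high)


@dataclass
class AgreementReport:
    """Bland–Altman + MAE + ICC for one night-level variable."""

    variable: str
    bias: float
    loa_low: float
    loa_high: float
    mae: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float

    def to_dict(self) -> dict:
        return {
            "variable": self.variable, "bias": self.bias,
            "loa_low": self.loa_low, "loa_high": self.loa_high,
            "mae": self.mae, "icc": self.icc,
            "icc_ci_low": self.icc_ci_low, "icc_ci_high": self.icc_ci_high,
        }


def agreement_report(variable: str, auto, manual) -> AgreementReport:
    """Full night-level agreement summary for one variable."""
    bias, lo, hi, mae = bland_altman(auto, manual)
    icc, ci_low, ci_high = icc_a1(auto, manual)
    return AgreementReport(
        variable=variable, bias=bias, loa_low=lo, loa_high=hi, mae=mae,
        icc=icc, icc_ci_low=ci_low, icc_ci_high=ci_high,
    )
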