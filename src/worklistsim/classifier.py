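"""Stochastic model of the per-finding binary classifier.

The neural network itself is out of scope: only its operating points
matter to the worklist.  For each finding the classifier is summarized by
a (TPR, FPR) pair; predictions are coin flips at those rates.  A
one-parameter binormal ROC family, matched to each finding's AUC, lets an
operating point be placed at any false-positive rate for sweep
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "OperatingPoint",
    "ROCModel",
    "low_fpr_preset",
    "low_fnr_preset",
    "perfect_operating_point",
    "sample_prediction",
    "tpr_at_fpr",
    "auc_from_operating_point",
    "operating_point_from_fpr",
    "default_roc_model",
]

# Operating point tuned for best average turnaround reduction: common
# FPR 0.05, per-finding TPR.
_LOW_FPR_TPR = {
    "pneumothorax": 0.82,
    "congestion": 0.71,
    "pleural_effusion": 0.86,
    "infiltrate": 0.75,
    "atelectasis": 0.61,
    "cardiomegaly": 0.75,
    "mass": 0.51,
    "foreign_object": 0.51,
}

# Operating point with a low false-negative rate: common TPR 0.95,
# per-finding FPR.
_LOW_FNR_FPR = {
    "pneumothorax": 0.20,
    "congestion": 0.24,
    "pleural_effusion": 0.21,
    "infiltrate": 0.27,
    "atelectasis": 0.39,
    "cardiomegaly": 0.18,
    "mass": 0.72,
    "foreign_object": 0.78,
}


@dataclass(frozen=True)
class OperatingPoint:
    """Per-finding true-positive and false-positive rates.

    ``fnr = 1 - tpr`` and ``tnr = 1 - fpr`` are derived, not stored.
    """

    names: tuple[str, ...]
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.tpr) == len(self.fpr)):
            raise ValueError("names, tpr, fpr must have equal length")
        for r in (*self.tpr, *self.fpr):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")

    @property
    def fnr(self) -> tuple[float, ...]:
        return tuple(1.0 - t for t in self.tpr)

    @property
    def tnr(self) -> tuple[float, ...]:
        return tuple(1.0 - f for f in self.fpr)

    def tpr_array(self) -> np.ndarray:
        return np.array(self.tpr)

    def fpr_array(self) -> np.ndarray:
        return np.array(self.fpr)

    @classmethod
    def from_csv(cls, path) -> "OperatingPoint":
        df = pd.read_csv(path)
        missing = {"finding", "tpr", "fpr"} - set(df.columns)
        if missing:
            raise ValueError(f"operating-point CSV missing columns: {sorted(missing)}")
        return cls(
            tuple(df["finding"].astype(str)),
            tuple(df["tpr"].astype(float)),
            tuple(df["fpr"].astype(float)),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"finding": self.names, "tpr": self.tpr, "fpr": self.fpr}
        ).to_csv(path, index=False)


def low_fpr_preset() -> OperatingPoint:
    """Bundled operating point with FPR 0.05 for every finding."""
    names = tuple(_LOW_FPR_TPR)
    return OperatingPoint(names, tuple(_LOW_FPR_TPR[n] for n in names), (0.05,) * 8)


def low_fnr_preset() -> OperatingPoint:
    """Bundled operating point with TPR 0.95 (FNR 0.05) for every finding."""
    names = tuple(_LOW_FNR_FPR)
    return OperatingPoint(names, (0.95,) * 8, tuple(_LOW_FNR_FPR[n] for n in names))


def perfect_operating_point(names: tuple[str, ...]) -> OperatingPoint:
    """Error-free classifier: TPR 1, FPR 0 — the prioritization upper bound."""
    k = len(names)
    return OperatingPoint(names, (1.0,) * k, (0.0,) * k)


def sample_prediction(
    true_labels: np.ndarray, op: OperatingPoint, rng: np.random.Generator
) -> np.ndarray:
    """Flip the classifier's coins for one exam (or a batch).

    A truly positive finding is predicted positive with probability TPR,
    a truly negative one with probability FPR; findings are independent of
    each other and of arrival time.  Accepts a length-K vector or an
    (n, K) matrix of ground-truth labels.
    """
    true_labels = np.asarray(true_labels, dtype=bool)
    k = len(op.names)
    if true_labels.shape[-1] != k:
        raise ValueError("label vector not aligned with operating point")
    p_positive = np.where(true_labels, op.tpr_array(), op.fpr_array())
    return rng.random(true_labels.shape) < p_positive


def tpr_at_fpr(auc: float, fpr: float) -> float:
    """TPR on an equal-variance binormal ROC curve with the given AUC.

    The curve is tpr = Phi(mu + Phi^-1(fpr)) with mu = sqrt(2) * Phi^-1(auc),
    the standard one-parameter ROC through a given AUC.  The endpoints
    tpr(0) = 0 and tpr(1) = 1 hold by continuity.
    """
    if not 0.5 <= auc <= 1.0:
        raise ValueError(f"auc {auc} outside [0.5, 1]")
    if not 0.0 <= fpr <= 1.0:
        raise ValueError(f"fpr {fpr} outside [0, 1]")
    if fpr == 0.0:
        return 0.0
    if fpr == 1.0:
        return 1.0
    mu = np.sqrt(2.0) * norm.ppf(auc)
    return float(norm.cdf(mu + norm.ppf(fpr)))


def auc_from_operating_point(tpr: float, fpr: float) -> float:
    """AUC of the binormal curve passing through one interior (FPR, TPR) point.

    Inverts :func:`tpr_at_fpr`: mu = Phi^-1(tpr) - Phi^-1(fpr), and
    auc = Phi(mu / sqrt(2)).  Used to recover per-finding AUC values from a
    published operating point when the full ROC curve is unavailable.
    """
    if not (0.0 < fpr < 1.0 and 0.0 < tpr < 1.0):
        raise ValueError("need an interior operating point to infer an AUC")
    mu = norm.ppf(tpr) - norm.ppf(fpr)
    return float(norm.cdf(mu / np.sqrt(2.0)))


@dataclass(frozen=True)
class ROCModel:
    """Per-finding AUC values parameterizing the binormal ROC family."""

    names: tuple[str, ...]
    auc: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.auc):
            raise ValueError("names and auc must have equal length")
        for a in self.auc:
            if not 0.5 <= a <= 1.0:
                raise ValueError(f"auc {a} outside [0.5, 1]")

    @classmethod
    def from_csv(cls, path) -> "ROCModel":
        df = pd.read_csv(path)
        missing = {"finding", "auc"} - set(df.columns)
        if missing:
            raise ValueError(f"ROC CSV missing columns: {sorted(missing)}")
        return cls(tuple(df["finding"].astype(str)), tuple(df["auc"].astype(float)))

    def to_csv(self, path) -> None:
        pd.DataFrame({"finding": self.names, "auc": self.auc}).to_csv(
            path, index=False
        )


def default_roc_model() -> ROCModel:
    """Per-finding AUCs inferred from the bundled low-FPR operating point.

    The published classifier's full ROC curves are not available as data,
    so each finding's AUC is backed out from its (TPR, FPR = 0.05) point
    under the binormal family.  This keeps the sweep experiments anchored
    to the same classifier the presets describe.
    """
    op = low_fpr_preset()
    aucs = tuple(
        auc_from_operating_point(t, f) for t, f in zip(op.tpr, op.fpr)
    )
    return ROCModel(op.names, aucs)


def operating_point_from_fpr(roc: ROCModel, fpr: float) -> OperatingPoint:
    """Place every finding at a common FPR on its binormal ROC curve."""
    tprs = tuple(tpr_at_fpr(a, fpr) for a in roc.auc)
    return OperatingPoint(roc.names, tprs, (float(fpr),) * len(roc.names))
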