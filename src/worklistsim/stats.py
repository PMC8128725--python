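"""Turnaround-time summaries, Welch's t-test, and operating-point sweeps.

Report turnaround time (RTAT) — minutes from acquisition to report
finalization — is the primary outcome.  Summaries are per true-label
class: an exam contributes to every finding it actually carries, and
exams with no finding form the "normal" class, so multi-label exams
appear in several rows and the rows overlap by design.

Strategy contrasts use Welch's unequal-variance two-sample t-test with
Welch-Satterthwaite degrees of freedom, two-sided, at alpha = 0.05, per
class without multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _replace

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .catalog import FindingCatalog
from .classifier import ROCModel, operating_point_from_fpr
from .simulate import ExamRecord, SimulationConfig, run_simulation

__all__ = [
    "DEFAULT_FPR_GRID",
    "WelchResult",
    "rtat_by_class",
    "summarize_rtat",
    "welch_t",
    "compare_strategies",
    "fpr_sweep",
]

# Log-ish spacing, dense near the small-FPR region where the optimum sits.
DEFAULT_FPR_GRID = (0.0, 0.01, 0.025, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float

    @property
    def significant(self) -> bool:
        """Two-sided significance at alpha = 0.05."""
        return self.p_value < 0.05


def rtat_by_class(
    records: list[ExamRecord], catalog: FindingCatalog
) -> dict[str, np.ndarray]:
    """RTAT samples per class (each finding plus "normal"), by true labels.

    Multi-label exams contribute to every class whose ground-truth flag
    is set, regardless of what was predicted.
    """
    if not records:
        raise ValueError("no records to summarize")
    rtats = np.array([r.rtat for r in records])
    labels = np.array([r.true_labels for r in records], dtype=bool)
    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(catalog.names):
        out[name] = rtats[labels[:, j]]
    out["normal"] = rtats[~labels.any(axis=1)]
    return out


def summarize_rtat(
    records: list[ExamRecord], catalog: FindingCatalog
) -> pd.DataFrame:
    """Per-class n / mean / median / max RTAT table (minutes).

    Rows follow urgency order with "normal" last, mirroring the usual
    per-finding turnaround reporting layout.
    """
    groups = rtat_by_class(records, catalog)
    rows = []
    for name in catalog.class_names:
        x = groups[name]
        rows.append(
            {
                "class": name,
                "n": int(x.size),
                "mean_min": float(x.mean()) if x.size else float("nan"),
                "median_min": float(np.median(x)) if x.size else float("nan"),
                "max_min": float(x.max()) if x.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def welch_t(sample_a, sample_b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), with
    Welch-Satterthwaite degrees of freedom.  Implemented from the
    defining formulas; requires at least two observations per sample and
    nonzero variance in at least one.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(na + nb - 2), 1.0)
        raise ValueError("both samples have zero variance but unequal means")
    sa, sb = va / na, vb / nb
    se = np.sqrt(sa + sb)
    t = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def compare_strategies(
    records_a: list[ExamRecord],
    records_b: list[ExamRecord],
    catalog: FindingCatalog,
) -> pd.DataFrame:
    """Per-class Welch comparison of two strategies' RTAT distributions."""
    groups_a = rtat_by_class(records_a, catalog)
    groups_b = rtat_by_class(records_b, catalog)
    rows = []
    for name in catalog.class_names:
        a, b = groups_a[name], groups_b[name]
        if a.size < 2 or b.size < 2:
            rows.append(
                {"class": name, "t": np.nan, "df": np.nan, "p": np.nan,
                 "significant": False}
            )
            continue
        res = welch_t(a, b)
        rows.append(
            {
                "class": name,
                "t": res.t_statistic,
                "df": res.degrees_of_freedom,
                "p": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def fpr_sweep(
    base_config: SimulationConfig,
    roc: ROCModel,
    fpr_grid=DEFAULT_FPR_GRID,
) -> pd.DataFrame:
    """Sweep the classifier's common false-positive rate.

    For each grid FPR, every finding is placed at that FPR on its
    binormal ROC curve, the priority simulation is rerun with the same
    seeds (common random numbers), and the mean RTAT of the most-urgent
    class (rank 1, by true labels) is recorded.  Returns a table with an
    ``argmin`` flag on the best grid point.  At FPR 0 nothing is flagged
    urgent and at FPR 1 everything is, so both endpoints degenerate to
    acquisition-order processing.
    """
    grid = [float(f) for f in fpr_grid]
    for f in grid:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fpr {f} outside [0, 1]")
    if 0.0 not in grid or 1.0 not in grid:
        raise ValueError("fpr grid must include both endpoints 0 and 1")
    rank1_name = base_config.catalog.names[0]
    means = []
    for f in grid:
        op = operating_point_from_fpr(roc, f)
        config = _replace(base_config, strategy="prio", operating_point=op)
        records = run_simulation(config)
        means.append(float(rtat_by_class(records, config.catalog)[rank1_name].mean()))
    df = pd.DataFrame({"fpr": grid, "mean_rtat_rank1": means})
    df["argmin"] = df["mean_rtat_rank1"] == df["mean_rtat_rank1"].min()
    return df
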