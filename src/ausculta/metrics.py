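"""Multilabel evaluation against the consensus reference standard.

For each phenomenon class, a rater's recording-level labels are compared
with the reference to give a 2x2 confusion table, from which recall
(sensitivity), precision, specificity, and F1 (the harmonic mean of
precision and recall) are computed.  Percentages are carried as exact
rationals internally and displayed at one decimal with half-up rounding.
Rater-vs-rater differences are assessed with a chi-square test (alpha =
0.05) on the 2x2 table of rater x (correct vs incorrect w.r.t. the
reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .phenomena import CLASSES


def round_half_up(x, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (display convention)."""
    if x is None:
        return None
    if isinstance(x, Fraction):
        q = Fraction(10) ** ndigits
        scaled = x * q
        floor = scaled.numerator // scaled.denominator
        rem = scaled - floor
        rounded = floor + (1 if rem >= Fraction(1, 2) else 0)
        return float(Fraction(rounded, 1) / q)
    from decimal import Decimal, ROUND_HALF_UP

    return float(Decimal(repr(float(x))).quantize(Decimal(f"1e-{ndigits}"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 recording-level counts for one class and one rater."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Recall, precision, specificity, and F1 as percentages.

    Exact values are kept as :class:`fractions.Fraction`; ``None`` marks a
    metric whose denominator is zero (undefined, deliberately not reported
    as 0).  ``*_pct`` properties round half-up to one decimal.
    """

    recall: Optional[Fraction]
    precision: Optional[Fraction]
    specificity: Optional[Fraction]
    f1: Optional[Fraction]

    @property
    def recall_pct(self):
        return round_half_up(self.recall * 100) if self.recall is not None else None

    @property
    def precision_pct(self):
        return round_half_up(self.precision * 100) if self.precision is not None else None

    @property
    def specificity_pct(self):
        return round_half_up(self.specificity * 100) if self.specificity is not None else None

    @property
    def f1_pct(self):
        return round_half_up(self.f1 * 100) if self.f1 is not None else None

    @property
    def undefined(self) -> list[str]:
        return [n for n in ("recall", "precision", "specificity", "f1")
                if getattr(self, n) is None]

    def as_pct_dict(self) -> dict:
        return {"recall": self.recall_pct, "precision": self.precision_pct,
                "specificity": self.specificity_pct, "f1": self.f1_pct}


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float
    alpha: float = 0.05
    continuity_correction: bool = False
    warning: Optional[str] = None

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


def confusion(reference: Mapping | pd.Series, rater: Mapping | pd.Series,
              class_name: str | None = None) -> ConfusionCounts:
    """Per-class confusion counts over a shared recording-id set.

    ``reference`` and ``rater`` map recording id -> bool (or are boolean
    Series indexed by id; pass DataFrames plus ``class_name`` to select a
    column).  Mismatched id sets raise with the offending ids listed.
    """
    if isinstance(reference, pd.DataFrame):
        reference = reference[class_name]
    if isinstance(rater, pd.DataFrame):
        rater = rater[class_name]
    ref = pd.Series(reference).astype(bool)
    rat = pd.Series(rater).astype(bool)
    missing_in_rater = sorted(set(ref.index) - set(rat.index))
    missing_in_ref = sorted(set(rat.index) - set(ref.index))
    if missing_in_rater or missing_in_ref:
        raise ValueError(
            "recording id mismatch: "
            f"missing from rater {missing_in_rater[:10]}, "
            f"missing from reference {missing_in_ref[:10]}"
        )
    rat = rat.reindex(ref.index)
    tp = int((ref & rat).sum())
    fp = int((~ref & rat).sum())
    tn = int((~ref & ~rat).sum())
    fn = int((ref & ~rat).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Exact metric suite from confusion counts.

    F1 is the harmonic mean of precision and recall, defined as 0 when both
    are 0; any metric with a zero denominator is ``None`` (undefined)."""
    recall = Fraction(c.tp, c.tp + c.fn) if c.tp + c.fn > 0 else None
    precision = Fraction(c.tp, c.tp + c.fp) if c.tp + c.fp > 0 else None
    specificity = Fraction(c.tn, c.tn + c.fp) if c.tn + c.fp > 0 else None
    f1 = _f1(precision, recall)
    return MetricSet(recall=recall, precision=precision, specificity=specificity, f1=f1)


def _f1(precision: Optional[Fraction], recall: Optional[Fraction]) -> Optional[Fraction]:
    if precision is None or recall is None:
        return None
    if precision == 0 and recall == 0:
        return Fraction(0)
    return 2 * precision * recall / (precision + recall)


def f1_from_printed(recall_pct, precision_pct) -> float:
    """Harmonic mean of a printed recall/precision pair, as a 1-decimal
    percentage — reproduces a published table's F1 column from its own
    printed inputs."""
    r = Fraction(str(recall_pct)) / 100
    p = Fraction(str(precision_pct)) / 100
    return round_half_up(_f1(p, r) * 100)


def macro_mean(per_class: Sequence[MetricSet | Mapping]) -> dict:
    """Unweighted mean over classes of each printed (1-decimal) metric.

    Operates on the rounded per-class percentages, then rounds the mean to
    one decimal — matching how a summary row is derived from a printed
    table.  Any undefined input yields an undefined (None) mean."""
    if not per_class:
        raise ValueError("need at least one class")
    out = {}
    for name in ("recall", "precision", "specificity", "f1"):
        vals = []
        for m in per_class:
            v = m.as_pct_dict()[name] if isinstance(m, MetricSet) else m[name]
            vals.append(v)
        if any(v is None for v in vals):
            out[name] = None
        else:
            exact = sum(Fraction(str(v)) for v in vals) / len(vals)
            out[name] = round_half_up(exact)
    return out


def chi_square_2x2(table: np.ndarray, continuity_correction: bool = False,
                   alpha: float = 0.05) -> ChiSquareResult:
    """Chi-square test of independence on a 2x2 contingency table."""
    obs = np.asarray(table, dtype=np.float64)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {obs.shape}")
    warning = None
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        return ChiSquareResult(0.0, 1, 1.0, alpha, continuity_correction,
                               warning="degenerate table (empty row or column)")
    expected = np.outer(row, col) / obs.sum()
    if expected.min() < 1.0:
        warning = f"expected cell count below 1 ({expected.min():.3f}); test unreliable"
    stat, p, dof, _ = scipy_stats.chi2_contingency(obs, correction=continuity_correction)
    return ChiSquareResult(float(stat), int(dof), float(p), alpha,
                           continuity_correction, warning)


def compare_raters(rater_a: pd.DataFrame | pd.Series, rater_b: pd.DataFrame | pd.Series,
                   reference: pd.DataFrame | pd.Series, class_name: str | None = None,
                   continuity_correction: bool = False) -> ChiSquareResult:
    """Chi-square comparison of two raters against the reference.

    Builds the 2x2 table of rater x (correct vs incorrect w.r.t. the
    reference) for one class and tests independence at alpha = 0.05."""
    ca = confusion(reference, rater_a, class_name)
    cb = confusion(reference, rater_b, class_name)
    table = np.array(
        [[ca.tp + ca.tn, ca.fp + ca.fn],
         [cb.tp + cb.tn, cb.fp + cb.fn]]
    )
    return chi_square_2x2(table, continuity_correction)


def majority_vote(label_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool several readers' label tables into one by per-class majority
    (ties -> positive).  A pooling convenience, not part of the reference
    procedure."""
    if not label_tables:
        raise ValueError("need at least one label table")
    idx = label_tables[0].index
    stack = np.stack([t.reindex(idx)[list(CLASSES)].to_numpy(dtype=float) for t in label_tables])
    pooled = stack.sum(axis=0) >= (len(label_tables) / 2.0)
    return pd.DataFrame(pooled, index=idx, columns=list(CLASSES))


#: Display names used in report rows.
CLASS_DISPLAY = {
    "coarse_crackle": "Coarse crackles",
    "fine_crackle": "Fine crackles",
    "wheeze": "Wheezes",
    "rhonchus": "Rhonchi",
}
REPORT_ROW_ORDER = ("coarse_crackle", "fine_crackle", "wheeze", "rhonchus")


def report_table(reference: pd.DataFrame, raters: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-class + Mean rows of the four metrics for each rater.

    Columns are a (metric, rater) MultiIndex of 1-decimal percentages; the
    Mean row averages the printed per-class values."""
    if not raters:
        raise ValueError("need at least one rater")
    per_rater = {}
    for name, labels in raters.items():
        sets = {c: metrics(confusion(reference, labels, c)) for c in CLASSES}
        per_rater[name] = sets
    rows = []
    index = []
    for c in REPORT_ROW_ORDER:
        index.append(CLASS_DISPLAY[c])
        row = {}
        for name in raters:
            for metric, val in per_rater[name][c].as_pct_dict().items():
                row[(metric, name)] = val
        rows.append(row)
    mean_row = {}
    for name in raters:
        mm = macro_mean([per_rater[name][c] for c in REPORT_ROW_ORDER])
        for metric, val in mm.items():
            mean_row[(metric, name)] = val
    rows.append(mean_row)
    index.append("Mean")
    cols = pd.MultiIndex.from_tuples(
        [(m, r) for m in ("recall", "precision", "specificity", "f1") for r in raters],
        names=["metric", "rater"],
    )
    return pd.DataFrame(rows, index=index, columns=cols)


def write_report(table: pd.DataFrame, out_dir: str | Path) -> None:
    """Report as CSV plus aligned text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "report.csv", lineterminator="\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(table.to_string(float_format=lambda v: f"{v:.1f}") + "\n")
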