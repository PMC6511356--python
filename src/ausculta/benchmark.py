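"""Published clinical benchmark: five pediatricians vs an automatic
detector on 522 auscultation recordings.

A published blind comparison evaluated recording-level detection of the
four phenomenon classes on 522 recordings from 50 pediatric patients
against a consensus reference standard (322 recordings accepted on
double-positive verification, 200 settled by a consilium).  This module
carries the printed percentage table and positive counts as *input data*
and provides utilities that recompute derived quantities from them: F1 from
printed recall/precision, summary (mean) rows, rater-advantage gaps in
percentage points, integer confusion tables consistent with the printed
metrics, and the rater-vs-rater chi-square tests.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .metrics import (
    ChiSquareResult,
    ConfusionCounts,
    chi_square_2x2,
    f1_from_printed,
    macro_mean,
    metrics,
    round_half_up,
)

#: Total recordings evaluated, and reference-standard composition.
N_RECORDINGS = 522
GS_COMPOSITION = {"double_positive": 322, "consilium": 200}

#: Reference-positive recordings per class.
POSITIVES = {
    "wheeze": 124,
    "rhonchus": 113,
    "fine_crackle": 112,
    "coarse_crackle": 66,
}

#: Printed per-class percentages (1 decimal) for the two raters.
PRINTED = {
    "doctors": {
        "coarse_crackle": {"recall": 56.1, "precision": 34.6, "specificity": 84.6, "f1": 42.8},
        "fine_crackle": {"recall": 72.3, "precision": 39.5, "specificity": 69.8, "f1": 51.1},
        "wheeze": {"recall": 58.1, "precision": 66.1, "specificity": 90.7, "f1": 61.8},
        "rhonchus": {"recall": 67.3, "precision": 55.9, "specificity": 85.3, "f1": 61.0},
    },
    "nn": {
        "coarse_crackle": {"recall": 56.1, "precision": 40.7, "specificity": 88.2, "f1": 47.1},
        "fine_crackle": {"recall": 83.9, "precision": 52.5, "specificity": 79.3, "f1": 64.6},
        "wheeze": {"recall": 78.2, "precision": 57.7, "specificity": 82.2, "f1": 66.4},
        "rhonchus": {"recall": 87.6, "precision": 61.1, "specificity": 84.6, "f1": 72.0},
    },
}

#: Printed Mean row of the benchmark table.
PRINTED_MEAN = {
    "doctors": {"recall": 63.5, "precision": 49.0, "specificity": 82.6, "f1": 54.2},
    "nn": {"recall": 76.5, "precision": 53.0, "specificity": 83.6, "f1": 62.5},
}

#: The F1 cells whose printed value is exactly the harmonic mean of the
#: printed recall/precision pair (the remaining two differ by one unit in
#: the last printed digit, an artifact of the table's own rounding).
SELF_CONSISTENT_F1_CELLS = (
    ("doctors", "coarse_crackle"),
    ("doctors", "fine_crackle"),
    ("doctors", "wheeze"),
    ("nn", "fine_crackle"),
    ("nn", "wheeze"),
    ("nn", "rhonchus"),
)


def recomputed_f1(rater: str, class_name: str) -> float:
    """F1 recomputed from the printed recall/precision pair."""
    cell = PRINTED[rater][class_name]
    return f1_from_printed(cell["recall"], cell["precision"])


def recomputed_mean_row(rater: str) -> dict:
    """Mean row recomputed from the printed per-class values."""
    return macro_mean([PRINTED[rater][c] for c in PRINTED[rater]])


def advantage_pp(metric: str) -> float:
    """Mean per-class advantage of the detector over the doctors, in
    percentage points of the printed per-class values."""
    diffs = [
        Fraction(str(PRINTED["nn"][c][metric])) - Fraction(str(PRINTED["doctors"][c][metric]))
        for c in PRINTED["nn"]
    ]
    return round_half_up(sum(diffs) / len(diffs))


def reconstruct_confusion(rater: str, class_name: str) -> ConfusionCounts:
    """Integer confusion counts consistent with the printed metrics.

    Searches tp in [0, P] and fp in [0, N-P] (P reference positives out of
    N = 522 recordings) for the unique pair whose recall, precision, and
    specificity all round back to the printed one-decimal values; raises if
    no or multiple candidates survive."""
    printed = PRINTED[rater][class_name]
    p_count = POSITIVES[class_name]
    n_neg = N_RECORDINGS - p_count
    candidates = []
    for tp in range(p_count + 1):
        if round_half_up(100 * Fraction(tp, p_count)) != printed["recall"]:
            continue
        for fp in range(n_neg + 1):
            if tp + fp == 0:
                continue
            if round_half_up(100 * Fraction(tp, tp + fp)) != printed["precision"]:
                continue
            if round_half_up(100 * Fraction(n_neg - fp, n_neg)) != printed["specificity"]:
                continue
            candidates.append(ConfusionCounts(tp=tp, fp=fp, tn=n_neg - fp, fn=p_count - tp))
    if len(candidates) != 1:
        raise ValueError(
            f"{rater}/{class_name}: {len(candidates)} integer confusion tables match "
            "the printed metrics"
        )
    return candidates[0]


def rater_comparison_chi_square(class_name: str, continuity_correction: bool = False) -> ChiSquareResult:
    """Chi-square (alpha = 0.05) on rater x (correct vs incorrect), with
    counts reconstructed from the printed benchmark."""
    tables = []
    for rater in ("doctors", "nn"):
        c = reconstruct_confusion(rater, class_name)
        tables.append([c.tp + c.tn, c.fp + c.fn])
    return chi_square_2x2(np.array(tables), continuity_correction)
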