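"""Diagnostic statistics: sensitivity/specificity, ROC, exact and rank tests,
and AFP marker combination.

Conventions: sensitivity is the percentage of cases at or above the copy
cutoff, specificity the percentage of controls below it.  AUROC is the
Mann-Whitney probability that a random case outscores a random control,
with ties credited one half.  The two-sided Fisher p-value follows the
point-probability rule (sum of all fixed-margin tables no more probable
than the observed one).  HCC subjects are AFP-negative below 20 ng/mL; the
two-marker rule calls a subject positive when either AFP exceeds its
threshold or the MSP call is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticSummary",
    "RocCurve",
    "QuadrantCounts",
    "wilson_ci",
    "sensitivity_specificity",
    "roc_auc",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "combine_with_afp",
    "quadrant_counts",
    "DEFAULT_AFP_THRESHOLD",
]

DEFAULT_AFP_THRESHOLD = 20.0


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: float  # percent of cases at/above the cutoff
    specificity: float  # percent of controls below the cutoff
    auroc: float
    cutoff: float
    n_case: int
    n_control: int
    sensitivity_ci: tuple[float, float]  # Wilson 95% CI, percent scale
    specificity_ci: tuple[float, float]


def _split(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must have the same length")
    cases = v[y]
    controls = v[~y]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both case and control groups must be non-empty")
    return cases, controls


def sensitivity_specificity(
    values: Sequence[float],
    labels: Sequence[bool],
    cutoff: float = 10.0,
) -> DiagnosticSummary:
    """Sensitivity/specificity at a cutoff plus AUROC, with Wilson 95% CIs.

    ``labels`` are booleans, True for cases.  A case counts as detected when
    its value is at or above the cutoff.
    """
    cases, controls = _split(values, labels)
    tp = int((cases >= cutoff).sum())
    tn = int((controls < cutoff).sum())
    _, auroc = roc_auc(values, labels)
    sens_ci = tuple(100.0 * x for x in wilson_ci(tp, len(cases)))
    spec_ci = tuple(100.0 * x for x in wilson_ci(tn, len(controls)))
    return DiagnosticSummary(
        sensitivity=100.0 * tp / len(cases),
        specificity=100.0 * tn / len(controls),
        auroc=auroc,
        cutoff=cutoff,
        n_case=len(cases),
        n_control=len(controls),
        sensitivity_ci=sens_ci,  # type: ignore[arg-type]
        specificity_ci=spec_ci,  # type: ignore[arg-type]
    )


def roc_auc(
    values: Sequence[float], labels: Sequence[bool]
) -> tuple[RocCurve, float]:
    """ROC curve and AUROC (Mann-Whitney probability, ties counted half)."""
    _split(values, labels)  # validates non-empty groups
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    fpr, tpr, thr = roc_curve(y, v)
    auc = float(roc_auc_score(y, v))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr), auc


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p (point-probability rule); a zero margin
    gives p = 1."""
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def kruskal_wallis(
    values: Sequence[float],
    groups: Sequence[str],
    merge_map: Mapping[str, str] | None = None,
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p, with optional group
    merging applied before testing (small groups pooled into one)."""
    v = np.asarray(values, dtype=float)
    g = [merge_map.get(x, x) if merge_map else x for x in groups]
    if len(v) != len(g):
        raise ValueError("values and groups must have the same length")
    labels = sorted(set(g))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups after merging")
    arrays = [v[np.array([x == lab for x in g])] for lab in labels]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("each group must be non-empty")
    if all(np.all(a == arrays[0][0]) for a in arrays):
        return 0.0, 1.0  # all observations identical: no evidence of difference
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def combine_with_afp(
    msp_call: bool,
    afp_ng_ml: float | None,
    threshold: float = DEFAULT_AFP_THRESHOLD,
) -> bool:
    """Two-marker rule: positive iff AFP exceeds its threshold or the MSP
    call is positive.  Subjects without an AFP value cannot be combined."""
    if afp_ng_ml is None:
        raise ValueError("AFP value missing; exclude the sample from combination")
    return bool(afp_ng_ml > threshold or msp_call)


@dataclass(frozen=True)
class QuadrantCounts:
    """Cross-classification of cases by AFP threshold and MSP copy cutoff."""

    afp_neg_msp_neg: int
    afp_neg_msp_pos: int
    afp_pos_msp_neg: int
    afp_pos_msp_pos: int

    @property
    def total(self) -> int:
        return (
            self.afp_neg_msp_neg
            + self.afp_neg_msp_pos
            + self.afp_pos_msp_neg
            + self.afp_pos_msp_pos
        )

    def percentages(self) -> dict[str, float]:
        t = self.total
        return {
            "afp_neg_msp_neg": 100.0 * self.afp_neg_msp_neg / t,
            "afp_neg_msp_pos": 100.0 * self.afp_neg_msp_pos / t,
            "afp_pos_msp_neg": 100.0 * self.afp_pos_msp_neg / t,
            "afp_pos_msp_pos": 100.0 * self.afp_pos_msp_pos / t,
        }


def quadrant_counts(
    afp_values: Sequence[float],
    msp_copies: Sequence[float],
    afp_threshold: float = DEFAULT_AFP_THRESHOLD,
    msp_cutoff: float = 10.0,
) -> QuadrantCounts:
    """Count cases in each (AFP +/-, MSP +/-) quadrant of the scatter."""
    afp = np.asarray(afp_values, dtype=float)
    msp = np.asarray(msp_copies, dtype=float)
    if afp.shape != msp.shape:
        raise ValueError("afp_values and msp_copies must be paired")
    afp_pos = afp > afp_threshold
    msp_pos = msp >= msp_cutoff
    return QuadrantCounts(
        afp_neg_msp_neg=int((~afp_pos & ~msp_pos).sum()),
        afp_neg_msp_pos=int((~afp_pos & msp_pos).sum()),
        afp_pos_msp_neg=int((afp_pos & ~msp_pos).sum()),
        afp_pos_msp_pos=int((afp_pos & msp_pos).sum()),
    )
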