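"""Model evaluation: bullseye subgroups, DeLong tests, and mode agreement.

The bullseye partition classifies patients by how the selected complaint
set touches them: *inner* patients carry a selected complaint themselves;
*middle* patients carry an unselected complaint whose category contains at
least one selected sibling (so the composition of their category changed);
*outer* patients belong to categories untouched by the selection.

AUC differences between models evaluated on the same patients are tested
with DeLong's nonparametric method for correlated ROC curves, computed from
per-observation placement components.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data_model import Cohort, SpecificationMask
from .errors import DegenerateVarianceError, UndefinedAUCError, ValidationError
from .fitness import CVResult

SUBGROUPS = ("inner", "middle", "outer")
MODELS = ("ga", "baseline_complaints", "baseline_categories")


def partition_bullseye(cohort: Cohort, mask: SpecificationMask) -> np.ndarray:
    """Label each record inner / middle / outer for a selected-complaint set."""
    if len(mask) != cohort.hierarchy.n:
        raise ValidationError("mask length does not match the hierarchy")
    selected = mask.bits.astype(bool)
    comp = cohort.complaint_codes
    cat = cohort.category_codes
    n_cats = len(cohort.hierarchy.categories)
    cat_touched = np.zeros(n_cats, dtype=bool)
    np.logical_or.at(cat_touched, cohort.hierarchy.parent_codes[selected], True)
    inner = selected[comp]
    middle = ~inner & cat_touched[cat]
    labels = np.where(inner, "inner", np.where(middle, "middle", "outer"))
    return labels


# --------------------------------------------------------------------------
# DeLong's method
# --------------------------------------------------------------------------

def _placements(scores: np.ndarray, positive: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-observation placement values (midrank formulation)."""
    x, y = scores[positive], scores[~positive]
    m, n = len(x), len(y)
    r_all = rankdata(np.concatenate([x, y]))
    r_x = rankdata(x)
    r_y = rankdata(y)
    v10 = (r_all[:m] - r_x) / n            # P(x_i > Y) with ties 1/2
    v01 = 1.0 - (r_all[m:] - r_y) / m      # P(X > y_j) with ties 1/2
    a = float((r_all[:m].sum() - m * (m + 1) / 2) / (m * n))
    return a, v10, v01


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


def delong_compare(probs_a, probs_b, labels) -> DeLongResult:
    """Paired DeLong test of AUC(a) - AUC(b) on the same observations.

    The variance of the difference is estimated from the empirical
    covariance of the two models' placement components; the two-sided p
    comes from the standard normal.  A self-comparison returns z = 0 and
    p = 1 exactly.
    """
    pa = np.asarray(probs_a, dtype=float)
    pb = np.asarray(probs_b, dtype=float)
    y = np.asarray(labels)
    if pa.shape != pb.shape or pa.shape != y.shape or pa.ndim != 1:
        raise ValidationError("probability vectors and labels must be aligned")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be 0/1")
    positive = y == 1
    m, n = int(positive.sum()), int((~positive).sum())
    if m == 0 or n == 0:
        raise UndefinedAUCError("DeLong comparison needs both outcome classes")

    auc_a, v10_a, v01_a = _placements(pa, positive)
    auc_b, v10_b, v01_b = _placements(pb, positive)
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = 0.0
    if m > 1:
        var += float(np.var(d10, ddof=1)) / m
    if n > 1:
        var += float(np.var(d01, ddof=1)) / n

    diff = auc_a - auc_b
    if var <= 0.0:
        if abs(diff) < 1e-15:
            return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise DegenerateVarianceError(
            f"zero DeLong variance with unequal AUCs (diff={diff:.3g})"
        )
    z = diff / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return DeLongResult(auc_a, auc_b, var, float(z), p)


def significance_stars(p: float | None) -> str:
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# --------------------------------------------------------------------------
# Bullseye report
# --------------------------------------------------------------------------

@dataclass
class BullseyeReport:
    subgroup_labels: np.ndarray
    sizes: dict[str, int]
    aucs: dict[str, dict[str, float | None]]       # subgroup -> model -> AUC
    delong: dict[str, dict[str, DeLongResult | None]]  # subgroup -> baseline -> test

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sub in (*SUBGROUPS, "overall"):
            row: dict = {"subgroup": sub, "n": self.sizes[sub]}
            for model in MODELS:
                row[f"auc_{model}"] = self.aucs[sub][model]
            for baseline in MODELS[1:]:
                t = self.delong[sub][baseline]
                row[f"p_ga_vs_{baseline}"] = None if t is None else t.p
                row[f"stars_ga_vs_{baseline}"] = (
                    "" if t is None else significance_stars(t.p)
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _subgroup_auc(probs: np.ndarray, y: np.ndarray) -> float | None:
    from .fitness import auc
    if len(np.unique(y)) < 2:
        return None
    return auc(probs, y)


def bullseye_report(
    cohort: Cohort,
    ga_cv: CVResult,
    baseline_complaints_cv: CVResult,
    baseline_categories_cv: CVResult,
    mask: SpecificationMask,
) -> BullseyeReport:
    """Per-subgroup and overall AUCs plus paired DeLong tests vs. baselines.

    All three CV results must share the same fold assignment (common random
    folds) so their per-patient probabilities are comparable.  A subgroup
    with a single outcome class gets an undefined (None) AUC and no test.
    """
    cvs = {
        "ga": ga_cv,
        "baseline_complaints": baseline_complaints_cv,
        "baseline_categories": baseline_categories_cv,
    }
    for name, cv in cvs.items():
        if len(cv.oof_probabilities) != cohort.n_records:
            raise ValidationError(f"{name}: CV result does not match the cohort")
        if not np.array_equal(cv.fold_assignment, ga_cv.fold_assignment):
            raise ValidationError(f"{name}: fold assignment differs from the GA run")

    labels = partition_bullseye(cohort, mask)
    y = cohort.outcome
    sizes: dict[str, int] = {}
    aucs: dict[str, dict[str, float | None]] = {}
    tests: dict[str, dict[str, DeLongResult | None]] = {}
    for sub in (*SUBGROUPS, "overall"):
        sel = np.ones(len(y), dtype=bool) if sub == "overall" else labels == sub
        sizes[sub] = int(sel.sum())
        aucs[sub] = {}
        tests[sub] = {}
        defined = sizes[sub] > 0 and len(np.unique(y[sel])) == 2
        for model, cv in cvs.items():
            aucs[sub][model] = (
                _subgroup_auc(cv.oof_probabilities[sel], y[sel]) if defined else None
            )
        for baseline in MODELS[1:]:
            tests[sub][baseline] = (
                delong_compare(
                    ga_cv.oof_probabilities[sel],
                    cvs[baseline].oof_probabilities[sel],
                    y[sel],
                )
                if defined
                else None
            )
    return BullseyeReport(labels, sizes, aucs, tests)


# --------------------------------------------------------------------------
# Predicted-probability shifts
# --------------------------------------------------------------------------

@dataclass
class ShiftHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int


def probability_shifts(
    ga_cv: CVResult,
    baseline_cv: CVResult,
    subgroups: np.ndarray,
    bin_width: float = 0.01,
) -> dict[str, ShiftHistogram]:
    """Per-subgroup histograms of (GA probability - baseline probability).

    Differences lie in [-1, 1]; counts are suited to a log-scale frequency
    axis when rendered.
    """
    diffs = ga_cv.oof_probabilities - baseline_cv.oof_probabilities
    if len(diffs) != len(subgroups):
        raise ValidationError("subgroup labels must align with the CV results")
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    out = {}
    for sub in SUBGROUPS:
        d = diffs[subgroups == sub]
        counts, _ = np.histogram(d, bins=edges)
        out[sub] = ShiftHistogram(edges, counts, len(d))
    return out


def shifts_to_frame(shifts: dict[str, ShiftHistogram]) -> pd.DataFrame:
    rows = []
    for sub, h in shifts.items():
        for lo, hi, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
            if c:
                rows.append({"subgroup": sub, "bin_low": lo, "bin_high": hi, "count": int(c)})
    return pd.DataFrame(rows, columns=["subgroup", "bin_low", "bin_high", "count"])


# --------------------------------------------------------------------------
# Agreement between flattened and hierarchical selections
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementSummary:
    jointly_selected_pct: float
    jointly_excluded_pct: float
    disagreement_pct: float

    @property
    def total_agreement_pct(self) -> float:
        return self.jointly_selected_pct + self.jointly_excluded_pct


def mask_agreement(
    mask_flattened: SpecificationMask, mask_hierarchical: SpecificationMask
) -> AgreementSummary:
    """Percent of complaints jointly selected / jointly excluded / disputed."""
    a, b = mask_flattened.bits, mask_hierarchical.bits
    if len(a) != len(b):
        raise ValidationError("masks must have equal length")
    n = len(a)
    joint_sel = int(np.sum((a == 1) & (b == 1)))
    joint_exc = int(np.sum((a == 0) & (b == 0)))
    dis = n - joint_sel - joint_exc
    return AgreementSummary(
        100.0 * joint_sel / n, 100.0 * joint_exc / n, 100.0 * dis / n
    )


# --------------------------------------------------------------------------
# Selection stability of top candidate solutions
# --------------------------------------------------------------------------

@dataclass
class StabilityResult:
    inclusion_fraction: np.ndarray  # per complaint, over the top-M masks
    inconsistent_share: float       # share of complaints with fraction in (0, 1)

    @property
    def inconsistent(self) -> np.ndarray:
        return (self.inclusion_fraction > 0) & (self.inclusion_fraction < 1)


def selection_stability(hall_of_fame: list) -> StabilityResult:
    """Per-complaint inclusion frequency across the top-M candidate masks.

    Accepts a list of masks or of (mask, fitness) pairs as stored in a
    :class:`~levelopt.ga.GAResult` hall of fame.
    """
    masks = [m[0] if isinstance(m, tuple) else m for m in hall_of_fame]
    if len(masks) < 2:
        raise ValidationError("stability needs at least 2 top masks")
    if len({len(m) for m in masks}) > 1:
        raise ValidationError("masks must have equal length")
    bits = np.stack([m.bits for m in masks])
    frac = bits.mean(axis=0)
    inconsistent = (frac > 0) & (frac < 1)
    return StabilityResult(frac, float(inconsistent.mean()))


def plot_probability_shifts(shifts: dict[str, ShiftHistogram], ax_row=None):
    """Render per-subgroup shift histograms with a log-scale count axis."""
    import matplotlib.pyplot as plt

    if ax_row is None:
        _, ax_row = plt.subplots(1, len(shifts), figsize=(4 * len(shifts), 3))
    for ax, (sub, h) in zip(np.atleast_1d(ax_row), shifts.items()):
        centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2
        ax.bar(centers, h.counts, width=np.diff(h.bin_edges), align="center")
        ax.set_yscale("log")
        ax.set_title(f"{sub} (n={h.n})")
        ax.set_xlabel("probability shift")
    return ax_row
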