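import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from levelopt import (
    SpecificationMask,
    auc,
    cv_fitness,
    bullseye_report,
    delong_compare,
    mask_agreement,
    partition_bullseye,
    probability_shifts,
    selection_stability,
)
from levelopt.errors import UndefinedAUCError, ValidationError
from levelopt.evaluation import significance_stars


def correlated_fixture(seed, n_pos=15, n_neg=25):
    """Two correlated probability vectors over the same labelled patients."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], [n_pos, n_neg])
    latent = rng.standard_normal(len(y)) + 0.9 * y
    a = 1 / (1 + np.exp(-(latent + 0.5 * rng.standard_normal(len(y)))))
    b = 1 / (1 + np.exp(-(0.8 * latent + 0.5 * rng.standard_normal(len(y)))))
    return a, b, y


def stratified_paired_bootstrap_var(a, b, y, n_boot, seed):
    """Variance of AUC(a)-AUC(b) over paired resamples within each class."""
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        yy = y[idx]
        diffs[i] = auc(a[idx], yy) - auc(b[idx], yy)
    return diffs.var(ddof=1)


class TestDeLong:
    def test_self_comparison_p_is_exactly_one(self):
        a, _, y = correlated_fixture(0)
        res = delong_compare(a, a, y)
        assert res.p == 1.0 and res.z == 0.0 and res.var_diff == 0.0

    def test_auc_outputs_match_auc_operation(self):
        a, b, y = correlated_fixture(1)
        res = delong_compare(a, b, y)
        assert res.auc_a == pytest.approx(auc(a, y), abs=1e-12)
        assert res.auc_b == pytest.approx(auc(b, y), abs=1e-12)

    def test_antisymmetry(self):
        a, b, y = correlated_fixture(2)
        fwd = delong_compare(a, b, y)
        rev = delong_compare(b, a, y)
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            delong_compare([0.1, 0.2], [0.3, 0.4], [1, 1])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_variance_agrees_with_paired_bootstrap(self, seed):
        a, b, y = correlated_fixture(seed)
        res = delong_compare(a, b, y)
        boot = stratified_paired_bootstrap_var(a, b, y, 20000, seed + 100)
        assert res.var_diff == pytest.approx(boot, rel=0.12)

    def test_agrees_with_r_proc(self, tmp_path):
        """Independent cross-check against pROC's correlated-ROC test."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        a, b, y = correlated_fixture(4)
        csv = tmp_path / "scores.csv"
        pd.DataFrame({"a": a, "b": b, "y": y}).to_csv(csv, index=False)
        script = (
            "suppressMessages(library(pROC));"
            f"d <- read.csv('{csv}');"
            "ra <- roc(d$y, d$a, levels=c(0,1), direction='<', quiet=TRUE);"
            "rb <- roc(d$y, d$b, levels=c(0,1), direction='<', quiet=TRUE);"
            "t <- roc.test(ra, rb, method='delong', paired=TRUE);"
            "cat(sprintf('%.12f %.12f', t$statistic, t$p.value))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        z_r, p_r = map(float, out.stdout.split())
        res = delong_compare(a, b, y)
        assert res.z == pytest.approx(z_r, abs=1e-8)
        assert res.p == pytest.approx(p_r, abs=1e-8)

    def test_significance_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == ""


class TestBullseyePartition:
    def test_worked_example(self, abdominal_cohort, abdominal_hierarchy):
        mask = SpecificationMask.from_selected(
            abdominal_hierarchy, ["abdominal cramping"]
        )
        labels = partition_bullseye(abdominal_cohort, mask)
        by_complaint = dict(zip(
            (r.complaint for r in abdominal_cohort.records), labels
        ))
        assert by_complaint["abdominal cramping"] == "inner"
        assert by_complaint["abdominal mass"] == "middle"
        assert by_complaint["tension headache"] == "outer"

    def test_zero_and_ones_masks(self, abdominal_cohort):
        n = abdominal_cohort.hierarchy.n
        assert (partition_bullseye(abdominal_cohort, SpecificationMask.zeros(n))
                == "outer").all()
        assert (partition_bullseye(abdominal_cohort, SpecificationMask.ones(n))
                == "inner").all()

    def test_partition_sizes(self, small_cohort):
        cohort, truth = small_cohort
        mask = truth.informative_mask
        labels = partition_bullseye(cohort, mask)
        assert len(labels) == cohort.n_records
        selected = mask.bits.astype(bool)
        inner_expected = int(selected[cohort.complaint_codes].sum())
        assert int((labels == "inner").sum()) == inner_expected
        touched_cats = set(cohort.hierarchy.parent_codes[selected])
        in_touched = int(np.isin(cohort.category_codes, list(touched_cats)).sum())
        assert int(((labels == "inner") | (labels == "middle")).sum()) == in_touched


@pytest.fixture(scope="module")
def cv_trio(small_cohort):
    cohort, truth = small_cohort
    mask = truth.informative_mask
    common = dict(k=5, fold_seed=17)
    return (
        cohort, mask,
        cv_fitness(cohort, mask, "flattened", **common),
        cv_fitness(cohort, None, "complaints_only", **common),
        cv_fitness(cohort, None, "categories_only", **common),
    )


class TestBullseyeReport:
    def test_self_comparison_all_p_one(self, cv_trio):
        cohort, mask, ga, _, _ = cv_trio
        rep = bullseye_report(cohort, ga, ga, ga, mask)
        for sub in rep.delong:
            for t in rep.delong[sub].values():
                if t is not None:
                    assert t.p == 1.0

    def test_zero_mask_degenerates_to_outer(self, cv_trio):
        cohort, _, _, base_c, base_g = cv_trio
        zero = SpecificationMask.zeros(cohort.hierarchy.n)
        ga = cv_fitness(cohort, zero, "flattened", k=5, fold_seed=17)
        rep = bullseye_report(cohort, ga, base_c, base_g, zero)
        assert rep.sizes["inner"] == 0 and rep.sizes["middle"] == 0
        assert rep.sizes["outer"] == rep.sizes["overall"]
        assert rep.aucs["inner"]["ga"] is None
        assert rep.aucs["outer"]["ga"] == rep.aucs["overall"]["ga"]

    def test_report_structure(self, cv_trio):
        cohort, mask, ga, base_c, base_g = cv_trio
        rep = bullseye_report(cohort, ga, base_c, base_g, mask)
        frame = rep.to_frame()
        assert list(frame["subgroup"]) == ["inner", "middle", "outer", "overall"]
        assert {"auc_ga", "auc_baseline_complaints", "auc_baseline_categories",
                "p_ga_vs_baseline_complaints", "p_ga_vs_baseline_categories"
                } <= set(frame.columns)
        assert sum(rep.sizes[s] for s in ("inner", "middle", "outer")) == \
            rep.sizes["overall"]

    def test_mismatched_folds_rejected(self, cv_trio):
        cohort, mask, ga, base_c, base_g = cv_trio
        other = cv_fitness(cohort, mask, "flattened", k=5, fold_seed=99)
        with pytest.raises(ValidationError, match="fold"):
            bullseye_report(cohort, other, base_c, base_g, mask)


class TestProbabilityShifts:
    def test_self_shift_is_zero(self, small_cohort):
        cohort, truth = small_cohort
        mask = truth.informative_mask
        ga = cv_fitness(cohort, mask, "flattened", fold_seed=17)
        subgroups = partition_bullseye(cohort, mask)
        shifts = probability_shifts(ga, ga, subgroups)
        for sub, h in shifts.items():
            assert h.counts.sum() == h.n == (subgroups == sub).sum()
            centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2
            nonzero = h.counts > 0
            if h.n:
                assert np.abs(centers[nonzero]).max() < 0.011

    def test_counts_conserved_against_baseline(self, small_cohort):
        cohort, truth = small_cohort
        mask = truth.informative_mask
        ga = cv_fitness(cohort, mask, "flattened", fold_seed=17)
        base = cv_fitness(cohort, None, "categories_only", fold_seed=17)
        subgroups = partition_bullseye(cohort, mask)
        shifts = probability_shifts(ga, base, subgroups)
        total = sum(h.counts.sum() for h in shifts.values())
        assert total == cohort.n_records


class TestAgreement:
    def test_identical_masks(self):
        mask = SpecificationMask(np.array([1, 1, 0, 0, 0, 1, 0, 0, 0, 1]))
        s = mask_agreement(mask, mask)
        assert s.jointly_selected_pct == pytest.approx(40.0)
        assert s.jointly_excluded_pct == pytest.approx(60.0)
        assert s.disagreement_pct == 0.0

    def test_complementary_masks(self):
        a = SpecificationMask(np.array([1, 0, 1, 0]))
        b = SpecificationMask(1 - a.bits)
        assert mask_agreement(a, b).disagreement_pct == 100.0

    def test_percentages_total_100(self, rng):
        for _ in range(20):
            a = SpecificationMask(rng.integers(0, 2, 37).astype(np.uint8))
            b = SpecificationMask(rng.integers(0, 2, 37).astype(np.uint8))
            s = mask_agreement(a, b)
            assert s.jointly_selected_pct + s.jointly_excluded_pct + \
                s.disagreement_pct == pytest.approx(100.0)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            mask_agreement(SpecificationMask.zeros(3), SpecificationMask.zeros(4))


class TestStability:
    def test_identical_masks_fully_consistent(self):
        masks = [SpecificationMask.from_string("1010")] * 5
        res = selection_stability(masks)
        assert res.inconsistent_share == 0.0
        np.testing.assert_array_equal(res.inclusion_fraction, [1, 0, 1, 0])

    def test_nineteen_of_twenty_counts_as_inconsistent(self):
        masks = [SpecificationMask.from_string("10")] * 19 + \
            [SpecificationMask.from_string("00")]
        res = selection_stability(masks)
        assert res.inclusion_fraction[0] == pytest.approx(0.95)
        assert bool(res.inconsistent[0])
        assert res.inclusion_fraction[1] == 0.0 and not res.inconsistent[1]

    def test_accepts_hall_of_fame_pairs(self):
        hof = [(SpecificationMask.from_string("110"), 0.8),
               (SpecificationMask.from_string("100"), 0.7)]
        res = selection_stability(hof)
        assert res.inclusion_fraction[0] == 1.0

    def test_needs_at_least_two(self):
        with pytest.raises(ValidationError):
            selection_stability([SpecificationMask.from_string("1")])
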