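"""Evaluation statistics against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicsaga.core import DomainAnnotation, GeneTable, LoopSet, make_binned_genome
from hicsaga.evaluation import (
    bootstrap_se,
    coarsen_phases,
    domain_lengths,
    evaluate_all,
    expression_t_tests,
    gene_expression_ve,
    loop_enrichment,
    overlap,
    replication_timing_ve,
    variance_explained,
    ve_bootstrap_se,
)

RES = 100_000


def brute_force_ve(labels, signal):
    """Independent sums-of-squares evaluation."""
    pred = np.empty_like(signal, dtype=float)
    for k in set(labels.tolist()):
        sel = labels == k
        pred[sel] = signal[sel].mean()
    ss_res = sum((s - p) ** 2 for s, p in zip(signal, pred))
    ss_tot = sum((s - signal.mean()) ** 2 for s in signal)
    return 1 - ss_res / ss_tot


class TestVarianceExplained:
    def test_hand_example(self):
        ann = DomainAnnotation(np.array([1, 1, 2, 2]), 2)
        r = variance_explained(ann, np.array([0.0, 2.0, 4.0, 6.0]))
        assert r.ve == pytest.approx(0.8)
        assert r.per_label_means == {1: 1.0, 2: 5.0}

    def test_single_label_gives_zero(self):
        ann = DomainAnnotation(np.ones(10, dtype=int), 1)
        r = variance_explained(ann, np.arange(10.0))
        assert r.ve == pytest.approx(0.0, abs=1e-12)

    def test_piecewise_constant_gives_one(self):
        ann = DomainAnnotation(np.array([1, 1, 2, 2, 3]), 3)
        r = variance_explained(ann, np.array([2.0, 2.0, -1.0, -1.0, 5.0]))
        assert r.ve == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 1000)
        labels = rng.integers(1, 6, n)
        signal = rng.normal(0, 2, n)
        ann = DomainAnnotation(labels, 5)
        assert variance_explained(ann, signal).ve == pytest.approx(
            brute_force_ve(labels, signal), abs=1e-10
        )

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            labels = rng.integers(1, 4, 50)
            signal = rng.standard_cauchy(50)
            ve = variance_explained(DomainAnnotation(labels, 3), signal).ve
            assert -1e-12 <= ve <= 1 + 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 4, 200)
        signal = rng.normal(size=200)
        ann = DomainAnnotation(labels, 3)
        v0 = variance_explained(ann, signal).ve
        v1 = variance_explained(ann, -2.5 * signal + 7).ve
        assert v0 == pytest.approx(v1)

    def test_nondecreasing_under_label_refinement(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            r = np.random.default_rng(seed)
            labels = r.integers(1, 4, 300)
            signal = r.normal(size=300)
            split = labels.copy()
            ones = np.flatnonzero(labels == 1)
            split[ones[r.random(ones.size) < 0.5]] = 4
            v = variance_explained(DomainAnnotation(labels, 3), signal).ve
            vr = variance_explained(DomainAnnotation(split, 4), signal).ve
            assert vr >= v - 1e-12

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            variance_explained(DomainAnnotation(np.array([1]), 1), np.array([1.0]))
        with pytest.raises(ValueError, match="zero variance"):
            variance_explained(DomainAnnotation(np.array([1, 2]), 2), np.array([3.0, 3.0]))


class TestGeneExpressionVe:
    def test_majority_label_with_tie_to_lowest(self):
        g = make_binned_genome([("chr1", 300_000)], RES)
        ann = DomainAnnotation(np.array([1, 1, 2]), 2)
        genes = GeneTable(["g1"], ["chr1"], [0], [300_000], [5.0])
        from hicsaga.evaluation import assign_gene_labels

        _, lab = assign_gene_labels(ann, genes, g)
        assert lab[0] == 1
        ann2 = DomainAnnotation(np.array([2, 1, 0]), 2)  # tie 1 vs 2 -> 1
        _, lab2 = assign_gene_labels(ann2, genes, g)
        assert lab2[0] == 1

    def test_piecewise_constant_transformed_expression_gives_one(self):
        g = make_binned_genome([("chr1", 400_000)], RES)
        ann = DomainAnnotation(np.array([1, 1, 2, 2]), 2)
        genes = GeneTable(
            ["a", "b", "c", "d"],
            ["chr1"] * 4,
            [0, 100_000, 200_000, 300_000],
            [50_000, 150_000, 250_000, 350_000],
            [3.0, 3.0, 8.0, 8.0],
        )
        assert gene_expression_ve(ann, genes, g).ve == pytest.approx(1.0)

    def test_genes_on_unannotated_bins_dropped(self):
        g = make_binned_genome([("chr1", 300_000)], RES)
        ann = DomainAnnotation(np.array([1, 2, 0]), 2)
        genes = GeneTable(
            ["a", "b", "c"],
            ["chr1"] * 3,
            [0, 100_000, 200_000],
            [90_000, 190_000, 290_000],
            [1.0, 4.0, 9.0],
        )
        r = gene_expression_ve(ann, genes, g)
        assert r.n_used == 2


class TestReplicationTimingVe:
    def test_constant_coarsening(self):
        g = make_binned_genome([("chr1", 200_000)], RES)
        fine = np.tile([0.25, 0.75], (200, 1))
        coarse = coarsen_phases(fine, 1000, g)
        np.testing.assert_allclose(coarse, [[0.25, 0.75], [0.25, 0.75]])

    def test_mean_over_phases(self):
        g = make_binned_genome([("chr1", 600_000)], RES)
        rng = np.random.default_rng(0)
        ann = DomainAnnotation(np.array([1, 1, 2, 2, 1, 2]), 2)
        fine = rng.dirichlet(np.ones(6), size=600)
        r = replication_timing_ve(ann, fine, 1000, g)
        finite = [v for v in r.per_phase if np.isfinite(v)]
        assert r.ve == pytest.approx(np.mean(finite))
        assert len(r.per_phase) == 6

    def test_degenerate_phase_excluded_with_warning(self):
        g = make_binned_genome([("chr1", 400_000)], RES)
        ann = DomainAnnotation(np.array([1, 2, 1, 2]), 2)
        fine = np.zeros((400, 2))
        fine[:, 0] = 1.0  # all mass in phase 1 -> both coarse tracks constant
        with pytest.warns(UserWarning, match="degenerate"):
            with pytest.raises(ValueError, match="no replication-timing phase"):
                replication_timing_ve(ann, fine, 1000, g, n_phases=2)

    def test_renormalization_excludes_zero_mass_bins(self):
        g = make_binned_genome([("chr1", 300_000)], RES)
        fine = np.zeros((300, 2))
        fine[:100, 0] = 3.0  # bin 0 only has mass
        fine[100:200, 1] = 1.0
        coarse = coarsen_phases(fine, 1000, g)
        np.testing.assert_allclose(coarse[0], [1.0, 0.0])
        np.testing.assert_allclose(coarse[2], [0.0, 0.0])


class TestLoopEnrichment:
    def _genome(self, n):
        return make_binned_genome([("chr1", n * RES)], RES)

    def _loop(self, b1, b2):
        return (
            ("chr1", b1 * RES + 40_000, b1 * RES + 60_000),
            ("chr1", b2 * RES + 40_000, b2 * RES + 60_000),
        )

    def test_hand_example_equal_coverage_all_same_label(self):
        g = self._genome(4)
        ann = DomainAnnotation(np.array([1, 1, 2, 2]), 2)
        pairs = [self._loop(0, 1)] * 5 + [self._loop(2, 3)] * 5
        loops = LoopSet([p[0] for p in pairs], [p[1] for p in pairs])
        e = loop_enrichment(ann, loops, g)
        assert np.trace(e.expected) == pytest.approx(5.0)
        assert np.trace(e.observed) == 10
        assert e.oe_score == pytest.approx(2.0)

    def test_all_cross_label_loops_score_zero(self):
        g = self._genome(4)
        ann = DomainAnnotation(np.array([1, 1, 2, 2]), 2)
        pairs = [self._loop(0, 2), self._loop(1, 3)]
        loops = LoopSet([p[0] for p in pairs], [p[1] for p in pairs])
        assert loop_enrichment(ann, loops, g).oe_score == pytest.approx(0.0)

    def test_single_label_always_one(self):
        g = self._genome(3)
        ann = DomainAnnotation(np.array([1, 1, 1]), 1)
        loops = LoopSet(*zip(*[self._loop(0, 1), self._loop(1, 2)]))
        loops = LoopSet(list(loops.anchor1), list(loops.anchor2))
        assert loop_enrichment(ann, loops, g).oe_score == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_expected_mass_sums_to_total(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        g = self._genome(n)
        ann = DomainAnnotation(rng.integers(1, 5, n), 4)
        pairs = [self._loop(*rng.integers(0, n, 2)) for _ in range(100)]
        loops = LoopSet([p[0] for p in pairs], [p[1] for p in pairs])
        e = loop_enrichment(ann, loops, g)
        assert e.expected.sum() == pytest.approx(e.total, abs=1e-9)
        assert e.observed.sum() == e.total

    def test_score_invariant_under_label_permutation(self):
        rng = np.random.default_rng(7)
        n = 40
        g = self._genome(n)
        labels = rng.integers(1, 4, n)
        pairs = [self._loop(*rng.integers(0, n, 2)) for _ in range(80)]
        loops = LoopSet([p[0] for p in pairs], [p[1] for p in pairs])
        s0 = loop_enrichment(DomainAnnotation(labels, 3), loops, g).oe_score
        lut = np.array([0, 3, 1, 2])
        s1 = loop_enrichment(DomainAnnotation(lut[labels], 3), loops, g).oe_score
        assert s0 == pytest.approx(s1)

    def test_dropped_anchor_counted(self):
        g = self._genome(3)
        ann = DomainAnnotation(np.array([1, 0, 1]), 1)
        loops = LoopSet(*map(list, zip(*[self._loop(0, 1), self._loop(0, 2)])))
        e = loop_enrichment(ann, loops, g)
        assert e.n_dropped == 1 and e.total == 1


class TestBootstrap:
    def test_degenerate_statistic_gives_zero_se(self):
        se = bootstrap_se(lambda idx: 1.23, 100, 50, seed=0)
        assert se == 0.0

    def test_single_label_ve_replicates_all_zero(self):
        rng = np.random.default_rng(0)
        ann = DomainAnnotation(np.ones(500, dtype=int), 1)
        se = ve_bootstrap_se(ann, rng.normal(size=500), n_reps=20, seed=1)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_se_of_mean_matches_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 400)
        se = bootstrap_se(lambda idx: x[idx].mean(), 400, 500, seed=4)
        assert se == pytest.approx(1 / np.sqrt(400), rel=0.2)

    def test_mostly_undefined_statistic_raises(self):
        def bad(idx):
            raise ValueError("undefined")

        with pytest.raises(ValueError, match="replicates"):
            bootstrap_se(bad, 10, 10, seed=0)


class TestOverlap:
    def test_identical_annotations_closed_form(self):
        labels = np.array([1, 1, 1, 2, 2, 3])
        ann = DomainAnnotation(labels, 3)
        r = overlap(ann, ann)
        cov = ann.coverage
        np.testing.assert_allclose(np.diag(r.fold_change), 1 / cov)
        off = r.fold_change[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)
        assert r.ari == pytest.approx(1.0)

    def test_independent_labelings_near_null(self):
        rng = np.random.default_rng(0)
        n = 100_000
        a = DomainAnnotation(rng.integers(1, 5, n), 4)
        b = DomainAnnotation(rng.integers(1, 5, n), 4)
        r = overlap(a, b)
        assert np.all(np.abs(r.fold_change - 1.0) < 0.1)
        assert abs(r.ari) < 0.01

    def test_fold_change_rows_permute_with_labels(self):
        rng = np.random.default_rng(1)
        la = rng.integers(1, 4, 500)
        lb = rng.integers(1, 3, 500)
        r0 = overlap(DomainAnnotation(la, 3), DomainAnnotation(lb, 2))
        lut = np.array([0, 2, 3, 1])
        r1 = overlap(DomainAnnotation(lut[la], 3), DomainAnnotation(lb, 2))
        for old in (1, 2, 3):
            np.testing.assert_allclose(r1.fold_change[lut[old] - 1], r0.fold_change[old - 1])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        labels=st.lists(st.integers(1, 3), min_size=8, max_size=30),
        perm=st.permutations([1, 2, 3]),
    )
    def test_ari_one_iff_identical_up_to_permutation(self, labels, perm):
        la = np.array(labels)
        lut = np.array([0] + list(perm))
        a = DomainAnnotation(la, 3)
        b = DomainAnnotation(lut[la], 3)
        assert overlap(a, b).ari == pytest.approx(1.0)


class TestEvaluateAll:
    def test_run_length_statistics(self):
        g = make_binned_genome([("chr1", 500_000)], RES)
        ann = DomainAnnotation(np.array([1, 1, 1, 2, 2]), 2)
        lens = domain_lengths(ann, g)
        assert lens.tolist() == [300_000, 200_000]
        rep = evaluate_all(ann, g)
        assert rep["domain_lengths_bp"]["mean"] == pytest.approx(250_000)

    def test_report_round_trips_through_json(self, tmp_path):
        import json

        g = make_binned_genome([("chr1", 500_000)], RES)
        ann = DomainAnnotation(np.array([1, 1, 2, 2, 1]), 2)
        rng = np.random.default_rng(0)
        rep = evaluate_all(ann, g, signals=rng.normal(size=(5, 2)))
        p = tmp_path / "r.json"
        p.write_text(json.dumps(rep))
        assert json.loads(p.read_text()) == json.loads(json.dumps(rep))

    def test_missing_inputs_noted_not_fatal(self):
        g = make_binned_genome([("chr1", 300_000)], RES)
        ann = DomainAnnotation(np.array([1, 2, 1]), 2)
        rep = evaluate_all(ann, g)
        assert "no genes provided" in rep["notes"]

    def test_expression_t_tests_detect_group_difference(self):
        g = make_binned_genome([("chr1", 2_000_000)], RES)
        labels = np.array([1] * 10 + [2] * 10)
        ann = DomainAnnotation(labels, 2)
        rng = np.random.default_rng(0)
        starts = np.arange(20) * RES + 10_000
        expr = np.where(np.arange(20) < 10, 50.0, 0.5) * rng.uniform(0.9, 1.1, 20)
        genes = GeneTable(
            [f"g{i}" for i in range(20)], ["chr1"] * 20, starts, starts + 50_000, expr
        )
        p = expression_t_tests(ann, genes, g)
        assert p[(1, 2)] < 1e-6
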