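"""Hypergeometric tail test, BH adjustment, and the overlap analysis runner."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from _oracles import bh_bruteforce, exhaustive_hypergeom_tail
from genora.curation import TargetList
from genora.enrichment import (
    AnalysisConfig,
    DomainError,
    bh_adjust,
    format_pvalue,
    hypergeom_tail,
    read_results_csv,
    run_overlap_analysis,
    run_overlap_analyses,
    write_results_csv,
)
from genora.genesets import GO, PUBLICATION, BackgroundRegistry, GeneSet, GeneSetCollection


class TestHypergeomTail:
    def test_k_zero_is_one(self):
        assert hypergeom_tail(0, 5, 4, 10) == 1.0

    def test_small_case_matches_exhaustive_enumeration(self):
        # C(5,3)C(5,1) + C(5,4)C(5,0) = 55 of C(10,4) = 210 draws
        assert hypergeom_tail(3, 5, 4, 10) == pytest.approx(55 / 210, abs=1e-12)
        assert float(exhaustive_hypergeom_tail(3, 5, 4, 10)) == pytest.approx(55 / 210)

    def test_all_population_marked_gives_one(self):
        assert hypergeom_tail(7, 9, 7, 9) == 1.0
        assert hypergeom_tail(3, 8, 3, 8) == 1.0

    @pytest.mark.parametrize(
        "k,K,n,N",
        [(1, 5, 4, 3), (1, 2, 5, 4), (4, 3, 5, 10), (-1, 3, 5, 10), (3, 2, 2, 10)],
    )
    def test_domain_errors(self, k, K, n, N):
        with pytest.raises(DomainError):
            hypergeom_tail(k, K, n, N)

    def test_matches_scipy_survival_function(self):
        """Independent route: scipy's sf(k-1) on a moderate grid."""
        for (k, K, n, N) in [(3, 50, 40, 500), (10, 42, 1378, 17600),
                             (22, 315, 1378, 17600), (1, 17, 458, 17600),
                             (5, 100, 500, 10000)]:
            expected = float(hypergeom(N, K, n).sf(k - 1))
            assert hypergeom_tail(k, K, n, N) == pytest.approx(expected, rel=1e-9)

    def test_non_increasing_in_k(self):
        values = [hypergeom_tail(k, 30, 50, 200) for k in range(0, 31)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_complementarity_of_upper_and_lower_tails(self):
        # P(X >= k) + P(X <= k-1) = 1, the lower tail expressed through the
        # complementary count Y = n - X ~ Hypergeom(N, N-K, n)
        for (k, K, n, N) in [(5, 30, 50, 200), (2, 10, 20, 60), (12, 40, 80, 150)]:
            upper = hypergeom_tail(k, K, n, N)
            lower = hypergeom_tail(n - k + 1, N - K, n, N)
            assert upper + lower == pytest.approx(1.0, abs=1e-10)

    def test_extreme_tail_stays_positive_and_accurate(self):
        """Log-space accumulation keeps ~1e-26 scale values representable."""
        for k, ceiling in [(73, 1e-15), (90, 1e-26), (120, 1e-50)]:
            p = hypergeom_tail(k, 315, 1378, 17600)
            assert 0 < p < ceiling
            expected_log = hypergeom(17600, 315, 1378).logsf(k - 1)
            assert math.log(p) == pytest.approx(float(expected_log), rel=1e-6)


class TestBHAdjust:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.04]) == [0.04]

    def test_uniform_spacing_example(self):
        # step-up by hand: adj = min suffix of (p_(j) * 4 / j) = 0.04 for all
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_two_value_example(self):
        assert bh_adjust([0.005, 0.1]) == pytest.approx([0.01, 0.1])

    def test_empty_input(self):
        assert bh_adjust([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(
        p=st.lists(
            st.floats(1e-12, 1.0, exclude_min=False, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_bruteforce_definition(self, p):
        adj = bh_adjust(p)
        brute = bh_bruteforce(p)
        assert adj == pytest.approx(brute, abs=1e-12)
        assert all(a >= x for a, x in zip(adj, p))
        assert all(a <= 1.0 for a in adj)


def test_format_pvalue_three_significant_digits():
    assert format_pvalue(1.8986e-4) == "1.90E-04"
    assert format_pvalue(1.39e-5) == "1.39E-05"
    assert format_pvalue(1.0) == "1.00E+00"


def small_world():
    universe = frozenset(f"G{i}" for i in range(40))
    registry = BackgroundRegistry(universes={GO: universe})
    sets = GeneSetCollection(
        source=GO,
        sets=[
            GeneSet("inA", frozenset({"G0", "G1", "G2", "G3"}), source=GO),
            GeneSet("outB", frozenset({"G30", "G31"}), source=GO),
        ],
    )
    target = TargetList("A", "toy", frozenset({"G0", "G1", "G2", "G10"}))
    return target, sets, registry


class TestRunOverlapAnalysis:
    def test_disjoint_target_all_pvalues_one(self):
        _, sets, registry = small_world()
        target = TargetList("A", "toy", frozenset({"G20", "G21"}))
        results = run_overlap_analysis(target, [sets], registry)
        assert all(r.k == 0 and r.p_raw == 1.0 and r.p_adj == 1.0 for r in results)

    def test_single_set_adjusted_equals_raw(self):
        target, sets, registry = small_world()
        single = GeneSetCollection(source=GO, sets=[sets.sets[0]])
        (res,) = run_overlap_analysis(target, [single], registry)
        assert res.p_adj == res.p_raw == pytest.approx(hypergeom_tail(3, 4, 4, 40))
        assert res.overlap_genes == ["G0", "G1", "G2"]

    def test_results_preserve_input_order_and_sorted_genes(self):
        target, sets, registry = small_world()
        results = run_overlap_analysis(target, [sets], registry)
        assert [r.set_name for r in results] == ["inA", "outB"]
        for r in results:
            assert r.overlap_genes == sorted(r.overlap_genes)

    def test_intersect_policy_restricts_n(self):
        universe = frozenset(f"G{i}" for i in range(10))
        registry = BackgroundRegistry(universes={GO: universe})
        sets = GeneSetCollection(source=GO, sets=[GeneSet("s", frozenset({"G1"}), source=GO)])
        # target has 2 genes outside the universe
        target = TargetList("A", "toy", frozenset({"G1", "G2", "X1", "X2"}))
        (res_int,) = run_overlap_analysis(
            target, [sets], registry, AnalysisConfig(target_universe_policy="intersect_background")
        )
        assert res_int.n == 2
        (res_raw,) = run_overlap_analysis(
            target, [sets], registry, AnalysisConfig(target_universe_policy="raw")
        )
        assert res_raw.n == 4
        assert res_raw.p_raw > res_int.p_raw  # larger n makes the overlap likelier

    def test_set_larger_than_background_rejected(self):
        registry = BackgroundRegistry(universes={GO: frozenset({"G1", "G2"})})
        sets = GeneSetCollection(
            source=GO, sets=[GeneSet("big", frozenset({"G1", "G2", "X3"}), source=GO)]
        )
        target = TargetList("A", "toy", frozenset({"G1"}))
        with pytest.raises(DomainError, match="background"):
            run_overlap_analysis(target, [sets], registry)

    def test_publication_set_uses_fallback_background(self):
        universe_go = frozenset(f"G{i}" for i in range(30))
        registry = BackgroundRegistry(
            universes={GO: universe_go, "Reactome": frozenset(list(universe_go)[:10])}
        )
        sets = GeneSetCollection(
            source=PUBLICATION,
            sets=[GeneSet("causal", frozenset({"G0", "G1"}), source=PUBLICATION)],
        )
        target = TargetList("A", "toy", frozenset({"G0", "G5"}))
        (res,) = run_overlap_analysis(target, [sets], registry)
        assert res.N == 30

    def test_correction_families_differ_for_multiple_targets(self):
        target, sets, registry = small_world()
        other = TargetList("A", "toy2", frozenset({"G0", "G30", "G31"}))
        per_list = run_overlap_analyses(
            [target, other], [sets], registry,
            AnalysisConfig(correction_family="per_target_list"),
        )
        per_run = run_overlap_analyses(
            [target, other], [sets], registry,
            AnalysisConfig(correction_family="per_run"),
        )
        assert set(per_list) == set(per_run) == {"toy", "toy2"}
        # same raw p-values either way
        for label in per_list:
            assert [r.p_raw for r in per_list[label]] == [r.p_raw for r in per_run[label]]
        # pooled family has m=4 instead of 2, so some adjusted value changes
        flat_list = [r.p_adj for rs in per_list.values() for r in rs]
        flat_run = [r.p_adj for rs in per_run.values() for r in rs]
        assert flat_list != flat_run

    def test_results_csv_round_trip(self, tmp_path):
        target, sets, registry = small_world()
        results = run_overlap_analysis(target, [sets], registry)
        path = write_results_csv(results, tmp_path / "res.csv")
        back = read_results_csv(path)
        assert [(r.set_name, r.k, r.overlap_genes) for r in back] == [
            (r.set_name, r.k, r.overlap_genes) for r in results
        ]
        assert [r.p_adj for r in back] == pytest.approx([r.p_adj for r in results])


def test_null_instance_raw_pvalues_are_conservative():
    """Under simple random sampling (rho=1) the raw p-value distribution
    should not be anti-conservative: P(p <= alpha) <= alpha + 3 binomial SE."""
    from genora.synthetic import SyntheticConfig, make_instance

    alpha = 0.05
    pvals = []
    for seed in range(40):
        config = SyntheticConfig(
            universe_sizes={"SYN": 2000},
            set_sizes={f"S{i}": 60 for i in range(5)},
            target_size=150,
            seed=seed,
        )
        inst = make_instance(config)
        results = run_overlap_analysis(inst.target, inst.collections, inst.registry)
        pvals.extend(r.p_raw for r in results)
    rate = np.mean([p <= alpha for p in pvals])
    bound = alpha + 3 * math.sqrt(alpha * (1 - alpha) / len(pvals))
    assert rate <= bound
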