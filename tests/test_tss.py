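"""TSS candidate calling, reproducibility, clustering and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from arraychrom import (TSSCallParams, call_candidates, call_tss,
                        classify_tss, cluster_candidates,
                        differential_tss_stub, keep_reproducible, mask_region,
                        quantify_windows)
from arraychrom.genome import Feature
from arraychrom.tss import TSSCluster, build_clusters
from conftest import make_coverage

PARAMS = TSSCallParams()


class TestCallCandidates:
    def test_flat_track_yields_nothing(self):
        cov = make_coverage(50, plus=[(i, 100) for i in range(50)])
        cand = call_candidates(cov, PARAMS)
        assert cand["+"].size == 0 and cand["-"].size == 0

    @pytest.mark.parametrize("prev,cur,expected", [
        (4, 25, True),    # increase 21 > 20 and fold 6.25 > 5
        (10, 31, False),  # increase 21 but fold only 3.1
        (0, 21, True),    # zero predecessor passes the fold criterion
        (0, 20, False),   # increase 20 is not > 20
        (4, 24, False),   # increase exactly 20, strict
    ])
    def test_candidate_rule(self, prev, cur, expected):
        cov = make_coverage(100, plus=[(49, prev), (50, cur)])
        cand = call_candidates(cov, PARAMS)
        assert (50 in cand["+"]) is expected

    def test_minus_strand_preceding_is_downstream_coordinate(self):
        # on the minus strand 5'->3' runs toward lower coordinates, so the
        # preceding position of i is i+1
        cov = make_coverage(100, minus=[(51, 4), (50, 25)])
        cand = call_candidates(cov, PARAMS)
        assert 50 in cand["-"]
        assert 51 not in cand["-"]

    def test_circular_wrap_of_preceding_position(self):
        cov = make_coverage(100, plus=[(99, 4), (0, 25)], circular=True)
        assert 0 in call_candidates(cov, PARAMS)["+"]
        cov = make_coverage(100, plus=[(99, 100), (0, 25)], circular=True)
        assert 0 not in call_candidates(cov, PARAMS)["+"]

    def test_absolute_count_mode_toggle(self):
        params = TSSCallParams(count_mode="absolute")
        cov = make_coverage(100, plus=[(49, 4), (50, 25)])
        assert 50 in call_candidates(cov, params)["+"]
        cov2 = make_coverage(100, plus=[(49, 100), (50, 119)])
        # difference 19 fails "increase" mode but count 119 passes "absolute"
        assert 50 not in call_candidates(cov2, PARAMS)["+"]
        # fold criterion still applies in absolute mode
        assert 50 not in call_candidates(cov2, params)["+"]

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_thresholds(self, seed):
        """Raising abs_min or fold_min never adds candidates."""
        rng = np.random.default_rng(seed)
        cov = make_coverage(200, plus=[(i, c) for i, c in
                                       enumerate(rng.poisson(8, 200))])
        base = set(call_candidates(cov, TSSCallParams())["+"])
        stricter_abs = set(call_candidates(
            cov, TSSCallParams(abs_min=30))["+"])
        stricter_fold = set(call_candidates(
            cov, TSSCallParams(fold_min=8))["+"])
        assert stricter_abs <= base
        assert stricter_fold <= base


class TestKeepReproducible:
    def test_two_of_four_kept_one_dropped(self):
        sets = [{"+": np.array([100, 200])}, {"+": np.array([100])},
                {"+": np.array([300])}, {"+": np.array([400])}]
        out = keep_reproducible(sets, min_samples=2)
        assert out["+"].tolist() == [100]

    def test_min_samples_one_is_union(self):
        sets = [{"+": np.array([1])}, {"+": np.array([2])}]
        assert keep_reproducible(sets, 1)["+"].tolist() == [1, 2]

    def test_strand_matched(self):
        sets = [{"+": np.array([100]), "-": np.array([])},
                {"+": np.array([]), "-": np.array([100])}]
        out = keep_reproducible(sets, 2)
        assert out["+"].size == 0 and out["-"].size == 0

    def test_too_few_sets_rejected(self):
        with pytest.raises(ValueError):
            keep_reproducible([{"+": np.array([1])}], min_samples=2)


def oracle_single_linkage(positions, gap):
    """Brute-force chaining oracle: independent of the implementation."""
    clusters = []
    for p in sorted(positions):
        if clusters and p - clusters[-1][-1] < gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


class TestClusterCandidates:
    @pytest.mark.parametrize("positions,expected_centres", [
        ([1000, 1002, 1004], [1002]),
        ([1000, 1005], [1000, 1005]),  # gap of 5 is NOT < 5: two clusters
        ([500], [500]),
        ([100, 103], [101]),           # even count: round toward lower
    ])
    def test_examples(self, positions, expected_centres):
        out = cluster_candidates(np.array(positions), cluster_gap=5)
        assert [c for c, _ in out] == expected_centres

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 500), max_size=40), st.integers(1, 10))
    def test_matches_oracle_and_partitions(self, positions, gap):
        out = cluster_candidates(np.array(sorted(positions)), gap)
        oracle = oracle_single_linkage(positions, gap)
        assert [list(m) for _, m in out] == oracle
        flat = [p for _, members in out for p in members]
        assert sorted(flat) == sorted(positions)  # partition-complete
        for centre, members in out:
            assert centre == int(np.floor(np.median(members)))

    def test_idempotent_on_centres(self):
        out = cluster_candidates(np.array([10, 11, 12, 40, 41]), 5)
        centres = np.array([c for c, _ in out])
        again = cluster_candidates(centres, 5)
        assert [c for c, _ in again] == centres.tolist()


class TestQuantifyWindows:
    def test_delta_and_uniform_tracks(self):
        cl = TSSCluster("chr", 50, "+", (50,))
        delta = make_coverage(101, plus=[(50, 30)])
        quantify_windows({"s": delta}, [cl], window=11)
        assert cl.counts["s"] == 30.0
        uniform = make_coverage(101, plus=[(i, 1) for i in range(101)])
        quantify_windows({"u": uniform}, [cl], window=11)
        assert cl.counts["u"] == 11.0

    def test_hand_summed_toy_window(self, rng):
        vals = rng.integers(0, 20, size=21)
        cov = make_coverage(21, plus=[(i, v) for i, v in enumerate(vals)])
        cl = TSSCluster("chr", 10, "+", (10,))
        quantify_windows({"s": cov}, [cl], window=11)
        assert cl.counts["s"] == float(vals[5:16].sum())

    def test_window_wraps_on_circular_replicon(self):
        cov = make_coverage(100, plus=[(99, 7), (0, 5)], circular=True)
        cl = TSSCluster("chr", 0, "+", (0,))
        quantify_windows({"s": cov}, [cl], window=11)
        assert cl.counts["s"] == 12.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            quantify_windows({}, [], window=10)


def _operon(start, end, strand, oid):
    return Feature("operon", start, end, strand, oid)


def _cds(start, end, strand, cid, parent):
    return Feature("CDS", start, end, strand, cid, parent)


class TestClassifyTSS:
    def setup_method(self):
        self.operons = [_operon(1000, 1600, "+", "op1")]
        self.cds = [_cds(1000, 1600, "+", "op1_cds1", "op1")]

    def test_primary_leaderless(self):
        cl = TSSCluster("chr", 998, "+", (998,), counts={"s": 50.0})
        out = classify_tss([cl], self.operons, self.cds)
        assert cl.tss_class == "primary"
        assert cl.utr_length == 2
        assert cl.leaderless is True

    def test_long_utr_not_leaderless(self):
        cl = TSSCluster("chr", 950, "+", (950,), counts={"s": 50.0})
        classify_tss([cl], self.operons, self.cds)
        assert cl.tss_class == "primary" and cl.leaderless is False
        assert cl.utr_length == 50

    def test_internal_sense_when_not_primary(self):
        primary = TSSCluster("chr", 998, "+", (998,), counts={"s": 90.0})
        internal = TSSCluster("chr", 1300, "+", (1300,), counts={"s": 10.0})
        classify_tss([primary, internal], self.operons, self.cds)
        assert primary.tss_class == "primary"
        assert internal.tss_class == "internal_sense"

    def test_antisense_inside_gene_body(self):
        cl = TSSCluster("chr", 1300, "-", (1300,))
        classify_tss([cl], self.operons, self.cds)
        assert cl.tss_class == "antisense"

    def test_intergenic_otherwise(self):
        cl = TSSCluster("chr", 5000, "+", (5000,))
        classify_tss([cl], self.operons, self.cds)
        assert cl.tss_class == "intergenic"

    def test_minus_strand_operon_utr(self):
        operons = [_operon(2000, 2600, "-", "op2")]
        cds = [_cds(2000, 2600, "-", "op2_cds1", "op2")]
        cl = TSSCluster("chr", 2604, "-", (2604,), counts={"s": 5.0})
        classify_tss([cl], operons, cds)
        assert cl.tss_class == "primary"
        assert cl.utr_length == 5  # CDS start is at coordinate 2599
        assert cl.leaderless is False

    def test_every_cluster_gets_exactly_one_class(self, small_genome, rng):
        centres = rng.integers(0, small_genome.length, size=60)
        clusters = [TSSCluster("chr", int(c), "+" if i % 2 else "-",
                               (int(c),)) for i, c in enumerate(centres)]
        classify_tss(clusters, small_genome.features_of("operon"),
                     small_genome.features_of("CDS"))
        assert all(c.tss_class in ("primary", "internal_sense", "antisense",
                                   "intergenic") for c in clusters)

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            classify_tss([TSSCluster("chr", 1, ".", (1,))], [], [])


class TestMaskRegion:
    def test_mask_boundaries(self):
        clusters = [TSSCluster("chr", c, "+", (c,)) for c in (99, 100, 149,
                                                              150)]
        out = mask_region(clusters, [(100, 150)])
        assert [c.centre for c in out] == [99, 150]

    def test_empty_mask_is_identity(self):
        clusters = [TSSCluster("chr", 5, "+", (5,))]
        assert mask_region(clusters, []) == clusters


class TestDifferentialStub:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["a1", "a2", "b1", "b2"])

    def test_equal_counts_zero_log2fc(self):
        counts = self._frame([[50, 50, 50, 50], [10, 10, 10, 10]])
        out = differential_tss_stub(counts, {"a1": "A", "a2": "A",
                                             "b1": "B", "b2": "B"})
        np.testing.assert_allclose(out["log2fc"], 0.0)

    def test_doubling_at_equal_depth(self):
        # equal library sizes, one cluster doubled; large counts make the
        # +1 pseudocount negligible
        counts = self._frame([[20000, 20000, 10000, 10000],
                              [10000, 10000, 20000, 20000]])
        out = differential_tss_stub(counts, {"a1": "A", "a2": "A",
                                             "b1": "B", "b2": "B"})
        assert out["log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-3)
        assert out["log2fc"].iloc[1] == pytest.approx(-1.0, abs=1e-3)

    def test_pvalue_matches_exact_binomial_enumeration(self):
        counts = pd.DataFrame([[10, 40]], columns=["a1", "b1"])
        # make libraries equal so the null proportion is 1/2
        counts.loc[1] = [1000, 970]
        out = differential_tss_stub(counts, {"a1": "A", "b1": "B"})
        pmf = stats.binom.pmf(np.arange(51), 50, 0.5)
        oracle = pmf[pmf <= pmf[10] * (1 + 1e-9)].sum()
        assert out["pvalue"].iloc[0] == pytest.approx(oracle, rel=1e-9)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame([[0, 5]], columns=["a1", "b1"])
        with pytest.raises(ValueError):
            differential_tss_stub(counts, {"a1": "A", "b1": "B"})


class TestFullCaller:
    def test_planted_tss_recovered_from_two_samples(self):
        truth = [(500, "+", 60.0), (1500, "-", 60.0)]
        from arraychrom import simulate_end_coverage
        samples = {
            f"s{i}": simulate_end_coverage(2000, truth, 20000, jitter=0,
                                           background_rate=1.0, seed=i)
            for i in (1, 2)}
        clusters = call_tss(samples, TSSCallParams())
        found = {(c.centre, c.strand) for c in clusters}
        assert (500, "+") in found and (1500, "-") in found
        assert all(c.counts["s1"] > 0 for c in clusters)
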