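import numpy as np
import pandas as pd
import pytest

from mbtemporal import profiling
from mbtemporal.profiling import (
    alpha_diversity, build_qmp, choose_target_depth, corrected_depth,
    filter_genera, rarefy_reads,
)
from tests.conftest import make_table


class TestRarefaction:
    def test_identity_at_full_depth(self, rng):
        row = np.array([5, 3, 2])
        out = rarefy_reads(row, 10, rng)
        assert (out == row).all()

    def test_below_depth_returns_none(self, rng):
        assert rarefy_reads(np.array([3, 1]), 10, rng) is None

    def test_hypergeometric_expectation(self, rng):
        """{A:80, B:20} at depth 50: mean(A) -> 40, every draw sums to 50."""
        draws = np.array([rarefy_reads(np.array([80, 20]), 50, rng)
                          for _ in range(10000)])
        assert (draws.sum(axis=1) == 50).all()
        assert (draws <= np.array([80, 20])).all()
        assert draws[:, 0].mean() == pytest.approx(40.0, abs=0.15)

    def test_seed_reproducible(self):
        r1 = rarefy_reads(np.arange(1, 20), 50, np.random.default_rng(4))
        r2 = rarefy_reads(np.arange(1, 20), 50, np.random.default_rng(4))
        assert (r1 == r2).all()


class TestCorrectedDepth:
    def test_unit_copy_numbers(self):
        assert corrected_depth([10, 20, 30], [1, 1, 1]) == 60

    def test_mean_copy_number_scaling(self):
        """~2000 raw reads at the 3.88 average copy number = 500 corrected."""
        counts = np.full(10, 194.0)  # total 1940
        cn = np.full(10, 3.88)
        assert corrected_depth(counts, cn) == pytest.approx(500.0)

    def test_hand_arithmetic(self):
        assert corrected_depth([10, 9], [2, 3]) == pytest.approx(8.0)


class TestQMPOptimization:
    def _table(self, corrected_totals):
        # one genus, cn=1 so corrected depth == raw total
        ab = np.array(corrected_totals, dtype=int)[:, None]
        return make_table(ab, [f"p{i}" for i in range(len(ab))],
                          [0] * len(ab))

    def test_optimum_retains_all_three(self):
        """Depths [20000, 4000, 30000] / loads [1e10,1e10,2e10]: D = 4e-7
        keeps all samples with rarefied totals 4000/4000/8000."""
        table = self._table([20000, 4000, 30000])
        loads = pd.Series([1e10, 1e10, 2e10], index=table.sample_ids)
        cn = pd.Series(1.0, index=table.genus_ids)
        build = build_qmp(table, cn, loads, min_reads=500, seed=0)
        assert build.target_depth == pytest.approx(4e-7)
        assert len(build.retained) == 3
        rarefied_totals = [round(build.target_depth * loads[s]) for s in build.retained]
        assert rarefied_totals == [4000, 4000, 8000]

    def test_low_read_sample_dropped(self):
        """With sample 2 at 400 corrected reads, the optimum moves to
        D = 1.5e-6 retaining samples 1 and 3."""
        table = self._table([20000, 400, 30000])
        loads = pd.Series([1e10, 1e10, 2e10], index=table.sample_ids)
        cn = pd.Series(1.0, index=table.genus_ids)
        build = build_qmp(table, cn, loads, min_reads=500, seed=0)
        assert build.target_depth == pytest.approx(1.5e-6)
        assert set(build.retained) == {"s0", "s2"}
        reasons = dict(zip(build.excluded["sample_id"], build.excluded["reason"]))
        assert reasons["s1"] == "low_reads"

    def test_optimizer_matches_brute_force(self, rng):
        """Retained-set size equals the exhaustive maximum over candidates."""
        for _ in range(300):
            n = int(rng.integers(2, 12))
            d_s = rng.uniform(1e-7, 5e-6, size=n)
            loads = rng.uniform(5e9, 5e11, size=n)
            min_reads = 500
            try:
                D, mask = choose_target_depth(d_s, loads, min_reads)
            except ValueError:
                best = max(
                    int(((d_s >= c) & (np.round(c * loads) >= min_reads)).sum())
                    for c in d_s)
                assert best == 0
                continue
            brute = max(
                int(((d_s >= c) & (np.round(c * loads) >= min_reads)).sum())
                for c in np.unique(d_s))
            assert int(mask.sum()) == brute
            assert (np.round(D * loads[mask]) >= min_reads).all()

    def test_qmp_unit_and_row_scaling(self, small_qmp, small_cohort):
        cohort, _ = small_cohort
        q = small_qmp.qmp
        assert q.unit == "cells_per_gram"
        loads = cohort.meta.loc[q.sample_ids, "load"]
        assert np.allclose(q.abundance.sum(axis=1), loads)

    def test_qmp_inverts_copy_number_distortion(self):
        """At high depth the QMP recovers the relative cell composition
        (total variation distance < 1e-2)."""
        from mbtemporal.synthetic import CohortSpec, generate_cohort

        spec = CohortSpec(n_participants=4, n_days=6, n_genera=25, seed=13,
                          read_depth=400000, detect_frac=0.0, miss_prob=0.0)
        cohort, truth = generate_cohort(spec)
        build = build_qmp(cohort.table, cohort.copy_numbers,
                          cohort.meta["load"], seed=1)
        qrel = build.qmp.relative()
        trel = truth.true_cells.div(truth.true_cells.sum(axis=1), axis=0)
        tvd = 0.5 * (qrel - trel.loc[qrel.index, qrel.columns]).abs().sum(axis=1)
        assert tvd.mean() < 1e-2


class TestAlphaDiversity:
    def test_two_equal_genera(self):
        a = alpha_diversity([5, 5])
        assert a.richness == 2
        assert a.shannon == pytest.approx(np.log(2))
        assert a.pielou == pytest.approx(1.0)

    def test_single_genus(self):
        a = alpha_diversity([7, 0])
        assert (a.richness, a.shannon, a.pielou) == (1, 0.0, None)

    def test_hand_arithmetic(self):
        a = alpha_diversity([3, 1])
        assert a.shannon == pytest.approx(0.5623, abs=1e-4)
        assert a.pielou == pytest.approx(0.8113, abs=1e-4)

    def test_all_zero_row(self):
        a = alpha_diversity([0, 0])
        assert (a.richness, a.shannon, a.pielou) == (None, None, None)

    def test_invariants(self, rng):
        for _ in range(50):
            row = rng.integers(0, 100, size=12)
            a = alpha_diversity(row)
            if a.richness and a.richness >= 2:
                assert 0 <= a.pielou <= 1 + 1e-12
                assert a.shannon <= np.log(a.richness) + 1e-12


class TestFilterGenera:
    def test_threshold_and_identity(self):
        ab = np.array([[996, 4, 0], [995, 5, 0]])  # genus 1 at 0.4-0.5%
        table = make_table(ab, ["p1", "p2"], [0, 0])
        kept = filter_genera(table, min_rel_abundance=0.005)
        assert kept == ["g0"]
        assert filter_genera(table, min_rel_abundance=0.0) == ["g0", "g1"]

    def test_prevalence_filter(self):
        # genus g1 present in only one participant's samples
        ab = np.array([[90, 10], [95, 5], [100, 0], [100, 0],
                       [100, 0], [100, 0], [100, 0], [100, 0]])
        parts = ["p1", "p1", "p2", "p2", "p3", "p3", "p4", "p4"]
        table = make_table(ab, parts, [0, 1, 0, 1, 0, 1, 0, 1])
        kept = filter_genera(table, 0.005, min_participants=1, min_samples=1)
        assert kept == ["g0"]
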