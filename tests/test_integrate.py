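"""Differential calling, Fisher association and the candidate screen."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from chromexpr import integrate as ig
from chromexpr import expression as xp
from chromexpr._stats import bh_adjust, fisher_enrichment, hypergeom_upper_tail
from chromexpr.core_io import GROUPS, BinnedTrackSet, GenomeAnnotation, PeakSet
from chromexpr.hmm import StatePath


def _tracks(ctrl, kd):
    arr = np.column_stack([ctrl, kd]).astype(float)
    return BinnedTrackSet(200, ["H3K27Ac_ctrl", "H3K27Ac_kd"], {"chr1": arr})


class TestDifferential:
    def test_equal_counts_unchanged(self):
        ts = _tracks([50, 50, 50, 50], [50, 50, 50, 50])
        res = ig.differential_k27ac(ts, ts, [("chr1", 0, 200), ("chr1", 200, 400)])
        assert all(r.direction == "unchanged" for r in res)

    def test_tenfold_drop_matches_binomial_oracle(self):
        # two regions engineered to equal library sizes: 100 vs 10 and 10 vs 100
        ts = _tracks([100, 10], [10, 100])
        res = ig.differential_k27ac(ts, ts, [("chr1", 0, 200), ("chr1", 200, 400)])
        r = res[0]
        assert r.log2fc == pytest.approx(math.log2(10 / 100), abs=1e-12)
        expected_p = 2 * binom.cdf(10, 110, 0.5)
        assert r.p == pytest.approx(expected_p, rel=1e-9)
        # BH over 2 tests with equal p-values keeps q == p
        assert r.q == pytest.approx(expected_p, rel=1e-9)
        assert r.direction == "decreased"
        assert res[1].direction == "increased"

    def test_zero_library_rejected(self):
        ts = _tracks([0, 0], [1, 1])
        with pytest.raises(ValueError, match="zero total"):
            ig.differential_k27ac(ts, ts, [("chr1", 0, 400)])

    def test_fold_change_gate_blocks_small_shifts(self):
        # significant but < 2-fold shift must stay unchanged
        ts = _tracks([12000, 8000], [8000, 12000])
        res = ig.differential_k27ac(ts, ts, [("chr1", 0, 200), ("chr1", 200, 400)])
        assert all(r.direction == "unchanged" for r in res)
        assert all(r.q < 0.05 for r in res)

    def test_regions_from_peaks_keeps_bookended_separate(self):
        ps = PeakSet("k", "", pd.DataFrame({
            "chrom": ["chr1"] * 3, "start": [0, 200, 500], "end": [200, 400, 700],
            "name": list("abc"), "score": [1.0] * 3, "summit_offset": [np.nan] * 3}))
        assert ig.regions_from_peaks(ps) == [
            ("chr1", 0, 200), ("chr1", 200, 400), ("chr1", 500, 700)]

    def test_planted_attenuation_recovered(self):
        from chromexpr import simulate as sim
        cfg = sim.SimulationConfig(seed=21, n_chroms=2, chrom_length=4_000_000,
                                   n_genes=200, n_candidates=0)
        rng = np.random.default_rng(cfg.seed)
        paths = sim.sample_state_paths(cfg, rng)
        tracks, peaks, truth_regions = sim.generate_chromatin(cfg, rng, paths)
        res = ig.differential_k27ac(tracks, tracks, peaks["H3K27Ac_ctrl"])
        called = {(r.chrom, r.start, r.end) for r in res if r.direction == "decreased"}
        truth = set(map(tuple, truth_regions))
        tp = len(called & truth)
        assert tp / len(truth) >= 0.9
        assert tp / max(1, len(called)) >= 0.9


class TestFisher:
    def test_worked_hypergeometric_example(self):
        # |class|=5, |cluster|=4, overlap 4 in a universe of 20:
        # p = C(5,4)C(15,0)/C(20,4) = 5/4845
        _, p = fisher_enrichment(4, 1, 0, 15)
        assert p == pytest.approx(5 / 4845, rel=1e-12)

    def test_empty_cluster_gives_p_one(self):
        res = ig.fisher_association({0: {"a", "b"}}, {"c": set()},
                                    {"a", "b", "c", "d"})
        assert res[0].p == 1.0

    def test_monotone_in_overlap_for_fixed_margins(self):
        N, K, n = 60, 20, 15
        ps = [hypergeom_upper_tail(k, N, K, n) for k in range(0, 16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ig.fisher_association({0: set()}, {0: set()}, set())

    def test_odds_ratio_haldane_on_zero_cell(self):
        odds, _ = fisher_enrichment(4, 1, 0, 15)
        assert odds == pytest.approx((4.5 * 15.5) / (1.5 * 0.5))

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestGenesForClass:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        n_bins = 500
        path = StatePath({"chr1": rng.integers(0, 3, size=n_bins)}, 3)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(30)],
            "chrom": "chr1",
            "start": rng.choice(n_bins * 200 - 400, size=30, replace=False),
            "end": 0,
            "strand": rng.choice(["+", "-"], size=30),
        })
        genes["end"] = genes["start"] + 300
        ann = GenomeAnnotation({"chr1": n_bins * 200}, genes)
        got = ig.genes_for_class(path, ann, bin_size=200, window=5000)
        tss = ann.tss
        arr = path.states["chr1"]
        for c in range(3):
            expected = set()
            for g in genes.gene_id:
                t = int(tss[g])
                for b in range(n_bins):  # O(genes x bins) oracle
                    overlaps = b * 200 < t + 5000 and (b + 1) * 200 > t - 5000
                    if overlaps and arr[b] == c:
                        expected.add(g)
                        break
            assert got[c] == expected

    def test_gene_on_undecoded_chromosome_in_no_list(self):
        path = StatePath({"chr1": np.zeros(10, dtype=int)}, 1)
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr2"],
                              "start": [0], "end": [100], "strand": ["+"]})
        ann = GenomeAnnotation({"chr1": 2000, "chr2": 2000}, genes)
        assert ig.genes_for_class(path, ann, 200)[0] == set()


class TestCandidateScreen:
    def _scenario(self, *, k27_overlap=True, decreased=True, reduction=0.75,
                  combo_lowest=True):
        genes = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                              "start": [50_000], "end": [52_000], "strand": ["+"]})
        ann = GenomeAnnotation({"chr1": 200_000}, genes)

        def ps(name, start, end):
            return PeakSet(name, "", pd.DataFrame({
                "chrom": ["chr1"], "start": [start], "end": [end],
                "name": [name], "score": [1.0], "summit_offset": [np.nan]}))

        erg = ps("erg", 40_000, 41_000)
        fli = ps("fli", 40_200, 41_200)
        k27 = (ps("k27", 40_500, 41_500) if k27_overlap
               else ps("k27", 100_000, 101_000))
        diff = [ig.DifferentialRegion("chr1", 40_500, 41_500, 100, 10, -3.3,
                                      1e-6, 1e-5,
                                      "decreased" if decreased else "unchanged")]
        ctrl = 1000.0
        combo = ctrl * (1 - reduction)
        single = combo * (2.0 if combo_lowest else 0.5)
        cols = pd.MultiIndex.from_tuples(GROUPS)
        vals = {("siControl", 3): ctrl, ("siERG", 3): single,
                ("siFLI1", 3): single, ("siERG+siFLI1", 3): combo}
        row = [vals.get(g, ctrl) for g in cols]
        gm = pd.DataFrame([row], index=pd.Index(["g1"], name="gene_id"),
                          columns=cols)
        return erg, fli, k27, diff, gm, ann

    def test_fully_satisfying_gene_is_candidate(self):
        recs = ig.candidate_screen(*self._scenario())
        assert recs[0].is_candidate
        assert all(recs[0].flags.values())

    def test_failure_modes_flag_exactly_one_criterion(self):
        for kw, flag in [
            (dict(decreased=False), "k27ac_reduced"),
            (dict(reduction=0.699), "expr_reduced_70"),
            (dict(combo_lowest=False), "combo_exceeds_singles"),
        ]:
            recs = ig.candidate_screen(*self._scenario(**kw))
            assert not recs[0].is_candidate
            failed = [k for k, v in recs[0].flags.items() if not v]
            assert failed == [flag], kw

    def test_threshold_is_strict_at_70_percent(self):
        # 70.1% reduction passes, exactly 70.0% fails (strict inequality)
        assert ig.candidate_screen(*self._scenario(reduction=0.701))[0].is_candidate
        assert not ig.candidate_screen(
            *self._scenario(reduction=0.700))[0].flags["expr_reduced_70"]

    def test_gene_missing_from_expression_fails_expression_criteria(self):
        erg, fli, k27, diff, gm, ann = self._scenario()
        recs = ig.candidate_screen(erg, fli, k27, diff, gm.drop(index="g1"), ann)
        assert not recs[0].flags["expr_reduced_70"]
        assert recs[0].flags["has_upstream_peak"]

    def test_either_mode_relaxes_tf_requirement(self):
        erg, fli, k27, diff, gm, ann = self._scenario()
        empty = PeakSet("fli1", "", pd.DataFrame(columns=fli.peaks.columns))
        both = ig.candidate_screen(erg, empty, k27, diff, gm, ann, tf_mode="both")
        either = ig.candidate_screen(erg, empty, k27, diff, gm, ann, tf_mode="either")
        assert not both[0].flags["has_upstream_peak"]
        assert either[0].flags["has_upstream_peak"]

    def test_screen_equals_intersection_of_criteria(self, noiseless_sim):
        res = noiseless_sim
        gm = xp.group_means(res.expression)
        gene_gm = xp.collapse_probes(xp.filter_probes(gm), gm,
                                     res.expression.probe_to_gene)
        diff = ig.differential_k27ac(res.tracks, res.tracks,
                                     res.peaks["H3K27Ac_ctrl"])
        recs = ig.candidate_screen(res.peaks["ERG"], res.peaks["FLI1"],
                                   res.peaks["H3K27Ac_ctrl"], diff, gene_gm,
                                   res.annotation)
        flags = pd.DataFrame([r.flags for r in recs],
                             index=[r.gene_id for r in recs])
        candidates = {r.gene_id for r in recs if r.is_candidate}
        assert candidates == set(flags.index[flags.all(axis=1)])
        assert candidates == set(res.truth.candidates)
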