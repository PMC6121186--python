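"""Matched-background enrichment: exact hypergeometric oracle, matching,
pruning, and overlap conventions."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylmr import (
    ClassShortageError,
    decorrelate_hits,
    enrich_test,
    hypergeometric_enrichment,
    matched_background,
    simulate_annotation_tracks,
    simulate_cpg_universe,
)
from methylmr.enrichment import overlaps_track


class TestOverlapConvention:
    def test_point_interval_boundaries(self):
        # CpG position is 1-based; converted to 0-based it overlaps
        # [start, end): position start+1 is in, position end+1 is out
        track = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [110], "name": ["t"]})
        cpgs = pd.DataFrame(
            {
                "CPG": ["a", "b", "c", "d"],
                "CHR": "1",
                "POS": [100, 101, 110, 111],
                "CLASS": "island",
            }
        )
        assert list(overlaps_track(cpgs, track)) == [False, True, True, False]

    def test_overlapping_intervals_merged(self):
        track = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [100, 105], "end": [110, 120], "name": "t"}
        )
        cpgs = pd.DataFrame(
            {"CPG": ["a"], "CHR": "1", "POS": [116], "CLASS": "island"}
        )
        assert overlaps_track(cpgs, track).all()


class TestMatchedBackground:
    def _universe(self, seed=0, n=3000):
        return simulate_cpg_universe(n, seed=seed)

    def test_single_class_hits_give_single_class_background(self):
        uni = self._universe()
        hits = uni[uni["CLASS"] == "island"].iloc[:30]
        bg = matched_background(hits, uni, size=100, seed=1)
        assert (bg["CLASS"] == "island").all()
        assert len(bg) == 100
        assert not set(bg["CPG"]) & set(hits["CPG"])

    def test_proportional_allocation_fifty_fifty(self):
        uni = self._universe()
        hits = pd.concat(
            [
                uni[uni["CLASS"] == "island"].iloc[:25],
                uni[uni["CLASS"] == "body"].iloc[:25],
            ]
        )
        bg = matched_background(hits, uni, size=200, seed=2)
        assert (bg["CLASS"].value_counts() == 100).all()

    def test_insufficient_class_names_the_class(self):
        uni = self._universe(n=100)
        hits = uni[uni["CLASS"] == "shore"].iloc[:5]
        with pytest.raises(ClassShortageError, match="shore"):
            matched_background(hits, uni, size=10_000, seed=3)

    def test_composition_matches_by_chi_square(self):
        # over 100 draws the background composition is indistinguishable
        # from the hit composition (chi-square p > 0.01 in >= 95 draws)
        uni = self._universe(seed=5, n=5000)
        rng = np.random.default_rng(6)
        hits = uni.iloc[rng.choice(len(uni), 200, replace=False)]
        expected = hits["CLASS"].value_counts(normalize=True)
        ok = 0
        for s in range(100):
            bg = matched_background(hits, uni, size=400, seed=s)
            obs = bg["CLASS"].value_counts()
            exp = expected.reindex(obs.index) * len(bg)
            p = stats.chisquare(obs.to_numpy(), exp.to_numpy()).pvalue
            ok += p > 0.01
        assert ok >= 95


class TestEnrichTest:
    def test_hypergeometric_exact_combinatorial_fixture(self):
        # population 20, successes 10, draw 5, observe 5:
        # p = C(10,5)/C(20,5) = 252/15504
        expected = comb(10, 5) / comb(20, 5)
        assert hypergeometric_enrichment(20, 10, 5, 5) == pytest.approx(expected)
        assert expected == pytest.approx(0.01625, abs=5e-5)

    def test_empty_inputs_flagged_untestable(self):
        uni = simulate_cpg_universe(100, seed=0)
        empty_track = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        res = enrich_test(uni.iloc[:5], empty_track, uni, n_perm=10, seed=1)
        assert not res.testable
        track, _ = simulate_annotation_tracks(uni, seed=2)
        res = enrich_test(uni.iloc[:0], track, uni, n_perm=10, seed=3)
        assert not res.testable

    def test_planted_signal_detected(self):
        uni = simulate_cpg_universe(5000, seed=7)
        hits_ids = list(np.random.default_rng(8).choice(uni["CPG"], 100, replace=False))
        track, _ = simulate_annotation_tracks(
            uni, planted_fold=4.0, background_rate=0.1, hits=hits_ids, seed=9
        )
        hits = uni[uni["CPG"].isin(hits_ids)]
        res = enrich_test(hits, track, uni, n_perm=999, seed=10)
        assert res.p_permutation < 0.01
        assert res.p_hypergeometric < 0.01
        assert res.fold == pytest.approx(4.0, rel=0.5)

    def test_no_enrichment_gives_null_like_p(self):
        uni = simulate_cpg_universe(4000, seed=11)
        ps = []
        for s in range(60):
            track, hit_ids = simulate_annotation_tracks(
                uni, planted_fold=1.0, seed=100 + s
            )
            hits = uni[uni["CPG"].isin(hit_ids)].iloc[:80]
            res = enrich_test(hits, track, uni, n_perm=199, seed=s)
            ps.append(res.p_permutation)
        # null permutation p: no excess of small values
        assert np.mean(np.asarray(ps) < 0.05) < 0.15

    def test_fold_estimate_converges_to_planted_fold(self):
        uni = simulate_cpg_universe(30_000, seed=12)
        hit_ids = list(
            np.random.default_rng(13).choice(uni["CPG"], 1000, replace=False)
        )
        track, _ = simulate_annotation_tracks(
            uni, planted_fold=3.0, background_rate=0.1, hits=hit_ids, seed=14
        )
        hits = uni[uni["CPG"].isin(hit_ids)]
        res = enrich_test(hits, track, uni, n_perm=99, seed=15, background_size=20_000)
        assert res.fold == pytest.approx(3.0, rel=0.1)

    def test_hypergeometric_shortcut_matches_explicit_resampling(self):
        # k_perm drawn per class from hypergeometric distributions must be
        # distributed like explicitly resampled matched backgrounds
        uni = simulate_cpg_universe(2000, seed=16)
        rng = np.random.default_rng(17)
        hits = uni.iloc[rng.choice(len(uni), 50, replace=False)]
        track, _ = simulate_annotation_tracks(
            uni, planted_fold=1.0, background_rate=0.2, seed=18
        )
        explicit = []
        for s in range(400):
            bg = matched_background(hits, uni, size=len(hits), seed=1000 + s)
            explicit.append(int(overlaps_track(bg, track).sum()))
        pool = uni[~uni["CPG"].isin(hits["CPG"])]
        ov = overlaps_track(pool, track)
        shortcut = np.zeros(400, dtype=int)
        for cls, need in hits["CLASS"].value_counts().items():
            mask = (pool["CLASS"] == cls).to_numpy()
            good = int(ov[mask].sum())
            shortcut += rng.hypergeometric(good, mask.sum() - good, need, size=400)
        p = stats.ks_2samp(explicit, shortcut).pvalue
        assert p > 0.01

    def test_permutation_and_hypergeometric_rank_agreement(self):
        # across 20 tracks of varying enrichment with a homogeneous
        # matching class, the two p-values order the tracks the same way
        # (Spearman rho > 0.9). Folds stay in the range where neither p
        # saturates (the permutation p bottoms out at 1/(n_perm+1), which
        # would tie all strongly enriched tracks).
        uni = simulate_cpg_universe(8000, seed=19, class_probs=(1.0, 0.0, 0.0))
        hit_ids = list(np.random.default_rng(20).choice(uni["CPG"], 100, replace=False))
        hits = uni[uni["CPG"].isin(hit_ids)]
        ph, pp = [], []
        for i, fold in enumerate(np.linspace(1.0, 1.8, 20)):
            track, _ = simulate_annotation_tracks(
                uni, planted_fold=fold, background_rate=0.1, hits=hit_ids, seed=30 + i
            )
            res = enrich_test(hits, track, uni, n_perm=9999, seed=60 + i)
            ph.append(res.p_hypergeometric)
            pp.append(res.p_permutation)
        rho = stats.spearmanr(ph, pp).statistic
        assert rho > 0.9


class TestDecorrelateHits:
    def _hits(self, chrom_pos):
        return pd.DataFrame(
            {
                "CPG": [f"c{i}" for i in range(len(chrom_pos))],
                "CHR": [c for c, _ in chrom_pos],
                "POS": [p for _, p in chrom_pos],
                "CLASS": "island",
            }
        )

    def test_close_pair_pruned_to_first(self):
        out = decorrelate_hits(self._hits([("1", 1000), ("1", 1010)]), 1000)
        assert list(out["POS"]) == [1000]

    def test_different_chromosomes_all_kept(self):
        out = decorrelate_hits(self._hits([("1", 1000), ("2", 1010)]), 1000)
        assert len(out) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hits = self._hits(
            [("1", int(p)) for p in np.sort(rng.integers(0, 20_000, size=15))]
        )
        hits = hits.drop_duplicates(subset=["CHR", "POS"])
        out = decorrelate_hits(hits, 1000)
        # oracle: walk positions in order, keep greedily
        kept, last = [], None
        for p in sorted(hits["POS"]):
            if last is None or p - last >= 1000:
                kept.append(p)
                last = p
        assert list(out["POS"]) == kept
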