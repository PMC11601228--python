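import itertools

import numpy as np
import pandas as pd
import pytest

from phagoscreen.guide_library import build_synthetic_library
from phagoscreen.screen_simulator import ScreenConfig, simulate_screen
from phagoscreen.screen_stats import (
    call_hits,
    compare_screens,
    empirical_fdr,
    gene_phenotype,
    gene_test,
    guide_lfc,
    infer_replicate_pairs,
    make_pseudogenes,
    normalize_counts,
    score_screen,
)


def exact_mwu_oracle(x, y):
    """Two-sided MWU p by full enumeration of group-1 rank placements."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1  # no ties assumed
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        r = np.sort(np.array(combo) + 1)
        u = r.sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


class TestNormalize:
    def test_even_split(self, validation_library):
        df = pd.DataFrame({"s": [50, 50]}, index=["a", "b"])
        rpm = normalize_counts(df, pseudocount=0)
        assert np.allclose(rpm["s"], 500_000)

    def test_scale_invariance(self):
        df = pd.DataFrame({"s": [10, 30, 60]})
        assert np.allclose(normalize_counts(df, 0), normalize_counts(df * 2, 0))

    def test_pseudocount_arithmetic(self):
        # guide with 0 of 99 total, pseudocount 0.5 on a 3-guide toy:
        # (0+0.5) / (99 + 3*0.5) * 1e6
        df = pd.DataFrame({"s": [0, 33, 66]})
        rpm = normalize_counts(df, 0.5)
        assert rpm["s"][0] == pytest.approx(0.5 / 100.5 * 1e6)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(pd.DataFrame({"s": [0, 0]}), 0)


class TestGuideLfc:
    def test_identical_bins_zero_lfc(self, validation_library):
        ids = validation_library.guide_ids
        df = pd.DataFrame({"r1_low": 100, "r1_high": 100}, index=ids, dtype=float)
        stats = guide_lfc(normalize_counts(df, 0), validation_library)
        assert np.allclose(stats["lfc_mean"], 0)

    def test_hand_computed_toy(self, validation_library):
        ids = validation_library.guide_ids
        low = pd.Series(100.0, index=ids)
        high = pd.Series(100.0, index=ids)
        high["ADNP_1"] = 400.0  # guide enriched 4x in the high bin
        df = pd.DataFrame({"r1_low": low, "r1_high": high})
        stats = guide_lfc(normalize_counts(df, 0), validation_library)
        # RPM renormalisation shrinks everything else: total high = 1300 vs 1000
        expected = np.log2((400 / 1300) / (100 / 1000))
        assert stats.loc["ADNP_1", "lfc_mean"] == pytest.approx(expected)

    def test_guide_at_ntc_median_has_zero_z(self, validation_library):
        # NTC lfcs are symmetric around the common normalisation constant K
        # (200x up and 2x down); every unchanged guide sits exactly at the
        # NTC median, so its robust z is exactly 0
        ids = validation_library.guide_ids
        df = pd.DataFrame({"r1_low": 100, "r1_high": 100}, index=ids, dtype=float)
        df.loc["NTC_1", "r1_high"] = 200
        df.loc["NTC_2", "r1_high"] = 50
        stats = guide_lfc(normalize_counts(df, 0), validation_library)
        ntc = stats.loc[stats["is_ntc"], "lfc_mean"].to_numpy()
        assert stats.loc["ADNP_1", "lfc_mean"] == pytest.approx(np.median(ntc))
        assert stats.loc["ADNP_1", "z"] == pytest.approx(0, abs=1e-9)

    def test_depth_invariance(self, validation_library, rng):
        ids = validation_library.guide_ids
        base = pd.DataFrame(rng.integers(50, 500, size=(len(ids), 2)),
                            index=ids, columns=["r1_low", "r1_high"]).astype(float)
        scaled = base.copy()
        scaled["r1_high"] *= 7.0
        a = guide_lfc(normalize_counts(base, 0), validation_library)
        b = guide_lfc(normalize_counts(scaled, 0), validation_library)
        assert np.allclose(a["lfc_mean"], b["lfc_mean"])

    def test_missing_pair_rejected(self, validation_library):
        df = pd.DataFrame({"r1_low": [1.0] * 10},
                          index=validation_library.guide_ids)
        with pytest.raises(ValueError):
            guide_lfc(df, validation_library)

    def test_pair_inference(self):
        pairs = infer_replicate_pairs(["r1_low", "r1_high", "r2_high", "r2_low"])
        assert pairs == [("r1_high", "r1_low"), ("r2_high", "r2_low")]


class TestGeneTest:
    def test_two_guides_beating_28_ntcs(self):
        p = gene_test([10.0, 11.0], list(np.linspace(-1, 1, 28)))
        assert p == pytest.approx(2 / 435, rel=1e-9)

    def test_central_u_p_capped_at_one(self):
        # interleave so U = n1*n2/2 exactly
        p = gene_test([2.0, 5.0], [1.0, 3.0, 4.0, 6.0])
        assert p == 1.0

    def test_exact_agrees_with_enumeration_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=2)
            y = rng.normal(size=8)
            assert gene_test(x, y) == pytest.approx(exact_mwu_oracle(x, y), abs=1e-12)

    def test_exact_close_to_normal_approximation(self, rng):
        """Exact and approximate p track each other at n1=2, n2=28.

        The normal approximation is good where it matters (small p, the
        hit-calling region) and only loosely accurate mid-range; the bounds
        below are the enumerated worst cases over the full U distribution.
        """
        from scipy import stats as sps

        for _ in range(100):
            x = rng.normal(size=2)
            y = rng.normal(size=28)
            exact = gene_test(x, y)
            approx = min(sps.mannwhitneyu(x, y, alternative="two-sided",
                                          method="asymptotic").pvalue, 1.0)
            assert abs(exact - approx) < 0.08
            if exact < 0.05:
                assert abs(exact - approx) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_test([], [1.0])


class TestGenePhenotype:
    @pytest.mark.parametrize(
        "lfcs, zs, mode, expected_fc",
        [
            ([1.0, 1.0], [5.0, 0.1], "abs_z", 2.0),
            ([2.0, 0.0], None, "equal", 2.0),
            ([3.0, 1.0], [3.0, 1.0], "abs_z", 2 ** 2.5),
        ],
    )
    def test_weighted_geometric_mean(self, lfcs, zs, mode, expected_fc):
        lfc, fc = gene_phenotype(lfcs, zs, mode)
        assert fc == pytest.approx(expected_fc)
        assert fc == pytest.approx(2.0 ** lfc)

    def test_equal_weights_equal_plain_geometric_mean(self, rng):
        lfcs = rng.normal(size=5)
        lfc, fc = gene_phenotype(lfcs, None, "equal")
        assert fc == pytest.approx(float(np.prod(2.0 ** lfcs) ** (1 / 5)))

    def test_weight_floor_keeps_null_guides(self):
        # a z=0 guide still receives the floor weight, not zero
        lfc, _ = gene_phenotype([4.0, 0.0], [4.0, 0.0], "abs_z")
        assert lfc == pytest.approx(4.0 * (4.0 / 4.25))


class TestPseudogenes:
    def test_28_choose_2_enumeration(self):
        ids = [f"NTC_{i}" for i in range(28)]
        groups = make_pseudogenes(ids, 2)
        assert len(groups) == 378
        assert len(set(groups)) == 378

    def test_three_choose_two(self):
        assert make_pseudogenes(["a", "b", "c"], 2) == [
            ("a", "b"), ("a", "c"), ("b", "c")]

    def test_sampling_path_deterministic(self):
        ids = [f"N{i}" for i in range(200)]
        a = make_pseudogenes(ids, 2, seed=4, max_enumerate=100, n_sampled=50)
        b = make_pseudogenes(ids, 2, seed=4, max_enumerate=100, n_sampled=50)
        assert a == b and len(a) == 50
        assert all(len(set(g)) == 2 for g in a)

    def test_oversized_group_rejected(self):
        with pytest.raises(ValueError):
            make_pseudogenes(["a"], 2)


class TestEmpiricalFdr:
    def test_all_pseudo_below_genes(self):
        q = empirical_fdr([5.0, 4.0], [1.0, 2.0], "positive")
        assert np.allclose(q, 0.0)

    def test_worked_threshold_example(self):
        q = empirical_fdr([5, 4, 3], [4.5, 1, 0.5, 0.2], "positive")
        assert np.allclose(q, [0.0, 0.25, 0.25])

    def test_negative_tail_mirrors(self):
        q_pos = empirical_fdr([5, 4, 3], [4.5, 1, 0.5, 0.2], "positive")
        q_neg = empirical_fdr([-5, -4, -3], [-4.5, -1, -0.5, -0.2], "negative")
        assert np.allclose(q_pos, q_neg)

    def test_null_genes_have_high_q(self, rng):
        meds = []
        for _ in range(20):
            scores = rng.normal(size=100)
            pseudo = rng.normal(size=400)
            meds.append(np.median(empirical_fdr(scores, pseudo, "positive")))
        assert np.mean(meds) > 0.8

    def test_q_monotone_in_score(self, rng):
        scores = rng.normal(size=50)
        q = empirical_fdr(scores, rng.normal(size=200), "positive")
        order = np.argsort(-scores)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestScoreScreen:
    def test_null_screen_no_confident_hits(self, fast_config):
        counts, _ = simulate_screen(fast_config)
        results, guides = score_screen(counts, fast_config.library)
        assert set(results.index) == set(fast_config.library.targeting_genes)
        assert (results["bh_q"] >= results["p_value"] - 1e-12).all()
        assert results["hit_class"].isin(["increase", "decrease", "none"]).all()

    def test_strong_effect_called_with_correct_sign(self, small_library):
        up, down = small_library.targeting_genes[:2]
        cfg = ScreenConfig(small_library, cells_per_guide=500,
                           effects={up: 2.0, down: -2.0}, seed=8)
        counts, _ = simulate_screen(cfg)
        results, _ = score_screen(counts, small_library)
        assert results.loc[up, "hit_class"] == "increase"
        assert results.loc[down, "hit_class"] == "decrease"
        assert results.loc[up, "phenotype_lfc"] > 0 > results.loc[down, "phenotype_lfc"]

    def test_alpha_one_calls_every_finite_gene(self, fast_config):
        counts, _ = simulate_screen(fast_config)
        results, _ = score_screen(counts, fast_config.library, alpha=0.999999)
        nonzero = results["phenotype_lfc"] != 0
        assert (results.loc[nonzero, "hit_class"] != "none").mean() > 0.9

    def test_fc_consistency_and_tail_partition(self, fast_config):
        counts, _ = simulate_screen(fast_config)
        results, _ = score_screen(counts, fast_config.library)
        assert np.allclose(results["phenotype_fc"], 2 ** results["phenotype_lfc"])
        inc = results["hit_class"] == "increase"
        dec = results["hit_class"] == "decrease"
        assert (results.loc[inc, "phenotype_lfc"] > 0).all()
        assert (results.loc[dec, "phenotype_lfc"] < 0).all()

    def test_pooled_mode_runs(self, fast_config):
        counts, _ = simulate_screen(fast_config)
        results, guides = score_screen(counts, fast_config.library, pooled=True)
        assert "lfc_pooled" in guides.columns
        assert len(results) == fast_config.library.n_genes


class TestCallHits:
    def test_bad_alpha(self):
        df = pd.DataFrame({"phenotype_lfc": [1.0], "q_pos": [0.0], "q_neg": [1.0]})
        with pytest.raises(ValueError):
            call_hits(df, 1.5)

    def test_tail_matched_fdr_column(self):
        df = pd.DataFrame({
            "phenotype_lfc": [1.0, -1.0, 0.0],
            "q_pos": [0.001, 0.5, 0.2],
            "q_neg": [0.9, 0.002, 0.3],
        })
        out = call_hits(df, 0.01)
        assert list(out["hit_class"]) == ["increase", "decrease", "none"]
        assert list(out["empirical_fdr"]) == [0.001, 0.002, 1.0]


class TestCompareScreens:
    def _results(self, genes, hits=(), lfcs=None):
        df = pd.DataFrame(index=pd.Index(genes, name="gene"))
        df["phenotype_lfc"] = lfcs if lfcs is not None else 0.0
        df["hit_class"] = ["increase" if g in hits else "none" for g in genes]
        return df

    def test_no_hits_empty_matrix(self):
        a = self._results(["g1", "g2"])
        lfc, sig = compare_screens({"beads": a, "synaptosomes": a})
        assert lfc.empty and sig.empty

    def test_single_screen_hit_flagged(self):
        genes = ["g1", "g2"]
        a = self._results(genes, hits=["g1"], lfcs=[0.8, 0.0])
        b = self._results(genes)
        lfc, sig = compare_screens({"synapse": a, "beads": b})
        assert list(lfc.index) == ["g1"]
        assert lfc.loc["g1", "synapse"] == pytest.approx(0.8)
        assert bool(sig.loc["g1", "synapse"]) and not bool(sig.loc["g1", "beads"])

    def test_mismatched_universe_rejected(self):
        a = self._results(["g1", "g2"])
        b = self._results(["g1", "g3"])
        with pytest.raises(ValueError, match="g2.*g3|g3.*g2"):
            compare_screens({"a": a, "b": b})

    def test_simulated_sign_pattern_matches_truth(self, small_library):
        genes = small_library.targeting_genes
        truth_signs = {}
        tables = {}
        for i, name in enumerate(["beads", "synaptosomes", "pruning"]):
            effects = {genes[0]: 2.0 if i % 2 == 0 else -2.0}
            truth_signs[name] = np.sign(effects[genes[0]])
            cfg = ScreenConfig(small_library, cells_per_guide=500,
                               effects=effects, seed=30 + i)
            counts, _ = simulate_screen(cfg)
            tables[name], _ = score_screen(counts, small_library)
        lfc, sig = compare_screens(tables)
        assert genes[0] in lfc.index
        for name, s in truth_signs.items():
            assert np.sign(lfc.loc[genes[0], name]) == s
            assert bool(sig.loc[genes[0], name])
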