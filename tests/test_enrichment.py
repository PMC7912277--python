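import numpy as np
import pandas as pd
import pytest

import scmra
from scmra.containers import Regulon, ValidationError
from oracles import brute_gsea_es, brute_regulon_es


def _signature(values, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(values))]
    return pd.Series(np.asarray(values, float), index=pd.Index(genes, name="gene"))


def _random_regulon(rng, universe, n_targets, tf="TFx"):
    targets = rng.choice(universe, size=n_targets, replace=False)
    return Regulon(
        tf=tf,
        targets=targets,
        modes=rng.choice([1.0, -1.0], size=n_targets),
        likelihoods=1.0 - rng.random(n_targets),
    )


class TestGseaEs:
    def test_top_ranked_singleton_scores_one(self, random_signature):
        top_gene = random_signature.idxmax()
        assert scmra.gsea_es(random_signature, [top_gene]) == pytest.approx(1.0)

    def test_bottom_ranked_singleton_scores_negative(self, random_signature):
        bottom = random_signature.idxmin()
        assert scmra.gsea_es(random_signature, [bottom]) < 0

    def test_matches_brute_force_on_random_sets(self, random_signature):
        rng = np.random.default_rng(0)
        genes = random_signature.index.to_numpy(dtype=object)
        for _ in range(20):
            gene_set = list(rng.choice(genes, size=rng.integers(1, 30), replace=False))
            expected = brute_gsea_es(genes, random_signature.to_numpy(), gene_set)
            assert scmra.gsea_es(random_signature, gene_set) == pytest.approx(
                expected, abs=1e-12
            )

    def test_no_overlap_rejected(self, random_signature):
        with pytest.raises(ValidationError, match="universe"):
            scmra.gsea_es(random_signature, ["not_a_gene"])


class TestRegulonEs:
    def test_two_target_formula(self):
        sig = _signature([2.0, -2.0] + [0.0] * 10)
        reg = Regulon("TF", np.array(["g000", "g001"], dtype=object),
                      np.array([1.0, -1.0]), np.array([1.0, 1.0]))
        assert scmra.regulon_es(sig, reg, min_size=2) == pytest.approx(2.0)

    def test_zero_scores_zero_es(self, random_signature):
        rng = np.random.default_rng(1)
        reg = _random_regulon(rng, random_signature.index.to_numpy(dtype=object), 12)
        zero_sig = random_signature * 0.0
        assert scmra.regulon_es(zero_sig, reg) == 0.0

    def test_matches_weighted_mean_oracle(self, random_signature):
        rng = np.random.default_rng(2)
        universe = random_signature.index.to_numpy(dtype=object)
        sig_map = dict(random_signature)
        for _ in range(20):
            reg = _random_regulon(rng, universe, 8)
            expected = brute_regulon_es(sig_map, reg.targets, reg.modes, reg.likelihoods)
            assert scmra.regulon_es(random_signature, reg, min_size=8) == pytest.approx(
                expected, abs=1e-12
            )

    def test_linearity_in_signature(self, random_signature):
        rng = np.random.default_rng(3)
        reg = _random_regulon(rng, random_signature.index.to_numpy(dtype=object), 15)
        es1 = scmra.regulon_es(random_signature, reg)
        es3 = scmra.regulon_es(random_signature * 3.0, reg)
        assert es3 == pytest.approx(3.0 * es1, rel=1e-12)

    def test_below_min_size_rejected(self, random_signature):
        rng = np.random.default_rng(4)
        reg = _random_regulon(rng, random_signature.index.to_numpy(dtype=object), 5)
        with pytest.raises(ValidationError, match="min_size"):
            scmra.regulon_es(random_signature, reg)


class TestPermutationNull:
    def test_seeded_determinism(self, random_signature):
        rng = np.random.default_rng(5)
        reg = _random_regulon(rng, random_signature.index.to_numpy(dtype=object), 20)
        n1 = scmra.permutation_null(random_signature, reg, n_perm=50, seed=9)
        n2 = scmra.permutation_null(random_signature, reg, n_perm=50, seed=9)
        np.testing.assert_array_equal(n1, n2)

    def test_gene_shuffle_null_centred_for_symmetric_signature(self):
        # antisymmetric scores: +x and -x in equal measure
        vals = np.concatenate([np.linspace(0.1, 3, 50), -np.linspace(0.1, 3, 50)])
        sig = _signature(vals)
        reg = Regulon("TF", sig.index[:12].to_numpy(dtype=object),
                      np.ones(12), np.ones(12))
        null = scmra.permutation_null(sig, reg, n_perm=2000, seed=0)
        assert abs(null.mean()) < 3 * null.std() / np.sqrt(len(null))

    def test_minimal_run_p_bound(self, random_signature):
        rng = np.random.default_rng(6)
        reg = _random_regulon(rng, random_signature.index.to_numpy(dtype=object), 20)
        null = scmra.permutation_null(random_signature, reg, n_perm=10, seed=1)
        es = scmra.regulon_es(random_signature, reg)
        _, p = scmra.nes(es, null)
        assert p >= 1 / 11

    def test_sample_shuffle_without_context_rejected(self, random_signature):
        rng = np.random.default_rng(7)
        reg = _random_regulon(rng, random_signature.index.to_numpy(dtype=object), 20)
        with pytest.raises(ValidationError, match="context"):
            scmra.permutation_null(random_signature, reg, scheme="sample_shuffle")


class TestNes:
    def test_degenerate_matched_null_gives_unit_nes_p_one(self):
        nes_val, p = scmra.nes(0.4, [0.4] * 100)
        assert nes_val == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        nes_val, p = scmra.nes(-0.4, [-0.4] * 100)
        assert nes_val == pytest.approx(-1.0)
        assert p == pytest.approx(1.0)

    def test_obs_twice_null_magnitude(self):
        null = [0.2, -0.2, 0.2, -0.2] * 25
        nes_val, _ = scmra.nes(0.4, null)
        assert nes_val == pytest.approx(2.0)

    def test_strictly_monotone_in_es_obs(self):
        rng = np.random.default_rng(8)
        null = rng.normal(scale=0.3, size=500)
        grid = np.linspace(-1.5, 1.5, 41)
        nes_vals = [scmra.nes(e, null)[0] for e in grid]
        assert np.all(np.diff(nes_vals) > 0)

    def test_all_zero_null_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            scmra.nes(0.5, [0.0] * 20)


class TestMra:
    def test_recovers_active_tfs(self, default_normalized):
        """TFs driving the population contrast rank top with small FDR."""
        truth = default_normalized["truth"]
        ann = default_normalized["annotation"]
        ln = default_normalized["lognorm"].values
        de = scmra.wilcoxon_de(
            ln[ann.index[ann.population == "BE2C"]],
            ln[ann.index[ann.population == "Kelly"]],
        )
        sig = scmra.group_signature(de)
        res = scmra.mra(sig, truth.regulons, n_perm=1000, seed=1)
        top5 = set(res.frame.head(5)["name"])
        true_tfs = {f"TF{i:02d}" for i in range(1, 6)}
        assert len(top5 & true_tfs) >= 4
        assert (res.frame.head(5)["fdr"] < 0.05).all()

    def test_sign_flip_negates_nes_with_shared_seed(self, random_signature):
        rng = np.random.default_rng(9)
        universe = random_signature.index.to_numpy(dtype=object)
        regs = [_random_regulon(rng, universe, 20, tf=f"T{i}") for i in range(5)]
        r1 = scmra.mra(random_signature, regs, n_perm=100, seed=3)
        r2 = scmra.mra(-random_signature, regs, n_perm=100, seed=3)
        nes1 = r1.frame.set_index("name")["nes"]
        nes2 = r2.frame.set_index("name")["nes"]
        np.testing.assert_allclose(nes1, -nes2.loc[nes1.index], rtol=1e-9)

    def test_summary_and_results_object(self, random_signature):
        rng = np.random.default_rng(10)
        universe = random_signature.index.to_numpy(dtype=object)
        regs = [_random_regulon(rng, universe, 20, tf=f"T{i}") for i in range(3)]
        model = scmra.MasterRegulatorAnalysis(random_signature, regs)
        res = model.fit(n_perm=50, seed=0)
        assert list(res.frame["nes"]) == sorted(res.frame["nes"], reverse=True)
        text = res.summary()
        assert "T0" in text and "nes" in text
        assert res.results[0].direction in (-1, 1)

    def test_small_regulons_skipped_in_batch(self, random_signature, caplog):
        rng = np.random.default_rng(11)
        universe = random_signature.index.to_numpy(dtype=object)
        regs = [
            _random_regulon(rng, universe, 20, tf="big"),
            _random_regulon(rng, universe, 4, tf="tiny"),
        ]
        res = scmra.mra(random_signature, regs, n_perm=50, seed=0)
        assert list(res.frame["name"]) == ["big"]


class TestGseaBatch:
    def test_top_scoring_set_maximally_enriched(self, random_signature):
        top50 = list(random_signature.sort_values(ascending=False).index[:50])
        rng = np.random.default_rng(12)
        decoy = list(rng.choice(random_signature.index.to_numpy(dtype=object), 30, replace=False))
        res = scmra.gsea_batch(
            random_signature, {"top": top50, "decoy": decoy}, n_perm=200, seed=0
        )
        frame = res.frame.set_index("name")
        assert frame.loc["top", "nes"] > 0
        assert frame.loc["top", "p_value"] == pytest.approx(1 / 201)

    def test_random_sets_not_enriched_in_most_seeds(self, random_signature):
        universe = random_signature.index.to_numpy(dtype=object)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            decoy = list(rng.choice(universe, 25, replace=False))
            res = scmra.gsea_batch(random_signature, {"decoy": decoy}, n_perm=200, seed=seed)
            if res.frame["p_value"].iloc[0] > 0.05:
                hits += 1
        assert hits >= 18

    def test_output_sorted_and_top_slicing(self, random_signature):
        rng = np.random.default_rng(13)
        universe = random_signature.index.to_numpy(dtype=object)
        sets = {
            f"S{i}": list(rng.choice(universe, 20, replace=False)) for i in range(25)
        }
        res = scmra.gsea_batch(random_signature, sets, n_perm=100, seed=0)
        nes_col = res.frame["nes"].to_numpy()
        assert np.all(np.diff(nes_col) <= 0)
        layout = res.top(10)
        assert len(layout) == 20
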