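import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
import scipy.stats

import scmra
from scmra.containers import ExprMatrix, Regulon, ValidationError


def _log10_expr(arr, genes=None):
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = [f"c{j}" for j in range(arr.shape[1])]
    return ExprMatrix(
        pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=cells), "log10TPM"
    )


class TestCellSignatures:
    def test_two_cells_one_gene_population_z(self):
        sigs = scmra.cell_signatures(_log10_expr([[1.0, 3.0], [0.5, 0.7]]))
        np.testing.assert_allclose(sigs.loc["g0"], [-1.0, 1.0])

    def test_mean_cell_gets_zero_signature(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(30, 5))
        arr[:, 0] = arr[:, 1:].mean(axis=1)  # first cell = mean of the rest
        arr = np.column_stack([arr[:, 1:].mean(axis=1), arr[:, 1:]])
        sigs = scmra.cell_signatures(_log10_expr(arr))
        # not exactly zero (the cell participates in the mean) but centred:
        assert np.abs(sigs.sum(axis=1)).max() < 1e-6 * sigs.shape[1]

    def test_constant_genes_dropped_single_cell_rejected(self):
        arr = np.vstack([np.ones(4), np.arange(4.0)])
        sigs = scmra.cell_signatures(_log10_expr(arr))
        assert list(sigs.index) == ["g1"]
        with pytest.raises(ValidationError, match="2 cells"):
            scmra.cell_signatures(_log10_expr([[1.0]]))


class TestScActivity:
    def test_population_restricted_tf_separates(self, default_normalized):
        truth = default_normalized["truth"]
        ann = default_normalized["annotation"]
        act = scmra.sc_activity(
            default_normalized["log10tpm"], truth.regulons[:8], n_perm=100, seed=1
        )
        a = act.loc[ann.population == "BE2C", "TF01"]
        b = act.loc[ann.population == "Kelly", "TF01"]
        assert scipy.stats.ttest_ind(a, b, equal_var=False).pvalue < 0.01
        assert a.mean() > b.mean()

    def test_constant_pseudo_cell_zero_activity(self, default_normalized):
        truth = default_normalized["truth"]
        x = default_normalized["log10tpm"].values.copy()
        gene_means = x.mean(axis=1)
        x["flat"] = gene_means  # a cell sitting exactly at the dataset mean
        sigs = scmra.cell_signatures(
            ExprMatrix(x, "log10TPM")
        )
        act = scmra.sc_activity(sigs, truth.regulons[:3], n_perm=50, seed=0)
        # its signature is ~0 in every gene, so every activity is ~0
        assert np.abs(act.loc["flat"]).max() < 0.05

    def test_antisymmetry_under_signature_negation(self, default_normalized):
        truth = default_normalized["truth"]
        sigs = scmra.cell_signatures(default_normalized["log10tpm"])
        sub = sigs.iloc[:, :40]
        a1 = scmra.sc_activity(sub, truth.regulons[:4], n_perm=50, seed=5)
        a2 = scmra.sc_activity(-sub, truth.regulons[:4], n_perm=50, seed=5)
        np.testing.assert_allclose(a1.to_numpy(), -a2.to_numpy(), rtol=1e-9, atol=1e-12)

    def test_hclust_separates_populations(self, default_normalized):
        truth = default_normalized["truth"]
        ann = default_normalized["annotation"]
        act = scmra.sc_activity(
            default_normalized["log10tpm"], truth.regulons, n_perm=100, seed=1
        )
        link = sch.linkage(act.to_numpy(), method="complete", metric="euclidean")
        cut = sch.fcluster(link, 2, criterion="maxclust")
        is_a = (ann["population"] == "BE2C").to_numpy()
        agree = max((cut[is_a] == 1).sum() + (cut[~is_a] == 2).sum(),
                    (cut[is_a] == 2).sum() + (cut[~is_a] == 1).sum()) / len(cut)
        assert agree >= 0.9

    def test_gene_set_objects_supported(self, default_normalized):
        truth = default_normalized["truth"]
        sigs = scmra.cell_signatures(default_normalized["log10tpm"]).iloc[:, :25]
        sets = {"S_program": truth.s_genes, "G2M_program": truth.g2m_genes}
        act = scmra.sc_activity(sigs, sets, n_perm=30, seed=0)
        assert act.shape == (25, 2)
        assert np.isfinite(act.to_numpy()).all()


class TestCellCycleScores:
    def test_scores_zero_when_list_equals_bin_average(self):
        rng = np.random.default_rng(1)
        n_genes, n_cells = 120, 30
        arr = np.abs(rng.normal(1.0, 0.2, size=(n_genes, n_cells)))
        # make every gene in the dataset identical per cell -> any control
        # drawn from the same bin cancels exactly
        arr = np.tile(arr[:1], (n_genes, 1))
        x = ExprMatrix(
            pd.DataFrame(
                arr,
                index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
                columns=[f"c{j}" for j in range(n_cells)],
            ),
            "lognorm",
        )
        scores = scmra.cc_scores(x, [f"g{i}" for i in range(6)],
                                 [f"g{i}" for i in range(6, 12)], seed=0)
        assert np.abs(scores.to_numpy()).max() < 1e-12

    def test_s_cells_score_higher_on_s_program(self, default_normalized):
        truth = default_normalized["truth"]
        scores = scmra.cc_scores(
            default_normalized["lognorm"], truth.s_genes, truth.g2m_genes, seed=1
        )
        s_cells = truth.cycle_labels == "S"
        frac = (scores.loc[s_cells.to_numpy(), "s_score"]
                > scores.loc[s_cells.to_numpy(), "g2m_score"]).mean()
        assert frac >= 0.9

    def test_invariant_to_gene_list_order(self, default_normalized):
        truth = default_normalized["truth"]
        ln = default_normalized["lognorm"]
        s1 = scmra.cc_scores(ln, truth.s_genes, truth.g2m_genes, seed=2)
        s2 = scmra.cc_scores(ln, truth.s_genes[::-1], truth.g2m_genes[::-1], seed=2)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())

    def test_too_few_list_genes_rejected(self, default_normalized):
        with pytest.raises(ValidationError, match=">= 5"):
            scmra.cc_scores(default_normalized["lognorm"], ["nope1", "nope2"], ["x"] * 6)


class TestAssignPhase:
    @pytest.mark.parametrize(
        "s,g2m,phase",
        [(-0.2, -0.1, "G1"), (0.5, 0.1, "S"), (0.1, 0.5, "G2M"), (0.0, -0.3, "S")],
    )
    def test_decision_rule(self, s, g2m, phase):
        calls = scmra.assign_phase(
            pd.DataFrame({"s_score": [s], "g2m_score": [g2m]}, index=["c"])
        )
        assert calls.loc["c", "phase"] == phase

    def test_recovery_on_synthetic_cells(self, default_normalized):
        truth = default_normalized["truth"]
        calls = scmra.assign_phase(
            scmra.cc_scores(default_normalized["lognorm"], truth.s_genes,
                            truth.g2m_genes, seed=3)
        )
        acc = (calls["phase"].to_numpy() == truth.cycle_labels.to_numpy()).mean()
        assert acc >= 0.85

    def test_phase_fractions_sum_to_one(self, default_normalized):
        truth = default_normalized["truth"]
        ann = default_normalized["annotation"]
        calls = scmra.assign_phase(
            scmra.cc_scores(default_normalized["lognorm"], truth.s_genes,
                            truth.g2m_genes, seed=4)
        )
        tab = scmra.phase_fractions(calls, ann["population"])
        np.testing.assert_allclose(tab.sum(axis=1), 1.0)
        assert set(tab.index) == {"BE2C", "Kelly"}
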