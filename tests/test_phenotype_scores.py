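"""Cell QC, metacell enrichment, EMT/IER scores, strata, composition."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from cotrial.phenotype_scores import (
    anchor_gene_signature,
    mc_enrichment,
    qc_filter_cells,
    score_mcs,
    state_composition,
    stratify,
    tf_trajectory,
    umi_per_1000,
)
from cotrial.synthetic_data import (
    CellMatrix,
    MetacellModel,
    MetacellSimConfig,
    simulate_metacells,
)


def make_cells(rows, n_mito=1):
    """CellMatrix from count rows; last ``n_mito`` genes are mitochondrial."""
    counts = np.asarray(rows)
    n_genes = counts.shape[1]
    genes = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n_genes)],
            "is_mito": [i >= n_genes - n_mito for i in range(n_genes)],
        }
    )
    cells = pd.DataFrame(
        {"cell": [f"c{i}" for i in range(len(counts))], "condition": "untreated", "mc": "MC1"}
    )
    return CellMatrix(sp.csr_matrix(counts), genes, cells)


def make_model(counts, index=None):
    counts = np.asarray(counts, dtype=float)
    idx = index or [f"MC{i + 1}" for i in range(counts.shape[0])]
    cols = [f"g{i}" for i in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=idx, columns=cols)
    genes = pd.DataFrame({"gene": cols, "is_mito": False})
    mcs = pd.DataFrame({"mc": idx, "state": "EM-hybrid", "n_cells": 10})
    return MetacellModel(df, genes, mcs)


class TestQCFilter:
    def test_exactly_750_nonmito_kept(self):
        cells = make_cells([[750, 0]])
        assert qc_filter_cells(cells).tolist() == [True]

    def test_exactly_40pct_mito_removed(self):
        cells = make_cells([[600, 400], [601, 399]])  # fracs 0.40 and just under
        mask = qc_filter_cells(cells, min_nonmito_umis=500)
        assert mask.tolist() == [False, True]

    def test_toy_six_cell_enumeration(self):
        # hand count: rows 0,2,4 pass both rules
        rows = [
            [800, 100],  # keep: 800 nonmito, 11% mito
            [700, 100],  # drop: nonmito < 750
            [750, 0],    # keep: boundary nonmito, no mito
            [900, 700],  # drop: mito frac 0.4375
            [1200, 300], # keep: 20% mito
            [600, 500],  # drop: both rules fail
        ]
        mask = qc_filter_cells(make_cells(rows))
        assert mask.tolist() == [True, False, True, False, True, False]

    def test_invariant_to_gene_order_and_chunking(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 400, size=(30, 10))
        cells = make_cells(counts, n_mito=3)
        mask = qc_filter_cells(cells, min_nonmito_umis=1000)
        perm = rng.permutation(10)
        cells_perm = CellMatrix(
            sp.csr_matrix(counts[:, perm]),
            cells.genes.iloc[perm].reset_index(drop=True),
            cells.cells,
        )
        np.testing.assert_array_equal(qc_filter_cells(cells_perm, min_nonmito_umis=1000), mask)
        halves = [
            qc_filter_cells(
                CellMatrix(sp.csr_matrix(counts[i : i + 15]), cells.genes, cells.cells.iloc[i : i + 15]),
                min_nonmito_umis=1000,
            )
            for i in (0, 15)
        ]
        np.testing.assert_array_equal(np.concatenate(halves), mask)

    def test_mito_heavy_metacell_cells_flagged(self):
        # one metacell with half its UMIs mitochondrial fails the 40% rule
        w = np.array([[1.0, 0, 0, 0], [0.5, 0, 0, 0.5]])
        cfg = MetacellSimConfig(n_mcs=2, mixture_weights=w, umis_per_mc=40000,
                                n_cells_per_mc=10, seed=0)
        model = simulate_metacells(cfg)
        mask = qc_filter_cells(model.cells)
        by_mc = pd.Series(mask, index=model.cells.cells["mc"]).groupby(level=0).mean()
        assert by_mc["MC001"] == 1.0 and by_mc["MC002"] == 0.0


class TestNormalizationAndEnrichment:
    def test_umi_per_1000_trivials(self):
        np.testing.assert_allclose(umi_per_1000([5, 0, 0]), [1000, 0, 0])
        mat = umi_per_1000(np.array([[1, 1], [3, 1]]))
        np.testing.assert_allclose(mat.sum(axis=1), 1000.0)
        with pytest.raises(ValueError):
            umi_per_1000([0, 0])

    def test_enrichment_matches_two_line_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 500, size=(6, 20)).astype(float)
        model = make_model(counts)
        eps = 1e-5
        f_mc = counts / counts.sum(axis=1, keepdims=True)
        f_pool = counts.sum(axis=0) / counts.sum()
        expected = np.log2((f_mc + eps) / (f_pool + eps))
        np.testing.assert_allclose(mc_enrichment(model, eps).to_numpy(), expected, atol=1e-12)

    def test_pooled_pseudo_mc_has_zero_enrichment(self):
        counts = np.array([[10.0, 20.0, 70.0]])  # single MC == pool
        model = make_model(counts)
        np.testing.assert_allclose(mc_enrichment(model).to_numpy(), 0.0, atol=1e-12)

    def test_doubled_fraction_is_about_plus_one(self):
        counts = np.array([[400.0, 600.0], [0.0, 1000.0]])  # pooled g0 fraction 0.2
        e = mc_enrichment(make_model(counts), eps=1e-9)
        assert e.iloc[0, 0] == pytest.approx(1.0, abs=1e-3)  # 0.4 vs 0.2


class TestSignaturesAndScores:
    def test_planted_program_dominates_anchor_signature(self):
        rng = np.random.default_rng(2)
        n_mcs, block = 30, 60
        latent = rng.normal(size=n_mcs)
        cols = {}
        for i in range(block):
            cols[f"prog{i:03d}" if i else "ANCHOR"] = latent + rng.normal(0, 0.1, n_mcs)
        for i in range(100):
            cols[f"noise{i:03d}"] = rng.normal(size=n_mcs)
        e = pd.DataFrame(cols)
        sig = anchor_gene_signature(e, "ANCHOR", n=50)
        assert "ANCHOR" in sig
        assert all(g == "ANCHOR" or g.startswith("prog") for g in sig)

    def test_n_larger_than_gene_count_returns_all(self):
        e = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                         columns=list("abcd"))
        assert len(anchor_gene_signature(e, "a", n=99)) == 4

    def test_absent_anchor_rejected(self):
        e = pd.DataFrame(np.zeros((3, 2)), columns=["x", "y"])
        with pytest.raises(KeyError):
            anchor_gene_signature(e, "KRT81")

    def test_score_is_signature_mean(self):
        rng = np.random.default_rng(3)
        e = pd.DataFrame(rng.normal(size=(4, 6)), columns=list("abcdef"))
        sig = ["a", "c", "e", "f", "b"]
        np.testing.assert_allclose(score_mcs(e, sig), e[sig].mean(axis=1))
        np.testing.assert_allclose(score_mcs(e, ["d"]), e["d"])

    def test_score_shifts_with_constant_enrichment_offset(self):
        e = pd.DataFrame(np.random.default_rng(4).normal(size=(4, 5)),
                         columns=list("abcde"))
        s0 = score_mcs(e, ["a", "b"])
        s1 = score_mcs(e + 2.5, ["a", "b"])
        np.testing.assert_allclose(s1 - s0, 2.5)

    def test_empty_signature_rejected(self):
        e = pd.DataFrame(np.zeros((3, 2)), columns=["x", "y"])
        with pytest.raises(ValueError):
            score_mcs(e, [])


class TestStratification:
    def test_separated_clusters_map_to_distinct_strata(self):
        scores = pd.Series(
            np.concatenate([np.full(4, c) for c in [0.0, 1.0, 2.0, 3.0, 4.0]]),
            index=[f"MC{i}" for i in range(20)],
        )
        strata = stratify(scores, 5)
        assert sorted(strata.unique()) == [1, 2, 3, 4, 5]
        assert strata.groupby(scores).nunique().max() == 1

    def test_degenerate_equal_scores_warn_single_stratum(self):
        scores = pd.Series(np.ones(6))
        with pytest.warns(UserWarning):
            strata = stratify(scores, 4)
        assert set(strata) == {1}

    def test_labels_monotone_in_score(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=40))
        strata = stratify(scores, 5)
        order = scores.sort_values().index
        assert strata[order].is_monotonic_increasing

    def test_fewer_mcs_than_strata_rejected(self):
        with pytest.raises(ValueError):
            stratify(pd.Series([1.0, 2.0]), 4)


class TestTrajectoriesAndComposition:
    def test_trajectory_matches_groupby_oracle_and_shapes(self):
        rng = np.random.default_rng(6)
        e = pd.DataFrame(rng.normal(size=(12, 4)), columns=["TF1", "TF2", "x", "y"],
                         index=[f"MC{i}" for i in range(12)])
        strata = pd.Series([1, 1, 2, 2, 3, 3] * 2, index=e.index)
        traj = tf_trajectory(e, ["TF1", "TF2"], strata)
        for tf in ["TF1", "TF2"]:
            for s in [1, 2, 3]:
                expected = e.loc[strata[strata == s].index, tf].mean()
                assert traj.loc[tf, s] == pytest.approx(expected)

    def test_constant_tf_flat_and_basis_tf_increasing(self):
        idx = [f"MC{i}" for i in range(10)]
        basis = pd.Series(np.linspace(-2, 2, 10), index=idx)
        e = pd.DataFrame({"FLAT": 1.0, "BASIS": basis}, index=idx)
        strata = stratify(basis, 5)
        traj = tf_trajectory(e, ["FLAT", "BASIS"], strata)
        np.testing.assert_allclose(traj.loc["FLAT"], 1.0)
        assert traj.loc["BASIS"].is_monotonic_increasing

    def test_absent_tf_dropped_with_warning(self):
        e = pd.DataFrame(np.zeros((4, 1)), columns=["TF1"])
        strata = pd.Series([1, 1, 2, 2], index=e.index)
        with pytest.warns(UserWarning):
            traj = tf_trajectory(e, ["TF1", "MISSING"], strata)
        assert list(traj.index) == ["TF1"]

    def test_state_composition_hand_table(self):
        cells = pd.DataFrame(
            {
                "cell": [f"c{i}" for i in range(10)],
                "condition": ["untreated"] * 4 + ["treated"] * 3 + ["post-treated"] * 3,
                "mc": ["A", "A", "B", "C", "B", "B", "D", "C", "D", "D"],
            }
        )
        states = pd.Series(
            {"A": "epithelial", "B": "EM-hybrid", "C": "mesenchymal", "D": "EM-hybrid-IER"}
        )
        comp = state_composition(cells, states)
        np.testing.assert_allclose(comp.sum(axis=1), 100.0, atol=1e-9)
        assert comp.loc["untreated", "epithelial"] == pytest.approx(50.0)
        assert comp.loc["treated", "EM-hybrid"] == pytest.approx(200.0 / 3.0)
        assert comp.loc["post-treated", "EM-hybrid-IER"] == pytest.approx(200.0 / 3.0)

    def test_unmapped_cells_rejected(self):
        cells = pd.DataFrame({"cell": ["c0"], "condition": ["untreated"], "mc": ["ZZ"]})
        with pytest.raises(ValueError):
            state_composition(cells, pd.Series({"A": "epithelial"}))


def test_planted_emt_gradient_recovered_by_scores():
    from cotrial.phenotype_scores import emt_strata

    model = simulate_metacells(MetacellSimConfig(seed=7))
    e = mc_enrichment(model)
    emt = emt_strata(model, e)
    w = model.mixture_weights.loc[emt.index]
    planted = (w["mesenchymal"] / (w["mesenchymal"] + w["epithelial"])).to_numpy()
    rho = scipy.stats.spearmanr(planted, emt["mes_minus_epi"].to_numpy()).statistic
    assert rho > 0.9
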