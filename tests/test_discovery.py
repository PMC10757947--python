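"""Ordination, Spearman co-occurrence, and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lipidremodel as lr

from conftest import make_balanced_table


# -- PCA --------------------------------------------------------------------

def test_ordinate_rank_one_data():
    """Collinear points: PC1 explains everything."""
    x = np.arange(10, dtype=float)
    m = pd.DataFrame({"a": x, "b": 2 * x})
    res = lr.ordinate(m)
    assert res.explained_variance_ratio["PC1"] == pytest.approx(1.0)


def test_ordinate_orthogonal_scores_and_reconstruction():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.normal(size=(20, 5)),
                     columns=[f"x{i}" for i in range(5)])
    res = lr.ordinate(m)
    cov = np.cov(res.scores.to_numpy(), rowvar=False)
    assert np.allclose(cov - np.diag(np.diag(cov)), 0, atol=1e-10)
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    centered = m.to_numpy() - m.to_numpy().mean(axis=0)
    assert np.allclose(recon, centered, atol=1e-8)


def test_ordinate_sign_convention_deterministic():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.normal(size=(15, 4)))
    r1, r2 = lr.ordinate(m), lr.ordinate(-m)
    for comp in r1.loadings.columns:
        j = r1.loadings[comp].abs().idxmax()
        assert r1.loadings.loc[j, comp] > 0


def test_ordinate_constant_column_with_scaling():
    m = pd.DataFrame({"flat": np.ones(10), "x": np.arange(10.0)})
    with pytest.raises(ValueError, match="flat"):
        lr.ordinate(m, scale=True)


def test_ordinate_separates_programmed_treatment_shift(filtered_sim):
    """OT vs HT centroids along PC1 of the TG species separate farther than
    the within-group spread (the generator programs a strong TG shift)."""
    table, _, _ = filtered_sim
    tg = [a for a in table.analytes if table.class_of(a) == "TG"]
    cells = lr.cell_ls_means(table.subset_analytes(tg))
    res = lr.ordinate(cells, scale=True)
    pc1 = res.scores["PC1"]
    treat = cells.index.get_level_values("treatment")
    ot, ht = pc1[treat == "OT"], pc1[treat == "HT"]
    sep = abs(ot.mean() - ht.mean())
    # within-HT spread is genuinely wide: HT response amplitude varies with
    # each genotype's programmed tolerance
    assert sep > max(ot.std(), ht.std())


# -- Spearman co-occurrence -------------------------------------------------

def test_cooccurrence_perfect_monotone():
    t = make_balanced_table(
        {"OT": {"PC 34:2": 1.0, "PE 34:3": 2.0, "TG 54:8": 9.0},
         "HT": {"PC 34:2": 2.0, "PE 34:3": 4.0, "TG 54:8": 1.0}},
        n_genotypes=4, noise_sd=0.0)
    # monotone structure across cells comes from the treatment contrast;
    # add genotype-graded amounts for a strict ordering
    amounts = t.amounts.copy()
    order = np.argsort(t.samples.index)
    amounts["PC 34:2"] += np.linspace(0, 0.5, len(amounts))
    amounts["PE 34:3"] += 2 * np.linspace(0, 0.5, len(amounts))
    amounts["TG 54:8"] = 10 - amounts["PC 34:2"]
    t2 = lr.LipidomeTable(t.samples, amounts, dict(t.species))
    corr = lr.cooccurrence_matrix(t2, observations="replicates")
    assert corr.loc["PC 34:2", "PE 34:3"] == pytest.approx(1.0)
    assert corr.loc["PC 34:2", "TG 54:8"] == pytest.approx(-1.0)


def test_cooccurrence_ties_match_rank_then_pearson():
    """With ties, Spearman equals Pearson on average ranks (brute force)."""
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0])
    expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
    got = stats.spearmanr(x, y).statistic  # route used by cooccurrence_matrix
    assert got == pytest.approx(expected)


def test_cooccurrence_symmetric_unit_diagonal(filtered_sim):
    table, _, _ = filtered_sim
    corr = lr.cooccurrence_matrix(table)
    a = corr.to_numpy()
    assert np.allclose(a, a.T)
    assert np.allclose(np.diag(a), 1.0)
    assert np.nanmax(a) <= 1.0 + 1e-12 and np.nanmin(a) >= -1.0 - 1e-12


def test_cooccurrence_constant_analyte_flagged():
    t = make_balanced_table(
        {"OT": {"PC 34:2": 1.0, "PE 34:3": 2.0, "TG 54:8": 1.0},
         "HT": {"PC 34:2": 2.0, "PE 34:3": 4.0, "TG 54:8": 1.0}},
        n_genotypes=3, noise_sd=0.01, seed=2)
    amounts = t.amounts.copy()
    amounts["TG 54:8"] = 1.0  # constant
    t2 = lr.LipidomeTable(t.samples, amounts, dict(t.species))
    with pytest.warns(UserWarning, match="constant"):
        corr = lr.cooccurrence_matrix(t2, observations="replicates")
    assert corr.loc["TG 54:8", "PC 34:2"] != corr.loc["TG 54:8", "PC 34:2"]  # NaN
    with pytest.warns(UserWarning, match="dropped"):
        ca = lr.cluster_lipids(corr, k=2)
    assert "TG 54:8" not in ca.items


# -- lipid clustering -------------------------------------------------------

def _block_corr():
    """Two perfectly separable blocks with cross-block rho = -1."""
    items = ["A1", "A2", "A3", "B1", "B2"]
    rho = pd.DataFrame(-1.0, index=items, columns=items)
    for grp in (["A1", "A2", "A3"], ["B1", "B2"]):
        for i in grp:
            for j in grp:
                rho.loc[i, j] = 1.0
    return rho


def test_cluster_lipids_recovers_blocks():
    ca = lr.cluster_lipids(_block_corr(), k=2)
    assert set(ca.members(1)) == {"A1", "A2", "A3"}  # largest first
    assert set(ca.members(2)) == {"B1", "B2"}


def test_cluster_lipids_k_equals_n_singletons():
    rho = _block_corr()
    ca = lr.cluster_lipids(rho, k=len(rho))
    assert sorted(ca.labels.unique()) == list(range(1, len(rho) + 1))


def test_cluster_lipids_k_too_large():
    with pytest.raises(ValueError):
        lr.cluster_lipids(_block_corr(), k=6)


def test_cluster_labels_invariant_to_row_order():
    rho = _block_corr()
    perm = ["B2", "A2", "B1", "A3", "A1"]
    ca1 = lr.cluster_lipids(rho, k=2)
    ca2 = lr.cluster_lipids(rho.loc[perm, perm], k=2)
    assert ca1.labels.sort_index().equals(ca2.labels.sort_index())


def test_cluster_newick_export():
    ca = lr.cluster_lipids(_block_corr(), k=2)
    nwk = ca.to_newick()
    assert nwk.strip().endswith(";")
    for item in ca.items:
        assert item in nwk


# -- genotype classification ------------------------------------------------

def test_classify_genotypes_k1_unlabeled(filtered_sim):
    table, _, _ = filtered_sim
    gc = lr.classify_genotypes(table, k=1)
    assert gc.tolerance_labels == {}
    assert set(gc.assignment.labels) == {1}


def test_classify_genotypes_anchor_overrides_score(filtered_sim):
    """With an anchor, the tolerant label follows the anchor's cluster even
    when the score would pick a different cluster."""
    table, truth, _ = filtered_sim
    weak = truth.weak_genotypes[0]
    gc = lr.classify_genotypes(table, k=6, anchors={weak: "tolerant"})
    anchor_cluster = int(gc.assignment.labels[weak])
    assert gc.tolerance_labels[anchor_cluster] == "tolerant"
    assert gc.cluster_scores.idxmax() != anchor_cluster


def test_classify_genotypes_unknown_anchor(filtered_sim):
    table, _, _ = filtered_sim
    with pytest.raises(ValueError, match="NOPE"):
        lr.classify_genotypes(table, anchors={"NOPE": "tolerant"})


def test_genotype_scores_track_programmed_tolerance(filtered_sim):
    """The remodeling score ranks genotypes like the programmed g."""
    table, truth, _ = filtered_sim
    scores = lr.genotype_remodeling_scores(table)
    rho = stats.spearmanr(scores[truth.g.index], truth.g).statistic
    assert rho >= 0.8
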