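"""Unsaturation indices, class summaries, fold changes, LS-means and LSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lipidremodel as lr
from lipidremodel import AcylChain, parse_species
from lipidremodel.remodeling import EmptyClassError

from conftest import make_balanced_table


# -- unsaturation indices ---------------------------------------------------

@pytest.mark.parametrize("name,expected", [
    ("DGDG 36:6", 3.0),
    ("TG 18:3_18:3_18:2", 8 / 3),
    ("PC 34:2", 1.0),
    ("LPC 18:2", 2.0),
])
def test_species_unsaturation_index(name, expected):
    assert lr.species_unsaturation_index(parse_species(name)) == \
        pytest.approx(expected)


def test_species_unsaturation_unsupported_class():
    with pytest.raises(ValueError, match="unsupported"):
        lr.species_unsaturation_index(parse_species("GSL 40:1;O2"))
    with pytest.raises(ValueError, match="unsupported"):
        lr.species_unsaturation_index(parse_species("Sitosterol-Glc"))


def test_class_unsaturation_index_weighted():
    """Hand-computed: UI(36:6)=3, UI(34:3)=1.5, amounts 2:1 -> 2.5."""
    t = make_balanced_table({
        "OT": {"DGDG 36:6": 2.0, "DGDG 34:3": 1.0},
        "HT": {"DGDG 36:6": 2.0, "DGDG 34:3": 1.0}})
    assert lr.class_unsaturation_index(t, "DGDG") == pytest.approx(2.5)


def test_class_unsaturation_index_degenerate_cases():
    single = make_balanced_table({"OT": {"PC 34:2": 5.0},
                                  "HT": {"PC 34:2": 5.0}})
    assert lr.class_unsaturation_index(single, "PC") == pytest.approx(1.0)
    sym = make_balanced_table({
        "OT": {"PC 34:2": 1.0, "PC 36:6": 1.0},
        "HT": {"PC 34:2": 1.0, "PC 36:6": 1.0}})
    assert lr.class_unsaturation_index(sym, "PC") == pytest.approx(2.0)
    zero = make_balanced_table({"OT": {"PC 34:2": 0.0},
                                "HT": {"PC 34:2": 0.0}})
    with pytest.raises(EmptyClassError):
        lr.class_unsaturation_index(zero, "PC")


def test_class_ui_invariant_to_species_splitting():
    """Splitting one species' amount into two identical-composition entries
    leaves the class index unchanged."""
    whole = make_balanced_table({
        "OT": {"DGDG 36:6": 2.0, "DGDG 34:3": 1.0},
        "HT": {"DGDG 36:6": 2.0, "DGDG 34:3": 1.0}})
    split = make_balanced_table({
        "OT": {"DGDG 18:3_18:3": 1.0, "DGDG 36:6": 1.0, "DGDG 34:3": 1.0},
        "HT": {"DGDG 18:3_18:3": 1.0, "DGDG 36:6": 1.0, "DGDG 34:3": 1.0}})
    assert lr.class_unsaturation_index(whole, "DGDG") == \
        pytest.approx(lr.class_unsaturation_index(split, "DGDG"))


# -- class totals and shares ------------------------------------------------

def test_class_shares_toy():
    t = make_balanced_table({
        "OT": {"MGDG 36:6": 49.0, "DGDG 36:6": 51.0},
        "HT": {"MGDG 36:6": 49.0, "DGDG 36:6": 51.0}})
    cs = lr.class_totals_and_shares(t).set_index(["treatment", "lipid_class"])
    assert cs.loc[("OT", "MGDG"), "share"] == pytest.approx(0.49)
    assert cs.loc[("OT", "DGDG"), "share"] == pytest.approx(0.51)


def test_zero_amount_class_leaves_shares_unchanged():
    base = {"MGDG 36:6": 49.0, "DGDG 36:6": 51.0}
    with_zero = dict(base, **{"TG 54:8": 0.0})
    cs1 = lr.class_totals_and_shares(
        make_balanced_table({"OT": base, "HT": base}))
    cs2 = lr.class_totals_and_shares(
        make_balanced_table({"OT": with_zero, "HT": with_zero}))
    s1 = cs1.set_index(["treatment", "lipid_class"])["share"]
    s2 = cs2.set_index(["treatment", "lipid_class"])["share"]
    assert s2.loc[("OT", "MGDG")] == pytest.approx(s1.loc[("OT", "MGDG")])


def test_shares_sum_to_one(filtered_sim):
    table, _, _ = filtered_sim
    cs = lr.class_totals_and_shares(table)
    for t in ("OT", "HT"):
        assert cs.loc[cs.treatment == t, "share"].sum() == pytest.approx(1.0)


# -- fold change ------------------------------------------------------------

def bruteforce_fold_change(table):
    """Independent oracle: enumerate (species, chain position) pairs one by
    one on per-treatment mean amounts (valid on balanced designs where
    LS-means equal treatment means)."""
    exp = table.amounts.loc[~table.qc_mask]
    treat = table.samples.loc[~table.qc_mask, "treatment"]
    means = {t: exp[treat == t].mean(axis=0) for t in ("OT", "HT")}
    sums = {"OT": {}, "HT": {}}
    for analyte in table.analytes:
        sp = table.species[analyte]
        if not sp.acyl_resolved or not sp.chains:
            continue
        for chain in sp.chains:  # one entry per position, multiplicity included
            key = (sp.headgroup.name, str(chain))
            for t in ("OT", "HT"):
                sums[t][key] = sums[t].get(key, 0.0) + means[t][analyte]
    out = {}
    for key, ot in sums["OT"].items():
        out[key] = np.nan if ot <= 0 else sums["HT"][key] / ot
    return out


def test_fold_change_single_species():
    t = make_balanced_table({"OT": {"TG 18:3_18:3_18:3": 1.0},
                             "HT": {"TG 18:3_18:3_18:3": 2.0}})
    fc = lr.acyl_fold_change(t)
    assert fc.cell("TG", "18:3") == pytest.approx(2.0)


def test_fold_change_occurrence_weighting():
    """Hand-computed: (1*1 + 0.5*2) / (2*1 + 1*2) = 0.5 for (PC, 18:3)."""
    t = make_balanced_table({
        "OT": {"PC 16:0_18:3": 2.0, "PC 18:3_18:3": 1.0},
        "HT": {"PC 16:0_18:3": 1.0, "PC 18:3_18:3": 0.5}})
    fc = lr.acyl_fold_change(t)
    assert fc.cell("PC", "18:3") == pytest.approx(0.5)
    # 16:0 occurs once in the first species only: 1.0/2.0
    assert fc.cell("PC", "16:0") == pytest.approx(0.5)


def test_fold_change_undefined_cells():
    t = make_balanced_table({
        "OT": {"TG 18:3_18:3_18:3": 1.0, "PC 16:0_18:1": 0.0},
        "HT": {"TG 18:3_18:3_18:3": 2.0, "PC 16:0_18:1": 1.0}})
    fc = lr.acyl_fold_change(t)
    assert np.isnan(fc.cell("PC", "16:0"))
    assert ("PC", "16:0") in fc.undefined
    assert np.isnan(fc.cell("TG", "16:0"))  # chain absent from class


def test_fold_change_oxidized_chain_not_merged():
    t = make_balanced_table({
        "OT": {"DGDG 18:3_18:3": 1.0, "DGDG 18:3_18:3;O": 1.0},
        "HT": {"DGDG 18:3_18:3": 2.0, "DGDG 18:3_18:3;O": 0.5}})
    fc = lr.acyl_fold_change(t)
    # 18:3 column: (2*2 + 0.5*1)/(2*1 + 1*1) = 1.5; 18:3;O column: 0.5/1
    assert fc.cell("DGDG", "18:3") == pytest.approx(1.5)
    assert fc.cell("DGDG", "18:3;O") == pytest.approx(0.5)


def test_fold_change_matches_bruteforce_on_random_tables():
    rng = np.random.default_rng(7)
    pool = [
        "DGDG 18:3_18:3", "DGDG 16:0_18:3", "MGDG 18:3_18:3",
        "MGDG 18:3_16:0", "PG 18:3_16:1", "PC 16:0_18:2", "PC 18:2_18:2",
        "PE 16:0_18:3", "TG 18:3_18:3_18:2", "TG 16:0_18:2_18:2",
        "sitosterol 18:2", "DG 16:0_18:3", "LPC 18:2", "SQDG 16:0_18:3",
        "DGDG 36:6", "PC 34:2", "DGDG 16:0_18:3;O", "PE 18:2_18:3",
        "Campesterol-Glc 16:0", "PA 18:3_18:3",
    ]
    for trial in range(5):
        k = rng.integers(5, len(pool) + 1)
        species = list(rng.choice(pool, size=k, replace=False))
        ot = {s: float(rng.uniform(0.1, 5)) for s in species}
        ht = {s: float(rng.uniform(0.1, 5)) for s in species}
        t = make_balanced_table({"OT": ot, "HT": ht})
        fc = lr.acyl_fold_change(t)
        oracle = bruteforce_fold_change(t)
        for (cls, ch), expected in oracle.items():
            got = fc.cell(cls, ch)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected), (trial, cls, ch)


# -- treatment comparison ---------------------------------------------------

def test_ls_means_equal_cell_means_noise_free():
    t = make_balanced_table({"OT": {"PC 34:2": 1.0}, "HT": {"PC 34:2": 1.91}})
    res = lr.treatment_comparison(t, "PC 34:2")
    assert res.ls_mean_ot == pytest.approx(1.0)
    assert res.ls_mean_ht == pytest.approx(1.91)
    assert res.mse == pytest.approx(0.0, abs=1e-20)
    assert res.percent_change == pytest.approx(91.0)


def test_lsd_against_textbook_formula():
    """Independent oracle: an OLS fit via pandas dummies + numpy lstsq, and
    the textbook LSD t(0.975, df) * sqrt(2*MSE/n_per_mean)."""
    rng = np.random.default_rng(3)
    t = make_balanced_table(
        {"OT": {"PC 34:2": 1.0}, "HT": {"PC 34:2": 2.0}},
        n_genotypes=2, n_blocks=3, noise_sd=0.01, seed=3)
    res = lr.treatment_comparison(t, "PC 34:2")

    meta = t.samples.loc[~t.qc_mask]
    y = t.amounts.loc[~t.qc_mask, "PC 34:2"].to_numpy()
    X = pd.get_dummies(
        meta.assign(gt=meta.genotype + ":" + meta.treatment)[
            ["genotype", "treatment", "gt", "block"]].astype(str),
        drop_first=True, dtype=float)
    X.insert(0, "intercept", 1.0)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
    resid = y - X.to_numpy() @ beta
    df_err = len(y) - np.linalg.matrix_rank(X.to_numpy())
    mse = resid @ resid / df_err
    n_per_mean = (meta.treatment == "OT").sum()
    lsd = stats.t.ppf(0.975, df_err) * np.sqrt(2 * mse / n_per_mean)

    assert res.df_error == df_err
    assert res.mse == pytest.approx(mse)
    assert res.lsd == pytest.approx(lsd)
    assert res.significant  # effect 1.0 >> noise 0.01


def test_treatment_comparison_class_total_and_trait():
    t = make_balanced_table({
        "OT": {"TG 18:3_18:3_18:3": 1.0, "TG 18:3_18:3_18:2": 0.5},
        "HT": {"TG 18:3_18:3_18:3": 2.0, "TG 18:3_18:3_18:2": 1.0}})
    res = lr.treatment_comparison(t, "TG")
    assert res.ls_mean_ot == pytest.approx(1.5)
    assert res.ls_mean_ht == pytest.approx(3.0)
    # arbitrary trait column (e.g. chlorophyll index)
    trait = pd.Series(
        np.where(t.samples.treatment == "HT", 0.89, 1.0),
        index=t.samples.index, name="chlorophyll")
    res2 = lr.treatment_comparison(t, trait.loc[~t.qc_mask])
    assert res2.percent_change == pytest.approx(-11.0)


@pytest.mark.parametrize("ot,ht,expected", [
    (1.0, 2.52, 152.0),
    (2.0, 1.0, -50.0),
    (1.0, 1.0, 0.0),
])
def test_percent_change(ot, ht, expected):
    assert lr.percent_change(ot, ht) == pytest.approx(expected)


def test_percent_change_requires_positive_reference():
    with pytest.raises(ValueError):
        lr.percent_change(0.0, 1.0)


# -- scale invariance -------------------------------------------------------

def test_scale_invariance():
    """Multiplying all amounts by a constant leaves shares, unsaturation
    indices, fold changes, and percent changes unchanged."""
    ot = {"DGDG 18:3_18:3": 2.0, "DGDG 16:0_18:3": 1.0,
          "TG 18:3_18:3_18:2": 0.2, "PC 34:2": 0.5}
    ht = {"DGDG 18:3_18:3": 1.2, "DGDG 16:0_18:3": 0.9,
          "TG 18:3_18:3_18:2": 0.5, "PC 34:2": 0.6}
    t1 = make_balanced_table({"OT": ot, "HT": ht}, noise_sd=0.05, seed=5)
    c = 37.5
    t2 = lr.LipidomeTable(t1.samples, t1.amounts * c, dict(t1.species))

    cs1 = lr.class_totals_and_shares(t1).set_index(["treatment", "lipid_class"])
    cs2 = lr.class_totals_and_shares(t2).set_index(["treatment", "lipid_class"])
    pd.testing.assert_series_equal(cs1["share"], cs2["share"])

    assert lr.class_unsaturation_index(t1, "DGDG") == \
        pytest.approx(lr.class_unsaturation_index(t2, "DGDG"))

    f1, f2 = lr.acyl_fold_change(t1).fold, lr.acyl_fold_change(t2).fold
    pd.testing.assert_frame_equal(f1, f2)

    r1 = lr.treatment_comparison(t1, "DGDG 18:3_18:3")
    r2 = lr.treatment_comparison(t2, "DGDG 18:3_18:3")
    assert r1.percent_change == pytest.approx(r2.percent_change)
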