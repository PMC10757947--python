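"""Core lipidome remodeling statistics.

* unsaturation indices — mean double bonds per acyl chain at the species
  level, amount-weighted at the class level;
* class totals and composition shares per treatment (on LS-means);
* the occurrence-weighted acyl-chain fold-change matrix (HT/OT per
  class x chain cell), with LSD significance tested on the per-sample
  occurrence-weighted sums;
* generic OT-vs-HT treatment comparisons for analytes, class totals, or
  arbitrary trait columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .design import ComparisonResult, FactorialFit, percent_change
from .io_qc import LipidomeTable
from .nomenclature import (
    AcylChain,
    LipidSpecies,
    UnresolvedSpeciesError,
    count_acyl_occurrences,
)

__all__ = [
    "species_unsaturation_index",
    "class_unsaturation_index",
    "unsaturation_by_treatment",
    "class_totals_and_shares",
    "structural_species_shares",
    "FoldChangeMatrix",
    "acyl_fold_change",
    "treatment_comparison",
    "compare_all_analytes",
    "percent_change",
]

#: default denominator population for species-level composition shares:
#: the diacyl membrane classes plus DG ("structural glycerolipids")
STRUCTURAL_CLASSES = ("DGDG", "MGDG", "SQDG", "PG", "PC", "PE", "PI", "PS",
                      "PA", "DG")


class EmptyClassError(ValueError):
    """A class-level statistic was requested for a class with zero total
    amount (or no retained species)."""


def species_unsaturation_index(species: LipidSpecies) -> float:
    """Average number of C-C double-bond equivalents per acyl chain:
    total double bonds divided by the number of acyl positions of the
    headgroup class. Extra oxygens are ignored."""
    npos = species.headgroup.n_acyl_positions
    if npos is None or npos < 1:
        raise ValueError(
            f"unsupported class {species.headgroup.name}: unknown or zero "
            f"acyl-chain count")
    return species.total_double_bonds / npos


def class_unsaturation_index(
    table: LipidomeTable,
    class_name: str,
    sample_ids: Optional[Sequence[str]] = None,
    weights: Optional[pd.Series] = None,
) -> float:
    """Amount-weighted mean of the member species' unsaturation indices:
    sum(species UI x species amount) / sum(species amount).

    Weights default to the mean amount over ``sample_ids`` (all
    experimental samples when omitted); a precomputed weight vector (e.g.
    treatment LS-means) can be passed instead.
    """
    members = [a for a in table.analytes
               if table.species[a].headgroup.name == class_name]
    if not members:
        raise EmptyClassError(f"no retained species in class {class_name}")
    if weights is None:
        amounts = table.amounts.loc[~table.qc_mask, members]
        if sample_ids is not None:
            amounts = amounts.loc[list(sample_ids)]
        weights = amounts.mean(axis=0)
    else:
        weights = weights.reindex(members)
    total = float(weights.sum())
    if total <= 0:
        raise EmptyClassError(f"class {class_name} has zero total amount")
    ui = np.array([species_unsaturation_index(table.species[a]) for a in members])
    return float((ui * weights.to_numpy()).sum() / total)


def unsaturation_by_treatment(
    table: LipidomeTable,
    classes: Optional[Iterable[str]] = None,
    include_run: bool = False,
) -> pd.DataFrame:
    """Class unsaturation index per treatment, weighting species by their
    treatment LS-mean amounts (rows = classes, columns = OT/HT)."""
    exp = table.experimental()
    fit = FactorialFit(exp.samples, exp.amounts, include_run=include_run)
    lsm = fit.ls_means()
    if classes is None:
        classes = sorted({table.class_of(a) for a in table.analytes
                          if table.species[a].headgroup.n_acyl_positions
                          not in (None, 0)})
    rows = {}
    for cls in classes:
        rows[cls] = {t: class_unsaturation_index(table, cls, weights=lsm.loc[t])
                     for t in ("OT", "HT")}
    return pd.DataFrame(rows).T[["OT", "HT"]]


def class_totals_and_shares(table: LipidomeTable,
                            include_run: bool = False) -> pd.DataFrame:
    """Per treatment and headgroup class: total LS-mean amount and its
    share of the grand total signal. Tidy frame with columns treatment,
    lipid_class, total, share; shares sum to 1 within a treatment."""
    exp = table.experimental()
    fit = FactorialFit(exp.samples, exp.amounts, include_run=include_run)
    lsm = fit.ls_means()  # rows OT/HT, cols analytes
    cls = pd.Series({a: table.class_of(a) for a in table.analytes})
    rows = []
    for t in ("OT", "HT"):
        totals = lsm.loc[t].groupby(cls).sum()
        grand = totals.sum()
        if grand <= 0:
            raise EmptyClassError(f"zero grand total under {t}")
        for c, v in totals.items():
            rows.append((t, c, float(v), float(v / grand)))
    return pd.DataFrame(rows, columns=["treatment", "lipid_class", "total", "share"])


def structural_species_shares(
    table: LipidomeTable,
    classes: Sequence[str] = STRUCTURAL_CLASSES,
    include_run: bool = False,
) -> pd.DataFrame:
    """Composition shares of summed C:DB molecular species (e.g. 36:6)
    within the structural glycerolipids, per treatment."""
    members = [a for a in table.analytes if table.class_of(a) in classes]
    sub = table.subset_analytes(members)
    exp = sub.experimental()
    fit = FactorialFit(exp.samples, exp.amounts, include_run=include_run)
    lsm = fit.ls_means()
    key = pd.Series({
        a: f"{sub.species[a].total_carbons}:{sub.species[a].total_double_bonds}"
        for a in members})
    rows = []
    for t in ("OT", "HT"):
        totals = lsm.loc[t].groupby(key).sum()
        grand = totals.sum()
        for comp, v in totals.sort_values(ascending=False).items():
            rows.append((t, comp, float(v / grand)))
    return pd.DataFrame(rows, columns=["treatment", "species", "share"])


# -- acyl-chain fold change -------------------------------------------------

@dataclass
class FoldChangeMatrix:
    """Headgroup class x acyl chain fold changes (HT/OT) of
    occurrence-weighted summed amounts, with per-cell LSD significance.

    ``fold`` is NaN where the cell is undefined (chain absent from the
    class's resolved species, or OT sum zero); ``undefined`` records the
    reason per such cell.
    """

    fold: pd.DataFrame
    significant: pd.DataFrame
    ls_mean_ot: pd.DataFrame
    ls_mean_ht: pd.DataFrame
    undefined: dict[tuple[str, str], str]

    def cell(self, lipid_class: str, chain: Union[str, AcylChain]) -> float:
        return float(self.fold.loc[lipid_class, str(chain)])


def occurrence_weighted_sums(table: LipidomeTable) -> pd.DataFrame:
    """Per-sample sums of amount x chain-occurrence for every (class, chain)
    pair, using only acyl-resolved species. Columns are a MultiIndex
    (lipid_class, chain)."""
    cols: dict[tuple[str, str], np.ndarray] = {}
    n = len(table.amounts)
    for analyte in table.analytes:
        sp = table.species[analyte]
        if not sp.acyl_resolved or not sp.chains:
            continue
        try:
            counts = count_acyl_occurrences(sp)
        except UnresolvedSpeciesError:
            continue
        vec = table.amounts[analyte].to_numpy(dtype=float)
        for chain, k in counts.items():
            key = (sp.headgroup.name, str(chain))
            cols[key] = cols.get(key, np.zeros(n)) + k * vec
    if not cols:
        raise ValueError("no acyl-resolved species in the table")
    out = pd.DataFrame(cols, index=table.amounts.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["lipid_class", "chain"])
    return out


def _chain_sort_key(chain_str: str) -> tuple:
    c = AcylChain.parse(chain_str)
    return (c.carbons, c.double_bonds, c.extra_oxygens)


def acyl_fold_change(table: LipidomeTable, alpha: float = 0.05,
                     include_run: bool = False) -> FoldChangeMatrix:
    """The fold-change matrix: for each headgroup class and acyl chain,
    [sum over species of amount x occurrences at HT] / [same at OT], on
    treatment LS-means; significance from the LSD test applied to the
    per-sample occurrence-weighted sums."""
    sums = occurrence_weighted_sums(table)
    exp_mask = ~table.qc_mask
    fit = FactorialFit(table.samples.loc[exp_mask], sums.loc[exp_mask],
                       include_run=include_run)
    lsm = fit.ls_means()
    lsd = fit.lsd(alpha)

    # numerical floor: an LS-mean this far below the column's data scale is
    # a zero that picked up floating-point noise in the OLS solve
    floor = 1e-9 * sums.abs().max(axis=0)

    classes = list(dict.fromkeys(c for c, _ in sums.columns))
    chains = sorted({ch for _, ch in sums.columns}, key=_chain_sort_key)
    fold = pd.DataFrame(np.nan, index=classes, columns=chains)
    sig = pd.DataFrame(False, index=classes, columns=chains)
    ot_m = pd.DataFrame(np.nan, index=classes, columns=chains)
    ht_m = pd.DataFrame(np.nan, index=classes, columns=chains)
    undefined: dict[tuple[str, str], str] = {}
    for cls in classes:
        for ch in chains:
            if (cls, ch) not in sums.columns:
                undefined[(cls, ch)] = "chain absent from class"
                continue
            ot = float(lsm.at["OT", (cls, ch)])
            ht = float(lsm.at["HT", (cls, ch)])
            ot_m.loc[cls, ch], ht_m.loc[cls, ch] = ot, ht
            if ot <= max(float(floor[(cls, ch)]), 0.0):
                undefined[(cls, ch)] = "OT occurrence-weighted sum is zero"
                continue
            fold.loc[cls, ch] = ht / ot
            sig.loc[cls, ch] = abs(ht - ot) > lsd[(cls, ch)]
    return FoldChangeMatrix(fold=fold, significant=sig, ls_mean_ot=ot_m,
                            ls_mean_ht=ht_m, undefined=undefined)


# -- generic treatment comparison -------------------------------------------

def _response_series(table: LipidomeTable, response) -> pd.Series:
    if isinstance(response, pd.Series):
        return response
    if isinstance(response, str):
        if response in table.amounts.columns:
            return table.amounts[response]
        members = [a for a in table.analytes
                   if table.class_of(a) == response]
        if members:
            return table.amounts[members].sum(axis=1).rename(response)
        raise KeyError(
            f"{response!r} is neither an analyte nor a headgroup class")
    raise TypeError("response must be an analyte/class name or a Series")


def treatment_comparison(
    table: LipidomeTable,
    response: Union[str, pd.Series],
    alpha: float = 0.05,
    include_run: bool = False,
) -> ComparisonResult:
    """OT-vs-HT comparison of one response variable (an analyte, a headgroup
    class total, or an externally supplied trait column aligned with the
    samples) under the factorial RCBD model: LS-means per treatment with
    standard errors, the LSD threshold, and significance at ``alpha``."""
    y = _response_series(table, response)
    meta = table.samples.loc[~table.qc_mask]
    common = meta.index.intersection(y.index)  # traits may omit QC samples
    fit = FactorialFit(meta.loc[common], y.loc[common].to_frame(),
                       include_run=include_run)
    return fit.compare(alpha)[0]


def compare_all_analytes(table: LipidomeTable, alpha: float = 0.05,
                         include_run: bool = False) -> pd.DataFrame:
    """One OT-vs-HT comparison per analyte, as a tidy frame."""
    mask = ~table.qc_mask
    fit = FactorialFit(table.samples.loc[mask], table.amounts.loc[mask],
                       include_run=include_run)
    rows = []
    for res in fit.compare(alpha):
        rows.append({
            "analyte": res.response,
            "lipid_class": table.class_of(res.response),
            "ls_mean_ot": res.ls_mean_ot,
            "ls_mean_ht": res.ls_mean_ht,
            "lsd": res.lsd,
            "percent_change": res.percent_change,
            "fold_change": res.fold_change,
            "significant": res.significant,
        })
    return pd.DataFrame(rows).set_index("analyte")
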