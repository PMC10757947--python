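"""Multivariate structure: PCA ordination, Spearman co-occurrence
clustering of lipids, and Ward clustering of genotypes with heat-tolerance
labeling.

Co-occurrence works on genotype x treatment LS-means (both treatments
inform the correlation), lipids are clustered by complete linkage on
Euclidean distances between rows of the correlation matrix — the standard
correlation-heatmap construction — and genotypes are clustered by Ward
linkage on z-scored HT LS-means of the tolerance panel (DGDG, MGDG, PG,
TG, SE species). A cluster is called tolerant when it holds the tolerant
anchor genotype or, absent anchors, when it maximizes
mean z(18:3-containing TG and SE) - mean z(18:3-containing DGDG/MGDG/PG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .design import FactorialFit
from .io_qc import LipidomeTable
from .nomenclature import AcylChain, UnresolvedSpeciesError, contains_chain

__all__ = [
    "OrdinationResult",
    "ordinate",
    "cell_ls_means",
    "cooccurrence_matrix",
    "ClusterAssignment",
    "cluster_lipids",
    "GenotypeClassification",
    "classify_genotypes",
    "genotype_remodeling_scores",
    "PANEL_CLASSES",
]

PANEL_CLASSES = ("DGDG", "MGDG", "PG", "TG", "SE")
_STORAGE = ("TG", "SE")
_MEMBRANE = ("DGDG", "MGDG", "PG")
_CHAIN_183 = AcylChain(18, 3, 0)


# -- ordination -------------------------------------------------------------

@dataclass
class OrdinationResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # analytes x components
    explained_variance_ratio: pd.Series
    mean: pd.Series
    scale: Optional[pd.Series] = None


def ordinate(matrix: pd.DataFrame, scale: bool = False,
             n_components: Optional[int] = None) -> OrdinationResult:
    """Principal component analysis of a samples x analytes matrix.

    Columns are centered (and unit-scaled when ``scale``); components are
    ordered by decreasing variance explained with a deterministic sign
    convention (the largest-magnitude loading of each component is
    positive). With all components retained, scores @ loadings.T
    reconstructs the centered (scaled) matrix.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 analytes")
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            names = [str(matrix.columns[i]) for i in bad[:5]]
            raise ValueError(f"constant column(s) cannot be unit-scaled: {names}")
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(Xc.shape)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: flip so each component's largest |loading| is positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s ** 2
    total = (Xc ** 2).sum()
    comp = [f"PC{j + 1}" for j in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(U * s, index=matrix.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=comp),
        explained_variance_ratio=pd.Series(var / total, index=comp),
        mean=pd.Series(mean, index=matrix.columns),
        scale=None if sd is None else pd.Series(sd, index=matrix.columns),
    )


# -- co-occurrence ----------------------------------------------------------

def cell_ls_means(table: LipidomeTable, include_run: bool = False) -> pd.DataFrame:
    """Genotype x treatment LS-means for every analyte (rows indexed by
    (genotype, treatment)); the observation vectors behind co-occurrence."""
    exp = table.experimental()
    fit = FactorialFit(exp.samples, exp.amounts, include_run=include_run)
    return fit.cell_ls_means()


def cooccurrence_matrix(table: LipidomeTable, observations: str = "cells",
                        include_run: bool = False) -> pd.DataFrame:
    """Pairwise Spearman rho among analytes (average-rank tie handling).

    ``observations="cells"`` (default) correlates genotype x treatment
    LS-means; ``"replicates"`` uses the raw experimental samples. Analytes
    that are constant across observations get NaN correlations (flagged
    with a warning) and must be dropped before clustering.
    """
    if observations == "cells":
        obs = cell_ls_means(table, include_run=include_run)
    elif observations == "replicates":
        obs = table.amounts.loc[~table.qc_mask]
    else:
        raise ValueError(f"unknown observations mode {observations!r}")
    X = obs.to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant analyte vector(s); their "
            f"correlations are undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = stats.spearmanr(X).statistic
    if X.shape[1] == 2:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2  # enforce exact symmetry
    return pd.DataFrame(rho, index=obs.columns, columns=obs.columns)


# -- clustering -------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """A flat cut of a hierarchical clustering: item -> label in 1..k.

    Labels are ordered by cluster size (descending), ties broken by the
    lexicographically smallest member, so they do not depend on input row
    order.
    """

    labels: pd.Series
    linkage_matrix: np.ndarray
    method: str
    metric: str
    k: int

    @property
    def items(self) -> list[str]:
        return list(self.labels.index)

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_newick(self) -> str:
        """Render the merge tree as a newick string (leaf names = items,
        branch lengths from merge heights)."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.items)
        return str(tree)


def _relabel_by_size(raw: np.ndarray, items: Sequence[str]) -> np.ndarray:
    order = {}
    for lab in np.unique(raw):
        members = [items[i] for i in np.flatnonzero(raw == lab)]
        order[lab] = (-len(members), min(members))
    ranked = sorted(order, key=order.get)
    remap = {lab: i + 1 for i, lab in enumerate(ranked)}
    return np.array([remap[l] for l in raw])


def cluster_lipids(corr: pd.DataFrame, k: int = 6) -> ClusterAssignment:
    """Complete-linkage agglomeration on Euclidean distances between rows
    of the Spearman correlation matrix, cut into ``k`` clusters."""
    if corr.isna().any().any():
        corr = corr.copy()
        dropped = 0
        while corr.isna().any().any():  # greedily drop the worst offender
            worst = corr.isna().sum(axis=1).idxmax()
            corr = corr.drop(index=worst, columns=worst)
            dropped += 1
        warnings.warn(f"dropped {dropped} analyte(s) with undefined "
                      f"correlations before clustering")
    items = list(corr.index)
    if k > len(items):
        raise ValueError(f"k={k} exceeds the {len(items)} clusterable items")
    D = pdist(corr.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(D, method="complete")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(_relabel_by_size(raw, items), index=items),
        linkage_matrix=Z, method="complete", metric="euclidean", k=k)


# -- genotype tolerance classification --------------------------------------

@dataclass
class GenotypeClassification:
    assignment: ClusterAssignment
    tolerance_labels: dict[int, str]            # cluster -> tolerant/susceptible
    cluster_scores: pd.Series                   # mean remodeling score per cluster
    genotype_scores: pd.Series                  # per-genotype remodeling score
    panel_z: pd.DataFrame                       # genotypes x panel analytes (z)

    def tolerant_genotypes(self) -> list[str]:
        labs = [c for c, v in self.tolerance_labels.items() if v == "tolerant"]
        out: list[str] = []
        for c in labs:
            out += self.assignment.members(c)
        return out

    def susceptible_genotypes(self) -> list[str]:
        labs = [c for c, v in self.tolerance_labels.items() if v == "susceptible"]
        out: list[str] = []
        for c in labs:
            out += self.assignment.members(c)
        return out


def _contains_183(table: LipidomeTable, analyte: str) -> bool:
    sp = table.species[analyte]
    try:
        return contains_chain(sp, _CHAIN_183)
    except UnresolvedSpeciesError:
        return False


def _panel_ht_z(table: LipidomeTable, panel_classes: Sequence[str],
                include_run: bool) -> pd.DataFrame:
    panel = [a for a in table.analytes if table.class_of(a) in panel_classes]
    if not panel:
        raise ValueError(f"no analytes in panel classes {panel_classes}")
    cells = cell_ls_means(table.subset_analytes(panel), include_run=include_run)
    ht = cells.xs("HT", level="treatment")
    sd = ht.std(axis=0, ddof=1).replace(0, np.nan)
    z = (ht - ht.mean(axis=0)) / sd
    return z.dropna(axis=1, how="all").fillna(0.0)


def genotype_remodeling_scores(table: LipidomeTable,
                               panel_z: Optional[pd.DataFrame] = None,
                               panel_classes: Sequence[str] = PANEL_CLASSES,
                               include_run: bool = False) -> pd.Series:
    """Per-genotype remodeling score: mean z of 18:3-containing TG and SE
    analytes minus mean z of 18:3-containing DGDG/MGDG/PG analytes, on HT
    LS-means. High scores mean strong heat-adaptive remodeling."""
    if panel_z is None:
        panel_z = _panel_ht_z(table, panel_classes, include_run)
    up = [a for a in panel_z.columns
          if table.class_of(a) in _STORAGE and _contains_183(table, a)]
    down = [a for a in panel_z.columns
            if table.class_of(a) in _MEMBRANE and _contains_183(table, a)]
    if not up or not down:
        raise ValueError("tolerance score needs 18:3-containing species in both "
                         "the TG/SE and the DGDG/MGDG/PG panel subsets")
    return (panel_z[up].mean(axis=1) - panel_z[down].mean(axis=1)).rename("score")


def classify_genotypes(
    table: LipidomeTable,
    k: int = 6,
    anchors: Optional[Mapping[str, str]] = None,
    panel_classes: Sequence[str] = PANEL_CLASSES,
    include_run: bool = False,
) -> GenotypeClassification:
    """Ward clustering of genotypes on z-scored HT LS-means of the
    tolerance-panel analytes, cut into ``k`` clusters, with tolerance
    labels.

    ``anchors`` maps genotype ids to "tolerant"/"susceptible"; when given,
    the anchor's cluster gets that label. Otherwise the cluster maximizing
    (resp. minimizing) the remodeling score is labeled tolerant (resp.
    susceptible). ``k=1`` yields a single unlabeled cluster.
    """
    z = _panel_ht_z(table, panel_classes, include_run)
    genos = list(z.index)
    if anchors:
        missing = [g for g in anchors if g not in genos]
        if missing:
            raise ValueError(f"anchor genotype(s) not in table: {missing}")
    if k > len(genos):
        raise ValueError(f"k={k} exceeds the {len(genos)} genotypes")
    Z = hierarchy.linkage(pdist(z.to_numpy(dtype=float)), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(_relabel_by_size(raw, genos), index=genos)
    assignment = ClusterAssignment(labels=labels, linkage_matrix=Z,
                                   method="ward", metric="euclidean", k=k)
    scores = genotype_remodeling_scores(table, panel_z=z,
                                        panel_classes=panel_classes,
                                        include_run=include_run)
    cscores = scores.groupby(labels).mean()
    tol_labels: dict[int, str] = {}
    if k > 1:
        if anchors:
            for g, lab in anchors.items():
                tol_labels[int(labels[g])] = lab
        if "tolerant" not in tol_labels.values():
            cand = cscores.drop(
                [c for c, v in tol_labels.items() if v == "susceptible"],
                errors="ignore")
            tol_labels[int(cand.idxmax())] = "tolerant"
        if "susceptible" not in tol_labels.values():
            cand = cscores.drop(
                [c for c, v in tol_labels.items() if v == "tolerant"],
                errors="ignore")
            tol_labels[int(cand.idxmin())] = "susceptible"
    return GenotypeClassification(assignment=assignment,
                                  tolerance_labels=tol_labels,
                                  cluster_scores=cscores,
                                  genotype_scores=scores,
                                  panel_z=z)
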