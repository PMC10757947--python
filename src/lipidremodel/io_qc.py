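"""Lipidome table container, readers/writers, and analyte quality control.

The container holds a samples-by-analytes amount matrix (normalized mass
spectral signal per mg leaf dry weight; a value of 1 corresponds to the
intensity of 1 nmol of internal standard) together with sample metadata:
genotype, temperature treatment (OT = optimal, HT = high), experimental
run, block, and a QC-pool flag. QC-pool samples are repeated measurements
of one pooled extract and carry no genotype/treatment.

Quality filtering removes analytes whose mean signal is below the limit of
detection (default 0.00005) or whose QC-pool coefficient of variation
exceeds 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .nomenclature import (
    DEFAULT_TAXONOMY,
    HeadgroupClass,
    LipidNameError,
    LipidSpecies,
    parse_species,
)

__all__ = [
    "LipidomeTable",
    "read_lipidome",
    "write_lipidome",
    "compute_analyte_cv",
    "analyte_cvs",
    "apply_qc_filters",
    "DEFAULT_LOD",
    "DEFAULT_CV_MAX",
]

DEFAULT_LOD = 0.00005
DEFAULT_CV_MAX = 0.3

TREATMENTS = ("OT", "HT")

_LONG_COLUMNS = ("sample_id", "genotype", "treatment", "run", "block",
                 "is_qc_pool", "species", "amount")
_META_COLUMNS = ("genotype", "treatment", "run", "block", "is_qc_pool")


@dataclass
class LipidomeTable:
    """Samples x analytes amounts plus sample metadata.

    ``samples``: DataFrame indexed by sample_id with columns genotype,
    treatment, run, block, is_qc_pool. ``amounts``: DataFrame with the same
    index and one column per analyte. ``species``: parsed
    :class:`LipidSpecies` per analyte name.
    """

    samples: pd.DataFrame
    amounts: pd.DataFrame
    species: dict[str, LipidSpecies] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.amounts.index):
            raise ValueError("samples and amounts must share the same sample_id index")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample_id")
        if self.amounts.columns.has_duplicates:
            raise ValueError("duplicate analyte names")
        vals = self.amounts.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("missing amounts are not allowed; use explicit 0 "
                             "for below-detection cells")
        if (vals < 0).any():
            raise ValueError("negative amounts are not allowed")
        missing = [c for c in self.amounts.columns if c not in self.species]
        for name in missing:
            self.species[name] = parse_species(name)
        bad_t = self.samples.loc[~self.samples["is_qc_pool"], "treatment"]
        unknown = set(bad_t.unique()) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatment label(s): {sorted(unknown)}")

    # -- convenience views ------------------------------------------------
    @property
    def analytes(self) -> list[str]:
        return list(self.amounts.columns)

    @property
    def qc_mask(self) -> pd.Series:
        return self.samples["is_qc_pool"].astype(bool)

    def experimental(self) -> "LipidomeTable":
        m = ~self.qc_mask
        return LipidomeTable(self.samples.loc[m], self.amounts.loc[m],
                             dict(self.species))

    def qc_pool_amounts(self) -> pd.DataFrame:
        return self.amounts.loc[self.qc_mask]

    def subset_analytes(self, names: Iterable[str]) -> "LipidomeTable":
        names = list(names)
        return LipidomeTable(self.samples, self.amounts[names],
                             {n: self.species[n] for n in names})

    def class_of(self, analyte: str) -> str:
        return self.species[analyte].headgroup.name

    def to_long(self) -> pd.DataFrame:
        long = self.amounts.stack().rename("amount").reset_index()
        long.columns = ["sample_id", "species", "amount"]
        meta = self.samples.reset_index(names="sample_id")
        return meta.merge(long, on="sample_id")[list(_LONG_COLUMNS)]

    def to_wide(self) -> pd.DataFrame:
        return pd.concat([self.samples, self.amounts], axis=1).reset_index(
            names="sample_id")


def _read_df(path, sep: Optional[str]) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def _parse_all(names: Iterable[str], taxonomy) -> dict[str, LipidSpecies]:
    species, errors = {}, []
    for i, name in enumerate(names):
        try:
            species[name] = parse_species(name, taxonomy)
        except LipidNameError as e:
            errors.append(f"  column/row {i}: {e}")
    if errors:
        raise LipidNameError("unparseable species name(s):\n" + "\n".join(errors))
    return species


def read_lipidome(
    path,
    format: Literal["long", "wide"] = "long",
    sep: Optional[str] = None,
    taxonomy: Mapping[str, HeadgroupClass] | None = None,
) -> LipidomeTable:
    """Read a lipidome quantification table from CSV/TSV.

    Long format needs columns sample_id, genotype, treatment, run, block,
    is_qc_pool, species, amount. Wide format needs the same metadata columns
    followed by one column per species.
    """
    df = _read_df(path, sep)
    taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
    if format == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long table missing required column(s): {missing}")
        bad = df["amount"].isna()
        if bad.any():
            raise ValueError(
                f"missing amount at row(s) {list(df.index[bad][:5])}")
        species = _parse_all(pd.unique(df["species"]), taxonomy)
        amounts = df.pivot(index="sample_id", columns="species", values="amount")
        if amounts.isna().any().any():
            raise ValueError("long table is not complete: some (sample, species) "
                             "cells are absent; every cell must be stated")
        meta = (df[["sample_id", *_META_COLUMNS]]
                .drop_duplicates("sample_id").set_index("sample_id"))
        amounts = amounts.loc[meta.index]
        amounts.columns.name = None
    else:
        missing = [c for c in ("sample_id", *_META_COLUMNS) if c not in df.columns]
        if missing:
            raise ValueError(f"wide table missing required column(s): {missing}")
        meta = df.set_index("sample_id")[list(_META_COLUMNS)]
        analyte_cols = [c for c in df.columns
                        if c not in ("sample_id", *_META_COLUMNS)]
        species = _parse_all(analyte_cols, taxonomy)
        amounts = df.set_index("sample_id")[analyte_cols].astype(float)
    meta = meta.copy()
    meta["is_qc_pool"] = meta["is_qc_pool"].astype(bool)
    meta["treatment"] = meta["treatment"].fillna("")
    return LipidomeTable(meta, amounts, species)


def write_lipidome(table: LipidomeTable, path,
                   format: Literal["long", "wide"] = "long",
                   sep: Optional[str] = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = table.to_long() if format == "long" else table.to_wide()
    df.to_csv(path, sep=sep, index=False)


# -- quality control -------------------------------------------------------

def compute_analyte_cv(table: LipidomeTable, analyte: str) -> float:
    """QC-pool coefficient of variation: sample SD (n-1 denominator) of the
    analyte over QC-pool samples divided by their mean; +inf when the mean
    is zero (such analytes are filtered)."""
    qc = table.qc_pool_amounts()[analyte].to_numpy(dtype=float)
    if qc.size < 2:
        raise ValueError(f"need >= 2 QC-pool samples to compute a CV, "
                         f"got {qc.size}")
    mean = qc.mean()
    if mean == 0:
        return math.inf
    return float(qc.std(ddof=1) / mean)


def analyte_cvs(table: LipidomeTable) -> pd.Series:
    """QC CV for every analyte at once."""
    qc = table.qc_pool_amounts()
    if len(qc) < 2:
        raise ValueError("need >= 2 QC-pool samples to compute CVs")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    return cv.where(mean > 0, np.inf)


def apply_qc_filters(
    table: LipidomeTable,
    lod: float = DEFAULT_LOD,
    cv_max: float = DEFAULT_CV_MAX,
    lod_mode: Literal["mean", "any", "all"] = "mean",
) -> tuple[LipidomeTable, pd.DataFrame]:
    """Remove analytes below the limit of detection or with excessive QC CV.

    The LOD rule compares, per analyte, the mean amount over experimental
    (non-QC) samples against ``lod`` with a strict ``<`` (``lod_mode``
    switches to any-sample / all-sample comparison). The CV rule removes
    analytes whose QC-pool CV is strictly greater than ``cv_max``. Returns
    the filtered table and a removal report (analyte, reason, value,
    threshold) with one row per removed analyte; the LOD reason takes
    precedence when both rules fire.
    """
    exp = table.amounts.loc[~table.qc_mask]
    if lod_mode == "mean":
        lod_stat = exp.mean(axis=0)
    elif lod_mode == "any":
        lod_stat = exp.min(axis=0)
    elif lod_mode == "all":
        lod_stat = exp.max(axis=0)
    else:
        raise ValueError(f"unknown lod_mode {lod_mode!r}")
    cvs = analyte_cvs(table)

    rows = []
    removed = []
    for analyte in table.analytes:
        if lod_stat[analyte] < lod:
            rows.append((analyte, "LOD", float(lod_stat[analyte]), lod))
            removed.append(analyte)
        elif cvs[analyte] > cv_max:
            rows.append((analyte, "CV", float(cvs[analyte]), cv_max))
            removed.append(analyte)
    report = pd.DataFrame(rows, columns=["analyte", "reason", "value", "threshold"])
    keep = [a for a in table.analytes if a not in set(removed)]
    return table.subset_analytes(keep), report
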