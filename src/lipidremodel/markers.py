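"""Marker-distribution arithmetic: expected vs observed SNP counts per
chromosome and per 10-Mb bin, with exact-binomial deviation flags.

Expected counts assume an even marker distribution: per chromosome,
(subgenome marker total / subgenome size in Mb) x chromosome size in Mb;
per bin, (chromosome marker total / chromosome size in Mb) x bin width in
Mb (the last, truncated bin's expectation is scaled by its actual width).
The significance procedure is an interpretation — a two-sided exact
binomial test of the observed count against p = expected/total — since no
specific test is prescribed for this arithmetic in the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenomeLayout",
    "read_layout",
    "read_markers",
    "validate_markers",
    "expected_per_chromosome",
    "expected_per_bin",
    "DeviationResult",
    "deviation_test",
    "chromosome_deviation",
    "bin_deviation",
]


@dataclass
class GenomeLayout:
    """Chromosome names, subgenome labels, and sizes in Mb."""

    table: pd.DataFrame  # columns: chrom, subgenome, size_mb

    def __post_init__(self) -> None:
        req = {"chrom", "subgenome", "size_mb"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"layout needs columns {sorted(req)}")
        if (self.table["size_mb"] <= 0).any():
            raise ValueError("chromosome sizes must be positive")
        if self.table["chrom"].duplicated().any():
            raise ValueError("duplicate chromosome names in layout")
        self.table = self.table.reset_index(drop=True)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.table["chrom"])

    def size_mb(self, chrom: str) -> float:
        return float(self.table.set_index("chrom").loc[chrom, "size_mb"])

    def subgenome_sizes(self) -> pd.Series:
        return self.table.groupby("subgenome")["size_mb"].sum()


def read_layout(path, sep: str = "\t") -> GenomeLayout:
    return GenomeLayout(pd.read_csv(path, sep=sep))


def read_markers(path, sep: str = "\t") -> pd.DataFrame:
    """Read a marker set: VCF (plain or bgzipped; only CHROM/POS used, one
    count per record) or a TSV with columns chrom, pos."""
    s = str(path)
    if s.endswith((".vcf", ".vcf.gz")):
        from cyvcf2 import VCF

        rows = [(v.CHROM, v.POS) for v in VCF(s)]
        return pd.DataFrame(rows, columns=["chrom", "pos"])
    df = pd.read_csv(path, sep=sep)
    if not {"chrom", "pos"}.issubset(df.columns):
        raise ValueError("marker table needs columns chrom, pos")
    return df[["chrom", "pos"]]


def validate_markers(layout: GenomeLayout, markers: pd.DataFrame) -> None:
    known = set(layout.chromosomes)
    offenders = sorted(set(markers["chrom"]) - known)
    if offenders:
        raise ValueError(f"marker chromosome(s) not in layout: {offenders}")
    sizes = layout.table.set_index("chrom")["size_mb"] * 1e6
    limit = markers["chrom"].map(sizes)
    bad = (markers["pos"] < 1) | (markers["pos"] > limit)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} marker position(s) outside "
                         f"chromosome bounds")


def expected_per_chromosome(layout: GenomeLayout,
                            markers: pd.DataFrame) -> pd.DataFrame:
    """Observed and expected marker counts per chromosome, with the
    expectation proportional to chromosome size within each subgenome."""
    validate_markers(layout, markers)
    tab = layout.table.copy()
    obs = markers["chrom"].value_counts()
    tab["observed"] = tab["chrom"].map(obs).fillna(0).astype(int)
    sub_tot = tab.groupby("subgenome")["observed"].transform("sum")
    sub_mb = tab.groupby("subgenome")["size_mb"].transform("sum")
    tab["expected"] = sub_tot / sub_mb * tab["size_mb"]
    tab["subgenome_total"] = sub_tot
    return tab


def expected_per_bin(layout: GenomeLayout, markers: pd.DataFrame,
                     bin_mb: float = 10.0) -> pd.DataFrame:
    """Observed and expected marker counts in half-open [start, start+bin)
    Mb bins along each chromosome; the final truncated bin's expectation
    is scaled by its actual width. Bin indices use (pos - 1)/1e6 with
    1-based positions."""
    if bin_mb <= 0:
        raise ValueError("bin_mb must be positive")
    validate_markers(layout, markers)
    rows = []
    by_chrom = dict(tuple(markers.groupby("chrom")))
    for rec in layout.table.itertuples(index=False):
        size, chrom = float(rec.size_mb), rec.chrom
        m = by_chrom.get(chrom)
        pos_mb = (m["pos"].to_numpy(dtype=float) - 1) / 1e6 if m is not None else \
            np.empty(0)
        total = pos_mb.size
        density = total / size  # markers per Mb under uniformity
        n_bins = int(np.ceil(size / bin_mb))
        idx = np.minimum((pos_mb // bin_mb).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        for b in range(n_bins):
            start = b * bin_mb
            end = min(start + bin_mb, size)
            rows.append((chrom, rec.subgenome, start, end,
                         int(counts[b]), density * (end - start), total))
    return pd.DataFrame(rows, columns=["chrom", "subgenome", "bin_start_mb",
                                       "bin_end_mb", "observed", "expected",
                                       "chromosome_total"])


@dataclass(frozen=True)
class DeviationResult:
    p_value: float
    flag: bool
    direction: str  # "high", "low", or "none"


def deviation_test(observed: int, expected: float, total: int,
                   alpha: float = 0.05) -> DeviationResult:
    """Two-sided exact binomial test of ``observed`` successes in ``total``
    trials against p = expected/total; flagged when p < alpha."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= observed <= total:
        raise ValueError("observed must lie in [0, total]")
    if expected <= 0:
        raise ValueError("expected must be positive")
    p0 = expected / total
    if p0 > 1:
        raise ValueError("expected exceeds total")
    res = stats.binomtest(int(observed), n=int(total), p=p0,
                          alternative="two-sided")
    flag = res.pvalue < alpha
    direction = "none"
    if flag:
        direction = "high" if observed > expected else "low"
    return DeviationResult(float(res.pvalue), bool(flag), direction)


def _attach_tests(df: pd.DataFrame, total_col: str, alpha: float) -> pd.DataFrame:
    out = df.copy()
    results = []
    for rec in out.itertuples(index=False):
        total = int(getattr(rec, total_col))
        if total == 0 or rec.expected <= 0:
            results.append(DeviationResult(np.nan, False, "none"))
            continue
        results.append(deviation_test(rec.observed, rec.expected, total, alpha))
    out["p_value"] = [r.p_value for r in results]
    out["flag"] = [r.flag for r in results]
    out["direction"] = [r.direction for r in results]
    return out


def chromosome_deviation(layout: GenomeLayout, markers: pd.DataFrame,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-chromosome observed/expected counts with binomial deviation
    flags (trials = the chromosome's subgenome marker total)."""
    return _attach_tests(expected_per_chromosome(layout, markers),
                         "subgenome_total", alpha)


def bin_deviation(layout: GenomeLayout, markers: pd.DataFrame,
                  bin_mb: float = 10.0, alpha: float = 0.05) -> pd.DataFrame:
    """Per-bin observed/expected counts with binomial deviation flags
    (trials = the chromosome's marker total)."""
    return _attach_tests(expected_per_bin(layout, markers, bin_mb),
                         "chromosome_total", alpha)
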