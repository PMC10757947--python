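"""Expected vs observed SNP counts per chromosome and per 10-Mb bin.

The expectation assumes markers distribute evenly with chromosome size
within each subgenome; an exact two-sided binomial test flags chromosomes
(or bins) that deviate. Here one chromosome is generated 3x enriched.
"""

import pandas as pd

from lipidremodel import (GenomeLayout, bin_deviation, chromosome_deviation,
                          generate_markers)

layout = GenomeLayout(pd.DataFrame({
    "chrom": [f"chr{i}" for i in range(1, 7)],
    "subgenome": ["A"] * 3 + ["B"] * 3,
    "size_mb": [110.0, 95.0, 140.0, 120.0, 105.0, 135.0],
}))
snps = generate_markers(layout, 14000, enrichment={"chr6": 3.0}, seed=2)

dev = chromosome_deviation(layout, snps)
print("per-chromosome observed vs expected:")
print(dev[["chrom", "subgenome", "observed", "expected", "p_value", "flag",
           "direction"]].round(3).to_string(index=False))

bins = bin_deviation(layout, snps, bin_mb=10)
flagged = bins[bins.flag]
print(f"\n{len(flagged)} of {len(bins)} 10-Mb bins deviate from a uniform "
      f"distribution; first few:")
print(flagged.head(5).round(2).to_string(index=False))
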