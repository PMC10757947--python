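"""Co-occurrence clustering of lipids and tolerance classification of
genotypes.

Lipids are clustered on Spearman correlations across genotype x treatment
LS-means (complete linkage); genotypes by Ward linkage on z-scored HT
levels of the DGDG/MGDG/PG/TG/SE panel. The generator plants 5 strong and
5 weak remodelers — the clusters labeled tolerant and susceptible should
recover them.
"""

from lipidremodel import (apply_qc_filters, classify_genotypes,
                          cluster_lipids, cooccurrence_matrix,
                          generate_lipidome)

table, truth = generate_lipidome(seed=1)
filtered, _ = apply_qc_filters(table)

corr = cooccurrence_matrix(filtered)
ca = cluster_lipids(corr, k=6)
print("lipid cluster sizes:", ca.labels.value_counts().sort_index().to_dict())
down, up = "MGDG 18:3_18:3", "TG 18:3_18:3_18:3"
print(f"rho({down}, {up}) = {corr.loc[down, up]:.2f}  "
      f"(clusters {ca.labels[down]} vs {ca.labels[up]}: membrane 18:3 loss "
      f"anti-correlates with TG 18:3 gain)")

gc = classify_genotypes(filtered, k=6)
print("\ncluster mean remodeling scores:",
      gc.cluster_scores.round(2).to_dict())
print("tolerant cluster:", sorted(gc.tolerant_genotypes()))
print("programmed strong remodelers:", sorted(truth.strong_genotypes))
print("susceptible cluster:", sorted(gc.susceptible_genotypes()))
print("programmed weak remodelers:", sorted(truth.weak_genotypes))

# anchor genotypes (e.g. known tolerant/susceptible parents) pin the labels
anchored = classify_genotypes(
    filtered, k=6, anchors={truth.strong_genotypes[0]: "tolerant",
                            truth.weak_genotypes[0]: "susceptible"})
print("anchored labels:", anchored.tolerance_labels)
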