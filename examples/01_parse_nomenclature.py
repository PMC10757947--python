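"""Parse and interrogate lipid shorthand names.

Shows how sum compositions, resolved acyl chains, oxidized chains, and
sterol conjugates are represented, and how chain occurrences are counted.
"""

from lipidremodel import (AcylChain, contains_chain, count_acyl_occurrences,
                          parse_species, species_unsaturation_index)

for name in ["DGDG 36:6", "TG 18:3_18:3_18:2", "DGDG 16:0_18:3;O",
             "sitosterol 18:2", "Sitosterol-Glc"]:
    sp = parse_species(name)
    print(f"{name:20s} class={sp.headgroup.name:4s} "
          f"C:DB={sp.total_carbons}:{sp.total_double_bonds} "
          f"resolved={sp.acyl_resolved}")

tg = parse_species("TG 18:3_18:3_18:2")
print("\nchain occurrences in TG 18:3_18:3_18:2:",
      {str(c): k for c, k in count_acyl_occurrences(tg).items()})
print("contains 18:3?", contains_chain(tg, AcylChain(18, 3)))
# unsaturation index = double bonds per acyl chain: here 8 bonds / 3 chains
print("unsaturation index:", round(species_unsaturation_index(tg), 3))
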