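"""Stop-codon-context codon bias and the overlapping-start-codon artifact.

Simulates a proteome in which 12% of genes have a downstream gene whose
ATG start codon overlaps their TGA stop (the 4-nt A-TGA overlap).  Those
genes necessarily end in an NNA codon, which shows up as an NNA codon
preference in the TGA stop-codon class — until the overlapping genes are
excluded, at which point the preference disappears.
"""

from termbias.bias import stop_context_bias, third_base_comparison
from termbias.proteome import detect_downstream_start_overlap
from termbias.simulate import ProteomeConfig, gen_proteome

table, truth = gen_proteome(
    ProteomeConfig(n_genes=8000, overlap_fraction=0.12, seed=7)
)
flags = detect_downstream_start_overlap(table)
print(f"{sum(flags.values())} of {len(table)} genes carry the AUGA overlap")

for label, kwargs in [
    ("all TGA-context genes", {}),
    ("overlap-flagged genes excluded", {"exclude_overlap": True, "overlap_flags": flags}),
]:
    tga = stop_context_bias(table.records, **kwargs)["TGA"]
    res = third_base_comparison(tga)
    nna = res["nna_vs_others"]
    print(
        f"{label}: mean log2(OR) of NNA codons = {res['mean_log2_or']['A']:+.3f}, "
        f"NNA-vs-others t-test p = {nna['p']:.2e}"
    )

print(
    "\nThe NNA preference in the TGA class is entirely driven by the "
    "overlapping start codons; removing the flagged genes removes the signal."
)
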