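"""Position-specific C-terminal amino-acid bias on a synthetic proteome.

Simulates 20,000 proteins in which lysine is 2.32x more likely than its
bulk frequency at the last position, then recovers that enrichment as a
terminal-vs-bulk odds ratio with Fisher/BH statistics.
"""

from termbias.bias import position_bias
from termbias.simulate import ProteomeConfig, gen_proteome

table, truth = gen_proteome(
    ProteomeConfig(n_genes=20000, mu={"K": {-1: 2.32}}, seed=42)
)
df = position_bias(table.records, positions=[-1])

print(df[df["symbol"].isin(list("KRTML"))][
    ["symbol", "obs_count", "obs_total", "odds_ratio", "q_value", "significant"]
].to_string(index=False))

k = df[df["symbol"] == "K"].iloc[0]
print(
    f"\nInjected lysine multiplier 2.32 at position -1; recovered odds ratio "
    f"{k['odds_ratio']:.2f} (q = {k['q_value']:.2e})."
)
print(
    "An odds ratio > 1 means the residue is enriched at the C-terminus "
    "relative to the bulk of the same sequences; all other residues stay "
    "near 1 under this null-plus-one-injection design."
)
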