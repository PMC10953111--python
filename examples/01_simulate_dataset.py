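"""Generate a small synthetic chromatin study and inspect its planted truth.

The generator lays out a toy fungal genome: genes >= 2 kb apart (a fraction
as divergent pairs sharing one promoter nucleosome), a phased nucleosome
array with an upstream NDR per gene, MNase fragments, replicate ChIP tracks
for H2A.Z / H3K4me3 / H3K27me3, and expression per strain. Everything is a
deterministic function of the seed.
"""

from nucposer import SimConfig, simulate_dataset

cfg = SimConfig(n_genes=60, chrom_length=400_000, seed=11)
ds = simulate_dataset(cfg)

print(f"genes: {len(ds.annotation.genes)}  divergent pairs: {len(ds.annotation.pairs)}")
print(f"MNase fragments: {len(ds.fragments)}")
print("chromatin classes planted:")
print(ds.truth["class_label"].value_counts().to_string())
k27_domains = ds.truth.loc[ds.truth["k27"], "k27_domain"].nunique()
print(f"H3K27me3 domains (>=3 adjacent genes each): {k27_domains}")

# The truth table records, per gene, the planted +1/-1 dyads and expression
# states that the analysis modules are later scored against.
print(ds.truth.head(3).to_string(index=False))
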