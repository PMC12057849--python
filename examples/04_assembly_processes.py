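"""Quantify community assembly processes with betaNTI and RCbray.

For every sample pair the phylogenetic null (tip shuffling) gives betaNTI
and the taxonomic null (probabilistic reassembly) gives RCbray; the pair
is then classified into heterogeneous/homogeneous selection, dispersal
limitation, homogenizing dispersal or undominated. Prints the percentage
contribution of each process overall and per group.
"""

from ecoassembly.assembly import pairwise_assembly, summarize_assembly
from ecoassembly.simulate import SimConfig, simulate_dataset

cfg = SimConfig(n_taxa=250, n_groups=3, reps_per_group=(4, 4, 4), depth=4000,
                selection_strength=0.4, dispersal_rate=0.0,
                env_gradient=(-2.0, 0.0, 2.0), seed=3)
table, tree, _, truth = simulate_dataset(cfg)

pw = pairwise_assembly(table, tree, n_null=199, seed=0)
print(f"{len(pw)} sample pairs; betaNTI range "
      f"[{pw['bnti'].min():.2f}, {pw['bnti'].max():.2f}]")

print("\nprocess contributions, all pairs (%):")
print(summarize_assembly(pw, "all").table.round(1).to_string())
print("\nwithin-group contributions (%):")
print(summarize_assembly(pw, "per-group").table.round(1).to_string())
# betaNTI > 2 between groups reflects the divergent environmental filter
# planted by the generator. Within a group, replicate draws from one pool
# are more similar than the reassembly null expects, which reads as
# homogenizing dispersal.
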