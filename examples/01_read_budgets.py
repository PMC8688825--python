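"""Inverse-genome-size read budgeting and read pre-treatment.

Species with large genomes contribute fewer reads to the pooled clustering:
budgets follow n_i = N * (1/G_i) / sum_j (1/G_j), summing exactly to N.
Reads are then subsampled, trimmed to 100 nt, tagged with the 4-character
species prefix and concatenated into one FASTA pool.
"""

import tempfile
from pathlib import Path

import numpy as np

from repeatfp import SpeciesProfile, allocate_budgets, prepare_reads

profiles = [
    SpeciesProfile("Fragaria_vesca", "FVES", genome_size=0.24),   # 1C Gbp
    SpeciesProfile("Rosa_canina", "RCAN", genome_size=1.13),
    SpeciesProfile("Malus_domestica", "MDOM", genome_size=0.75),
]
profiles = allocate_budgets(profiles, total_reads=3000)
for p in profiles:
    print(f"{p.label:18s} G={p.genome_size:5.2f}  budget={p.budget:5d} reads")
print("total:", sum(p.budget for p in profiles))

# subsample/trim/tag a synthetic read file per species
rng = np.random.default_rng(0)
raw = {
    p.label: [(f"read{i}", "".join(rng.choice(list("ACGT"), 150)))
              for i in range(p.budget + 100)]
    for p in profiles
}
with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "pool.fasta"
    readset = prepare_reads(raw, profiles, trim_to=100, seed=1, out_fasta=out)
    print(f"pooled {len(readset)} reads of {readset.read_length} nt "
          f"-> {out.name}; per species: {readset.counts_per_species()}")
# Each species contributes exactly its budget; identifiers start with the
# 4-character prefix, so species membership survives the pooled clustering.
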