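"""Hybrid genomes in the fingerprint: F1 and matroclinal (Canina-type) mixtures.

A hybrid's repeat pool mixes its parents' copies with maternal weight w
(0.5 for an F1; 0.8 under the asymmetric Canina meiosis, where egg cells
contribute four chromosome sets and pollen one).  The fingerprint places an
F1 between its parents in the PCoA, and a w = 0.8 hybrid closer to its
maternal parent.
"""

from repeatfp import HybridSpec
from repeatfp.fingerprint import gower_distance
from repeatfp.pipeline import run_pipeline, simulate_study

for w, name in ((0.5, "F1"), (0.8, "Canina-type (80% maternal)")):
    spec = HybridSpec("H", maternal="A", paternal="C", maternal_fraction=w)
    reads, *_ = simulate_study(seed=7, hybrid=spec)
    result = run_pipeline(reads, seed=7)
    ax1 = result.pcoa_obs.coordinates.iloc[:, 0]
    g = gower_distance(result.master_obs)
    print(f"\n{name} hybrid of A (maternal) x C (paternal), w={w}:")
    print(f"  PCoA axis 1:  A={ax1['A']:+.3f}  H={ax1['H']:+.3f}  C={ax1['C']:+.3f}")
    print(f"  Gower d(H,A)={g.loc['H', 'A']:.3f}  d(H,C)={g.loc['H', 'C']:.3f}"
          f"  -> closer to {'maternal A' if g.loc['H','A'] < g.loc['H','C'] else 'paternal C'}")
# The w = 0.8 case mirrors matroclinal inheritance: the hybrid's repeatome
# distance to its mother is clearly smaller than to its father.
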