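"""Synthetic repeatome generator with a known phylogeny.

Repeat families (tandem satellites, rDNA-like arrays, dispersed TE-like
elements) evolve from a consensus along a user-supplied tree under a
Jukes–Cantor (JC69) substitution process: per site, the number of
substitution events on a branch is Poisson(rate x branch length) and each
event replaces the base by one of the three others uniformly.  Each species
then receives its copies of every family, with additional per-copy
intra-genomic divergence.  Hybrid genomes are weighted mixtures of parental
repeat pools (w = 0.5 for an F1; w = 0.8 maternal for the asymmetric Canina
meiosis of dogroses, where egg cells contribute four chromosome sets and
pollen one).

Reads are sampled uniformly within repeat copies/arrays, with a configurable
fraction of "background" single-copy reads (i.i.d. random sequence, emulating
the non-repetitive genome fraction which at genome-skimming coverage
essentially never overlaps itself).  A truth table maps every read back to
its family, copy and — for hybrids — parental origin.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from .species import ReadSet, SpeciesProfile, decode_seq, encode_seq

__all__ = [
    "RepeatFamily",
    "HybridSpec",
    "RepeatCopy",
    "evolve_families",
    "make_hybrid",
    "sample_reads",
    "random_sequence",
    "default_families",
    "default_study",
    "ring_satellite_family",
]


@dataclass(frozen=True)
class RepeatFamily:
    """One repeat family in the simulated repeatome.

    ``rate`` is in expected substitutions per site per unit branch length;
    ``intra_divergence`` is the extra per-copy divergence (same units) applied
    within each genome, emulating imperfect homogenization of the family.
    """

    family_id: str
    kind: str  # "tandem" | "dispersed"
    consensus: str
    rate: float = 1.0
    copy_number: int = 20
    annotation_label: str | None = None
    intra_divergence: float = 0.01

    def __post_init__(self):
        if self.kind not in ("tandem", "dispersed"):
            raise ValueError(f"kind must be tandem or dispersed, got {self.kind!r}")
        if len(self.consensus) < 20:
            raise ValueError("monomer/consensus length must be >= 20")
        if self.copy_number < 0:
            raise ValueError("copy number must be non-negative")


@dataclass(frozen=True)
class HybridSpec:
    """A hybrid whose repeat pool mixes two parents with maternal weight w."""

    child: str
    maternal: str
    paternal: str
    maternal_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.maternal_fraction <= 1.0:
            raise ValueError("maternal fraction must lie in [0, 1]")


@dataclass
class RepeatCopy:
    """One repeat copy (or, for tandem families, one full monomer array)."""

    family_id: str
    seq: np.ndarray  # uint8 codes
    annotation_label: str | None = None
    origin: str | None = None  # parental species label, for hybrid pools


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return decode_seq(rng.integers(0, 4, size=length, dtype=np.uint8))


def _mutate(seq: np.ndarray, dist: float, rng: np.random.Generator) -> np.ndarray:
    """JC69 evolution of ``seq`` over total branch length ``dist`` (rate folded in).

    Per site the event count is Poisson(dist); each event jumps to a uniformly
    chosen different base, so P(site unchanged) = 1/4 + 3/4 exp(-4 dist / 3).
    """
    out = seq.copy()
    if dist <= 0:
        return out
    k = rng.poisson(dist, size=out.shape)
    while (active := k > 0).any():
        idx = np.flatnonzero(active)
        jumps = rng.integers(1, 4, size=idx.size, dtype=np.uint8)
        out[idx] = (out[idx] + jumps) % 4
        k[idx] -= 1
    return out


def evolve_families(
    tree: str, families: list[RepeatFamily], seed: int
) -> dict[str, list[RepeatCopy]]:
    """Evolve every family along the Newick ``tree``; return per-species pools.

    Each species pool holds one :class:`RepeatCopy` per dispersed copy, and
    one concatenated monomer array per tandem family.
    """
    tnode = skbio.TreeNode.read(io.StringIO(tree))
    leaves = [t.name for t in tnode.tips()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("tree leaf labels must be unique")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    pools: dict[str, list[RepeatCopy]] = {lab: [] for lab in leaves}
    for fam in families:
        cons = encode_seq(fam.consensus)
        # evolve the consensus down the tree (preorder; root carries cons)
        seqs = {id(tnode): cons}
        for node in tnode.preorder(include_self=False):
            blen = node.length or 0.0
            if blen < 0:
                raise ValueError("branch lengths must be non-negative")
            seqs[id(node)] = _mutate(seqs[id(node.parent)], fam.rate * blen, rng)
        for tip in tnode.tips():
            leaf_seq = seqs[id(tip)]
            copies = [
                _mutate(leaf_seq, fam.intra_divergence, rng)
                for _ in range(fam.copy_number)
            ]
            if not copies:
                continue
            if fam.kind == "tandem":
                pools[tip.name].append(
                    RepeatCopy(fam.family_id, np.concatenate(copies), fam.annotation_label)
                )
            else:
                pools[tip.name].extend(
                    RepeatCopy(fam.family_id, c, fam.annotation_label) for c in copies
                )
    return pools


def make_hybrid(
    pools: dict[str, list[RepeatCopy]],
    spec: HybridSpec,
    seed: int,
    genome_sizes: dict[str, float] | None = None,
) -> tuple[list[RepeatCopy], float | None]:
    """Build a hybrid repeat pool as a weighted resample of the parents.

    For each family, the hybrid receives round(w*n_mat + (1-w)*n_pat) copies;
    each copy is drawn from the maternal pool with probability w and from the
    paternal pool otherwise (falling back to the non-empty parent if a family
    is private to one side).  Returns the pool and, when ``genome_sizes`` is
    given, the hybrid genome size w*G_mat + (1-w)*G_pat.
    """
    for parent in (spec.maternal, spec.paternal):
        if parent not in pools:
            raise ValueError(f"parent {parent!r} not present in the species pools")
    w = spec.maternal_fraction
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def by_family(label):
        out: dict[str, list[RepeatCopy]] = {}
        for c in pools[label]:
            out.setdefault(c.family_id, []).append(c)
        return out

    mat, pat = by_family(spec.maternal), by_family(spec.paternal)
    hybrid: list[RepeatCopy] = []
    for fam_id in sorted(set(mat) | set(pat)):
        n_mat, n_pat = len(mat.get(fam_id, ())), len(pat.get(fam_id, ()))
        n_h = int(round(w * n_mat + (1.0 - w) * n_pat))
        for _ in range(n_h):
            take_mat = rng.random() < w
            source, origin = (
                (mat, spec.maternal) if take_mat else (pat, spec.paternal)
            )
            if not source.get(fam_id):
                source, origin = (
                    (pat, spec.paternal) if take_mat else (mat, spec.maternal)
                )
            copy = source[fam_id][rng.integers(len(source[fam_id]))]
            hybrid.append(
                RepeatCopy(copy.family_id, copy.seq.copy(), copy.annotation_label, origin)
            )
    gsize = None
    if genome_sizes is not None:
        gsize = w * genome_sizes[spec.maternal] + (1.0 - w) * genome_sizes[spec.paternal]
    return hybrid, gsize


def sample_reads(
    pools: dict[str, list[RepeatCopy]],
    profiles: list[SpeciesProfile],
    read_length: int = 100,
    error_rate: float = 0.0,
    background_fraction: float = 0.6,
    seed: int = 0,
    both_strands: bool = True,
) -> tuple[ReadSet, pd.DataFrame]:
    """Sample ``budget`` reads per species; return the pool and a truth table.

    Each read is, with probability ``background_fraction``, an i.i.d. random
    "single-copy" read; otherwise a uniform-start substring of a repeat copy
    chosen with probability proportional to its length (copies shorter than
    the read are excluded).  Reads may come from either strand; sequencing
    error substitutes each base independently with ``error_rate``.
    """
    root = np.random.SeedSequence(seed)
    child = root.spawn(len(profiles))
    ids, rows, spidx = [], [], []
    truth_rows = []

    for i, prof in enumerate(profiles):
        if prof.budget == 0:
            continue
        pool = pools.get(prof.label)
        if not pool:
            raise ValueError(f"empty repeat pool for species {prof.label!r}")
        rng = np.random.default_rng(child[i])
        lengths = np.array([len(c.seq) for c in pool], dtype=float)
        lengths[lengths < read_length] = 0.0
        if lengths.sum() == 0 and background_fraction < 1.0:
            raise ValueError(
                f"species {prof.label!r}: no repeat copy is at least "
                f"{read_length} nt long"
            )
        weights = lengths / lengths.sum() if lengths.sum() else None

        for r in range(prof.budget):
            rid = f"{prof.prefix}r{r:06d}"
            if rng.random() < background_fraction:
                seq = rng.integers(0, 4, size=read_length, dtype=np.uint8)
                fam, copy_idx, start, origin = "background", -1, -1, prof.label
            else:
                copy_idx = int(rng.choice(len(pool), p=weights))
                copy = pool[copy_idx]
                start = int(rng.integers(0, len(copy.seq) - read_length + 1))
                seq = copy.seq[start : start + read_length].copy()
                fam = copy.family_id
                origin = copy.origin or prof.label
            strand = "+"
            if both_strands and rng.random() < 0.5:
                seq = (3 - seq)[::-1]
                strand = "-"
            if error_rate > 0:
                err = rng.random(read_length) < error_rate
                if err.any():
                    jumps = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
                    seq[err] = (seq[err] + jumps) % 4
            ids.append(rid)
            rows.append(seq)
            spidx.append(i)
            truth_rows.append(
                (rid, prof.label, fam, copy_idx, start, strand, origin)
            )

    readset = ReadSet(ids, np.vstack(rows), spidx, profiles)
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "species", "family", "copy_index", "start", "strand", "origin"],
    )
    return readset, truth


def ring_satellite_family(
    rng: np.random.Generator,
    family_id: str = "SAT_ring",
    monomer_length: int = 120,
    copy_number: int = 80,
    annotation_label: str | None = None,
) -> RepeatFamily:
    """A low-divergence tandem satellite preset.

    Reads from such an array tile a near-invariant monomer, so the similarity
    graph of its cluster takes the distinctive ring shape seen for 5S
    rDNA-like satellites.
    """
    return RepeatFamily(
        family_id,
        "tandem",
        random_sequence(rng, monomer_length),
        rate=0.3,
        copy_number=copy_number,
        annotation_label=annotation_label,
        intra_divergence=0.005,
    )


DEFAULT_TREE = (
    "((A:0.01,B:0.01):0.015,(C:0.01,D:0.01):0.015,(E:0.01,F:0.01):0.015);"
)


def default_families(seed: int) -> list[RepeatFamily]:
    """The default 20-family repeatome: 14 dispersed TE-like elements,
    4 tandem satellites, a 45S rDNA-like and a 5S rDNA-like array.

    Divergence rates keep cross-species read identity above the 90% edge
    threshold on the default tree, the precondition for shared clusters.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fams = [
        RepeatFamily(f"TE{i + 1:02d}", "dispersed", random_sequence(rng, 600),
                     rate=1.0, copy_number=30)
        for i in range(14)
    ]
    fams += [
        RepeatFamily(f"SAT{i + 1}", "tandem", random_sequence(rng, 170),
                     rate=1.0, copy_number=60)
        for i in range(4)
    ]
    fams.append(
        RepeatFamily("rDNA_45S", "tandem", random_sequence(rng, 400),
                     rate=1.0, copy_number=40, annotation_label="45S_rDNA")
    )
    fams.append(
        ring_satellite_family(rng, "rDNA_5S", monomer_length=120, copy_number=80,
                              annotation_label="5S_rDNA")
    )
    return fams


def default_study(
    reads_per_species: int = 2000, seed: int = 0
) -> tuple[str, list[RepeatFamily], list[SpeciesProfile]]:
    """The six-species balanced study used throughout the examples and tests:
    equal genome sizes, 20 repeat families, ``reads_per_species`` reads each.
    """
    profiles = [
        SpeciesProfile(lab, lab * 4, genome_size=1.0, budget=reads_per_species)
        for lab in "ABCDEF"
    ]
    return DEFAULT_TREE, default_families(seed), profiles
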