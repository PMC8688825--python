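"""Species metadata, inverse-genome-size read budgeting and read pre-treatment.

The comparative-clustering method deliberately feeds *fewer* reads from large
genomes into the pooled analysis: read budgets are allocated in indirect
(harmonic) proportion to genome size, n_i = N * (1/G_i) / sum_j (1/G_j), so
that species with large, repeat-rich genomes do not dominate the similarity
graph through self-similarity.  Reads are trimmed to a fixed length, tagged
with a unique four-character species prefix, and concatenated into a single
FASTA pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SpeciesProfile",
    "ReadSet",
    "allocate_budgets",
    "prepare_reads",
    "read_species_table",
    "PREFIX_LENGTH",
]

PREFIX_LENGTH = 4

# nucleotide codes used throughout: A=0 C=1 G=2 T=3, anything else = 4 ("N")
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,N/other=4)."""
    return _CODE[np.frombuffer(str(seq).upper().encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


@dataclass(frozen=True)
class SpeciesProfile:
    """One species (or individual) in a comparative study.

    genome_size is in any consistent unit (e.g. 1C Mbp); budget is the number
    of reads allocated to this species by :func:`allocate_budgets`.
    """

    label: str
    prefix: str
    genome_size: float
    budget: int = 0

    def __post_init__(self):
        if len(self.prefix) != PREFIX_LENGTH:
            raise ValueError(
                f"prefix must be exactly {PREFIX_LENGTH} characters, got {self.prefix!r}"
            )
        if not self.genome_size > 0:
            raise ValueError(f"genome size must be positive, got {self.genome_size}")
        if self.budget < 0:
            raise ValueError("budget must be non-negative")


def _check_unique_prefixes(profiles) -> None:
    seen = {}
    for p in profiles:
        if p.prefix in seen:
            raise ValueError(
                f"duplicate prefix {p.prefix!r} for {seen[p.prefix]} and {p.label}"
            )
        seen[p.prefix] = p.label


def read_species_table(path) -> list[SpeciesProfile]:
    """Load a species table TSV with columns label, prefix, genome_size."""
    df = pd.read_csv(path, sep="\t", dtype={"prefix": str})
    profiles = [
        SpeciesProfile(str(r.label), str(r.prefix), float(r.genome_size))
        for r in df.itertuples()
    ]
    _check_unique_prefixes(profiles)
    return profiles


def allocate_budgets(
    profiles: list[SpeciesProfile], total_reads: int, floor: int = 0
) -> list[SpeciesProfile]:
    """Allocate read budgets in indirect proportion to genome size.

    budget_i = round(total_reads * (1/G_i) / sum_j (1/G_j)) with
    largest-remainder rounding so that the budgets sum exactly to
    ``total_reads`` and every budget is at least ``floor``.  Species whose
    harmonic share falls below the floor are pinned to it and the remainder is
    re-shared among the rest.
    """
    if not profiles:
        raise ValueError("no species profiles given")
    _check_unique_prefixes(profiles)
    for p in profiles:
        if not p.genome_size > 0:
            raise ValueError(f"non-positive genome size for {p.label}")
    if total_reads < floor * len(profiles):
        raise ValueError(
            f"total_reads={total_reads} cannot satisfy floor={floor} "
            f"for {len(profiles)} species"
        )

    budgets: dict[str, int] = {}
    active = list(profiles)
    remaining = int(total_reads)
    while True:
        wsum = sum(1.0 / p.genome_size for p in active)
        raw = {p.label: remaining * (1.0 / p.genome_size) / wsum for p in active}
        low = [p for p in active if raw[p.label] < floor]
        if not low:
            break
        for p in low:
            budgets[p.label] = floor
            remaining -= floor
        active = [p for p in active if p not in low]
        if not active:  # everything pinned to the floor
            raw = {}
            break

    # largest-remainder rounding on the still-active species
    base = {lab: math.floor(v) for lab, v in raw.items()}
    leftover = remaining - sum(base.values())
    order = sorted(raw, key=lambda lab: (-(raw[lab] - base[lab]), lab))
    for lab in order[:leftover]:
        base[lab] += 1
    budgets.update(base)

    return [replace(p, budget=budgets[p.label]) for p in profiles]


class ReadSet:
    """A pool of equal-length, prefix-tagged reads from several species.

    Reads are stored as an (n_reads, read_length) uint8 code matrix plus
    parallel arrays of identifiers (prefix + original id) and species
    indices.  This is the in-memory form consumed by the similarity-graph
    builder; :meth:`to_fasta` / :meth:`from_fasta` give the on-disk form.
    """

    def __init__(self, ids, matrix, species_idx, profiles):
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype=np.uint8)
        self.species_idx = np.asarray(species_idx, dtype=np.int64)
        self.profiles = list(profiles)
        if self.matrix.ndim != 2:
            raise ValueError("read matrix must be 2-D (reads x positions)")
        if not (len(self.ids) == self.matrix.shape[0] == len(self.species_idx)):
            raise ValueError("ids, matrix and species indices must align")
        prefixes = {p.prefix: i for i, p in enumerate(self.profiles)}
        for rid in self.ids:
            if rid[:PREFIX_LENGTH] not in prefixes:
                raise ValueError(f"read id {rid!r} has no registered prefix")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def read_length(self) -> int:
        return self.matrix.shape[1]

    @property
    def species_labels(self) -> list[str]:
        return [p.label for p in self.profiles]

    def counts_per_species(self) -> dict[str, int]:
        counts = np.bincount(self.species_idx, minlength=len(self.profiles))
        return {p.label: int(c) for p, c in zip(self.profiles, counts)}

    def sequences(self) -> list[str]:
        return [decode_seq(row) for row in self.matrix]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.matrix):
                fh.write(f">{rid}\n{decode_seq(row)}\n")

    @classmethod
    def from_fasta(cls, path, profiles) -> "ReadSet":
        prefix_to_idx = {p.prefix: i for i, p in enumerate(profiles)}
        ids, rows, spidx = [], [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            pref = rec.id[:PREFIX_LENGTH]
            if pref not in prefix_to_idx:
                raise ValueError(f"read {rec.id!r}: prefix {pref!r} not registered")
            ids.append(rec.id)
            rows.append(encode_seq(str(rec.seq)))
            spidx.append(prefix_to_idx[pref])
        if not rows:
            raise ValueError(f"no reads found in {path}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal read lengths in {path}: {sorted(lengths)}")
        return cls(ids, np.vstack(rows), spidx, profiles)


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def prepare_reads(
    raw: dict[str, object],
    profiles: list[SpeciesProfile],
    trim_to: int = 100,
    seed: int = 0,
    out_fasta=None,
) -> ReadSet:
    """Subsample, trim and prefix-tag reads into one concatenated pool.

    ``raw`` maps species label -> FASTA/FASTQ path, or -> in-memory list of
    ``(id, sequence)`` pairs.  For each species exactly ``budget`` reads are
    drawn uniformly at random without replacement (reads shorter than
    ``trim_to`` are skipped first), truncated to the first ``trim_to`` bases
    and renamed ``prefix + original id``.  Sampling is seeded and the output
    (including FASTA bytes) is deterministic for a given seed.
    """
    _check_unique_prefixes(profiles)
    root = np.random.SeedSequence(seed)
    child_seeds = root.spawn(len(profiles))

    ids, rows, spidx = [], [], []
    for i, prof in enumerate(profiles):
        if prof.budget == 0:
            continue
        source = raw.get(prof.label)
        if source is None:
            raise ValueError(f"no raw reads supplied for species {prof.label!r}")
        if isinstance(source, (str, Path)):
            path = Path(source)
            records = [
                (rec.id, str(rec.seq))
                for rec in SeqIO.parse(str(path), _sniff_format(path))
            ]
        else:
            records = [(rid, str(seq)) for rid, seq in source]
        usable = [(rid, seq) for rid, seq in records if len(seq) >= trim_to]
        if len(usable) < prof.budget:
            raise ValueError(
                f"species {prof.label!r}: only {len(usable)} usable reads "
                f"(length >= {trim_to}) for a budget of {prof.budget}"
            )
        rng = np.random.default_rng(child_seeds[i])
        take = np.sort(rng.choice(len(usable), size=prof.budget, replace=False))
        for j in take:
            rid, seq = usable[j]
            ids.append(prof.prefix + rid)
            rows.append(encode_seq(seq[:trim_to]))
            spidx.append(i)

    if not rows:
        raise ValueError("all species have zero budget; nothing to prepare")
    readset = ReadSet(ids, np.vstack(rows), spidx, profiles)
    if out_fasta is not None:
        readset.to_fasta(out_fasta)
    return readset
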