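"""Seeded synthetic proteomes, libraries and expression tables with ground truth.

Every pipeline stage is testable offline: the generator emits a
proteome FASTA whose background residues are drawn i.i.d. from a
configurable frequency vector, overwrites planted peptide occurrences
at known coordinates, and records exactly those plants in a truth
table. Because planting overwrites rather than inserts, protein lengths
are exact; because the background is i.i.d., the expected number of
coincidental occurrences of a length-k peptide has the closed form
sum over proteins of (L - k + 1) * prod(f(residue)) — used to sanity-check
the generator itself.

All randomness flows from a single integer seed through independent
named streams (lengths / background / placements / library /
expression), so identical specs reproduce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._masses import AVERAGE
from .errors import ValidationError
from .library_io import (
    BiopeptideLibrary,
    BiopeptideRecord,
    ExpressionRecord,
    MassSpec,
    ProteinRecord,
    compute_peptide_mass,
)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_BYTES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# 18 activity-category labels mirroring the granularity of curated
# bioactive-peptide databases; used round-robin by generate_library.
DEFAULT_ACTIVITIES: tuple[str, ...] = (
    "ACE inhibitor",
    "DPP-4 inhibitor",
    "antioxidative",
    "antibacterial",
    "anticancer",
    "antithrombotic",
    "immunomodulating",
    "opioid",
    "antiamnestic",
    "hypotensive",
    "renin inhibitor",
    "antiviral",
    "antiaging",
    "hypocholesterolemic",
    "stimulating",
    "binding",
    "neuropeptide",
    "alpha-glucosidase inhibitor",
)


@dataclass(frozen=True)
class Plant:
    """One peptide occurrence to write into the background."""

    peptide_id: str
    sequence: str
    protein_index: int  # 0-based index into the generated proteome
    start: int          # 1-based position within the protein


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic proteome.

    Defaults emulate a plant-proteome scan at reduced size: protein
    lengths are normal(400, 100) residues (clipped at 1), background
    residue usage uniform over the 20 standard amino acids.
    """

    n_proteins: int = 1000
    length_mean: float = 400.0
    length_sd: float = 100.0
    residue_frequencies: tuple[float, ...] | None = None  # order = ALPHABET
    plants: tuple[Plant, ...] = ()
    seed: int = 0
    protein_id_prefix: str = "p"

    def frequencies(self) -> np.ndarray:
        if self.residue_frequencies is None:
            return np.full(20, 1 / 20)
        f = np.asarray(self.residue_frequencies, dtype=float)
        if f.shape != (20,):
            raise ValidationError("residue_frequencies must have 20 entries")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError("residue_frequencies must sum to 1")
        if (f < 0).any():
            raise ValidationError("residue_frequencies must be non-negative")
        return f

    def validate(self) -> None:
        if self.n_proteins < 0:
            raise ValidationError("n_proteins must be >= 0")
        self.frequencies()
        for p in self.plants:
            if not (0 <= p.protein_index < self.n_proteins):
                raise ValidationError(
                    f"plant {p.peptide_id!r}: protein_index {p.protein_index} out of range"
                )
            if p.start < 1:
                raise ValidationError(f"plant {p.peptide_id!r}: start must be >= 1")


@dataclass(frozen=True)
class TruthRow:
    protein_id: str
    peptide_id: str
    start: int
    end: int


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tpeptide_id\tstart\tend\n")
            for r in self.rows:
                fh.write(f"{r.protein_id}\t{r.peptide_id}\t{r.start}\t{r.end}\n")

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        rows = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                prot, pep, start, end = line.rstrip("\n").split("\t")
                rows.append(TruthRow(prot, pep, int(start), int(end)))
        return cls(rows)


def _stream(seed: int, channel: int) -> np.random.Generator:
    return np.random.default_rng([seed, channel])


def _draw_lengths(spec: SyntheticSpec) -> np.ndarray:
    rng = _stream(spec.seed, 1)
    raw = rng.normal(spec.length_mean, spec.length_sd, size=spec.n_proteins)
    return np.maximum(np.rint(raw).astype(int), 1)


def generate_proteome(
    spec: SyntheticSpec,
    *,
    plant_pool: Sequence[tuple[str, str]] | BiopeptideLibrary | None = None,
    n_random_plants: int = 0,
) -> tuple[list[ProteinRecord], TruthTable]:
    """Generate a proteome plus the truth table of planted occurrences.

    Explicit plants come from ``spec.plants``; additionally
    ``n_random_plants`` placements are drawn (uniform protein, uniform
    valid position, non-overlapping with previous plants in the same
    protein) from ``plant_pool``, a library or ``(peptide_id, sequence)``
    sequence. A plant that cannot fit raises a spec error. The truth
    table records exactly the planted occurrences; the background may
    coincidentally contain further occurrences, so a scan recovers a
    superset of the truth table.
    """
    spec.validate()
    lengths = _draw_lengths(spec)
    freqs = spec.frequencies()
    total = int(lengths.sum())
    rng_bg = _stream(spec.seed, 2)
    codes = rng_bg.choice(20, size=total, p=freqs)
    flat = bytearray(_ALPHABET_BYTES[codes].tobytes())

    offsets = np.concatenate([[0], np.cumsum(lengths)])
    width = max(4, len(str(max(spec.n_proteins, 1))))
    ids = [f"{spec.protein_id_prefix}{i + 1:0{width}d}" for i in range(spec.n_proteins)]

    occupied: dict[int, list[tuple[int, int]]] = {}
    truth_rows: list[TruthRow] = []
    planted_seqs: list[str] = []

    def place(peptide_id: str, seq: str, pidx: int, start: int) -> None:
        k = len(seq)
        end = start + k - 1
        if end > lengths[pidx]:
            raise ValidationError(
                f"plant {peptide_id!r} at protein {pidx}, start {start}: "
                f"extends beyond protein length {lengths[pidx]}"
            )
        off = int(offsets[pidx])
        flat[off + start - 1 : off + end] = seq.encode()
        occupied.setdefault(pidx, []).append((start, end))
        truth_rows.append(TruthRow(ids[pidx], peptide_id, start, end))
        planted_seqs.append(seq)

    for p in spec.plants:
        place(p.peptide_id, p.sequence.upper(), p.protein_index, p.start)

    if n_random_plants:
        if plant_pool is None:
            raise ValidationError("n_random_plants > 0 requires a plant_pool")
        pool = (
            [(r.peptide_id, r.sequence) for r in plant_pool]
            if isinstance(plant_pool, BiopeptideLibrary)
            else list(plant_pool)
        )
        if not pool:
            raise ValidationError("plant_pool is empty")
        rng_plant = _stream(spec.seed, 3)
        for _ in range(n_random_plants):
            pep_id, seq = pool[int(rng_plant.integers(len(pool)))]
            placed = False
            for _attempt in range(1000):
                pidx = int(rng_plant.integers(spec.n_proteins))
                max_start = int(lengths[pidx]) - len(seq) + 1
                if max_start < 1:
                    continue
                start = int(rng_plant.integers(1, max_start + 1))
                end = start + len(seq) - 1
                if any(s <= end and start <= e for s, e in occupied.get(pidx, [])):
                    continue
                place(pep_id, seq.upper(), pidx, start)
                placed = True
                break
            if not placed:
                raise ValidationError(
                    f"could not place peptide {pep_id!r} after 1000 attempts"
                )

    proteins = [
        ProteinRecord(ids[i], "synthetic", flat[int(offsets[i]): int(offsets[i + 1])].decode())
        for i in range(spec.n_proteins)
    ]
    by_id = {p.protein_id: p for p in proteins}
    for r, seq in zip(truth_rows, planted_seqs):  # self-check: slice equality
        if by_id[r.protein_id].slice(r.start, r.end) != seq:
            raise ValidationError(
                f"planted occurrence of {r.peptide_id!r} in {r.protein_id} was "
                "overwritten by a later plant (overlapping explicit plants?)"
            )
    truth_rows.sort(key=lambda r: (r.protein_id, r.start, r.peptide_id))
    return proteins, TruthTable(truth_rows)


def generate_library(
    n: int,
    length_range: tuple[int, int] = (2, 60),
    activities: Sequence[str] = DEFAULT_ACTIVITIES,
    seed: int = 0,
) -> BiopeptideLibrary:
    """Synthetic biopeptide library: n records, lengths uniform in range,
    activity labels assigned round-robin, stated masses computed from the
    average residue table (so mass validation passes at 0.01 Da)."""
    lo, hi = length_range
    if n < 0:
        raise ValidationError("n must be >= 0")
    if not (1 <= lo <= hi):
        raise ValidationError(f"invalid length range {length_range}")
    rng = _stream(seed, 4)
    records = []
    for i in range(n):
        k = int(rng.integers(lo, hi + 1))
        seq = "".join(ALPHABET[c] for c in rng.integers(0, 20, size=k))
        act = activities[i % len(activities)]
        records.append(
            BiopeptideRecord(
                peptide_id=f"BP{i + 1:05d}",
                name=f"synthetic {act} peptide {i + 1}",
                sequence=seq,
                mass=round(compute_peptide_mass(seq, MassSpec("average", 0.01)), 4),
                activities=(act,),
                out_of_range=not (2 <= k <= 60),
            )
        )
    return BiopeptideLibrary(records, provenance=f"synthetic(seed={seed})")


def generate_expression(
    gene_ids: Sequence[str],
    fraction_up: float = 0.3,
    effect: float = 2.0,
    seed: int = 0,
) -> tuple[list[ExpressionRecord], list[str]]:
    """Expression table with a known upregulated subset.

    The chosen fraction of genes gets log2fc = +effect; the rest draw
    uniformly from [-3, 0.5], i.e. strictly below the conventional
    upregulation cutoff of 1.0. Returns the records (input gene order)
    and the truth list of upregulated gene ids.
    """
    if not 0 <= fraction_up <= 1:
        raise ValidationError("fraction_up must be in [0, 1]")
    rng = _stream(seed, 5)
    n = len(gene_ids)
    n_up = int(round(fraction_up * n))
    up_idx = set(rng.choice(n, size=n_up, replace=False).tolist()) if n_up else set()
    records = []
    truth = []
    for i, gid in enumerate(gene_ids):
        if i in up_idx:
            fc = float(effect)
            truth.append(gid)
        else:
            fc = float(rng.uniform(-3.0, 0.5))
        records.append(ExpressionRecord(gid, round(fc, 4), "seed_vs_leaf"))
    return records, truth


def expected_background_hits(
    sequence: str, lengths: Iterable[int], freqs: Mapping[str, float] | None = None
) -> float:
    """Expected coincidental occurrences of ``sequence`` in an i.i.d.
    background: sum over proteins of (L - k + 1) * prod f(residue)."""
    if freqs is None:
        freqs = {c: 1 / 20 for c in ALPHABET}
    p = math.prod(freqs[c] for c in sequence)
    k = len(sequence)
    return float(sum(max(L - k + 1, 0) for L in lengths) * p)


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            header = f">{p.protein_id}" + (f" {p.description}" if p.description else "")
            fh.write(header + "\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def write_expression(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tcontrast\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc}\t{r.contrast}\n")
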