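"""Input models and parsers: biopeptide library, proteome FASTA, expression table.

The reference library is a delimited text file (TSV or CSV) with five
fields per curated peptide: an identifier, a free-text biological-role
name, the amino-acid sequence, an optional chemical mass in daltons, and
one or more biological-activity category labels. Header spelling is
normalised through an alias table, so both canonical headers
(``id, name, sequence, mass, activity``) and the variants seen in
published BIOPEP-UWM exports (including ``biopeptid_name``) load without
configuration.

Bioactive peptides are, by the working definition used here, small:
2-60 residues. Records outside that range are rejected unless loaded
with ``allow_out_of_range=True``, in which case they are kept and tagged.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from ._masses import (
    AVERAGE,
    MONOISOTOPIC,
    STANDARD_RESIDUES,
    WATER_AVERAGE,
    WATER_MONOISOTOPIC,
)
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

MIN_PEPTIDE_LENGTH = 2
MAX_PEPTIDE_LENGTH = 60

# header-alias table: normalised header -> canonical field
_HEADER_ALIASES: dict[str, str] = {
    "id": "id",
    "peptide_id": "id",
    "biopeptide_id": "id",
    "name": "name",
    "peptide_name": "name",
    "biopeptide_name": "name",
    "biopeptid_name": "name",  # spelling used in published library exports
    "biological_role": "name",
    "sequence": "sequence",
    "seq": "sequence",
    "peptide_sequence": "sequence",
    "mass": "mass",
    "chemical_mass": "mass",
    "activity": "activity",
    "activities": "activity",
    "activity_category": "activity",
    "biological_activity_category": "activity",
}

_MANDATORY_FIELDS = ("id", "name", "sequence", "activity")


@dataclass(frozen=True)
class BiopeptideRecord:
    """One curated bioactive peptide (a library row)."""

    peptide_id: str
    name: str
    sequence: str
    mass: float | None
    activities: tuple[str, ...]
    out_of_range: bool = False

    def __post_init__(self) -> None:
        if not self.activities:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: empty activity set"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class BiopeptideLibrary:
    """Ordered, id-unique collection of :class:`BiopeptideRecord`.

    The library is *type*-indexed: distinct records may share an
    identical sequence (the same peptide can be curated under several
    roles), but ``peptide_id`` is unique.
    """

    records: list[BiopeptideRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self._by_id: dict[str, BiopeptideRecord] = {}
        for rec in self.records:
            if rec.peptide_id in self._by_id:
                raise ValidationError(f"duplicate peptide_id {rec.peptide_id!r}")
            self._by_id[rec.peptide_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BiopeptideRecord]:
        return iter(self.records)

    def __contains__(self, peptide_id: str) -> bool:
        return peptide_id in self._by_id

    def get(self, peptide_id: str) -> BiopeptideRecord:
        return self._by_id[peptide_id]

    @property
    def activities(self) -> tuple[str, ...]:
        """All activity labels, sorted, deduplicated."""
        return tuple(sorted({a for r in self.records for a in r.activities}))


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry. Positions on the sequence are 1-based inclusive."""

    protein_id: str
    description: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates."""
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    log2fc: float
    contrast: str = ""


@dataclass(frozen=True)
class MassSpec:
    """Which residue-mass table to use and at what tolerance (Da)."""

    mode: str = "average"  # "average" | "monoisotopic"
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("average", "monoisotopic"):
            raise ValueError(f"unknown mass mode {self.mode!r}")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")


def _normalise_header(header: str) -> str:
    h = header.strip().lower()
    if "(" in h:  # drop parenthetical remarks, e.g. "(biological role)"
        h = h.split("(", 1)[0].strip()
    return h.replace(" ", "_")


def _detect_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    return "," if path.suffix.lower() == ".csv" else "\t"


def _map_columns(columns: Iterable[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map raw file headers to canonical field names.

    ``column_map`` lets a caller bind arbitrary headers to canonical
    fields (raw header -> canonical name); it takes precedence over the
    built-in alias table.
    """
    out: dict[str, str] = {}
    extra = {(_normalise_header(k)): v for k, v in (column_map or {}).items()}
    for col in columns:
        norm = _normalise_header(col)
        canon = extra.get(norm) or _HEADER_ALIASES.get(norm)
        if canon and canon not in out.values():
            out[col] = canon
    return out


def load_library(
    path: str | Path,
    *,
    strict: bool = True,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
    activity_delimiter: str = ";",
    allow_out_of_range: bool = False,
) -> BiopeptideLibrary:
    """Read and validate a biopeptide library from delimited text.

    In strict mode any invalid row (non-standard residue, bad mass,
    out-of-range length without the override) raises
    :class:`ValidationError` naming the row; in lenient mode invalid rows
    are skipped and a count is logged. Duplicate peptide ids are an error
    in either mode.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = _map_columns(df.columns, column_map)
    have = set(colmap.values())
    missing = [f for f in _MANDATORY_FIELDS if f not in have]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"headers found: {list(df.columns)}"
        )
    df = df.rename(columns=colmap)

    records: list[BiopeptideRecord] = []
    seen: set[str] = set()
    n_skipped = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        pid = str(getattr(row, "id")).strip()
        seq = str(getattr(row, "sequence")).strip().upper()
        problems: list[str] = []
        bad = sorted(set(seq) - STANDARD_RESIDUES)
        if not seq:
            problems.append("empty sequence")
        elif bad:
            problems.append(f"non-standard residue(s) {''.join(bad)!r} in sequence {seq!r}")
        out_of_range = not (MIN_PEPTIDE_LENGTH <= len(seq) <= MAX_PEPTIDE_LENGTH)
        if out_of_range and not allow_out_of_range and not problems:
            problems.append(
                f"length {len(seq)} outside [{MIN_PEPTIDE_LENGTH}, {MAX_PEPTIDE_LENGTH}] "
                "(pass allow_out_of_range=True to keep)"
            )
        mass_raw = str(getattr(row, "mass", "")).strip() if "mass" in have else ""
        mass: float | None = None
        if mass_raw:
            try:
                mass = float(mass_raw)
            except ValueError:
                problems.append(f"non-numeric mass {mass_raw!r}")
        acts = tuple(
            dict.fromkeys(
                a.strip()
                for a in str(getattr(row, "activity")).split(activity_delimiter)
                if a.strip()
            )
        )
        if not acts:
            problems.append("empty activity field")
        if problems:
            msg = f"{path} row {row_no} (peptide {pid!r}): " + "; ".join(problems)
            if strict:
                raise ValidationError(msg)
            logger.warning("skipping: %s", msg)
            n_skipped += 1
            continue
        if pid in seen:
            raise ValidationError(f"{path} row {row_no}: duplicate peptide_id {pid!r}")
        seen.add(pid)
        records.append(
            BiopeptideRecord(pid, str(getattr(row, "name")).strip(), seq, mass, acts,
                             out_of_range=out_of_range)
        )
    if n_skipped:
        logger.warning("%s: skipped %d invalid row(s) in lenient mode", path, n_skipped)
    return BiopeptideLibrary(records, provenance=str(path))


def write_library(
    lib: BiopeptideLibrary,
    path: str | Path,
    *,
    delimiter: str | None = None,
    activity_delimiter: str = ";",
) -> None:
    """Write a library back to delimited text (round-trips with ``load_library``)."""
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["id", "name", "sequence", "mass", "activity"])
        for r in lib:
            w.writerow(
                [
                    r.peptide_id,
                    r.name,
                    r.sequence,
                    "" if r.mass is None else repr(r.mass),
                    activity_delimiter.join(r.activities),
                ]
            )


def load_proteome(path: str | Path) -> list[ProteinRecord]:
    """Parse an amino-acid FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; a single trailing stop symbol ``*`` is
    stripped; internal ``*`` (and any ambiguity codes) are kept verbatim
    and simply can never be matched. Duplicate ids are an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_nt_like = 0
    total_residues = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValidationError(f"{path}: duplicate protein_id {pid!r}")
        seen.add(pid)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        n_nt_like += sum(seq.count(c) for c in "ACGTN")
        total_residues += len(seq)
        records.append(ProteinRecord(pid, desc, seq))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    elif total_residues and n_nt_like / total_residues >= 0.95:
        logger.warning(
            "%s: %.1f%% of residues are ACGTN — is this a nucleotide file?",
            path, 100 * n_nt_like / total_residues,
        )
    return records


def load_expression(
    path: str | Path, *, delimiter: str | None = None
) -> list[ExpressionRecord]:
    """Read a differential-expression table (columns ``gene_id``, ``log2fc``).

    Rows with a non-numeric or non-finite log2 fold-change are rejected
    with their row number logged; extra columns are ignored. An optional
    ``contrast`` column is carried through.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = {_normalise_header(c): c for c in df.columns}
    if "gene_id" not in cols or "log2fc" not in cols:
        raise SchemaError(
            f"{path}: need columns gene_id and log2fc; found {list(df.columns)}"
        )
    i_fc = df.columns.get_loc(cols["log2fc"])
    i_gene = df.columns.get_loc(cols["gene_id"])
    i_contrast = df.columns.get_loc(cols["contrast"]) if "contrast" in cols else None
    records: list[ExpressionRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        raw = str(row[i_fc]).strip()
        gene = str(row[i_gene]).strip()
        contrast = str(row[i_contrast]).strip() if i_contrast is not None else ""
        try:
            val = float(raw)
        except ValueError:
            logger.warning("%s row %d: non-numeric log2fc %r — rejected", path, row_no, raw)
            continue
        if not math.isfinite(val):
            logger.warning("%s row %d: non-finite log2fc %r — rejected", path, row_no, raw)
            continue
        records.append(ExpressionRecord(gene, val, contrast))
    return records


def compute_peptide_mass(sequence: str, spec: MassSpec = MassSpec()) -> float:
    """Chemical mass of a peptide: sum of residue masses plus one water (Da)."""
    if not sequence:
        raise ValidationError("cannot compute the mass of an empty sequence")
    seq = sequence.upper()
    table, water = (
        (AVERAGE, WATER_AVERAGE) if spec.mode == "average" else (MONOISOTOPIC, WATER_MONOISOTOPIC)
    )
    try:
        return sum(table[c] for c in seq) + water
    except KeyError as exc:
        raise ValidationError(
            f"non-standard residue {exc.args[0]!r} in sequence {sequence!r}"
        ) from None


@dataclass(frozen=True)
class MassDiscrepancy:
    peptide_id: str
    stated: float
    computed: float

    @property
    def delta(self) -> float:
        return self.stated - self.computed


@dataclass
class MassReport:
    """Result of :func:`validate_library_masses`.

    ``discrepancies`` holds records whose stated mass differs from the
    computed one by more than the tolerance under the requested mode;
    ``missing`` lists records with no stated mass. When a library's mass
    convention (average vs monoisotopic) is unknown, run the validator
    once in each mode and compare the two reports.
    """

    mode: str
    tolerance: float
    discrepancies: list[MassDiscrepancy]
    missing: list[str]

    @property
    def ok(self) -> bool:
        return not self.discrepancies


def validate_library_masses(lib: BiopeptideLibrary, spec: MassSpec = MassSpec()) -> MassReport:
    """Flag library records whose stated mass disagrees with the sequence."""
    discrepancies: list[MassDiscrepancy] = []
    missing: list[str] = []
    for rec in lib:
        if rec.mass is None:
            missing.append(rec.peptide_id)
            continue
        computed = compute_peptide_mass(rec.sequence, spec)
        if abs(rec.mass - computed) > spec.tolerance:
            discrepancies.append(MassDiscrepancy(rec.peptide_id, rec.mass, computed))
    return MassReport(spec.mode, spec.tolerance, discrepancies, missing)
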