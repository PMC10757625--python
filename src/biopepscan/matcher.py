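"""Exact multi-pattern localisation of library peptides in a proteome.

The default engine is an Aho-Corasick automaton compiled to a sparse
DFA, so a scan costs one transition per protein residue regardless of
library size — essential at realistic scale (thousands of peptides
against tens of thousands of proteins). A naive per-peptide
sliding-window scan is retained both as a ``naive`` engine option and as
the independent oracle in the test suite.

Conventions:

* coordinates are 1-based inclusive everywhere a hit is reported
  (internally the automaton works with 0-based offsets);
* overlapping occurrences are counted by default — for a peptide of
  length k in a homopolymer of length n this yields n - k + 1 hits;
  ``overlapping=False`` switches to leftmost non-overlapping counting
  per peptide;
* matching is exact over the 20 standard residues; ``X``, ``*`` and any
  other ambiguity code in a protein match nothing;
* two library records with the same sequence each receive a hit per
  occurrence (the library is type-indexed).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ConsistencyError
from .library_io import BiopeptideLibrary, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class MatchHit:
    """One exact occurrence of a library peptide within a protein."""

    protein_id: str
    peptide_id: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    peptide_sequence: str


@dataclass(frozen=True)
class ProteinPeptideCount:
    """Aggregated hits of one peptide in one protein (never zero)."""

    protein_id: str
    peptide_id: str
    peptide_name: str
    n_hits: int
    peptide_sequence: str
    locations: tuple[tuple[int, int], ...]  # sorted (start, end) pairs


class AhoCorasick:
    """Multi-pattern exact matcher over uppercase strings.

    Classic goto/fail/output construction; after the breadth-first fail
    pass the goto function is completed into a sparse DFA (transitions
    that would land at the root are left implicit), so scanning needs no
    fail-chasing. Duplicate patterns are accepted; each occurrence
    reports every pattern index with that string.
    """

    def __init__(self, patterns: Sequence[str]):
        self.patterns = list(patterns)
        goto: list[dict[str, int]] = [{}]
        out: list[list[int]] = [[]]
        for idx, pat in enumerate(self.patterns):
            if not pat:
                raise ValueError("empty pattern")
            state = 0
            for ch in pat:
                nxt = goto[state].get(ch)
                if nxt is None:
                    goto.append({})
                    out.append([])
                    nxt = len(goto) - 1
                    goto[state][ch] = nxt
                state = nxt
            out[state].append(idx)

        fail = [0] * len(goto)
        queue: deque[int] = deque()
        for child in goto[0].values():
            queue.append(child)
        while queue:
            state = queue.popleft()
            for ch, child in goto[state].items():
                queue.append(child)
                f = fail[state]
                fail[child] = goto[f].get(ch, 0)
                if out[fail[child]]:
                    out[child] = out[child] + out[fail[child]]
            # complete this state's transitions into DFA form
            f = fail[state]
            for ch, target in goto[f].items():
                if ch not in goto[state]:
                    goto[state][ch] = target

        self._dfa = goto
        self._out: list[tuple[int, ...]] = [tuple(o) for o in out]
        self._lengths = [len(p) for p in self.patterns]

    def iter_matches(self, text: str) -> Iterator[tuple[int, int]]:
        """Yield ``(pattern_index, start_offset)`` pairs, 0-based, in end order."""
        dfa = self._dfa
        out = self._out
        lengths = self._lengths
        state = 0
        get_default = {}.get
        for i, ch in enumerate(text):
            state = dfa[state].get(ch, 0)
            o = out[state]
            if o:
                end = i + 1
                for pidx in o:
                    yield pidx, end - lengths[pidx]


def naive_occurrences(pattern: str, text: str) -> Iterator[int]:
    """All (overlapping) 0-based start offsets of ``pattern`` in ``text``."""
    i = text.find(pattern)
    while i != -1:
        yield i
        i = text.find(pattern, i + 1)


def _leftmost_nonoverlapping(starts: Sequence[int], k: int) -> list[int]:
    kept: list[int] = []
    next_free = 0
    for s in starts:
        if s >= next_free:
            kept.append(s)
            next_free = s + k
    return kept


def find_matches(
    lib: BiopeptideLibrary,
    proteome: Iterable[ProteinRecord],
    *,
    engine: str = "automaton",
    overlapping: bool = True,
) -> Iterator[MatchHit]:
    """Stream every exact occurrence of every library peptide.

    Hits are emitted in deterministic order: protein input order, then
    start position, then peptide_id. An empty library yields an empty
    stream (with a warning).
    """
    if engine not in ("automaton", "naive"):
        raise ValueError(f"unknown engine {engine!r}")
    if len(lib) == 0:
        logger.warning("empty biopeptide library: no matches possible")
        return

    # unique sequence -> records carrying it (library order preserved)
    by_seq: dict[str, list] = {}
    for rec in lib:
        by_seq.setdefault(rec.sequence, []).append(rec)
    seqs = list(by_seq)

    ac = AhoCorasick(seqs) if engine == "automaton" else None

    for protein in proteome:
        text = protein.sequence
        # starts0[seq_index] -> sorted list of 0-based starts
        if ac is not None:
            starts0: dict[int, list[int]] = {}
            for sidx, s0 in ac.iter_matches(text):
                starts0.setdefault(sidx, []).append(s0)
            for lst in starts0.values():
                lst.sort()
        else:
            starts0 = {
                sidx: list(naive_occurrences(seq, text))
                for sidx, seq in enumerate(seqs)
            }
            starts0 = {k: v for k, v in starts0.items() if v}

        hits: list[MatchHit] = []
        pid = protein.protein_id
        for sidx, starts in starts0.items():
            seq = seqs[sidx]
            k = len(seq)
            if not overlapping:
                starts = _leftmost_nonoverlapping(starts, k)
            for rec in by_seq[seq]:
                rid = rec.peptide_id
                for s0 in starts:
                    hits.append(MatchHit(pid, rid, s0 + 1, s0 + k, seq))
        hits.sort(key=lambda h: (h.start, h.peptide_id))
        yield from hits


def count_hits(
    hits: Iterable[MatchHit], lib: BiopeptideLibrary
) -> list[ProteinPeptideCount]:
    """Group a hit stream into one record per (protein, peptide) pair.

    Protein order follows first appearance in the stream; peptides are
    ordered by first hit within each protein. The total of ``n_hits``
    over all records equals the stream length.
    """
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        if h.peptide_id not in lib:
            raise ConsistencyError(
                f"hit refers to peptide {h.peptide_id!r} absent from the library"
            )
        grouped.setdefault((h.protein_id, h.peptide_id), []).append((h.start, h.end))
    out: list[ProteinPeptideCount] = []
    for (prot, pep), locs in grouped.items():
        locs.sort()
        rec = lib.get(pep)
        out.append(
            ProteinPeptideCount(prot, pep, rec.name, len(locs), rec.sequence, tuple(locs))
        )
    return out


MATCH_REPORT_COLUMNS = (
    "protein_id",
    "peptide_id",
    "peptide_name",
    "n_hits",
    "peptide_sequence",
    "locations",
)


def write_match_report(counts: Iterable[ProteinPeptideCount], path: str | Path) -> None:
    """Write the per-protein match table as TSV.

    Locations are semicolon-joined ``start-end`` pairs, 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(MATCH_REPORT_COLUMNS) + "\n")
        for c in counts:
            locs = ";".join(f"{s}-{e}" for s, e in c.locations)
            fh.write(
                f"{c.protein_id}\t{c.peptide_id}\t{c.peptide_name}\t"
                f"{c.n_hits}\t{c.peptide_sequence}\t{locs}\n"
            )


def read_match_report(path: str | Path) -> list[ProteinPeptideCount]:
    """Re-load a match report written by :func:`write_match_report`."""
    out: list[ProteinPeptideCount] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MATCH_REPORT_COLUMNS:
            raise ConsistencyError(
                f"{path}: unexpected match-report header {header}"
            )
        for line in fh:
            prot, pep, name, n_hits, seq, locs = line.rstrip("\n").split("\t")
            locations = tuple(
                (int(a), int(b))
                for a, b in (pair.split("-") for pair in locs.split(";") if pair)
            )
            out.append(
                ProteinPeptideCount(prot, pep, name, int(n_hits), seq, locations)
            )
    return out


def iter_hits_from_counts(counts: Iterable[ProteinPeptideCount]) -> Iterator[MatchHit]:
    """Expand grouped counts back into individual hits."""
    for c in counts:
        for s, e in c.locations:
            yield MatchHit(c.protein_id, c.peptide_id, s, e, c.peptide_sequence)
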