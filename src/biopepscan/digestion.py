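"""In-silico gastrointestinal proteolysis and match releasability.

This module is an EXTENSION of the core scanner: exact matching tells
you a bioactive peptide's sequence is embedded in a protein, but not
whether digestion can actually liberate it. Here each protein is cut
according to protease specificity rules and every match is classified:

* ``exact_release`` — the hit's coordinates coincide with a digest
  fragment, so the peptide is released intact;
* ``contained``     — the hit lies inside a single fragment (it would
  need further, e.g. exopeptidase, trimming);
* ``split``         — at least one cleavage site falls inside the hit,
  so these proteases destroy the peptide.

Rules follow the PeptideCutter-style P1/P1' convention: a protease cuts
the backbone after a P1 residue unless the next (P1') residue blocks it.
Built-in rules ship for trypsin, chymotrypsin (high specificity), pepsin
(pH 1.3) and pancreatic elastase — deliberately simplified to the
P1/P1' level; carboxypeptidases and other exopeptidases have no site
rule and are out of scope. User-defined rules load from a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import yaml

from .errors import ConsistencyError, ValidationError
from .library_io import ProteinRecord
from .matcher import MatchHit


@dataclass(frozen=True)
class CleavageRule:
    """P1/P1' specificity of one endoprotease.

    ``p1_residues``: residues after which the bond is cut.
    ``blocked_p1prime``: residues that, immediately following the bond,
    block cleavage (classically proline).
    ``extra_predicates``: optional callables ``(sequence, site) -> bool``
    over the uppercased sequence and the candidate cut position
    (1-based, cut falls between ``site`` and ``site + 1``); all must
    return True for the site to be kept.
    """

    protease_name: str
    p1_residues: frozenset[str]
    blocked_p1prime: frozenset[str] = frozenset()
    extra_predicates: tuple[Callable[[str, int], bool], ...] = ()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise ValidationError(
                f"rule {self.protease_name!r}: p1_residues must be non-empty"
            )

    def cleavage_sites(self, sequence: str) -> list[int]:
        """1-based positions after which this protease cuts.

        A site ``p`` means the bond between residues ``p`` and ``p + 1``
        is hydrolysed; the protein C-terminus is never a site.
        """
        seq = sequence.upper()
        p1 = self.p1_residues
        blocked = self.blocked_p1prime
        sites = [
            p
            for p in range(1, len(seq))
            if seq[p - 1] in p1 and seq[p] not in blocked
        ]
        for pred in self.extra_predicates:
            sites = [p for p in sites if pred(seq, p)]
        return sites


BUILTIN_RULES: dict[str, CleavageRule] = {
    r.protease_name: r
    for r in (
        CleavageRule("trypsin", frozenset("KR"), frozenset("P")),
        CleavageRule("chymotrypsin_high_specificity", frozenset("FYW"), frozenset("P")),
        CleavageRule("pepsin_ph1.3", frozenset("FL"), frozenset("P")),
        CleavageRule("pancreatic_elastase", frozenset("AVSG"), frozenset("P")),
    )
}


def load_rules(path: str | Path) -> list[CleavageRule]:
    """Load protease rules from a YAML config.

    Format: one mapping per protease under the top-level key ``proteases``
    (or a bare list), with fields ``name``, ``cleave_after`` and optional
    ``not_before``, each residue string, e.g.::

        proteases:
          - name: trypsin
            cleave_after: KR
            not_before: P
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blocks = doc.get("proteases", doc) if isinstance(doc, Mapping) else doc
    if not isinstance(blocks, list):
        raise ValidationError(f"{path}: expected a list of protease blocks")
    rules = []
    for block in blocks:
        try:
            rules.append(
                CleavageRule(
                    str(block["name"]),
                    frozenset(str(block["cleave_after"]).upper()),
                    frozenset(str(block.get("not_before", "")).upper()),
                )
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: protease block missing {exc}") from None
    return rules


@dataclass(frozen=True)
class DigestFragment:
    """One peptide produced by digestion. ``n_missed`` > 0 marks merged
    fragments that are extras on top of the base partition."""

    protein_id: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    sequence: str
    n_missed: int = 0


def cleavage_sites(
    sequence: str, rules: Sequence[CleavageRule]
) -> list[int]:
    """Sorted union of cleavage sites over all rules."""
    sites: set[int] = set()
    for rule in rules:
        sites.update(rule.cleavage_sites(sequence))
    return sorted(sites)


def digest(
    protein: ProteinRecord,
    rules: Sequence[CleavageRule],
    missed_cleavages: int = 0,
) -> list[DigestFragment]:
    """Cut one protein with the combined rule set.

    The ``n_missed == 0`` fragments form an exact partition of the
    protein (contiguous, non-overlapping, concatenating to the full
    sequence). With ``missed_cleavages = m`` every merged run of up to
    ``m + 1`` adjacent fragments is additionally emitted, flagged with
    its missed-cleavage count.
    """
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    seq = protein.sequence
    if not seq:
        return []
    if not rules:
        import logging

        logging.getLogger(__name__).warning(
            "empty rule set: %s left as a single fragment", protein.protein_id
        )
    sites = cleavage_sites(seq, rules)
    bounds = [0, *sites, len(seq)]
    base = [
        DigestFragment(protein.protein_id, bounds[i] + 1, bounds[i + 1],
                       seq[bounds[i]: bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]
    out = list(base)
    for m in range(1, missed_cleavages + 1):
        for i in range(len(base) - m):
            start = base[i].start
            end = base[i + m].end
            out.append(
                DigestFragment(protein.protein_id, start, end,
                               seq[start - 1: end], n_missed=m)
            )
    return out


def digest_proteome(
    proteome: Iterable[ProteinRecord],
    rules: Sequence[CleavageRule],
    missed_cleavages: int = 0,
) -> dict[str, list[DigestFragment]]:
    return {
        p.protein_id: digest(p, rules, missed_cleavages) for p in proteome
    }


EXACT_RELEASE = "exact_release"
CONTAINED = "contained"
SPLIT = "split"


@dataclass(frozen=True)
class ReleasabilityCall:
    hit: MatchHit
    status: str  # exact_release | contained | split
    protease_set: tuple[str, ...]


def classify_releasability(
    hits: Iterable[MatchHit],
    fragments_by_protein: Mapping[str, Sequence[DigestFragment]],
    rules_used: Sequence[str],
) -> Iterator[ReleasabilityCall]:
    """Assign exactly one releasability status to every hit.

    A hit is ``exact_release`` iff its coordinates equal some fragment's
    (merged fragments count: a peptide spanning m missed cleavages is
    releasable under m missed cleavages); ``split`` iff a base-partition
    boundary falls strictly inside it and it equals no fragment;
    ``contained`` otherwise.
    """
    protease_set = tuple(rules_used)
    cache: dict[str, tuple[set[tuple[int, int]], list[int]]] = {}
    for hit in hits:
        if hit.protein_id not in fragments_by_protein:
            raise ConsistencyError(
                f"hit in protein {hit.protein_id!r} but no digest fragments for it"
            )
        if hit.protein_id not in cache:
            frags = fragments_by_protein[hit.protein_id]
            coords = {(f.start, f.end) for f in frags}
            boundaries = sorted(
                f.end for f in frags if f.n_missed == 0
            )[:-1]  # last base fragment end is the C-terminus, not a cut
            cache[hit.protein_id] = (coords, boundaries)
        coords, boundaries = cache[hit.protein_id]
        if (hit.start, hit.end) in coords:
            status = EXACT_RELEASE
        elif any(hit.start <= b < hit.end for b in boundaries):
            status = SPLIT
        else:
            status = CONTAINED
        yield ReleasabilityCall(hit, status, protease_set)


RELEASABILITY_COLUMNS = (
    "protein_id", "peptide_id", "start", "end", "peptide_sequence",
    "status", "protease_set",
)


def write_releasability_report(
    calls: Iterable[ReleasabilityCall], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RELEASABILITY_COLUMNS) + "\n")
        for c in calls:
            h = c.hit
            fh.write(
                f"{h.protein_id}\t{h.peptide_id}\t{h.start}\t{h.end}\t"
                f"{h.peptide_sequence}\t{c.status}\t{';'.join(c.protease_set)}\n"
            )
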