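"""Activity-level aggregation and differential-expression cross-referencing.

Per activity category the summary reports four counts, because "how
many biopeptides were found" is genuinely ambiguous and the choices
differ by orders of magnitude at proteome scale:

* ``n_peptide_types`` — distinct library peptides with >= 1 hit,
* ``n_instances``     — total occurrences (every exact match counts),
* ``n_pairs``         — distinct (protein, peptide) pairs,
* ``n_proteins``      — distinct proteins hit.

A multi-activity peptide contributes its full counts to each of its
activity categories, so instance totals summed over activities can
exceed the raw hit count by exactly sum over hits of (|activities| - 1).

Cross-referencing takes a differential-expression table and counts the
upregulated genes (log2 fold-change >= threshold, inclusive; default
1.0) whose protein products carry at least one biopeptide, together
with the union of activity categories those products carry.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .library_io import BiopeptideLibrary, ExpressionRecord
from .matcher import ProteinPeptideCount

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivitySummary:
    activity: str
    n_peptide_types: int
    n_instances: int
    n_pairs: int
    n_proteins: int


@dataclass(frozen=True)
class UpregulatedCarrierSummary:
    contrast: str
    threshold: float
    n_genes: int
    activities: tuple[str, ...]


def summarize_by_activity(
    counts: Sequence[ProteinPeptideCount],
    lib: BiopeptideLibrary,
    *,
    include_empty: bool = False,
) -> list[ActivitySummary]:
    """One summary row per activity category, alphabetically sorted.

    Activities with zero hits are omitted unless ``include_empty``.
    """
    per_activity: dict[str, dict[str, object]] = {}
    if include_empty:
        for act in lib.activities:
            per_activity[act] = {"types": set(), "instances": 0, "pairs": 0, "proteins": set()}
    for c in counts:
        for act in lib.get(c.peptide_id).activities:
            agg = per_activity.setdefault(
                act, {"types": set(), "instances": 0, "pairs": 0, "proteins": set()}
            )
            agg["types"].add(c.peptide_id)
            agg["instances"] += c.n_hits
            agg["pairs"] += 1
            agg["proteins"].add(c.protein_id)
    return [
        ActivitySummary(
            act,
            len(agg["types"]),
            agg["instances"],
            agg["pairs"],
            len(agg["proteins"]),
        )
        for act, agg in sorted(per_activity.items())
    ]


def cross_reference_expression(
    counts: Sequence[ProteinPeptideCount],
    lib: BiopeptideLibrary,
    expr: Iterable[ExpressionRecord],
    *,
    threshold: float = 1.0,
    id_map: Mapping[str, str] | None = None,
) -> tuple[UpregulatedCarrierSummary, pd.DataFrame]:
    """Count upregulated genes whose proteins carry biopeptides.

    ``id_map`` maps gene_id -> protein_id and defaults to identity.
    A gene is counted iff its log2fc >= threshold (inclusive) AND its
    protein has at least one hit. Returns the summary plus a per-gene
    detail table (gene_id, log2fc, n_hits, activities).
    """
    hits_by_protein: dict[str, list[ProteinPeptideCount]] = {}
    for c in counts:
        hits_by_protein.setdefault(c.protein_id, []).append(c)

    rows = []
    all_activities: set[str] = set()
    contrast = ""
    n_unknown = 0
    for rec in expr:
        if not contrast and rec.contrast:
            contrast = rec.contrast
        protein_id = id_map.get(rec.gene_id, rec.gene_id) if id_map else rec.gene_id
        if id_map and rec.gene_id in id_map and id_map[rec.gene_id] not in hits_by_protein:
            n_unknown += 1
        if rec.log2fc < threshold:
            continue
        carried = hits_by_protein.get(protein_id)
        if not carried:
            continue
        acts = sorted({a for c in carried for a in lib.get(c.peptide_id).activities})
        all_activities.update(acts)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "log2fc": rec.log2fc,
                "n_hits": sum(c.n_hits for c in carried),
                "activities": ";".join(acts),
            }
        )
    if n_unknown:
        logger.warning("id_map points %d gene(s) at proteins with no hits", n_unknown)
    detail = pd.DataFrame(rows, columns=["gene_id", "log2fc", "n_hits", "activities"])
    detail = detail.sort_values("gene_id", kind="stable").reset_index(drop=True)
    summary = UpregulatedCarrierSummary(
        contrast, threshold, len(detail), tuple(sorted(all_activities))
    )
    return summary, detail


ACTIVITY_SUMMARY_COLUMNS = (
    "activity", "n_peptide_types", "n_instances", "n_pairs", "n_proteins"
)


def write_activity_summary(
    summaries: Sequence[ActivitySummary], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write the per-activity table; JSON mirrors the TSV 1:1."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(ACTIVITY_SUMMARY_COLUMNS) + "\n")
            for s in summaries:
                fh.write(
                    f"{s.activity}\t{s.n_peptide_types}\t{s.n_instances}\t"
                    f"{s.n_pairs}\t{s.n_proteins}\n"
                )
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump([asdict(s) for s in summaries], fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_carriers(
    summary: UpregulatedCarrierSummary,
    detail: pd.DataFrame,
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Write the per-gene carrier table (TSV) or its JSON twin."""
    path = Path(path)
    if fmt == "tsv":
        detail.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        doc = {
            "contrast": summary.contrast,
            "threshold": summary.threshold,
            "n_genes": summary.n_genes,
            "activities": list(summary.activities),
            "genes": detail.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
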