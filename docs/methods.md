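# Methods

## Matching model

The scanner treats the proteome as plain uppercase text and the
curated library as a set of exact patterns over the 20-letter amino
acid alphabet. All library sequences are compiled into one Aho–Corasick
automaton: a trie with failure links, which the constructor flattens
into a sparse DFA (transitions that would return to the root are left
implicit), so scanning takes exactly one dictionary lookup per residue
and no failure-chasing. Output sets are propagated along failure links
at build time, so peptides that are suffixes of other peptides are
reported at the same position. The naive per-peptide sliding-window
scan (`str.find` with step 1) is kept as a second engine; the two are
compared on randomized instances in the tests and in the acceptance
script, which is the strongest correctness evidence the package has.

Decisions embedded in the matching semantics:

* **Overlaps count.** "How many times a peptide occurs" is defined as
  the number of start positions, overlapping included; this is the only
  convention under which homopolymeric counts are well defined
  (n − k + 1) and a re-scan of any reported location succeeds. A
  leftmost non-overlapping mode exists for sensitivity analysis.
* **No ranking.** Exact matching admits no scoring, so all matches are
  reported; "best match" semantics would be vacuous here.
* **Case and ambiguity codes.** Sequences are uppercased at load.
  Library peptides must use the 20 standard residues (strict mode
  errors on B/J/Z/X/U/O, lenient mode skips the row). Proteins keep
  ambiguity codes and internal `*` verbatim; since no pattern contains
  them, they can never participate in a match — a match cannot cross a
  stop. A single trailing `*` is stripped at load.
* **Coordinates** are 1-based inclusive in every report; internally the
  automaton uses 0-based offsets, converted at the `MatchHit` boundary.
* **Type- vs sequence-indexing.** The library may hold distinct records
  with identical sequences (the same peptide curated under different
  roles); each record receives its own hits, so per-activity
  aggregation is faithful to the curation rather than to unique strings.

## Peptide mass

A peptide's chemical mass is the sum of residue (dehydrated) masses
plus one water. Average and monoisotopic residue tables are embedded as
versioned constants (`biopepscan._masses`, tag `expasy-2021`) so
validation is reproducible offline; the monoisotopic table is
cross-checked against pyteomics in the test suite. Curated library
exports do not state which convention their mass column uses, so the
validator takes the mode as a parameter and is intended to be run in
both modes when the provenance is unknown; records missing a mass are
listed separately rather than flagged. Default tolerance 0.5 Da
(loose enough for rounding in curated exports); the synthetic generator
states average-mode masses rounded to 4 decimals, consistent at
0.01 Da.

## Digestion model (extension)

Proteolysis is simulated at the specificity level only: a
`CleavageRule` is a set of P1 residues (cut after) and blocking P1′
residues (no cut before), evaluated on the uppercased sequence, with an
optional escape hatch for positional predicates. This is the
PeptideCutter convention, deliberately simplified — no cleavage
probabilities, no pH or kinetics, no exopeptidase trimming
(carboxypeptidases therefore have no rule). The shipped rules are:

| protease | cleave after | blocked by |
|---|---|---|
| trypsin | K, R | P |
| chymotrypsin (high specificity) | F, Y, W | P |
| pepsin (pH 1.3) | F, L | P |
| pancreatic elastase | A, V, S, G | P |

Pepsin and elastase specificity is genuinely broader and
context-dependent in vivo; the P1/P1′ reduction above is the
documented approximation. Users can supply their own rules via YAML.

With `missed_cleavages = 0` the fragments of a protein form an exact
partition (the tested invariant); with m > 0, merged runs of up to
m + 1 adjacent fragments are emitted additionally, flagged with their
missed-cleavage count so the partition stays recoverable.

**Releasability** is this package's own trichotomy — the upstream
matching method does not define one. A hit is `exact_release` iff its
coordinates equal some fragment's (merged fragments included: a peptide
spanning one missed cleavage is releasable at one missed cleavage);
`split` iff a base-partition boundary falls strictly inside it and it
equals no fragment; `contained` otherwise. Exact-release takes priority
over the boundary test so the statuses stay mutually exclusive when
merged fragments are present. Adding rules can only add cleavage
sites, so calls move monotonically away from `contained`.

## Aggregation and expression cross-reference

Per activity category the summary reports distinct peptide types,
total instances, distinct (protein, peptide) pairs and distinct
proteins. Multi-activity peptides contribute fully to each of their
categories, so summing instances over categories exceeds the raw hit
count by exactly Σ_hits (|activities| − 1) — an identity the tests
assert. Activity labels are taken verbatim from the library file; the
package imposes no vocabulary.

The upregulation cutoff is inclusive (log2FC ≥ threshold, default
1.0). Gene↔protein mapping defaults to identity (proteomes whose
protein ids are gene ids need no map); an explicit `id_map` supports
other nomenclatures. Raising the threshold can only shrink the carrier
set and its activity union.

## Synthetic data

The generator emulates the study conditions the pipeline is meant for:
a proteome of configurable size (default 1,000 proteins for tests;
48,090 × mean 400 aa — a realistic plant-proteome scale — in the
large smoke test), protein lengths normal(400, 100) clipped at 1,
background residues i.i.d. from a configurable frequency vector
(default uniform), and planted peptide occurrences that overwrite the
background at recorded coordinates, keeping lengths exact. The truth
table lists exactly the plants; a scan returns a superset (the
background can coincidentally contain a peptide), which is why the
planted-recovery check asserts containment, not equality. The i.i.d.
background admits a closed-form expected coincidental hit count,
Σ_proteins (L − k + 1)·Π f(residue), which a 200-replicate test holds
the generator to within 4 standard errors.

What the background does **not** model: residue composition bias,
local repeats, homology between proteins, or real peptide length
distributions (synthetic library lengths are uniform on [2, 60];
curated libraries are heavily skewed toward di- and tripeptides).
Passing tests therefore demonstrate the correctness of matching,
counting, digestion and cross-referencing — not biological discovery
performance on real proteomes.

All generators draw from named, seed-derived `numpy` streams
(`default_rng([seed, channel])`), so equal specs give byte-identical
FASTA/TSV output and the independent channels keep, e.g., library
generation from perturbing proteome generation.

## Problem sizes and numerical choices

The acceptance script runs the full pipeline at 5,000 proteins ×
~400 aa against 1,000 peptides (a deliberate reduction of the
realistic 48,090 × 4,341 scale, which the test suite runs once as a
smoke test); randomized cross-checks use 100 instances of ≤ 50
proteins × ≤ 200 residues. Ties in hit ordering are broken
deterministically (protein input order, then start, then peptide id);
report rows sort alphabetically by activity; all outputs are
byte-stable across reruns. Degenerate inputs are defined rather than
rejected: an empty library or proteome yields an empty stream; an
empty rule set leaves each protein as one fragment (everything
`contained` or `exact_release`); a header-only table is an empty
collection.

## Known limitations

* Exact matching only — no substitution tolerance, no I/L
  equivalence, no motif patterns; a single-residue variant of a curated
  peptide is invisible.
* The releasability trichotomy ignores exopeptidase trimming, so
  `contained` understates true releasability for peptides near
  fragment termini.
* Digestion rules are specificity caricatures of pepsin and elastase.
* The library is taken as ground truth; no curation or deduplication
  beyond id uniqueness is attempted.
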