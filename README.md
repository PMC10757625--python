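# biopepscan

Exhaustive annotation of a proteome with curated bioactive peptides
("biopeptides"): every exact occurrence of every library peptide in
every protein, aggregated per biological-activity category, optionally
cross-referenced with differential expression and classified for
releasability under in-silico gastrointestinal digestion.

## The problem

Dietary proteins are hydrolysed in the gut by proteases (pepsin,
trypsin, chymotrypsin, elastase, carboxypeptidases) into small peptides.
Many such peptides of 2–60 residues have physiological activities
beyond nutrition — angiotensin-converting-enzyme (ACE) inhibition
(antihypertensive), dipeptidyl-peptidase-4 (DPP-4) inhibition
(antidiabetic), antioxidative, antimicrobial and many more — and are
curated in databases such as BIOPEP-UWM together with their role, mass
and activity category. Given a predicted proteome, the first question
is simply *which curated peptides are embedded in which proteins, where,
and how often* — an exact multi-pattern string-matching problem at the
scale of thousands of peptides against tens of thousands of proteins.

`biopepscan` answers it with an Aho–Corasick automaton: all library
peptides are compiled into one failure-link automaton (further
flattened into a sparse DFA), so a whole proteome is scanned in a
single pass, one transition per residue, regardless of library size.
For a library of P peptides totalling M residues and a proteome of N
residues with H occurrences the scan costs O(M + N + H) instead of the
naive O(P·N). The naive sliding-window scan is retained as a
cross-checking engine (`--engine naive`). Overlapping occurrences are
counted by default (a length-k peptide occurs n−k+1 times in a length-n
homopolymer); `--no-overlap` switches to leftmost non-overlapping
counting.

Two downstream layers interpret the raw matches:

* **Activity summary** — per activity category: distinct peptide types
  with ≥ 1 hit, total occurrences ("instances"), distinct
  (protein, peptide) pairs, distinct proteins. Instances and pairs are
  both always reported, since "how many biopeptides a proteome carries"
  is ambiguous between the two by orders of magnitude.
* **Expression cross-reference** — genes with log2 fold-change ≥ a
  cutoff (inclusive; default 1.0) whose protein products carry ≥ 1
  biopeptide, with the union of activity categories carried.
* **Digestion / releasability (extension)** — proteins are cut by
  PeptideCutter-style P1/P1′ rules (built-ins: trypsin, chymotrypsin
  high-specificity, pepsin pH 1.3, pancreatic elastase) and each match
  is classified `exact_release` (fragment boundaries coincide with the
  match), `contained` (inside one fragment) or `split` (a cleavage site
  cuts through it). Exact matching alone does not tell you whether the
  proteases can actually liberate the peptide; this stage closes that
  gap.

A seeded synthetic-data module generates proteomes with planted peptide
occurrences recorded in a ground-truth table, synthetic libraries with
consistent masses, and expression tables with a known upregulated
subset, so the whole pipeline is testable offline.

## Worked example

```sh
biopepscan simulate --outdir sim --n-proteins 500 --n-peptides 100 --plants 40 --seed 11
biopepscan scan     --library sim/library.tsv --proteome sim/proteome.fasta --outdir out
biopepscan digest   --proteome sim/proteome.fasta --matches out/matches.tsv --outdir out
biopepscan summarize --matches out/matches.tsv --library sim/library.tsv \
                     --expression sim/expression.tsv --outdir out
```

The scan logs the library/proteome sizes and per-activity totals:

```
INFO biopepscan: library: 100 peptides; proteome: 500 proteins
INFO biopepscan: total hits: 561 over 358 (protein, peptide) pairs
INFO biopepscan:   ACE inhibitor: 2 types, 4 instances, 4 proteins
INFO biopepscan:   DPP-4 inhibitor: 2 types, 19 instances, 18 proteins
...
INFO biopepscan: upregulated carrier genes (log2FC >= 1): 93 carrying 13 activities
```

i.e. 561 exact peptide occurrences were found across 358 distinct
(protein, peptide) pairs; 4 of them are occurrences of the library's 2
matched ACE-inhibitor peptides; 93 of the simulated upregulated genes
encode proteins carrying at least one biopeptide. `out/matches.tsv`
holds the six-field match report (protein id, peptide id, peptide name,
hit count, peptide sequence, semicolon-joined 1-based locations):

```
protein_id  peptide_id  peptide_name                           n_hits  peptide_sequence  locations
p0001       BP00043     synthetic immunomodulating peptide 43  3       LC                243-244;357-358;393-394
```

and `out/releasability.tsv` adds the digestion verdict per hit
(`split` here: some protease cuts inside the dipeptide's location).

The same stages are importable as a library
(`biopepscan.find_matches`, `count_hits`, `summarize_by_activity`,
`cross_reference_expression`, `digest`, `classify_releasability`, ...).

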