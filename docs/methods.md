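# Methods

This note records the models, conventions and numerical choices behind
`ferretforge`, and what the synthetic fixtures do and do not emulate.

## Frame selection

Nucleotide entries are translated in all six frames under the standard
genetic code. Frame numbering is fixed and length-independent: frames
1–3 are the forward strand at offsets 0–2, frames 4–6 the reverse
complement at offsets 0–2. (Some translation tools number reverse
frames differently depending on sequence length mod 3; the fixed
convention here makes frame labels deterministic and comparable across
sequences, and is documented on every output via the `frame=<k>`
description tag.)

Degenerate IUPAC codons are translated by enumerating their
completions: all-stop renders `*`, a single consistent amino acid
renders that amino acid, anything else renders `X`. An open reading
frame is a maximal stop-free run of the peptide — `X` does not break a
run, and no start codon is required, because assembled transcripts are
frequently 5′-truncated. The frame with the longest ORF wins; ties go
to the lowest frame number. The *full* frame peptide is retained rather
than the ORF substring, preserving partial flanking coding signal for
domain annotation; the `--orf-only` flag on `ferretforge translate`
switches to the trimmed behaviour for users who want strict ORFs.

## Pfam post-processing

Filtering uses each family's *trusted cutoff* — the highest-stringency
bitscore threshold curated by Pfam per profile — applied to the
full-sequence bitscore (the first TC value); hits at exactly the
cutoff are kept (≥). Hits whose family lacks a cutoff are dropped and
tallied as a warning rather than an error. When a protein retains
several families, the highest bitscore wins, with ties broken by lower
E-value and then lexicographic accession so the reduction is total and
deterministic. The per-entry Pfam count consumed by QC counts
*distinct families* among best annotations (the `hits` count mode is
available via `count_mode`). Pfam accession versions (`.N`) are
stripped everywhere so hits join thresholds across Pfam releases.

## Marker-based contamination screening

Marker families are re-derived from the input corpus: families whose
name begins with a ribosomal-protein pattern (default prefix
`Ribosomal`, extendable) and that appear in strictly more than 90% of
entries. On a production corpus this yields the several dozen
ribosomal-protein families that are near-universally transcribed; a
fixed published marker list can be supplied instead to reproduce a
specific build.

Each marker sequence is placed by LCA over its alignment hits: hits
with E-value above 1e-5 are discarded, and of the rest only those
within 10% of the best bitscore are retained (mirroring the `--top 10`
semantics of the commonly used protein aligner). The LCA of the
retained subject taxids is rolled up into lineage bins — the deepest
bin on the placement's root path, `Other` when no bin lies on it,
`Unknown` when no hit survives. The report carries 21 categories: 19
named lineage bins plus `Other` and `Unknown`.

The contamination estimate is

    contam_pct = 100 × (placed markers outside the expected bin)
                       / (placed markers)

with `Unknown` excluded from numerator and denominator by default:
unplaced markers reflect reference incompleteness, not contamination,
and penalizing them would conflate the two. The alternative
(`unknown_policy="count"`) treats unplaced markers as outside the
expected lineage. The estimate is absent (not 0) when no marker could
be placed. Entries whose own taxid falls in no configured bin are
reported with expected lineage `Other` and a warning, since "outside
the expected lineage" is then ill-defined.

Numeric bin taxids are supplied by config rather than hard-coded: they
are a property of the taxonomy release in use, not of the method. The
19 default bin *names* ship with the package.

## Validation flags

All thresholds are strict inequalities: `LOW_SEQS` below 1,200 raw
sequences, `LOW_PFAMS` below 500 distinct families (assigned only when
`LOW_SEQS` is absent, so the `qc_flag` column carries at most one
value), and contamination flags above 50% — an entry at exactly
1,200/500/50.0 is clean. Entries with either floor flag are excluded
from marker-screen estimation (their annotation content is too thin to
place reliably). External contamination reports join by entry id; the
override list for externally misattributed 100%-contamination calls is
configurable. `accepted` is Y exactly when no flag is set, and remains
user-overridable (with an audit log) to customize builds.

## Clustering

Pooling by taxid keeps strain-level diversity: entries sharing a taxid
contribute to one pool, terminal stops stripped. Clustering is greedy
longest-first, single-linkage to the representative: identity is
exact-residue matches over all columns of a global alignment scored
with BLOSUM62 and affine gaps (open 11, extend 1), and a sequence may
join only when the shorter/longer length ratio is at least the
coverage floor (0.8) — in an end-to-end global alignment the shorter
sequence is fully aligned, so the length ratio *is* the coverage of
the longer sequence by the shorter. Both knobs are exposed; exact
parameter parity with production clustering tools is not claimed, as
their coverage defaults are implementation-specific. An identity
bound (`identity ≤ min_len/max_len`) and an exact-duplicate hash path
skip most alignments, which keeps thousand-sequence pools fast;
production-scale corpora would delegate to an external clusterer
behind the same interface.

`mft` identifiers are consecutive ten-digit zero-padded integers from
`mft0000000001`, ordered by (taxid, representative's entry id, pool
order) — a fixed, documented convention chosen because only the
ten-digit width is externally specified.

## Core transcribed genes

Catalogs are built from accepted transcriptome-derived entries only
(TSA and SAT; genome and SAG entries would bias the set toward genes
present in genomes but not reliably transcribed). Strain taxids
collapse onto their species-rank ancestor (nodes with no species
ancestor are used as-is with a warning), and a species carries a family
if any of its entries does. A family enters the catalog when observed
in at least 95% of the lineage's species; the smallest qualifying
count is ⌈0.95·n⌉ — 28 of 29 taxa, for example. Lineage definitions
support clade subtraction (include taxid, exclude taxids) for cases
like a parent clade excluding its best-sampled subclade. Completeness
of a taxon bin is `100 × |bin ∩ catalog| / |catalog|`.

## Pipeline

The build runs translate → annotate → validate → cluster → CTG. Each
stage reads its inputs from files written by earlier stages, so a
rerun with an unchanged configuration resumes from the last completed
stage; the manifest stores a hash of the semantic parameters only (no
paths or timestamps), which also makes two builds of the same corpus
byte-identical. Any stage failure halts with the stage name.

## Synthetic fixtures

The generators emulate the *decision structure* of real inputs, not
their biology:

- the toy taxonomy has one node per report lineage and species/strain
  leaves under the populated lineages;
- proteomes are uniform random 80–300-residue sequences whose "domain
  content" is planted directly in generated domain tables, with scores
  drawn above or below the family's trusted cutoff;
- marker hit tables place each marker's top-bitscore band wholly
  inside the intended lineage (own or contaminant, a Bernoulli draw at
  the planted mixing fraction ρ), with a below-band decoy and an
  E-value-failing hit to exercise the retention rules;
- planted-CDS records embed a stop-free coding sequence at a known
  frame inside random flanks, redrawn until the planted frame's ORF is
  strictly longest.

Default corpus size is 2 lineages × 3 species × 2 entries × 40
sequences with 10 marker sequences over 8 ribosomal families — chosen
so the whole build, including clustering, runs in seconds. Passing
tests on these fixtures demonstrates that the *logic* (filtering,
placement, flag arithmetic, clustering semantics, catalog thresholds)
is correct; it says nothing about HMM search sensitivity, aligner
bitscore distributions, or real contamination structure, all of which
live outside the package boundary. In particular the contamination
estimator's parameter recovery is exact up to binomial sampling noise
*because* the fixtures make every LCA placement unambiguous; real
marker placements also carry reference-incompleteness error, which is
why the `Unknown` category exists.

Because the desk-scale corpus is far below the production floors, the
pipeline examples and tests scale `min_seqs`/`min_pfams` to the corpus
(30/5); the flag boundary semantics themselves are always tested at
the real 1,200/500/50 values.

## Known limitations

- Greedy clustering is O(n·clusters) alignments in the worst case;
  fine at reference-entry scale per taxid, not a linclust substitute.
- Name-based marker selection inherits Pfam's naming conventions; a
  family named atypically would need an extra pattern.
- Taxid curation (resolving organism names to taxonomy ids) is out of
  scope: entries must arrive with taxids, with `merged.dmp` honored
  for retired ids and unknown ids treated as errors.
- PR² identifiers are carried as pass-through metadata only.
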