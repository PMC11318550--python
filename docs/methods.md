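# Methods

This note documents the models, numerical choices and limitations behind
`slimscan`, in the order the pipeline runs.

## Motif model and scanning

Motifs are regular expressions restricted to the subset with exact,
enumerable semantics: literals, character classes (with `^` negation and
`A-Z` ranges), `.`, bounded quantifiers `{m}`, `{m,n}`, `?`, capturing
groups and alternation.  Unbounded quantifiers (`*`, `+`), anchors, escapes
and look-around are rejected at compile time.  This restriction is what
makes the minimum/maximum match length, the per-group admissible residue
sets and the analytical pattern probability computable.

Patterns are normalised before compilation: `.` and negated classes are
expanded to explicit classes over the 20 standard amino acids.  Consequence:
non-standard letters in sequences (X, U, B, Z) never satisfy an amino-acid
class or `.`; only an explicit literal can match them.

Coordinates are 0-based half-open internally and 1-based inclusive in every
report, matching UniProt conventions.  At each start position, matching is
anchored and greedy (leftmost alternative, maximal quantifier repetition),
which makes match counts deterministic.  With `overlapping=True` (the
default — SLiM instances may overlap) a match attempt is made at every
position; with `overlapping=False` scanning resumes after each match end.
Zero-width matches (possible when every atom is optional) are never
reported.  Flanks are truncated at sequence boundaries.

## Pattern probability

For background distribution *B* the per-position match probability is the
sum over all fixed-length expansions of the product of per-position class
probabilities, where a class probability is the summed background frequency
of its members.  The sum deliberately omits inclusion–exclusion, so for
patterns whose expansions overlap (e.g. `.{1,3}`) the value can exceed the
true union probability, and even 1; a warning is emitted in that case.  This
matches the convention of the ELM-style per-position probability that the
enrichment analysis compares decoy counts against.  The expansion count is
capped (default 10⁶) to bound memory and time.

The background is a parameter: uniform 1/20 by default, with a
SwissProt-like average composition available as a preset
(`BackgroundFrequencies.swissprot()`), because published per-position
probabilities rarely state their background and results depend on it.

## PSSM training and scoring

One PSSM column per capturing group.  Training counts residues observed
inside each group across instances; each residue in a variable-length group
is weighted by 1/(group length in that instance), so every instance
contributes exactly one unit of mass per column and long groups do not
dominate.  Counts are Laplace-smoothed with pseudocount k (default 1 —
training sets built from PTM-filtered matches are small and need smoothing):

    f(g,a) = (c(g,a) + k) / (Σ_a c(g,a) + 20k),  w(g,a) = log2(f(g,a)/B(a))

A match scores S = Σ_g mean(w(g, r) for residues r in group g); empty groups
contribute 0, and a non-standard residue inside a group takes the column
minimum rather than raising.  The reported score is
100·(S − s_min)/(s_max − s_min) clipped to [0, 100], where s_min/s_max sum
the per-column extrema **restricted to each group's admissible residue
class**.  Restricting to the class makes 100 attainable exactly by the
per-column consensus and 0 by the per-column worst compatible residue; using
the theoretical (class-restricted) range rather than the observed score
range keeps the scale independent of the particular match list.  A fully
degenerate pattern (every group a single fixed residue) has s_min = s_max
and is rejected, as no ranking is possible.

Note that with a fixed pseudocount, duplicating every training instance
*does* change the matrix slightly (the smoothing weight halves relative to
the counts); exact duplication invariance holds only in the k→0 limit.

The PSSM file format is plain text: `#`-prefixed metadata (pattern,
background, pseudocount, s_min, s_max) followed by one row per column with
20 tab-separated log-odds weights in alphabetical amino-acid order.  Missing
normalisation constants are recomputed from the weights and pattern on read.

## Decoy generation

Decoy sequences are per-record Fisher–Yates permutations from a single
seeded RNG stream consumed in dataset order, so one integer seed fully
reproduces a decoy database.  Position 1 is always held fixed, preserving
the prevalence of the initial methionine so that motifs requiring it are
neither artificially enriched nor depleted.  In `preserve_idr` mode the
sequence is cut at annotated disordered-region boundaries and each segment
(disordered and ordered alike) is shuffled within itself, preserving the
distinctive composition of disordered regions; records without annotations
fall back to the full shuffle, overlapping intervals are merged with a
notice, and out-of-bounds intervals are an error.  Segment-wise shuffling is
the stricter reading of "shuffle regions separately"; a variant pooling all
disordered residues of a protein before redistribution would also preserve
overall IDR composition but not per-segment composition, and is not built.
Decoy accessions get a `decoy_` prefix and their gene symbols are dropped,
preventing accidental joins with real PTM/feature tables.

## Enrichment statistics

The "proportion" compared between target and decoy is matches per residue
(total residues = positions scanned), the same unit used to normalise
datasets of different size.  The test is a two-sided pooled two-proportion
z-test; Fisher's exact test is exposed for small counts.  Degenerate tables
(both proportions 0 or 1) return p = 1.  q-values are Benjamini–Hochberg
step-up across all motifs in one table — the family is explicit and fixed.
Classification: enriched iff ratio ≥ 2 and q ≤ 0.05; depleted iff
ratio ≤ 0.5 and q ≤ 0.05 (both cuts configurable).  A zero decoy count gets
a Haldane-style +0.5 on both counts **for the ratio only** (flagged in the
output); p-values always use the untouched counts.

Ratio-vs-score-threshold curves count matches with score ≥ t at each
threshold; counts are non-increasing in t by construction and the same
continuity rule applies.

## Annotation

All containment tests are 1-based inclusive; a site at a span boundary is
inside.  The default PTM scope is the whole match span; a group-scoped mode
restricts the join to one capturing group, which is the right choice for
modified-residue motifs with a defined acceptor group.  PhosphoSitePlus
tables are read with their non-tabular preamble tolerated, MOD_RSD suffixes
decoded (`-p`, `-ub`, `-ac`, `-me`, `-gl`, …) and ambiguous sites dropped by
default.  dbPTM-style tables are headerless with a configurable column map;
when a proteome is supplied, sites whose residue is implausible for the
modification (e.g. phosphorylation on alanine) or whose position exceeds the
sequence are flagged but kept by default — flag-don't-drop, since the
databases document the issue without prescribing removal.

Auxiliary-motif co-search marks each primary match with whether its protein
carries at least one auxiliary hit above a score threshold, plus the count
of passing hits and the best auxiliary score; an option restricts the output
to those primaries.

## Synthetic data

The fixture generator emulates the statistical skeleton of the real inputs:
i.i.d. sequences from a chosen composition with a forced initial methionine,
planted pattern-compatible instances at uniformly chosen spans (never
covering position 1, never overlapping each other, with a truth table),
modification sites on planted acceptor positions with configurable coverage
and Poisson spurious-site noise, and non-overlapping disordered intervals
covering a target fraction of residues.  It does **not** emulate homology
between proteins, compositional autocorrelation, realistic disorder
prediction, or position-dependent PTM biases — so green tests demonstrate
the statistical machinery is correct and well-calibrated, not that any
particular biological motif is detectable in real proteomes.

Problem sizes used by the test suite and the acceptance script (2,500 ×
421-residue proteins for probability calibration, 100 independent
motif/table draws of 125 × 401-residue proteins for the null model, 20
seeds of 500 × 400-residue proteins for planted-motif power, 2,000 training
instances for PSSM recovery, 271 + 271 proteins for the PTM train/test
workflow) were chosen so each statistical check has comfortable power
margins at desk scale.  The probability-calibration patterns are built from
mutually disjoint per-position residue chunks so matches cannot self-overlap
and the binomial standard error is exact.

## Numerical and design notes

- The null-model simulation draws one motif per independent dataset; sharing
  one dataset across many motifs correlates their counts and inflates the
  variance of the summed target/decoy ratio.
- `filter_identical` keeps the highest-scoring occurrence of each distinct
  matched string (ties: first in scan order), preserving scan order.
- BH adjustment delegates to `statsmodels` and is cross-checked against the
  hand-applied step-up formula in the tests; the z-test is cross-checked
  against a closed-form normal-CDF computation.
- FASTA metadata: the FASTA format carries no comment lines, so decoy seeds
  and options live in `Dataset.metadata` and in the TSV `#` preambles, not
  in decoy FASTA output.

## Known limitations

- No full-PCRE semantics (by design); ELM patterns using look-around or
  unbounded repeats must be rewritten with explicit bounds.
- The pattern probability is per-position and ignores overlap between
  expansions; for highly degenerate patterns it is an upper bound.
- Single-decoy design: uncertainty from decoy randomness is explored by
  re-running with different seeds, not by permutation p-values.
- Identifier resolution is offline against a loaded proteome copy; no live
  database queries, GO-term subproteome retrieval or proteome version
  management.
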