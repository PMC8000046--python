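# Methods

## Observation model

The unit of counting is the integrated Function;Family observation: a
four-field EC label (fourth field `*` when only the sub-subclass of the
activity is predicted; the `-` placeholder some annotators emit is
normalized to `*`) paired with a CAZy family. Equality is on the (EC,
family) pair; subfamily and CUPP-group suffixes (`GH5_7`, `GH7:2.1`) are
collapsed to the parent family before key construction, since the family is
the level at which function extrapolation is made. A protein carrying two EC
predictions in one family yields two observations — counting is over
observations, not proteins — while byte-identical duplicate annotation rows
collapse to one instance, so re-annotation artifacts cannot inflate scores.

Exclusions: all GT families (biosynthetic, not degradative) and, by default,
the LPMO families AA9, AA10, AA11, AA13–AA17, where current annotation
cannot resolve molecular function. The LPMO list is configurable because the
CAZy LPMO census grows over time. Records without any EC prediction
(typically CBM-only hits) yield no observation: no predicted function, no
Function;Family pair.

## Substrate resolution and the half-count rule

Observation keys are mapped to target substrates by declarative rules
(EC pattern, family pattern, substrate set), where each pattern is a literal
label or the whole-field wildcard `*`. Resolution takes the most specific
match: exact EC + exact family, then exact EC, then exact family, then a
catch-all. Under literal matching at most one rule per tier can match a key,
and duplicate pattern pairs are rejected when a map loads, so resolution is
a function of the key alone and is independent of row order; an ambiguity
error path exists for defensive completeness. Unmapped keys contribute to no
substrate (they remain visible at debug log level).

A rule with k substrates gives each weight 1/k. The motivating case is
k = 2 — an activity genuinely shared between two polymers counts half for
each — and 1/k is its unique conservative generalization: every mapped
observation contributes total weight exactly 1, which is what makes the
Total column equal the sum of the four substrate columns in both counting
modes. Weights apply identically to redundant and unique scores; applying
them only to redundant counts would break the U ≤ R invariant whenever a
dual-substrate key occurs once. Lignin flows through the same machinery as
the three polysaccharides.

The bundled map (36 rules over canonical cellulase, xylanase, pectinase and
ligninolytic activities, including feruloyl esterase as a genuine
xylan+pectin dual) is assembled for testing and demonstration; it makes no
claim of curation completeness and real analyses should pass their own map.

## Scores, rounding, degenerate cases

R_s sums weights over all instances, U_s over distinct keys; since the
distinct keys are a subset of instances with identical weights, U_s ≤ R_s
holds per substrate, with equality exactly when no key repeats. RMS = R/U is
therefore ≥ 1 whenever U > 0. When U = 0 (and in particular 0/0) the RMS is
undefined and reported as `NA` — a sentinel rather than 0 or ∞, so undefined
values can never order against real ones. Flags (`*` above 8, `¤` below 3)
are decided on the unrounded ratio; the reported value is rounded half-up to
one decimal (half-up, not banker's, reproduces the published 108/22 → 4.9
convention and is the convention for all serialized scores, which print with
at most one decimal and no trailing `.0`). Full precision is retained in
memory and in the JSON report.

Rankings are competition-style ("1224"): equal scores share the minimum rank
and carry a tie flag rather than an invented order; a secondary sort on
species name (then genome id) makes output order deterministic. Both the
tie-aware rank and the ordinal file position are written, since downstream
consumers want one or the other. Rank-window censuses count ranked
*positions* (1-based, inclusive), so a window of width w always accounts for
exactly w genomes regardless of ties; the published 500/1000 boundary
overlap is resolved as [1,500], [501,1000], [1001,end]. Genus summaries use
the mean-of-central-pair median for even counts.

Assembly selection maximizes coverage × contig N50, with N50 defined as the
largest L such that contigs ≥ L cover at least half the assembly. Exact
product ties break on higher coverage, then lexicographically smaller
accession — an invented but fixed chain, needed only for determinism.
Missing coverage values are read as 0 with a warning (public assembly
metadata is often incomplete; dying on one record would be worse than
deprioritizing it).

## Synthetic data: what it emulates and what it does not

The generator emulates the *statistical shape* of an annotated cohort: per
genome and substrate, `u_s` distinct observation keys, each with
1 + Poisson(m_s − 1) protein copies — at least one gene per present key,
mean copy number m_s, so the scored per-substrate RMS converges to m_s as
u_s grows (at u_s = 200 the mean RMS over 20 seeds sits within 5% of m_s;
the per-seed standard deviation is √(m−1)/√u_s). Synthetic ECs live in the
fictitious class 9, which no real enzyme uses, so generated keys can never
collide with a real substrate map. Dual-substrate keys are created for
substrate pairs along a fixed cycle, with per-substrate dual counts kept
even and bounded by the smaller budget of the pair, so the weighted unique
score equals u_s *exactly* for every genome, substrate, seed and dual
fraction — uniqueness is deterministic by construction, and only copy
numbers are stochastic. Candidate assembly triples are built so the first
accession dominates on coverage × N50, making the intended representative
known.

What the generator does **not** emulate: real sequences or gene models,
annotation error (every synthetic record is correct), shared keys between
genomes (each genome draws independently, so cross-genome profile
correlation structure is absent), heavy-tailed copy-number distributions,
and incomplete or fragmented assemblies. Tests passing on synthetic cohorts
therefore demonstrate that the arithmetic — counting, weighting, ranking,
selection — is correct under known ground truth; they say nothing about
annotation quality on real genomes, which is the upstream annotator's
burden.

Default problem sizes in the test and acceptance suites (cohorts of 3–10
genomes, repertoires up to 200 keys per substrate, 20 seeds, 200 random
scoring fixtures) were chosen as the smallest sizes at which the stochastic
recovery bounds are comfortably inside their tolerances; all suites run in
well under a minute.

## Input dialects

Annotation tables are TSV with a header and `#` comments; column names and
the multi-EC delimiter (default `;`) are configurable because annotator
output dialects differ, and the default column set is modeled on public
CUPP-style output without asserting exact equivalence. Unknown extra columns
are ignored. Rows with an unparseable family are rejected with row-numbered
diagnostics — fatal by default, skippable in non-strict mode. Genome
metadata validates phyla against a declared, extensible controlled list.

## Known limitations

* Hotspot *identities* on real cohorts depend entirely on the substrate map
  supplied; the bundled illustrative map is not a curated production map.
* Half-count weighting in unique mode is a declared convention; a map with
  many dual-substrate rules will produce fractional unique scores, which are
  reported with one decimal.
* No statistical testing of score differences is performed, and no
  phylogenetic correction is applied to rankings.
* Diploid or duplicated assemblies inflate redundant scores; comparing
  redundant against unique rankings (or the RMS) partially exposes, but does
  not correct, this.
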