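# Methods

This note records the models, estimators, parameter choices, and known
limitations behind `coevotraj`, in the order the pipeline runs.

## Paired-alignment assembly

Cognate pairing uses genome-ordinal gene identifiers: an HK and an RR whose
indices differ by exactly one are treated as an operonic cognate pair.
Ambiguous adjacencies (an HK flanked by two RRs, or vice versa) are all
retained and reported, rather than resolved by a heuristic — lossless and
auditable; downstream filters see every candidate pair. Concatenated rows
place all HK columns before all RR columns, and per-column provenance
(source protein, source column) travels with the alignment through every
filter.

**Gap filter.** A column is removed when its gap fraction is *strictly*
greater than the threshold (default 0.10): a column with exactly 10% gaps
survives. The filter is idempotent, and the returned column map records
old→new indices plus, when a reference row is designated, 1-based residue
numbers in the ungapped reference sequences of each protein (the familiar
"EnvZ T250" style). Reference numbering restarts at the HK/RR boundary.

**Redundancy filter.** Pairwise identity excludes double-gap positions
from the denominator and counts gap-vs-residue as a mismatch; identity is
undefined (an error) when every position is a double gap. Rows are scanned
greedily in input order and dropped when *strictly* more than 90% identical
to an already-kept row — two rows at exactly the bound are both kept. The
greedy first-seen-kept rule is deterministic given input order; no optimal
minimum-set cover is attempted.

## Mutual information and the column-average adjustment

The estimator is the plug-in MI over observed frequencies, in nats by
default (a `log_base` option rescales). Gaps form a 21st symbol so every
column pair is estimated over the identical row set; a pairwise-deletion
mode is available but changes the effective sample size per pair. The
self-pair MI(i,i) equals the column entropy and is excluded both from
reported pairs and from the per-column averages (an `avg_include_self`
flag adds it back; including the entropy would let conserved columns
deflate their own averages). The adjusted score divides raw MI by the mean
of the two columns' averages; a zero denominator (only possible when every
raw score of both columns is zero) defines the adjusted score as 0.

The plug-in estimator is biased upward at finite sample size by roughly
(|X|−1)(|Y|−1)/2n nats; the column-average adjustment absorbs most of this
because the bias is shared across a column's pairings. That is precisely
why adjusted scores of independent columns concentrate near 1 while a
deterministically coupled pair, whose raw MI approaches the column entropy
(≈ ln 20), stands several-fold above. No shuffle-null p-values enter the
default pipeline (a shuffle utility exists for diagnostics); pair calling
uses the fixed adjusted threshold of 3.5. Only inter-protein (HK×RR) pairs
are reported by default, since partner specificity lives at the interface;
intra-protein pairs are available behind a flag.

## Specificity schemes and trajectory combinatorics

A scheme is an ordered list of mutable units, each a set of residue
positions with a start and a target allele. Units may span several
residues mutated atomically — the response regulator's β5-α5 loop (PFN→TTP)
is one unit of width three. Variant names concatenate per-unit residue
strings in unit order and are parseable back to allele vectors; this makes
dendrogram leaves and interaction-matrix labels self-describing. The
built-in kinase scheme uses the published EnvZ positions 250/254/255; the
regulator scheme uses ordinal positions because the analysis never
dereferences them against a structure.

Codon costs are minimum Hamming distances over all codon pairs of the
standard genetic code (stop codons excluded; alternative NCBI tables can be
named). Note the min-over-pairs quantity is *not* a metric: C→G and G→E
each cost 1 but C→E costs 3, because the two legs use different glycine
codons. Multi-residue units cost the sum of per-residue minima.

**Insulated-path search.** States are (kinase variant, regulator variant);
moves flip exactly one unit in one protein. By default units only flip
start→target (no reversions), so all complete paths have exactly
k_kinase + k_regulator steps; a reversion flag lifts this (simple paths
only). A state is admissible when the pair transfers phosphate — by the
matrix's binary call, or by intensity ≥ an explicit threshold — and, when a
cross-talk kinase is named, when that kinase does not phosphorylate the
state's regulator. Binary calls default to intensity above 10% of the
kinase's profile maximum; gel-based substrate calls are a judgment the data
tables cannot reproduce, so the threshold is declared configuration, not a
fit. Alternating kinase/regulator mutation order is offered as a filter but
not required. Missing matrix entries fail loudly with the absent variant's
name.

**Epistasis table.** For each unit and each background assignment of the
other units, the table records the change in substrate set caused by
flipping that unit (k·2^(k−1) rows per protein); a unit whose effect
differs across backgrounds is flagged context-dependent.

## Profile normalization and two-way clustering

Band intensities are comparable only within one kinase's profile, so each
row is rescaled to percent of its maximum; all-zero rows stay zero and are
flagged. Regulators (columns) are clustered with uncentered-correlation
distance, 1 − Σxy/√(Σx²Σy²), which treats proportional profiles as
identical — appropriate when overall exposure differs between gels; kinases
(rows) use Euclidean distance, which preserves magnitude differences
between kinase activities. Agglomeration is average linkage by default
(the classic clustering tools leave this choice open; single, complete and
centroid are accepted, and outputs are tagged with the metric and linkage
used). Items are sorted lexicographically by label before linkage so tie
merges are reproducible. Slow kinases assayed at two time points enter as
separate rows with suffixed labels. Trees serialize to Newick with branch
lengths equal to merge-height differences.

**Split concordance.** An internal node is concordant with a unit when,
among the node's leaves, one child carries only the start allele and the
other only the target allele of that unit. Units are reported in order of
their shallowest concordant split (root = depth 1), giving the empirical
contribution hierarchy. Two distinct variant leaves in a cherry always
differ at some unit, so a tree over distinct parseable leaves necessarily
has *some* concordant split; the interesting signal is which unit owns the
shallow splits.

## Synthetic data

Alignment rows are i.i.d. uniform over the chosen alphabet (default all 20
amino acids) — deliberately no phylogeny, which isolates the MI estimator
from tree-induced correlation; on real data the redundancy filter only
approximates this. A planted pair couples the RR column to the HK column
through a random bijection with the stated coupling probability; gaps are
injected per column at a fixed rate, and near-duplicate rows can be
appended to exercise the redundancy filter. Defaults (500 rows, 50+50
columns) keep the finite-sample MI background (~0.36 nats) well below the
entropy of a coupled column, so the 3.5 threshold separates planted from
background pairs; benchmarks use 10 seeds at this size, which runs in
seconds.

Panel intensities follow base − Σ_u weight_u·mismatch_u + Gaussian noise,
clipped at zero, where regulator unit u mismatches when its allele differs
from the kinase's preferred allele (kinase unit u positionally; units
beyond the kinase's count prefer the start allele). Defaults: weights
(4, 2, 1, 8) over (pos1, pos2, pos3, loop) — the loop dominates, then
positions 1 > 2 > 3 with factor-two gaps; base 20 keeps intensities
positive before noise; noise σ = 0.25, a quarter of the smallest weight,
i.e. small relative to every weight gap. Hierarchy-recovery benchmarks run
100 seeded replicates.

Interaction matrices derive binary calls from a unit-matching rule
(transfer iff at least q positionally aligned units agree, or any callable
rule); ground-truth path existence is stored from an exhaustive
breadth-first search so the path enumerator can be validated independently.

## What passing the synthetic benchmarks does and does not show

Recovery of planted pairs shows the estimator and adjustment behave as
designed under i.i.d. sampling with deterministic coupling; real alignments
add phylogenetic correlation, alignment error, and weaker, many-body
couplings, so real-data thresholds trade precision against recall in ways
the benchmark cannot certify. Likewise the panel generator produces
additive unit effects plus noise, whereas measured phosphotransfer shows
strong epistasis; the clustering benchmark certifies the readout machinery
(normalization, metrics, concordance), not additivity of real specificity
residues.

## Numerical and degenerate-input choices

MI values are clipped at 0 to remove −0.0 rounding dust; oracle agreement
is asserted to 1e−12. Uncentered correlation errors on zero vectors and is
clipped into [−1, 1] before distances are formed. Zero-row alignments
cannot be gap-filtered; single-column alignments have no MI matrix;
single-item panels cannot be clustered — all are explicit errors rather
than silent degenerate output. Every generator is a pure function of its
spec and seed.
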