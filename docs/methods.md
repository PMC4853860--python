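# Methods notes

## Pipeline model

The analysis starts from identified-peptide evidence — one row per peptide
observation per sample, carrying the peptide sequence, its mapped
accessions, an integrated chromatographic area, and a q-value — and assumes
database searching, FDR control, and the merging of technical injections
happened upstream. Ingestion keeps rows with q-value ≤ 0.01 and peptide
length ≥ 6 residues; everything dropped is counted and reported so that
`ingested = kept + dropped(q) + dropped(length)` always holds.

### Protein inference

Protein grouping is deterministic parsimony, applied per sample:

1. accessions with identical observed peptide sets merge into one group;
2. an accession whose peptide set is a proper subset of another's is
   absorbed into that group (applied largest-set-first, so chains collapse);
3. each remaining shared peptide is assigned to exactly one group — the one
   with the larger full peptide set, ties broken by lexicographically
   smallest member accession — so peptide counts never double-count;
4. groups left without any assigned peptide carry no independent evidence
   and are dropped.

This makes the partition idempotent (regrouping a group's own evidence
reproduces it) and order-independent. Commercial platforms use their own
unpublished grouping rules, so group/accession counts from this
implementation are comparable in spirit but not bit-for-bit with vendor
reports.

Supergroups are the transitive closure of "shares at least one accession"
across all samples' groups, computed by union–find and identified by their
lexicographically smallest accession, which makes the partition independent
of input order. Linkage via shared peptides alone is deliberately not used:
the operational notion is shared ("alternative") accessions in replicate
reports.

### Quantification

Top3 abundance is the mean of the three largest per-peptide areas of a
group in a sample. Two choices were genuinely open:

* **Repeated observations of one peptide** (e.g., split chromatographic
  features) collapse to their maximum area before ranking. Maximum is
  robust to feature splitting; summing would double-count split peaks.
* **Groups with fewer than three observed peptides** are still quantified
  (mean of what was observed) but flagged `sub-top3`. Keeping
  quantification total and pushing the ≥3-peptide policy into the secretion
  caller keeps the two rules independently testable.

Missing is never zero: a group without qualifying peptides in a sample has
a missing cell, excluded from every ppm denominator. ppm values are
`area / Σ area × 10⁶` per sample, with the denominator over all quantified
groups or only called-secreted ones; in either mode the nonmissing ppm of
the denominator set sums to 10⁶ up to floating-point rounding (~1e-16
relative, against a 1e-9 tolerance).

When chained supergroup linkage puts two same-sample groups into one
supergroup, the cell takes the maximum member Top3 (a `sum` option exists).
A literal duplicate assignment of one group raises an internal consistency
error instead.

### Secretion calling

The decision rule: compute the arithmetic mean of the group's control
abundances (`control_reference`), the per-treatment-sample ratio to it, and
call a group secreted iff the ratio is **strictly greater than 3** in **at
least 2** SIV-PS replicates and the group's maximum per-treatment-sample
peptide count is **at least 3**. The ratio boundary is exclusive: a ratio
of exactly 3.0 never counts as up.

Groups never detected in either control have an undefined ratio. The
default `infinite_ratio` policy treats missing control cells as zero in the
mean and assigns ratio +∞ to any positive treatment abundance — detected in
treatment and never in control is the strongest possible evidence of
secretion, and several canonical secreted proteins behave exactly this way.
The alternative `pseudo_floor` policy substitutes a configurable positive
floor, making every ratio finite; it is strictly more conservative. A
consequence of the default worth knowing: absent-in-control groups exceed
*any* finite fold threshold, so the called set only empties at a threshold
of +∞ (the monotonicity tests encode this).

The per-sample quantity fed to the ratio is the group's Top3 abundance.
Upstream platforms summarize two LC-MS injections per sample into a
"median" before this step; injections are merged upstream here, so the
per-sample Top3 is the corresponding quantity.

### Classification and motif scans

Conventional secretion requires a signal peptide and a negative C-terminal
ER-retention scan (final four residues exactly HDEL or KDEL — an
ER-retained protein is resident, not secreted). Unconventional secretion
requires no signal peptide and a SecretomeP-style neural-network score at
or above 0.5 — the predictor's conventional cutoff; reported per-protein
examples classify identically at 0.5 or 0.6. Everything else is
unclassified, and called accessions without an annotation record surface
in an explicit `unannotated` bucket. The N-glycosylation sequon is
Asn-Xaa-Ser/Thr with Xaa ≠ Pro (the biochemical sequon), counted with
overlaps and reported 1-based. External predictors (SignalP/SecretomeP/
TMHMM/GPI/palmitoylation/localization) are consumed as table columns, never
re-implemented.

Size bins are left-closed/right-open at 20 and 50 kDa by default (a 20-kDa
protein lands in 20–50). GPI-anchored proteins ("GAPs") are those with an
ω-site call at FDR ≤ 0.1 %; the reported overlap is the fraction of GAPs
with ≥ 1 predicted palmitoylation site, undefined (reported as such) when
there are no GAPs.

### Comparative statistics

Pairwise sample-type comparisons filter supergroups to ≥ 3 peptides and
presence in ≥ 1 replicate of the type. "Percent overlap" is reported under
all three denominators (union, A, B) because no convention is privileged.
Enrichment is the upper-tail hypergeometric `P(X ≥ k)` with the detected
background as population; no multiple-testing correction by default
(Benjamini–Hochberg behind a flag), mirroring a plain p < 0.05 readout.
Terms are flat labels; no GO-graph propagation. Correlation with transcript
levels is Pearson on log10-transformed values (nonpositive values excluded
pairwise), p-value from the t distribution with n−2 df.

## Synthetic-data generator

The generator emulates the experiment's structure, not its instrument: 2
unpollinated-pistil controls, 4 SIV-PS, 4 PT24-PS, 4 SIV-PP, 4 PT24-PP
samples; a 500-protein default cohort of 20 conventional + 40
unconventional secreted proteins, 340 pistil-background proteins, and 100
cytosolic contaminants.

Peptide areas are multiplicative:
`area = abundance × ionization(peptide) × presence(class, sample type) ×
lognormal(σ)`, with per-observation dropout (default 5 %) and an intensity
floor. Presence multipliers: secreted classes carry the planted fold
(default 5) in SIV-PS, are absent from controls unless a leak rate is set,
and a configurable fraction (default 0.5) is SIV-only (absent from
PT24-PS); pistil background sits at baseline in controls and SIV-PS only;
contaminants are present in **every** sample at a low relative level
(default 0.05) — modelling consistent low-level cytosolic carry-over, which
is what enrichment-quality assays show, rather than sporadic
presence/absence that would manufacture absent-in-control false positives
unrelated to the caller's behaviour.

Other choices, made once:

* Protein abundances are lognormal (ln-mean ln(1e5), σ = 1); per-peptide
  ionization factors are lognormal (σ = 0.5) and fixed across samples, so
  the cross-sample CV of a peptide isolates the noise term
  (`CV = sqrt(exp(σ²) − 1)`, which the tests verify in closed form).
* Peptide counts per protein are 1 + Poisson(6); planted secreted proteins
  are floored at 3 peptides so that the planted truth is recoverable *in
  principle* under the ≥3-peptide rule — recovery metrics then measure the
  caller, not an identifiability floor baked into the truth. Real datasets
  have a larger singleton fraction than this model.
* Peptides are unique across proteins unless a sharing fraction is
  configured (each peptide then independently maps to a second random
  accession), exercising grouping and supergroup linkage.
* Sequences are synthetic tryptic-like strings (7–20 residues, ending
  K/R, no internal K/R); full-length "proteins" are their concatenation
  with an N-terminal Met, a hydrophobic signal-peptide-like prefix for
  conventional proteins, and a C-terminal KDEL on requested ER-decoys.
  They are folded into a FASTA for motif-scan tests, nothing more.
* Transcript levels use a Gaussian copula on the log scale, so the
  population log–log Pearson correlation with abundance equals the
  requested coupling exactly.
* Generated q-values are uniform below 0.009 (the generator emulates a
  post-search confident report); the ingestion filters are exercised by
  hand-made rows in the tests.
* All randomness derives from the config seed (sub-streams at seed+1..+4
  for mapping, evidence, annotations, transcripts); identical config and
  seed give byte-identical output files.

What passing tests on this generator do **not** show: robustness to
retention-time drift, shared-peptide-rich homolog families at realistic
density, heavy-tailed intensity error, or search-engine identification
biases. The generator validates the bookkeeping and the decision rule under
a controlled noise model, not instrument physics.

## Problem sizes used in the checks

The automated checks run the default 500-protein cohort; the multi-seed
recovery check uses 20 seeds of the 2-control + 4-SIV-PS design (the
acceptance script reports a 10-seed average), 1000-instance oracle
comparisons for Top3 and the motif scanners, exhaustive rational-arithmetic
hypergeometric enumeration for populations up to 12, and 100-seed
Monte-Carlo checks of the transcript-coupling recovery at n = 200.

## Known limitations

* Parsimony and supergroup counts are rule-dependent; vendor-platform
  counts will differ under any independent implementation.
* The caller implements a thresholded fold-change rule by design; it
  produces no p-values and none are invented.
* Overlap percentages depend on the denominator convention; consumers must
  pick one explicitly.
* The ER-retention scan is an exact C-terminal tetrapeptide match; degenerate
  variants (e.g., RDEL) are not matched.
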