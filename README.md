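# ptsecretome

Quantitative analysis of pollen tube secretomes from label-free LC-MS/MS
peptide evidence.

When pollen tubes grow through a cut pistil and emerge into medium
(the semi-in-vivo, "SIV", preparation), the proteins they secrete can be
collected and quantified against unpollinated-pistil controls. The hard part
is not the mass spectrometry but the bookkeeping afterwards: collapsing
peptide evidence into parsimony protein groups, linking groups across
replicates into supergroups, quantifying them reproducibly, and deciding —
against a background of pistil proteins and cytosolic carry-over — which
groups are genuinely secreted. `ptsecretome` implements that pipeline as a
tested Python library and CLI for proteomics analysts working with
secretome-style enrichment experiments.

## What it computes

* **Protein inference.** Per-sample parsimony groups: accessions with
  identical peptide sets merge, subsets are absorbed, shared peptides are
  assigned uniquely (greedy set cover). Groups sharing accessions across
  replicates are linked transitively into supergroups (union–find).
* **Top3 quantification.** A group's abundance in a sample is the mean area
  of its three most intense peptides,
  `Top3 = (a(1) + a(2) + a(3)) / 3` with `a(i)` the i-th largest
  per-peptide maximum area. Relative abundance is expressed in parts per
  million: `ppm_i = area_i / Σ_j area_j × 10⁶`, with the denominator over
  all quantified groups or only the called-secreted ones.
* **Secretion calling.** A group is called secreted when its abundance
  ratio to the averaged controls is **strictly > 3** in **≥ 2** treatment
  (SIV-PS) replicates and the group was identified from **≥ 3** peptides.
  Groups never seen in controls get an infinite ratio by default (a
  pseudo-count floor is available).
* **Pathway classification.** Called accessions are split into
  conventionally secreted (signal peptide, no C-terminal HDEL/KDEL
  ER-retention motif) and unconventionally secreted (no signal peptide,
  SecretomeP-style NN score ≥ 0.5), using a supplied predictor table plus
  in-house motif scans (ER retention, N-X-[S/T] sequons with X ≠ P).
* **Comparative statistics.** Filtered set overlaps between sample types,
  log–log Pearson correlation of protein ppm with transcript levels, and
  upper-tail hypergeometric term overrepresentation
  `p = P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`.
* **Synthetic data.** A ground-truthed generator emulating the full design
  (2 controls, 4 SIV-PS, 4 PT24-PS, 4 SIV-PP, 4 PT24-PP) with planted
  conventional/unconventional secreted proteins, pistil background,
  cytosolic contaminants, lognormal intensity noise, and detection dropout
  — so every stage is testable without any raw-data download.

## Worked example

```
ptsecretome simulate --seed 7 --out demo_data
ptsecretome call --evidence demo_data --design demo_data/design.tsv \
    --annotations demo_data/annotations.tsv --fasta demo_data/proteins.fasta \
    --out demo_results
```

The `call` command prints a run summary such as:

```json
{
  "peptides_ingested": 30886,
  "peptides_kept": 30886,
  "peptides_dropped_q_value": 0,
  "peptides_dropped_length": 0,
  "n_protein_groups": 4668,
  "n_supergroups": 500,
  "n_called_secreted": 60,
  "n_called_accessions": 60,
  "classification": {
    "pct_conventional": 33.33, "n_conventional": 20,
    "pct_unconventional": 66.67, "n_unconventional": 40,
    "pct_unclassified": 0.0, "n_unclassified": 0,
    "pct_unannotated": 0.0, "n_unannotated": 0,
    "n_total": 60
  }
}
```

(percentages truncated here for layout). Reading: 30 886 confident peptide
observations collapse to 4 668 per-sample
protein groups and 500 cross-replicate supergroups; 60 supergroups pass the
3-fold / 3-peptide / 2-sample rule — exactly the 20 conventional and 40
unconventional proteins this simulation planted. On real data the same
outputs (`groups.tsv`, `supergroups.tsv`, `abundance_*.tsv`, `calls.tsv`,
`classification.tsv`) are produced from your evidence TSVs.

Pairwise comparison and enrichment work on those outputs:

```
ptsecretome compare --a SIV-PS --b PT24-PS --results demo_results \
    --design demo_data/design.tsv
ptsecretome correlate --results demo_results \
    --transcriptome demo_data/transcriptome.tsv
```

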