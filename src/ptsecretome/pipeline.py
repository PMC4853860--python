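"""End-to-end orchestration: evidence -> groups -> supergroups -> Top3 ->
ppm -> secretion calls -> classification.

The functions here are thin, deterministic glue over the stage modules;
the command line interface in :mod:`ptsecretome.cli` and the test suite
both drive the pipeline through this layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import calling as call_mod
from . import evidence as ev_mod
from . import quant as quant_mod
from .errors import ConfigurationError


@dataclass
class CallResult:
    evidence: pd.DataFrame
    ingest_counts: dict
    groups: list
    supergroups: list
    areas: pd.DataFrame
    sub_top3: pd.DataFrame
    peptide_counts: pd.DataFrame
    ppm_all: pd.DataFrame
    ppm_secreted: pd.DataFrame | None
    calls: list
    called_sgs: set
    classification: list = field(default_factory=list)
    class_summary: dict = field(default_factory=dict)

    @property
    def sg_accessions(self) -> dict[str, frozenset]:
        return {sg.sg_id: sg.union_accessions for sg in self.supergroups}


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sample_type": str})
    if not {"sample_id", "sample_type"} <= set(design.columns):
        raise ConfigurationError(f"{path}: design needs sample_id and sample_type columns")
    return design


def load_evidence_dir(evidence_dir, q_value_max=0.01, min_peptide_length=6):
    """Read and concatenate every ``evidence_*.tsv`` in a directory."""
    paths = sorted(Path(evidence_dir).glob("evidence_*.tsv"))
    if not paths:
        raise ConfigurationError(f"no evidence_*.tsv files in {evidence_dir}")
    frames, totals = [], {"ingested": 0, "kept": 0, "dropped_q_value": 0, "dropped_length": 0}
    for p in paths:
        df, counts = ev_mod.read_evidence(p, q_value_max, min_peptide_length)
        frames.append(df)
        for k in totals:
            totals[k] += counts[k]
    return pd.concat(frames, ignore_index=True), totals


def peptide_count_matrix(supergroups, sample_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {s: [sg.peptide_count_in(s) for sg in supergroups] for s in sample_ids},
        index=[sg.sg_id for sg in supergroups],
    )


def run_call(
    evidence: pd.DataFrame,
    design: pd.DataFrame,
    params: call_mod.CallingParams = call_mod.CallingParams(),
    ingest_counts: dict | None = None,
    annotations: pd.DataFrame | None = None,
    sequences: dict[str, str] | None = None,
    nn_threshold: float = ann_mod.DEFAULT_NN_THRESHOLD,
) -> CallResult:
    """Run grouping, quantification, calling, and (optionally) classification."""
    groups = ev_mod.build_groups_all_samples(evidence)
    supergroups = ev_mod.build_supergroups(groups)
    sample_ids = list(design["sample_id"])
    areas, sub_top3 = quant_mod.assemble_abundance_matrix(supergroups, evidence, sample_ids)
    pep_counts = peptide_count_matrix(supergroups, sample_ids)
    calls = call_mod.call_secreted(
        areas, design, params, peptide_counts=pep_counts, sub_top3=sub_top3
    )
    called = call_mod.called_set(calls)
    ppm_all = quant_mod.ppm_matrix(areas)
    ppm_secreted = quant_mod.ppm_matrix(areas, called=called) if called else None

    result = CallResult(
        evidence=evidence,
        ingest_counts=ingest_counts or {},
        groups=groups,
        supergroups=supergroups,
        areas=areas,
        sub_top3=sub_top3,
        peptide_counts=pep_counts,
        ppm_all=ppm_all,
        ppm_secreted=ppm_secreted,
        calls=calls,
        called_sgs=called,
    )
    if annotations is not None:
        called_accs = sorted(set().union(*(result.sg_accessions[sg] for sg in called))) if called else []
        records, summary = ann_mod.classify_secretion(
            called_accs, annotations, sequences=sequences, nn_threshold=nn_threshold
        )
        result.classification = records
        result.class_summary = summary
    return result


def write_call_outputs(result: CallResult, outdir) -> dict:
    """Write every stage's output and a JSON run summary; returns the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev_mod.groups_to_frame(result.groups).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    ev_mod.supergroups_to_frame(result.supergroups).to_csv(
        outdir / "supergroups.tsv", sep="\t", index=False
    )
    result.areas.to_csv(outdir / "abundance_areas.tsv", sep="\t", index_label="sg_id")
    result.sub_top3.to_csv(outdir / "sub_top3_flags.tsv", sep="\t", index_label="sg_id")
    result.ppm_all.to_csv(outdir / "abundance_ppm_all.tsv", sep="\t", index_label="sg_id")
    if result.ppm_secreted is not None:
        result.ppm_secreted.to_csv(
            outdir / "abundance_ppm_secreted.tsv", sep="\t", index_label="sg_id"
        )
    call_mod.calls_to_frame(result.calls).to_csv(outdir / "calls.tsv", sep="\t", index=False)
    if result.classification:
        pd.DataFrame(
            {
                "accession": [r.accession for r in result.classification],
                "secretion_class": [r.secretion_class for r in result.classification],
                "evidence": [r.evidence for r in result.classification],
            }
        ).to_csv(outdir / "classification.tsv", sep="\t", index=False)

    counts = result.ingest_counts
    summary = {
        "peptides_ingested": counts.get("ingested"),
        "peptides_kept": counts.get("kept"),
        "peptides_dropped_q_value": counts.get("dropped_q_value"),
        "peptides_dropped_length": counts.get("dropped_length"),
        "n_protein_groups": len(result.groups),
        "n_supergroups": len(result.supergroups),
        "n_called_secreted": len(result.called_sgs),
        "n_called_accessions": int(
            len(set().union(*(result.sg_accessions[sg] for sg in result.called_sgs)))
        ) if result.called_sgs else 0,
        "classification": {
            k: (float(v) if isinstance(v, float) else v)
            for k, v in result.class_summary.items()
        },
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, allow_nan=True))
    return summary


def read_fasta_sequences(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
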