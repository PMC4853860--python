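"""Control-relative secretion calling.

A protein group is called pollen tube-secreted when, relative to the
average of the unpollinated-pistil control samples, its abundance is more
than ``fold_threshold``-fold up (strict inequality) in at least
``min_samples`` treatment replicates, and the group was identified from at
least ``min_peptides`` peptides.  The defaults (3-fold, 3 peptides, 2 of
the treatment samples) are the rule as used in semi-in-vivo secretome studies.

Groups detected in treatment but never in any control have an undefined
ratio; the default ``infinite_ratio`` policy treats them as up-regulated
(missing control values average in as zero and a positive/zero ratio is
+inf).  The alternative ``pseudo_floor`` policy substitutes a configurable
positive floor for missing control values so every ratio is finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

CONTROL_TYPE = "control"
TREATMENT_TYPE = "SIV-PS"


@dataclass(frozen=True)
class CallingParams:
    fold_threshold: float = 3.0
    min_peptides: int = 3
    min_samples: int = 2
    absent_control_policy: str = "infinite_ratio"
    pseudo_floor_value: float = 1.0

    def __post_init__(self):
        if self.fold_threshold <= 0:
            raise ConfigurationError("fold_threshold must be positive")
        if self.min_peptides < 1 or self.min_samples < 1:
            raise ConfigurationError("min_peptides and min_samples must be >= 1")
        if self.absent_control_policy not in ("infinite_ratio", "pseudo_floor"):
            raise ConfigurationError(
                f"unknown absent_control_policy {self.absent_control_policy!r}"
            )
        if self.pseudo_floor_value <= 0:
            raise ConfigurationError("pseudo_floor_value must be positive")


@dataclass
class SecretionCall:
    sg_id: str
    control_reference: float
    per_sample_ratio: dict[str, float]  # NaN = group missing in that sample
    n_samples_up: int
    peptide_count_max: int
    verdict: bool
    reason: str
    sub_top3_everywhere: bool = False


def _design_samples(design: pd.DataFrame, sample_type: str) -> list[str]:
    return list(design.loc[design["sample_type"] == sample_type, "sample_id"])


def call_secreted(
    areas: pd.DataFrame,
    design: pd.DataFrame,
    params: CallingParams = CallingParams(),
    peptide_counts: pd.DataFrame | None = None,
    sub_top3: pd.DataFrame | None = None,
    treatment_type: str = TREATMENT_TYPE,
) -> list[SecretionCall]:
    """Apply the secretion decision rule to every row of the abundance matrix.

    ``areas``: supergroup x sample Top3 matrix (NaN = missing).
    ``design``: DataFrame with columns ``sample_id``, ``sample_type``.
    ``peptide_counts``: per-(supergroup, sample) distinct-peptide counts;
    the rule uses the maximum over treatment samples.
    Every group receives a call record, including negative verdicts with a
    reason.
    """
    controls = _design_samples(design, CONTROL_TYPE)
    treatments = _design_samples(design, treatment_type)
    if len(controls) < 2:
        raise ConfigurationError(f"need >=2 control samples, found {len(controls)}")
    if len(treatments) < 2:
        raise ConfigurationError(
            f"need >=2 {treatment_type} samples, found {len(treatments)}"
        )
    missing_cols = [s for s in controls + treatments if s not in areas.columns]
    if missing_cols:
        raise ConfigurationError(f"samples not in abundance matrix: {missing_cols}")

    calls = []
    for sg_id, row in areas.iterrows():
        ctrl = row[controls].to_numpy(dtype=float)
        if params.absent_control_policy == "pseudo_floor":
            ctrl = np.where(np.isnan(ctrl), params.pseudo_floor_value, ctrl)
        else:
            ctrl = np.where(np.isnan(ctrl), 0.0, ctrl)
        control_reference = float(ctrl.mean())

        ratios: dict[str, float] = {}
        n_up = 0
        for s in treatments:
            a = row[s]
            if np.isnan(a):
                ratios[s] = float("nan")
                continue
            if control_reference > 0:
                r = a / control_reference
            else:
                r = math.inf if a > 0 else float("nan")
            ratios[s] = r
            if r > params.fold_threshold:
                n_up += 1

        if peptide_counts is not None:
            pep_max = int(peptide_counts.loc[sg_id, treatments].max())
        else:
            pep_max = 0

        if sub_top3 is not None:
            obs = ~row[treatments].isna()
            sub_everywhere = bool(obs.any() and sub_top3.loc[sg_id, treatments][obs].all())
        else:
            sub_everywhere = False

        verdict = n_up >= params.min_samples and pep_max >= params.min_peptides
        if verdict:
            reason = (
                f"up >{params.fold_threshold:g}x in {n_up} treatment samples, "
                f"{pep_max} peptides"
            )
        elif n_up < params.min_samples:
            reason = f"up in only {n_up} of {len(treatments)} treatment samples"
        else:
            reason = f"only {pep_max} peptides (minimum {params.min_peptides})"
        calls.append(
            SecretionCall(
                sg_id=sg_id,
                control_reference=control_reference,
                per_sample_ratio=ratios,
                n_samples_up=n_up,
                peptide_count_max=pep_max,
                verdict=verdict,
                reason=reason,
                sub_top3_everywhere=sub_everywhere,
            )
        )
    return calls


def called_set(calls: list[SecretionCall]) -> set[str]:
    return {c.sg_id for c in calls if c.verdict}


def calls_to_frame(calls: list[SecretionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "sg_id": c.sg_id,
            "control_reference": c.control_reference,
            "n_samples_up": c.n_samples_up,
            "peptide_count_max": c.peptide_count_max,
            "verdict": c.verdict,
            "reason": c.reason,
        }
        for s, r in c.per_sample_ratio.items():
            row[f"ratio_{s}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PuritySummary:
    n_groups: int
    n_called: int
    n_sub_top3_excluded: int
    n_infinite_ratio_calls: int
    sensitivity: float | None = None
    specificity: float | None = None
    false_discovery_proportion: float | None = None


def purity_summary(
    calls: list[SecretionCall],
    truth_secreted: set[str] | None = None,
    sg_accessions: dict[str, frozenset] | None = None,
) -> PuritySummary:
    """Run-quality counts and, on synthetic data, recovery vs planted labels.

    ``truth_secreted`` holds planted secreted accessions; a supergroup is a
    true positive when any of its accessions (via ``sg_accessions``) is
    planted secreted.
    """
    n_called = sum(c.verdict for c in calls)
    n_sub = sum(1 for c in calls if c.sub_top3_everywhere and not c.verdict)
    n_inf = sum(
        1
        for c in calls
        if c.verdict and any(math.isinf(r) for r in c.per_sample_ratio.values())
    )
    summary = PuritySummary(
        n_groups=len(calls),
        n_called=n_called,
        n_sub_top3_excluded=n_sub,
        n_infinite_ratio_calls=n_inf,
    )
    if truth_secreted is not None and sg_accessions is not None:
        tp = fp = fn = tn = 0
        for c in calls:
            is_secreted = bool(sg_accessions.get(c.sg_id, frozenset()) & truth_secreted)
            if c.verdict and is_secreted:
                tp += 1
            elif c.verdict:
                fp += 1
            elif is_secreted:
                fn += 1
            else:
                tn += 1
        summary.sensitivity = tp / (tp + fn) if tp + fn else None
        summary.specificity = tn / (tn + fp) if tn + fp else None
        summary.false_discovery_proportion = fp / (tp + fp) if tp + fp else 0.0
    return summary


def recovery_vs_truth(
    calls: list[SecretionCall],
    sg_accessions: dict[str, frozenset],
    truth_secreted: set[str],
) -> dict[str, float]:
    """Accession-level recovery of planted secreted proteins.

    Unlike :func:`purity_summary` (which scores detected supergroups), the
    sensitivity here penalizes planted proteins that never made it into any
    called supergroup — including ones never detected at all.
    """
    called_accs: set[str] = set()
    for c in calls:
        if c.verdict:
            called_accs |= set(sg_accessions.get(c.sg_id, frozenset()))
    tp = len(called_accs & truth_secreted)
    fp = len(called_accs - truth_secreted)
    sensitivity = tp / len(truth_secreted) if truth_secreted else float("nan")
    fdp = fp / len(called_accs) if called_accs else 0.0
    return {"sensitivity": sensitivity, "false_discovery_proportion": fdp,
            "n_called_accessions": len(called_accs)}
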