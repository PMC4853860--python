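"""Top3 label-free quantification and parts-per-million normalization.

A protein group's abundance in a sample is the mean area of its three most
intense peptides there (Top3).  Repeated observations of one peptide are
collapsed to their maximum area first, which is robust to split
chromatographic features.  Groups quantified from fewer than three distinct
peptides are still quantified (mean of what was observed) but flagged
"sub-top3"; whether they can ever be called secreted is governed by the
caller's own minimum-peptide rule.

ppm values express a group's share of total quantified signal in a sample:
``ppm_i = area_i / sum_j area_j * 1e6`` where the denominator runs over all
quantified groups or only the called-secreted ones.  Missing is never
conflated with zero: a group with no qualifying peptides in a sample has a
missing (NaN) cell, excluded from every denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evidence import ProteinGroup, SuperGroup


def top3_area(group: ProteinGroup, evidence: pd.DataFrame) -> tuple[float, bool]:
    """Top3 abundance of one group from its sample's evidence.

    Returns ``(area, sub_top3_flag)``; ``(nan, False)`` when none of the
    group's peptides were observed.  ``evidence`` must be the group's
    sample's table; rows for other peptides are ignored.
    """
    sub = evidence[
        (evidence["sample_id"] == group.sample_id)
        & evidence["peptide_sequence"].isin(group.peptide_set)
    ]
    if sub.empty:
        return float("nan"), False
    per_peptide = sub.groupby("peptide_sequence")["area"].max()
    top = np.sort(per_peptide.to_numpy())[::-1][:3]
    return float(top.mean()), len(per_peptide) < 3


def ppm_normalize(areas: pd.Series, called: set | None = None) -> pd.Series:
    """Normalize one sample's areas to parts per million.

    ``areas`` is indexed by group/supergroup id; NaN cells stay NaN and do
    not enter the denominator.  With ``called`` given (secreted-only mode)
    the denominator — and the returned values — are restricted to the
    called identifiers.
    """
    values = areas if called is None else areas[areas.index.isin(called)]
    total = values.sum(skipna=True)
    if not np.isfinite(total) or total <= 0 or values.notna().sum() == 0:
        raise ConfigurationError("nothing to normalize: no nonmissing areas")
    return values / total * 1e6


def assemble_abundance_matrix(
    supergroups: list[SuperGroup],
    evidence: pd.DataFrame,
    sample_ids: list[str] | None = None,
    aggregate: str = "max",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the supergroup x sample Top3 abundance matrix.

    Returns ``(areas, sub_top3)``: a float matrix (NaN = not observed) and a
    parallel boolean matrix flagging cells quantified from fewer than three
    peptides.  When chained linkage puts two same-sample groups into one
    supergroup, the cell takes the ``aggregate`` ("max" or "sum") of their
    Top3 areas and is flagged sub-top3 if every contributing group was.
    """
    if aggregate not in ("max", "sum"):
        raise ConfigurationError(f"unknown aggregate {aggregate!r}")
    if sample_ids is None:
        sample_ids = sorted(evidence["sample_id"].unique())
    # per-sample peptide -> max observed area (repeat observations collapsed)
    max_area = evidence.groupby(["sample_id", "peptide_sequence"])["area"].max()
    peptide_areas: dict[str, dict[str, float]] = {
        sid: sub.droplevel("sample_id").to_dict()
        for sid, sub in max_area.groupby(level="sample_id")
    }

    index = [sg.sg_id for sg in supergroups]
    if len(set(index)) != len(index):
        raise ConfigurationError("duplicate supergroup ids")
    areas = pd.DataFrame(np.nan, index=index, columns=sample_ids)
    flags = pd.DataFrame(False, index=index, columns=sample_ids)

    for sg in supergroups:
        seen: set[str] = set()
        for g in sg.member_groups:
            if g.group_id in seen:
                raise ConfigurationError(f"group {g.group_id} assigned twice in {sg.sg_id}")
            seen.add(g.group_id)
            lookup = peptide_areas.get(g.sample_id)
            if lookup is None:
                continue
            observed = [lookup[p] for p in g.peptide_set if p in lookup]
            if not observed:
                continue
            top = sorted(observed, reverse=True)[:3]
            value, sub = float(np.mean(top)), len(observed) < 3
            cell = areas.at[sg.sg_id, g.sample_id]
            if np.isnan(cell):
                areas.at[sg.sg_id, g.sample_id] = value
                flags.at[sg.sg_id, g.sample_id] = sub
            else:
                combined = max(cell, value) if aggregate == "max" else cell + value
                areas.at[sg.sg_id, g.sample_id] = combined
                flags.at[sg.sg_id, g.sample_id] = bool(flags.at[sg.sg_id, g.sample_id] and sub)
    return areas, flags


def ppm_matrix(areas: pd.DataFrame, called: set | None = None) -> pd.DataFrame:
    """Column-wise :func:`ppm_normalize`; columns with no data stay all-NaN."""
    out = {}
    for col in areas.columns:
        try:
            out[col] = ppm_normalize(areas[col], called=called)
        except ConfigurationError:
            out[col] = areas[col] * np.nan
    return pd.DataFrame(out).reindex(areas.index if called is None else sorted(called))
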