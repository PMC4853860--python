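"""Peptide evidence ingestion and protein inference.

The pipeline starts from identified-peptide evidence tables (one row per
peptide observation per sample run).  Accessions indistinguishable by the
observed peptides are collapsed into per-sample protein groups by a
deterministic parsimony rule, and groups from different replicates and
sample types are linked into cross-replicate supergroups through shared
("alternative") accessions.

Evidence TSV schema (tab-separated, one header line)::

    peptide_sequence  sample_id  area  accessions  q_value

``accessions`` is a semicolon-joined list of protein identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ParseError

EVIDENCE_COLUMNS = ["peptide_sequence", "sample_id", "area", "accessions", "q_value"]

#: Default identification filters: q-value below 1 % and at least six residues.
DEFAULT_Q_VALUE_MAX = 0.01
DEFAULT_MIN_PEPTIDE_LENGTH = 6


@dataclass(frozen=True)
class ProteinGroup:
    """A per-sample parsimony group of accessions sharing peptide evidence."""

    group_id: str
    sample_id: str
    member_accessions: frozenset[str]
    representative: str
    peptide_set: frozenset[str]

    @property
    def peptide_count(self) -> int:
        return len(self.peptide_set)


@dataclass
class SuperGroup:
    """Cross-replicate transitive union of protein groups via shared accessions."""

    sg_id: str
    member_groups: list[ProteinGroup] = field(default_factory=list)

    @property
    def member_group_ids(self) -> frozenset[str]:
        return frozenset(g.group_id for g in self.member_groups)

    @property
    def union_accessions(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.member_groups:
            out |= g.member_accessions
        return frozenset(out)

    @property
    def peptide_count_max(self) -> int:
        return max(g.peptide_count for g in self.member_groups)

    @property
    def present_in_samples(self) -> frozenset[str]:
        return frozenset(g.sample_id for g in self.member_groups)

    def peptide_count_in(self, sample_id: str) -> int:
        """Largest member-group peptide count within one sample (0 if absent)."""
        counts = [g.peptide_count for g in self.member_groups if g.sample_id == sample_id]
        return max(counts, default=0)


def read_evidence(
    path,
    q_value_max: float = DEFAULT_Q_VALUE_MAX,
    min_peptide_length: int = DEFAULT_MIN_PEPTIDE_LENGTH,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read one evidence TSV and apply the identification filters.

    Rows with q-value above ``q_value_max`` or peptides shorter than
    ``min_peptide_length`` residues are dropped.  Returns the filtered table
    (with ``accessions`` parsed to frozensets) and a dict of ingestion
    counts: ``{"ingested", "kept", "dropped_q_value", "dropped_length"}``.

    Raises :class:`ParseError` naming the line number on a malformed row
    (non-numeric area or q-value, empty accession list).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file, expected header {EVIDENCE_COLUMNS}")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    rows = []
    counts = {"ingested": len(df), "kept": 0, "dropped_q_value": 0, "dropped_length": 0}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            area = float(row.area)
            q_value = float(row.q_value)
        except ValueError:
            raise ParseError(f"{path}: line {idx}: non-numeric area or q_value")
        accs = frozenset(a for a in str(row.accessions).split(";") if a)
        if not accs:
            raise ParseError(f"{path}: line {idx}: empty accession list")
        if q_value > q_value_max:
            counts["dropped_q_value"] += 1
            continue
        if len(row.peptide_sequence) < min_peptide_length:
            counts["dropped_length"] += 1
            continue
        counts["kept"] += 1
        rows.append(
            {
                "peptide_sequence": row.peptide_sequence,
                "sample_id": row.sample_id,
                "area": area,
                "accessions": accs,
                "q_value": q_value,
            }
        )
    out = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    return out, counts


def _as_accession_set(value) -> frozenset[str]:
    """Accept either parsed accession sets or the TSV's semicolon-joined form."""
    if isinstance(value, str):
        return frozenset(a for a in value.split(";") if a)
    return frozenset(value)


def build_protein_groups(evidence: pd.DataFrame) -> list[ProteinGroup]:
    """Infer parsimony protein groups from one sample's evidence.

    The rule, applied deterministically:

    1. accessions with identical observed peptide sets are merged;
    2. an accession set whose peptides are a proper subset of another's is
       absorbed into that group;
    3. remaining shared peptides are each assigned to exactly one group —
       the one with the larger full peptide set, ties broken by
       lexicographically smallest member accession;
    4. groups left with no assigned peptide carry no independent evidence
       and are dropped (greedy set cover).

    The representative is the lexicographically smallest member accession.
    """
    if evidence.empty:
        return []
    samples = set(evidence["sample_id"])
    if len(samples) != 1:
        raise ValueError(f"evidence spans multiple samples: {sorted(samples)}")
    sample_id = samples.pop()

    acc_peptides: dict[str, set[str]] = {}
    for row in evidence.itertuples(index=False):
        for acc in _as_accession_set(row.accessions):
            acc_peptides.setdefault(acc, set()).add(row.peptide_sequence)

    # 1. merge identical peptide sets
    by_set: dict[frozenset[str], set[str]] = {}
    for acc, peps in acc_peptides.items():
        by_set.setdefault(frozenset(peps), set()).add(acc)

    # 2. absorb proper subsets (largest first so chains collapse fully)
    proto = sorted(by_set.items(), key=lambda kv: (-len(kv[0]), min(kv[1])))
    kept: list[tuple[set[str], set[str]]] = []  # (full peptide set, members)
    for peps, members in proto:
        for kept_peps, kept_members in kept:
            if peps < kept_peps:
                kept_members |= members
                break
        else:
            kept.append((set(peps), set(members)))

    # 3. unique peptide assignment
    claimants: dict[str, list[int]] = {}
    for i, (peps, _) in enumerate(kept):
        for p in peps:
            claimants.setdefault(p, []).append(i)
    assigned: dict[int, set[str]] = {i: set() for i in range(len(kept))}
    for p, idxs in claimants.items():
        winner = min(idxs, key=lambda i: (-len(kept[i][0]), min(kept[i][1])))
        assigned[winner].add(p)

    groups = []
    for i, (_, members) in enumerate(kept):
        if not assigned[i]:
            continue  # no independent evidence after assignment
        rep = min(members)
        groups.append(
            ProteinGroup(
                group_id=f"{sample_id}::{rep}",
                sample_id=sample_id,
                member_accessions=frozenset(members),
                representative=rep,
                peptide_set=frozenset(assigned[i]),
            )
        )
    groups.sort(key=lambda g: g.representative)
    return groups


def build_groups_all_samples(evidence: pd.DataFrame) -> list[ProteinGroup]:
    """Run :func:`build_protein_groups` per sample over a combined table."""
    groups: list[ProteinGroup] = []
    for _, sub in evidence.groupby("sample_id", sort=True):
        groups.extend(build_protein_groups(sub))
    return groups


def build_supergroups(groups: list[ProteinGroup]) -> list[SuperGroup]:
    """Link protein groups into supergroups by shared accessions.

    Two groups belong to the same supergroup when they share at least one
    accession, transitively (union-find).  The partition is independent of
    input order: supergroups are identified by their lexicographically
    smallest union accession.
    """
    if not groups:
        return []
    parent = list(range(len(groups)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    acc_first: dict[str, int] = {}
    for i, g in enumerate(groups):
        for acc in g.member_accessions:
            if acc in acc_first:
                union(acc_first[acc], i)
            else:
                acc_first[acc] = i

    clusters: dict[int, list[ProteinGroup]] = {}
    for i, g in enumerate(groups):
        clusters.setdefault(find(i), []).append(g)

    sgs = []
    for members in clusters.values():
        members.sort(key=lambda g: (g.sample_id, g.representative))
        anchor = min(min(g.member_accessions) for g in members)
        sgs.append(SuperGroup(sg_id=f"SG::{anchor}", member_groups=members))
    sgs.sort(key=lambda sg: sg.sg_id)
    return sgs


def groups_to_frame(groups: list[ProteinGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "sample_id": [g.sample_id for g in groups],
            "representative": [g.representative for g in groups],
            "accessions": [";".join(sorted(g.member_accessions)) for g in groups],
            "peptide_count": [g.peptide_count for g in groups],
        }
    )


def supergroups_to_frame(sgs: list[SuperGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sg_id": [sg.sg_id for sg in sgs],
            "member_group_ids": [";".join(sorted(sg.member_group_ids)) for sg in sgs],
            "union_accessions": [";".join(sorted(sg.union_accessions)) for sg in sgs],
            "peptide_count_max": [sg.peptide_count_max for sg in sgs],
            "present_in_samples": [";".join(sorted(sg.present_in_samples)) for sg in sgs],
        }
    )
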