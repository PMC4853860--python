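"""Evidence ingestion, parsimony grouping, and supergroup assembly."""

import random

import pandas as pd
import pytest

from ptsecretome.errors import ParseError
from ptsecretome.evidence import (
    build_protein_groups,
    build_supergroups,
    read_evidence,
)

from conftest import make_evidence


def write_tsv(path, rows):
    header = "peptide_sequence\tsample_id\tarea\taccessions\tq_value\n"
    path.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))


class TestReadEvidence:
    def test_q_value_and_length_filters(self, tmp_path):
        path = tmp_path / "evidence_S1.tsv"
        write_tsv(
            path,
            [
                ("PEPTIDEK", "S1", 100.0, "P1", 0.001),   # kept
                ("PEPTIDER", "S1", 100.0, "P1", 0.02),    # q-value above 1 %
                ("SHORK", "S1", 100.0, "P1", 0.001),      # 5 residues
            ],
        )
        df, counts = read_evidence(path)
        assert list(df["peptide_sequence"]) == ["PEPTIDEK"]
        assert counts == {
            "ingested": 3, "kept": 1, "dropped_q_value": 1, "dropped_length": 1
        }

    def test_boundary_q_value_kept(self, tmp_path):
        path = tmp_path / "evidence_S1.tsv"
        write_tsv(path, [("PEPTIDEK", "S1", 1.0, "P1;P2", 0.01)])
        df, _ = read_evidence(path)
        assert len(df) == 1
        assert df["accessions"].iloc[0] == frozenset({"P1", "P2"})

    def test_empty_after_header_is_not_an_error(self, tmp_path):
        path = tmp_path / "evidence_S1.tsv"
        write_tsv(path, [])
        df, counts = read_evidence(path)
        assert df.empty and counts["ingested"] == 0

    @pytest.mark.parametrize(
        "row", [("PEPTIDEK", "S1", "not-a-number", "P1", 0.001),
                ("PEPTIDEK", "S1", 100.0, "", 0.001)],
        ids=["non_numeric_area", "empty_accessions"],
    )
    def test_malformed_row_names_line_number(self, tmp_path, row):
        path = tmp_path / "evidence_S1.tsv"
        write_tsv(path, [("OKPEPTIDEK", "S1", 1.0, "P1", 0.001), row])
        with pytest.raises(ParseError, match="line 3"):
            read_evidence(path)


def groups_from(pairs):
    """Build groups from (peptide, accessions) evidence in one sample."""
    rows = [(pep, "S1", 10.0, accs, 0.001) for pep, accs in pairs]
    return build_protein_groups(make_evidence(rows))


class TestParsimonyGrouping:
    def test_identical_evidence_merges(self):
        groups = groups_from([("AAAAAAK", "P1;P2"), ("CCCCCCK", "P1;P2")])
        assert len(groups) == 1
        assert groups[0].member_accessions == {"P1", "P2"}
        assert groups[0].representative == "P1"
        assert groups[0].peptide_count == 2

    def test_subset_absorption(self):
        groups = groups_from(
            [("AAAAAAK", "P1"), ("BBBBBBK", "P1;P2"), ("CCCCCCK", "P1")]
        )
        assert len(groups) == 1
        assert groups[0].member_accessions == {"P1", "P2"}

    def test_disjoint_evidence_stays_separate(self):
        groups = groups_from(
            [("AAAAAAK", "P1"), ("BBBBBBK", "P1"), ("CCCCCCK", "P2"), ("DDDDDDK", "P2")]
        )
        assert len(groups) == 2
        assert {g.representative for g in groups} == {"P1", "P2"}

    def test_shared_peptide_assigned_to_larger_group_once(self):
        # b maps to both; P1's full set is larger, so b goes to P1's group
        groups = groups_from(
            [("AAAAAAK", "P1"), ("BBBBBBK", "P1;P2"), ("CCCCCCK", "P2"),
             ("DDDDDDK", "P1")]
        )
        total = sum(g.peptide_count for g in groups)
        assert total == 4  # no double counting
        by_rep = {g.representative: g for g in groups}
        assert "BBBBBBK" in by_rep["P1"].peptide_set
        assert "BBBBBBK" not in by_rep["P2"].peptide_set

    def test_idempotence_on_random_instances(self):
        rng = random.Random(0)
        for trial in range(20):
            pairs = []
            for i in range(30):
                accs = ";".join(
                    sorted({f"P{rng.randrange(10)}" for _ in range(rng.randint(1, 3))})
                )
                pairs.append((f"PEP{i:03d}K", accs))
            groups = groups_from(pairs)
            # re-derive evidence implied by the groups and regroup
            rederived = [
                (pep, ";".join(sorted(g.member_accessions)))
                for g in groups
                for pep in g.peptide_set
            ]
            regrouped = groups_from(rederived)
            assert {
                (g.member_accessions, g.peptide_set) for g in groups
            } == {(g.member_accessions, g.peptide_set) for g in regrouped}


def brute_force_components(groups):
    """Independent oracle: connected components of the group/accession graph."""
    n = len(groups)
    adj = {
        i: {
            j for j in range(n)
            if j != i and groups[i].member_accessions & groups[j].member_accessions
        }
        for i in range(n)
    }
    seen, components = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.add(k)
            stack.extend(adj[k] - seen)
        components.append(frozenset(groups[j].group_id for j in comp))
    return set(components)


def random_group_table(rng, n_samples=4, n_groups=30):
    rows = []
    for s in range(n_samples):
        for g in range(n_groups // n_samples + 1):
            accs = ";".join(
                sorted({f"P{rng.randrange(15)}" for _ in range(rng.randint(1, 3))})
            )
            rows.append((f"PEP{s}_{g}K", f"S{s}", 10.0, accs, 0.001))
    from ptsecretome.evidence import build_groups_all_samples

    return build_groups_all_samples(make_evidence(rows))


class TestSupergroups:
    def test_shared_accession_chains_groups(self):
        rows = [
            ("AAAAAAK", "S1", 10.0, "P1;P2", 0.001),
            ("BBBBBBK", "S2", 10.0, "P2;P3", 0.001),
        ]
        from ptsecretome.evidence import build_groups_all_samples

        sgs = build_supergroups(build_groups_all_samples(make_evidence(rows)))
        assert len(sgs) == 1
        assert sgs[0].union_accessions == {"P1", "P2", "P3"}
        assert sgs[0].present_in_samples == {"S1", "S2"}

    def test_no_sharing_identity_case(self):
        rows = [
            ("AAAAAAK", "S1", 10.0, "P1", 0.001),
            ("BBBBBBK", "S1", 10.0, "P2", 0.001),
            ("CCCCCCK", "S2", 10.0, "P3", 0.001),
        ]
        from ptsecretome.evidence import build_groups_all_samples

        groups = build_groups_all_samples(make_evidence(rows))
        sgs = build_supergroups(groups)
        assert len(sgs) == len(groups)

    def test_partition_property(self):
        rng = random.Random(1)
        groups = random_group_table(rng)
        sgs = build_supergroups(groups)
        assert sum(len(sg.member_groups) for sg in sgs) == len(groups)
        all_ids = [g.group_id for sg in sgs for g in sg.member_groups]
        assert len(all_ids) == len(set(all_ids))

    def test_order_invariance_and_brute_force_oracle(self):
        rng = random.Random(2)
        for trial in range(5):
            groups = random_group_table(rng)
            reference = {
                frozenset(sg.member_group_ids) for sg in build_supergroups(groups)
            }
            assert reference == brute_force_components(groups)
            for _ in range(5):
                shuffled = groups[:]
                rng.shuffle(shuffled)
                permuted = {
                    frozenset(sg.member_group_ids)
                    for sg in build_supergroups(shuffled)
                }
                assert permuted == reference
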