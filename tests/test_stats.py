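"""Set overlaps, transcriptome correlation, hypergeometric enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ptsecretome.errors import ConfigurationError
from ptsecretome.evidence import build_groups_all_samples, build_supergroups
from ptsecretome.stats import (
    ComparisonFilter,
    correlate_transcriptome,
    filtered_supergroup_set,
    overlap,
    term_enrichment,
)

from conftest import make_evidence


def design_two_types():
    rows = [(f"SIV-PS{i}", "SIV-PS", i) for i in range(1, 5)]
    rows += [(f"PT24-PS{i}", "PT24-PS", i) for i in range(1, 5)]
    return pd.DataFrame(rows, columns=["sample_id", "sample_type", "replicate"])


class TestFilteredSet:
    def build_sgs(self, layout):
        """spec: accession -> (n_peptides, samples)."""
        rows = []
        for acc, (n_pep, samples) in layout.items():
            for s in samples:
                for i in range(n_pep):
                    rows.append((f"{acc}PEP{i:02d}K", s, 10.0, acc, 0.001))
        return build_supergroups(build_groups_all_samples(make_evidence(rows)))

    def test_peptide_and_presence_filters(self):
        sgs = self.build_sgs(
            {
                "P1": (2, ["SIV-PS1", "SIV-PS2"]),     # too few peptides
                "P2": (5, ["SIV-PS3"]),                # 1 of 4 replicates is enough
                "P3": (5, ["PT24-PS1"]),               # wrong sample type
            }
        )
        out = filtered_supergroup_set(sgs, "SIV-PS", design_two_types())
        names = {sg.sg_id for sg in sgs if "P2" in sg.union_accessions}
        assert out == names

    def test_unknown_sample_type_rejected(self):
        sgs = self.build_sgs({"P1": (3, ["SIV-PS1"])})
        with pytest.raises(ConfigurationError, match="unknown sample type"):
            filtered_supergroup_set(sgs, "XX-PS", design_two_types())

    def test_empty_input(self):
        assert filtered_supergroup_set([], "SIV-PS", design_two_types()) == set()

    def test_stricter_filter_is_subset(self):
        sgs = self.build_sgs(
            {f"P{i}": (i % 6 + 1, [f"SIV-PS{1 + i % 4}"]) for i in range(12)}
        )
        loose = filtered_supergroup_set(sgs, "SIV-PS", design_two_types(),
                                        ComparisonFilter(min_peptides=1))
        strict = filtered_supergroup_set(sgs, "SIV-PS", design_two_types(),
                                         ComparisonFilter(min_peptides=4))
        assert strict <= loose


class TestOverlap:
    def test_forced_arithmetic(self):
        r = overlap({"a", "b", "c"}, {"b", "c", "d"})
        assert r.n_intersection == 2 and r.n_union == 4
        assert r.fraction_of_union == pytest.approx(0.5)
        assert r.fraction_of_a == pytest.approx(2 / 3)
        assert r.n_union + r.n_intersection == r.n_a + r.n_b

    def test_identity_and_disjoint(self):
        same = overlap({"a", "b"}, {"a", "b"})
        assert (same.fraction_of_union, same.fraction_of_a, same.fraction_of_b) == (1, 1, 1)
        disjoint = overlap({"a"}, {"b"})
        assert disjoint.n_intersection == 0 and disjoint.fraction_of_union == 0.0

    def test_union_fraction_symmetric(self):
        a, b = {"a", "b", "c", "d"}, {"c", "d", "e"}
        assert overlap(a, b).fraction_of_union == overlap(b, a).fraction_of_union


def rational_upper_tail(k, N, K, n) -> Fraction:
    """Exhaustive-enumeration oracle: P(X >= k) as an exact rational."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return total


class TestEnrichment:
    def test_brute_force_enumeration_example(self):
        # foreground of 2 from a background of 4 where the term covers 2:
        # P(both drawn members carry the term) = 1/C(4,2) = 1/6 for k=2
        bg = {"a", "b", "c", "d"}
        fg = {"a", "b"}
        results = term_enrichment(fg, bg, {"T": {"a", "b"}})
        (r,) = results
        assert r.k_in_set == 2
        assert r.p_value == pytest.approx(float(Fraction(1, 6)), abs=1e-12)

    def test_term_absent_from_foreground_has_p_one(self):
        results = term_enrichment({"a"}, {"a", "b", "c"}, {"T": {"b"}})
        (r,) = results
        assert r.k_in_set == 0 and r.p_value == pytest.approx(1.0)

    def test_term_covering_whole_background_p_one(self):
        bg = {"a", "b", "c", "d"}
        results = term_enrichment({"a", "b"}, bg, {"T": set(bg)})
        assert results[0].p_value == pytest.approx(1.0)

    def test_foreground_must_be_subset(self):
        with pytest.raises(ConfigurationError):
            term_enrichment({"z"}, {"a"}, {})

    def test_monotone_in_k(self):
        N, K, n = 30, 12, 10
        ps = [float(sps.hypergeom.sf(k - 1, N, K, n)) for k in range(0, 11)]
        assert all(p2 <= p1 + 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_matches_rational_oracle_spot_checks(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = float(rational_upper_tail(k, N, K, n))
            assert float(sps.hypergeom.sf(k - 1, N, K, n)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_significance_flag_and_sorting(self):
        bg = {f"x{i}" for i in range(40)} | {"a", "b", "c"}
        fg = {"a", "b", "c"}
        results = term_enrichment(
            fg, bg, {"hit": {"a", "b", "c"}, "flat": set(bg)}, alpha=0.05
        )
        assert results[0].term == "hit" and results[0].significant
        assert not results[-1].significant


class TestCorrelation:
    def test_exact_lines(self):
        x = pd.Series([1.0, 2.0, 4.0, 8.0], index=list("abcd"))
        up = correlate_transcriptome(x, x**2)
        assert up["r"] == pytest.approx(1.0)
        down = correlate_transcriptome(x, 1.0 / x)
        assert down["r"] == pytest.approx(-1.0)

    def test_pairwise_missing_exclusion(self):
        x = pd.Series([1.0, 2.0, 4.0, np.nan], index=list("abcd"))
        y = pd.Series([2.0, 4.0, 8.0, 16.0], index=list("abcd"))
        out = correlate_transcriptome(x, y)
        assert out["n_pairs"] == 3 and out["r"] == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ConfigurationError, match=">=3"):
            correlate_transcriptome(x, x)

    def test_zero_variance_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ConfigurationError, match="undefined"):
            correlate_transcriptome(x, y)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        idx = [f"p{i}" for i in range(50)]
        x = pd.Series(rng.lognormal(0, 1, 50), index=idx)
        y = pd.Series(rng.lognormal(0, 1, 50), index=idx)
        base = correlate_transcriptome(x, y)["r"]
        perm = rng.permutation(idx)
        assert correlate_transcriptome(x[perm], y)["r"] == pytest.approx(base)

    def test_per_cluster_results(self):
        rng = np.random.default_rng(8)
        idx = [f"p{i}" for i in range(60)]
        x = pd.Series(rng.lognormal(0, 1, 60), index=idx)
        y = x ** 1.5
        clusters = pd.Series(["R1"] * 30 + ["R2"] * 30, index=idx)
        out = correlate_transcriptome(x, y, clusters=clusters)
        assert set(out["clusters"]) == {"R1", "R2"}
        assert out["clusters"]["R1"]["r"] == pytest.approx(1.0)
        assert out["clusters"]["R1"]["n_pairs"] == 30
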