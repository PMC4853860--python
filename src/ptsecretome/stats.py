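"""Set comparisons, transcriptome correlation, and term overrepresentation.

Pairwise sample-type comparisons use supergroups filtered by the field-standard
rule — at least three peptides and presence in at least one replicate of
the sample type.  Because "percent overlap" has three natural denominators
(union, set A, set B), all three are reported and none is privileged.

Term overrepresentation uses the upper-tail hypergeometric test
``P(X >= k)`` with population ``N`` (background), ``K`` annotated members,
and a draw of ``n`` (foreground); no multiple-testing correction is applied
by default, with Benjamini-Hochberg available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .evidence import SuperGroup


@dataclass(frozen=True)
class ComparisonFilter:
    min_peptides: int = 3
    min_replicates_present: int = 1


@dataclass(frozen=True)
class OverlapResult:
    set_a_label: str
    set_b_label: str
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    fraction_of_union: float
    fraction_of_a: float
    fraction_of_b: float


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k_in_set: int
    n_set: int
    K_in_background: int
    N_background: int
    p_value: float
    significant: bool


def filtered_supergroup_set(
    supergroups: list[SuperGroup],
    sample_type: str,
    design: pd.DataFrame,
    comparison_filter: ComparisonFilter = ComparisonFilter(),
) -> set[str]:
    """Supergroups eligible for a pairwise comparison of one sample type.

    Keeps supergroups with ``peptide_count_max >= min_peptides`` that are
    present in at least ``min_replicates_present`` replicates of
    ``sample_type`` (per the design table).
    """
    type_samples = set(design.loc[design["sample_type"] == sample_type, "sample_id"])
    if not type_samples:
        raise ConfigurationError(f"unknown sample type {sample_type!r}")
    out = set()
    for sg in supergroups:
        if sg.peptide_count_max < comparison_filter.min_peptides:
            continue
        n_present = len(sg.present_in_samples & type_samples)
        if n_present >= comparison_filter.min_replicates_present:
            out.add(sg.sg_id)
    return out


def overlap(set_a: set, set_b: set, label_a: str = "A", label_b: str = "B") -> OverlapResult:
    inter = set_a & set_b
    union = set_a | set_b
    return OverlapResult(
        set_a_label=label_a,
        set_b_label=label_b,
        n_a=len(set_a),
        n_b=len(set_b),
        n_intersection=len(inter),
        n_union=len(union),
        fraction_of_union=len(inter) / len(union) if union else 0.0,
        fraction_of_a=len(inter) / len(set_a) if set_a else 0.0,
        fraction_of_b=len(inter) / len(set_b) if set_b else 0.0,
    )


def correlate_transcriptome(
    abundance: pd.Series,
    transcript: pd.Series,
    clusters: pd.Series | None = None,
    log_transform: bool = True,
) -> dict:
    """Pearson correlation between protein abundance (ppm) and transcript level.

    Both series are indexed by accession; pairs with a missing or (under
    log transform) nonpositive value on either axis are excluded pairwise.
    The p-value is two-sided from the t distribution with n-2 degrees of
    freedom.  With ``clusters`` given (accession -> cluster label), results
    are additionally reported per cluster.
    """
    df = pd.DataFrame({"a": abundance, "t": transcript}).dropna()
    if log_transform:
        df = df[(df["a"] > 0) & (df["t"] > 0)]
        df = np.log10(df)
    if len(df) < 3:
        raise ConfigurationError(f"need >=3 mapped pairs, found {len(df)}")
    if df["a"].nunique() == 1 or df["t"].nunique() == 1:
        raise ConfigurationError("correlation undefined: zero variance on one axis")
    r, p = sps.pearsonr(df["a"], df["t"])
    out = {"r": float(r), "p_value": float(p), "n_pairs": len(df), "clusters": {}}
    if clusters is not None:
        for label, accs in clusters.groupby(clusters):
            idx = df.index.intersection(accs.index)
            sub = df.loc[idx]
            if len(sub) >= 3 and sub["a"].nunique() > 1 and sub["t"].nunique() > 1:
                cr, cp = sps.pearsonr(sub["a"], sub["t"])
                out["clusters"][str(label)] = {
                    "r": float(cr), "p_value": float(cp), "n_pairs": len(sub)
                }
            else:
                out["clusters"][str(label)] = {
                    "r": float("nan"), "p_value": float("nan"), "n_pairs": len(sub)
                }
    return out


def term_enrichment(
    foreground: set,
    background: set,
    term_members: dict[str, set],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric overrepresentation of terms in the foreground.

    For each term with at least one foreground member, tests
    ``P(X >= k)`` where X is hypergeometric with population
    ``N = |background|``, ``K`` background members carrying the term, and
    draws ``n = |foreground|``.  Significance is ``p < alpha`` on the raw
    p-value, or on the Benjamini-Hochberg adjusted one when
    ``bh_correct`` is set.  Results sorted by p-value then term.
    """
    if not foreground <= background:
        raise ConfigurationError("foreground must be a subset of background")
    N = len(background)
    n = len(foreground)
    results = []
    for term in sorted(term_members):
        members = term_members[term] & background
        K = len(members)
        k = len(members & foreground)
        if K == 0:
            continue
        # upper tail; k = 0 gives P(X >= 0) = 1
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        results.append((term, k, K, p))
    results.sort(key=lambda t: (t[3], t[0]))
    if bh_correct and results:
        m = len(results)
        raw = [p for *_, p in results]
        adj = np.minimum.accumulate(
            [min(1.0, p * m / (i + 1)) for i, p in enumerate(raw)][::-1]
        )[::-1]
        sig = [a < alpha for a in adj]
    else:
        sig = [p < alpha for *_, p in results]
    return [
        EnrichmentResult(term, k, n, K, N, p, bool(s))
        for (term, k, K, p), s in zip(results, sig)
    ]


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "k_in_set": [r.k_in_set for r in results],
            "n_set": [r.n_set for r in results],
            "K_in_background": [r.K_in_background for r in results],
            "N_background": [r.N_background for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
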