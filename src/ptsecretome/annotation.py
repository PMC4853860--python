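"""Secretion-pathway classification and in-house motif scans.

External predictor outputs (signal peptide, SecretomeP-style neural-network
score, transmembrane helices, GPI omega-site, palmitoylation sites,
localization) are consumed as columns of an annotation table — the
predictors themselves are not re-implemented here.  What is computed
in-house: the C-terminal ER-retention motif scan (HDEL/KDEL), the
N-glycosylation sequon count (Asn-Xaa-Ser/Thr, Xaa != Pro), molecular
weight binning, and the GPI-anchor/palmitoylation overlap.

Classification of a called protein:

* conventional — has an N-terminal signal peptide and no C-terminal
  ER-retention motif (an HDEL/KDEL protein is ER-resident, not secreted);
* unconventional — no signal peptide but a secretion neural-network score
  at or above ``nn_threshold`` (default 0.5, the predictor's conventional
  cutoff);
* unclassified — neither rule fires;
* unannotated — no annotation record was supplied (reported, never
  silently dropped).

Residue coordinates are 1-based; the C-terminus is the last residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError

ANNOTATION_COLUMNS = [
    "accession",
    "has_signal_peptide",
    "secretomep_nn_score",
    "tmh_expected_aa",
    "gpi_omega_flag",
    "gpi_fdr",
    "n_palmitoylation_sites",
    "predicted_localization",
    "molecular_weight_kda",
    "family_terms",
    "go_terms",
]

_ER_MOTIFS = ("HDEL", "KDEL")
_SEQUON_RE = re.compile(r"N(?=[^P][ST])")

DEFAULT_NN_THRESHOLD = 0.5
DEFAULT_GPI_FDR_MAX = 0.001  # 0.1 % FDR cutoff for confident GPI-anchor calls
DEFAULT_SIZE_EDGES = (20.0, 50.0)  # kDa


def scan_er_retention(sequence: str) -> bool:
    """True iff the final four residues are exactly HDEL or KDEL."""
    if len(sequence) < 4:
        return False
    return sequence[-4:].upper() in _ER_MOTIFS


def scan_nglyc_sequons(sequence: str) -> tuple[int, list[int]]:
    """Count N-glycosylation sequons N-X-[S/T], X != P, overlapping allowed.

    Returns ``(count, 1-based positions of the Asn)``.
    """
    positions = [m.start() + 1 for m in _SEQUON_RE.finditer(sequence.upper())]
    return len(positions), positions


@dataclass(frozen=True)
class SecretionClass:
    accession: str
    secretion_class: str  # conventional | unconventional | unclassified | unannotated
    evidence: str


def classify_secretion(
    accessions,
    annotations: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    nn_threshold: float = DEFAULT_NN_THRESHOLD,
) -> tuple[list[SecretionClass], dict[str, float]]:
    """Classify each called accession and summarize class percentages.

    ``annotations`` is indexed by (or has a column) ``accession``.
    ``sequences`` supplies protein sequences for the ER-retention scan; an
    accession without a sequence skips the scan (scan treated negative).
    Returns the per-accession records and a summary of percentages over the
    called set (conventional/unconventional/unclassified/unannotated,
    summing to 100 when the set is nonempty).
    """
    ann = annotations
    if "accession" in ann.columns:
        ann = ann.set_index("accession")
    sequences = sequences or {}

    records = []
    for acc in sorted(set(accessions)):
        if acc not in ann.index:
            records.append(SecretionClass(acc, "unannotated", "no annotation record"))
            continue
        row = ann.loc[acc]
        sp = bool(row["has_signal_peptide"])
        nn = row.get("secretomep_nn_score", float("nan"))
        er = scan_er_retention(sequences[acc]) if acc in sequences else False
        if sp and not er:
            records.append(
                SecretionClass(acc, "conventional", "signal peptide, no ER-retention motif")
            )
        elif sp and er:
            records.append(
                SecretionClass(acc, "unclassified", "signal peptide but C-terminal HDEL/KDEL")
            )
        elif pd.notna(nn) and float(nn) >= nn_threshold:
            records.append(
                SecretionClass(acc, "unconventional", f"no SP, NN score {float(nn):.2f}")
            )
        else:
            records.append(SecretionClass(acc, "unclassified", "no SP, NN score below threshold"))

    n = len(records)
    summary = {}
    for cls in ("conventional", "unconventional", "unclassified", "unannotated"):
        k = sum(r.secretion_class == cls for r in records)
        summary[f"pct_{cls}"] = 100.0 * k / n if n else float("nan")
        summary[f"n_{cls}"] = k
    summary["n_total"] = n
    return records, summary


def size_bins(weights_kda, edges=DEFAULT_SIZE_EDGES) -> pd.DataFrame:
    """Bin molecular weights (kDa) into left-closed/right-open size classes.

    Default bins: <20, 20-50, >=50 kDa.  Returns a DataFrame with columns
    ``bin``, ``count``, ``percent`` (percentages sum to 100; empty input
    yields an empty frame).
    """
    weights = list(weights_kda)
    if any(w <= 0 for w in weights):
        raise ConfigurationError("molecular weights must be positive")
    edges = sorted(edges)
    labels = [f"<{edges[0]:g}"]
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"{lo:g}-{hi:g}")
    labels.append(f">={edges[-1]:g}")
    if not weights:
        return pd.DataFrame(columns=["bin", "count", "percent"])
    counts = [0] * len(labels)
    for w in weights:
        i = sum(w >= e for e in edges)  # left-closed: w == edge goes up
        counts[i] += 1
    total = len(weights)
    return pd.DataFrame(
        {"bin": labels, "count": counts, "percent": [100.0 * c / total for c in counts]}
    )


def gap_palmitoyl_overlap(
    annotations: pd.DataFrame, gpi_fdr_max: float = DEFAULT_GPI_FDR_MAX
) -> tuple[float | None, int]:
    """Fraction of confident GPI-anchored proteins also predicted palmitoylated.

    Confident GPI-anchored proteins (GAPs) are those with an omega-site
    call at FDR <= ``gpi_fdr_max``.  Returns ``(fraction, n_gaps)``;
    fraction is None when there are no GAPs (undefined).
    """
    ann = annotations
    if "accession" in ann.columns:
        ann = ann.set_index("accession")
    gaps = ann[
        ann["gpi_omega_flag"].astype(bool)
        & (pd.to_numeric(ann["gpi_fdr"], errors="coerce") <= gpi_fdr_max)
    ]
    if gaps.empty:
        return None, 0
    frac = float((gaps["n_palmitoylation_sites"].astype(int) >= 1).mean())
    return frac, len(gaps)


def read_annotations(path) -> pd.DataFrame:
    """Read the annotation TSV; set/list columns stay semicolon-joined strings."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        from .errors import ParseError

        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    bad = df["gpi_omega_flag"].astype(bool) & df["gpi_fdr"].isna()
    if bad.any():
        from .errors import ParseError

        raise ParseError(f"{path}: gpi_omega_flag set without gpi_fdr for "
                         f"{df.loc[bad, 'accession'].tolist()}")
    return df
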