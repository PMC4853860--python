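"""Ground-truthed synthetic data for the secretome pipeline.

Emulates the structure of a semi-in-vivo pollen tube secretome experiment:
two unpollinated-pistil control samples (C1, C2), four semi-in-vivo
secretome replicates (SIV-PS1..4), four in vitro 24-h secretome replicates
(PT24-PS1..4), and four total-proteome replicates of each (SIV-PP, PT24-PP).
Planted proteins fall into four truth classes:

* ``secreted_conventional`` — signal-peptide proteins secreted into the
  medium; up ``fold_secreted_vs_control``-fold in SIV-PS relative to any
  control signal (absent from controls unless a leak rate is configured);
* ``secreted_unconventional`` — secreted without a signal peptide but with
  a high secretion neural-network score;
* ``pistil_background`` — pistil-derived proteins present at the same
  baseline level in controls and SIV-PS samples;
* ``cytosolic_contaminant`` — low-level cytosolic carry-over present in
  every sample (the semi-in-vivo preparation keeps this small but nonzero).

Peptide areas are multiplicative: true abundance x fixed per-peptide
ionization factor x class-and-sample presence multiplier x lognormal noise
(parameter ``lognormal_sigma``), observations independently dropped at
``detection_dropout_rate`` and removed below ``intensity_floor``.  A fixed
seed makes every output byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

CLASSES = (
    "secreted_conventional",
    "secreted_unconventional",
    "pistil_background",
    "cytosolic_contaminant",
)

#: residues allowed inside a tryptic-like peptide (no internal K/R, no ambiguity codes)
_INTERIOR = "ACDEFGHILMNPQSTVWY"


def default_design() -> list[tuple[str, str, int]]:
    """(sample_id, sample_type, replicate) rows of the standard experiment."""
    rows = [("C1", "control", 1), ("C2", "control", 2)]
    for stype in ("SIV-PS", "PT24-PS", "SIV-PP", "PT24-PP"):
        for rep in range(1, 5):
            rows.append((f"{stype}{rep}", stype, rep))
    return rows


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic run.

    Class counts default to a 500-protein cohort with 60 planted secreted
    proteins; secreted proteins are planted 5-fold above any control-side
    signal, with lognormal noise sigma 0.2 and a 5 % per-observation
    detection dropout.
    """

    n_secreted_conventional: int = 20
    n_secreted_unconventional: int = 40
    n_pistil_background: int = 340
    n_cytosolic_contaminant: int = 100
    design: list[tuple[str, str, int]] = field(default_factory=default_design)
    fold_secreted_vs_control: float = 5.0
    lognormal_sigma: float = 0.2
    detection_dropout_rate: float = 0.05
    intensity_floor: float = 1.0
    control_leak_rate: float = 0.0
    peptide_share_fraction: float = 0.0
    siv_only_fraction: float = 0.5
    contaminant_level: float = 0.05
    mean_extra_peptides: float = 6.0
    n_er_decoys: int = 0
    nn_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.fold_secreted_vs_control <= 1:
            raise ConfigurationError("fold_secreted_vs_control must be > 1")
        if not 0 <= self.detection_dropout_rate <= 1:
            raise ConfigurationError("detection_dropout_rate must be in [0, 1]")
        if self.lognormal_sigma < 0:
            raise ConfigurationError("lognormal_sigma must be >= 0")
        if self.intensity_floor <= 0:
            raise ConfigurationError("intensity_floor must be positive")
        design = pd.DataFrame(self.design, columns=["sample_id", "sample_type", "replicate"])
        if (design["sample_type"] == "control").sum() < 2:
            raise ConfigurationError("design needs >= 2 control samples")
        if (design["sample_type"] == "SIV-PS").sum() < 2:
            raise ConfigurationError("design needs >= 2 SIV-PS samples")

    @property
    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.design, columns=["sample_id", "sample_type", "replicate"])

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["design"] = [list(row) for row in d["design"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "seed" not in d:
            raise ConfigurationError(f"{path}: simulation config must set a seed")
        if "design" in d:
            d["design"] = [tuple(row) for row in d["design"]]
        return cls(**d)


@dataclass
class TruthProtein:
    accession: str
    true_class: str
    true_abundance: float
    peptide_sequences: list[str]
    molecular_weight_kda: float
    family_terms: frozenset[str]
    go_terms: frozenset[str]
    transcript_level: float = float("nan")
    siv_only: bool = False  # secreted only after pistil passage, absent from PT24-PS
    er_decoy: bool = False  # carries a C-terminal KDEL to exercise the ER scan

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_sequences)


_FAMILY_POOLS = {
    "secreted_conventional": ["GH16", "ProtInhibitor_II", "Cu_oxidase", "LRR_1", "Fasciclin"],
    "secreted_unconventional": ["Histone", "RRM_1", "HSP70", "Proteasome"],
    "pistil_background": ["Extensin", "PME", "AGP"],
    "cytosolic_contaminant": ["Ribosomal", "ADH", "Tubulin"],
}
_GO_POOLS = {
    "secreted_conventional": ["GO:0005576", "GO:0006952", "GO:0008810"],
    "secreted_unconventional": ["GO:0005524", "GO:0006457"],
    "pistil_background": ["GO:0005618", "GO:0042545"],
    "cytosolic_contaminant": ["GO:0005737", "GO:0006412"],
}
# molecular-weight lognormal (ln-kDa mean, sigma) and clip range per class
_MW_MODEL = {
    "secreted_conventional": (np.log(28.0), 0.45, 8.4, 105.0),
    "secreted_unconventional": (np.log(30.0), 0.55, 5.4, 138.0),
    "pistil_background": (np.log(38.0), 0.6, 5.0, 250.0),
    "cytosolic_contaminant": (np.log(42.0), 0.6, 10.0, 250.0),
}


def _random_peptide(rng: np.random.Generator, used: set[str]) -> str:
    """Unique tryptic-like peptide: 7-20 residues, ends in K/R."""
    while True:
        length = int(rng.integers(7, 21))
        body = "".join(rng.choice(list(_INTERIOR), size=length - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in used:
            used.add(pep)
            return pep


def generate_truth(config: SimulationConfig) -> list[TruthProtein]:
    """Draw the ground-truth protein cohort for one simulated experiment."""
    rng = np.random.default_rng(config.seed)
    counts = {
        "secreted_conventional": config.n_secreted_conventional,
        "secreted_unconventional": config.n_secreted_unconventional,
        "pistil_background": config.n_pistil_background,
        "cytosolic_contaminant": config.n_cytosolic_contaminant,
    }
    used_peptides: set[str] = set()
    proteins = []
    i = 0
    for cls in CLASSES:
        for j in range(counts[cls]):
            i += 1
            acc = f"NT_{i:06d}"
            abundance = float(np.exp(rng.normal(np.log(1e5), 1.0)))
            n_pep = 1 + int(rng.poisson(config.mean_extra_peptides))
            # planted secreted proteins carry at least the three peptides the
            # decision rule requires, so recovery measures the caller, not an
            # identifiability floor baked into the truth
            if cls.startswith("secreted"):
                n_pep = max(n_pep, 3)
            peptides = [_random_peptide(rng, used_peptides) for _ in range(n_pep)]
            mu, sg, lo, hi = _MW_MODEL[cls]
            mw = float(np.clip(np.exp(rng.normal(mu, sg)), lo, hi))
            fam_pool = _FAMILY_POOLS[cls]
            fams = {fam_pool[int(rng.integers(len(fam_pool)))]} if rng.random() < 0.6 else set()
            go_pool = _GO_POOLS[cls]
            gos = {go_pool[int(rng.integers(len(go_pool)))]}
            secreted = cls.startswith("secreted")
            proteins.append(
                TruthProtein(
                    accession=acc,
                    true_class=cls,
                    true_abundance=abundance,
                    peptide_sequences=peptides,
                    molecular_weight_kda=mw,
                    family_terms=frozenset(fams),
                    go_terms=frozenset(gos),
                    siv_only=secreted and rng.random() < config.siv_only_fraction,
                    er_decoy=False,
                )
            )
    # ER-retained decoys are flagged among the conventional proteins
    conventional = [p for p in proteins if p.true_class == "secreted_conventional"]
    for p in conventional[: config.n_er_decoys]:
        p.er_decoy = True
    return proteins


def peptide_accession_map(
    truth: list[TruthProtein], config: SimulationConfig
) -> dict[str, frozenset[str]]:
    """Peptide -> mapped accessions; a configured fraction map to a second protein.

    Sharing is drawn deterministically from the config seed, independently
    per peptide, so the realized shared fraction concentrates around
    ``peptide_share_fraction``.
    """
    rng = np.random.default_rng(config.seed + 1)
    accs = [p.accession for p in truth]
    mapping: dict[str, frozenset[str]] = {}
    for p in truth:
        for pep in p.peptide_sequences:
            owners = {p.accession}
            if len(accs) > 1 and rng.random() < config.peptide_share_fraction:
                other = p.accession
                while other == p.accession:
                    other = accs[int(rng.integers(len(accs)))]
                owners.add(other)
            mapping[pep] = frozenset(owners)
    return mapping


def _presence_multiplier(
    p: TruthProtein, sample_type: str, config: SimulationConfig, rng: np.random.Generator
) -> float:
    """Class x sample-type abundance multiplier (0 = absent)."""
    secreted = p.true_class.startswith("secreted")
    if sample_type == "control":
        if secreted:
            return 1.0 if rng.random() < config.control_leak_rate else 0.0
        if p.true_class == "pistil_background":
            return 1.0
        return config.contaminant_level
    if sample_type == "SIV-PS":
        if secreted:
            return config.fold_secreted_vs_control
        if p.true_class == "pistil_background":
            return 1.0
        return config.contaminant_level
    if sample_type == "PT24-PS":
        if secreted:
            return 0.0 if p.siv_only else config.fold_secreted_vs_control
        if p.true_class == "pistil_background":
            return 0.0
        return config.contaminant_level
    # total proteomes: pollen tube cellular content, no pistil material
    if secreted:
        return 1.0
    if p.true_class == "pistil_background":
        return 0.0
    return 1.0


def simulate_experiment(
    truth: list[TruthProtein], config: SimulationConfig
) -> pd.DataFrame:
    """Generate the combined peptide-evidence table (one row per observation).

    Columns match the evidence TSV schema: peptide_sequence, sample_id,
    area, accessions (semicolon-joined), q_value.
    """
    if not truth:
        raise ConfigurationError("truth cohort is empty")
    design = config.design_frame
    if design.empty:
        raise ConfigurationError("design is empty")
    rng = np.random.default_rng(config.seed + 2)
    pep_map = peptide_accession_map(truth, config)

    # fixed per-peptide ionization efficiency (flyability), shared across samples
    ion = {
        pep: float(np.exp(rng.normal(0.0, 0.5)))
        for p in truth
        for pep in p.peptide_sequences
    }

    rows = []
    for sample_id, sample_type in zip(design["sample_id"], design["sample_type"]):
        for p in truth:
            mult = _presence_multiplier(p, sample_type, config, rng)
            if mult == 0.0:
                continue
            for pep in p.peptide_sequences:
                if rng.random() < config.detection_dropout_rate:
                    continue
                noise = (
                    float(np.exp(rng.normal(0.0, config.lognormal_sigma)))
                    if config.lognormal_sigma > 0
                    else 1.0
                )
                area = p.true_abundance * ion[pep] * mult * noise
                if area < config.intensity_floor:
                    continue
                rows.append(
                    {
                        "peptide_sequence": pep,
                        "sample_id": sample_id,
                        "area": area,
                        "accessions": ";".join(sorted(pep_map[pep])),
                        "q_value": round(float(rng.uniform(0.0, 0.009)), 6),
                    }
                )
    return pd.DataFrame(
        rows, columns=["peptide_sequence", "sample_id", "area", "accessions", "q_value"]
    )


_SP_PREFIX = "KTNLFLFLIFSLLVLSSA"  # signal-peptide-like hydrophobic stretch


def protein_sequences(truth: list[TruthProtein]) -> dict[str, str]:
    """Full-length synthetic sequences: peptides concatenated, with an
    N-terminal Met, a signal-peptide-like prefix for conventional proteins,
    and a C-terminal KDEL on ER-retained decoys."""
    out = {}
    for p in truth:
        seq = "M"
        if p.true_class == "secreted_conventional":
            seq += _SP_PREFIX
        seq += "".join(p.peptide_sequences)
        if p.er_decoy:
            seq += "KDEL"
        out[p.accession] = seq
    return out


def generate_annotations(truth: list[TruthProtein], config: SimulationConfig) -> pd.DataFrame:
    """Predictor-output table consistent with the planted truth classes.

    Conventional proteins carry a signal peptide; unconventional ones have
    no signal peptide but a neural-network secretion score above the
    threshold; background and contaminants score below it.  A slice of the
    conventional proteins is flagged GPI-anchored at FDR below 0.1 % and
    palmitoylation co-occurs on most of those.
    """
    if not truth:
        raise ConfigurationError("truth cohort is empty")
    rng = np.random.default_rng(config.seed + 3)
    thr = config.nn_threshold
    rows = []
    for p in truth:
        cls = p.true_class
        sp = cls == "secreted_conventional"
        if cls == "secreted_unconventional":
            nn = float(rng.uniform(thr + 0.05, 0.98))
        elif sp:
            nn = float(rng.uniform(0.0, 1.0))  # not used by the classifier
        else:
            nn = float(rng.uniform(0.0, max(thr - 0.05, 0.01)))
        gap = sp and rng.random() < 0.15
        gpi_fdr = float(rng.uniform(0.0, 0.0008)) if gap else float("nan")
        if gap:
            n_palm = int(rng.integers(1, 4)) if rng.random() < 0.6 else 0
        else:
            n_palm = int(rng.poisson(0.1))
        loc = "extracellular" if cls.startswith("secreted") else (
            "cell wall" if cls == "pistil_background" else "cytoplasm"
        )
        tmh = 0.0 if cls.startswith("secreted") else float(rng.exponential(4.0))
        rows.append(
            {
                "accession": p.accession,
                "has_signal_peptide": sp,
                "secretomep_nn_score": round(nn, 4),
                "tmh_expected_aa": round(tmh, 2),
                "gpi_omega_flag": gap,
                "gpi_fdr": gpi_fdr,
                "n_palmitoylation_sites": n_palm,
                "predicted_localization": loc,
                "molecular_weight_kda": round(p.molecular_weight_kda, 2),
                "family_terms": ";".join(sorted(p.family_terms)),
                "go_terms": ";".join(sorted(p.go_terms)),
            }
        )
    return pd.DataFrame(rows)


def generate_transcriptome(
    truth: list[TruthProtein],
    coupling: float,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Transcript levels with a chosen log-scale correlation to abundance.

    Gaussian copula: the population Pearson correlation between log
    transcript level and log true abundance equals ``coupling``.  Replicate
    columns add small measurement noise around the drawn level; the
    ``transcript_level`` column is the noise-free draw.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ConfigurationError("coupling must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    log_ab = np.log(np.array([p.true_abundance for p in truth]))
    z = (log_ab - log_ab.mean()) / (log_ab.std() if log_ab.std() > 0 else 1.0)
    eps = rng.standard_normal(len(truth))
    log_t = np.log(50.0) + 1.0 * (coupling * z + np.sqrt(1.0 - coupling**2) * eps)
    level = np.exp(log_t)
    df = pd.DataFrame(
        {"accession": [p.accession for p in truth], "transcript_level": level}
    )
    for r in range(1, n_replicates + 1):
        df[f"rep_{r}"] = level * np.exp(rng.normal(0.0, 0.05, size=len(truth)))
    for p, lvl in zip(truth, level):
        p.transcript_level = float(lvl)
    return df


def truth_to_frame(truth: list[TruthProtein]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [p.accession for p in truth],
            "true_class": [p.true_class for p in truth],
            "true_abundance": [p.true_abundance for p in truth],
            "n_peptides": [p.n_peptides for p in truth],
            "molecular_weight_kda": [p.molecular_weight_kda for p in truth],
            "siv_only": [p.siv_only for p in truth],
            "er_decoy": [p.er_decoy for p in truth],
            "transcript_level": [p.transcript_level for p in truth],
        }
    )


def write_dataset(outdir, config: SimulationConfig, coupling: float = 0.4) -> dict[str, str]:
    """Write the full synthetic dataset to ``outdir``; returns a manifest
    of file paths -> SHA-256 checksums."""
    import hashlib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    evidence = simulate_experiment(truth, config)
    transcript = generate_transcriptome(truth, coupling, seed=config.seed + 4)
    annotations = generate_annotations(truth, config)
    seqs = protein_sequences(truth)

    paths = []
    for sample_id, sub in evidence.groupby("sample_id", sort=True):
        path = outdir / f"evidence_{sample_id}.tsv"
        sub.to_csv(path, sep="\t", index=False, float_format="%.6f")
        paths.append(path)
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    transcript.to_csv(outdir / "transcriptome.tsv", sep="\t", index=False, float_format="%.6f")
    truth_to_frame(truth).to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.6f")
    config.design_frame.to_csv(outdir / "design.tsv", sep="\t", index=False)
    paths += [
        outdir / "annotations.tsv",
        outdir / "transcriptome.tsv",
        outdir / "truth.tsv",
        outdir / "design.tsv",
    ]

    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(seqs[p.accession]), id=p.accession, description=p.true_class)
        for p in truth
    ]
    fasta_path = outdir / "proteins.fasta"
    SeqIO.write(records, fasta_path, "fasta")
    paths.append(fasta_path)

    config.to_yaml(outdir / "config.yaml")
    paths.append(outdir / "config.yaml")

    manifest = {
        str(path.name): hashlib.sha256(path.read_bytes()).hexdigest() for path in paths
    }
    return manifest
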