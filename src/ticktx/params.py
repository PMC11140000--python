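"""Pipeline-wide thresholds and tuning parameters.

All thresholds used by the extraction/quantification/DE stages live in one
immutable-ish dataclass so that a run is fully described by a single small
configuration file (plain ``key: value`` text, YAML-compatible).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class PipelineParams:
    """Thresholds governing every stage of the pipeline.

    Attributes
    ----------
    min_orf_nt:
        Minimum open-reading-frame length (nucleotides) for the
        homology-evidence route.
    min_coverage_fraction:
        Minimum fraction of a matching database protein that the local
        alignment must cover for a CDS to be accepted by homology.
    min_signal_orf_aa:
        Minimum protein length (amino acids) of a Met-initiated ORF
        submitted to the signal-peptide predictor.
    cluster_identity:
        Nucleotide identity at or above which near-identical CDS are
        consolidated into one representative.
    min_tpm:
        Expression filter: a CDS is kept when its TPM reaches this value in
        every replicate of at least one (stage, feeding-group) cell.
    lfc_threshold:
        Absolute log2 fold-change at or above which a contrast is called
        significant (jointly with the FDR threshold).
    fdr_threshold:
        Benjamini-Hochberg FDR below which a contrast is called significant.
    contaminant_taxa:
        Taxon tags whose best hits mark a CDS as a potential contaminant.
    contaminant_margin_bits:
        A CDS with a contaminant best hit is rescued when a non-contaminant
        hit scores within this margin of the best score.
    homology_score_min:
        Raw local-alignment score floor below which a pairwise comparison
        yields no hit.
    rng_seed:
        Seed for any stochastic step (none in the core pipeline; kept here
        so a config file fully determines a run).
    """

    min_orf_nt: int = 100
    min_coverage_fraction: float = 0.70
    min_signal_orf_aa: int = 40
    cluster_identity: float = 0.95
    min_tpm: float = 5.0
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    contaminant_taxa: frozenset = field(
        default_factory=lambda: frozenset({"vertebrate", "bacteria"})
    )
    contaminant_margin_bits: float = 10.0
    homology_score_min: float = 50.0
    gap_open: int = 11
    gap_extend: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_orf_nt <= 0:
            raise ValueError("min_orf_nt must be positive")
        if not (0.0 < self.min_coverage_fraction <= 1.0):
            raise ValueError("min_coverage_fraction must be in (0, 1]")
        if self.min_signal_orf_aa <= 0:
            raise ValueError("min_signal_orf_aa must be positive")
        if not (0.0 < self.cluster_identity <= 1.0):
            raise ValueError("cluster_identity must be in (0, 1]")
        for name in ("min_tpm", "lfc_threshold", "fdr_threshold",
                     "homology_score_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.contaminant_taxa, (list, set, tuple)):
            self.contaminant_taxa = frozenset(self.contaminant_taxa)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, frozenset):
                value = ", ".join(sorted(value))
                lines.append(f"{key}: [{value}]")
            else:
                lines.append(f"{key}: {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineParams":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a key-value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown parameter(s): {sorted(unknown)}")
        return cls(**raw)
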