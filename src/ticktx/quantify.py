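"""TPM computation and the replicate-consistent expression filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """CDS x library counts with lengths and a TPM layer."""

    counts: pd.DataFrame  # integer counts
    lengths: pd.Series  # nt per CDS, aligned to counts.index
    tpm: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.tpm.index):
            raise ValueError("counts/tpm row mismatch")
        if list(self.counts.columns) != list(self.tpm.columns):
            raise ValueError("counts/tpm column mismatch")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionMatrix:
    """Transcripts-per-million per library.

    rate_i = count_i / length_i(kb); tpm_i = rate_i / sum_j rate_j * 1e6.
    Each library's TPM column sums to 1e6 (all-zero libraries stay zero and
    are logged).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero_libs = totals.index[totals == 0].tolist()
    if zero_libs:
        logger.warning("all-zero libraries: %s", zero_libs)
    safe_totals = totals.replace(0, 1.0)
    tpm = rate.div(safe_totals, axis=1) * 1e6
    return ExpressionMatrix(counts=counts, lengths=lengths, tpm=tpm)


def filter_expressed(matrix: ExpressionMatrix, design, min_tpm: float = 5.0) -> list:
    """Ids of CDS with TPM >= ``min_tpm`` in every replicate of at least one
    (stage, group) cell. The comparison is inclusive."""
    keep = pd.Series(False, index=matrix.tpm.index)
    for stage in design.stages:
        for group in design.groups:
            libs = design.cell(stage, group)
            keep |= (matrix.tpm[libs] >= min_tpm).all(axis=1)
    kept = matrix.tpm.index[keep].tolist()
    logger.info("expression filter (TPM >= %g): kept %d / %d CDS",
                min_tpm, len(kept), len(keep))
    return kept
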