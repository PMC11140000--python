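"""Rule-based signal-peptide prediction.

A deliberately transparent stand-in for a trained predictor, modelling the
canonical tripartite architecture of secretory signal peptides:

* n-region — at least one basic residue (K/R) within residues 2-6;
* h-region — a hydrophobic core: some window of 7 consecutive residues
  inside positions 6-25 with mean Kyte-Doolittle hydropathy > 1.6;
* c-region — a small-residue cleavage context: the earliest position p in
  [12, 40] whose residues at p-3 and p-1 are in {A, G, S, C, T, V}
  (the "(-3, -1) rule"); cleavage occurs before residue p, i.e. the mature
  protein starts at 1-based position p.

Positions above are 1-based, matching the signal-peptide literature. An
external prediction table can replace this heuristic throughout the
pipeline (see :mod:`ticktx.extract`).
"""

from __future__ import annotations

from dataclasses import dataclass

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

SMALL_RESIDUES = frozenset("AGSCTV")
H_WINDOW = 7
H_REGION_SPAN = (6, 25)  # 1-based inclusive positions eligible for the core
H_MEAN_MIN = 1.6
C_RANGE = (12, 40)  # 1-based inclusive range for the cleavage position


@dataclass(frozen=True)
class SignalCall:
    is_positive: bool
    cleavage_index: int | None = None  # 1-based first residue of the mature protein
    score: float = 0.0

    def __post_init__(self):
        if self.is_positive != (self.cleavage_index is not None):
            raise ValueError("cleavage_index must be present iff positive")


NEGATIVE = SignalCall(False, None, 0.0)


def predict_signal_peptide(protein: str) -> SignalCall:
    """Classify an N-terminal sequence; negative unless it starts with M."""
    protein = protein.upper()
    if not protein.startswith("M"):
        return NEGATIVE
    # n-region
    if not any(a in "KR" for a in protein[1:6]):
        return NEGATIVE
    # h-region: best 7-residue mean hydropathy inside positions 6..25
    lo, hi = H_REGION_SPAN
    region = protein[lo - 1:hi]
    best = None
    for i in range(len(region) - H_WINDOW + 1):
        window = region[i:i + H_WINDOW]
        mean = sum(KYTE_DOOLITTLE.get(a, 0.0) for a in window) / H_WINDOW
        if best is None or mean > best:
            best = mean
    if best is None or best <= H_MEAN_MIN:
        return NEGATIVE
    # c-region: earliest (-3, -1) small-residue context
    for p in range(C_RANGE[0], min(C_RANGE[1], len(protein)) + 1):
        if protein[p - 4] in SMALL_RESIDUES and protein[p - 2] in SMALL_RESIDUES:
            return SignalCall(True, p, best)
    return NEGATIVE
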