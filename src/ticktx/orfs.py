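"""Six-frame open-reading-frame enumeration.

ORFs are stop-to-stop stretches of translatable codons; sequence ends count
as boundaries and a codon containing an ambiguous base (anything outside
A/C/G/T) breaks the frame rather than translating to X, so ambiguous runs
cannot bridge two unrelated ORFs. When an ORF is terminated by a stop codon
its interval includes that stop codon (so a minimal ``ATG...stop`` gene of
k coded residues spans 3k + 3 nucleotides); the protein never includes the
stop. All intervals are 0-based, half-open, on the transcript's forward
strand; minus-strand ORFs carry forward-strand coordinates plus a strand
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Orf:
    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2, offset on the reading strand
    start: int  # forward-strand, 0-based
    end: int  # forward-strand, half-open
    protein: str
    met_positions: list = field(default_factory=list)
    stop_bounded: bool = False  # True when a 3' stop codon is included
    transcript_length: int = 0

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}|{self.strand}{self.frame}|{self.start}"

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    def aa_interval_forward(self, aa_start: int, aa_end: int,
                            to_orf_end: bool = False) -> tuple:
        """Forward-strand nt interval of protein residues [aa_start, aa_end).

        With ``to_orf_end`` the 3' boundary is the ORF end (through the stop
        codon when present) instead of the last residue of ``aa_end``.
        """
        if not (0 <= aa_start <= aa_end <= len(self.protein)):
            raise ValueError("aa interval out of bounds")
        # on-strand coordinates relative to the ORF 5' boundary
        on_start = 3 * aa_start
        on_end = self.nt_length if to_orf_end else 3 * aa_end
        if self.strand == "+":
            return self.start + on_start, self.start + on_end
        return self.end - on_end, self.end - on_start


def find_orfs(transcript_id: str, seq: str, min_len_nt: int = 100) -> list:
    """Enumerate ORFs of at least ``min_len_nt`` nucleotides in all six frames."""
    seq = seq.upper()
    L = len(seq)
    orfs = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            seg_start = None
            protein = []

            def close(end_on_strand: int, stop_bounded: bool) -> None:
                nonlocal seg_start, protein
                if seg_start is not None and protein:
                    length = end_on_strand - seg_start
                    if length >= min_len_nt:
                        if strand == "+":
                            start, end = seg_start, end_on_strand
                        else:
                            start, end = L - end_on_strand, L - seg_start
                        prot = "".join(protein)
                        orfs.append(
                            Orf(
                                transcript_id,
                                strand,
                                frame,
                                start,
                                end,
                                prot,
                                [i for i, a in enumerate(prot) if a == "M"],
                                stop_bounded,
                                L,
                            )
                        )
                seg_start = None
                protein = []

            pos = frame
            while pos + 3 <= L:
                codon = s[pos:pos + 3]
                if not _ACGT.issuperset(codon):
                    close(pos, False)
                elif codon in STOP_CODONS:
                    close(pos + 3, True)
                else:
                    if seg_start is None:
                        seg_start = pos
                    protein.append(CODON_TO_AA[codon])
                pos += 3
            close(pos, False)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs
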