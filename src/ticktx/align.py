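"""Local protein alignment and proteome-wide homology search.

Alignment is optimal affine-gap local alignment (BLOSUM62, gap open 11,
gap extend 1 in the BLAST convention: a gap of length k costs open + k *
extend). Optimal scores are computed for every (query, subject) pair with a
compiled Gotoh kernel; the full traceback (spans, identity) is recovered
with Biopython's :class:`PairwiseAligner` only for pairs reaching the score
floor, which keeps an all-versus-all search tractable without heuristic
seeding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from numba import njit
from Bio.Align import PairwiseAligner, substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}
_MATRIX = np.asarray(_BLOSUM62, dtype=np.int64)
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_NEG_INF = np.int64(-(10 ** 9))


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    subject_description: str
    subject_length: int
    subject_span: tuple  # 0-based half-open on the subject
    query_span: tuple  # 0-based half-open on the query
    score: float
    identity_fraction: float
    db_rank: int
    taxon_tag: str

    @property
    def subject_coverage(self) -> float:
        return (self.subject_span[1] - self.subject_span[0]) / self.subject_length


def _encode(protein: str, label: str) -> np.ndarray:
    if not protein:
        raise ValueError(f"{label}: empty protein sequence")
    bad = set(protein) - VALID_RESIDUES
    if bad:
        raise ValueError(f"{label}: unknown residue(s) {sorted(bad)}")
    return np.array([_AA_INDEX[a] for a in protein], dtype=np.int64)


@njit(cache=True)
def _gotoh_local_score(q, s, matrix, open_cost, extend_cost):
    """Optimal local alignment score, affine gaps (Gotoh, linear memory)."""
    n, m = len(q), len(s)
    H = np.zeros(m + 1, dtype=np.int32)
    E = np.full(m + 1, np.int32(-(10 ** 8)), dtype=np.int32)
    best = np.int32(0)
    go = np.int32(open_cost)
    ge = np.int32(extend_cost)
    for i in range(n):
        row = matrix[q[i]]
        diag = np.int32(0)  # H[i-1][0]
        prev = np.int32(0)  # H[i][j-1]
        F = np.int32(-(10 ** 8))
        for j in range(m):
            e = E[j + 1] - ge
            eo = H[j + 1] - go
            if eo > e:
                e = eo
            E[j + 1] = e
            F -= ge
            fo = prev - go
            if fo > F:
                F = fo
            h = diag + row[s[j]]
            if e > h:
                h = e
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j + 1]
            H[j + 1] = h
            prev = h
            if h > best:
                best = h
    return int(best)


def local_score(query: str, subject: str,
                gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal local-alignment score of two proteins (BLOSUM62)."""
    q = _encode(query, "query")
    s = _encode(subject, "subject")
    return float(_gotoh_local_score(q, s, _MATRIX,
                                    np.int64(gap_open + gap_extend),
                                    np.int64(gap_extend)))


def _make_aligner(gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    # Biopython charges open_gap_score for the first gapped position
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_local(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    score_min: float = 50.0,
    gap_open: int = 11,
    gap_extend: int = 1,
    subject_description: str = "",
    db_rank: int = 1,
    taxon_tag: str = "",
) -> HomologyHit | None:
    """Best local alignment of ``query`` against ``subject``.

    Returns ``None`` when the optimal score is below ``score_min``.
    Identity is counted over all alignment columns (gap columns count
    against identity).
    """
    score = local_score(query, subject, gap_open, gap_extend)
    if score < score_min:
        return None
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(query, subject)[0]
    blocks = alignment.aligned
    qspan = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
    sspan = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
    identities = 0
    columns = 0
    q_blocks, s_blocks = blocks
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q is not None:
            columns += (qs - prev_q) + (ss - prev_s)  # gap columns
        for a, b in zip(query[qs:qe], subject[ss:se]):
            identities += a == b
        columns += qe - qs
        prev_q, prev_s = qe, se
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        subject_description=subject_description,
        subject_length=len(subject),
        subject_span=sspan,
        query_span=qspan,
        score=float(alignment.score),
        identity_fraction=identities / columns if columns else 0.0,
        db_rank=db_rank,
        taxon_tag=taxon_tag,
    )


_TAG_RE = re.compile(r"(taxon|db)=([^|\s]+)")


def parse_description_tags(description: str) -> tuple:
    """Extract ``(taxon, db_rank)`` from a ``taxon=<tag>|db=<rank>`` suffix."""
    tags = dict(_TAG_RE.findall(description))
    taxon = tags.get("taxon", "unknown")
    try:
        db_rank = int(tags.get("db", 99))
    except ValueError:
        db_rank = 99
    return taxon, db_rank


def search_all(
    queries: Mapping[str, str] | Iterable,
    proteome,
    score_min: float = 50.0,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> dict:
    """All-versus-all local alignment of query proteins against a proteome.

    ``proteome`` is an iterable of FASTA entries whose descriptions carry
    ``taxon=<tag>|db=<rank>`` annotations. Hits per query are sorted by
    (score desc, db_rank asc, subject_length desc, subject_id asc), a total
    order, so ranking is deterministic.
    """
    if hasattr(queries, "items"):
        query_items = list(queries.items())
    else:
        query_items = [(e.id, e.seq) for e in queries]
    subjects = []
    for entry in proteome:
        taxon, db_rank = parse_description_tags(entry.description)
        subjects.append(
            (entry.id, entry.seq, entry.description, taxon, db_rank,
             _encode(entry.seq, entry.id))
        )
    open_cost = np.int64(gap_open + gap_extend)
    extend_cost = np.int64(gap_extend)
    results = {}
    for query_id, query in query_items:
        q_enc = _encode(query, query_id)
        hits = []
        for subject_id, subject, desc, taxon, db_rank, s_enc in subjects:
            score = _gotoh_local_score(q_enc, s_enc, _MATRIX, open_cost, extend_cost)
            if score < score_min:
                continue
            hit = align_local(
                query_id, query, subject_id, subject,
                score_min=score_min, gap_open=gap_open, gap_extend=gap_extend,
                subject_description=desc, db_rank=db_rank, taxon_tag=taxon,
            )
            if hit is not None:
                hits.append(hit)
        hits.sort(key=lambda h: (-h.score, h.db_rank, -h.subject_length, h.subject_id))
        results[query_id] = hits
    return results
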