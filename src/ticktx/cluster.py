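"""Greedy incremental consolidation of near-identical CDS.

Sequences are sorted by (length desc, id asc) and each joins the first
existing cluster whose representative it matches at or above the identity
threshold, else founds a new cluster — the classic greedy-incremental
scheme of redundancy-removal tools. Identity is computed from a semi-global
alignment of the shorter sequence within the longer (edlib, infix mode):
matching columns over all alignment columns of the shorter sequence's
aligned extent, so fragments of a longer CDS are absorbed by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd


@dataclass
class Cluster:
    representative_id: str
    member_ids: list = field(default_factory=list)
    identities: dict = field(default_factory=dict)


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned within the longer."""
    if not a or not b:
        raise ValueError("empty sequence")
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(query, target, mode="HW", task="path")
    dist = res["editDistance"]
    columns = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            columns += int(num)
            num = ""
    # columns counts M, I and D ops; matches = columns - (mismatches + indels)
    return (columns - dist) / columns if columns else 0.0


def cluster_greedy(sequences: dict, cluster_identity: float = 0.95) -> list:
    """Cluster ``{id: nucleotide sequence}`` at ``cluster_identity``.

    First-fit assignment in founding order; deterministic and invariant to
    the input dict's ordering because candidates are sorted first.
    """
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    clusters = []
    for seq_id in order:
        seq = sequences[seq_id]
        placed = False
        for cluster in clusters:
            ident = pairwise_identity(seq, sequences[cluster.representative_id])
            if ident >= cluster_identity:
                cluster.member_ids.append(seq_id)
                cluster.identities[seq_id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(seq_id, [seq_id], {seq_id: 1.0}))
    return clusters


def clusters_to_frame(clusters) -> pd.DataFrame:
    rows = [
        (c.representative_id, m, c.identities[m])
        for c in clusters
        for m in c.member_ids
    ]
    return pd.DataFrame(rows, columns=["representative_id", "member_id", "identity"])


def representatives(clusters) -> list:
    return [c.representative_id for c in clusters]
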