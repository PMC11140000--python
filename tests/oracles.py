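"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a different route than the package
(brute force, naive dynamic programming, simulation, closed form) so that
agreement is evidence of correctness rather than of shared code.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BLOSUM62 = None  # loaded lazily in dp_local_score


def sixframe_orfs_bruteforce(seq: str, min_len_nt: int):
    """All stop-to-stop ORFs in six frames via full-frame translation.

    Returns a set of (strand, start, end, protein) with forward-strand
    0-based half-open intervals; intervals include a terminating stop codon.
    Codons containing non-ACGT characters break segments (as would an 'X'
    in the translation).
    """
    results = set()
    L = len(seq)
    for strand in "+-":
        s = seq.upper() if strand == "+" else str(Seq(seq.upper()).reverse_complement())
        for frame in range(3):
            ncod = (L - frame) // 3
            codons = [s[frame + 3 * i: frame + 3 * i + 3] for i in range(ncod)]
            aas = []
            for c in codons:
                if any(ch not in "ACGT" for ch in c):
                    aas.append("X")
                else:
                    aas.append(str(Seq(c).translate()))
            i = 0
            while i < ncod:
                if aas[i] in "*X":
                    i += 1
                    continue
                j = i
                while j < ncod and aas[j] not in "*X":
                    j += 1
                # segment of coding codons i..j-1; stop at j included if '*'
                end_cod = j + 1 if j < ncod and aas[j] == "*" else j
                start_nt = frame + 3 * i
                end_nt = frame + 3 * end_cod
                if end_nt - start_nt >= min_len_nt:
                    protein = "".join(aas[i:j])
                    if strand == "+":
                        interval = (start_nt, end_nt)
                    else:
                        interval = (L - end_nt, L - start_nt)
                    results.add((strand, interval[0], interval[1], protein))
                i = j + 1
    return results


def dp_local_score(a: str, b: str, gap_open_total: int = 12,
                   gap_extend: int = 1) -> int:
    """Naive full-matrix affine-gap local alignment (three explicit DP
    tables, no rolling arrays); first gap position costs ``gap_open_total``."""
    global BLOSUM62
    if BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        BLOSUM62 = {(x, y): int(m[x, y]) for x in m.alphabet for y in m.alphabet}
    n, m_len = len(a), len(b)
    NEG = -10 ** 9
    H = [[0] * (m_len + 1) for _ in range(n + 1)]
    E = [[NEG] * (m_len + 1) for _ in range(n + 1)]
    F = [[NEG] * (m_len + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m_len + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open_total)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open_total)
            H[i][j] = max(0,
                          H[i - 1][j - 1] + BLOSUM62[(a[i - 1], b[j - 1])],
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def bh_stepup_by_hand(pvals):
    """Benjamini-Hochberg step-up computed literally from its definition."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = min(1.0, running_min)
    return q


def mc_conditional_p(a: int, b: int, n_a: int, n_b: int, phi: float,
                     n_draws: int = 100_000, seed: int = 0):
    """Monte-Carlo oracle for the exact conditional NB test.

    Draws group-sum pairs from the same NB laws, conditions on the observed
    total, and estimates P(pmf(X) <= pmf(a)). Returns (p_estimate, se).
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    total = a + b
    mu = total / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    p_a = r_a / (r_a + n_a * mu)
    p_b = r_b / (r_b + n_b * mu)
    x = rng.negative_binomial(r_a, p_a, size=n_draws)
    y = rng.negative_binomial(r_b, p_b, size=n_draws)
    keep = (x + y) == total
    x = x[keep]
    if x.size == 0:
        return float("nan"), float("nan")
    logpmf = (stats.nbinom.logpmf(x, r_a, p_a)
              + stats.nbinom.logpmf(total - x, r_b, p_b))
    obs = (stats.nbinom.logpmf(a, r_a, p_a)
           + stats.nbinom.logpmf(b, r_b, p_b))
    hits = logpmf <= obs + 1e-9
    p_hat = hits.mean()
    se = float(np.sqrt(p_hat * (1 - p_hat) / hits.size))
    return float(p_hat), se
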