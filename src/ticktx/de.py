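"""Exact-test differential expression between feeding groups.

The test is the classic exact conditional test for two groups of
negative-binomial counts: per CDS, counts are scaled to a common effective
library size, summed within each group, and the two group sums — NB with
means ``n_A * mu`` / ``n_B * mu`` and dispersions ``phi / n_A`` /
``phi / n_B`` — are compared conditionally on their total, summing the
probabilities of all outcomes no more likely than the observed one (the
two-sided exact construction). With ``phi = 0`` the conditional law is
exactly Binomial(T, n_A / (n_A + n_B)).

Normalization is a trimmed-mean-of-log-ratios (TMM-style) factor per
library; dispersion is a single common value estimated by the method of
moments within replicate cells. Both are deliberate simplifications of the
moderated machinery of full GLM packages: they keep the pipeline exact,
dependency-light and deterministic at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Pairwise contrasts computed within each developmental stage, in the
#: temporal order of the feeding groups (plus the endpoints comparison).
DEFAULT_CONTRASTS = (
    ("UF", "FED6h"),
    ("FED6h", "FED12h"),
    ("FED12h", "FED24h"),
    ("FED24h", "FED5d"),
    ("UF", "FED5d"),
)

LOG2FC_PRIOR = 0.125  # pseudo-count keeping fold changes finite at zero


@dataclass(frozen=True)
class DEResult:
    cds_id: str
    stage: str
    group_a: str
    group_b: str
    log2fc: float  # B over A
    p_value: float
    q_value: float = np.nan
    significant: bool = False
    direction: str = "ns"  # 'up' | 'down' | 'ns'

    @property
    def contrast(self) -> str:
        return f"{self.stage}:{self.group_a}-vs-{self.group_b}"


def norm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                 trim_a: float = 0.05) -> pd.Series:
    """TMM-style total scaling factors, rescaled to geometric mean 1.

    The reference is the library whose depth is closest to the median depth
    (ties: first in column order). Per library, CDS with a zero in either
    library are dropped, the ``trim_m`` tails of the log-ratios and the
    ``trim_a`` tails of the mean log-abundance are trimmed, and the
    composition factor is the precision-weighted mean of the remaining
    (proportion-scale) log-ratios. The returned factor is the library's
    relative effective size — depth times composition factor — so a library
    with exactly doubled counts gets twice the factor of its twin, and
    scaling counts by ``1 / factor`` absorbs the depth difference.
    """
    depths = counts.sum(axis=0)
    if (depths == 0).any():
        bad = depths.index[depths == 0].tolist()
        raise ValueError(f"all-zero libraries: {bad}")
    median_depth = depths.median()
    ref_lib = (depths - median_depth).abs().idxmin()
    ref = counts[ref_lib].to_numpy(dtype=float)
    n_ref = depths[ref_lib]
    log_factors = {}
    for lib in counts.columns:
        if lib == ref_lib:
            log_factors[lib] = 0.0
            continue
        obs = counts[lib].to_numpy(dtype=float)
        n_obs = depths[lib]
        mask = (obs > 0) & (ref > 0)
        if not mask.any():
            raise ValueError(f"no CDS shared between {lib} and reference")
        p_obs = obs[mask] / n_obs
        p_ref = ref[mask] / n_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        w = 1.0 / ((n_obs - obs[mask]) / (n_obs * obs[mask])
                   + (n_ref - ref[mask]) / (n_ref * ref[mask]))
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        log_factors[lib] = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    f = pd.Series({lib: 2.0 ** lf for lib, lf in log_factors.items()})
    f = f[counts.columns] * depths  # relative effective size
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    return f


def effective_sizes(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.Series:
    """Effective library sizes on the scale of the observed depths."""
    if factors is None:
        factors = norm_factors(counts)
    depths = counts.sum(axis=0)
    return factors * float(np.exp(np.log(depths).mean()))


def estimate_dispersion(counts: pd.DataFrame, design,
                        factors: pd.Series | None = None,
                        min_mean: float = 5.0) -> float:
    """Common NB dispersion by the method of moments.

    Per CDS, ``phi_g = sum_c (s2_c - mu_c) / sum_c mu_c^2`` over the
    replicate cells (on counts normalized to the common effective library
    size); the common dispersion is the median of ``phi_g`` over CDS whose
    overall normalized mean exceeds ``min_mean``, floored at 0.

    Because the within-cell variances carry only ``df = sum_c (n_c - 1)``
    degrees of freedom, the median of the raw moment estimates is biased
    low (the median of a chi-square_df variate is below its mean). Each
    per-CDS estimate is therefore rescaled by ``q = median(chi2_df) / df``
    — ``phi_g / q + (1 - q) / (q * mu_g)`` — before the median is taken,
    which restores the estimator's calibration at few replicates and
    vanishes as df grows.
    """
    eff = effective_sizes(counts, factors)
    common = float(np.exp(np.log(eff).mean()))
    norm = counts * (common / eff)
    num = np.zeros(len(counts.index))
    den = np.zeros(len(counts.index))
    df = 0
    for stage in design.stages:
        for group in design.groups:
            libs = design.cell(stage, group)
            if len(libs) < 2:
                continue
            cell = norm[libs]
            mu = cell.mean(axis=1).to_numpy()
            s2 = cell.var(axis=1, ddof=1).to_numpy()
            num += s2 - mu
            den += mu ** 2
            df += len(libs) - 1
    if df == 0 or not (den > 0).any():
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_g = np.where(den > 0, num / den, 0.0)
    q = stats.chi2.ppf(0.5, df) / df
    overall = norm.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(overall > 0,
                             phi_g / q + (1 - q) / (q * overall), 0.0)
    eligible = corrected[overall > min_mean]
    if eligible.size == 0:
        return 0.0
    return float(max(0.0, np.median(eligible)))


def _conditional_p(a: int, b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional p-value for group sums ``a`` and ``b``."""
    total = a + b
    if total == 0:
        return 1.0
    x = np.arange(total + 1)
    if phi <= 0:
        # Poisson limit: conditional on the total, x is exactly binomial
        logp = stats.binom.logpmf(x, total, n_a / (n_a + n_b))
    else:
        mu = total / (n_a + n_b)
        # sum of n iid NB(mu, phi) is NB(mean n*mu, dispersion phi/n),
        # i.e. scipy size r = n/phi with the same success probability
        r_a, r_b = n_a / phi, n_b / phi
        logp = (stats.nbinom.logpmf(x, r_a, r_a / (r_a + n_a * mu))
                + stats.nbinom.logpmf(total - x, r_b, r_b / (r_b + n_b * mu)))
    prob = np.exp(logp - logp.max())
    obs = prob[a]
    p = prob[prob <= obs * (1 + 1e-12)].sum() / prob.sum()
    return float(min(1.0, p))


def exact_nb_test(counts_a, counts_b, phi: float,
                  eff_a=None, eff_b=None) -> tuple:
    """Exact conditional NB test of two count groups.

    ``counts_a`` / ``counts_b`` are per-library counts for one CDS;
    ``eff_a`` / ``eff_b`` the matching effective library sizes (defaults:
    equal sizes). Returns ``(log2fc, p_value)`` with the fold change of B
    over A computed from normalized group means with a prior count of
    0.125.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = len(counts_a), len(counts_b)
    if eff_a is None:
        eff_a = np.ones(n_a)
    if eff_b is None:
        eff_b = np.ones(n_b)
    eff_a = np.asarray(eff_a, dtype=float)
    eff_b = np.asarray(eff_b, dtype=float)
    common = np.exp(np.mean(np.log(np.concatenate([eff_a, eff_b]))))
    scaled_a = counts_a * (common / eff_a)
    scaled_b = counts_b * (common / eff_b)
    a = int(round(scaled_a.sum()))
    b = int(round(scaled_b.sum()))
    log2fc = float(np.log2((scaled_b.mean() + LOG2FC_PRIOR)
                           / (scaled_a.mean() + LOG2FC_PRIOR)))
    if a + b == 0:
        return 0.0, 1.0
    return log2fc, _conditional_p(a, b, n_a, n_b, phi)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results, lfc_threshold: float = 2.0,
            fdr_threshold: float = 0.05) -> list:
    """Attach BH q-values and significance flags to one contrast's results.

    Significant iff ``|log2FC| >= lfc_threshold`` and ``q < fdr_threshold``;
    direction follows the sign of the fold change.
    """
    if not results:
        return []
    q = bh_fdr([r.p_value for r in results])
    out = []
    for r, qv in zip(results, q):
        sig = abs(r.log2fc) >= lfc_threshold and qv < fdr_threshold
        direction = "ns"
        if sig:
            direction = "up" if r.log2fc > 0 else "down"
        out.append(DEResult(r.cds_id, r.stage, r.group_a, r.group_b,
                            r.log2fc, r.p_value, float(qv), sig, direction))
    return out


def run_contrasts(counts: pd.DataFrame, design, params,
                  contrasts=DEFAULT_CONTRASTS) -> pd.DataFrame:
    """All within-stage pairwise contrasts on a counts matrix.

    Normalization factors and the common dispersion are estimated once from
    the full matrix; BH correction is applied within each contrast.
    """
    factors = norm_factors(counts)
    eff = effective_sizes(counts, factors)
    phi = estimate_dispersion(counts, design, factors)
    logger.info("common dispersion estimate: %.4f", phi)
    frames = []
    for stage in design.stages:
        for group_a, group_b in contrasts:
            if group_a not in design.groups or group_b not in design.groups:
                continue  # partial designs use the contrasts they can
            libs_a = design.cell(stage, group_a)
            libs_b = design.cell(stage, group_b)
            results = []
            for cds_id in counts.index:
                lfc, p = exact_nb_test(
                    counts.loc[cds_id, libs_a].to_numpy(),
                    counts.loc[cds_id, libs_b].to_numpy(),
                    phi,
                    eff[libs_a].to_numpy(),
                    eff[libs_b].to_numpy(),
                )
                results.append(DEResult(cds_id, stage, group_a, group_b, lfc, p))
            called = call_de(results, params.lfc_threshold, params.fdr_threshold)
            frames.append(pd.DataFrame(
                dict(
                    cds_id=[r.cds_id for r in called],
                    stage=stage,
                    group_a=group_a,
                    group_b=group_b,
                    log2fc=[r.log2fc for r in called],
                    p_value=[r.p_value for r in called],
                    q_value=[r.q_value for r in called],
                    significant=[r.significant for r in called],
                    direction=[r.direction for r in called],
                )
            ))
    df = pd.concat(frames, ignore_index=True)
    with np.errstate(divide="ignore"):
        df["neg_log10_q"] = -np.log10(df["q_value"])
    n_sig = int(df["significant"].sum())
    logger.info("significant calls: %d / %d tests", n_sig, len(df))
    return df
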