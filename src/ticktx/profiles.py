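"""Class-level temporal expression profiles, Z-score heatmap and sample MDS.

Three complementary summaries of the filtered expression matrix:

* per-class percent TPM per library, averaged (mean, SD) across the
  replicates of each (stage, group) cell — the temporal profile of each
  functional class;
* row-wise Z-scores of the TPM matrix with agglomerative (average-linkage,
  Euclidean) leaf orders for rows and columns — the heatmap layout;
* classical (Torgerson) multidimensional scaling of pairwise library
  distances, where the distance is the root-mean-square of the ``top_n``
  largest absolute log2 TPM ratios between the two libraries (a
  leading-fold-change distance, as used for sample MDS of count data).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

TPM_PRIOR = 0.5  # added before log ratios in the MDS distance


def class_percent_tpm(tpm: pd.DataFrame, classification: dict, design) -> pd.DataFrame:
    """Mean and SD of per-class percent TPM across replicates of each cell.

    ``classification`` maps every row of ``tpm`` to a class label; an
    unclassified CDS is an error. Returns a tidy frame
    (class_label, stage, group, mean_percent, sd_percent).
    """
    missing = [i for i in tpm.index if i not in classification]
    if missing:
        raise ValueError(f"unclassified CDS: {missing[:5]}")
    labels = pd.Series({i: classification[i] for i in tpm.index})
    percent = tpm.groupby(labels, sort=True).sum() / 1e6 * 100.0
    rows = []
    for class_label in percent.index:
        for stage in design.stages:
            for group in design.groups:
                values = percent.loc[class_label, design.cell(stage, group)]
                rows.append(
                    dict(
                        class_label=class_label,
                        stage=stage,
                        group=group,
                        mean_percent=float(values.mean()),
                        sd_percent=float(values.std(ddof=1)),
                    )
                )
    return pd.DataFrame(rows)


def percent_tpm_by_library(tpm: pd.DataFrame, classification: dict) -> pd.DataFrame:
    """Per-class percent TPM per library (columns sum to 100)."""
    labels = pd.Series({i: classification[i] for i in tpm.index})
    return tpm.groupby(labels, sort=True).sum() / 1e6 * 100.0


def zscore_rows(tpm: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores with sample SD (ddof=1); constant rows become 0."""
    mean = tpm.mean(axis=1)
    sd = tpm.std(axis=1, ddof=1)
    centred = tpm.sub(mean, axis=0)
    z = centred.div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z


def cluster_heatmap(values: pd.DataFrame) -> tuple:
    """Average-linkage Euclidean leaf orders for rows and columns.

    Rows/columns are pre-sorted by id so the result is invariant to the
    input ordering (ties resolved by id).
    """
    values = values.sort_index(axis=0).sort_index(axis=1)
    row_order = list(values.index)
    col_order = list(values.columns)
    if len(values.index) > 2:
        lk = linkage(pdist(values.to_numpy(), metric="euclidean"), method="average")
        row_order = [values.index[i] for i in leaves_list(lk)]
    if len(values.columns) > 2:
        lk = linkage(pdist(values.to_numpy().T, metric="euclidean"), method="average")
        col_order = [values.columns[i] for i in leaves_list(lk)]
    return row_order, col_order


def _leading_lfc_distance(tpm: pd.DataFrame, top_n: int) -> pd.DataFrame:
    log_tpm = np.log2(tpm.to_numpy(dtype=float) + TPM_PRIOR)
    n = log_tpm.shape[1]
    d = np.zeros((n, n))
    k = min(top_n, log_tpm.shape[0])
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(log_tpm[:, i] - log_tpm[:, j])
            if k < diff.size:
                top = np.partition(diff, diff.size - k)[-k:]
            else:
                top = diff
            d[i, j] = d[j, i] = float(np.sqrt(np.mean(top ** 2)))
    return pd.DataFrame(d, index=tpm.columns, columns=tpm.columns)


def classical_mds(distance: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Torgerson MDS: double-centre the squared distances and eigendecompose."""
    d2 = distance.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, n_components))
    for k in range(min(n_components, n)):
        lam = max(eigval[k], 0.0)
        axis = eigvec[:, k] * np.sqrt(lam)
        if len(axis) and axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis  # sign convention: largest-magnitude loading positive
        coords[:, k] = axis
    return pd.DataFrame(
        coords, index=distance.index,
        columns=[f"dim{k + 1}" for k in range(n_components)],
    )


def mds_samples(tpm: pd.DataFrame, design=None, top_n: int = 500,
                libraries=None) -> pd.DataFrame:
    """2-D MDS coordinates of libraries from leading-log-fold-change distances.

    ``libraries`` restricts the embedding to a subset (e.g. one stage).
    """
    if libraries is not None:
        tpm = tpm[list(libraries)]
    if tpm.shape[1] < 3:
        raise ValueError("MDS needs at least 3 libraries")
    distance = _leading_lfc_distance(tpm, top_n)
    return classical_mds(distance, n_components=2)
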