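"""Recovery metrics of a pipeline run against planted ground truth.

These comparisons quantify how much of the simulation's planted signal the
pipeline recovers: CDS intervals, contaminant flags, class labels, and
differential-expression calls at the planted amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DEFAULT_CONTRASTS
from .pipeline import PipelineResult


@dataclass
class RecoveryReport:
    class_label_recovery: float
    contaminant_recovery: float
    interval_recovery: float
    n_planted: int
    n_contaminant: int


def _records_by_transcript(result: PipelineResult) -> dict:
    by_tx = {}
    for rec in result.records:
        by_tx.setdefault(rec.transcript_id, []).append(rec)
    return by_tx


def _planted_record(recs, t):
    """The extracted record corresponding to the planted CDS: exact interval
    match preferred, then any same-strand overlap, else None."""
    exact = [r for r in recs if r.strand == t.strand
             and r.start == t.cds_start and r.end == t.cds_end]
    if exact:
        return exact[0]
    overlap = [r for r in recs if r.strand == t.strand
               and r.start < t.cds_end and r.end > t.cds_start]
    return overlap[0] if overlap else None


def recovery_report(result: PipelineResult, truth) -> RecoveryReport:
    """Recovery of planted truth, judged on the extracted CDS that matches
    each planted interval (extra CDS from decoy ORFs on the same transcript
    are a separate phenomenon and do not enter these rates)."""
    by_tx = _records_by_transcript(result)
    labels = {i: c.class_label for i, c in result.classification.items()}

    n_planted = n_interval = n_class = 0
    n_contam = n_contam_ok = 0
    for t in truth:
        recs = by_tx.get(t.transcript_id, [])
        planted = _planted_record(recs, t)
        if t.contaminant:
            n_contam += 1
            n_contam_ok += planted is not None and planted.contaminant
            continue
        n_planted += 1
        if planted is not None and (planted.strand == t.strand
                                    and planted.start == t.cds_start
                                    and planted.end == t.cds_end):
            n_interval += 1
        assigned = None
        if planted is not None and not planted.contaminant:
            rep = result.member_to_rep.get(planted.cds_id)
            if rep in labels:
                assigned = labels[rep]
        if assigned == t.class_label:
            n_class += 1
    return RecoveryReport(
        class_label_recovery=n_class / n_planted if n_planted else float("nan"),
        contaminant_recovery=n_contam_ok / n_contam if n_contam else float("nan"),
        interval_recovery=n_interval / n_planted if n_planted else float("nan"),
        n_planted=n_planted,
        n_contaminant=n_contam,
    )


def de_recall(result: PipelineResult, truth, planted_abs_lfc: float = 4.0,
              min_mean_tpm: float = 50.0) -> tuple:
    """Recall of planted DE at |log2FC| = ``planted_abs_lfc``.

    Considers every (CDS, stage, contrast) whose planted fold change has the
    target magnitude and whose mean TPM across the contrast's libraries is
    at least ``min_mean_tpm``; recalled when the pipeline calls it
    significant in the planted direction. Returns ``(recall, n_eligible)``.
    """
    by_tx = _records_by_transcript(result)
    rep_for_tx = {}
    for t in truth:
        planted = _planted_record(by_tx.get(t.transcript_id, []), t)
        if planted is None:
            continue
        rep = result.member_to_rep.get(planted.cds_id)
        if rep in result.classification:
            rep_for_tx[t.transcript_id] = rep
    de = result.de_table.set_index(["cds_id", "stage", "group_a", "group_b"])
    tpm = result.matrix.tpm
    design = result.design
    n_eligible = n_recalled = 0
    for t in truth:
        if t.contaminant:
            continue
        rep = rep_for_tx.get(t.transcript_id)
        for (a, b), planted in t.log2fc.items():
            if abs(planted) != planted_abs_lfc:
                continue
            for stage in design.stages:
                libs = design.cell(stage, a) + design.cell(stage, b)
                if rep is not None and tpm.loc[rep, libs].mean() < min_mean_tpm:
                    continue
                # a planted transcript the pipeline lost entirely stays
                # eligible and counts against recall
                n_eligible += 1
                if rep is None:
                    continue
                row = de.loc[(rep, stage, a, b)]
                if bool(row["significant"]) and np.sign(row["log2fc"]) == np.sign(planted):
                    n_recalled += 1
    return (n_recalled / n_eligible if n_eligible else float("nan"), n_eligible)


def null_type1_rate(n_cds: int = 2000, phi: float = 0.1, n_reps: int = 3,
                    n_runs: int = 20, seed: int = 0,
                    baseline_range=(50.0, 500.0),
                    size_factor_range=(0.7, 1.3)) -> float:
    """Fraction of p-values below 0.05 under a null (flat) simulation.

    Two groups of ``n_reps`` libraries, NB counts with common dispersion
    ``phi`` and per-library size factors; normalization, dispersion
    estimation and the exact test run exactly as in the pipeline. Averaged
    over ``n_runs`` independent simulations.
    """
    from .de import (effective_sizes, estimate_dispersion, exact_nb_test,
                     norm_factors)
    from .design import build_design

    rng = np.random.default_rng(seed)
    design = build_design(stages=("s1",), groups=("A", "B"),
                          replicates_per_cell=n_reps)
    libs = design.library_ids
    rates = []
    for _ in range(n_runs):
        mu = rng.uniform(*baseline_range, size=n_cds)
        sf = rng.uniform(*size_factor_range, size=len(libs))
        mean = np.outer(mu, sf)
        if phi > 0:
            r = 1.0 / phi
            counts = rng.negative_binomial(r, r / (r + mean))
        else:
            counts = rng.poisson(mean)
        df = pd.DataFrame(counts, columns=libs,
                          index=[f"g{i}" for i in range(n_cds)])
        factors = norm_factors(df)
        eff = effective_sizes(df, factors).to_numpy()
        phi_hat = estimate_dispersion(df, design, factors)
        pvals = np.empty(n_cds)
        arr = df.to_numpy()
        for i in range(n_cds):
            _, pvals[i] = exact_nb_test(arr[i, :n_reps], arr[i, n_reps:],
                                        phi_hat, eff[:n_reps], eff[n_reps:])
        rates.append(float(np.mean(pvals < 0.05)))
    return float(np.mean(rates))


def profile_shape_checks(result: PipelineResult, truth) -> dict:
    """Qualitative reproduction checks of the planted temporal profiles.

    Returns dict with:
    - ``u_shape_ok``: every planted U-shape class satisfies, in every stage,
      unfed > early and late > early mean percent TPM (early = first fed group);
    - ``unknown_induced_ok``: the "unknown" class percent rises from unfed to
      the first fed group in every stage;
    - ``stage_silhouettes``: mean silhouette of the {unfed},{early},{late}
      clustering over per-stage MDS coordinates.
    """
    from sklearn.metrics import silhouette_score

    design = result.design
    groups = list(design.groups)
    unfed, first_fed, late = groups[0], groups[1], groups[-1]
    prof = result.class_profiles.set_index(["class_label", "stage", "group"])

    shape_by_class = {}
    for t in truth:
        if t.class_label:
            shape_by_class[t.class_label] = t.shape
    present = {c for c, *_ in prof.index}

    u_ok = True
    for cls, shape in shape_by_class.items():
        if shape != "u_shape" or cls not in present:
            continue
        for stage in design.stages:
            uf = prof.loc[(cls, stage, unfed), "mean_percent"]
            early = prof.loc[(cls, stage, first_fed), "mean_percent"]
            fed5d = prof.loc[(cls, stage, late), "mean_percent"]
            if not (uf > early and fed5d > early):
                u_ok = False
    unknown_ok = True
    if "unknown" in present:
        for stage in design.stages:
            uf = prof.loc[("unknown", stage, unfed), "mean_percent"]
            early = prof.loc[("unknown", stage, first_fed), "mean_percent"]
            if not (early > uf):
                unknown_ok = False
    else:
        unknown_ok = False

    cluster_of = {unfed: 0, late: 2}
    sils = {}
    for stage, coords in result.mds_by_stage.items():
        lib_group = {l.library_id: l.group for l in design.libraries}
        labels = [cluster_of.get(lib_group[lib], 1) for lib in coords.index]
        sils[stage] = float(silhouette_score(coords.to_numpy(), labels))
    return dict(u_shape_ok=u_ok, unknown_induced_ok=unknown_ok,
                stage_silhouettes=sils)
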