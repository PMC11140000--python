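"""End-to-end orchestration: transcripts + proteome + counts -> results.

Stage order mirrors the analysis the package implements: CDS extraction
(homology + signal evidence), contaminant removal, redundancy consolidation
at 95% nucleotide identity, TPM quantification, the replicate-consistent
TPM >= 5 filter, vocabulary classification, within-stage exact-test
contrasts, and class-level temporal profiles with heatmap/MDS layouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import profiles as _profiles
from .cluster import cluster_greedy, clusters_to_frame
from .de import run_contrasts
from .design import StudyDesign
from .extract import extract_cds, records_to_frame
from .io import write_counts, write_fasta, write_table, SeqEntry
from .params import PipelineParams
from .quantify import ExpressionMatrix, compute_tpm, filter_expressed

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    params: PipelineParams
    design: StudyDesign
    records: list  # all CdsRecords (contaminants flagged, not removed)
    hits_by_orf: dict
    clusters: list
    member_to_rep: dict
    matrix: ExpressionMatrix  # representatives x libraries
    kept_ids: list
    classification: dict  # kept cds_id -> Classification
    de_table: pd.DataFrame
    class_profiles: pd.DataFrame
    percent_by_library: pd.DataFrame
    zscores: pd.DataFrame
    heatmap_row_order: list = field(default_factory=list)
    heatmap_col_order: list = field(default_factory=list)
    mds_all: pd.DataFrame | None = None
    mds_by_stage: dict = field(default_factory=dict)

    @property
    def kept_records(self) -> dict:
        by_id = {r.cds_id: r for r in self.records}
        return {i: by_id[i] for i in self.kept_ids}


def run_all(
    transcripts,
    proteome,
    counts: pd.DataFrame,
    design: StudyDesign,
    params: PipelineParams | None = None,
    vocabulary=None,
    hits_by_orf: dict | None = None,
    signal_table: dict | None = None,
    mds_top_n: int = 500,
) -> PipelineResult:
    """Run every stage; ``counts`` rows may be keyed by cds id or by
    transcript id (each extracted CDS then inherits its transcript's row)."""
    params = params or PipelineParams()
    vocabulary = vocabulary or _classify.default_vocabulary()

    records, hits_by_orf = extract_cds(
        transcripts, proteome, params, hits_by_orf, signal_table
    )
    clean = [r for r in records if not r.contaminant]

    clusters = cluster_greedy({r.cds_id: r.nt_seq for r in clean},
                              params.cluster_identity)
    member_to_rep = {m: c.representative_id for c in clusters for m in c.member_ids}
    reps = {c.representative_id for c in clusters}
    rep_records = [r for r in clean if r.cds_id in reps]
    logger.info("clustering: %d CDS -> %d representatives", len(clean), len(reps))

    rows = []
    for rec in rep_records:
        if rec.cds_id in counts.index:
            row = counts.loc[rec.cds_id]
        elif rec.transcript_id in counts.index:
            row = counts.loc[rec.transcript_id]
        else:
            raise ValueError(f"no counts for {rec.cds_id} / {rec.transcript_id}")
        rows.append(row.rename(rec.cds_id))
    rep_counts = pd.DataFrame(rows)[design.library_ids]
    lengths = pd.Series({r.cds_id: r.end - r.start for r in rep_records})

    matrix = compute_tpm(rep_counts, lengths)
    kept_ids = filter_expressed(matrix, design, params.min_tpm)

    hits_for = {r.cds_id: hits_by_orf.get(r.orf_id, []) for r in rep_records}
    classification = {
        cds_id: _classify.classify_cds(cds_id, hits_for[cds_id], vocabulary)
        for cds_id in kept_ids
    }

    kept_counts = matrix.counts.loc[kept_ids]
    kept_tpm = matrix.tpm.loc[kept_ids]
    de_table = run_contrasts(kept_counts, design, params)

    labels = {i: c.class_label for i, c in classification.items()}
    class_profiles = _profiles.class_percent_tpm(kept_tpm, labels, design)
    percent_by_library = _profiles.percent_tpm_by_library(kept_tpm, labels)
    zscores = _profiles.zscore_rows(kept_tpm)
    row_order, col_order = _profiles.cluster_heatmap(zscores)
    mds_all = _profiles.mds_samples(kept_tpm, design, top_n=mds_top_n)
    mds_by_stage = {
        stage: _profiles.mds_samples(
            kept_tpm, design, top_n=mds_top_n,
            libraries=[l.library_id for l in design.libraries if l.stage == stage],
        )
        for stage in design.stages
    }

    return PipelineResult(
        params=params, design=design, records=records, hits_by_orf=hits_by_orf,
        clusters=clusters, member_to_rep=member_to_rep, matrix=matrix,
        kept_ids=kept_ids, classification=classification, de_table=de_table,
        class_profiles=class_profiles, percent_by_library=percent_by_library,
        zscores=zscores, heatmap_row_order=row_order, heatmap_col_order=col_order,
        mds_all=mds_all, mds_by_stage=mds_by_stage,
    )


def annotation_table(result: PipelineResult) -> pd.DataFrame:
    """Plain-TSV analog of an annotated-CDS spreadsheet (kept CDS only)."""
    by_id = {r.cds_id: r for r in result.records}
    rows = []
    for cds_id in result.kept_ids:
        rec = by_id[cds_id]
        cls = result.classification[cds_id]
        hit = rec.best_hit
        rows.append(dict(
            cds_id=cds_id,
            transcript_id=rec.transcript_id,
            start=rec.start, end=rec.end, strand=rec.strand,
            evidence=rec.evidence,
            class_label=cls.class_label,
            matched_keyword=cls.matched_keyword or "",
            best_hit_subject=hit.subject_id if hit else "",
            best_hit_description=hit.subject_description if hit else "",
            best_hit_score=hit.score if hit else float("nan"),
            best_hit_coverage=hit.subject_coverage if hit else float("nan"),
            signal_positive=bool(rec.signal and rec.signal.is_positive),
            cleavage_index=(rec.signal.cleavage_index
                            if rec.signal and rec.signal.is_positive else ""),
        ))
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, out_dir: str | Path) -> dict:
    """Write every stage output as TSV/FASTA under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {r.cds_id: r for r in result.records}
    paths = {}

    def _save(name, fn):
        paths[name] = out / name
        fn(paths[name])

    _save("extraction_report.tsv",
          lambda p: write_table(records_to_frame(result.records), p))
    _save("cds_nt.fasta", lambda p: write_fasta(
        [SeqEntry(i, by_id[i].nt_seq) for i in result.kept_ids], p))
    _save("cds_protein.fasta", lambda p: write_fasta(
        [SeqEntry(i, by_id[i].protein) for i in result.kept_ids], p))
    _save("clusters.tsv",
          lambda p: write_table(clusters_to_frame(result.clusters), p))
    _save("tpm.tsv", lambda p: result.matrix.tpm.to_csv(p, sep="\t", index_label="id"))
    _save("counts_used.tsv", lambda p: write_counts(result.matrix.counts, p))
    _save("kept_ids.txt",
          lambda p: p.write_text("\n".join(result.kept_ids) + "\n"))
    _save("annotation.tsv", lambda p: write_table(annotation_table(result), p))
    _save("de.tsv", lambda p: write_table(result.de_table, p))
    _save("class_profiles.tsv", lambda p: write_table(result.class_profiles, p))
    _save("zscores.tsv", lambda p: result.zscores
          .loc[result.heatmap_row_order, result.heatmap_col_order]
          .to_csv(p, sep="\t", index_label="id"))
    _save("mds.tsv", lambda p: result.mds_all.to_csv(p, sep="\t", index_label="library_id"))
    return paths
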