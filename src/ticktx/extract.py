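"""CDS extraction from assembled transcripts.

Two evidence routes, mirroring how de novo transcriptome pipelines recover
coding regions:

* homology — an ORF whose best database hit covers at least
  ``min_coverage_fraction`` of the subject protein and whose ORF spans at
  least ``min_orf_nt`` nucleotides. The CDS 5' end is the alignment start
  pulled back to the nearest in-frame Met at or upstream of it (if any);
  the 3' end runs to the ORF boundary, through the stop codon when present
  (homology CDS need not begin with Met: assemblies contain 5'-truncated
  transcripts).
* signal — among Met-initiated sub-ORFs of at least ``min_signal_orf_aa``
  residues whose translation the signal-peptide predictor accepts, the most
  5' Met wins and sets the start. When both routes accept the same ORF the
  signal start takes precedence.

Contaminant flagging: a CDS is a potential contaminant when its best hit
carries a contaminant taxon tag and no non-contaminant hit scores within
``contaminant_margin_bits`` of that best score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .align import HomologyHit, search_all
from .orfs import Orf, find_orfs
from .params import PipelineParams
from .signalpep import SignalCall, predict_signal_peptide

logger = logging.getLogger(__name__)


@dataclass
class CdsRecord:
    cds_id: str
    transcript_id: str
    start: int  # forward strand, 0-based
    end: int  # half-open; includes the stop codon when stop-bounded
    strand: str
    protein: str
    nt_seq: str
    evidence: str  # 'homology' | 'signal' | 'both'
    best_hit: HomologyHit | None = None
    signal: SignalCall | None = None
    contaminant: bool = False
    orf_id: str = ""


def _cds_nt(transcript_seq: str, start: int, end: int, strand: str) -> str:
    from .orfs import revcomp

    region = transcript_seq[start:end]
    return region if strand == "+" else revcomp(region)


def call_cds_by_homology(
    orf: Orf, hits: list, params: PipelineParams, transcript_seq: str
) -> CdsRecord | None:
    """Homology-evidence CDS for one ORF, or ``None``."""
    if not hits or orf.nt_length < params.min_orf_nt:
        return None
    best = hits[0]
    if best.subject_coverage < params.min_coverage_fraction:
        return None
    q_start, q_end = best.query_span
    upstream_mets = [m for m in orf.met_positions if m <= q_start]
    aa_start = max(upstream_mets) if upstream_mets else q_start
    start, end = orf.aa_interval_forward(aa_start, len(orf.protein), to_orf_end=True)
    return CdsRecord(
        cds_id="",
        transcript_id=orf.transcript_id,
        start=start,
        end=end,
        strand=orf.strand,
        protein=orf.protein[aa_start:],
        nt_seq=_cds_nt(transcript_seq, start, end, orf.strand),
        evidence="homology",
        best_hit=best,
        orf_id=orf.orf_id,
    )


def refine_start(
    orf: Orf,
    params: PipelineParams,
    transcript_seq: str,
    signal_table: dict | None = None,
) -> CdsRecord | None:
    """Signal-evidence CDS: most-5' Met whose sub-ORF is signal-positive.

    ``signal_table`` optionally maps protein sequences to precomputed
    :class:`~ticktx.signalpep.SignalCall` objects (an external predictor's
    output); the built-in heuristic is used otherwise.
    """
    best_call = None
    best_met = None
    for met in orf.met_positions:
        sub = orf.protein[met:]
        if len(sub) < params.min_signal_orf_aa:
            continue
        if signal_table is not None:
            call = signal_table.get(sub, None)
            if call is None:
                continue
        else:
            call = predict_signal_peptide(sub)
        if call.is_positive:
            best_call, best_met = call, met
            break  # met_positions ascending: first positive is most 5'
    if best_call is None:
        return None
    start, end = orf.aa_interval_forward(best_met, len(orf.protein), to_orf_end=True)
    return CdsRecord(
        cds_id="",
        transcript_id=orf.transcript_id,
        start=start,
        end=end,
        strand=orf.strand,
        protein=orf.protein[best_met:],
        nt_seq=_cds_nt(transcript_seq, start, end, orf.strand),
        evidence="signal",
        signal=best_call,
        orf_id=orf.orf_id,
    )


def flag_contaminants(records: list, hits_by_orf: dict, params: PipelineParams) -> list:
    """Set the contaminant flag on each record (returns the same list).

    No-hit records are kept: absence of similarity makes a CDS 'unknown',
    not a contaminant.
    """
    for rec in records:
        hits = hits_by_orf.get(rec.orf_id, [])
        if not hits:
            rec.contaminant = False
            continue
        best = hits[0]
        if best.taxon_tag not in params.contaminant_taxa:
            rec.contaminant = False
            continue
        rescue = any(
            h.taxon_tag not in params.contaminant_taxa
            and h.score >= best.score - params.contaminant_margin_bits
            for h in hits
        )
        rec.contaminant = not rescue
    return records


def extract_cds(
    transcripts,
    proteome,
    params: PipelineParams,
    hits_by_orf: dict | None = None,
    signal_table: dict | None = None,
) -> tuple:
    """Run ORF finding, homology search and both evidence routes.

    Returns ``(records, hits_by_orf)``. ``hits_by_orf`` may be supplied to
    bypass the built-in aligner (e.g. an externally computed hit table).
    At most one CDS is emitted per ORF; cds ids are
    ``<transcript_id>.c<k>`` in transcript order.
    """
    seq_by_id = {t.id: t.seq for t in transcripts}
    min_query_nt = min(params.min_orf_nt, 3 * params.min_signal_orf_aa)
    orfs_by_transcript = {}
    queries = {}
    all_orfs = {}
    for t in transcripts:
        orfs = find_orfs(t.id, t.seq, min_len_nt=min_query_nt)
        orfs_by_transcript[t.id] = orfs
        for orf in orfs:
            all_orfs[orf.orf_id] = orf
            if orf.nt_length >= params.min_orf_nt:
                queries[orf.orf_id] = orf.protein
    if hits_by_orf is None:
        logger.info("homology search: %d query ORFs vs %d subjects",
                    len(queries), len(list(proteome)))
        hits_by_orf = search_all(
            queries, proteome,
            score_min=params.homology_score_min,
            gap_open=params.gap_open, gap_extend=params.gap_extend,
        )
    records = []
    for t in transcripts:
        n = 0
        for orf in orfs_by_transcript[t.id]:
            hits = hits_by_orf.get(orf.orf_id, [])
            hom = call_cds_by_homology(orf, hits, params, seq_by_id[t.id])
            sig = refine_start(orf, params, seq_by_id[t.id], signal_table)
            rec = None
            if hom is not None and sig is not None:
                sig.evidence = "both"
                sig.best_hit = hom.best_hit
                rec = sig
            elif sig is not None:
                rec = sig
            elif hom is not None:
                rec = hom
            if rec is not None:
                n += 1
                rec.cds_id = f"{t.id}.c{n}"
                records.append(rec)
    flag_contaminants(records, hits_by_orf, params)
    n_contam = sum(r.contaminant for r in records)
    logger.info("extracted %d CDS (%d flagged as contaminants)",
                len(records), n_contam)
    return records, hits_by_orf


def records_to_frame(records) -> pd.DataFrame:
    """Extraction report: one row per CDS."""
    rows = []
    for r in records:
        hit = r.best_hit
        rows.append(
            dict(
                cds_id=r.cds_id,
                transcript_id=r.transcript_id,
                start=r.start,
                end=r.end,
                strand=r.strand,
                evidence=r.evidence,
                length_nt=r.end - r.start,
                best_hit_subject=hit.subject_id if hit else "",
                best_hit_score=hit.score if hit else float("nan"),
                best_hit_coverage=hit.subject_coverage if hit else float("nan"),
                best_hit_taxon=hit.taxon_tag if hit else "",
                signal_positive=bool(r.signal and r.signal.is_positive),
                cleavage_index=(r.signal.cleavage_index
                                if r.signal and r.signal.is_positive else ""),
                contaminant=r.contaminant,
            )
        )
    return pd.DataFrame(rows)
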