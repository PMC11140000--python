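"""Synthetic study generator with planted ground truth.

Emulates the data a feeding-timecourse transcriptome study produces —
assembled transcripts, a taxon-tagged reference proteome, and per-library
read counts for a stages x feeding-groups x replicates design — with every
quantity the downstream pipeline estimates planted and recorded:

* each non-"unknown" transcript embeds a CDS back-translated (uniform
  random synonymous codons) from a mutated copy of a database protein,
  flanked by random UTRs, on a random strand;
* signal-peptide transcripts start their protein with an n/h/c-region
  pattern the built-in predictor accepts (cleavage after residue 19);
* "unknown" transcripts carry a novel secreted protein with no database
  relative; "unknown conserved" transcripts hit database entries whose
  descriptions are uninformative ("hypothetical protein");
* contaminant transcripts derive from vertebrate- or bacteria-tagged
  database proteins;
* counts are negative-binomial around per-group means following one of
  four temporal shapes — ``u_shape`` (high unfed, dropped while feeding,
  recovered at the late timepoint), ``induced`` (the mirror image),
  ``late_switch`` (near-zero except the late timepoint) and ``flat`` —
  scaled by per-library size factors.

The generator guards its own ground truth: in-frame leader ATGs upstream of
a planted start are patched out, and non-signal proteins are rejection-
sampled until no Met-initiated suffix fools the signal-peptide predictor,
so planted starts are unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import RULE_CLASSES, UNKNOWN, UNKNOWN_CONSERVED, Vocabulary, default_vocabulary
from .de import DEFAULT_CONTRASTS
from .design import StudyDesign, build_design
from .io import SeqEntry
from .orfs import CODON_TO_AA, revcomp
from .params import PipelineParams
from .signalpep import predict_signal_peptide

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_FOR = {}
for codon, aa in CODON_TO_AA.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
STOPS = ("TAA", "TAG", "TGA")

#: Temporal shape of each default functional class. Housekeeping classes are
#: flat; blood-meal classes are U-shaped; the storage class switches on late;
#: the "unknown" class is induced by the blood meal.
DEFAULT_SHAPE_BY_CLASS = {
    "proteinase inhibitor": "u_shape",
    "proteinase": "u_shape",
    "lipocalin": "u_shape",
    "mucin": "u_shape",
    "secreted": "u_shape",
    "immunity": "u_shape",
    "oxidant metabolism": "u_shape",
    "extracellular matrix": "u_shape",
    "storage": "late_switch",
    "cytoskeletal": "flat",
    "protein synthesis machinery": "flat",
    "protein modification machinery": "flat",
    "protein export machinery": "flat",
    "proteasome machinery": "flat",
    "transcription machinery": "flat",
    "transcription factor": "flat",
    "signal transduction": "flat",
    "metabolism, energy": "flat",
    "metabolism, carbohydrate": "flat",
    "metabolism, lipid": "flat",
    "metabolism, amino acid": "flat",
    "metabolism, nucleotide": "flat",
    "transporters and channels": "flat",
    UNKNOWN_CONSERVED: "u_shape",
    UNKNOWN: "induced",
}

#: Baseline mean-count range (at the unfed reference) per temporal shape.
DEFAULT_BASELINE_RANGES = {
    "u_shape": (200.0, 2000.0),
    "induced": (20.0, 200.0),
    "flat": (50.0, 500.0),
    "late_switch": (2.0, 8.0),
}


@dataclass
class SimParams:
    """Study conditions for the synthetic data.

    Defaults emulate the reference design: 25 functional classes x 20
    transcripts over 45 libraries, a 16-fold feeding-response amplitude
    (log2 fold change of 4, comfortably past the |log2FC| >= 2 calling
    threshold), and a common NB dispersion of 0.1 — a typical biological
    coefficient of variation of ~0.32 for bulk replicates.
    """

    n_classes: int = 25
    transcripts_per_class: int = 20
    fraction_unknown: float = 0.04
    fraction_unknown_conserved: float = 0.04
    fraction_contaminant: float = 0.08
    fraction_signal_peptide: float = 0.30
    mean_cds_aa: int = 150
    utr_len_range: tuple = (30, 150)
    dispersion: float = 0.1
    aa_mutation_rate: float = 0.03
    proteins_per_class: int = 5
    fold_change: float = 16.0
    late_fold: float = 64.0
    baseline_ranges: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RANGES))
    shape_by_class: dict = field(default_factory=lambda: dict(DEFAULT_SHAPE_BY_CLASS))
    size_factor_range: tuple = (0.7, 1.3)
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("fraction_unknown", "fraction_unknown_conserved",
                     "fraction_contaminant", "fraction_signal_peptide"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fraction_unknown + self.fraction_unknown_conserved > 1.0:
            raise ValueError("unknown fractions exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.utr_len_range
        if not (0 <= lo <= hi):
            raise ValueError("utr_len_range must be ordered and non-negative")
        if self.fold_change <= 1 or self.late_fold <= 1:
            raise ValueError("fold changes must exceed 1")


@dataclass
class TruthRecord:
    transcript_id: str
    class_label: str
    shape: str
    strand: str
    cds_start: int
    cds_end: int  # includes the stop codon
    protein: str
    signal_peptide: bool
    cleavage_index: int | None
    contaminant: bool
    taxon: str
    source_subject: str
    baseline: float
    dispersion: float
    log2fc: dict = field(default_factory=dict)  # (group_a, group_b) -> planted lfc


def group_multipliers(shape: str, groups, fold: float, late_fold: float) -> dict:
    """Per-group mean multipliers; groups are (unfed, early..., late)."""
    unfed, late = groups[0], groups[-1]
    early = list(groups[1:-1])
    mult = {g: 1.0 for g in groups}
    if shape == "u_shape":
        for g in early:
            mult[g] = 1.0 / fold
    elif shape == "induced":
        for g in early:
            mult[g] = fold
    elif shape == "late_switch":
        mult[late] = late_fold
    elif shape != "flat":
        raise ValueError(f"unknown shape {shape!r}")
    return mult


def planted_log2fc(shape: str, groups, fold: float, late_fold: float,
                   contrasts=DEFAULT_CONTRASTS) -> dict:
    mult = group_multipliers(shape, groups, fold, late_fold)
    return {
        (a, b): float(np.log2(mult[b] / mult[a]))
        for a, b in contrasts
        if a in mult and b in mult
    }


def _random_protein(rng, length: int, min_signal_orf_aa: int = 40,
                    max_tries: int = 200) -> str:
    """Random Met-initiated protein with no signal-positive Met suffix."""
    for _ in range(max_tries):
        body = "".join(rng.choice(list(AA20), size=length - 1))
        protein = "M" + body
        if not _any_signal_positive(protein, min_signal_orf_aa):
            return protein
    raise RuntimeError("could not sample a signal-negative protein")


def _any_signal_positive(protein: str, min_aa: int) -> bool:
    for i, a in enumerate(protein):
        if a == "M" and len(protein) - i >= min_aa:
            if predict_signal_peptide(protein[i:]).is_positive:
                return True
    return False


def _signal_prefix(rng) -> str:
    """A 19-residue signal peptide the built-in predictor accepts
    (cleavage before residue 20)."""
    mid = "".join(rng.choice(list("FIWY"), size=3))
    return "M" + str(rng.choice(list("KR"))) + mid + "L" * 11 + "ASA"


def _mutate_protein(rng, protein: str, rate: float, keep_prefix: int,
                    min_signal_orf_aa: int, want_signal: bool,
                    max_tries: int = 200) -> str:
    """Substitute residues at ``rate``, sparing the first ``keep_prefix``
    and the last 5 residues, without creating spurious signal positives."""
    n = len(protein)
    positions = np.arange(keep_prefix, max(keep_prefix, n - 5))
    for _ in range(max_tries):
        mutated = list(protein)
        for pos in positions:
            if rng.random() < rate:
                choices = [a for a in AA20 if a != mutated[pos] and a != "M"]
                mutated[pos] = str(rng.choice(choices))
        candidate = "".join(mutated)
        if want_signal or not _any_signal_positive(candidate, min_signal_orf_aa):
            return candidate
    raise RuntimeError("could not mutate without creating a signal positive")


def _back_translate(rng, protein: str) -> str:
    return "".join(str(rng.choice(_CODONS_FOR[aa])) for aa in protein)


def _random_utr(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list("ACGT"), size=n))


def _leader_translation(forward: str, cds_start: int) -> str:
    """In-frame translation upstream of the CDS start, back to the nearest
    in-frame stop (the leader residues the planted ORF contributes)."""
    aas = []
    pos = cds_start - 3
    while pos >= 0:
        codon = forward[pos:pos + 3]
        if codon in STOPS or codon not in CODON_TO_AA:
            break
        aas.append(CODON_TO_AA[codon])
        pos -= 3
    return "".join(reversed(aas))


def _has_spurious_signal(seq: str, planted_strand: str, planted_start: int,
                         planted_end: int, min_signal_orf_aa: int) -> bool:
    """True when any Met-initiated sub-ORF outside the planted ORF would be
    accepted by the signal-peptide predictor (it would create a decoy CDS
    that can shadow the planted one downstream)."""
    from .orfs import find_orfs

    for orf in find_orfs("scan", seq, min_len_nt=3 * min_signal_orf_aa):
        in_frame = (
            orf.strand == planted_strand
            and orf.start <= planted_start
            and orf.end >= planted_end
            and ((planted_start - orf.start) % 3 == 0 if planted_strand == "+"
                 else (orf.end - planted_end) % 3 == 0)
        )
        if in_frame:
            continue  # the planted ORF itself is screened at protein level
        for met in orf.met_positions:
            if len(orf.protein) - met < min_signal_orf_aa:
                continue
            if predict_signal_peptide(orf.protein[met:]).is_positive:
                return True
    return False


def _patch_inframe_leader(seq: list, cds_start: int) -> None:
    """Remove in-frame ATGs upstream of the CDS start (back to the first
    in-frame stop), so the planted Met is the 5'-most candidate start."""
    pos = cds_start - 3
    while pos >= 0:
        codon = "".join(seq[pos:pos + 3])
        if codon in STOPS:
            break
        if codon == "ATG":
            seq[pos] = "C"  # ATG -> CTG (Leu), never a stop
        pos -= 3


def generate_reference_proteome(sim: SimParams, vocabulary: Vocabulary | None = None,
                                rng=None) -> tuple:
    """Tagged reference proteins plus the bookkeeping the transcript
    generator needs.

    Returns ``(entries, class_proteins, hypothetical_ids, contaminant_ids)``
    where ``class_proteins`` maps informative class -> list of entry ids.
    """
    vocab = vocabulary or default_vocabulary()
    rng = rng or np.random.default_rng(sim.rng_seed)
    informative = [c for c in vocab.classes if c not in RULE_CLASSES]
    n_informative = sim.n_classes - len(RULE_CLASSES)
    if n_informative > len(informative):
        raise ValueError(
            f"n_classes={sim.n_classes} needs {n_informative} informative "
            f"classes; vocabulary has {len(informative)}"
        )
    informative = informative[:n_informative]
    templates = ("{kw} precursor", "putative {kw}", "probable {kw} homolog",
                 "{kw}, partial")
    entries = []
    class_proteins = {}
    for label in informative:
        ids = []
        keywords = vocab.keywords[label]
        for k in range(sim.proteins_per_class):
            protein = _random_protein(
                rng, int(rng.integers(int(0.8 * sim.mean_cds_aa),
                                      int(1.2 * sim.mean_cds_aa) + 1)))
            desc = None
            for attempt in range(len(keywords) * len(templates)):
                kw = keywords[(k + attempt) % len(keywords)]
                cand = templates[attempt % len(templates)].format(kw=kw)
                found = vocab.match(cand)
                if found is not None and found[3] == label:
                    desc = cand
                    break
            if desc is None:
                raise RuntimeError(f"no collision-free description for {label!r}")
            db_rank = 1 + (k % 3)
            pid = f"{label.replace(' ', '_').replace(',', '')}_p{k + 1}"
            entries.append(SeqEntry(pid, protein, f"{desc}|taxon=tick|db={db_rank}"))
            ids.append(pid)
        class_proteins[label] = ids
    from .align import local_score

    score_floor = PipelineParams().homology_score_min
    informative_entries = list(entries)

    def _unrelated_protein() -> str:
        # the uninformative pool must not resemble any informative subject,
        # or transcripts planted on it would inherit an informative label
        for _ in range(100):
            protein = _random_protein(rng, int(rng.integers(
                int(0.8 * sim.mean_cds_aa), int(1.2 * sim.mean_cds_aa) + 1)))
            if all(local_score(protein, e.seq) < score_floor
                   for e in informative_entries):
                return protein
        raise RuntimeError("could not sample an unrelated protein")

    hypothetical_ids = []
    n_hyp = max(1, sim.proteins_per_class * 2)
    for k in range(n_hyp):
        pid = f"hyp_p{k + 1}"
        entries.append(SeqEntry(pid, _unrelated_protein(),
                                f"hypothetical protein OH{k + 1:03d}|taxon=tick|db=2"))
        hypothetical_ids.append(pid)
    contaminant_ids = []
    if sim.fraction_contaminant > 0:
        for taxon, stem, word in (("vertebrate", "vert_p", "serum factor"),
                                  ("bacteria", "bact_p", "envelope factor")):
            for k in range(max(1, sim.proteins_per_class)):
                protein = _random_protein(rng, int(rng.integers(
                    int(0.8 * sim.mean_cds_aa), int(1.2 * sim.mean_cds_aa) + 1)))
                pid = f"{stem}{k + 1}"
                entries.append(SeqEntry(
                    pid, protein,
                    f"{taxon} {word} {k + 1}|taxon={taxon}|db=4"))
                contaminant_ids.append(pid)
    return entries, class_proteins, hypothetical_ids, contaminant_ids


def generate_transcripts(sim: SimParams, proteome_bundle, vocabulary=None,
                         rng=None, pipeline_params: PipelineParams | None = None):
    """Plant one CDS per transcript; returns ``(transcripts, truth_records)``."""
    vocab = vocabulary or default_vocabulary()
    rng = rng or np.random.default_rng(sim.rng_seed + 1)
    params = pipeline_params or PipelineParams()
    entries, class_proteins, hypothetical_ids, contaminant_ids = proteome_bundle
    seq_by_id = {e.id: e.seq for e in entries}
    informative = list(class_proteins)
    n_core = sim.n_classes * sim.transcripts_per_class
    n_unknown = int(round(sim.fraction_unknown * n_core))
    n_uc = int(round(sim.fraction_unknown_conserved * n_core))
    n_contaminant = int(round(sim.fraction_contaminant * n_core))
    n_informative_tx = n_core - n_unknown - n_uc
    per_class = [n_informative_tx // len(informative)] * len(informative)
    for i in range(n_informative_tx % len(informative)):
        per_class[i] += 1

    plan = []  # (class_label, source_id or None, want_signal, contaminant, taxon)
    for label, n_tx in zip(informative, per_class):
        sources = class_proteins[label]
        for k in range(n_tx):
            want_signal = bool(rng.random() < sim.fraction_signal_peptide)
            plan.append((label, sources[k % len(sources)], want_signal, False, "tick"))
    for k in range(n_uc):
        plan.append((UNKNOWN_CONSERVED, hypothetical_ids[k % len(hypothetical_ids)],
                     False, False, "tick"))
    for k in range(n_unknown):
        plan.append((UNKNOWN, None, True, False, "tick"))
    for k in range(n_contaminant):
        src = contaminant_ids[k % len(contaminant_ids)]
        taxon = "vertebrate" if src.startswith("vert") else "bacteria"
        plan.append(("", src, False, True, taxon))

    shapes = sim.shape_by_class
    # subjects a transcript must NOT resemble at the pipeline's score floor:
    # "unknown" CDS have no database relative at all; "unknown conserved" CDS
    # may resemble only the uninformative (hypothetical) pool.
    hyp_set = set(hypothetical_ids)
    transcripts = []
    truth = []
    for idx, (label, source_id, want_signal, contaminant, taxon) in enumerate(plan):
        tid = f"tx{idx:04d}"
        if label == UNKNOWN:
            forbidden = [e for e in entries]
        elif label == UNKNOWN_CONSERVED:
            forbidden = [e for e in entries if e.id not in hyp_set]
        else:
            forbidden = []  # a strong informative/contaminant source hit dominates

        protein = None
        forward = None
        for attempt in range(120):
            if protein is None or attempt % 12 == 11:
                if source_id is None:
                    mature = _random_protein(
                        rng, int(rng.integers(int(0.6 * sim.mean_cds_aa),
                                              int(1.0 * sim.mean_cds_aa) + 1)))
                    protein = _signal_prefix(rng) + mature[1:]
                else:
                    base = seq_by_id[source_id]
                    mutated = _mutate_protein(
                        rng, base, sim.aa_mutation_rate, keep_prefix=1,
                        min_signal_orf_aa=params.min_signal_orf_aa,
                        want_signal=want_signal)
                    protein = (_signal_prefix(rng) + mutated) if want_signal else mutated
            cds = _back_translate(rng, protein) + str(rng.choice(STOPS))
            utr5 = _random_utr(rng, *sim.utr_len_range)
            utr3 = _random_utr(rng, *sim.utr_len_range)
            assembled = list(utr5 + cds + utr3)
            cds_start = len(utr5)
            cds_end = cds_start + len(cds)
            _patch_inframe_leader(assembled, cds_start)
            candidate = "".join(assembled)
            if _has_spurious_signal(candidate, "+", cds_start, cds_end,
                                    params.min_signal_orf_aa):
                continue
            if forbidden:
                from .align import local_score

                query = _leader_translation(candidate, cds_start) + protein
                if any(local_score(query, e.seq) >= params.homology_score_min
                       for e in forbidden):
                    continue
            forward = candidate
            break
        if forward is None:
            raise RuntimeError(f"could not assemble a clean transcript for {tid}")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            seq, start, end = forward, cds_start, cds_end
        else:
            seq = revcomp(forward)
            start, end = len(forward) - cds_end, len(forward) - cds_start
        shape = "flat" if contaminant else shapes[label]
        lo, hi = sim.baseline_ranges[shape]
        baseline = float(rng.uniform(lo, hi))
        truth.append(TruthRecord(
            transcript_id=tid,
            class_label=label,
            shape=shape,
            strand=strand,
            cds_start=start,
            cds_end=end,
            protein=protein,
            signal_peptide=want_signal,
            cleavage_index=20 if want_signal else None,
            contaminant=contaminant,
            taxon=taxon,
            source_subject=source_id or "",
            baseline=baseline,
            dispersion=sim.dispersion,
            log2fc=planted_log2fc(shape, list(build_design().groups),
                                  sim.fold_change, sim.late_fold),
        ))
        transcripts.append(SeqEntry(tid, seq, f"planted class={label or 'contaminant'}"))
    logger.info("generated %d transcripts (%d contaminant, %d unknown, %d unknown conserved)",
                len(transcripts), n_contaminant, n_unknown, n_uc)
    return transcripts, truth


def generate_counts(truth, design: StudyDesign, sim: SimParams, rng=None) -> pd.DataFrame:
    """NB counts per (transcript, library) following each planted shape."""
    rng = rng or np.random.default_rng(sim.rng_seed + 2)
    if sim.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    groups = list(design.groups)
    size_factor = {
        lib.library_id: float(rng.uniform(*sim.size_factor_range))
        for lib in design.libraries
    }
    data = {}
    mult_by_shape = {
        shape: group_multipliers(shape, groups, sim.fold_change, sim.late_fold)
        for shape in ("u_shape", "induced", "flat", "late_switch")
    }
    for rec in truth:
        mult = mult_by_shape[rec.shape]
        row = np.empty(len(design.libraries), dtype=np.int64)
        for j, lib in enumerate(design.libraries):
            mean = rec.baseline * mult[lib.group] * size_factor[lib.library_id]
            if sim.dispersion == 0:
                row[j] = rng.poisson(mean)
            else:
                r = 1.0 / sim.dispersion
                row[j] = rng.negative_binomial(r, r / (r + mean))
        data[rec.transcript_id] = row
    counts = pd.DataFrame.from_dict(
        data, orient="index", columns=[l.library_id for l in design.libraries]
    )
    counts.index.name = "id"
    return counts


@dataclass
class Simulation:
    sim: SimParams
    design: StudyDesign
    proteome: list
    transcripts: list
    truth: list
    counts: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.truth:
            row = dict(
                transcript_id=r.transcript_id, class_label=r.class_label,
                shape=r.shape, strand=r.strand, cds_start=r.cds_start,
                cds_end=r.cds_end, protein=r.protein,
                signal_peptide=r.signal_peptide,
                cleavage_index=r.cleavage_index if r.cleavage_index else "",
                contaminant=r.contaminant, taxon=r.taxon,
                source_subject=r.source_subject, baseline=r.baseline,
                dispersion=r.dispersion,
            )
            for (a, b), v in r.log2fc.items():
                row[f"lfc_{a}_vs_{b}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def simulate(sim: SimParams | None = None, design: StudyDesign | None = None,
             vocabulary: Vocabulary | None = None) -> Simulation:
    """Full synthetic study: proteome, transcripts, truth and counts."""
    sim = sim or SimParams()
    design = design or build_design()
    vocab = vocabulary or default_vocabulary()
    rng = np.random.default_rng(sim.rng_seed)
    bundle = generate_reference_proteome(sim, vocab, rng)
    transcripts, truth = generate_transcripts(sim, bundle, vocab, rng)
    counts = generate_counts(truth, design, sim, rng)
    return Simulation(sim, design, bundle[0], transcripts, truth, counts)
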