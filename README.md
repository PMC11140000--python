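# ticktx

Toolkit for the transcriptome analysis of blood-feeding arthropods sampled
across a feeding timecourse — built around the kind of study that profiles
a soft tick's whole-body transcriptome in immature stages (larva, two
nymphal instars) unfed and at 6 h, 12 h, 24 h and 5 d after a blood meal,
three replicates per condition (45 libraries).

From assembled transcripts, a taxon-tagged reference proteome, and
per-library counts, the pipeline produces an annotated, quantified,
differentially-expressed catalogue of coding sequences:

1. **CDS extraction** — six-frame ORFs (>= 100 nt), accepted either by
   homology (best local alignment covering >= 70% of a database protein;
   Smith–Waterman–Gotoh, BLOSUM62, gap 11/1) or by a signal-peptide route
   (Met-initiated sub-ORFs >= 40 aa screened by an n/h/c-region heuristic,
   most-5' positive Met sets the start); vertebrate/bacterial best hits are
   flagged as contaminants.
2. **Redundancy consolidation** — greedy clustering at >= 95% nucleotide
   identity, longest sequence as representative.
3. **Quantification** — TPM per library; keep CDS with TPM >= 5 in all
   three replicates of at least one (stage, group) cell.
4. **Functional classification** — an ordered ~170-keyword vocabulary over
   25 classes scanned against ranked hit descriptions (earliest keyword in
   the first keyword-bearing description wins); no hits → "unknown", only
   uninformative hits → "unknown conserved".
5. **Differential expression** — exact conditional negative-binomial test
   per within-stage contrast (UF→6h→12h→24h→5d and UF→5d), TMM-style
   normalization, moment-based common dispersion, Benjamini–Hochberg FDR;
   significant iff |log2FC| >= 2 and q < 0.05.
6. **Profiles** — per-class percent-TPM timecourses (mean ± SD), row-wise
   Z-score heatmap with average-linkage ordering, and classical MDS of
   libraries on a leading-log-fold-change distance.

A first-class **synthetic-study generator** (`ticktx.simulate`) plants CDS,
signal peptides, contaminants, class keywords and four temporal expression
shapes (unfed-high "U", blood-meal-induced, late-switch, flat) with full
ground truth, so the whole chain is testable without any external data.
See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
from ticktx import SimParams, simulate, run_all
from ticktx.evaluate import recovery_report, de_recall

study = simulate(SimParams(rng_seed=1))       # 540 transcripts, 45 libraries
result = run_all(study.transcripts, study.proteome, study.counts, study.design)

print(len(result.records), "CDS extracted,",
      sum(r.contaminant for r in result.records), "contaminants flagged,",
      len(result.kept_ids), "kept after the TPM filter")
print(recovery_report(result, study.truth))
print("DE recall at planted |log2FC|=4: %.3f (n=%d)"
      % de_recall(result, study.truth))
```

prints

```
540 CDS extracted, 40 contaminants flagged, 500 kept after the TPM filter
RecoveryReport(class_label_recovery=1.0, contaminant_recovery=1.0, interval_recovery=1.0, n_planted=500, n_contaminant=40)
DE recall at planted |log2FC|=4: 0.998 (n=1200)
```

i.e. on the default synthetic study every planted coding interval, class
label and contaminant flag is recovered, and 99.8% of the planted 16-fold
expression changes are called significant in the right direction. The
class-level profiles in `result.class_profiles` show the planted biology:
U-shaped classes drop sharply at 6 h and recover by day 5, while the
"unknown" class is induced by the blood meal; `result.mds_by_stage`
separates each stage's libraries into the unfed / early-fed / late-fed
clusters.

The same flows are available from the shell:

```bash
ticktx simulate --seed 1 --out-dir sim/
ticktx run-all --transcripts sim/transcripts.fasta --proteome sim/proteome.fasta \
       --counts sim/counts.tsv --design sim/design.tsv --out-dir out/
```

`out/` then holds the extraction report, CDS FASTAs, cluster table, TPM
matrix, annotation TSV (the plain-text analog of an annotated-CDS
spreadsheet), per-contrast DE tables, class profiles, ordered Z-score
matrix and MDS coordinates. Individual stages (`extract-cds`, `search`,
`cluster`, `quantify`, `classify`, `de`, `profile`) run standalone and
accept externally computed hit tables (`--hits-in`) or signal-peptide
predictions (`--signal-in`).

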