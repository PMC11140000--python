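# Methods

`ticktx` reimplements, as a tested library, the analysis chain used to
characterise the whole-body transcriptome of a fast-feeding soft tick
across development and a blood-meal timecourse: immature stages (larva,
first and second nymphal instars) sampled unfed (UF) and at 6 h, 12 h,
24 h and 5 days after feeding, three biological replicates per cell —
45 libraries in all. Because the real sequencing data and the reference
databases are external, the package ships a synthetic-study generator
whose planted ground truth makes every stage testable end to end. This
note documents the models, the parameters that matter, and the design
choices taken where the procedure was genuinely open.

## CDS extraction

ORFs are enumerated in all six frames as stop-to-stop stretches of
translatable codons. Sequence ends count as boundaries; a codon containing
any non-ACGT base breaks the frame rather than translating to X, so
ambiguous runs cannot bridge unrelated ORFs. An ORF terminated by a stop
codon includes that codon in its interval, so the default 100-nt minimum
counts the stop. All coordinates are 0-based, half-open, on the forward
strand, with minus-strand features carrying a strand flag.

Two evidence routes emit a coding region from an ORF:

* **Homology.** Each ORF of >= 100 nt is aligned against a taxon-tagged
  reference proteome (optimal Smith-Waterman-Gotoh local alignment,
  BLOSUM62, gap open 11 / extend 1 in the BLAST convention; a raw score
  floor of 50 stands in for a database-size-dependent E-value, which is
  meaningless on a synthetic database). A CDS is accepted when the best
  hit covers at least 70% of the subject protein. Its 5' end is the
  alignment start pulled back to the nearest in-frame Met at or upstream
  of it; the 3' end runs through the ORF's stop codon. Homology CDS need
  not begin with Met — de novo assemblies contain 5'-truncated
  transcripts, and the coverage rule, not the start codon, is the
  acceptance criterion.
* **Signal peptide.** Every Met-initiated sub-ORF of >= 40 residues is
  screened by a transparent tripartite heuristic (below); among positive
  sub-ORFs the most 5' Met sets the start. When both routes accept one
  ORF the signal start wins (evidence `both`).

The signal heuristic models the canonical architecture rather than a
trained classifier: an n-region with at least one K/R in residues 2–6, an
h-region window of 7 consecutive residues within positions 6–25 whose mean
Kyte–Doolittle hydropathy exceeds 1.6, and a c-region "(-3,-1)" context —
the earliest position p in [12, 40] with small residues (A/G/S/C/T/V) at
p-3 and p-1 — giving the cleavage point. It is deliberately simple and
deterministic; an externally computed prediction table can be supplied to
replace it (`--signal-in`), which is how a trained predictor slots in.

**Contaminants.** A CDS whose best hit carries a vertebrate or bacterial
taxon tag is flagged unless a non-contaminant hit scores within 10 score
units of the best (an ambiguity margin; the field practice "remove
vertebrate/bacterial sequences" does not specify a rule, so the margin is
this package's choice, exposed as `contaminant_margin_bits`). CDS with no
hits are kept — absence of similarity defines the "unknown" class, not
contamination.

## Redundancy consolidation

CDS sharing >= 95% nucleotide identity are consolidated greedily:
sequences sorted by (length desc, id asc) join the first existing cluster
whose representative they match, else found a new one — the semantics of
standard greedy-incremental tools. Identity is computed from a semi-global
(infix) alignment of the shorter sequence within the longer (edlib):
matching columns over alignment columns of the shorter sequence's aligned
extent, so fragments are absorbed by their full-length parent. Nucleotide
(not protein) identity is used, matching how assembly redundancy is
normally removed.

## Quantification and filtering

Counts are taken as given (read mapping is out of scope; the counts file
is an input). TPM uses the CDS length as effective length:
`rate = count / length_kb`, `tpm = rate / sum(rate) * 1e6` per library.
The expression filter keeps a CDS when TPM >= 5 in **every** replicate of
at least one (stage, group) cell, the comparison inclusive. Filtering runs
after contaminant removal.

## Functional classification

An ordered vocabulary maps hit descriptions to classes: 25 classes, the
last two ("unknown conserved", "unknown") rule-assigned. Hits are walked
in rank order — (score desc, database priority asc, subject length desc,
subject id asc), a total order — and the first keyword-bearing description
decides; within it, the keyword with the smallest character offset wins,
ties broken by vocabulary order. No hits at all → "unknown"; hits but no
keyword (typically "hypothetical protein" entries) → "unknown conserved".
Matching is case-insensitive and whole-word, phrases allowed.

The shipped vocabulary (25 classes, 167 keywords drawn from the families
that dominate tick sialotranscriptomes: metalloproteases, Kunitz and other
proteinase inhibitors, lipocalins, mucins, storage proteins, housekeeping
machinery, ...) is a reconstruction, not a published list, and is fully
user-replaceable; the loader rejects a keyword appearing in two classes.
A positive signal-peptide call is reported as its own column and never
promotes a CDS into the "secreted" class — no such rule is documented for
the original annotator.

## Differential expression

Within each stage, five pairwise contrasts follow the feeding timecourse:
UF→6h, 6h→12h, 12h→24h, 24h→5d and UF→5d.

* **Normalization** is a trimmed-mean-of-log-ratios factor per library
  against the library of median depth: CDS zero in either library are
  dropped, the 30% tails of the log-ratios and 5% tails of mean
  log-abundance trimmed, and the factor is the precision-weighted mean of
  the remaining log-ratios, with factors rescaled to geometric mean 1.
* **Dispersion** is a single common NB dispersion φ (variance μ + φμ²)
  estimated by the method of moments within replicate cells and summarised
  by the median across CDS with normalized mean > 5. The median of the raw
  per-CDS moments is biased low at few replicates (the statistic is driven
  by a chi-square with df = Σ(n_cell − 1), whose median sits below its
  mean); each per-CDS value is therefore rescaled by
  `q = median(chi2_df)/df` (plus the matching mean-offset term) before the
  median. At df = 4 the correction is ~19%; it vanishes as replication
  grows. Without it the exact test is measurably anti-conservative
  (empirically ~0.075 at the nominal 0.05 under the package's own null
  simulation); with it the null rejection rate is ~0.052.
* **The exact test**: counts are scaled to the common effective library
  size and rounded; the two group sums a and b — NB(n_A·μ, φ/n_A) and
  NB(n_B·μ, φ/n_B) — are compared conditionally on T = a + b by summing
  the probabilities of all splits no more likely than the observed one.
  At φ = 0 the conditional law is exactly Binomial(T, n_A/(n_A+n_B)), and
  the tests verify both that limit and the φ > 0 case against a
  Monte-Carlo oracle. log2 fold changes come from normalized group means
  with a prior count of 0.125 so zero groups stay finite.
* **Significance**: Benjamini–Hochberg within each contrast;
  a CDS is called when |log2FC| >= 2 (inclusive) and q < 0.05.

Common dispersion only — no tagwise shrinkage, no GLMs, no batch terms:
a deliberate simplification that keeps the stage exact and deterministic
at desk scale.

## Profiles, heatmap, MDS

Class profiles are percent TPM (class sum / 10^6 × 100, a partition of
100% per library), averaged with SD across the replicates of each cell.
The heatmap layer is row-wise Z-scores (sample SD; constant rows → 0) with
average-linkage Euclidean leaf orders on rows and columns, computed after
sorting by id so the layout is input-order invariant. Sample MDS is
classical (Torgerson) scaling of a leading-fold-change distance: per
library pair, the root-mean-square of the 500 largest |log2 ratios| of
TPM + 0.5. The first two principal coordinates are reported with the
largest-magnitude loading of each axis made positive. `top_n = 500` and
the 0.5 prior are fixed, logged choices.

## The synthetic study

The generator emulates the study's conditions, not its sequences:

* **Design**: 3 stages × 5 feeding groups × 3 replicates (45 libraries).
* **Classes**: 25; 20 transcripts per class (500 planted transcripts),
  plus 8% contaminant transcripts (vertebrate/bacterial sources). The
  "unknown" class (4%) carries novel secreted proteins with no database
  relative; "unknown conserved" (4%) derives from a pool of "hypothetical
  protein" database entries.
* **Sequences**: each planted CDS is a back-translation (uniform random
  synonymous codons, keeping nucleotide identity between paralogs low) of
  a mutated copy (3% residue substitutions, termini spared) of a database
  protein, flanked by 30–150 nt UTRs on a random strand. 30% of
  informative-class transcripts (and all "unknown" transcripts — a CDS
  with no homology evidence must enter through the signal route, as in the
  real pipeline) start with a 19-residue signal peptide the heuristic
  accepts, cleavage after residue 19.
* **Counts**: NB(μ·s_l, φ = 0.1) with library size factors s_l ~ U(0.7,
  1.3). Four temporal shapes drive μ per group: `u_shape` (high unfed,
  16-fold down while feeding, recovered at day 5), `induced` (the mirror:
  16-fold up at 6–24 h), `late_switch` (near zero until a 64-fold rise at
  day 5) and `flat`. Class→shape assignment: the blood-meal classes
  (proteinases, their inhibitors, lipocalins, mucins, extracellular
  matrix, immunity, oxidant metabolism, secreted, unknown conserved) are
  U-shaped; "unknown" is induced; storage switches late; the 14
  housekeeping classes are flat. The 16-fold amplitude (|log2FC| = 4)
  sits well past the |log2FC| >= 2 calling threshold, and keeping the
  majority of transcripts flat is what makes trimmed-mean normalization
  valid — a transcriptome in which nearly everything changes 16-fold is
  not normalizable from counts alone.
* **Ground-truth hygiene.** The generator guards recoverability of its own
  truth: in-frame leader ATGs upstream of a planted start are patched out;
  non-signal proteins are rejection-sampled until no Met suffix fools the
  signal heuristic; assemblies are resampled until no decoy signal-positive
  Met-ORF exists outside the planted ORF (such decoys, being superstrings
  of the planted CDS in another frame, would absorb it at clustering); and
  "unknown"/"unknown conserved" transcripts are resampled until they have
  no chance alignment at the score floor to forbidden subjects — at
  ~780k query×subject comparisons, random local alignments at score 50
  are not rare.

What the generator does **not** emulate: read-level sequencing error,
fragment-length effects on effective length, multi-mapping ambiguity,
assembly chimerism/fragmentation, tagwise dispersion variation, and
batch structure. Passing tests therefore demonstrate the pipeline's
correctness and calibration under its stated model, not robustness to
those real-data pathologies.

## Problem sizes and determinism

Default desk-scale sizes — 540 transcripts, 135 database proteins,
45 libraries — keep a full run around 1–2 minutes on one core while
leaving every class with enough members for profile statistics. All
randomness flows from explicit seeds (`SimParams.rng_seed`, CLI `--seed`);
repeated runs are byte-identical. The null-calibration check uses 20
simulations of 2000 CDS at φ = 0.1, 3 vs 3 replicates.

## Known limitations

* The homology stage is full dynamic programming (no seeding); it is
  quadratic and meant for desk-scale databases, not NR.
* The signal heuristic trades sensitivity/specificity for transparency;
  on random Met-ORFs it fires at a few percent, which is why external
  predictions are pluggable.
* The score floor (50) replaces E-values and is not database-size aware.
* One CDS per ORF; no sub-optimal alignment stitching, frameshift repair
  or UTR annotation.
* The exact test assumes a common dispersion; strongly gene-specific
  overdispersion will be under- or over-called relative to a tagwise
  method.
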