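# Methods

## Scope and model of the data

A neuropeptide precursor (prohormone) is modelled as: an N-terminal signal
peptide, then one or more copies of a mature peptide, each flanked by
two-residue cleavage sites that are basic (K/R), acidic (D/E), mixed or
other. An amidated peptide is followed in the precursor by a glycine whose
backbone nitrogen becomes the C-terminal amide during PAM-catalyzed
maturation; an N-terminal Q or E may cyclize to pyroglutamate. All
coordinates are 0-based, half-open.

## Mass chemistry

Residue and modification masses are derived from hard-coded monoisotopic
atomic masses (H 1.00782503207, C 12, N 14.0030740048, O 15.9949146196,
S 31.97207100; proton 1.00727646688 Da), so the four modification deltas are
consequences of the chemistry rather than constants: amidation replaces the
C-terminal OH with NH2 (N+H−O = −0.98402 Da), pyroGlu from E loses water
(−18.01057), from Q loses ammonia (−17.02655), Met oxidation gains O
(+15.99491). Theoretical spectra contain b and y ions for charge states up
to the precursor charge; the C-terminal amide shifts only y ions,
pyroglutamate only b ions, oxidized methionines whichever fragment contains
them. m/z = (M + z·proton)/z.

Spectral comparison (endogenous vs synthetic peptide validation) uses
cosine similarity after greedy nearest-peak matching within a tolerance
(default 0.3 Da, the fragment tolerance of the searches): candidate pairs
are taken in order of ascending m/z difference, ties toward lower m/z;
unmatched peaks contribute zero to the dot product but remain in the norms,
bounding the score in [0, 1]. The similarity statistic itself is this
package's choice — the comparison step it implements is usually presented
visually.

## PSM curation

Stage order: (1) remove every PSM whose precursor protein has a
domain/motif hit outside the configured neuropeptide-related set at
e ≤ 1e-10 (ordinary proteins, not prohormones); (2) keep C-terminally
amidated identifications; (3) one representative per precursor — highest
score, ties broken toward the longer peptide (truncation products are
common preparation artefacts), then lexicographically. The pipeline is
idempotent and each stage returns a subset of its input. Scores are kept
engine-local; no cross-engine rescoring is attempted. The allowed-motif
list is configuration, not code.

## Precursor annotation

Peptides are located by exact substring search (all occurrences, overlaps
allowed; absences are reported, never dropped silently). The N-terminal
cleavage site is the 2 residues preceding the span; the C-terminal site is
the 2 residues following it, skipping one glycine when the peptide is
amidated (the donor is part of the linker, not the site). Sites truncated
by the precursor boundary are omitted, not fabricated. Context matrices
cover site (2) + flank (6) residues on the precursor side of each junction
— geometry configurable, since published logo layouts are ambiguous about
peptide-side residues; out-of-bounds positions are gap-padded and excluded
from frequency normalization. Mono-basic cleavage is classified "other":
only two-residue sites are modelled.

## Precursor similarity clustering

Pairwise similarity is the optimal Smith–Waterman local alignment score
(BLOSUM62; NCBI-convention affine gaps, existence 11, extension 1, i.e. a
gap of length L costs 11 + L), computed with Biopython's PairwiseAligner.
Scores become e-values via the Karlin–Altschul form E = K·m·n′·exp(−λS)
with the published gapped-BLOSUM62 constants λ = 0.267, K = 0.041 and
effective space m × (total database residues). Edges are kept at E ≤ 1e-5;
clusters are connected components — the upstream network tool lays out, but
does not partition, so components are the explicit interpretation here.
Hits are undirected (max score per unordered pair); reciprocity is not
required. Non-standard residues map to the matrix wildcard X with a logged
warning.

## Peptide–GPCR prediction

Descriptors use the five z-scale physicochemical components per residue
(Sandberg et al. 1998). The peptide descriptor (37-dim) is the z-scale mean
over the sequence, the position-specific z-scales of the 3 N-terminal and 3
C-terminal residues, the length, and an amidation indicator; the receptor
descriptor (35-dim) is the per-segment z-scale mean of the seven
transmembrane segments in order. Receptors without exactly seven annotated
TM segments are excluded from prediction. These descriptor definitions are
a documented stand-in with the same outer-product architecture as the
original compound–protein-interaction model, whose exact peptide-descriptor
construction lives in prior work; they are swappable components.

A pair is featurized as the row-major linearized outer product (37×35 =
1295 features). Non-interactions for training are random peptide×receptor
recombinations of the positive set, excluding positive pairs, at a 1:1
ratio by default. The classifier is an RBF SVM behind a standardizing
scaler, with Platt-calibrated probabilities in [0, 1]; training is
deterministic under a fixed seed. Defaults C = 10, gamma = "scale"; a
fixed-seed cross-validated grid search is available (`hyperparams="grid"`)
but is not the default because recovery proved insensitive to it and
calibrated grid search is costly.

Numerical note: calibrated probabilities saturate at 1.0 for strong pairs
(differences ~1e-10), making rankings among them meaningless; predictions
therefore also carry the uncalibrated decision margin, which is monotone
with the probability and keeps full precision, and the assignment step
ranks by it. Receptor assignment follows the communication-score rule: each
receptor is assigned to the peptide on which it attains its maximum score
(ties by peptide identifier), then each peptide keeps at most its five best
assigned receptors — a partial matching on the receptor side.

Family representatives: a family that is a pure length-variant ladder (all
members C-terminally aligned substrings of the longest) is represented by
the longest form; otherwise by the edit-distance medoid (ties: longer, then
lexicographic; a second representative on an exact tie). At most two.

## Single-cell stage

Counts are normalized per cell to a fixed library size (value/total ×
scale; 1,000 or 10,000 molecules depending on dataset depth), with per-cell
totals computed before the gene filter so removed genes still contribute;
genes with <10 total UMIs are then dropped. Cluster summaries are
arithmetic means of normalized values per annotated cluster (median by
flag); dot-plot export scales each gene row by its maximum (z-scoring is an
alternative the source plots do not disambiguate; max-scaling is the
default). One homologue per gene family is chosen by the largest summed
cluster mean. A peptide's target profile is the element-wise sum of its
assigned receptors' cluster means; receptors absent from the matrix are
reported, and lineage-specific cluster masking is a configuration list, not
an automatic rule. Cell clustering itself is an input.

## Synthetic world

All generators draw from labelled sub-streams of one master seed and are
byte-reproducible; manifests record the planted truth and are re-verified
against the emitted sequences at generation time.

* **Precursors** (default 50; 200 in the annotation benchmark): signal
  peptide (M + 17–23 hydrophobics), 1–4 copies of a 6–16-residue peptide
  whose alphabet excludes K/R/D/E/G (so sites and donors cannot arise
  inside peptides), sites drawn basic with probability 0.7 else acidic, a
  donor G after amidated copies (80%), and a C-terminal aromatic bias that
  is purely cosmetic. Accidental extra peptide occurrences are rejected and
  redrawn.
* **PSM tables** (1,000 records in the benchmark): the true amidated
  peptide of each precursor gets its precursor's top score; decoys are
  truncation variants, free-acid forms, and contaminant-precursor records
  whose precursors carry a disallowed motif hit below 1e-10. Benign hits
  (allowed motif, or disallowed above the cutoff) are planted on true
  precursors to exercise the filter's negative space.
* **CPI tables** (150 peptides × 300 receptors; 600 positives + 600
  shuffle negatives): the truth is a bilinear form b(p,r) = z(p)ᵀWz(r) on
  z-scored descriptors. W is random noise plus a rank-one term per cognate
  pair (12 by default, strength 0.5) aligned with that pair's descriptor
  directions — co-evolved pairs get an affinity gap over background, while
  the label rule stays exactly "b exceeds a threshold". Interactions are
  the top 1.5% of the grid (sparse, like real ligand–receptor matrices);
  negatives come from the bottom tail, so shuffle negatives are rule-false
  when label noise is zero. With iid-style bilinear values and no cognate
  structure, per-receptor runner-ups sit at the threshold by order
  statistics and no classifier could recover a ≥90% benchmark from binary
  labels; the cognate construction is what makes the recovery benchmark
  well-posed. Receptors with 5 or 6 TM segments are added as distractors
  for the 7-TM filter.
* **UMI matrices** (2,000 genes × 5,000 cells, 8 clusters): negative
  binomial counts (dispersion θ = 2), gene baselines lognormal around 0.1
  UMIs/cell (≈ a few hundred UMIs per cell, like shallow whole-organism
  atlases), markers (including the planted receptor genes) at baseline 1.0
  elevated 8-fold in a home cluster, plus ~20 genes planted below the
  10-UMI filter.

What a green test establishes: that the implementations recover exactly
what was planted under the stated noise model. The generators do not
emulate chimeric spectra, shared peptides between precursors, batch
effects, ambient RNA, receptor families with correlated sequences, or
cross-species homology — so green tests say nothing about robustness to
those.

## Determinism and numerics

Every stochastic step is seeded (master seed → labelled sub-streams; SVM
internals under `random_state`); two runs of the pipeline with one config
are byte-identical, with no timestamps in outputs. Tables are written with
fixed float formats. Tolerances: modification deltas asserted to 1e-4 Da
(the precision of the printed search parameters); context-matrix frequency
normalization to 1e-9; alignment scores are exact integers in matrix units.

## Known limitations

No FDR/decoy modelling; no spectrum prediction (identification-level
simulation only); no de novo signal-peptide or TM-segment prediction
(annotations are inputs; the generator's TM geometry is synthetic); e-value
constants cover the BLOSUM62 11/1 regime only; the SVM transfers nothing
from the original trained model — at desk scale the dataset-level counts of
the source study are out of reach by construction.
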