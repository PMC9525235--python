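# neuropep

A toolkit for mass-spectrometry-driven neuropeptidomics of basal metazoans
(comb jellies, sea anemones, sponges — any organism whose peptide repertoire
is being charted from scratch). It covers the computational stages between a
search engine's peptide-spectrum matches and a map of which cell types each
neuropeptide talks to:

1. **PSM curation** (`psm_filter`) — remove identifications whose precursor
   protein carries a non-neuropeptide domain hit (e ≤ 1e-10), keep
   C-terminally amidated peptides (the −0.98402 Da hallmark of secreted
   neuropeptides), and pick one top-scoring representative per precursor.
2. **Precursor annotation** (`precursor_annot`) — locate mature peptides in
   their precursors, classify the 2-residue cleavage sites as basic (K/R),
   acidic (D/E), mixed or other, check the glycine amide donor and
   N-terminal pyroglutamate, and build logo-ready position × amino-acid
   frequency matrices for the sites plus 6-residue flanks.
3. **Mass chemistry** (`masschem`) — monoisotopic masses and b/y fragment
   spectra for peptidoforms, with modification deltas derived from atomic
   composition (amidation −0.98402, pyroGlu from E −18.01057, from Q
   −17.02655, Met oxidation +15.99491 Da), and a greedy-matched cosine
   similarity for validating endogenous spectra against synthetic peptides.
4. **Precursor clustering** (`precursor_cluster`) — all-against-all
   Smith–Waterman similarity (BLOSUM62, affine 11/1 gaps), Karlin–Altschul
   e-values, edges at e ≤ 1e-5, clusters as connected components.
5. **Peptide–GPCR prediction** (`gpcr_pred`) — peptide and 7-TM receptor
   z-scale descriptors, linearized outer-product features, a calibrated
   two-class SVM scoring every pair in [0, 1], shuffle-generated negatives,
   receptor-to-peptide assignment (each receptor to its best peptide, at
   most five receptors per peptide).
6. **Single-cell target mapping** (`sc_expression`) — per-cell UMI
   normalization to a fixed library size, the <10-total-UMI gene filter,
   per-cluster mean expression (dot-plot matrices, max-scaled per gene),
   highest-expressed homologue per family, and peptide target profiles as
   the sum of assigned receptors' cluster means.
7. **Synthetic data** (`synthetic_data`) — generators with ground-truth
   manifests for every input above, so the whole pipeline is testable
   offline, plus an orchestrator (`pipeline`) and a CLI (`neuropep`).

## Worked example

```python
from neuropep.masschem import Peptidoform, monoisotopic_mass, by_fragments

npwa = Peptidoform("IGSDIKLVPGAGGNPW", c_amidated=True)   # the NPWa peptide
print(round(monoisotopic_mass(npwa), 5))   # 1578.85183  (neutral, Da)
print(len(by_fragments(npwa, charge=2).peaks))  # 60 theoretical b/y peaks
```

End-to-end on synthetic data (also: `neuropep run-all --seed 0 --out out/`):

```python
from neuropep.pipeline import PipelineConfig, run
manifest = run(PipelineConfig(seed=0), "out")
print(manifest["stages_run"])
# ['filter', 'annotate', 'cluster', 'predict', 'targets']
```

This writes, among others, `curated_psms.tsv` (31 curated identifications
for seed 0), `clusters.tsv` (the precursor similarity partition),
`assignments.tsv` (receptor→peptide assignments) and `peptide_targets.tsv`,
the peptide × cell-cluster target table whose rows are sums of each
peptide's assigned receptors' normalized cluster means — e.g. for seed 0:

```
peptide_id     C00     C01     C02     C03 ...
PEP003      640.50   69.18   75.25   82.69
PEP009       92.17  659.60   80.51   75.17
PEP010      154.00  179.40  739.48  167.24
```

Each peptide's hottest cluster (640.5 molecules per 10,000 UMIs for PEP003
in C00, and so on) is the cell type its predicted receptors are most
expressed in — its putative target cell population.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic inputs from the seed, runs every pipeline stage
end to end (curation → annotation → clustering → prediction → target
mapping) and writes the results JSON.

## Documentation

`docs/methods.md` describes the models, parameter choices, the synthetic
world and its limits, and numerical decisions.
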