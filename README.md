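# crysprop

Sequence-based prediction of protein crystallization propensity.

Solving a protein structure by X-ray crystallography means surviving a
pipeline of experimental steps — cloning, production of protein material,
purification, crystallization, and growth of diffraction-quality crystals —
and most targets fail somewhere along the way. Structural-genomics centers
therefore triage candidate targets by predicted propensity to pass each
step. `crysprop` implements such a predictor end to end for
bioinformaticians and structural biologists: it encodes a protein sequence
into a large physicochemical candidate feature set, selects informative
features, trains stacked probability classifiers for the five pipeline
steps, and bins targets into five difficulty tiers.

## The method

**Five prediction tasks.** Targets from crystallization-trial registries
are assigned to five classes by their final trial status: CLF (cloning
failed; status `selected`), MF (material production failed; `cloned`,
`expressed`), PF (purification failed; `soluble`, `purified`), CF
(crystallization failed; `crystallized`, `diffraction`, `poor diffraction`)
and CRYS (crystallizable; `crystal structure`, `in PDB`). Each task is a
binary problem with composition rules that condition on reaching the step
(for example the purification task uses only PF as negatives and CF ∪ CRYS
as positives, excluding upstream failures).

**2,924 candidate features.** For a sequence s of length N with per-residue
secondary-structure (H/E/C), disorder (D/O) and burial/exposure (B/E)
tracks:

* 3 × 544 AAindex features — for every property scale P in a 544-entry
  AAindex snapshot, the mean P over all residues, over exposed residues,
  and over buried residues;
* 1,060 PROFEAT-style descriptors — dipeptide composition (400),
  normalized Moreau–Broto, Moran and Geary autocorrelation (3 properties ×
  30 lags each), composition/transition/distribution over seven 3-class
  physicochemical partitions (21 + 21 + 105), quasi-sequence-order
  descriptors over two residue-distance matrices (160), amphiphilic
  pseudo-amino-acid composition (80), and total amino-acid properties (3);
* 232 sequence/structure features — amino-acid and grouped compositions,
  exposure/secondary-structure/disorder segment statistics, cross-track
  combinations (e.g. frequency of exposed His), and global properties
  (length, pI, net charge, hydropathy, ...).

**Feature selection.** Features are ranked by mRMR (minimum redundancy,
maximum relevance): greedily maximize I(f; y) − mean I(f; g) over selected
g, with plug-in mutual information on tercile-discretized features. The
one-step strategy ranks all 2,924 candidates and keeps 300; the two-step
strategy first keeps 100 from each of the three AAindex blocks, then ranks
the 300-feature pool together with the 1,292 non-AAindex candidates
(1,592 in all) and keeps 300. A wrapper stage — IFS (evaluate ranked
prefixes) or FFS (greedy forward selection) — then picks the subset whose
5-fold cross-validated AUC is maximal.

**Two-level stacking.** Level-1 is one probability-output SVM per task
(POLY/RBF/sigmoid kernels, C and γ tunable by grid search). Level-2 takes
the 5-vector of level-1 probabilities as input, one SVM per task, trained
on out-of-fold level-1 predictions so no model ever scores a row it was
trained on. The final crystallizability probability maps to difficulty
tiers: Optimal (≥ 0.6), Suboptimal ([0.55, 0.6)), Average ([0.45, 0.55)),
Difficult ([0.2, 0.45)), Very difficult (< 0.2).

The bundled AAindex snapshot leads with genuine published scales
(Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, flexibility,
polarizability, polarity, van der Waals volume, helix/strand propensity)
and pads to the 544-entry count with clearly labelled synthetic scales;
see `docs/methods.md`.

## Worked example

```sh
crysprop simulate --kind sequences --n 12 --seed 3 --out seqs.fa
crysprop encode seqs.fa --out feats.tsv
crysprop train feats.tsv labels.json --seed 0 --out model.bundle
crysprop predict seqs.fa model.bundle --out preds.tsv
head -3 preds.tsv
```

```
protein_id  CLF      MF       PF       CF       CRYS     tier
syn00001    0.26229  0.51065  0.43819  0.41471  0.77926  Optimal
syn00002    0.26229  0.51065  0.43819  0.41471  0.77926  Optimal
```

Each row gives the predicted probability that the protein passes cloning
(CLF column), material production (MF), purification (PF), crystallization
(CF) and yields a solved structure (CRYS), plus the difficulty tier derived
from the CRYS probability. `crysprop prioritize` sorts targets by the CRYS
column, best first. (`labels.json` maps each task to per-protein 0/1
labels; the probabilities above come from a demonstration model trained on
random labels, which is why the rows coincide.)

The library surface mirrors the pipeline: `crysprop.features.encode_all`
(encoding), `crysprop.select` (mRMR/IFS/FFS), `crysprop.mlcore`
(SVMs, stacking, tiers), `crysprop.datasets` (status-record filtering,
class assignment, redundancy reduction, splits, simulators) and
`crysprop.evaluate` (metrics, ROC, correlations, feature contribution).

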