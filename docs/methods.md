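# Methods

This note records the scientific and numerical choices behind `crysprop`:
what the models assume, which parameters matter, what the synthetic
generators do and do not emulate, and where the design was genuinely open.

## Problem setting

A crystallization target either fails at one of four experimental steps —
cloning, production of protein material, purification, crystallization
(including diffraction quality) — or yields a solved structure. Class
labels come from trial registries: each target's trials are filtered
(authentic stop status, 2006–2010 date window, X-ray method) and collapsed
to the most advanced status, which maps to one of five classes
(CLF/MF/PF/CF/CRYS). Five binary prediction tasks are built with
composition rules that condition on reaching the step; e.g. the
purification task contrasts PF negatives against CF ∪ CRYS positives and
excludes CLF/MF targets, which never reached purification. The status
precedence chain is total (`selected < cloned < expressed < soluble <
purified < purification failed < crystallization failed < crystallized <
poor diffraction < diffraction < crystal structure < structure successful
< in PDB`); statuses that appear only in class definitions are slotted
next to their pipeline stage. Status matching is case- and
whitespace-insensitive.

## Candidate feature set (2,924 features)

The registry is fixed and fingerprinted; every encoder is a pure function
of (sequence, annotation, parameters).

| block | size | notes |
|---|---|---|
| AAindex seq/exposed/buried | 3 × 544 | mean property per scale over all/exposed/buried residues; an empty exposure class falls back to the whole-sequence mean |
| dipeptide composition | 400 | n_ab/(N−1), row-major over the alphabetical alphabet |
| Moreau–Broto / Moran / Geary | 3 × 90 | 3 properties (hydropathy, flexibility, polarizability) × 30 lags; Moreau–Broto standardizes the scale over the 20 residues; zero-variance sequences and lags ≥ N give 0 |
| CTD | 21 + 21 + 105 | seven 3-class partitions; distribution reports 100·pos/N at the 1st occurrence and at k = ⌈q·n⌉ for q ∈ {.25, .5, .75, 1}; absent class → five zeros |
| quasi-sequence-order | 160 | per distance matrix: 30 raw couplings τ_d = Σ d(s_i, s_{i+d})² plus 50 normalized descriptors with weight w = 0.1 |
| amphiphilic pseudo-AA composition | 80 | λ = 30, w = 0.05; correlation terms interleave standardized hydrophobicity/hydrophilicity; the normalizer uses Σ\|τ\| so the vector sums to 1 whenever all τ ≥ 0 |
| total AA properties | 3 | sequence-summed autocorrelation scales / N |
| compositions | 87 | AA (20), five-class (5), ten functional groups (10), grouped dipeptides over five classes (25), grouped tripeptides over three classes (27) |
| annotation-derived | 145 | exposure (65), secondary structure (37), disorder (13), cross-track (20), sequence-global (10) |

Class alphabets. The three-class (tripeptide) alphabet is hydrophobic =
FIMLVYCAW, hydrophilic = RKNDEP, neutral = THGSQ; Trp is assigned
hydrophobic so the groups partition all 20 residues. The five-class
alphabet is hydrophobic = ACFILMVWY, hydrophilic = NQST, neutral = GP,
positive = HKR, negative = DE. The ten functional groups follow side-chain
chemistry (sulfhydryl M, phenyl FWY, carboxyl DE, guanidyl R, imidazole H,
primary amino K, thiol C, amido NQ, hydroxyl ST, non-polar AGILPV).

Isoelectric point. Henderson–Hasselbalch net charge over termini and
ionizable side chains (EMBOSS-style pKa values), root found by bisection on
[0, 14] to 1e-4 pH units; the charge curve is monotone decreasing so the
root is unique.

### Bundled data assets

A real 544-entry AAindex1 release is not redistributed here. The snapshot
is generated deterministically at import: eight genuine published scales
(Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity,
Bhaskaran–Ponnuswamy flexibility, Charton polarizability, Grantham
polarity, normalized van der Waals volume, Chou–Fasman helix and strand
propensities) followed by synthetic scales (ids `SYNIDX0009`…`SYNIDX0544`)
drawn once from a fixed-seed normal distribution. The synthetic entries
are structurally valid property scales but carry no biochemical meaning;
conclusions about *which* AAindex property matters cannot be read off
them, while every count, interface and algorithm exercised on the snapshot
is exactly as it would be with the real release. The Grantham distance
matrix is computed from Grantham's composition/polarity/volume formula
(reproducing the printed table to integer rounding); the second
sequence-order matrix is a synthetic physicochemical distance over
standardized hydropathy/hydrophilicity/volume, standing in for a
Schneider–Wrede-style matrix.

### Baseline annotators

External predictor output (ss2-style secondary structure, per-residue
disorder/accessibility tables) is accepted through adapters. When absent,
deterministic baselines fill the tracks so the encoder never requires
external binaries: exposure = windowed mean of standardized hydropathy
below 0 (window 9); secondary structure = argmax of windowed Chou–Fasman
helix/strand propensity against a fixed coil baseline of 1.0, ties to
coil; disorder = windowed fraction (window 21) of disorder-promoting
residues (DEKRSQPG) at or above 0.3. Windowed means average both scan
directions so a reversed sequence yields exactly reversed tracks. These
baselines are simple propensity rules — they do not emulate any particular
predictor's output numerically, and annotation-derived features computed
from them reflect the rule, not true structure.

## Feature selection

Mutual information uses equal-frequency tercile discretization with a
stable tie-break; a feature with at most three distinct values keeps those
values as categories (a binary feature scores as itself; a constant
carries zero information) and the statistic is rank-invariant. mRMR uses
the difference criterion; scores are compared at 1e-12 resolution so
mathematically tied candidates break to registry order deterministically.
One-step selection ranks all 2,924 features and keeps 300. Two-step
selection keeps 100 per AAindex block, then ranks the 300-feature pool
with the 1,292 non-AAindex features (1,592 candidates) and keeps 300.

IFS evaluates ranked prefixes by stratified 5-fold cross-validated AUC and
returns the prefix with maximal AUC, smallest prefix on ties. FFS adds the
single best candidate per round and stops when the improvement is ≤ 1e-4
AUC (the first round is always accepted). Wrapper cross-validation scores
folds with the SVM decision function — rank-identical to the calibrated
probability and several times cheaper; the final deployed models are
probability-calibrated.

## Classifiers and stacking

Classifiers are support-vector machines (scikit-learn's libsvm binding)
behind a standardization step whose statistics are frozen at training.
Kernels POLY/RBF/sigmoid; `coef0` is set to 1 for POLY and sigmoid — the
homogeneous odd polynomial can globally invert its decision scores on
near-degenerate inputs. Grid search maximizes mean stratified 5-fold CV
AUC over (kernel, C, γ), first grid point winning ties. No class
re-weighting is applied: the tasks are trained on their natural
imbalance.

The production stacked model trains level-2 on out-of-fold level-1
probabilities (5-fold), so no row's meta-features come from a model that
saw it; inference uses the full level-1 models. Level-2 input is always
the complete 5-vector of task probabilities. The default level-2
configuration is a polynomial kernel with C = 1, γ = 0.1 — a smooth,
near-linear combiner appropriate for five probability-scale inputs.

### Measuring the stacking effect

Whether level-2 beats level-1 is a statement about *information routing*,
and it depends on each task's first-level model being trained on its own
corpus: the other tasks' outputs then carry signal from targets (and
shared-signal estimates) the task's own model never saw. With a single
common training set the task's own level-1 output already contains all
predictable signal, and a second-level combiner can only pay estimation
cost — no protocol choice changes that. `mlcore.stacking_experiment`
therefore mirrors the production setting: rows are partitioned into five
disjoint level-1 training sets (one per task), a stacking set for training
level-2, and an untouched test set on which both levels are scored. No
model scores a row it was trained on, by construction. Defaults: n = 2000
proteins, p = 60 features, k = 10 informative per task, effect δ = 0.5,
shared-signal fraction ρ as specified by the caller. Under shared signal
(ρ = 0.8) the five level-1 outputs are complementary noisy estimates of
the shared component and level-2 gains ≈ 0.03 AUC on average; with
independent tasks (ρ = 0) it matches level-1 to within ±0.02.

## Synthetic generators

`simulate_sequences` draws i.i.d. sequences (uniform lengths, configurable
residue composition). `simulate_status_records` plants a class per target
and emits a consistent trial history — a final in-window X-ray trial, up
to three less-advanced earlier trials, and decoys (pre-window dates,
non-X-ray methods, work-in-progress stop conditions) that the filters must
remove; in-progress decoys never carry a terminal status, which would be
self-contradictory. `simulate_planted` emits a standard-normal feature
table with a shared latent factor realized as the normalized sum of a
dedicated feature subset and per-task informative subsets; labels follow

    logit_t = δ·√k·(√ρ·z + √(1−ρ)·s_t)

so ρ is exactly the fraction of signal variance shared between tasks, and
ρ = 0 reduces to independent logistic models with per-feature effect δ.

What passing these tests shows — and does not. The generators exercise the
algorithms under known ground truth: filtering semantics, selection
recovery, stacking direction, metric correctness. They do not reproduce
real sequence statistics (no homology structure, no length/composition
biases of real registries), real predictor annotations, or the actual
feature–outcome relationships of crystallization data; measured AUCs here
say nothing about performance on real targets.

## Numerical conventions and degenerate inputs

Zero-variance sequences give 0 for Moran/Geary; lags and couplings beyond
the sequence length give 0; an absent CTD class gives five zeros; an empty
exposure class falls back to the whole-sequence mean; sequences shorter
than 2 (dipeptides) or 3 (tripeptides) give zero blocks. Metric
denominators of zero yield 0 with a degeneracy flag rather than an
exception; AUC uses average ranks (half credit for ties). AAindex `NA`
values are imputed with the index's mean over available residues. Feature
tables round-trip TSV at full precision (`%.17g` with round-trip float
parsing). Model bundles embed a format version and refuse to load
mismatched or truncated payloads.

## Known limitations

* The 232-slot sequence/structure block layout is canonical to this
  package (stable, documented ids) rather than a reproduction of any
  external per-feature list; likewise the registry's block order.
* The synthetic AAindex tail and the second sequence-order matrix make
  per-feature *identities* in those blocks uninterpretable (counts and
  algorithms are unaffected).
* Redundancy reduction implements greedy longest-first clustering with
  global-alignment identity; it honors the ≥ threshold contract but is not
  a word-heuristic clustering tool and is quadratic in corpus size.
* Difficulty-tier fractions and absolute benchmark AUCs on real corpora
  are out of reach without the original trial registry snapshot and
  external structure predictors; the package measures its claims on
  synthetic conditions instead.
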