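# Methods

## Problem setting

Primary single-concentration HTS flags actives against a target; a
counter-screen ("artefact") assay repeats the measurement with every
detection component except the target. Activity there indicates
interference with the detection technology itself (a CIAT), not target
engagement. The package models three widely used technologies
(AlphaScreen, FRET, TR-FRET) but is agnostic to the names: a technology is
just a group of assays sharing a detection chemistry and an interference
mechanism.

## Curation model

Raw results are long tables of (compound, assay, flag, flag source).

* **Flag reconciliation** (per compound × primary assay). Z-score-derived
  flags are considered whenever a conclusive one exists; percent-effect
  flags are a fallback only. Among the considered flags, any `active`
  wins over `inactive` (single-concentration screens: an observed hit at
  the same conditions outranks a miss). Pairs with only inconclusive
  flags are dropped. "Same conditions" is interpreted as same assay id;
  concentration metadata is not modeled.
* **Labeling** (per compound × technology). Compounds active in at least
  one artefact-linked primary assay receive a label: active in *any*
  artefact assay of the technology → CIAT, inactive in all → NCIAT, no
  conclusive artefact result → excluded. Labels are derived once per
  technology; compounds labeled in several technologies are kept
  independently per technology, since interference is
  technology-specific. Artefact activity is consumed as a binary flag —
  the concentration–response thresholds that produce it are upstream of
  this package.
* Structures that RDKit cannot parse are discarded, with counts logged.

The PubChem ingestion path applies the same logic to BioAssay CSV
exports: Active→CIAT, Inactive→NCIAT, inconclusive discarded, compounds
with conflicting labels across a technology's assays discarded.

## Classifier

`RandomForestClassifier` over binary 1024-bit, radius-2 Morgan circular
fingerprints (hashed bit collisions are left to the standard scheme; no
count vectors). Hyperparameters are chosen by random search scored by the
mean Matthews correlation coefficient over a stratified 3-fold
cross-validation (two thirds train / one third validation per fold).
The default search space is {trees 100–1000, depth ∞/10/20, min leaf
1–10, features sqrt/log2}; it is configurable, and when tuning is skipped
the forest uses 300 trees, unlimited depth, sqrt features. The decision
threshold is 0.5 — probabilities are reported, and no reweighting is
applied at the observed 22–44 % class prevalences.

Two overfitting controls accompany every analysis: 10-fold stratified
cross-validation (folds disjoint in compounds) and label randomization
(shuffle the CIAT/NCIAT labels, repeat the cross-validation; AUC must
collapse to ~0.5).

## Binomial survivor function

For a compound tested in `N` distinct assays and active in `A` of them,
with pooled hit rate `h` (active results / all conclusive results over
the considered assays),

    pBSF = -log10( P(X >= A) ),    X ~ Binomial(N, h).

`pBSF >= 2` classifies a compound as interfering: a score of 2 means at
most a 1 % chance of so many actives arising by chance. A decibel-style
variant (`-10·log10`, i.e. ten times larger) is available behind the
`decibel` flag for comparability with sources that print the scaled
form; the cutoff↔1 % correspondence fixes the unscaled reading as the
default.

Numerics: the tail is evaluated as a log-sum-exp over log-binomial terms
(`gammaln`), never as naive powers, so small hit rates and large `N` do
not underflow; the single-term case `A = N` uses the closed form
`-N·log10(h)`, exact in double precision. Replicates within one assay
collapse to a single (tested, active?) pair before counting. `h` is
pooled across the considered assays; a per-assay-h generalization is out
of scope.

In leave-one-assay-out use, histories and `h` are computed over all
primary assays of the technology except the held-out one; compounds with
`N = 0` in the remaining assays are reported as unpredictable rather than
scored.

## Evaluation protocol

For each artefact-linked primary assay of a technology: train/score on
all other assays, predict the held-out assay's actives. Held-out
compounds also active in a training assay form **Set A** (previously
seen); the rest form **Set B** (novel). Training labels are the
technology-wide CIAT/NCIAT labels; the hold-out removes assay
*membership*, mirroring a prospective deployment where all accumulated
artefact evidence is available.

Metrics: MCC (0 when any denominator factor is 0), recall, precision
(0 when their denominators vanish), ROC AUC from score ranking with the
midrank tie convention (random-forest probabilities and binary PAINS
scores tie heavily). Assays with ≤ 5 CIATs among their actives, or
without Set-B compounds, appear in reports flagged excluded rather than
silently dropped. When methods are compared, metrics are computed on the
identical compound set every method can predict (BSF cannot score
never-tested compounds). Per-technology summaries average assays
unweighted; weighting by compound count is a caller-side choice.

The nearest-neighbor analysis computes, for each held-out CIAT classified
TP or FN, the mean Tanimoto similarity to its 5 nearest training CIATs
and 5 nearest training NCIATs (ties broken by training row order; k is
reduced with a warning if a class is smaller). Raw per-compound values
are the test surface; kernel-density plots are a rendering.

The scaling experiment grows BSF's assay universe from the artefact-linked
base set plus 20–100 % of the unlinked pool (`round(fraction · pool)`
assays, seeded) and tracks BSF AUC/MCC on the compounds it can predict,
against the constant RFC baseline trained once on the base assays, along
with the mean history depth per compound.

## Synthetic campaign generator

The generator emulates the *structure* of proprietary counter-screen
datasets so the pipeline is testable without them:

* a combinatorial library (scaffold templates × mid fragments × tails,
  canonicalized and deduplicated — unique, parseable structures by
  construction);
* per technology, one planted interference chemotype with a mechanistic
  rationale: benzyl thioethers (singlet-oxygen quenchers) for bead-based
  luminescence, nitroaromatics (fluorescence quenchers) for FRET,
  1,3-diketones (lanthanide chelators) for TR-FRET. These defaults are
  deliberately *not* PAINS patterns: on curated counter-screen data the
  PAINS alerts recover only a few percent of true interferers, and the
  generator reproduces that regime. A catechol fragment is planted
  independently of the labels so PAINS fires on a small uncorrelated
  background. Quinone and azo-dye fragments (which *are* PAINS) remain
  selectable for studying the overlap;
* ground truth: P(CIAT) = `p_ciat_given_motif` for carriers of the
  technology's motif (determined by substructure matching, not by
  construction flags), `p_ciat_no_motif` otherwise;
* assay structure: `n_primary_assays` artefact-linked primaries per
  technology (one artefact assay each) plus `n_extra_primary_assays`
  unlinked primaries that contribute screening history but never labels —
  real screening decks contain many more primaries than counter-screened
  ones, and the history-based score needs that depth;
* readouts: true activity at `base_hit_rate` per assay; CIATs additionally
  read out active with per-assay penetrance `ciat_primary_hit_rate`
  (interference in a single-concentration primary is strong but not
  deterministic — with deterministic interference even one prior test
  would make the history score near-perfect, which curated data
  contradict); artefact outcomes equal ground truth flipped with
  `artefact_flip_noise`; a fraction of rows carry an extra, less reliable
  percent-effect flag and ~1 % of Z-score flags are inconclusive, to
  exercise reconciliation.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| n_compounds | 20 000 | campaign scale that keeps a full evaluation in minutes on one CPU |
| technologies / motifs | 3 | AlphaScreen-, FRET-, TR-FRET-like |
| linked primaries per technology | 8 | typical counter-screened subset of a deck |
| unlinked primaries | 20 | history pool for the promiscuity score |
| motif_fraction | 0.15 | share of the library carrying each chemotype |
| p_ciat_given_motif / p_ciat_no_motif | 0.25 / 0.00625 | odds ratio 40; places cross-validated AUC at ~0.78–0.80, inside the 0.72–0.83 range reported for curated counter-screen data |
| base_hit_rate | 0.05 | single-concentration primary hit rate |
| ciat_primary_hit_rate | 0.45 | interference penetrance per primary |
| artefact_flip_noise | 0.05 | counter-screen call error |
| multiplicity (linked) | 1:0.60, 2:0.25, 3:0.15 | both Set A and Set B arise |
| multiplicity (unlinked) | 0:0.85, 1:0.12, 2:0.03 | most compounds have thin histories |
| target_ciat_prevalence | 0.224 | CIAT share among primary actives in curated training sets (20–45 % across technologies) |

Prevalence calibration solves analytically for the CIAT marginal that
yields the target prevalence among primary actives given the hit rate,
penetrance and multiplicity distribution, then rescales
(`p_ciat_given_motif`, `p_ciat_no_motif`) by a common factor — preserving
the structure→interference odds ratio — and verifies the realized
prevalence within ±0.05, with up to three reseeded retries before raising
a calibration error. All randomness flows from one seed through named
substreams (library, truth, assignment, noise); identical configurations
give byte-identical campaigns.

### What the generator does and does not emulate

It reproduces: the primary/artefact assay topology, flag-source
heterogeneity, label noise, realistic prevalences and multiplicities, and
a genuine structure→interference relationship learnable from
fingerprints. It does **not** emulate: dose–response curves or potency
thresholds, plate effects and Z-score computation (flags are consumed as
given), chemical series correlations beyond the planted fragments,
technology-specific assay panels of different sizes, or true
polypharmacology that could confound the promiscuity score. Passing tests
therefore demonstrate that the pipeline recovers planted signal under
realistic noise and protocol structure — not that any particular AUC will
be attained on a given proprietary dataset.

## Numerical and protocol choices

* MCC with any zero denominator factor → 0; recall/precision with zero
  denominators → 0.
* ROC AUC undefined (single-class slice) → NaN, excluded from averages.
* Tanimoto of two empty fingerprints → 0 (avoids 0/0; empty fingerprints
  are pathological and logged).
* Nearest-neighbor ties at equal similarity break by training row order
  for determinism.
* The bundled PAINS catalog is RDKit's FilterCatalog transcription of the
  480 published alerts (families A, B, C merged); any other SMARTS
  transcription can be loaded from a one-pattern-per-line file.
* `pbsf` guards `A > N`, hit rates outside [0, 1], and returns +inf only
  for the impossible record `h = 0, A > 0`.

## Problem sizes used by the shipped tests

The campaign-scale validation runs one 20 000-compound campaign with all
three technologies (cross-validation per technology, LOAO comparison on
one) plus a noiseless 20 000-compound campaign for exact label recovery;
the scaling experiment uses ten 3 000-compound campaigns with a deepened
unlinked-assay multiplicity so mean histories reach ~10 tests. These
sizes keep the full suite within a few minutes on a single CPU while
leaving per-assay CIAT counts well above the >5 reporting filter.

## Known limitations

* The forest sees only 2D fingerprints; interference mechanisms with 3D
  or physicochemical determinants (aggregation, solubility) are out of
  scope.
* BSF uses one pooled hit rate; strongly heterogeneous assay panels would
  warrant per-assay rates.
* The LOAO protocol shares technology-wide labels between training and
  held-out compounds in Set A by design (prospective reading); it does
  not measure generalization for those compounds, which is exactly why
  Set B is reported separately.
* PubChem ingestion trusts the exported activity outcome; no dose-response
  re-analysis is attempted.
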