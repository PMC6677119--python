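# Methods

`topoland` compares the structural feature landscape of two halves of a
bacterial proteome: the **cytoplasmome** (soluble cytoplasmic proteins,
including nucleoid-, ribosome- and peripherally membrane-associated ones)
and the **secretome** (proteins translocated across the inner membrane:
periplasmic enzymes, lipoproteins, outer-membrane β-barrels, surface and
extracellular proteins).  The working hypothesis behind the feature set is
that secreted proteins are under selection for *delayed folding*: they must
stay translocation-competent (unfolded, soluble) during cytoplasmic transit
and only fold after crossing the membrane.  That predicts a secretome
enriched in polar/small residues and intrinsic disorder, depleted in
hydrophobic patches and aggregation-prone regions, with higher backbone
flexibility, higher relative contact order and a narrower, β-rich fold
repertoire — and those contrasts are what the pipeline quantifies.

All analyses operate on **mature sequences**: the cleavable N-terminal
signal peptide (an annotation input, never predicted) is removed first, and
every residue coordinate in the package is 1-based inclusive on the mature
chain.  Per-residue predictor outputs (disorder, backbone dynamics, early
folding, aggregation propensity) are consumed as score tracks; the package
post-processes them but does not re-implement the predictors.

## Feature definitions

**Composition fractions.** Counts over non-`X` residues divided by the
non-`X` length.  Three sets follow a published composition convention in
which sets overlap (polar `DEKHRQNSCTYW`; broad hydrophobic
`ILVFYWHTCGAMK`; small `GSAC`); charged `DEHKR`, aromatic `FWY`, aliphatic
`AILV` and TOP-IDP-style disorder-promoting `ARGQSPEK` complete the
defaults.  All sets are overridable — the broad "hydrophobic" set is a
composition bookkeeping category only and deliberately *not* used for patch
calling.

**GRAVY** is the arithmetic mean Kyte–Doolittle hydropathy over non-`X`
residues.

**Isoelectric point.** Henderson–Hasselbalch net charge with the EMBOSS pKa
set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1).  The charge is strictly decreasing in pH, so the unique zero is
found by bisection on [0, 14] to |charge| < 1e-4 (~0.0001 pH units,
tighter than the 0.01 pH tolerance the tests assert against an independent
dense-grid oracle).

**Biosynthetic cost** is the mean Akashi–Gojobori cost per residue in
high-energy phosphate-bond (ATP) equivalents; the table ships as a named
constant and is swappable.

**Hydrophobic patches** are maximal runs of ≥ 5 residues from the strict
patch set `ACFILMVW` (the Kyte–Doolittle-positive core plus W).  Reported
per protein: patches per 100 residues, mean patch length, mean patch K&D
score, and the flanking peptides (default width 5, the "flanking
quintapeptides") for downstream composition analyses.

**Segment calling.** A segment is a maximal run of positions with track
score ≥ threshold, kept when its length reaches the kind's minimum (5 for
IDRs, foldons and APRs).  Defaults follow the conventions of the predictors
the tracks come from, since the analysis consumes their outputs: disorder
≥ 0.5, early folding ≥ 0.163, aggregation ≥ 5.0 on a 0–100 scale.  All are
config.  Segment positions classify as N (starting within the first 30
residues), C (extending into the last 30) or M, with N taking precedence on
short chains.

**IDRs and IDPs.** IDRs split into short (5–19 residues) and long (≥ 20).
Coverage is computed after merging overlapping/adjacent IDRs; a protein is
an IDP when merged coverage ≥ 30% (inclusive).  The eight disorder
parameters used for the classifier ablation are: IDRs per 100 residues,
coverage, the IDP flag, mean disorder score, short-IDR count, long-IDR
count, longest-IDR length, and an N-terminal-IDR indicator.

**APR gatekeepers** are the up-to-3 residues flanking each aggregation-prone
region on either side, truncated at the termini, deduplicated across APRs
and excluded when they fall inside another APR; their residue composition is
reported as frequencies over gatekeeper positions.  The 3-residue flank
width is a package default (config), chosen to cover the charge/Pro/Gly
gatekeeper motifs described for aggregation suppression without bleeding
into neighbouring structure.

**Contact order.** A contact is any heavy-atom pair between residues i and
j within 6.0 Å with j − i ≥ 1 (the original contact-order convention; a
CA-only mode exists for CA traces).  Absolute CO is the mean sequence
separation over contacts; relative CO divides by the modeled length L,
defined as first-to-last resolved residue inclusive, so unresolved interior
gaps count toward L but contribute no contacts — a convention reproducible
from coordinates alone.  rCO is invariant under rigid motion and residue
renumbering, equals 1/L for an ideal extended chain and never exceeds 1.

**Fold census.** Fold assignments (SCOP-style classes a/b/c/d, plus f for
membrane folds, excluded in the soluble-only view) are censused per
topology group: a fold is *unique* to a group when all its occurrences lie
there, *rare* when it occurs 1–3 times proteome-wide, *frequent* at ≥ 4,
and *popular* within a group when it provides ≥ 3% of that group's fold
instances.  Class composition counts each distinct fold once per group
(repertoire view); an instance-weighted alternative is the popularity
computation itself.

**Variability score.** VS = standard deviation of log2 abundance across
growth conditions.  This choice is scale-free under multiplicative noise,
exactly zero for constant rows, and invariant under global rescaling of the
matrix; a coefficient-of-variation mode is provided as an alternative, and
class boundaries accept either quartiles (default) or explicit cutoffs,
with boundary ties resolved downward.

## Group statistics and classifier

Numeric features are compared with the Kruskal–Wallis rank test (midranks,
tie correction); boolean features with Fisher's exact test (two-sided, 2×2;
chi-square for > 2 groups).  Raw p-values map to the star scheme
(*** < 0.001, ** < 0.01, * < 0.05, # ≥ 0.05); no multiple-testing
correction is applied by default, a correction being deliberately left to
the caller since the star ledger is descriptive, not confirmatory.

The cytoplasmome-vs-secretome classifier replaces an AutoML step with a
transparent, fully seeded equivalent: repeated stratified cross-validation
(10 folds × 10 repeats) around a pipeline of median imputation,
standardisation and L1-regularised logistic regression (C = 1, liblinear).
Imputation, scaling and fitting all happen inside each training fold, so no
test-fold information leaks into preprocessing — verified by a canary
feature equal to the original labels under label permutation, which scores
at chance.  The L1 penalty provides embedded feature selection; the
non-zero coefficients of a final full-data fit are reported as the
informative subset with weights.  Metrics (AUC, accuracy, per-class
precision) are fold means with seeded percentile-bootstrap 95% CIs.  The
ablation suite runs all features, non-disorder features and the eight
disorder parameters on identical CV splits so the three reports are
pairwise comparable.

## The synthetic proteome

The generator produces the *study conditions* every recovery test runs
under; its defaults are fixed once and are not tuning knobs.

* **Composition**: per-group 20-residue target vectors; each protein's
  composition is a Dirichlet draw around its group target (concentration
  400) and its sequence a multinomial draw from that.  The targets were
  chosen so that, in expectation, the secretome is higher in polar, small
  and disorder-promoting fractions and the cytoplasmome higher in
  hydrophobic, charged, aromatic and aliphatic fractions, GRAVY and
  biosynthetic cost — the qualitative contrast pattern the pipeline is
  meant to detect.  Group mean compositions converge to within ±0.01 of
  the targets by n = 500.
* **Lengths** are log-normal (median ≈ 245 residues, log-SD 0.35, floor
  60), a realistic bacterial protein length distribution.
* **Tracks**: Gaussian noise (SD 0.04 on 0–1 scales, 0.5 on the 0–100
  aggregation scale) smoothed with a 5-residue moving average to mimic the
  positional autocorrelation of per-residue predictors, around group-
  specific baselines below threshold; planted segments are plateaus at
  threshold + 3 × noise-SD (SNR 3).  IDR planting densities are 0.7
  (cytoplasmome) vs 1.1 (secretome) per 100 residues; foldon and APR
  densities favour the cytoplasmome (1.3 vs 0.9 and 0.86 vs 0.60).
* **Structures** are ideal-geometry CA traces — helix (rise 1.5 Å,
  100°/residue, radius 2.3 Å; sequence-local contacts, low rCO), extended
  (3.8 Å spacing), hairpin (two antiparallel strands 5 Å apart; long-range
  contacts, high rCO) — capped at 80 residues to keep contact maps cheap.
  The secretome receives hairpins 75% of the time, the cytoplasmome 25%,
  programming the higher-secretome-rCO contrast.
* **Abundance**: 13-condition log-normal rows, per-protein log2 mean drawn
  around a group mean (cytoplasmome higher), per-protein variability class
  drawn from a configurable mix with class log2-SDs 0.05/0.3/0.7/1.5.
* **Folds**: a declarative design (fold id, class letter, unique-to-group
  or shared, count) realised by sampling carrier proteins; the census must
  recover the design exactly.

Every programmed contrast is recorded in an effect-direction ledger
(feature → group expected higher); the end-to-end test demands each ledger
direction be recovered with p < 0.01 at 400 proteins per group.

What the generator does **not** emulate: real amino-acid ordering
(sequences are i.i.d. given composition, so there is no genuine secondary
structure or motif grammar), real predictor behaviour (tracks are noise
around planted truth, not functions of the sequence), realistic fold
geometry, phylogenetic correlation between proteins, or annotation errors.
Passing tests therefore demonstrate that the *pipeline machinery* is
correct and well calibrated — that segment callers match exhaustive scans,
statistics match enumeration oracles, planted truth is recovered — not that
the biological effect sizes on a real proteome will match.  On real data
the headline numbers depend on the reference proteome, the external
predictors and their thresholds.

## Numerical choices and degenerate inputs

* Thresholds are inclusive throughout (score ≥ threshold; coverage ≥ 30%;
  ≥ 4 occurrences = frequent; ≥ 3% = popular), and boundary behaviour is
  pinned by exact tests.
* Segment merging fuses overlapping *or directly adjacent* segments and is
  idempotent; mean scores are length-weighted on merge.
* Empty or all-`X` sequences, zero-contact structures, non-positive
  abundances, sub-minimal flank widths and out-of-bounds segments raise
  errors rather than producing silent NaNs; summaries with no called
  segments report NaN means and zero frequencies.
* Redundancy reduction is greedy longest-first (ties keep input order)
  with identity = matches / alignment length of a deterministic global
  alignment (match 1, mismatch −1, gap open −2, extend −0.5), mirroring the
  greedy incremental clustering convention of CD-HIT at a 0.90 threshold.
  The exact word-size/coverage parameters of production clustering tools
  are not reproduced; at package scale the greedy policy is exact and
  oracle-checkable.
* The pI bisection runs a fixed 200 iterations or until |charge| < 1e-4;
  determinism matters more here than the last bit of precision.
* Classifier determinism: every stochastic component (CV splits, liblinear,
  bootstrap) is seeded from the single run seed; reports are bit-identical
  across runs with the same seed.

## Known limitations

* The 79-feature manifest of a full proteome study is approximated by the
  ~35 features computable from the package's inputs; the feature table is
  extensible and the count is not asserted anywhere.
* Fisher's exact test covers the 2-group boolean case exactly; the > 2
  group boolean case falls back to chi-square rather than a network
  algorithm for r×c exact tests.
* `ss_content` consumes annotation segments; no DSSP-style assignment from
  coordinates is attempted.
* Structure reading keeps the first altLoc, first MODEL and one chain, and
  treats numbering gaps as unresolved residues; insertion codes are not
  modeled.
* The variability-score formula and class cutoffs on real data are
  study-specific; both are configuration here (log-SD + quartiles by
  default), and explicit cutoffs are the fidelity path when a study's
  values are known.
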