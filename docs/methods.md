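# Methods

`loadmapper` analyses block-design working-memory fMRI in which cognitive
load (1-back vs 3-back) and induced anxiety (safe vs threat-of-shock) are
manipulated orthogonally, and a pharmacological arm (methylphenidate-like,
"MPH") is compared with placebo ("PLA").  Two complementary analyses are
implemented: explicit load/anxiety contrast parameters on network-averaged
BOLD, and a TDA Mapper shape-graph analysis quantified with participation
coefficients.  Because no public dataset accompanies this design, a
synthetic generator with known ground truth drives every experiment; all
empirical statements below are computed by the test suite or the analysis
scripts in this repository.

## Synthetic sessions

A session is two runs of 225 volumes at TR = 2 s.  Each run holds 8 blocks —
two per load x anxiety condition, in a seeded pseudo-random order — each
block being 8 s (4 frames) of instruction followed by 18 letters at 2 s
intervals (36 s).  The 49 frames per run not covered by blocks are
distributed as evenly sized inter-block fixation gaps (the gap layout is a
package choice; block ordering and total coverage are the constraints that
matter).  Exactly 6 of the 18 trials per block (33%) are matches, placed
uniformly among positions eligible under the N-back rule (position > N);
non-match letters are resampled to avoid accidental matches.  Three shocks
per run are placed on threat-block letter frames.

BOLD per parcel of network *j* is

    baseline + (a_j + c_p) * load(t) + b_j * threat(t)  [+ drift + noise]

where `load(t)`/`threat(t)` are boxcars over letter frames, optionally
convolved per run with a canonical double-gamma HRF (peak 6 s, undershoot
16 s) normalised to unit sum so a long block's plateau keeps the nominal
amplitude.  `a_j` and `b_j` are the generative load and anxiety effects
(signal units); `c_p ~ N(0, state_separation^2)` is a per-parcel
load-response pattern that gives a subject geometrically distinct 1-back and
3-back activation states ("segregated dynamics"); white noise has sd 1 by
default and drift combines a random linear slope with a ~128 s sinusoid.
Motion is a 6-parameter random walk (sd 0.01 mm/frame; rotations scaled to
match under the 50 mm convention) plus Bernoulli single-frame spikes
(rate 0.02, magnitude 0.5 mm), which puts median censoring near 10% under
the default threshold.

Default effect sizes, chosen once as plausible for a working-memory block
design: `a = (0.3, 0.3, 0.3, 0.3, 0.3, 0.8, -0.6)` across the 7 canonical
networks (frontoparietal control strongly recruited, default mode
deactivated), `b = (0, 0, 0, 0.3, 0.3, 0, 0.2)` (salience/limbic/default
respond to threat), noise sd 1.  Cohorts assign the MPH arm `a + delta`
(default delta 0.4) and, in the segregated variant, `state_separation = 1.0`
(same units as the noise sd) — a moderate per-parcel heterogeneity that
separates load states without overwhelming noise.

What the generator does *not* emulate: spatial autocorrelation between
parcels, physiological (cardiac/respiratory) noise, HRF variability across
regions and subjects, non-stationary arousal effects of shocks, and
behaviour generated from the neural state (accuracy is drawn from a simple
condition/drug model).  Passing tests therefore demonstrate correctness of
the estimators and algorithms under a known forward model, not robustness
to every property of real BOLD.

## Preprocessing

Framewise displacement is the Power formulation: sum of absolute
translation increments plus 50 mm times absolute rotation increments, first
frame of each run set to 0.  Frames with FD > 0.2 mm are censored together
with 1 frame back and 2 forward, clipped at run boundaries.  Nuisance
removal is one per-run OLS against [intercept, linear trend, 6 motion
parameters] with betas estimated on non-censored frames only and residuals
formed everywhere — a single projection that demeans, detrends and removes
motion simultaneously.  Censored frames are linearly interpolated (edge
frames take the nearest retained value) before a zero-phase order-4
Butterworth band-pass (0.009–0.08 Hz, forward-backward per run), after
which censored frames are dropped.  Interpolation and filtering never cross
run boundaries.  Network series are unweighted means of member parcels.

## Load and anxiety parameters

Signal strength SS per condition is, by default, the mean of the cleaned
network series over that condition's letter-phase frames after shifting
labels by a hemodynamic lag (default 2 frames = 4 s); a GLM estimator
(condition indicators, optionally HRF-convolved, plus intercept) is
available as a config switch.  The contrasts are

    alpha = ((SS_3b^safe - SS_1b^safe) + (SS_3b^threat - SS_1b^threat)) / 2
    beta  = ((SS_3b^threat - SS_3b^safe) + (SS_1b^threat - SS_1b^safe)) / 2

Scenario labels (load-only "A", anxiety-only "B", both "C", "null") use a
tolerance band epsilon (default 0 for arithmetic checks; a small positive
value for noisy data).  The qualitative scenarios are defined for
non-negative parameters only; reliably negative estimates are flagged
"other" rather than forced into a scenario.

Recovery semantics: with the boxcar forward model (`hrf="none"`), no drift
and no filtering, the condition-mean estimator inverts the generator
exactly, so noiseless alpha-hat/beta-hat equal the ground truth to machine
precision and noisy estimates are exactly unbiased — this is the regime the
recovery and calibration experiments use.  With HRF convolution and the
band-pass applied, block onsets/offsets and stop-band loss shrink the
contrasts multiplicatively (roughly a factor of 3 under defaults); group
*comparisons* are unaffected because the shrinkage is common to all
subjects, but absolute alpha/beta from the full chain should not be read in
generative units.  This is a known limitation, not a defect of the
estimator.

## Mapper

1. **Filter.**  Pairwise distances (Euclidean by default; correlation
   distance optional) in the original frames-by-parcels space; a symmetric
   kNN graph (union of directed neighbourhoods) weighted by those
   distances; all-pairs shortest paths; classical MDS of the geodesic
   matrix into d = 2.  If k is unspecified, the smallest
   k >= ceil(log2(n)) giving a connected graph is used; an explicit k with
   a disconnected graph gets components bridged by their single shortest
   inter-component links, guaranteeing finite geodesics.  Eigenvector signs
   are fixed (largest-magnitude loading positive) for reproducibility.
2. **Cover.**  An r x r grid (default r = 18 bins per axis) over the
   per-subject coordinate range, each interval widened to w/(1-g) so
   adjacent bins overlap by exactly the gain fraction g (default 0.70) of
   their width; membership is closed-interval containment.
3. **Partial clustering.**  Single linkage within each bin on
   original-space distances, cut at the midpoint of the first empty bin of
   a 10-bin histogram spanning the observed linkage-height range (no empty
   bin, or all heights equal, means one cluster).  Anchoring the histogram
   at the minimum height rather than zero matters: anchored at zero, the
   first "empty" bin falls below the noise floor and every bin shatters
   into singletons.
4. **Graph.**  Nodes are clusters; an edge joins two nodes sharing at
   least one frame.

The filter does not depend on r or g, so parameter sweeps reuse each
subject's embedding and only recompute steps 2–4.

## Annotation and participation coefficient

A graph is coloured by one task factor at a time (load or anxiety).  Node
proportions count letter-phase member frames only (instruction and fixation
are excluded; configurable); each node's community is its dominant level,
ties broken by canonical level order (1-back before 3-back, safe before
threat) for determinism.  The participation coefficient of node *i* is

    P_i = 1 - sum_s (kappa_is / k_i)^2

with unweighted link counts; nodes whose members are all unannotated are
excluded, and isolated nodes (k_i = 0) are excluded from the per-graph mean
but reported.  The per-graph summary is the unweighted mean over included
nodes (median available as config).  Because PC implicitly assumes
comparable community sizes, a balance check reports node counts and
within-community degree per community with permutation p-values (size
imbalance against an equal-probability label null; intramodular imbalance
against label permutation, which holds sizes fixed).  In the synthetic
cohorts the segregated graphs are often measurably imbalanced — the
generator makes no effort to equate community sizes — so the balance check
should be read per dataset rather than assumed to pass.

## Statistics

The permutation group test uses the difference in group means with
label permutations and an add-one corrected two-sided p; with 199
permutations the achievable p-values make rejection at the 5% level exact,
and 1,000 seeded null cohorts show a rejection rate inside 5% +/- 2%.  The
partial Spearman correlation ranks x and y (average ranks on ties),
residualises both ranks on the covariates by least squares, and correlates
the residuals, with a permutation p-value; covariates are used as given
(rank covariates beforehand to reproduce conventions that rank everything).

## Problem sizes used by the experiments

Chosen as the package's desk scale so each experiment reads clearly:

- Design-constant checks: full sessions (2 x 225 volumes), 1,000-seed
  sweeps for structural invariants.
- Recovery/bias: 200 cohorts at 25/arm with a 35-parcel map (5 per
  network) — parcel count is irrelevant to the contrast arithmetic, and the
  deviation pool of 70,000 network estimates puts the Monte-Carlo standard
  error near 2e-4.
- Segregation direction: 100 cohorts at 10/arm, 105 parcels (15 per
  network), default (r, g) = (18, 0.70); grid stability on further cohorts
  across r in {14, 16, 18, 20, 22} x g in {0.6, 0.7, 0.8}.
- Null calibration: 1,000 cohorts at 6/arm, 35 parcels, 199 permutations.
- The analysis scripts run one 25/arm cohort at 105 parcels end to end.

The 105-parcel choice for the shape-graph experiments is substantive, not
just economical: at 400 parcels the *shared* network-level load response
(present in both arms) already saturates load segregation — distance
concentration in high dimensions makes the same relative offset cut the kNN
graph more cleanly — driving both arms' mean PC to the floor and erasing
the group contrast.  At 15 parcels per network the segregated arm separates
and the integrated arm does not, which is the regime the group comparison
is designed to detect.  This sensitivity of Mapper contrasts to feature
dimensionality is a genuine limitation worth knowing about when applying
the pipeline to real parcellations.

## Numerical notes

- All randomness flows from explicit seeds; cohorts spawn per-subject
  substreams via `numpy.random.SeedSequence`, so any subject is
  reproducible independently of cohort size.
- Classical MDS drops axes with non-positive eigenvalues (they collapse to
  zero coordinates); the degenerate all-identical-frames input returns a
  zero embedding with a warning.
- Cover membership uses a relative tolerance of 1e-12 at the interval
  boundaries so extreme points are never dropped by rounding.
- `fcluster` cut thresholds are taken at empty-histogram-bin midpoints so
  no linkage height can sit exactly on the cut.
- Known limitation: the single-linkage gap heuristic is scale-free but can
  split elongated clusters when a bin happens to contain a sparse chain;
  this is inherent to the method, and the cover overlap (g = 0.70) is what
  re-links such fragments in the graph.
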