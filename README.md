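# loadmapper

Analysis pipeline for block-design working-memory fMRI in which cognitive
load (1-back vs 3-back) and induced anxiety (safe vs threat-of-shock) are
manipulated orthogonally across two groups (a cognitive enhancer arm, "MPH",
vs placebo, "PLA").  It asks the question: does the drug shift how neural
resources are deployed across load and anxiety — and does it make
whole-brain activity patterns for low and high load more distinct?

Two complementary analyses are implemented over a common preprocessing
chain, together with a synthetic-data generator that makes the whole
pipeline testable end to end with known ground truth:

1. **Load/anxiety contrast parameters.**  For each subject *S_i* and
   network *Net_j*, condition signal strengths
   SS<sup>{safe,threat}</sup><sub>{1-back,3-back}</sub> are estimated from
   cleaned network-averaged BOLD and collapsed into two parameters:

       alpha = ((SS_3b^safe − SS_1b^safe) + (SS_3b^threat − SS_1b^threat)) / 2
       beta  = ((SS_3b^threat − SS_3b^safe) + (SS_1b^threat − SS_1b^safe)) / 2

   alpha is the average load effect (3-back > 1-back), beta the average
   anxiety effect (threat > safe); networks are classified as load-driven
   (alpha > 0, beta = 0), anxiety-driven, or both.

2. **TDA Mapper shape graphs.**  Each subject's cleaned frames-by-parcels
   matrix is embedded with a geodesic (kNN shortest-path) filter and
   classical MDS, covered by an 18 x 18 grid of bins with 70% overlap,
   partially clustered within bins in the original space (single linkage,
   histogram-gap cut), and turned into a graph whose nodes are clusters of
   time frames and whose edges mark shared frames.  Graphs are annotated by
   load or anxiety, and condition segregation is quantified with the
   participation coefficient P_i = 1 − Σ_s (κ_is / k_i)²: low mean PC means
   the annotation's communities barely touch (segregated whole-brain
   states), high mean PC means they interdigitate (integrated).

Preprocessing implements the standard functional chain: framewise
displacement (Power convention, 50 mm rotation radius), censoring at
FD > 0.2 mm with back-1/forward-2 dilation, per-run regression of intercept
+ trend + 6 motion parameters (betas fit on retained frames only), linear
interpolation across censored frames, zero-phase 0.009–0.08 Hz band-pass,
frame removal, and 7-network parcel aggregation.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Run the analysis scripts in order (a simulated 25-per-arm cohort, 105
parcels; intermediate data lands under `scratch/`, tables under
`results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_alpha_beta.py
python analysis/04_mapper_pc.py
python analysis/05_group_and_behavior.py
python analysis/06_parameter_sweep.py
```

Output of the run recorded here (seed 7):

```
cleaned 50 subjects; censored fraction 9.7% on average (range 4.4%-16.7%)

alpha group difference significant in 7/7 networks (drug arm higher in all of them: True)
beta group difference significant in 0/7 networks

mean participation coefficient by annotation and arm:
group     MPH   PLA
anxiety 0.131 0.156
load    0.100 0.162

axis=anxiety: drug-placebo mean-PC difference -0.0256, p=0.1408
axis=load:    drug-placebo mean-PC difference -0.0622, p=0.0006999
load-PC vs 3-back accuracy (high load):          rho(46) = -0.38, p = 0.006
load-PC vs threat accuracy (induced anxiety):    rho(46) = -0.44, p = 0.001

group-difference sign constant across all 15 cells: True (sign [-1])
```

Reading these numbers: the drug arm (generated with a larger load response
and load-segregated dynamics) shows a higher load parameter alpha in every
network but no anxiety-parameter difference; its shape graphs have lower
mean PC under the load annotation (more segregated 1-back/3-back states)
but not under the anxiety annotation; lower load-PC predicts better
high-load and threat accuracy with age and sex controlled; and the PC group
difference keeps its sign across the whole resolution/gain grid
(r in 14–22, g in 0.6–0.8).

A thin CLI wraps the same library calls for single sessions, e.g.:

```bash
loadmapper --seed 3 --out-dir /tmp/demo simulate --n-parcels 105
loadmapper --out-dir /tmp/demo mapper --input /tmp/demo/timeseries.tsv \
    --resolution 18 --gain 0.70
```

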