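# Methods

`phytoactive` correlates molecular-feature intensities across
botanical-extract fractions with a bioassay readout to rank candidate
bioactive compounds. This note records the models, their assumptions, the
parameters that matter, and the choices made where the design was open.

## Data model

A screen consists of a fraction × feature intensity matrix per electrospray
ionization mode (`FeatureMatrix`, features named `"RT_mz"` with retention
time to 2 decimals and m/z to 4) and a per-fraction % viability vector with
replicate standard errors (`BioactivityVector`). POS- and NEG-mode matrices
are kept separate end to end; rank lists never mix modes. Three or more
fractions are required by every model (the toy minimum for a variance); the
intended scale is ~21 fractions.

## Preprocessing

**Adduct/isotopologue collapsing.** Flow-injection electrospray records a
compound several times: [M−H]⁻, its sodium-exchange satellite (+21.9819 Da),
isotopologues (+1.0034 Da), etc. `deconvolute` merges features when a rule
offset relates their m/z within ±0.01 Da, retention times agree, and their
cross-fraction profiles correlate (Pearson ≥ 0.9 by default); groups close
transitively. The merged feature keeps the lowest-m/z member's id (the
un-offset parent) and sums the group's intensities, so total matrix
intensity is conserved exactly. This is a deliberately simple stand-in for
vendor deconvolution software; it does not handle charge states or in-source
fragments.

**Log transform.** Intensities span decades, so models run on
`ln(x + δ)` with δ = half the minimum nonzero intensity ("half-min"), a
scale-adaptive pseudo-count that keeps zeros finite; a fixed δ can be
supplied instead. The transform is strictly monotone for every non-negative
input.

**Response scale.** The viability response can be modelled as-is (%) or as
`ln(max(v, 1%))`. The selectivity ratio and the default Elastic Net
pipeline model the % scale directly: the package's reference world (and the
usual linearization of a dose–response readout against log concentration)
makes viability linear in the spiked features' log intensities, and
log-transforming the response then mis-specifies the model — empirically it
re-assigns selection mass from true spikes to presence/absence confounders,
because `ln` exaggerates the low-viability tail where the assay noise is
proportionally huge. The log-response variant remains available
(`log_response=True`) for data where a multiplicative error model is more
plausible.

## Selectivity ratio

A PLS1 model of viability on the (autoscaled) log matrix is rotated onto
its regression vector b — the target projection:

    t_tp = X b / ‖b‖        p_tp = Xᵀ t_tp / (t_tpᵀ t_tp)

Per feature j, explained and residual variances along t_tp are
v_expl = ‖t_tp p_tp,j‖² and v_resid = ‖x_j − t_tp p_tp,j‖², and
SR_j = v_expl/v_resid = f/(1−f) with f the explained fraction; SR = 1 marks
50 % variance explained, the conventional screening threshold. Features
with zero residual get SR = +∞ and rank first; ties break by ascending m/z.
The per-feature decomposition is independent of any positive rescaling of
t_tp.

Choices: PLS1 is fitted through scikit-learn's `PLSRegression` on
pre-centred/scaled data (an independent textbook NIPALS implementation
serves as the test oracle); component count is picked by leave-one-out
cross-validation over 1..min(10, n−2), minimizing RMSECV with ties to the
smaller model, and can be fixed explicitly for reproducibility; column
autoscaling is on by default (regression models are scaling-sensitive, and
autoscaling is the SR literature's convention) and exposed as a flag.

## Elastic Net ensemble

One penalized regression on 21 samples is an unstable selector, so the
ranking statistic is the selection frequency over an ensemble (default
1000) of Elastic Net fits. Each member draws a same-size bootstrap
resample of fractions, standardizes X within the resample, and fits at a
fixed L1/L2 mix with the penalty weight chosen by internal 5-fold CV on
the resample; coefficients are mapped back through the within-resample
standard deviations. Features are ranked by selection frequency, then mean
|coefficient| over selected members, then ascending m/z; the "of N" in the
report is the count of features ever selected, a data-dependent outcome.

The default mixing weight is `alpha = 0.2` (ridge-leaning). Bioactive
compounds in plant extracts typically arrive as families of co-fractionating
isomers/homologues whose profiles are nearly collinear; at `alpha = 0.5`
the L1 term splits selection across such a family, collapsing the
selection frequency of its weakest member, while a ridge-heavier mix keeps
the family in together (the grouping effect that motivates Elastic Net over
the lasso in the first place). `alpha` is a config field; 0.5 reproduces an
even mix.

Numerical/efficiency settings (config fields, defaults chosen to keep a
1000-member ensemble at ~20 s on one CPU for 21 × 300 data): penalty path
of 15 values down to `eps = 0.02` of the critical penalty, coordinate
descent with random coordinate selection and tolerance 3e-3, all seeded —
the whole ensemble is bitwise reproducible from `EnsembleConfig.seed`.

## Molecular networking

Spectra are merged (greedy single pass: precursors within ±0.01 Da and
cosine ≥ 0.95 form a consensus with intensity-weighted mean fragment m/z —
a simplified stand-in for full MS/MS clustering), then scored all-pairs.
The modified cosine (default) pairs fragment peaks within ±0.05 Da directly
or offset by the precursor mass difference; candidate pairs are matched
greedily by descending intensity product with each peak used at most once
(an exact bipartite-assignment option exists and bounds the greedy score
from above in tests). Intensities are L2-normalized per spectrum, so
self-similarity is exactly 1 and disjoint spectra score exactly 0. Edges
require cosine ≥ 0.70 and ≥ 6 matched peaks; components with ≥ 3 nodes are
reported as clusters. No degree pruning is applied by default.

Bioactivity mapping attaches to each node (matched to a feature by
precursor m/z within ±0.01 Da, and retention time within 0.2 min when both
carry one) a pie of slice weights — the feature's intensity share in every
fraction containing it — with each fraction's viability bin
(full ≥ 100 %, partial ≥ 50 %, low < 50 %; configurable). Unmatched nodes
are tagged `unmapped`. Export is GraphML with dict attributes serialized
as JSON strings; the module's own reader restores them losslessly.

## Annotation

Feature m/z → neutral mass via [M∓H] arithmetic (proton mass
1.007276 Da); library entries within a closed ±10 ppm window are returned
sorted by |ppm error|. The window is relative, so its absolute width
scales with library mass. MS/MS validation counts reference fragments
matched by any observed fragment within 50 ppm; ≥ 3 matches (configurable)
validates, entries without reference fragments are indeterminate rather
than failed.

## Synthetic world

The generator emulates the screening campaign the package targets, and its
defaults are the stated conditions: 21 fractions, 1500 features (tests use
300), 3 spiked bioactives, viability clipped to [5, 117] %.

- **Profiles.** Each feature follows an elution-like Gaussian bump over the
  fraction index (random centre, width 1.2–3 fractions, log-normal
  amplitude), multiplied by log-normal measurement noise (σ = 0.25) and
  floored at a limit of detection — so most features are absent from most
  fractions, as in real fractionation fingerprints.
- **Bioactive family.** The spikes model a family of co-fractionating
  isomers (the typical situation for plant phenolics such as the
  caffeoylquinic acids): one shared elution profile (width 3–4) on a
  positive baseline (so log intensity is defined everywhere),
  amplitude-scaled per member with small proportional jitter (σ = 0.1).
- **Response.** viability = clip(b₀ + Σ c_s·ln x_s + ε, 5, 117), ε ~
  N(0, 3²) — the noise of a replicate-averaged assay mean (n ≈ 12) — with
  b₀ anchoring the mean at 55 %. Default effect sizes (16, 11, 8 % per
  log-unit) were chosen once so simulated spans approximate the observed
  5–117 % range without saturating the clip bounds.
- **Satellites.** 30 parent features get proportional satellite copies
  (+21.9819, +1.0034 Da; intensity ratio 0.1–0.5), exercising
  deconvolution.
- **Spectra.** Families share all but two fragment peaks (member-specific
  peaks at low intensity) drawn from mutually disjoint, well-separated m/z
  sets, guaranteeing intra-family cosine ≥ 0.70 with ≥ 6 matched peaks and
  no inter-family edges; singletons get their own fragment sets. Spiked
  features head their assigned family.
- **Library.** Caffeoylquinic-acid anchors (mono-CQA at neutral
  353.0874 + 1.007276, di-CQA at 515.1191 + 1.007276, quercetin as the
  [M+H]⁺ anchor 303.0502 − 1.007276), entries for the spikes, decoys
  offset +50 ppm from real features (never annotatable at 10 ppm), and
  far-off fillers. NEG matrices also plant three fixed anchor feature ids
  (including one with no library match) for annotation fixtures.

Everything is a pure function of the config (seed included):
bitwise-identical outputs for identical configs.

**What a green test does not establish.** The generator produces smooth,
independent, unimodal profiles with homoscedastic assay noise; real
fractionation data carry segment structure from multi-stage partitioning,
ion suppression, correlated (non-satellite) co-elution, and heteroscedastic
assay error. Recovery results here quantify behaviour in the stated world,
not performance guarantees on instrument data. In particular, features
whose elution happens to align with the bioactive region are genuinely
correlated with bioactivity — the method is a correlation screen, and the
synthetic world keeps such confounders rare, not absent.

## Known limitations

- The deconvolution stand-in can over-merge coincidental m/z pairs with
  correlated profiles, and never splits chimeric features.
- SR with leave-one-out component selection can overfit at very small
  fraction counts; fix `n_components` for such data.
- The consensus "top-K union" (default K = 50) is a reporting choice, not
  an inference procedure; the overlap count is descriptive.
- Greedy peak matching can under-score spectra with dense, ambiguous
  fragment clusters; use `exact_matching=True` when that matters.
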