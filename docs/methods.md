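# Methods

## Pipeline

For each subject the package receives a T×N matrix of region-mean BOLD
signals (rows = time points, columns = the N = 90 AAL cerebral regions
in fixed atlas order; a reduced synthetic atlas of any even size is
available for fast studies).  The temporal chain is:

1. **Volume discard** (optional, default 0): drop the first n volumes.
   Synthetic data are generated post-equilibration, so the default run
   length of T = 230 already corresponds to a 240-volume acquisition
   with 10 volumes discarded.
2. **Linear detrend**: per-column least-squares line (intercept +
   slope) removed; columns end zero-mean.
3. **Band-pass 0.01–0.1 Hz**: ideal (brick-wall) FFT mask — retain bins
   with low ≤ f ≤ high, zero all others including DC, inverse
   transform.  The ideal filter was chosen over an IIR design because
   it is exactly reproducible and parameter-free; its edge ringing is
   acceptable at record lengths of ~200 samples.  The high cutoff must
   lie below Nyquist = 1/(2·TR).
4. **Pearson correlation** over all region pairs; diagonal fixed at 1;
   a zero-variance region is a hard error naming the region.
5. **Binarization across the sparsity grid** (default 0.10…0.50 in
   steps of 0.01, 41 levels): all off-diagonal pairs are ranked once by
   *signed* correlation descending, ties broken lexicographically by
   (i, j); at sparsity s the top round-half-up(s·N(N−1)/2) pairs become
   edges.  Consequences: results are fully deterministic; strong
   negative correlations are never edges (the conventional choice in
   binarized resting-state connectomics); and edge sets are nested
   across the sweep because every threshold keeps a prefix of the same
   ranking.  An r-value cutoff mode is deliberately not the default:
   the sweep is defined on sparsity so that all subjects' networks have
   identical edge counts at each level.

## Nodal metrics

Computed natively on the boolean adjacency matrix (no graph library in
the implementation path; networkx and brute-force path enumeration
serve as independent test oracles):

- degree k_i;
- clustering C_i = 2e_i/(k_i(k_i−1)), 0 when k_i < 2;
- all-pairs hop distances by level-synchronous BFS; unreachable = ∞;
- nodal efficiency (1/(N−1))·Σ 1/d_ij with 1/∞ = 0;
- nodal local efficiency = global efficiency of the subgraph induced by
  the node's neighbours, distances measured **within** the induced
  subgraph (Latora–Marchiori convention — implementations differ on
  this point, so it is stated explicitly);
- betweenness by Brandes' algorithm over unordered pairs, reported
  normalized by (N−1)(N−2)/2 (raw values via a flag).  Normalization is
  a convention choice; group t-tests are scale-invariant, so it cannot
  change significance calls.

Disconnected graphs are expected at low sparsity and handled by
1/∞ = 0 everywhere; no largest-component restriction.

**AUC aggregation**: the metric-vs-sparsity profile is collapsed by the
trapezoidal integral over the grid (span 0.40 for the default grid).  A
`mean` mode divides by the span for a sweep-average interpretation;
both modes differ by a positive constant, so downstream inference is
unchanged.

## Statistics

- Node-wise group comparison: two-tailed **pooled-variance (Student)**
  t-test on nodal AUCs, df = n_A + n_B − 2.  Pooled rather than Welch
  is the default because recomputing the reference cohort's age
  contrast (66.69 ± 7.03, n = 23 vs 63.44 ± 8.16, n = 18) under both
  conventions shows the pooled form reproduces the published 1.368
  (Welch gives ≈1.34); `--welch` is available.
- Sex: Pearson χ² on the 2×2 table without continuity correction
  (reproduces the published 0.770 from 8/15 vs 4/14).
- Significance: uncorrected p < α (default 0.05), matching the
  reference analysis across 90 nodes × 5 metrics; Benjamini–Hochberg
  FDR is provided as an option and labelled in outputs.
- Behavior–topology correlations: computed only for metric/region pairs
  that survive the group test; subjects from both groups pooled; pairs
  with a missing score dropped pairwise (n is whatever the data
  provide).  Pearson r with the exact two-tailed t-transform
  p = 2·P(T_{n−2} ≥ |r|√((n−2)/(1−r²))); when Shapiro–Wilk (α = 0.05)
  rejects normality for either variable the same machinery runs on
  ranks (Spearman with the t approximation).  A constant variable is
  treated as non-normal rather than an error.

## Synthetic cohorts

The generator is a stand-in: the underlying study design is
observational and specifies no generative model, so these choices are
the package's own, made for testability and plausibility rather than
biophysical fidelity.

- **Ground truth**: a random geometric graph (closest point pairs on
  the unit square) at density 0.15 — spatially clustered like
  parcellated cortex, giving clustering-type effects something to act
  on.  The patient group shares the control base graph with planted
  effects applied: `cluster_deficit(v, m)` removes a fraction m of the
  edges among v's neighbours; `degree_gain(v, m)` connects v to a
  fraction m of its non-neighbours.  Default planting: magnitude-0.6
  clustering deficit at the bilateral temporal-pole nodes (TPOmid.L/R,
  atlas indices 87/88).
- **Covariance**: Σ = D^{−1/2}(wA + λI)D^{−1/2} with w = 1 and
  λ = w·(max(0, −λ_min(A)) + 0.5), auto-increased if needed, so Σ is
  always positive definite with unit diagonal; adjacent regions
  correlate at w/λ ≈ 0.2 on the 90-node graph, a realistic magnitude
  for region-pair functional connectivity.
- **Time series**: x_t = φ·x_{t−1} + ε_t with ε ~ N(0, Σ), φ = 0.3, a
  50-sample burn-in, plus white measurement noise of SD 0.25.
  Band-limited spectral content is imposed by the downstream filter
  rather than shaped here — simpler, and sufficient for testing the
  chain.  Defaults T = 230, TR = 2 s mirror a 240-volume, TR = 2 s
  acquisition with 10 volumes discarded.
- **Behavioral scores**: score = group mean + SD·z with z =
  √(1−β²)·ε + β·(standardized topology summary), sign-flipped for CDR
  so that higher network integrity implies higher UPSIT/MMSE/MoCA/MES/
  BNT and lower CDR; β defaults to 0.4.  The topology summary is the
  subject's measured clustering AUC at the planted nodes (whole-brain
  mean if none), so the score linkage passes through the same noisy
  measurement chain as the analysis.  Group means/SDs default to the
  reference cohort's descriptives (e.g. UPSIT 13.13 ± 5.09 AD vs
  23.23 ± 5.87 NC).  Scores are clipped to their scale ranges (MMSE,
  MoCA 0–30; MES 0–100; BNT 0–30, assuming the 30-item form; UPSIT
  0–40; CDR 0–3, continuous); clipping slightly distorts tails, which
  the wide-tolerance mean checks absorb.
- **Determinism**: every draw derives from (config seed, stream tag,
  subject index) via numpy's SeedSequence; regeneration is
  byte-identical.

What the generator does **not** emulate: hemodynamic response shape,
physiological (cardiac/respiratory) noise, motion artifacts, spatial
autocorrelation beyond the graph structure, and site/scanner effects.
Passing tests therefore demonstrate that the pipeline recovers
topological structure from correlation-faithful, temporally
autocorrelated data — not that it is robust to every artifact of real
fMRI.

## Calibration and power studies

Two whole-pipeline studies (in `neurograph.experiments`) run the full
simulate → clean → correlate → binarize → metrics → AUC → t-test chain:

- **Null calibration**: no-effect cohorts (15+15 subjects, 20 regions,
  T = 120, 5-point grid 0.10…0.50); every node-wise test is a null
  draw.  The 20-region, 5-threshold, T = 120 scale keeps 500 cohorts in
  a few CPU-minutes while exercising every stage; the measured
  rejection rate sits at the nominal 0.05.
- **Planted recovery**: magnitude-0.6 clustering deficit at the two
  default nodes, 20/group, T = 230, full 41-point grid; a node counts
  as recovered when its clustering AUC differs at p < 0.05 with the
  patient mean below control.  The long-run per-node recovery rate
  under these conditions is ≈0.8, so individual 50-replicate estimates
  fluctuate around that value.

The acceptance script reports the null rate over 250 replicates and the
recovery rate over 50 — sizes chosen to give stable estimates at desk
scale.

## Degenerate inputs and numerical choices

- Round-half-up edge counts (0.10·4005 = 400.5 → 401); floating-point
  products are used directly, safe at these magnitudes.
- Correlations clipped to [−1, 1] before ranking; diagonal forced to 1.
- t-tests refuse zero pooled variance; correlations refuse constant
  variables and n < 3 (rows are skipped, not fabricated).
- Covariance construction retries with λ ← 1.5λ until the smallest
  eigenvalue clears 1e−10.
- All file outputs use fixed numeric formats (`%.17g` matrices,
  `%.12g` tables) so reruns are byte-identical.

## Known limitations

- Sparsity thresholding of the *signed* correlation matrix is one of
  several defensible conventions (absolute-value ranking and r-value
  cutoffs exist in the literature); the choice is documented above and
  localized in `connectivity`.
- No covariate adjustment (age/sex/education) in the group tests, no
  global network metrics, and no correction for the 450 simultaneous
  nodal tests by default — deliberate scope decisions mirroring the
  reference analysis.
- Real-data preprocessing upstream of region time series (slice-timing,
  realignment, spatial normalization, smoothing, voxel-to-region
  extraction) is out of scope; the package starts at the T×N matrix.
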