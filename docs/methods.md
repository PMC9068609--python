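# Methods

This note documents the models and procedures `plankmap` implements, the
defaults it chooses where the procedure leaves freedom, what the synthetic
generator does and does not emulate, and the numerical decisions that affect
results.

## Community typing

**Self-organizing map.** Each taxonomic group's samples are represented as
within-group relative-abundance vectors (proportions re-normalized after
subsetting, no further transform — compositions are comparable across depths
and library sizes after rarefaction). A Kohonen map with a rectangular 6×6
grid is trained online: per step one sample is drawn (epoch-shuffled order),
its Euclidean best-matching unit (BMU) located, and every prototype moved
toward the sample with weight `lr(t) · exp(−d²_grid / 2σ(t)²)`. The learning
rate decays linearly 0.5 → 0.01 and the neighborhood radius from half the
grid diagonal → 0.5 over 20 epochs (classical Kohonen defaults; all exposed
in `SomConfig`). Prototypes are initialized from randomly drawn samples.
Training is fully deterministic given the seed; BMU distance ties break to
the lowest neuron index. Quantization error (mean sample-to-BMU distance) is
recorded per epoch. With the radius forced to zero the update reduces to
online k-means, which the tests exploit as an oracle check.

**Two-cluster cut and labeling.** Neuron prototypes are clustered by Ward
linkage (Euclidean) and the tree cut at k = 2 — the analysis is about a
binary nearshore/offshore contrast and deeper cuts are out of scope. Cluster
ids are arbitrary; semantics come solely from geography: per cluster,
station weights are the frequency of that cluster among the station's
samples, the weighted centroid is the weight-normalized mean of station
(lon, lat), and the cluster whose centroid lies closer to the coast is
labeled nearshore. "Closer to the coast" uses a coastline polyline
(minimum haversine distance, R = 6371 km, over vertices and interpolated
segment points) when one is supplied, and otherwise the same occurrence
weights applied to the stations' own distance-to-coast metadata. An exact
centroid-distance tie raises an error demanding a manual label rather than
guessing. Every downstream statistic is invariant to swapping cluster ids,
which the tests assert.

**Differential-abundance screen.** Per ASV, the mean within-sample relative
abundance over nearshore samples minus over offshore samples; ASVs whose
absolute difference strictly exceeds the 99th percentile of all absolute
differences are flagged. This is a descriptive screen, not a hypothesis
test.

## Diversity

Shannon entropy is computed in nats; the log base is a parameter because the
convention is not universal. Alpha diversity is per sample (post-
rarefaction), averaged per station or per cruise, with an optional
surface/DCM filter. Gamma diversity pools all of a station's reads — both
depth horizons, all cruises, by default — before applying the index; on
equal-depth (rarefied) samples pooling can only preserve or increase
entropy, so gamma ≥ mean alpha station-wise, an invariant the suite checks
by brute force. Bray-Curtis similarity is `1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`; on
proportion vectors the dissimilarity equals half the L1 distance. The
warm/cool phase comparison takes, per station and group, the mean similarity
over all cross-phase sample pairs (not medoids — the plainest reading of a
mean between-phase similarity) on within-group relative abundances, at the
surface by default; stations lacking either phase and samples with zero
group reads are omitted with a report, never silently.

## Rarefaction and station summaries

Libraries are subsampled to 17,000 reads without replacement (multivariate
hypergeometric — the physical model of drawing reads), once, before any
group subsetting; samples below the cutoff are removed and reported.
Station-level environmental summaries take, per cast, the bottle nearest
10 m for temperature, salinity, NO₃, PO₄, SiO₄ and chl-a, plus the
interpolated nitracline depth, and report the arithmetic mean, the
coefficient of variation and the observation count across cruises. CV uses
the sample (n−1) standard deviation — per-station n is small (the GLM stage
requires only ≥ 4) — and whether the original analysis used population or
sample sd is unknowable from the text; a single observation yields a mean
but no CV, and a zero mean with positive sd yields a missing CV with a
warning.

## Environmental derivations

**Nitracline depth** scans a cast downward for the first bottle pair
bracketing the 1 µM threshold and interpolates linearly; if the shallowest
bottle already meets the threshold the shallowest sampled depth is returned
(no extrapolation above the data); if the threshold is never reached the
value is missing with flag `deeper-than-profile`, and such casts are
excluded from station means (substituting the deepest sampled depth is left
to the caller as a sensitivity option). The first (shallowest) crossing is
used when profiles are non-monotone, matching the conventional definition.
The depth is monotone non-decreasing in the threshold, within the sampled
depth range or missing — both property-tested.

**Regional slope.** Per cruise, OLS of nitracline depth (m) on distance to
coast (km) over stations with a non-missing nitracline; at least 3 stations
required, otherwise the slope is missing with a report. Slope standard
errors are classical (σ̂²/Sxx with n−2 dof); the estimates match a
normal-equations oracle to 1e−10.

**Indices.** Regionally available nitrate is BEUTI/CUTI, set missing where
|CUTI| < 1e−6 rather than infinite. The 2-month moving average is a
centered 61-day window with truncated edge windows — the original smoothing
is visual and exactness is not claimed. Primary production: daily = 2 ×
half-day incubation; euphotic-zone integration is the arithmetic mean over
the six light-level measurements (a warning, and the mean of what is
available, if not six).

## Driver attribution

**GLMs.** Single-predictor models with intercept: binomial-logit for the
per-station nearshore frequency, gaussian-identity for station mean alpha.
The binomial response is carried as (successes, trials) at station level —
fitting the bare frequency would discard the trial counts that weight the
likelihood — and stations with fewer than 4 samples (one year of quarterly
data) are excluded. Fitting is by iteratively reweighted least squares,
convergence when the max coefficient change < 1e−8 (≤ 100 iterations);
quasi-separation (|η| > 30) marks the fit non-converged, and non-converged
fits are excluded from ranking with a report. The binomial log-likelihood
includes the combinatorial constant, so AIC values are comparable with other
likelihood software; rankings are unaffected either way. The gaussian AIC
counts the variance as a parameter (k = coefficients + 1) and guards a zero
residual variance with a floor of 1e−12. Significance is a Wald test on the
slope (normal for binomial, t for gaussian) at p ≤ 0.05 — single-slope
models make a likelihood-ratio test redundant. AIC ranks are assigned
within a response only; no multiple-testing adjustment is applied (none is
in the procedure being implemented — a known limitation).

**Phase fits and smoother.** Nearshore proportion per cruise is regressed
on the cruise's regional nitracline slope separately per climate phase
(OLS, t-based 95% CI on the slope; phases with < 3 cruises skipped with a
report). Bivariate smoothers are a single penalized cubic smoothing spline
with GCV-chosen penalty plus a pointwise 95% band from 500 case-resampling
bootstrap refits (deterministic given the seed); fewer than 4 unique x
values fall back to a straight line with a warning. This deliberately
realizes "a GAM" as its one-smoother special case — that is the only use
the analysis makes of it.

## The synthetic world

The generator emulates the post-processing inputs of a ~40-station,
six-year quarterly survey (~1,920 samples at two depth horizons) with known
ground truth; all randomness flows from one master seed through named
`SeedSequence` children (region, endmembers, communities, reads).

- **Nitracline field.** `N(s,c) = a_c + b_c·dist(s) + ε`, ε truncated
  normal (sd 3 m, ±2.5 sd), the realized field floored at 2 m
  (outcropping). Phase base slopes 0.05 / 0.25 / 0.15 m km⁻¹ (warm / cool /
  intermediate) and intercepts 30 / 14 / 18 m. Upwelling seasonality moves
  both parameters together — slope × (1 ± 0.4 seasonally), intercept ∓ 10 m
  — because that covariation *is* the mechanism behind the slope–proportion
  coupling: steepening the slope with a fixed intercept deepens the whole
  field and would couple negatively. Per-cruise jitter: slope sd
  0.01 m km⁻¹, intercept sd 1 m.
- **Profiles.** Nitrate is piecewise linear around the crossing
  (0.05 µM m⁻¹) over a per-cast background U(0.05, 0.45) µM, so linear
  interpolation at 1 µM recovers the realized nitracline exactly; a
  per-cast drawdown factor U(0.15, 1) scales bottles strictly above the
  bracketing pair (biological consumption decouples surface nitrate from
  the nitracline without touching the crossing or monotonicity). The other
  variables are linear functions of N plus independent per-cast noise plus
  station-persistent "site effects" — persistent noise is essential,
  otherwise station means over 24 cruises converge onto noiseless copies of
  the nitracline field and the driver ranking becomes a coin flip among
  collinear proxies. Chl-a has a deep-chlorophyll-maximum vertical shape
  normalized so the 10 m bottle reads exactly the linear-in-N surface
  value.
- **Communities.** Per group, a nearshore endmember (sparse Dirichlet,
  α = 0.3, over half the group's ASVs) and an offshore endmember (even
  Dirichlet, α = 2, over all of them), so offshore entropy exceeds
  nearshore by construction. Sample composition is `w·near + (1−w)·off`
  with `w = logistic(−k(N − 25 m))`, k = 0.3 m⁻¹, plus per-sample logit
  noise (sd 0.5); the true label is nearshore iff w > 0.5. Surface and DCM
  samples are independent draws from the same station-level weight — no
  vertical niche structure. In the decoupled (2019–2020-analog) phase,
  w follows the station's *long-term mean* nitracline plus a shared
  per-cruise offset (sd 6 m): the spatial gradient persists while the
  cruise-level slope–proportion relation is severed, mirroring the
  qualitative behavior of that period.
- **Reads.** Library sizes log-normal (median 50,000, σ = 0.5, so ~1.5–2%
  of libraries fall below the 17,000-read cutoff), counts multinomial.
  Taxonomy strings embed the generating group so the group-mapping config
  recovers membership exactly.

**What a green test establishes — and does not.** The generator produces
exactly two community types mixed along one environmental axis, with
covariates that are noisy linear functions of that axis. Recovery therefore
demonstrates that the pipeline finds structure *of the kind the analysis
assumes*; it says nothing about sequencing error, compositional artifacts,
more-than-two community regimes, vertical niche separation, spatial
autocorrelation, or real taxonomies — all deliberately outside the
generator. Effect sizes are the package's own calibration (no quantitative
compositional contrast is published to match), chosen once so that recovery
tests are meaningful, and the paper-analog claims (nitracline depth as
AIC-best driver, positive slope coupling) hold on this data *by
construction*.

## Reproducibility

Every stochastic step (simulation, rarefaction, SOM initialization and
sample order, bootstrap) is seeded from explicit arguments; the pipeline
derives per-stage streams from one master seed and records seed, config
hash, library versions and per-stage row counts in a JSON manifest. Two
runs with the same seed and config produce byte-identical output tables
(floats are serialized with a fixed format). Failures are isolated per
taxonomic group and recorded in the manifest rather than aborting the run.
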