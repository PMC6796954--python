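# Methods

This note records the statistical model behind `traitfilter`, the design
choices that were genuinely open, the defaults and why they were chosen,
and what the synthetic generator does and does not emulate.

## The filtering statistic

The unit of analysis is the pollinator cup: all individuals of one taxon
(bee or fly) captured in one cup during one season. For a cup with k ≥ 2
individuals and trait values t₁…t_k:

- `CWM = mean(tᵢ)` — each captured individual carries weight one, which is
  an abundance-weighted species mean when individuals carry their species'
  trait value. A `species_mean` mode (average of per-species means weighted
  by within-cup abundance) is provided; for tables where individuals carry
  measured traits the two modes differ only through intraspecific
  variation.
- `obsRange = max(tᵢ) − min(tᵢ)`.
- The null distribution of the range conditions on *individual richness*
  k: draw k individuals without replacement from the regional pool (every
  captured individual of the taxon across the whole gradient, seasons and
  habitats pooled), B = 1,000 times. Richness conditioning matters because
  E[range] grows with k; comparing cups of different sizes without it
  confounds abundance with filtering.
- Two standardizations are always computed: the ratio form
  `(obsRange − nullMean)/nullMean` and the z form
  `(obsRange − nullMean)/nullSD`. The significance rule |SES| ≥ 1.96
  (two-tailed α = 0.05) is only calibrated for the z form, which is
  therefore the default `mode`; the ratio form is retained in all outputs
  for comparability with how sesRange values are conventionally printed.
  The threshold is configurable.
- Classification: significant and negative → `strong_filter`; significant
  and positive → `weak_filter`; otherwise `consistent_with_null`.

Numerical details. Only the minimum and maximum of a subset determine its
range, so when `C(n, k) ≤ 10,000` the exact null distribution is computed
by pair counting — the number of k-subsets whose extremes are the i-th and
j-th order statistics is `C(j−i−1, k−2)` — and flagged `exhaustive`;
Monte-Carlo error vanishes there. Null SDs are population SDs over the B
draws. Null distributions are cached per (trait, k) and built in sorted-k
order so results do not depend on sample order. Samples with k = 1 have an
undefined range; they are excluded from SES but retained for CWM. A cup
whose null SD is zero (k = pool size, or a constant pool) raises an
explicit undefined-SES error rather than returning ±inf.

Calibration caveat: the null distribution of a range is right-skewed, so
the two-tailed z rule is not exactly α = 0.05 at small k — for k = 2 or 3
the lower tail can be unreachable (`nullMean/nullSD < 1.96` bounds SES
from below). Measured over a realistic cup-size mixture the empirical
rejection rate under trait-neutral assembly is ≈ 0.04–0.06 (the
acceptance suite asserts 0.05 ± 0.025). The same floor means very small
cups can never individually register significant filtering; detection
rests on moderate-k cups.

## Zone-level inference

CWM and sesRange are analyzed with classical fixed-effects one-way ANOVA
with life zone as the only predictor, cup-level values pooled across
sites, habitats and seasons as replicates, followed by Tukey HSD
(studentized-range) multiple comparisons — eight analyses for the default
two taxa × two traits × two metrics. Pooling cups treats them as
exchangeable within zone; a `site_mean` unit is provided for designs where
the site is the preferred replication unit (df within = 6 in the default
design). Intraspecific trends: species present in ≥ 3 zones with ≥ 2
individuals per zone are tested per trait by the same ANOVA across zones;
when p < 0.05 (configurable) the direction is the sign of the slope of
zone means on elevation rank.

## The synthetic survey generator

The generator emulates a pan-trap survey along a three-zone forested
elevation gradient and is the package's test bed; its defaults are the
study conditions every acceptance check runs under.

**Design.** 3 life zones (ponderosa 2,400 m, mixed conifer 2,600 m,
spruce-fir 3,200 m; mean annual temperature metadata 9.6/7.4/5.2 °C — the
middle value is a linear interpolation, metadata only) × 3 sites × one
12-cup array (4 white/4 yellow/4 blue) × 2 seasons = 108 cups per season,
216 in total. The published trap arithmetic is ambiguous (two habitats per
site × 12 cups × 9 sites would give 216 per season, but 108 per season is
the stated total); the default `site_array` layout keeps one array per
site with habitat as an array-level label, matching the printed per-season
count, and a `habitat_arrays` layout (one array per site × habitat, 216
cups/season) is exposed for the other reading.

**Species pools.** 178 bee and 96 fly species. Zone occupancy is Bernoulli
per species with probabilities declining in elevation for bees
(0.70/0.50/0.25) and nearly flat for flies (0.60/0.55/0.50), reproducing
the strong bee richness decline. Abundance weights are log-normal
(σ = 1.0, a standard rank-abundance shape) and renormalized within zone.

**Traits.** Zone-level targets are community means: bee darkness 35/35/78,
bee volume 302/302/598 mm³, fly darkness 14.90/31.21/34.69, fly volume
100/145/286 mm³. Distribution families are not knowable from community
means alone and were chosen for positivity/boundedness: log-normal for
volume (option: gamma) and scaled beta on [0, 222] for darkness (option:
normal); both are config options. Zone SDs (bee volume 250/250/450, bee
darkness 18/18/18; fly volume 80/110/200, fly darkness 8/12/12) were set
so the species-mean spread matches the magnitude of variation across
common species in such surveys (bee species means span roughly 10–2,600
mm³). Each species draws one quantile per trait and keeps it across zones
(comonotonic draws), so multi-zone species shift with their zone targets —
this is what produces realistic intraspecific trends. Individuals add
mean-preserving noise (multiplicative log-normal for volume, additive
normal clipped to [0, 222] for darkness) with CV 0.07 of the species mean,
in the typical range of intraspecific insect size variation.

**Catches.** Individuals are allocated to zones by per-taxon abundance
shares (bees 0.40/0.33/0.27 declining, flies 0.20/0.30/0.50 increasing),
to cups by attractiveness weights drawn Gamma(1) per cup (pan-trap catches
are overdispersed; uniform allocation is available via
`catch_clumping_shape=None`), and to species by within-zone relative
abundance. Totals are exact: 1,283 bees + 639 flies = 1,922 rows.

**Filtering.** The `filtering_strength` dial (per taxon and zone, default
bee = 3.0 at spruce-fir only) narrows the bee species pool at high
elevation: species quantiles are confined to a central window of width
`w = exp(−strength)` (symmetric truncation about the median) and the
result is recentred on the zone target so the community *mean* stays on
target while the *range* narrows; strength → ∞ collapses the pool SD to
zero, strength 0 is the identity. One-sided (upper-tail) truncation was
implemented first and rejected: for heavy-tailed traits the upper 5% of a
log-normal pool has a *larger* SD than the whole pool, which inverts the
intended effect on body volume. For flies the dial only shifts the mean
(`filtering_mode="shift"`, default strength 0), preserving the documented
contrast: bee range narrowing plus mean increase, fly mean increase
without narrowing.

The strength default and the catch/abundance defaults above were
identified together so that the default configuration reproduces the
qualitative headline the generator exists to emulate — a significantly
negative zone-mean bee darkness SES at spruce-fir (≈ −3.4 ± 0.4 across
seeds) with fly SES far from significance (|SES| < 0.8) — robustly across
seeds. Under uniform catches the mean spruce-fir bee cup holds ~3.6
individuals and the SES floor noted above makes zone-level significance
unattainable at *any* strength; overdispersed catches are both more
realistic and what gives the statistic its power. Zone-mean bee *volume*
SES fluctuates around −2 (SD ≈ 0.8 across seeds) because the volume-range
null is dominated by the pool's heavy tail; it is reported but is not a
stable property of these conditions, and the recovery test asserts the
darkness contrast only.

**Specimen images.** `render_specimen` inverts the morphometrics: it draws
dorsal/lateral/anterior views of an ellipsoidal body (aspect ratios
width/length and height/length uniform on 0.35–0.60, so π/6·L·W·H equals
the record's volume exactly) on an 11% neutral-gray plate, with thin
"leg/wing" strokes excluded from the body mask. Darkness maps to fill
intensity by the inverse of the measurement mapping. Measuring a rendered
set recovers volume within 2% (pixel quantization at the default ~400 px
long axis; ≥ 200 px suffices) and darkness within 1 unit (two integer
quantizations of ≤ 0.5 bin each). Darkness endpoints are exact: an
all-black body measures 222, all-white 0.

**What the generator does not emulate** — and hence what green tests do
not certify about field data: phenology, floral resources, trap-color
preference, weather and capture efficiency are out of scope by design;
cup catches are independent across cups given their weights (no spatial
autocorrelation among neighboring traps); season and habitat have no
effect on traits (the survey found none); and because both traits rise
with elevation in parallel, individual-level volume and darkness are
positively correlated through the zone means (r ≈ 0.2–0.5), whereas real
surveys can show them uncorrelated within zones. Conclusions about real
communities still require the real specimen table, which the pipeline
ingests through the same CSV schema.

## Reproducibility

All randomness flows from `numpy.random.Generator`. The pipeline fans one
run seed into independent per-stage streams (generation, null model) via
`SeedSequence.spawn`, so stages are independently reproducible and a full
run is bit-identical under a fixed (config, seed) pair; the run metadata
records a sha256 config hash, seed, B, mode and package version.
`scripts/acceptance.py` pools the community-mean recovery over 25
independently seeded paper-scale surveys (a plain variance-reduction
choice: the grand CWM is unbiased for the configured zone mean, and
averaging replicates shrinks the pool-sampling noise well below
survey-scale precision) and evaluates null calibration on 1,000 cups from
a 1,000-individual trend-free pool with B = 1,000 — a few seconds of
compute; the 100-run contrast-recovery check in the test suite takes
about five minutes on one CPU.
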