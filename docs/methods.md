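# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that matter.

## Image-based % mitotic chromatin binding

### Procedure

A measurement unit is an interphase image and the following metaphase image
of the same nucleus (`NucleusFramePair`). The quantification:

1. **Diameter estimation** — Otsu threshold, largest connected component,
   equivalent-circle diameter `2*sqrt(area/pi)`. The original workflow was a
   manual ImageJ measurement; an automatic histogram threshold is the
   faithful unattended replacement, and the threshold is overridable.
2. **Rescaling** — both frames are resampled (bilinear) so the interphase
   nucleus is 37 px across; intensities are divided by the squared zoom so
   total signal is conserved up to interpolation error. At this scale the
   metaphase nuclear area is 52 px across.
3. **Totals** — sums over circular areas of 37 px (interphase) and 52 px
   (metaphase) diameter, pixel-center inclusion. Their ratio is the nuclear
   retention of the fusion protein through mitosis.
4. **Plate axis** — principal axis of intensity-weighted second moments of
   above-threshold pixels in the 52 px zone; the profile axis is that
   orientation + 90°. An isotropic zone (a non-binder with no visible plate)
   raises an error asking for a user-supplied axis, mirroring the manual
   fallback of reading the division axis from later time points.
5. **Profile** — 46 × 16 px rectangle centred on the nucleus, long axis along
   the profile axis; each of the 46 positions is the mean of 16 bilinear
   samples across the rectangle. Positions are reported 1-based (1..46).
6. **Normalization** — the 46-point profile is scaled so its area equals the
   metaphase total signal, making profiles of different lines comparable on
   one absolute scale.
7. **Zone enrichment** — baseline = mean of the 31 flank positions
   (1–15 and 31–46); enrichment = sum of (value − baseline) over the
   chromatin zone, positions 16–30. Negative per-position deviations are not
   clipped; a negative zone sum (degenerate non-binder) is carried through
   and only floored at 0 when a line percentage is formed, with a warning.
8. **% mitotic binding** — 100 × mean(variant enrichments) / mean(reference
   enrichments). Enrichment is computed per nucleus first and averaged per
   line (rather than averaging profiles first) because the reported spread
   is the per-nucleus standard deviation; the mean profile is produced for
   display only. The normalization constant is shared across all lines of a
   run.

### Known measurement bias

The fixed 37/52 px measuring disks clip the point-spread-function tails, and
they clip relatively more signal from the smaller interphase disk. On blurred
synthetic pairs this biases the retention ratio a few percent above 1; on
pairs generated directly at the reference geometry with no blur the ratio is
exactly 1. The % binding is unaffected because it is a ratio of identically
measured quantities.

### Embryo-pair generator

The generator plants a known bound fraction: the metaphase frame places that
fraction of the total signal on a plate-shaped rectangle (length 0.8 × zone
diameter, width 6 px at reference scale — chosen to resemble real metaphase
plates; plate shape is not critical to any conclusion) and spreads the rest
uniformly over the metaphase zone. The interphase frame is a disk with a
low-frequency multiplicative texture (Gaussian-smoothed noise, σ = 8 px,
strength 0.3) standing in for the heterogeneous interphase distribution of
the real fusion proteins. Both frames carry identical total signal before
noise — matching the observed near-complete retention of the nuclear pool —
then receive Gaussian PSF blur (σ = 1.2 px) and Poisson (or Gaussian) noise
over a flat background. Defaults render nuclei at twice the reference scale
(74 px interphase diameter) so the rescaling step is genuinely exercised.
Not emulated: 3-D structure and deconvolution, chromosome-arm morphology,
neighbouring nuclei in crowded fields, photobleaching. Passing tests
therefore demonstrate correctness of the measurement chain on images with
the assumed statistical structure, not robustness to those real-data
complications.

## FCS reaction–diffusion kinetics

### Model

Fluorescent molecules exchange between free diffusion (*Df*, µm²/s) and an
immobile bound state with pseudo-first-order association rate *k\*on* (1/s)
and dissociation rate *koff* (1/s); binding sites are implicit and
well-mixed, which is what makes the association pseudo-first-order. Derived
quantities: bound fraction BF = k\*on/(k\*on+koff), residence time = 1/koff;
both are concentration-independent. The observation volume is a 3-D Gaussian
with lateral 1/e² waist *w* and structural (axial/lateral) parameter *s*;
its effective volume is π^{3/2} w³ s.

The pure-diffusion autocorrelation is the closed form
G(τ) = (1/n)(1+τ/τD)⁻¹(1+τ/(s²τD))^{-1/2}, τD = w²/(4 Df).

For the full model, concentration fluctuations of the free/bound pair relax,
per spatial mode q, under the 2 × 2 matrix
M(q) = [[−Df q² − k\*on, koff], [k\*on, −koff]]. With equal brightness and
ideal-solution initial conditions, G(τ) is the observation-volume-filtered
sum Σᵢⱼ [exp(M τ)]ᵢⱼ fⱼ over equilibrium fractions f. The angular part of
the anisotropic Gaussian filter integrates to an erf expression, leaving a
single radial integral evaluated on a composite Gauss–Legendre grid uniform
in log q (64 panels × 5 points from 2·10⁻⁴/w to 13/w), with the 2 × 2 matrix
exponential in analytic eigen form (all exponents ≤ 0, so no overflow; the
sinh(dτ)/d factor switches to its τ-limit below dτ = 10⁻⁸). Normalizing by
the same quadrature at τ = 0 makes G(0) = 1/n exact by construction and
cancels slowly varying quadrature bias. Verified accuracy against the
closed-form limits: ≤ 2·10⁻⁶ relative against pure diffusion, ≤ 1.3·10⁻⁴ in
the fast-exchange limit (D_eff = Df/(1+k\*on/koff)), ≤ 10⁻³ against the
reaction-dominant hybrid form deep in that regime.

### Fitting

Weighted nonlinear least squares in log-parameter space (positivity by
construction), with a grid of starts (n₀ = 1/G at the first lag; Df over
{1, 5, 20, 80} µm²/s plus a half-amplitude-lag guess; five (k\*on, koff)
pairs); the two starts with lowest initial RSS are refined and the best
refined solution kept. Lags below 10 µs are excluded by default (detector
afterpulsing region in real data). Replicate-curve standard errors provide
inverse-variance weights when available, else weights are uniform. Standard
errors come from the Jacobian at the optimum, mapped back to the linear
scale by the delta method. Noiseless round-trips recover all four parameters
to better than 10⁻³ relative; model choice (pure vs full) is always
user-specified, never automatic.

Outlier screening: per-curve distance = median absolute difference from the
pointwise median curve; curves beyond the cohort median distance plus 3 MADs
are discarded; at least one curve is always retained and two mutually
distant curves are both kept with a warning (no majority to decide). The
originally used criterion is unspecified; this MAD rule is one defensible
choice and the multiplier is configurable.

Volume calibration: fluorescein dilution-series curves are fitted with the
pure-diffusion model at fixed Df = 425 µm²/s; ordinary least squares of
fitted molecule number on molar concentration, through the origin, gives
V = slope/N_A litres. The structural parameter is not measurable this way
and defaults to s = 5 (typical for confocal FCS), configurable; the beam
waist follows from w = (V/(π^{3/2}s))^{1/3}.

Group comparison: one-way ANOVA plus Dunnett's many-to-one test against the
reference line (scipy implementation), with stars at p < 0.01 and p < 0.001.

### Particle oracle

An independent first-principles check: point emitters in a periodic box
(≥ 10 beam waists wide) undergo Brownian steps of sd √(2 Df dt), switch
free↔bound with exact exponential probabilities 1−e^{−k dt}, are immobile
while bound, and contribute a 3-D Gaussian observation weight to the
fluorescence trace. Particle numbers are drawn Poisson per independent
segment and correlation numerator/denominator are pooled across segments, so
the estimator is grand-canonical and free of the fixed-N amplitude
suppression a closed box would impose. Lags are log-spaced integer multiples
of the timestep up to a tenth of the segment; per-lag standard errors come
from the scatter across segments. The oracle and the analytic model agree
within 3 SE at every lag in pure-diffusion, reaction-dominant and
fast-exchange regimes (and in practice within ~0.5 SE), which validates both
sides, since they share no code path. The inner loop is numba-compiled with
numba's own seeded RNG; runs are deterministic given the seed.

The analytic-curve generator (five measurements per nucleus by default,
matching typical acquisition) adds i.i.d. Gaussian noise relative to the
amplitude and corrupts a planted floor(rate × n) subset of curves (amplitude
× U(2,5) or additive drift) to exercise the screening step. Real FCS noise
is lag-correlated and heteroscedastic; the generator's i.i.d. noise is a
simplification, so recovery statistics here bound what ideal-noise data
allow rather than guaranteeing field performance.

## RNA-seq categorization

Design: four genotypes (wild type, and rescue lines expressing the wild-type
fusion, a BAH-domain deletion, and the BAH deletion plus a first-AT-hook
mutation) × three replicates. RPKM = 10⁹·count/(length·library size), with
library size defaulting to the column sum. Filters (strict inequalities, as
worded): length < 200 bp, and summed per-genotype mean RPKM < 1.0; filtered
genes carry a dedicated category id (16). Pairwise comparisons run along the
adjacent pairs of the genotype chain; fold change is the ratio of replicate
means after adding a 0.01-RPKM pseudocount (guards division by zero; also
used for threshold comparisons); the p-value is a two-sample equal-variance
t test on the three untransformed replicate RPKMs — the most literal reading
of a "t test based on the standard deviation of the three replicates" —
with Welch and log-scale variants available. No multiple-testing correction
is applied (raw p-values against a fixed 0.01 cut-off, as in the original
analysis). Identical replicate sets yield p = 1 with a degeneracy flag.

Categories: the ordered call triple maps to a numbered category. Four
anchors are fixed by the published scheme — (none,none,down) → 2,
(none,down,none) → 3, (up,none,none) → 6, (none,none,none) → 15 — and the
remaining 23 of the 27 possible triples receive stable ids from the unused
pool {1, 4, 5, 7–14, 17–28} in lexicographic order (down < none < up). These
unanchored ids are implementation-stable but not guaranteed to match the
original figure, whose full numbering is not in the text. A gene's category
comes from the fold-change calls alone; the strict count within a category
additionally requires p < 0.01 on every non-"none" comparison (vacuously
satisfied by the all-"none" category), so counts report as
"n_strict (n_total)", the strict set is a subset of the total, and the
categories partition the retained genes.

Count generator: negative-binomial counts (var = µ + φµ², dispersion φ,
Poisson below φ = 10⁻⁸) around gene-level Gamma-spread baselines
(mean 200), with planted pattern triples applied cumulatively along the
genotype chain (×effect_fold up, ÷effect_fold down), plus configurable
shares of short (< 200 bp) and essentially silent genes to exercise the
filters. Power, measured by simulation with this generator: a planted
4-fold change is called by fold change alone in ≥ 95% of runs at dispersion
0.05, but the strict p < 0.01 call at 3 replicates only becomes
near-certain at stronger effect/lower dispersion (8-fold at dispersion
0.02); exact triple-pattern recovery degrades to ~90% by dispersion 0.1
because null comparisons begin to throw false fold-change calls.

## Genetic-rescue scoring

The intercross mut1/TM3 × mut2/TM3 produces four equiprobable zygote
classes; balancer homozygotes die, so expected survivor fractions are
(1, 1, v)/(2+v) with v the transheterozygote viability — 1/3 each at full
viability, which is the exact value behind the conventional "33%". Percent
rescue = 100 × (observed transhet fraction)/(1/3), computed against the
exact 1/3, not the rounded 33%. Sampling can exceed 100%; values above 120%
warn rather than cap, since they indicate scoring problems, not valid
biology. Maternal wild-type contribution affects the biology of rescue but
not the scoring arithmetic, and no adjustment is attempted. Phenotype
frequencies are compared with two-sided Fisher exact tests (sidedness is a
convention choice; the original is unstated) with stars at p < 0.01, 0.005,
0.0005; an exhaustive hypergeometric enumeration provides the independent
oracle in the tests. The cross generator draws multinomial zygotes and
thins the transheterozygote class binomially.

## Determinism and problem sizes

Every generator takes a single integer seed and is bit-reproducible;
pipeline runs are bit-reproducible from (config, seed). The validation
suites run at desk scale: particle-oracle checks use 1.5–5 s segments at
20–2 µs timesteps with ~180 particles (about half a minute per regime);
recovery statistics use 50 simulated nuclei of 5 curves each; Dunnett
type-I control uses 100 replicate null simulations of 4 × 12 observations;
image checks use 160 px frames, 3–6 nuclei per line. These sizes give
comfortable statistical margins for the assertions made while keeping the
full suite to a few minutes.

## Limitations

- The unanchored category ids are conventions of this implementation.
- The imaging stage assumes one nucleus per frame, already
  maximum-projected; no tracking, stage detection, or deconvolution.
- The full-model quadrature underestimates G at extreme lag/stiffness
  combinations (τ beyond ~10⁶ τD); irrelevant for the lag ranges fitted.
- The FCS fit treats the observation volume as known (from calibration);
  volume misestimation propagates into n and Df but cancels in the bound
  fraction and residence time only insofar as the shape is well described.
- Whether Df should be shared across lines during nuclear fits is left to
  the caller (per-line fits by default).
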