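# Methods

This note documents the statistical model behind `nsepscreen`, the
defaults it ships with, and the choices made where the underlying
experimental procedure leaves the implementation open.

## The measurement model

One *sample* is a cuvette of cells imaged ~50 min after exposure; the raw
observable is the integrated Yo-Pro-1 (YP) fluorescence per cell. The
per-sample summary is the mean or the median over the 400–2000 quantified
cells; both metrics run through the identical downstream chain. The median
exists because dead cells take up YP regardless of exposure: a handful of
very bright cells moves a sample mean by tens of percent but moves the
median by at most one order statistic.

ΔF = summary(exposed) − summary(sham) removes "spontaneous" dye uptake.
Normalization to the mean SCR ΔF of the same plate group *and experiment*
(taken as 100%) removes day-to-day multiplicative gain: any factor common
to all samples of a plate cancels exactly, which the tests assert to
1e-9 relative precision.

Pooling across the 3–8 independent experiments gives each variant its
ΔF̄ (mean of normalized ΔF) and S² (sample variance of those values
divided by their count, i.e. the squared standard error of ΔF̄). The
replicate unit for a KO is the experiment. For the SCR control group the
replicate unit is the *individual SCR sample* (2–4 per plate per
experiment): per-experiment SCR means are 100 by construction and carry
no dispersion, so the control group's spread has to come from the sample
level. Its mean is still exactly 100.

## Hit statistics

**SSMD** in the unpaired unequal-variance form:
`(ΔF̄_KO − ΔF̄_SCR)/√(S²_KO + S²_SCR)`, with |SSMD| > 1 as the "strong
effect" threshold. Zero-dispersion degenerate pools give a signed
infinity, carried with a flag and excluded from threshold counts.

**Dunnett's test** (classical pooled-variance form) compares every KO of
one plate group against the shared SCR control; one plate group and
metric is one family. The family-wise two-sided adjusted p-value is
P(max_j |T_j| ≥ |t_i|) under the joint null, where the T_j share the
control mean and the pooled scale. It is evaluated by conditioning on the
control deviate (Gauss–Hermite, 96 nodes) and the pooled scale
s ~ χ_ν/√ν (Gauss–Legendre, 96 nodes over the central 1−2·10⁻¹⁴ mass of
the χ distribution). This is deterministic and accurate to ~1e-12: with
one comparison it reproduces Student's two-sided p to 1e-8 or better, and
it agrees with an independent QMC implementation (scipy's) to its
precision. Critical values come from Brent root-finding on the same CDF.
For a typical family (19–20 KOs, n = 3 per group), the two-sided critical
|t| at α = 0.05 is ≈ 3.0–3.1, which is why "t > 3" is a workable rule of
thumb for screens of this geometry.

A variant is a **hit** only if adjusted p < α *and* SSMD crosses the
threshold in the same direction; either metric (mean or median) may
qualify it, the stronger class winning. An SSMD excursion alone is a
"possible" hit — in a null screen with n = 3 experiments, |SSMD| > 1
happens frequently by chance (S² is a noisy 3-replicate variance), which
is exactly why the dual criterion exists.

**Replication concordance.** A hit must come from at least one series and
be supported by the other: same-direction SSMD beyond threshold, or a
same-direction ΔF̄ beyond the consistency margin (default ≥ 120% for up,
≤ 80% for down). Opposite-direction evidence demotes to `none`; a variant
absent from one series is `untested`. This rule is a codification of a
narrative practice, not a uniquely determined procedure; the margins are
exposed as parameters.

## The synthetic screen generator

The generator exists to give the pipeline inputs with known ground truth
under the screen's own statistical structure. It emulates:

* per-cell baseline YP: log-normal (non-negative, right-skewed,
  unimodal), mean 100 a.u., CV 0.5;
* exposure increment: an independent log-normal additive increment with
  mean `slope_per_pulse × pulses × plate_scale` (default 10 a.u./pulse;
  20 pulses → mean increment 200 a.u.) and CV 1.2; mean ΔF is therefore
  linear through the origin in pulse number;
* mosaicism: a two-component mixture — only the edited fraction of cells
  feels the KO's multiplicative effect on the increment, unedited cells
  respond like SCR. Expected ΔF is `(1−r)·slope·N·(1 + f·(e−1))` for
  effect e, editing fraction f, outlier rate r, which the tests use as
  the closed-form oracle;
* heavy-dose divergence: above 50 pulses a configurable cell fraction
  (default 0.4) is reassigned to a broad component (mean ×2, CV ×3) as a
  proxy for swelling/rupture, so the distribution peak degrades and mean
  and median leave the linear trend with inflated scatter;
* plate gain: one log-normal scale factor per (experiment, plate),
  CV 0.1, applied to the exposure increment and recorded in the ground
  truth;
* dead-cell outliers: with probability 0.005 per cell the fluorescence is
  replaced by a bright log-normal draw (mean 5000 a.u.) regardless of
  condition — bright in sham and exposed alike, so it inflates the
  mean-metric noise without biasing the direction.

Default design geometry: 20 KO variants + 3 SCR per plate, 3 experiments,
800 cells/sample, 20 pulses. With these defaults a per-experiment
normalized ΔF has an SD of roughly 5–10% (mean metric), matching the
scale of error bars typical of such screens, and the replication series
at 4–8 experiments detect 1.4× effects with near-complete power while
the all-null false-positive rate of the dual criterion stays well under
5% (measured over 200 simulated screens in the acceptance suite).

Reproducibility: every sample draws from its own `SeedSequence` substream
keyed by (seed, experiment, plate, variant, condition), so single samples
can be re-drawn without generating the whole screen, and a fixed seed
reproduces the screen byte-for-byte.

What the generator does **not** model: uptake kinetics over the 50-min
incubation (endpoint only), well-position effects, correlations between
cells, culture aging between experiments, or any biophysics of pore
formation. Passing tests therefore demonstrate that the *statistics* of
the pipeline behave correctly under the assumed noise structure, not that
the noise structure matches any particular instrument.

## Image quantification

Synthetic fields render each cell as two Gaussian spots: nuclear (sigma
3 px, amplitude-scaled) and YP (sigma 5 px, normalized so the spot
*integral* equals the cell's YP amount). Quantification: global Otsu
threshold on the nuclear channel + connected components (≥ 20 px), with a
class-separation guard (foreground must exceed background by 3 background
SDs) so a blank noise field yields zero nuclei rather than thresholded
noise clusters. Nuclear regions are expanded by 10 px into cell regions;
expansion assigns contested pixels to the nearest region, so regions
never overlap. Background is the median YP outside all cell regions and
is subtracted per pixel before integration. With the default radii
(~99% of a sigma-5 spot falls within a 16-px region) the measured mean
matches the generating mean within 5% at 200 cells, and nuclei closer
than about one sigma may merge — documented behavior, not an error.

## Cleavage assay model

Band intensity is taken as proportional to DNA mass, uncorrected for
fragment length; one cut splits a duplex into two equal-mass fragments,
so CF = (B+C)/(A+B+C) from a simulated lane estimates the mismatched
fraction directly. The expected mismatched fraction under random
re-annealing is 1 − Σpᵢ²; over two-class pools it is maximized at equal
frequencies with value exactly 0.5 — the assay's detection ceiling in the
usual wild-type + single-indel reading. Pools with several distinct indel
classes can exceed 0.5; the ceiling is a statement about the two-class
case. Reported CF is raw (no heteroduplex-formation-efficiency
correction).

## Dose bookkeeping

The dose-response stage fits ΔF vs pulse number by OLS over 0–50 pulses
and judges above-limit points against the extrapolated 95% *prediction*
band — a prediction interval, not a confidence band, because a single
measured point (not the regression line) is being tested.

Adiabatic heating uses ΔT = σE²τN/(ρc), deliberately ignoring all heat
dissipation (a strict upper bound, linear in N). Default medium:
σ = 1.4 S/m, ρc = 4.18×10⁶ J·m⁻³·K⁻¹ — typical growth-medium/water
values, configurable since media differ. With 300-ns, 7 kV/cm pulses this
gives 0.985 K for 20 pulses and exactly double for 40.

## Expression–LD50 stage

Per gene, Pearson R of expression vs LD50 across cell lines, two-sided p
from the t transform on n−2 degrees of freedom; LD50 enters untransformed
(linear axis). Selection keeps genes with R ≥ 0.9 and p ≤ 0.02 (no
multiple-testing correction across the candidate list — the stage is a
screen, and its output is validated by pooling, not by per-gene claims).
Pooling concatenates the baseline-shifted (expression, LD50) pairs of all
selected genes rather than averaging per-gene R; the baseline is the most
sensitive line (lowest LD50), whose expression defines zero. The shift
does not change per-gene R (translation invariance) but is what makes
cross-gene pooling meaningful.

The synthetic panel plants 8 LD50-linear genes among 60 candidates over 6
lines whose LD50 ladder is log-spaced across an 80-fold range; planted
noise is 15% of the signal spread, i.e. a true R ≈ 0.99, so the n = 6
sampling distribution of R clears the 0.9 threshold in ~96% of draws —
the selection recovers ≥ 7 of 8 planted genes on average across seeds.

## Problem sizes and runtimes

The statistical acceptance checks use: 200 simulated null screens
(20 KO + 3 SCR, 3 experiments, 800 cells/sample) for the false-positive
rate; a 10⁶-draw Monte-Carlo null for the Dunnett critical value at
k = 19, n = 3; 100 seeds for the expression-recovery rate. These sizes
put Monte-Carlo error comfortably below the margins being asserted while
keeping the full suite under two minutes on one core.

## Known limitations

* The concordance rule formalizes a narrative practice; other codifications
  are defensible.
* Experiment-level pooling assumes normalized ΔF values are exchangeable
  across days; slow drifts in culture state are not modeled.
* The median-metric ΔF of small samples is discrete-ish (order
  statistics), so its S² can be zero; the resulting infinite SSMDs are
  flagged rather than smoothed.
* Image segmentation is a deliberately simple global-threshold pipeline;
  dense fields or uneven illumination need a real segmentation stack.
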