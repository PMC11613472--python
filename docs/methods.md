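# Methods

This note documents the models, rules and numerical choices behind each
analysis stage, what the synthetic-data generators emulate, and the known
limitations.

## WES copy-number calling

A tumor's copy-number profile is a per-locus (or per-segment) table of
absolute copy numbers. Average ploidy is estimated in two passes: the
provisional ploidy is the unweighted mean copy number over all loci; loci
whose copy number is at least 4.0× the provisional value are treated as
hailstorm events (complex amplifications of 10–100× background that would
otherwise inflate the ploidy) and excluded; the final ploidy is the mean
of the remainder. The 4.0 exclusion factor deliberately reuses the
high-amplification calling bound, and is configurable
(`estimate_ploidy(..., hailstorm_fc=...)`); a segment-length-weighted mean
is available by flag for segment-level input. The mean is unweighted by
default because locus-level gene tables carry no meaningful length. Sex
chromosomes are not treated specially.

Calls are a deterministic partition of fold change *FC = CN / ploidy*
with inclusive boundaries exactly as printed: loss *FC ≤ 0.5*,
amplification *FC ≥ 1.5*, high amplification *FC ≥ 4.0*, neutral
otherwise. In cohort summaries a high amplification also counts as an
amplification (≥ 1.5 subsumes ≥ 4.0).

Ploidy estimation is biased upward by real gains that escape the
hailstorm cut (e.g. a broad 3.5× event); truth-label recovery on
synthetic profiles therefore holds when event loci are a small fraction
(≲ 5%) of the profile, which is also the regime of the cohort data this
emulates.

## Targeted-panel analysis

Variants pass five conjunctive gates: caller allele frequency > 0.027,
alternative observations ≥ 5, unique alternative observations ≥ 3, depth
≥ 250, VAF ≥ 0.10 (all boundary-inclusive where "≥" is printed). Because
the gates are a conjunction, the passing set is independent of gate
order; the rejection log names the first failing gate in the order listed
above. Zygosity is read off the VAF: ≥ 0.75 homozygous, 0.33–0.75
heterozygous, < 0.33 low-VAF. Clinical tier labels (AMP/ASCO/CAP) are
carried through as input annotation, never computed: they require curated
databases.

Gene-level CNV from an ordered primer track uses linear fold change
(log2 inputs are converted with 2^x on read): per-primer classes are
deletion < 0.1, loss in the closed interval [0.1, 0.6], amplification
> 1.75. The loss interval is implemented closed at both ends; the
boundary behavior is pinned by tests. Decision order:

1. **Full-gene** call when a strict majority (> 50%) of primers share
   one non-neutral class and every remaining primer *approximates* that
   class's boundary — within a multiplicative ±25% band (e.g. ≤ 0.75
   still approximates the 0.6 loss bound). The band captures
   near-threshold noise without admitting clearly neutral primers, and
   is configurable (`PanelThresholds.approx_band`).
2. Else **focal** call when ≥ 6 consecutive primers share one
   non-neutral class; the longest qualifying stretch wins, ties breaking
   in class order deletion, loss, amplification.
3. Else no call.

Genes with fewer than 6 primers are not evaluable. An amplification is
flagged *highly amplified* when fold change × assumed ploidy exceeds 8
copies on ≥ 3 primers of the supporting set ("multiple primers" is
pinned at 3, configurable); the assumed ploidy defaults to 2.

Depth normalization against a control panel: each sample's per-primer
depths are divided by that sample's median depth, then by the median of
the controls' own median-normalized depths at the same primer. Primers
absent from controls or with zero control median are dropped with a
warning.

## Tumor growth velocity (rate-based T/C)

Caliper pairs give *V = 0.5 a b²* (a = long, b = short diameter;
mis-entered pairs are swapped with a warning). Volumes are transformed as
log₁₀(max(V, 50 mm³)): the 50 mm³ floor prevents unreliable small-volume
measurements from dominating the log scale. The floor makes slopes of
regressing tumors conservative once volumes cross it — by design. Growth
velocity is the OLS slope of floored log₁₀ volume vs day (day 0 = first
on-study measurement); an animal needs ≥ 2 distinct days.

Arms are compared with a two-sided pooled-variance Student t-test on the
per-animal slopes (Welch available by flag); degenerate zero-variance
groups are handled explicitly (equal means → t = 0, p = 1). The treated
arm's mean slope is classified against a stasis tolerance of 0.005
log₁₀/day (~12% volume change per week): below −tol regression, above
+tol growth, else stasis. The tolerance defines "net-zero growth"
numerically and is configurable. A two-factor fixed-effects ANOVA
(slope ~ subtype × arm) is provided for cross-subtype response
comparisons. Normalized cohort curves divide each animal's volumes by its
day-0 volume and average per arm per day (mean ± SEM).

## QPI dry-mass kinetics and GR dose response

Dry mass from a phase map: with OPL in µm per pixel and pixel area in
µm², mass(pg) = Σ(OPL·area) / α, where the refractive increment
α = 1.8×10⁻⁴ m³/kg = 0.18 µm³/pg; phase in radians is converted via
OPL = φλ/2π (wavelength required). Segmentation follows Sobel gradient →
intensity threshold → morphological closing, hole-filling, small-object
removal (min area 50 px) → distance-transform-seeded watershed to split
touching cells. The gradient threshold uses Li's minimum-cross-entropy
method by default rather than Otsu: with cells of very different
brightness in one field, Otsu places the cut between dim and bright
*edges* and loses the dim cells entirely (Otsu remains available by
config). When integrating per-cell mass, faint above-background pixels
just outside the edge mask are assigned to the nearest label
(`capture_halo`), so per-cell masses sum to the whole-image mass to well
under 1% on synthetic fixtures.

Per-cell SGR is the OLS slope of ln(mass) vs time (tracks shorter than
`min_track_frames` = 5 are excluded with a log entry). Whole-image
"normalized mass" is total *segmented* mass per frame divided by the
frame-0 value — segmented rather than the raw field integral, to exclude
debris — and growth velocity is its linear-regression slope. Default
analysis is per-image population statistics; no frame-to-frame cell
tracking is required for any of the reported quantities.

Drug response uses the growth-rate-inhibition convention
GR = 2^(k/k_ctrl) − 1 (GR = 1 unaffected, 0 cytostatic, negative
cytotoxic). GR is not evaluable when the control culture is not growing
(k_ctrl ≤ 0). GR50 comes from a bounded least-squares fit of
GR(c) = gr_inf + (1 − gr_inf)/(1 + (c/gr50)^hill) with gr_inf ∈ [−1, 1],
hill ∈ (0, 5], gr50 ∈ [min positive dose/10, max dose×10], multi-started
over five gr50 decades. GR50 is reported **non-estimable** when the
fitted curve never crosses 0.5 inside the tested dose range or the fit
pins gr50 at a bound — the honest outcome for drugs that leave the
culture growing, rather than an extrapolated number. RMS residual above
0.15 flags a low-quality fit (still reported). An endpoint-mass EC50 is
not the default readout; the GR formulation is preferred because it is
insensitive to division-rate differences between cultures.

Response descriptors from time-resolved SGR windows: depth of response is
the minimum over time of the treated/control mean-SGR ratio (clipped at
0); time of response is the first window in which the treated mean drops
below 50% of control (not-reached when it never does); heterogeneity is
the SD of single-cell SGR in the final window. These definitions are
convention-dependent (windowing choices change the numbers) and are
documented here as the package's fixed convention.

## Histology scoring

TfR1 (ferroptosis readout): membranous stain intensity (integer 0–3) ×
percent positive cells, range 0–300. CD31: mean and SD of vessel counts
over 10× fields (single field → SD reported 0 and flagged). Stain
comparisons use the same pooled t-test as the growth module. Drift
concordance: a model-passage with ≥ 2 raters is concordant when all
rater scores (ordinal 0–4) pairwise differ by ≤ 1 (tolerance
configurable); the rate is reported per passage class with the
denominator = evaluable model-passages. Score trajectories compare the
rounded-mean rater consensus between low and high passage
(increased vs maintained-or-decreased). Consensus-by-rounded-mean and
the per-model denominator are package conventions where the source
protocol is silent.

## Synthetic-data generators

Each generator emulates one input modality at the study's conditions and
returns ground truth (`truth_` columns) beside the data; identical spec +
seed gives byte-identical output, and zero noise reproduces closed forms
exactly.

* **CN profiles**: flat base ploidy (default 2.0) plus disjoint events
  (loss/amp/high-amp/hailstorm; hailstorms ≥ 10× ploidy); Gaussian noise
  on copy number, clipped at 0.
* **Primer tracks**: unit fold change with whole-gene (deletion 0.05,
  loss 0.3, amp 3.0) or focal events; Gaussian noise in log2 space.
* **Tumor cohorts**: V(t) = 10^(log₁₀V₀ + slope·t) with multiplicative
  log-normal noise (mean-one parameterization); volumes decompose into
  caliper pairs via a pinned aspect ratio a = 1.5 b, b = (V/0.75)^{1/3}.
  Defaults: 8 animals/arm, V₀ = 100 mm³, twice-weekly measurement over
  21 days — the drug-study design this emulates.
* **Cell mass tracks**: per-cell exponential mass growth with rate drawn
  around k(c) = k_ctrl·log₂(1 + GR_truth(c)), where GR_truth is a
  three-parameter logistic (plateau gr_inf, default −0.5; control SGR
  0.02 h⁻¹; between-cell SD 0.005 h⁻¹; 20 frames at 0.5 h), so the GR
  metric of the population mean reproduces the logistic exactly;
  per-frame multiplicative log-normal noise.
* **Phase images**: raised-cosine blobs whose pixel sum equals the
  specified integrated OPL exactly; overlap only with an explicit flag
  (for watershed tests).

What the generators do *not* emulate — and what passing tests therefore
do not show: sequencing read-level artifacts (mappability, GC bias, UMI
errors), segmentation-algorithm boundary errors in real CNV profiles,
caliper operator bias (only unbiased multiplicative noise), cell
migration in/out of the field, optical halo/flat-field artifacts, and
non-exponential growth (confluence, quiescence). Real-data performance
depends on those factors; the suites establish correctness of the rules
and estimators, not robustness to acquisition artifacts.

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses 200 random primer tracks, 20 CN profiles of
200 loci per check, 100 growth cohorts (8 animals/arm) for slope
recovery, 1000 null replicates for t-test calibration, 20 QPI
simulations of 200 cells/dose × 7 doses, and 100 phase-image layouts —
sizes at which every Monte-Carlo margin is comfortably resolved while
the full run stays under a minute.
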