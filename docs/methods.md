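# Methods

## The scientific problem

Pregnant mice change not only how much they eat, drink, move and sleep but
*when*. Because these behaviours are strongly circadian, comparing groups
hour-by-hour with a time × group ANOVA misses the interesting structure:
whether the *peaks* of behaviour shift in time or change in height. This
package implements a two-part analysis for individually housed mice in
metabolic cages under a 12:12 light–dark cycle (ZT0 = lights-on; dark =
ZT12–ZT24): a threshold rule for the onset of dark-phase activity, and a
Bayesian spline model of each behaviour's daily curve from which peaks are
characterised posterior-draw by posterior-draw.

## Data preparation

Raw records arrive per interval (≤ 300 s) per mouse and behaviour. Food
events below 0.002 g are excluded (strictly `<`; the boundary is kept) —
these are scale jitter, not intake. Sleep is stillness lasting ≥ 40 s;
seconds belonging to such runs count as asleep even where a run straddles
5-min block boundaries, and wakefulness is the complement. Intake and
activity are summed within 5-min blocks and reported hourly (sum of the 12
blocks, i.e. per-hour units); wake fractions are averaged. An hour with an
unrecorded 5-min slot is missing, never rescaled — rescaling from partial
hours would bias amplitudes. A slot is *recorded* if any behaviour has
data there, so an hour whose tiny food events were all excluded counts as
zero intake, not as missing. Study days map to blocks [0.5, 6.5),
[6.5, 12.5), [12.5, 17.5] — boundary days belong to the later block, so a
termination day ends a block.

## Activity onset

Cage activity (distance moved, including fine movement) has no crisp
"onset" like wheel running, so onset is defined against each mouse's own
behaviour: the threshold is the arithmetic mean of all its acclimation
dark-phase 5-min activity values, and onset on a night is the start time
(hours after lights-off, 5-min resolution) of the first run of three
consecutive blocks strictly above threshold. "Strictly" because a mouse
sitting exactly at its acclimation mean is not clearly active. A missing
block breaks a run. Nights with no qualifying run are recorded as 12 h
(censored) and enter the analysis at that value; no survival-analysis
treatment is applied, keeping the onset outcome a simple per-night number.
Group comparison uses `onset ~ pregnancy × night(categorical)` with a
random intercept per mouse (statsmodels MixedLM, REML; Powell fallback
when L-BFGS hits a singular profile, and an OLS fallback — flagged
non-converged — when the mixed fit degenerates, whose estimates coincide
on balanced data). Per-night contrasts are two-sided Wald tests without
multiplicity correction.

## The circadian spline model

### Time axis and basis

Hours are placed at their midpoints and unwrapped to ZT6→ZT30 (ZT0–ZT6 of
calendar day *d* becomes ZT24–ZT30 of cycle *d −* 1), so the dark phase
sits mid-axis. The basis is a natural cubic spline with 13 evenly spaced
knots from ZT8.5 to ZT28.5 (spacing 5/3 h) treated as *interior* knots,
with boundary knots at the hourly data range (ZT6.5, ZT29.5) — the same
function space as R's `splines::ns(t, knots = seq(8.5, 28.5, by = 5/3))`.
Treating ZT8.5 as a *boundary* knot was considered and rejected: the basis
is linear left of its boundary knot, and least-squares projections of
realistic curves then cannot place a local maximum near ZT9, where
late-light behavioural peaks occur. For sampling, the design columns are
QR-orthonormalised against the 24 hourly midpoints — a fixed invertible
reparametrisation that leaves the function space unchanged but keeps
coefficients O(1) (the raw truncated-power columns are nearly collinear).

### Likelihoods and transforms

Food, water and activity are non-negative with right-skewed residuals;
they are modelled on the square-root scale with Gaussian errors, and
fitted means are returned to the response scale per draw as
`mean² + residual variance` — the exact mean of a squared Gaussian.
Wakefulness is a fraction in (0, 1) and uses a beta likelihood with logit
link and a single precision φ; observed 0/1 values are nudged by half a
second out of 300 (ε = 1/600) into the open support.

### Structure

Stage 1 models the acclimation period: spline × group fixed effects plus a
random intercept per mouse, fitted with the same samplers; each mouse's
profile (group curve + its intercept, on the link scale, per ZT hour)
becomes a covariate in stage 2. Stage 2 is the study model: a full
spline × group × block interaction in cell-means form (one intercept +
spline per group-block cell), the centred acclimation covariate with an
estimated coefficient (an offset-mode alternative was considered; the
estimated coefficient is more honest about how informative the baseline
is), and nested random intercepts for mouse and for block-within-mouse.
Predicted group curves add back γ × (stage-1 group curve − centring
constant), since the covariate carries circadian shape shared with the
spline; stage-1 coefficient *draws* are cycled through stage-2 draws so
stage-1 estimation uncertainty propagates into the curve credible bands
(per-mouse covariate values remain point estimates — a deliberate,
documented approximation of the classical two-stage design).

### Samplers

No probabilistic-programming backend is used; the samplers are part of the
package. The Gaussian model is fully conjugate and uses Gibbs sampling
(multivariate normal draw for the coefficients, vectorised normal draws
for the random intercepts, inverse-gamma draws for the variances). The
beta model uses adaptive Metropolis-within-Gibbs: per-cell blockwise
multivariate random-walk proposals shaped by working-weight Fisher
approximations, vectorised per-effect proposals for the random intercepts,
a log random walk for φ, conjugate variance draws, and — crucial for
mixing — exact likelihood-invariant "interweaving" Gibbs moves that
transfer mass along the ridges between cell intercepts and random-effect
means, and along the acclimation-covariate direction that the spline span
can absorb. Priors are weakly informative: N(0, 100²) on (orthonormalised)
coefficients — effectively flat, matching the reference analysis's
non-informative default — inverse-gamma(10⁻³, 10⁻³) on variances, and a
wide normal on log φ. The reference sampler setting is 3 chains × 10,000
iterations, the first half burn-in and the remainder thinned by keeping
every 4th draw (3,750 retained; the alternative "discard a quarter"
reading of the thinning rule is not used). Desk-scale work and the test
suite use a reduced preset (2 × 2,000 → 500 draws) and a tiny smoke preset
(1 × 400). Convergence is summarised by the maximum split-R̂ over curve
coefficients; fits above 1.05 are flagged and peak inference refuses them
unless forced.

## Peak inference

Curves are evaluated on a 0.05 h grid (3-min resolution, finer than any
contrast of interest). Within each window — I ZT8–12, II ZT12–15, III
ZT15–18, IV ZT18–24, V ZT24–28 — a draw *has a peak* iff an interior grid
point exceeds both neighbours strictly and lies inside the half-open
window; window-edge maxima are trends, not peaks, and do not count. Among
several maxima the largest wins; ties go to the earliest. Summaries report
presence (% of draws) per group, time/amplitude means with 2.5/97.5%
quantiles over peak-bearing draws, and pregnant − non-pregnant differences
computed per draw over draws where *both* groups have a peak (the coherent
posterior analogue of "for mice with detected peak"; marginal conditioning
is available as a switch). When fewer than 1% of draws have joint
presence, the difference is reported as undefined. Significance is a
credible interval excluding zero, endpoints at zero counting as crossing.
Both time and amplitude contrasts are assessed; no multiplicity correction
is applied across windows.

## The synthetic cohort

The generator exists so every downstream stage can be tested against known
truth. A behaviour's mean curve is a smooth periodic baseline
(shape-preserving PCHIP through control points on [0, 24), deliberately a
different function family from the model basis so the model is never
tested against itself) plus one Gaussian bump per window. Pregnancy
effects act per study block as bump-time delays and amplitude
fold-changes, an overall dark-phase activity scaling (smooth ramps just
inside the dark phase), and a per-night activity-onset gate that holds
pregnant activity at a sub-threshold level after lights-off and then
replays the normal early-dark activity rise shifted by the gate — so the
detected onset delay equals the injected one by construction. Records are
generated per 300-s interval: intake/activity as
`clip(√(level/12) + mouse intercept + ε, 0)²` with one sqrt-scale ε per
mouse-hour (behavioural noise is bout-like, hence correlated within the
hour; this matches the model's hourly residual while keeping the induced
mean inflation, +12σ² per hour, to ≈0.01 g/h), and wakefulness as beta
draws around the logit-shifted profile mean. The default cohort mirrors
the study design: 12 non-pregnant and 31 pregnant mice, 7 acclimation
days, terminations of 4/2/6 and 10/10/11 mice at days 6.5/12.5/17.5.

Default parameter values: curve levels approximate the study system's raw
means (nocturnal bias with ~68% of food intake in the dark; activity of a
few m/h by day and tens of m/h at night; wake ≈0.2 by day, ≈0.75 at
night); effect sizes emulate the reported contrasts (late-light food peak
delayed ≈1.6 h and ≈2–3-fold higher from mid-pregnancy, dark-phase
activity scaled to 0.45/0.45/0.33 per block, onset delays ramping
1.86→6.07 h). Per-hour variances are not published for the real system;
noise SDs (0.032 √g, 0.064 √m, beta precision 40, intercept SDs 0.006 /
0.06 / 0.25 logit) were fixed once at design time, calibrated with
noise-free least-squares projections and seed-pinned recovery runs so that
the injected effects are recoverable at the study's sample sizes, and are
synthetic choices, not estimates from any real cohort. Bump widths
(≈1–1.2 h) keep every window's peak representable by the 13-knot spline;
one deliberate exception remains — the mid-pregnancy dark-phase food surge
swamps the pregnant window-III peak in late pregnancy, mirroring the low
detection rates real data show there.

What passing tests do and do not show: the generator draws from (nearly)
the model's own families with smooth, spline-representable curves and
mouse-level heterogeneity limited to intercepts. Recovery and calibration
results therefore validate the machinery — transforms, samplers, peak
logic, interval construction — not robustness to meal-bout microstructure,
ultradian rhythm, mouse-specific peak times, or cage artefacts, none of
which are simulated.

## Numerical choices and degenerate inputs

Grid step 0.05 h; peak times are grid-quantised, so onset/peak contrasts
carry up to one grid/block step of quantisation. Negative sqrt-scale draws
truncate at zero before squaring (intake cannot be negative). The beta
sampler refuses responses outside the open unit interval rather than
silently nudging twice. Zero-variance onset data (identical series) fall
back to OLS with the fit flagged, and a numerically null interaction
reports p = 1. Mice absent from acclimation receive their group's stage-1
curve as covariate, with a warning. Duplicate 5-min blocks and negative
record values are rejected loudly.

## Known limitations

Peak-time and amplitude estimates inherit a small smoothing bias from the
fixed 13-knot basis (differences of ≈0.05–0.15 h / a few percent of
amplitude at the feature scales used here); credible intervals at the
study's sample sizes dominate it, but at much larger n the intervals would
concentrate on the slightly smoothed curve, not the generating one — a
property of any fixed-basis regression. Fitted hourly amplitudes include
the within-hour measurement-noise mean (+12σ²; cancels in group
differences). The acclimation covariate is a plug-in estimate at mouse
level. Wake fits at the reduced sampler setting occasionally flag split-R̂
slightly above 1.05; the full reference setting mixes well below it. The
β precision is constant rather than modelled, and the rejected exploratory
variants (continuous gestational-day interactions via linear or spline
terms) are documented design history, not implemented alternatives.
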