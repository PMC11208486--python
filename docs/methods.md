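# Methods

## Models and assumptions

The package rests on a two-state picture of co-solvent-induced unfolding:
at fixed temperature only fully folded and fully unfolded enzyme are
populated, and the free energy of folding is linear in the co-solvent
concentration, ΔG_folding(c) = m_folding·(c_U50 − c). The unfolded
fraction is then logistic in c with midpoint c_U50 and steepness
m_folding/(RT). Spectroscopic melt data rarely show flat plateaus, so the
observed signal model adds free linear baselines for the folded and
unfolded states (the "extended" two-state model). The model is
direction-agnostic: whether the fluorescence ratio rises or falls on
unfolding is absorbed by the baselines, never assumed.

Activity versus co-solvent concentration is modelled as a logistic decay
(activity requires the folded state) plus a Gaussian boost centred at
c_Amax, capturing the widely observed activation at low co-solvent
amounts. The logistic term uses a *negative* exponent sign relative to the
unfolding fraction, so it decays with concentration for positive
m_folding; it is implemented exactly in that parameterisation.

Units: concentrations are % (v/v) throughout; m_folding is stored in
J·mol⁻¹ per % (v/v) so m/(RT)·c is dimensionless; R = 8.314 J·mol⁻¹·K⁻¹.
All public interfaces and file formats use °C; kelvin is internal only.

## Fitting

Both fits minimise a sum of squared residuals with
`scipy.optimize.least_squares` (trust-region reflective, bounded),
tolerances 1e-12.

**Unfolding (six parameters: α_F, β_F, α_U, β_U, m_folding, c_U50).**
Lower bound 0 on all six, upper bound 100 on c_U50 only. Parameters are
divided by characteristic scales before optimisation so every optimizer
variable is O(1): the observed signal magnitude for α terms, signal range
per concentration range for β terms, RT/c-range for m_folding, and the
concentration range for c_U50. Deterministic multi-start: c_U50 starts at
25/50/75 % of the largest observed concentration; the folded/unfolded
baselines start at straight lines through the first/last two points
(clipped into bounds); m_folding starts at a logistic-slope heuristic in
which the 10–90 % transition spans a quarter of the concentration range.
Lowest final cost wins; ties go to the earliest start. A fit is
*analyzable* only when the fitted baseline separation at the midpoint is
at least 20 % (configurable) of the observed signal range — flat or
featureless data yield `analyzable=False` and no c_U50 rather than a
meaningless number.

**Activity (six parameters: ξ, ν, σ, c_Amax, c_A50, m_folding).** Bounds:
ξ, ν, c_Amax, c_A50 ≥ 0; σ ≥ 10; c_Amax, c_A50 ≤ 100; m_folding free but
rescaled by RT/c-range (only m needs scaling — the other parameters are
already on comparable scales). The default cost adds L2 penalties
0.01·c_Amax² and 0.001·ξ², applied to the *raw* parameter values (the
printed λ magnitudes match raw %-scale parameters); the penalties are
implemented as extra residuals √λ·θ and can be disabled
(`regularization=False`) for parameter-recovery studies. Multi-start:
c_A50 at 25/50/75 % of the maximal concentration, c_Amax at the argmax of
the observed activity, ν at the activity nearest c = 0, ξ at 0 and at
(peak − baseline)·σ√(2π). With no boost in the data the Gaussian term
collapses (ξ → 0) and c_Amax becomes unidentifiable — its value is then
reported but meaningless, which is why recovery checks only assert c_Amax
where a boost exists.

## Melting temperatures

T_m is the inflection point of the melt curve: the signal is smoothed with
a quadratic Savitzky–Golay filter (default window 7 points), differenced
against temperature with central differences, and the temperature of
maximum |dS/dT| returned. A transition is accepted only when the
derivative peak exceeds 3× the median |dS/dT| (flat and purely linear
traces report "no transition") and when the signal amplitude exceeds
floating-point noise. A peak on the first or last sample is flagged as a
boundary result and reported as an inequality ("> 90 °C") with the numeric
sentinel retained; boundary values are excluded from ΔT_m arithmetic by
an explicit error.

Isothermal slices read each ramp at the requested temperature by linear
interpolation between adjacent samples; how the instrument software reads
fixed-temperature values is not standardised, and linear interpolation on
a 0.5 °C grid introduces error far below the fit uncertainty.

## Initial rates

The linear range of an A340 trace is found by a sliding-window search
maximising window length subject to R² ≥ 0.99 and a minimum window of
30 % of the trace, after an optional dead time (default 0 s); earliest
start wins ties. A perfectly flat trace is a perfect zero-slope fit
(rate 0), and a rising absorbance is flagged but quantified. The slope is
converted by Lambert–Beer: rate = |slope|/(ε·l) in M·s⁻¹, then to
µmol·min⁻¹·mg⁻¹ using the enzyme mass concentration. The default
extinction coefficient ε = 6220 M⁻¹·cm⁻¹ is the standard NAD(P)H value at
340 nm — a configurable default, not a measured fact; the optical path
length of a microplate well depends on fill volume and is therefore a
required input (≈ 0.56 cm for 200 µl in a typical 96-well plate, as an
approximate example only). Because R² is insensitive to a short shoulder
after a long straight segment, a gentle late-time curvature can leave a
few post-knee points inside the default window; tightening
`min_r_squared` excludes them (see the test suite for both behaviours).

## Downstream analyses

Rankings sort a stability measure descending (rank 1 = most stable) and
encode rank r of n as (n − r + 1) plus signs. Ties receive the average
rank numerically and share the competition-rank symbol count; enzymes
missing a measure are listed separately, never imputed. Rank divergence
reports per-enzyme shifts plus a Spearman rank correlation as a supporting
statistic. Operating windows interpolate the c_U50-versus-temperature
boundary linearly; a condition is inside iff its concentration is
*strictly* below the curve (on-curve counts as outside), and queries
outside the temperature span raise unless clamping is requested. Pearson
correlation drops incomplete pairs and reports the count used; SEM is the
sample standard deviation over √n, undefined for n = 1.

## Synthetic data

The generators invert each analysis: isothermal slices and activity
profiles are drawn from the two models plus Gaussian noise (absolute or
relative to the curve amplitude; single noise model — no published error
model exists for such data, and the default relative sd of ~1 % is a
heuristic matched to the scatter of typical nanoDSF data). Melt curves are
a logistic in temperature (default width 2 °C) over linear baselines on a
uniform grid (default 20–90 °C at 0.5 °C, emulating a constant-rate ramp);
midpoints up to 120 °C are representable so boundary handling can be
exercised. Kinetic traces invert the Lambert–Beer chain, optionally with
an exponential bend after half the trace to exercise linear-range
selection. Scenario objects tie these together for one enzyme/solvent
across a temperature grid with the true c_U50 decreasing linearly in
temperature (default −0.6 % (v/v)/°C from 30 % at 25 °C), consistent with
the general observation that hotter conditions unfold at lower co-solvent
concentrations. All noise is seeded; identical seeds give bit-identical
datasets. What the generators do *not* emulate: plate/edge-well effects,
photobleaching and other drift, replicate capillary variation, substrate
depletion kinetics beyond a single bend, and non-Gaussian outliers — so
passing recovery tests demonstrate correctness of the estimators under the
models' own assumptions, not robustness to every real-data pathology.

## Problem sizes and verification

Recovery tests use the models' native design: 19-point concentration grids
(0–45 % in 2.5 % steps), 141-point melt curves, 49–97-point kinetic
traces. The precision study runs 100 seeded generate-then-fit replicates
at noise sd = 1 % of the transition amplitude (about 0.002 signal units
for a 0.2-amplitude transition) and summarises the spread of fitted c_U50
as a sample standard deviation; `scripts/acceptance.py` reports that
spread and the extracted T_m of a noise-free 49.0 °C melt curve, deriving
every replicate seed deterministically from `--seed`. Noise-free fits
recover generating parameters to ≤ 0.1 % (v/v) in the midpoints and ~1 %
relative elsewhere; under 1 % noise the c_U50 spread is ≈ 0.1 % (v/v),
comfortably below the ~2 % uncertainty quoted for such measurements.

## Known limitations

Two-state only: no intermediates, no multi-domain unfolding, no
temperature dependence of m_folding, no ΔH/ΔS decomposition. The activity
model is empirical — ξ and ν have no direct kinetic interpretation, and
the fitter is agnostic to whether activities are specific or relative
(axis units are the caller's responsibility). Vendor instrument exports
must be pre-converted to the documented long-format CSV; no binary
parsers are included.
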