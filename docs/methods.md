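# Methods

## Residence-time estimation

A residence time (time-integrated activity coefficient) τ is the
integral over all time of an organ's fraction-of-injected-activity
curve, in hours. The pipeline computes it in two parts.

**Measured part.** Scan frames have unequal durations (the 240-min
acquisition is re-binned as 7×1, 2×5 and 4×10 min frames, then 10-min
frames to 237 min and one closing 3-min frame), so integration uses the
trapezoid rule on *frame midpoints*, not frame edges. A t=0 anchor is
prepended by default: 0 %ID for organs and 100 %ID for the whole body,
reflecting an intravenous bolus that is entirely in the body but not
yet in any organ at injection. Anchoring is configurable
(`residence_times(..., anchor=False)`) because integrating from the
first midpoint instead changes τ by at most the area of the first
half-frame.

**Tail.** Beyond the last frame, activity is extrapolated by physical
decay of the radionuclide only — no biological clearance — which
integrates in closed form to A_end/(100·λ). The tail starts at the last
frame *midpoint* with the last measured activity; since the integral is
independent of its start time, this choice only affects which activity
sample feeds it. The default half-life is fluorine-18's 109.77 min;
any value can be supplied through `DecayConstants`.

**Decay correction.** Integration requires physically decaying
activity. Curves flagged `decay_corrected` are automatically
"uncorrected" (multiplied by e^{−λt} at frame midpoints) before
integration, with a log message — silently integrating corrected
curves would inflate τ by up to a factor of two over a 240-min ¹⁸F
scan. The flag is explicit metadata in every TAC file because exported
curves from analysis software can be either.

**Remainder.** τ_remainder = τ_whole-body − Σ τ_organ. Overlapping
VOIs can overcount slightly, so a deficit below 2% of the whole-body τ
clamps to zero with a logged warning; a larger deficit raises, since it
indicates corrupt input. Whole-body τ is additionally validated against
the pure-physical-decay bound 1/λ (= 2.6394 h for ¹⁸F) with 5% slack,
matching the measurement tolerance on whole-body activity.

## Interspecies normalisation

Each organ τ is multiplied by (b_r/o_r)·(o_h/b_h): the rat organ's
kinetics transferred to an organ occupying the human organ's share of
body mass. Body masses are b_r = 332.67 g, b_h = 73 000 g (adult male)
and 60 000 g (adult female). The whole-body τ is *not* scaled — total
cumulated activity is fixed by decay physics and no whole-body factor
is defined — and the remainder is recomputed after organ scaling, with
the same clamping rule. Re-normalising an already-normalised set is an
error (the flag travels with the data). The bundled organ-mass tables
are editable reference fixtures (literature-typical rat masses,
reference phantom human masses); substitute study-specific masses for
real work.

## Dose engine

Absorbed doses are the exact MIRD matrix–vector product
D_T = Σ_S τ_S·S(T←S), joined by organ *label* so organ order in any
input file is irrelevant. The remainder is an explicit S-matrix source
column; the phantom-internal mass-weighted remainder correction some
dosimetry programs apply is deliberately not re-derived, as it requires
phantom composition data beyond the declared inputs. The urinary
bladder is a static source (no voiding model). Effective dose is
Σ_T w_T·D_T with the weight sum validated to 1 ± 1e-9; radiation
weighting is 1 for positron/photon emissions, so mGy/MBq and mSv/MBq
coincide numerically.

The shipped S-value matrices are synthetic: diagonal terms from the
mean ¹⁸F positron energy deposited locally per unit cumulated activity
(plus a 30% photon self-absorption allowance), off-diagonal terms from
an inverse-square annihilation-photon kernel with attenuation, and a
flat distributed-source remainder column. They are physically plausible
and diagonally dominant but are *not* Monte-Carlo phantom S-values;
absolute doses computed from them exercise the machinery, not any
phantom. The tissue-weight file is an ICRP-60-style scheme renormalised
to the eight modelled targets so its sum is exactly 1.

## Bias analysis

Predicted organ doses are regressed on measured clinical doses by
ordinary least squares with an intercept (matching common graphing
software defaults; a through-origin option exists). Only the slope
feeds the bias summary: mean percent bias = |1 − slope|·100. The slope
95% CI uses the t distribution at the fit's residual degrees of
freedom; a model differs from the line of identity iff 1 falls outside
the inclusive CI. Bland–Altman summaries use differences
predicted − true against pair means with limits of agreement at
mean ± 1.96 SD (n−1 denominator).

The LLI-wall sensitivity check refits with and without that organ and
reports the ratio of mean percent biases (with/without). "Precision
improvement" has no unique numerical definition; the bias ratio is the
package's operationalisation and is isolated in one function so an
alternative can be plugged in.

The correction factor is the arithmetic mean (and range) of the mean
percent biases of the normalised-FBP model family, rounded to integer
percent only at report level. On the published sixteen-model slope
table shipped with the package this gives 42% (range 22.07–58.34).
Two rows of that table print bias values inconsistent with their own
slopes (11.26 vs the recomputed 12.6, and 47.87 vs 48.7) — presumed
printing errors; the formula is implemented as defined and those two
printed values are simply not used as checks. The simplified correction
divides predictions by (1 − bias/100); the exact mode divides by the
fitted slope.

## Synthetic-data generator

The generator exists so every stage is testable without animal data.
Organ curves follow a two-rate model
A(t) = 100·f·(e^{−k_out·t} − e^{−k_up·t})/peak · e^{−λt}, sampled at
frame midpoints with multiplicative lognormal noise (activities are
positive; mean-1 noise with configurable CV, default 5%). The default
kinetic preset is kidney-dominant with bladder accumulation — the
biodistribution signature of renally cleared peptide tracers
(f: kidneys 0.28, bladder 0.10, liver 0.06, intestine 0.05, lungs and
heart 0.02, brain 0.01). The whole-body curve is the 100 %ID physical
decay envelope reduced by a saturating excreted fraction (12%
asymptote, rate 0.02/min) and clipped to the envelope, so it never
exceeds 100 %ID.

Reconstruction bias is modelled statistically: the iterative member of
each scan pair scales the *source-organ* activities by ρ (default 1.6)
with independent noise. The whole-body curve is not scaled — scaling it
too would violate the 100 %ID bound and could not preserve a
non-negative remainder — so the ρ recovery analysis, like the
underlying relationship it emulates, runs on organ residence-time
pairs. All randomness flows through one seeded generator;
identical seeds give bit-identical outputs, including the fixture
bundle files.

The generator emulates the frame schedule, kinetic shape, noise
character and reconstruction-ratio structure of real rodent dosimetry
data. It does not emulate partial-volume effects, VOI delineation
error, inter-animal kinetic variability beyond noise, or image-domain
reconstruction artefacts — so passing tests demonstrate correctness of
the computational pipeline, not fidelity of any particular animal
study. Quantities that depend on the real animal data and true phantom
S-values (absolute organ doses, per-study r², the τ-ratio means near
1.6, the exact LLI improvement range) are covered by structural
property tests (linearity, physical bounds, outlier behaviour) rather
than numeric reproduction.

## Numerical and interface choices

- Times are minutes in files, hours for τ; the conversion lives in one
  function. Activities are %ID in files, fractions inside integrals.
- TAC files round-trip bit-exactly: floats are written with 17
  significant digits and parsed with round-trip precision.
- Organ labels pass through a controlled vocabulary; unknown names
  raise rather than being dropped, and paired VOIs (left/right kidney
  or lung) are summed into the single phantom organ at read time.
- Dose-ranking ties break alphabetically for determinism.
- Simulation sizes in tests and the acceptance script (dense 0.1-min
  sampling for the decay oracle, 200 Monte-Carlo replicates, 6-subject
  cohorts) were chosen as the smallest sizes at which the stochastic
  estimates are stable to well within their tolerances.

## Known limitations

- No biological (multi-exponential) tail fitting — decay-only
  extrapolation is the method implemented, by design.
- No dynamic bladder voiding model.
- The synthetic S-values support testing and demonstration only;
  reproducing production dosimetry numbers requires real phantom
  S-value tables in the documented CSV layout.
- Allometric (power-law) interspecies scaling is out of scope; only
  mass-fraction scaling is provided.
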