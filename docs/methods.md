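# Methods

## The measurement and the chronogram model

A COPAS Biosort large-object flow cytometer records one event per object:
time of flight (TOF, proportional to axial length and hence a proxy for
developmental stage), extinction (EXT, integrated optical density), green
peak height, and — with the profiler option — an ordered sequence of green
PMT samples along the passage axis. Two facts shape the analysis: the
passage orientation (head- or tail-first) is random per worm, and an export
contains non-worm objects (bubbles, eggs, debris).

A chronogram summarizes a whole mixed-stage population as a developmental
pseudo-time course without tracking individuals: after filtering, profiles
are sorted by length, oriented to a common head/tail polarity, and all
worms of each exact observed length are averaged into one row. Exact-length
grouping (no binning) is deliberate — each row is "the mean profile of all
worms of length L", and unobserved lengths are skipped and recorded rather
than interpolated. Row averaging is unnormalized by default; per-worm
max-normalization before averaging is an option, since raw exports carry
meaningful absolute PMT scales that normalization would discard.

## Orientation by Pearson correlation chaining

Adjacent worms in the length-sorted chain are developmentally similar, so
their longitudinal profiles correlate strongly when oriented alike. Walking
from the anchor (the longest worm by default — adults have the strongest,
most asymmetric signature), each profile is kept or reversed, whichever
direction has the larger Pearson coefficient against the previously
oriented neighbor. "Pearson correlation" here is the raw product-moment
coefficient used as an alignment score; no hypothesis test or p-value is
involved. Unequal-length neighbors are both linearly resampled to a fixed
common grid (default 100 points) before correlating — symmetric treatment
that avoids biasing toward either profile's length.

The greedy choice is globally optimal, not a heuristic: writing the flip
state of profile *i* as sᵢ ∈ {0,1}, each adjacency term of the chain score
Σᵢ r(pᵢ, pᵢ₊₁) depends only on sᵢ⊕sᵢ₊₁ (reversing both sequences leaves r
unchanged), so the terms can be maximized independently given an arbitrary
anchor state. Consequently (a) the chain attains the maximum over all 2ⁿ
orientation assignments, which the test suite verifies against a
brute-force enumeration, and (b) the global polarity of the result is
arbitrary — every downstream comparison is defined up to a global
left-right mirror, and mirror-sensitive summaries (the chronogram ROI
signal) evaluate both polarities and report the larger.

Numerical conventions: profiles are 0-indexed with body position normalized
to [0, 1], endpoints inclusive; resampling preserves endpoints exactly and
is exact on affine profiles; a zero-variance sequence has undefined r
(sentinel, not 0); |r_keep − r_flip| ≤ 1e−9 counts as a tie (palindromic
profiles land here only through floating-point residue of resampling), and
ties keep the profile as-is with an `ambiguous` flag. Length ties in the
sort are broken by event id for reproducibility.

## Filters

* Artifact rules (event level): reject TOF < 30 or EXT/TOF > 10. Bubbles
  scatter light strongly for their transit time, giving an EXT/TOF ratio
  far above any worm, whose EXT grows roughly linearly with length. The
  thresholds are tunable; the defaults separate the synthetic artifact
  model from synthetic worms with a wide margin.
* Length rule (profile level): remove profiles with fewer than 80 samples
  (strictly "smaller than", so an 80-sample profile is kept). This discards
  eggs, debris and hatchling larvae. The threshold is in profile-sample
  units; TOF and sample count are kept as distinct fields and never
  converted into each other, even though the synthetic generator happens to
  set them equal.

Every filter returns the retained dataset plus an explicit rejection report
(event id and the rule that fired), so records_in = records_out +
records_rejected holds at every stage and the chronogram's Σ n_merged
equals the retained profile count.

## Population statistics

Per-worm fluorescence is summarized as the mean of the profile samples —
reversal-invariant and, unlike the integral, not confounded by worm length
(the integral is exposed as an option). The gated summary averages per-worm
means over events with TOF strictly greater than the gate (default 200;
250 for the gonad-onset variant). Two-population comparison reports the
effect ratio of gated means, a two-sided Wilcoxon rank-sum test on the
per-worm gated means (computed via the equivalent Mann-Whitney U in scipy;
chosen because fluorescence distributions are far from normal — no
distributional assumption is warranted), and two directional flags:
growth_delayed (median TOF lower in the treated group) and
fluorescence_reduced (effect ratio < 1). Length histograms use half-open,
left-closed bins [k·w, (k+1)·w).

## The synthetic population generator

The generator produces the statistical structure the pipeline assumes, with
per-event ground truth (true length, gonadal amplitude, passage
orientation, artifact flag), so every stage is testable against known
answers. Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `length_log_mean`, `length_log_sd` | 5.5, 0.45 | log-normal length (profile samples); median ≈ 245, spanning ~80 (L1) to ~900 (adult) |
| `gonad_onset_length` | 250 | length above which the gonadal signature appears (L3/L4 transition) |
| `gonad_ramp_length` | 50 | lengths over which the gonadal amplitude ramps from 0 to full — the gonad grows with the worm rather than switching on |
| `gonad_center`, `gonad_width` | 0.55, 0.08 | Gaussian bump position/width as body-length fractions |
| `gonad_amplitude` | 800 | gonadal GFP peak (PMT units), dominating the body signal as a bright reporter does |
| `head_marker_amplitude` | 20 | anterior bump at position 0.15 (width 0.05), emulating pharyngeal autofluorescence; the anteroposterior asymmetry that makes orientation recoverable |
| `baseline`, `noise_sd` | 5, 3 | body autofluorescence; additive Gaussian sample noise, clipped at 0 (PMT counts are non-negative; additive rather than lognormal noise keeps the noise-free oracle linear) |
| `flip_probability` | 0.5 | random passage orientation |
| irradiated condition | growth_delay 0.3 (log units, ≈ 26 % shorter), gonad_reduction 0.3, agenesis_fraction 0 | the two reported phenotypes — stunted growth and reduced gonadal reporter — modeled independently; no dose-response model (a single dose condition) |
| `bubble_rate`, `debris_rate` | 0 (opt-in) | bubbles: TOF ∈ [5, 25) with EXT/TOF ∈ [20, 50); debris/eggs: profile length uniform in [10, 79] |

TOF is set equal to the profile sample count and EXT = 0.5·length·(1+ε)
for simplicity; the pipeline relies on neither equality. All draws come
from one `numpy.random.default_rng(seed)` (PCG64), so identical configs
give identical populations across platforms.

The single-Gaussian gonadal signature is a simplification (the adult gonad
is bilobed); the growth ramp was chosen over a hard on/off amplitude
because an amplitude discontinuity at the onset length creates one
adjacent pair in the chain whose correlation sign is noise-dominated — a
failure mode real populations, where the signal develops gradually, do not
exhibit. With the defaults, the closed-form expectation of the noise-free
profile mean gives a gated (TOF > 250) control mean of ≈ 168 PMT units and
an irradiated/control ratio of ≈ 0.33 at gonad_reduction 0.3 — close to
but not exactly the reduction factor, because baseline and head-marker
terms do not scale with the gonadal signal.

What passing tests on these populations do **not** show about real data:
real exports have TOF–sample-count calibration offsets, autofluorescence
that varies with stage and food, bimodal adult gonad signatures, detector
saturation, and non-Gaussian noise. The generator is a correctness harness
for the pipeline's logic (orientation, merging, conservation, gating), not
a biophysical simulation.

## Dosimetry

D [Gy] = 1.6×10⁻⁹ · LET [keV·µm⁻¹] · F [cm⁻²] for a thin unit-density
target under constant LET (no range/straggling or beam-transport model;
for 3 MeV protons across a worm's ~30 µm thickness the constant-LET
approximation is conventional). The coefficient is the conventional
rounded value; a CODATA-elementary-charge variant (1.602176634×10⁻⁹) is
selectable. Raster budgeting converts the scan field with 1 µm² = 10⁻⁸ cm²
and rounds proton counts **up** so the delivered dose is never below the
request; a 10⁻⁶ relative snap-to-integer precedes the ceiling so that
analytically exact counts (e.g. 40,000 protons for 300 Gy at LET 12 over
16×16 µm²) are not inflated by one proton of binary floating-point residue.

## Problem sizes used in the automated checks

The test suite exercises the pipeline at the sizes the method targets:
orientation recovery on 300-worm populations, effect recovery at 500 per
group over 10 seeds, directional phenotype flags at 450 vs 514 per group
over 100 seeds, and rank-test null calibration over 1000 same-config pairs
at 200 per group — chosen so the whole suite completes in well under a
minute of simulation-dominated work while keeping binomial/standard-error
bands tight enough to be informative.

## Known limitations

* Orientation assumes anteroposterior asymmetry in the profile; a
  population with symmetric profiles (no anterior marker, no gonadal
  signal) is unorientable and will be flagged ambiguous, not guessed.
* A single mis-orientation mid-chain flips the polarity of everything
  downstream of it; the chain is robust when adjacent-length worms are
  similar, but sparse length coverage (large gaps between adjacent worms)
  weakens the correlation signal.
* Exact-length grouping makes rows with n_merged = 1 noisy; the optional
  width-k binning trades length resolution for row averaging.
* Single green channel only; no elastic (dynamic-time-warping) alignment;
  no EXT-based chronograms.
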