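# Methods

This note records the models behind `emtqa`, the parameters that matter,
what the synthetic phantom does and does not emulate, and the design
choices made where the underlying procedure left the design open.

## Signal model

A recording holds, at 40 Hz, the 3-D position of a solenoid sensor driven
through implanted catheters by an afterloader, three chest fiducial
positions, and per-sample afterloader annotations (STOP / MOVE_IN /
MOVE_OUT, dwell index, catheter id).  The solenoid channel is modelled as

    z(t) = x(t) + b(t) + ε(t),            ε ~ N(0, σ² I)

with x(t) the stop-and-go track along the catheter (piecewise constant at
dwell positions, constant-speed transit between them), b(t) the breathing
displacement shared with the fiducials, plus occasional all-zero dropout
rows written by the tracker.  Units are millimetres and seconds throughout;
coordinate frames are arbitrary right-handed frames, which is admissible
because the final comparison is distance-based.

## Stage 1 — particle filter

A bootstrap (sampling-importance-resampling) filter with state
θ = (l, x, y, z, t).  The drift model

    f(l, t) = R_A·L + s + a/2 + Σ_{i=1..7} (b_i cos ω_i t + c_i sin ω_i t) + ε^(x)

is fully configurable; every coefficient defaults to zero, reducing the
evolution to a position random walk — a deliberately weak prior, since the
afterloader's speed profile varies between devices.  The likelihood is an
isotropic Gaussian on the three position components only; l and t carry no
measurement.  Defaults: N = 1000 particles, state noise 0.5 mm, observation
noise 0.5 mm, systematic resampling when the effective sample size drops
below N/2.  If every likelihood underflows (a dropout 100+ mm away), the
particle cloud is reinitialised around the observation and a warning is
logged; the resulting spike is exactly what the outlier stage repairs.
On the 1-D linear-Gaussian reduction the filter reproduces the Kalman mean
(checked in the tests at N = 100…10000).

## Stage 2 — SSA outlier repair and breathing reference

Embedding dimension K defaults to min(40, T/4) — at 40 Hz a 1 s window,
long enough to straddle dropout bursts, short next to a breathing period,
and keeping the segment length L = T−K+1 well above K.  Series are
decomposed **without mean removal**, so the first component carries the
local trend used as the replacement value; this follows the operational
description of the repair (raw entries are replaced by first-component
entries) rather than the zero-mean convention of the textbook presentation.

The outlier rule |x − median(x)| > 2·std(x) is evaluated per axis over the
full series in a single pass; the union of the per-axis index sets, dilated
by ±2 samples (the unquantified "neighbouring entries"), is patched on
every axis.  Note two intrinsic properties of the rule: a Gaussian signal
always has ≈5% of samples beyond 2 sd, and the replacement value is taken
from the SSA of the *corrupted* series, so it is biased toward the dropout
by roughly dropout-magnitude/K.  Both are accepted: patches land mostly on
transit samples and plateau tails, where the first component is an accurate
local trend.

The breathing reference is the three-fiducial average reduced to its first
SSA component per axis.  Because a sinusoid occupies an SSA *eigenpair*,
the first component retains the waveform only up to a quadrature remainder
(correlation ≈ 0.95–0.99 in practice) — sufficient for mode
identification, which is correlation-based.

## Stage 3 — EEMD breathing removal

EMD sifting uses cubic-spline envelopes through the local extrema (plateau
extrema collapse to their midpoint — dwell segments are flat), mirror
extension of two extrema at each boundary, a Cauchy-type SD stopping
criterion at 0.2 with at most 10 siftings per mode, and at most 12 modes.
EEMD averages E = 10 sifting runs, each on the signal plus fresh white
noise of sd 0.2 × signal sd; members with fewer modes are padded with zero
modes just before the trend so trends stay aligned when averaging.

**Protection.**  The spectral area of a mode, A = Σ_r |C(r)|/(T·T_s), keys
the protection of stop information.  Thresholding raw mm-scale areas is
meaningless across signal scales, so the pipeline thresholds the area under
the *peak-normalised* spectrum, Σ_r|C(r)| / (T·max_r|C(r)|) ∈ [1/T, 1],
against A_th = 0.04.  Broadband modes — the abrupt stop-and-go
displacements spread over the whole band — score a few tenths regardless of
amplitude or record length; narrowband breathing modes concentrate their
mass next to a tall spectral peak and score ~10⁻³–10⁻².  Peak
normalisation, unlike energy normalisation, is insensitive to the flat
ensemble-noise floor that EEMD averaging leaves in every mode.  The final
(trend) component is additionally always protected by the pipeline: the
catheter track's ramp lives in the trend and breathing is zero-mean, so
removing the trend can never be intended.

**Identification.**  Each unprotected sensor mode is compared against every
oscillatory mode of the breathing reference; it is flagged when its best
match passes the criterion: |PCC| ≥ 0.4, JSD ≤ 0.3, or KLD ≤ 1.2
(natural-log divergences on √T-bin histograms over the pooled range of the
pair, zero bins smoothed with ε = 10⁻⁴ ≤ 10⁻³).  Two guards keep the
comparison physical: only modes whose dominant frequency lies in the human
breathing band 0.1–1.5 Hz are flaggable or candidates (a ~90 s record holds
only a few cycles of slower drift modes, whose correlations are therefore
high-variance and once in a while spuriously exceed any threshold — and
removing a slow track mode costs millimetres), and reference modes carrying
less than 10% of the reference sd are not candidates.  The thresholds were
calibrated on thirty synthetic scenarios (seeds 11–20 × three breathing
modes, disjoint from every seed used in the tests): 0.4 and 0.3 were
confirmed for PCC and JSD; for KLD the conventional 0.3 flags almost
nothing — matching-mode KLD on fine histograms sits around 0.5–0.8, an
order of magnitude below mismatched modes — hence 1.2.  Reconstruction sums
the non-flagged modes; removal may be iterated with re-decomposition
(`eemd.max_iterations`, default 1, stops early when nothing is flagged),
and `--drop-imfs` provides the manual expert override.

**Per-catheter processing.**  The whole chain runs on each catheter's
contiguous segment separately.  Within one segment the track is a single
monotone staircase; concatenating catheters injects large inter-catheter
excursions into the 0.1–0.5 Hz band, which measurably contaminates the
breathing modes (in a direct comparison, whole-record processing lost to
the no-cleaning baseline on half of the calibration scenarios, per-catheter
processing on none).

## Stage 4 — dwell extraction and MDS registration

Dwell positions are the component-wise means of the samples in each STOP
run (runs are delimited by command, dwell-index or catheter changes), with
the sample count N_s recorded.  Classical MDS embeds each point set from
its pairwise distances: (D)ₘₘ′ = −½ d²(xₘ, xₘ′), double-centring, spectral
coordinates X̂ = Λ^{1/2}Vᵀ over the top-3 eigenvalues; fewer than three
positive eigenvalues (collinear/coplanar geometry) is an error.  Spectral
embeddings carry an arbitrary rotation and per-axis sign, so the measured
embedding is mapped onto the plan embedding by orthogonal Procrustes over
the matched (catheter, dwell index) correspondences — translation and
rotation free, **no scaling** (deviations are physical mm), reflection
accepted only when it strictly lowers the residual (it usually is needed,
precisely because of the sign ambiguity).  A `method="direct"` mode skips
the spectral embedding and aligns raw coordinates; for exact Euclidean data
the two routes coincide (tested).  Plan positions never traversed are
reported but excluded from all means.  Isotropic distances are used
throughout; no anisotropy-aware weighting is applied.

## Synthetic phantom

The generator emulates: catheters on a two-row template grid as
circular arcs (default curvature 0.003 /mm) cut to ≤ 287.5 mm; dwell points
every 2.5 mm starting 5 mm from the tip; dwell times uniform on 0.1–5 s
quantised to the 40 Hz grid; transit at 50 mm/s (admissible range
25–500 mm/s); a random rigid CT→EMT frame change (rotation 0.3–2.5 rad —
the field-generator frame is unrelated to the CT frame); breathing as a
harmonic sum with Ornstein–Uhlenbeck-modulated amplitude and frequency
(chest 0.30 Hz, belly 0.20 Hz, speaking 0.35 Hz with ~5× the jitter and a
bursty envelope), default per-axis amplitude (3, 1.5, 0.75) mm — a
dominantly one-directional chest displacement roughly perpendicular to the
catheter axes; i.i.d. Gaussian measurement noise (default sd 0.5 mm, the
scale of reported EMT accuracy); Bernoulli zero-dropouts.  All randomness
derives from the scenario seed.

Not emulated: field-generator distance-dependent noise anisotropy and
metal-induced field distortion, tissue deformation and catheter bending
between sessions, sensor-orientation (6-DoF) content, and afterloader
timing jitter.  Passing tests therefore demonstrate that the chain removes
additive quasi-periodic motion artifacts and dropouts under realistic
geometry — not that it compensates field distortion or non-rigid anatomy
change.

## Problem sizes

Tests and the acceptance script use four catheters with eight dwell
points each (~90 s, ~3600 samples per recording), five replicates per
breathing mode — sizes chosen so the full suite runs in about a minute
while every stage operates in its intended regime.  The generator defaults
keep the full study conditions (287.5 mm catheters, complete dwell
ladders), which are reached by simply not capping `n_dwells_per_catheter`.

## Known limitations

* Breathing that shares a band with the dwell-step cadence cannot be fully
  separated by mode decomposition; removal captures the dominant-axis
  breathing mode (~50–70% of its dwell-level effect) and leaves weak-axis
  residues.  Speaking-mode bursts spread breathing into the protected
  broadband modes, which is visible as slightly larger post-cleaning
  deviations.
* The divergence-based measures (KLD, JSD) compare amplitude histograms,
  which are phase-blind; they occasionally flag noise-like modes whose
  histograms resemble a breathing mode's.  Agreement with PCC stays within
  ~0.2–0.5 mm on synthetic scenarios, but PCC is the default for a reason.
* With fewer than four matched dwell pairs, or (near-)coplanar dwell
  geometry, the registration is undefined and the pipeline raises.
* The 2·std outlier rule is distribution-dependent: on heavy-tailed
  segments it under-flags, on compact segments it flags ~5% tails; the
  SSA replacement makes both failure modes cheap.
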