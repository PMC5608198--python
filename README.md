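# emtqa

Automatic analysis of electromagnetic-tracking (EMT) recordings for
dwell-position quality assurance in high-dose-rate (HDR) breast
brachytherapy.

## The problem

During HDR breast brachytherapy a radioactive source is stepped through
catheters implanted in the breast, stopping at planned *dwell positions*
(2.5 mm apart, first position 5 mm from the catheter tip) for planned
*dwell times*.  Between treatment sessions the catheters can shift, so
before each session a 5-DoF solenoid sensor is driven through the catheters
by the afterloader and tracked at 40 Hz by an electromagnetic field
generator.  The recorded track is corrupted by measurement noise,
occasional tracker dropouts (written as all-zero rows), and — dominantly —
the patient's breathing motion, which three chest-mounted fiducial sensors
record independently.  The task is to recover the clean dwell positions and
quantify their deviation from the CT-based treatment plan, even though plan
and EMT session live in different coordinate frames.

## The method

The chain, applied per catheter and per spatial axis:

1. **Particle filter** (sequential importance resampling, N = 1000).  Latent
   state θ = (l, x, y, z, t); state evolution
   f(l,t) = R_A·L + s + a/2 + Σᵢ₌₁⁷ (bᵢ cos ωᵢt + cᵢ sin ωᵢt) + ε⁽ˣ⁾ (a
   random walk under the zero defaults); observations h(θ) = θ + ε⁽ᶻ⁾ with
   an isotropic Gaussian likelihood on the position block.
2. **Singular spectrum analysis** (SSA).  The Hankel trajectory matrix
   X (L×K, T = K+L−1) is eigendecomposed through XᵀX; anti-diagonal
   averaging returns additive components.  Samples failing the outlier rule
   |x − median(x)| > 2·std(x) (tracker dropouts) are replaced, together with
   ±2 neighbours, by first-SSA-component values; all other samples are kept
   bit-identical so stop information survives.  The averaged fiducial
   signal, reduced to its first SSA component, is the breathing reference.
3. **Ensemble empirical mode decomposition** (EEMD, E = 10 sifting runs
   with fresh white noise).  Both the sensor signal and the breathing
   reference are decomposed into intrinsic mode functions (IMFs).  Modes
   whose peak-normalised Fourier-spectrum area Σᵣ|C(r)| / (T·max|C|)
   exceeds A_th = 0.04 are *protected*: broadband modes carry the abrupt
   stop-and-go displacements.  Unprotected sensor modes similar to a
   breathing mode — by Pearson correlation (|PCC| ≥ 0.4), Jensen–Shannon
   divergence (≤ 0.3) or Kullback–Leibler divergence (≤ 1.2) — are dropped
   from the reconstruction.
4. **Classical multidimensional scaling** (MDS).  Dwell positions are the
   point-cloud means of each afterloader STOP run.  Plan and measurement
   are embedded from their pairwise distances ((D)ₘₘ′ = −½d²(xₘ,xₘ′),
   double-centred, X̂ = Λ^{1/2}Vᵀ), aligned by correspondence-based
   orthogonal Procrustes over matched (catheter, dwell index) keys, and the
   deviation of each dwell pair is the Euclidean distance in mm.

A seeded synthetic phantom generator (stop-and-go motion, three breathing
modes — calm chest, calm belly, erratic speaking — Gaussian noise,
zero-dropout outliers) makes every stage testable without any download.

## Worked example

```bash
emtqa simulate --out-dir . --mode chest --n-catheters 4 --n-dwells 8 \
               --catheter-length 50 --seed 11
emtqa run plan.json recording.csv report.csv --seed 11
```

prints

```
catheter  n_pairs  mean_deviation_mm
       1        8              0.649
       2        8              1.425
       3        8              0.807
       4        8              0.686
global mean over 32 pairs: 0.892 mm
```

Each row is one implanted catheter with the mean distance (mm) between its
reconstructed dwell positions and the treatment plan after breathing
removal and frame registration; the global mean is the per-pair average
over all 32 dwell pairs.  For this scenario the same comparison without any
cleaning gives a 1.15 mm global mean, i.e. the pipeline removed most of the
injected 3 mm breathing artifact.  `report.csv` holds one row per dwell
pair plus per-catheter and global summary lines; `--figure out.png` adds
the deviation-vs-dwell-pair plot with catheter separators.

The same chain is scriptable from Python:

```python
from emtqa import (PhantomScenario, generate_plan, generate_recording,
                   run_pipeline, PipelineConfig)
scenario = PhantomScenario(seed=11)
plan = generate_plan(scenario)
recording, truth = generate_recording(plan, scenario)
report = run_pipeline(plan, recording, PipelineConfig(seed=11))
print(report.global_mean)
```

## Layout

```
src/emtqa/io_formats.py          plan (JSON), recording (CSV), report (CSV)
src/emtqa/synthetic_phantom.py   seeded phantom scenario generator
src/emtqa/particle_tracking.py   SIR particle filter
src/emtqa/ssa_core.py            SSA, outlier detection and repair
src/emtqa/eemd_core.py           EMD/EEMD, protection, breathing removal
src/emtqa/similarity_measures.py PCC, histograms, KLD/JSD, entropy, MI
src/emtqa/mds_registration.py    dwell extraction, MDS, Procrustes, report
src/emtqa/pipeline.py            orchestration and configuration
src/emtqa/cli.py                 simulate / track / clean / compare / run
docs/methods.md                  models, parameters, design choices
```
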