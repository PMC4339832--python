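# wingstroke

Decomposition of insect wing-stroke kinematics into least-dependent
components.

Tethered fruit flies modulate an ~200 Hz wing stroke with subtle,
intermittent deformations driven by their steering-muscle system: yaw-torque
events, flight-force adjustments, pitch-related changes of the
downstroke-to-upstroke duration ratio, period-2 alternations, slow periodic
modulations.  Several such deformations are typically active at once and
superpose linearly, so no single kinematic parameter isolates them.  This
package recovers them blindly: it reads each wingbeat cycle as one sample of
a 16-dimensional signal **X** (the stroke angle of both wings at 8 phases of
the cycle), and finds the linear components

```
Z = W X,    I(Z_i, Z_j) -> min
```

whose mutual information — a measure of full statistical dependence, not
just correlation — is minimal.  MI is estimated with the Kraskov
k-nearest-neighbour estimator (k = 12); the separating matrix **W** is
found by whitening followed by Jacobi rotation sweeps that minimize the
summed pairwise MI.  Each component's time course is the activation of a
stroke deformation mode (column of **W**⁻¹); components are screened by
spectral flatness (Wiener entropy), tested for significance against a
shuffle-surrogate MI null, reconstructed individually or with
artifact-carrying components suppressed, and classified into seven
recurring kinematic pattern types.

The package is aimed at researchers analysing long quasiperiodic movement
recordings (insect flight, gait) who want independently controlled
components rather than principal components.  A fully seeded synthetic
two-wing recording generator with known injected patterns stands in for
tracker hardware, so the entire chain is testable end to end.

## Layout

```
src/wingstroke/     the library: synthetic, preprocessing, phase_signals,
                    milca, dependence, reconstruction, classification,
                    scenarios, pipeline, cli
analysis/           numbered narrative drivers (01_simulate ... 08_cohort)
scripts/acceptance.py   recomputes the benchmark quantities from scratch
tests/              pytest suite
docs/methods.md     model, numerics, design choices, limitations
```

## Worked example

Run the numbered analyses in order (large intermediates go to `scratch/`,
tables to `results/`):

```
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_extract_signals.py
python analysis/04_decompose.py
python analysis/05_dependence.py
python analysis/06_reconstruct.py
python analysis/07_classify.py
python analysis/08_cohort.py        # cohort of 10 simulated flies
```

The demo recording holds 2600 wingbeat cycles with all seven pattern types
plus three mistracking artifacts injected simultaneously — a deliberately
hard, maximally dense segment.  Output from the run:

```
02: 2598 cycles detected; 0 discarded ([])
    wingbeat period 5.006 +- 0.025 ms (frequency 199.8 Hz)
03: X: 16 signals x 2598 cycles; 1 segment(s) of 2500 cycles
    baseline downstroke-to-upstroke ratio: median 1.485 (min 1.071 during
    the injected ratio event)
04: converged=True after 4 sweeps (summed fitted MI drops per sweep:
    [1.594, 0.617, 0.163, 0.0])
05: alpha=0.01 threshold: 0.0167 nats (0.0241 bits)
    85.0% of the 120 component pairs are statistically independent
07: injected types: ['I', 'II', 'III', 'IV', 'V', 'VI', 'VII']
    recovered types: ['I', 'III', 'V', 'VI', 'VII']; 8 broadband-noise
    components
06: mistracking isolated in component 1 (|r|=0.73); RMS error vs clean
    ground truth 0.429 -> 0.371 deg
08: frequent types (>= 25% of 10 flies): ['I','II','III','IV','V','VI','VII']
    modal frequent-type count by batch size: {5: 5, 6: 6, 7: 7, 8: 7, 9: 6,
    10: 7}
    repeatability: mean co-occurring types per segment pair 2.80 (range 2-4)
```

Reading this: the injected mid-stroke mistracking does not trip the
double-dorsal-maximum discard rule (it is removed later, by component
suppression); the baseline duration ratio sits in the 1.45–1.55 band
typical of tethered flight and drops toward 1.1 during the injected
ventral-phase event; most of the 120 component pairs fall below the
shuffle-null significance threshold; five of the seven simultaneously
active deformations land in separate, correctly typed components (the
symmetric amplitude events and the period-2 alternation share a similar
deformation direction and stay partially mixed in this extreme segment —
with fewer concurrent patterns, as in the cohort run of step 08, all seven
types classify cleanly); suppressing the component that captured the
mistracking artifacts lowers the reconstruction error against the
artifact-free ground truth (step 06 runs this on a dedicated twin pair of
recordings).  The cohort step classifies 20 segments from 10 simulated
flies, recovers each fly's repertoire, and reproduces the
frequent-pattern bootstrap: batches of 7 flies already find the full-set
count of frequent types, batches of 5 typically miss one.

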