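# gbcpop

Population modeling of globular bushy cells (GBCs) with an adaptive
coincidence counting neuron.

GBCs in the anteroventral cochlear nucleus receive many medium-sized
auditory-nerve (AN) synapses and relay precisely timed spikes to the
binaural brainstem.  Driven by high-frequency tones they show
primary-like-with-notch (PL_N) or onset-L (On_L) peristimulus time
histograms with irregular sustained firing; driven by low-frequency tones
they phase-lock and entrain *better* than their AN inputs.  Real units,
however, vary widely, so instead of one "gold standard" cell this package
builds a *population* of models spanning that variability, for auditory
neuroscientists who need many realistic, cheap GBC units (e.g. as a front
end for binaural circuit models).

## The model

Each of `M_E` input fibers contributes a rectangular count of duration
`W_E` (the coincidence window) and amplitude `A_E`; the summed count
`v(t)` triggers an output spike when it reaches the adaptive threshold

```
theta(t) = theta_S + theta_D(t),    theta_S = 1,
T_A * d(theta_D)/dt = -theta_D(t) + S_A * v(t),
```

followed by an absolute refractory period `T_R`.  The threshold adapts to
the recent input level, so only well-synchronized input volleys fire the
cell — asynchronous input raises the bar under itself.  On the fixed
0.01-ms grid the threshold ODE has an exact per-step digital solution, so
the simulation involves no ODE solver at all.  The six parameters
(`M_E, W_E, A_E, T_R, T_A, S_A`) are screened over a 7×10×9×9×10×10 grid
(567,000 instances); instances are kept as PL_N when SR < 30 spikes/s,
DR ≥ 150 spikes/s, 0.65 ≤ CV′ ≤ 0.95, VS > 0.9, EI > 0.9 and the smoothed
PSTH passes four notch/peak shape criteria (On_L: the same with
DR in [50, 150)).

AN inputs come either from the built-in surrogate generator — spontaneous
rate 70 spikes/s, sigmoidal rate-level function, onset adaptation,
frequency-dependent phase-locking realized by wrapped-Gaussian jitter,
absolute + relative refractoriness — or from external spike-time files
(`trial,fiber,time_ms`).  See `docs/methods.md` for every model and
numerical choice.

## Worked example

Run the exemplar instance (`M_E=20, W_E=0.32 ms, A_E=0.40, T_R=1.2 ms,
T_A=0.25 ms, S_A=0.80`) through the selection battery:

```python
from gbcpop import DEFAULT_PARAMS
from gbcpop.population import InstanceEvaluator, SelectionProtocol

ev = InstanceEvaluator(protocol=SelectionProtocol.desk(n_trials=200), seed=1)
row = ev.evaluate(DEFAULT_PARAMS)
for k in ("sr", "dr", "cv_prime", "vs", "ei",
          "first_peak_rate", "first_notch_width", "category"):
    print(k, row[k])
```

prints

```
sr 14.6
dr 266.6666666666667
cv_prime 0.6931722684128483
vs 0.9407931752806569
ei 0.9897828863346104
first_peak_rate 2138.8888888888887
first_notch_width 0.6000000000000001
category PLN
```

Reading it: in silence the cell fires at 14.6 spikes/s — far below its
fibers' 70 spikes/s, because isolated input spikes stay subthreshold.  A
7 kHz, 70 dB SPL tone drives 266.7 spikes/s of irregular sustained firing
(CV′ 0.69) with a ~2100 spikes/s onset peak followed by a 0.6-ms notch —
the PL_N signature.  A 350 Hz tone yields vector strength 0.94 and
entrainment 0.99, above the ~0.81 phase-locking of any single input
fiber: coincidence detection sharpens timing.  All criteria pass, so the
instance is classified `PLN`.

The same battery scales to a parameter screen from the shell:

```sh
gbcpop grid-run --preset desk --seed 0 --out population.csv
gbcpop stack --population population.csv --value dr --out stack.csv --png stack.png
gbcpop analyze --population population.csv --out analysis/
gbcpop validate --population population.csv --protocol frequency --out bounds.csv
```

`grid-run --preset desk` screens 729 instances (3 values per dimension
around the exemplar, 100 trials) in about a minute; `stack` renders the
6-D grid as a nested 2-D dimensional-stacking image; `analyze` reports
connectivity of the accepted set, parameter correlations and polynomial
input–output fits; `validate` computes population VS/EI envelopes under
held-out stimuli (frequency sweeps, high-level 500 Hz "tail" tones, SAM
tones).  `gbcpop fra` computes a frequency response area with threshold
curve and Q10.

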