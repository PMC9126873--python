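# zeitgeber

Simulation and analysis of a **forced cell-free genetic clock**: a
two-gene activator–repressor oscillator (σ28 activating TetR, TetR
repressing σ28) running in a semi-continuous microfluidic ring reactor
and periodically perturbed by an external zeitgeber signal.  The
package is for researchers studying entrainment and complex dynamics —
period doubling, degenerate cycles, chaos — in synthetic biochemical
oscillators, and for anyone who needs a clean reference implementation
of the associated trace analysis.

## Model

Four ODEs for activator/repressor mRNA and protein, with Hill-type
regulation and dilution at rate δ:

```
ṙ_a = α_a / (1 + (h/K_h)^n_h) − (δ + 1/τ_m,a) r_a     ȧ = k_TL,a r_a − δ a
ṙ_h = α_h / (1 + (K_a/a)^n_a) − (δ + 1/τ_m,h) r_h     ḣ = k_TL,h r_h − δ h
```

The reactor replaces a volume fraction R every t_int = 15 min
(δ = −ln(1−R)/t_int), which sets the intrinsic period T ≈ Cπ/δ with
C ≈ 1.  Feeding the input species every k-th cycle gives a zeitgeber of
period T_in = k·t_int, and the dynamics is organised by the single
bifurcation parameter

```
λ = T_in / T ≈ k · (−ln(1−R)) / π .
```

Entrainment (m = 1 cycles), period doubling (m = 2, 4), and — at high
Hill coefficients — chaos appear as λ is tuned through ≈ 1.  The
rotation number m is measured from the sequence of equilibrated signal
maxima: the smallest shift k under which the sequence repeats to within
a 10% closure threshold.

## Worked example

```python
from dataclasses import replace
from zeitgeber import run_reactor, refresh_for_lambda
from zeitgeber import metrics, bifurcation
from zeitgeber.presets import get_preset

# free-running clock, 48 h at R = 0.25
params, protocol = get_preset("free")
trace = run_reactor(params, protocol)
est = metrics.acf_period(trace, "a")
print(f"free-running period: {est.period_h:.2f} +/- {est.uncertainty_h:.2f} h")
pm = metrics.phase_metrics(trace, "a")
print(f"regime: {pm.regime} (damping ratio gamma = {pm.gamma:.3f})")

# forced clock at lambda = 1.20: a period-doubled 4-cycle
params, protocol = get_preset("forced")
protocol = replace(protocol, R=refresh_for_lambda(1.20, protocol.k),
                   n_cycles=1012)
trace = run_reactor(params, protocol)
res = bifurcation.classify_trace(trace, "h")
print(f"forced at lambda = 1.20: rotation number m = {res.m}")
mx = bifurcation.detect_cycle_maxima(trace, "h")
pts = bifurcation.count_return_points(metrics.return_map(mx.heights))
print(f"distinct return-map points: {pts}")
```

prints

```
free-running period: 2.55 +/- 0.13 h
regime: sustained (damping ratio gamma = 1.019)
forced at lambda = 1.20: rotation number m = 4
distinct return-map points: 4
```

The free-running period (2.55 h) sits close to π/δ = 2.73 h; the forced
run at λ = 1.20 repeats only every four forcing periods and its maximum
return map visits four distinct points — the signature of two
successive period doublings.

## Command line

`zeitgeber` exposes the same pipelines as subcommands:

```sh
zeitgeber simulate-forced --lam 1.2 --n-cycles 1012 --out trace.csv
zeitgeber analyze-trace trace.csv
zeitgeber bifurcation-1d --lambda-min 0.6 --lambda-max 1.8 --points 25 --out scan/
zeitgeber synth --seed 7 --cv 0.05 --fatigue --out dataset/
zeitgeber reproduce period_doubling --out bundle/
```

Traces are plain CSV (`cycle, time_h`, one column per channel); every
bundle writes a `manifest.json` sufficient to re-run it.

## Synthetic data

`zeitgeber.synth` generates pseudo-experimental datasets — noisy
raw-intensity traces with an invertible calibration block, a spiked
exponentially decaying reference-dye channel, optional late-run fatigue
(the refresh ratio dropping by one percentage point after 36 h), and
Hill titration tables — always alongside the noise-free ground truth,
so every estimator in the package can be validated end to end.

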