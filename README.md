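# spikescale

Hierarchical temporal processing in spiking data: per-unit estimation of
**correlation timescales**, **predictability** and **information
timescales** from single-unit spike trains, a **branching-network
simulator** as synthetic ground truth, and **hierarchical Bayesian
models** for comparing the measures across brain areas.

## Who this is for

Systems neuroscientists asking whether temporal processing is organized
hierarchically across areas — e.g. along the mouse visual pathway from
thalamus through V1 to higher cortical areas — using chronically recorded
single-unit spike trains (Neuropixels-style data exported to CSV).  The
package covers the full analysis chain downstream of spike sorting and
quality filtering.

## The measures

For a spike train binarized at Δt = 5 ms (a_t = 1 iff a spike falls in
[t, t+Δt)):

* **Correlation timescale τ_C** — decay constant of the dominant
  exponential in the spike-train autocorrelation
  C(T) = (⟨a_t a_{t−T}⟩ − ⟨a_t⟩²)/(⟨a_t²⟩ − ⟨a_t⟩²), fitted as
  f(T) = A₁e^(−T/τ₁) + A₂e^(−T/τ₂) over lags 30 ms – 10 s; the term with
  the larger coefficient defines τ_C, the other absorbs slow
  stimulus-/state-driven decay (τ_sec).
* **Predictability R(T)** — fraction of the current-bin spiking entropy
  explained by mutual information with past spiking in a window of length
  T (d = 5 binary past bins with geometrically stretched widths, plug-in
  MI with shuffle-bias correction).  Its saturation value is the total
  predictability **R_tot**, and the gain-weighted rise point of R(T) is
  the information timescale **τ_R**.

The branching network (N binary units, sparse random weights normalized
so each unit activates on average m others, sigmoidal external drive with
homeostatic rate control at ν* = 3.5 Hz) ties these measures to a single
mechanistic knob, the recurrent amplification a/h = 1/(1 − m): with
uncorrelated external input all three measures grow with a/h, while with
temporally correlated (Ornstein–Uhlenbeck, τ_ext = 30 ms) input the
predictability starts high, falls to a minimum near a/h ≈ 20 and rises
again.  Area differences are modelled hierarchically: per-mouse
intercepts/slopes from normal parent distributions, skew-log-normal
(timescales) or log-normal (R_tot) unit likelihoods, and PSIS-LOO ELPD to
compare a *cortical groups* model (V1 vs higher cortical offset) against
a *cortical hierarchy* model (linear in the anatomical hierarchy score).
See `docs/methods.md` for model details and numerical choices.

## Worked example

Simulate a branching network at a/h = 10 with correlated input and
measure one recorded unit:

```python
from spikescale import BNConfig, simulate
from spikescale.branching import measure_unit

cfg = BNConfig(m=0.9, input_mode="ou", t_equil=300, t_record=600, seed=101)
rec = simulate(cfg)
print(f"realized rate {rec.realized_rate:.3f} Hz")
row = measure_unit(rec.trains[0], seed=1)
print(f"tau_C {row['tau_C']:.1f} ms, tau_R {row['tau_R']:.1f} ms, "
      f"R_tot {row['R_tot']:.4f}")
```

prints

```
realized rate 3.431 Hz
tau_C 17.0 ms, tau_R 38.3 ms, R_tot 0.0052
```

The homeostat holds the mean unit rate near the 3.5 Hz target; at this
amplification the unit's autocorrelation decays over tens of
milliseconds, and past spiking explains ~0.5% of the current-bin entropy
— an order of magnitude more than the same network yields with
uncorrelated input, reflecting the temporally correlated drive.

The numbered scripts under `analysis/` run the full study at reduced
scale: network simulations (`01`), per-unit measurement (`02`),
amplification sweeps for both input modes (`03`), Bayesian parameter
recovery with model comparison and LOO-PIT calibration (`04`), and
area-level descriptive statistics (`05`).  Each writes its tables under
`results/`.

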