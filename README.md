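# fretcascade

Quantitative two-step FRET analysis for a conjugated-polymer /
dye-labeled-aptamer potassium sensor.

The sensor couples a cationic polyfluorene conjugated polymer (CP, the
light-harvesting donor) to a 15-base guanine-rich aptamer carrying 6-FAM at
its 5′ end and TAMRA at its 3′ end.  K⁺ ions fold the aptamer into a
G-quadruplex, pulling the two dyes together and switching on a sequential
CP → 6-FAM → TAMRA energy cascade; the resulting TAMRA fluorescence
enhancement is the K⁺ read-out.  `fretcascade` implements the complete
time-resolved analysis of that system for spectroscopists working with
TCSPC (time-correlated single photon counting) data:

* **spectra** — spectral overlap integral `J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ`
  (M⁻¹·cm⁻¹·nm⁴), Förster distance
  `R₀ = 0.2108 [κ² n⁻⁴ Q_D J]^{1/6}` Å, and conversion of distances to
  FRET (`k = τ_D⁻¹ (R₀/R)⁶`) and photo-induced charge-transfer
  (`k = k₀ e^{−βR}`) rates.
* **decay_fitting** — exact wrapped-IRF reconvolution of multi-exponential
  decays `I(t) = I₀ + a₁e^{−t/τ₁} + a₂e^{−t/τ₂}` (80 MHz repetition,
  12.5 ns window, Gaussian IRF of 190 ps FWHM), Poisson-MLE or weighted
  least-squares fitting, and a reduced-χ²-plus-runs-test model-order rule.
* **kinetics** — exciton population dynamics `dNᵢ/dt = gᵢ − Nᵢ/τ_int,i −
  Nᵢ/τ*_nr,i ± transfer terms`, propagated exactly by matrix exponentials
  with closed quantum bookkeeping; time-dependent decay rate
  `k(t) = [g − dN/dt]/N` and scenario differences `Δk(t)`.
* **efficiency** — lifetime efficiency `φ = 1 − τ_DA/τ_D`, time-resolved
  efficiency `E(t) = [I_D − I_DA]/I_D`, and the acceptor gain efficiency
  `η(t) = [I_with − I_w/o]/I_w/o` (pointwise or cumulative).
* **synthetic** — a first-class generator for every input: vibronic
  mirror-image spectra pinned to the published peak wavelengths and
  extinction maxima, distance-parameterized assay scenarios, and Poisson
  TCSPC histograms with wrap-around.

## Worked example

```python
import numpy as np
from fretcascade.synthetic import simulate_tcspc, table1_model, tamra_gain_demo
from fretcascade.decay_fitting import fit_decay
from fretcascade.efficiency import cumulative_gain_efficiency

# simulate the with-K+ CP decay (a1=0.73 τ1=0.19 ns, a2=0.27 τ2=1.46 ns)
trace = simulate_tcspc(table1_model("cp_with_K"), total_counts=1_000_000, seed=1)
fit = fit_decay(trace, n_components=2)
print([round(tau, 3) for tau in fit.model.lifetimes_ns],
      [round(a, 2) for a in fit.model.amplitudes])

# acceptor gain efficiency at 2 ns from the calibrated TAMRA curves
t = np.linspace(0.0, 4.0, 401)
I_wo, I_with = tamra_gain_demo(t)
eta = cumulative_gain_efficiency(t, I_wo, I_with, 2.0, mode="pointwise")
print(f"eta(2 ns) = {100 * eta:.0f}%")
```

prints

```
[0.191, 1.46] [0.73, 0.27]
eta(2 ns) = 230%
```

i.e. the reconvolution fit recovers the generating fast/slow lifetimes and
pre-exponential weights from the Poisson photon histogram, and the
K⁺-induced TAMRA enhancement evaluates to a 230% gain efficiency at 2 ns.

A `fretcascade` command-line interface exposes the same steps
(`overlap`, `fit`, `simulate`, `efficiency`, `pipeline`); e.g.

```bash
fretcascade pipeline --scenario complex_with_K --seed 1 --out-dir run/
```

runs simulate → fit → rate curves → efficiency end to end and writes a
JSON report.

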