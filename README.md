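# p2dvolt

Pseudo-two-dimensional (P2D) simulation and analysis of redox-mediated
voltammetry at porous catalyst-modified electrodes, built around the
electrochemical reduction of metronidazole (MTZ) at a cobalt-oxide
nanolayer on glassy carbon.

Electrochemical sensors based on porous electrocatalyst films couple three
processes that a single-domain model cannot separate: analyte diffusion
through the quiescent electrolyte, hindered diffusion and distributed
reaction inside the porous layer, and the redox-state dynamics of the
mediating surface couple (here Co²⁺/Co³⁺).  `p2dvolt` resolves all three
and provides the downstream electroanalytical workflows a sensor developer
needs: cyclic voltammetry and chronoamperometry simulation, peak
extraction, Tafel analysis with rate-constant recovery, mediator-state
curves, catalyst-utilization analysis and concentration calibration.

## Model

Two coupled 1-D continua exchange mass at the electrode interface:

* **Electrolyte** (depth coordinate `x ∈ [0, L_e]`):
  `∂C/∂t = D ∂²C/∂x²`, with `C = C_bulk` at `x = L_e` and a flux balance at
  `x = 0` equal to the total consumption in the layer.
* **Porous layer** (pseudo-coordinate `r ∈ [0, δ]`):
  `ε ∂C_s/∂t = D_eff ∂²C_s/∂r² − R_vol`, no-flux at the impermeable
  substrate (`r = 0`), concentration continuity
  `C_s(δ, t) = C(0, t)` at the outer face.  `D_eff = D ε^1.5` (Bruggeman).
* **Reaction**: `R_vol = a_v k₀ C_s θ`, where `θ(r, t)` is the Co³⁺ site
  fraction, `k₀` the heterogeneous rate constant (m s⁻¹) and `a_v` the
  specific catalytic area per volume.
* **Mediation (EC′ cycle)**: `dθ/dt = k_ox (1 − θ) − k_red θ C_s/C_bulk`.
  The activation rate `k_ox` combines the faradaic linkage
  `|j_c|/(n F Γ)` — with `j_c` the cathodic branch of the interfacial
  Butler–Volmer law `j = j₀ [e^{(1−α)fη} − (C/C_bulk) e^{−αfη}]`,
  `η = E − E_eq`, `f = F/RT` — and a steep cooperative activation switch
  that turns the layer on near the reduction wave (see
  `docs/methods.md`).
* **Observable current**: `j = −nF ∫₀^δ R_vol dr + j_direct` (cathodic
  negative), with a four-electron overall reduction and a one-electron
  rate-determining step.

The coupled system is discretized with conservative finite volumes
(geometrically graded x-grid, uniform r-grid) and integrated with a BDF
stiff solver at relative tolerance 1e-4.

## Worked example

```python
import p2dvolt as pv

params = pv.default_parameters()          # baseline sensor parameterization
vgram, history = pv.run_cv(params)        # 0.2 -> -1.2 -> 0.2 V at 50 mV/s

E_pk, j_pk = pv.find_cathodic_peak(vgram)
fit = pv.tafel_analysis(vgram, params)
print(E_pk, j_pk, fit.slope, fit.alpha_est, fit.k0_eff)
```

prints (reference resolution, nx=1000, nr=200):

```
-0.6999  -0.6000  92.54  0.639  4.956e-04
```

i.e. the cathodic peak sits at −0.70 V vs Ag/AgCl with a peak current
density of −0.60 A m⁻² (the sensing observable), the Tafel slope of
92.5 mV dec⁻¹ corresponds to a charge-transfer coefficient α ≈ 0.64 for a
one-electron rate-determining step, and the rate-constant extraction
recovers the configured k₀ = 5.0 × 10⁻⁴ m s⁻¹ to within 1%.  The same
analysis of the bare-electrode simulation returns
k₀ = 4.8 × 10⁻⁵ m s⁻¹ — the order-of-magnitude kinetic enhancement from
the catalyst layer.

The `examples/` directory holds one short script per capability
(baseline CV, Tafel extraction, mediator dynamics, catalyst utilization,
sensing calibration, chronoamperometry); each prints the numbers it
computes and a line on what they mean.  A thin CLI mirrors the library:

```sh
p2dvolt simulate-cv --output run1        # traces + JSON summary + manifest
p2dvolt analyze --input run1/voltammogram.csv --kind coox
p2dvolt validate                         # reference-target pass/fail table
```

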