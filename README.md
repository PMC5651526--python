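# hemotherm

Desk-scale simulation pipeline for the thermal hemocompatibility of fully
implantable waste-heat sources cooled by descending-aorta blood flow.

Mechanical circulatory support devices (total artificial hearts, left
ventricular assist devices) powered by a fully implanted thermal source must
dissipate tens of watts of waste heat — 64 W for a TAH-class source, 24 W
for an LVAD-class one — without cooking the blood that carries it away.
`hemotherm` models the blood conduit / heat-conductor assembly on the
descending aorta as a reduced-dimension conjugate heat-transfer problem and
asks the engineering questions that decide biocompatibility: how hot does
the blood-contacting interface get, where along the exchanger, how much do
intraluminal fins and a copper heat guide help, and what temperature
histories do individual platelets and red blood cells accumulate.

## Model

* **Rheology.** Blood is an incompressible shear-thinning fluid with the
  Carreau–Yasuda law
  μ(γ̇) = μ∞ + (μ₀ − μ∞)[1 + (λγ̇)^a]^{(n−1)/a}
  (μ₀ = 0.16 Pa·s, μ∞ = 0.0035 Pa·s, λ = 8.2 s, n = 0.2128, a = 0.64,
  ρ_b = 1050 kg/m³).
* **Flow.** Fully developed pulsatile flow in the exchanger conduit:
  ρ_b ∂u/∂t = g(t) + ∂/∂y(μ ∂u/∂y), with the axial pressure gradient g(t)
  solved each step so the flow integral matches a synthetic cardiac
  waveform (period 1 s, descending mean 5 L/min, systolic peak 4× mean).
* **Energy.** ρᵢc_{p,i} ∂T/∂t + ρ_b c_{p,b} u ∂T/∂x = ∇·(kᵢ∇T) across the
  blood lumen and the zoned solids (titanium conduit, aluminum housing,
  copper heat guide), with a prescribed-flux source band (−n·q = P₀/A),
  perfect external insulation, 37 °C inflow, and a two-step steady →
  periodic-transient solve.
* **Cells.** Lagrangian platelets (3 µm) and red blood cells (7 µm) with
  Stokes drag, τ_p = ρ_p d_p²/(18 μ_b), specular wall reflection, and
  marginated (∝ r³) platelet seeding.
* **Dose.** Per-cell Thermal Exposure Index, TEI = Σ Δt_i (T_i + T_{i+1})/2
  in s·°C, plus cumulative time above hyperthermia-effect thresholds
  (protein denaturation above 45 °C, hemolysis at 50 °C × 1 h, ...).

Four exchanger configurations are built in: `base64`, `base24`, `fins64`
(2 mm titanium splitter) and `finsguide64` (splitter plus a 0.25 cm copper
guide wrapped to the far side of the lumen).

## Worked example

```python
import hemotherm as ht

geom, grid, source = ht.build_design("base64", resolution=6.0)
flux_table = ht.map_power_to_surrogate(source, geom, grid)
wave = ht.descending_fraction(ht.make_inlet_waveform(seed=1), 0.7)

vf = ht.solve_unsteady_profile(wave, grid, ht.BLOOD_CY)
Tf, report = ht.solve_transient(grid, vf, flux_table, inlet_T=37.0)

bal = ht.enthalpy_balance(Tf, grid, vf)
prof = ht.interface_temperature_profile(Tf, grid, window=5)
print(f"blood enthalpy gain {bal['cycle_mean_W']:.2f} W")
print(f"peak interface T {prof['peak_C']:.1f} C "
      f"at {prof['argmax_pct']:.0f}% of the exchanger")
```

prints

```
blood enthalpy gain 64.00 W
peak interface T 68.5 C at 73% of the exchanger
```

i.e. the periodic state removes the full 64 W through the blood (discrete
conservation closes to well under 1%), and the time-averaged
blood-contacting interface peaks far above the physiological range, shifted
downstream of the source centre (50%) by the convective heat transport —
the reason the finned and heat-guided designs exist.  The same objects feed
`seed_cells`/`track` and the `tei_summary` population table.

The shell entry point wraps the same stages:

```sh
hemotherm run --design base64 --out runs/
hemotherm validate --suite all
hemotherm report --run runs/base64_<hash>
```

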