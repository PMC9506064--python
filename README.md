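# localep

Multiscale modelling of **localized electroporation of adherent cells on
commercial porous cell-culture-insert substrates**, for designing
low-voltage gene electrotransfer experiments.

Standard cell-culture inserts carry a track-etched PET membrane
(0.4–3.0 µm pores) on which adherent cells grow. Placing one electrode
in the well below the substrate and one in the insert above it and
applying millisecond pulses of a few tens of volts localizes the
electric field inside the substrate pores. The field leaking out of
each pore mouth permeabilizes only the small patch of cell membrane
directly above it — localized electroporation — while plasmid DNA in
the bottom well is driven electrophoretically through the pores into
the permeabilized cells. This package answers the quantitative design
questions behind that experiment:

* **Membrane scale** — the asymptotic electroporation model. Each
  membrane element carries an areal density *N* of fixed-radius
  (1 nm) electropores obeying

  d*N*/d*t* = α e^{(U/V_ep)²} (1 − (N/N₀) e^{−q(U/V_ep)²}),

  with the added membrane conductance
  G_ep = N·2σ_p π r_p² / (π r_p + 2 d_m) and the interface condition
  n·J = (G_cm + G_ep)·U_cm + C_cm dU_cm/dt.

* **Cell scale** (`localep.unitcell`) — a periodic unit cell: one
  adherent cell (half oblate spheroid, flat face 100 nm above the
  substrate) over a square lattice of substrate pores matching the
  manufacturer porosity. A pseudo-3D resistor/capacitor network
  (pore conduits, laterally conducting gap film with annular
  refinement at every pore mouth, per-site interior sheet, dome
  membrane) is coupled to the nonlinear membrane model and integrated
  over the 10 ms pulse, yielding spatial electropore maps, the
  electroporated area fraction, and onset voltages.

* **Device scale** (`localep.insert`) — axisymmetric finite-volume
  solve of the full insert-in-well system with the substrate
  homogenized into an areal conductance
  G_subs,eff = ρ·2σ_e π r² / (π r + 2 d) (channel plus two-sided
  access resistance), giving the U_subs(r) profile, the U_subs/U_app
  fraction, and the system resistance U_app/I.

* **Design layer** (`localep.design`) — closed forms for substrate
  conductance/resistance, pore areal fraction, and the electrophoretic
  DNA translocation time t_trans = d² / (µ·U_subs).

* **Verification** (`localep.oracle`, `localep.traces`) — a
  brute-force fine-grid axisymmetric oracle used to verify the network
  reduction, and synthetic voltage/current pulse traces (with
  generator droop) for the resistance-estimation utility.

## Worked example

```python
from localep import (
    InsertGeometry, ElectrodeConfig, solve_insert,
    build_unit_cell, solve_pulse, electroporated_area_fraction,
    onset_voltage_sweep, default_cells, default_substrates,
    effective_substrate_conductance, translocation_time, default_dna,
)

subs = default_substrates()          # 0.4 / 1.0 / 3.0 um pore substrates
cell = default_cells()["large"]      # 15 um x 40 um adherent cell

# closed forms
print(effective_substrate_conductance(subs["0.4um"], sigma_e=1.5))
# 365.5083354170546            # S/m^2 homogenized substrate conductance
print(translocation_time(default_dna(), subs["0.4um"], U_subs=2.5) * 1e3)
# 1.0666666666666667           # ms for a plasmid to cross the substrate

# device scale: resistance and substrate voltage fraction
sol = solve_insert(InsertGeometry(), ElectrodeConfig(), subs["0.4um"])
print(round(sol.resistance, 1), round(100 * sol.mean_usubs_fraction, 1))
# 155.7 53.2                   # ohm; percent of U_app across the substrate

# cell scale: electroporation map for a 10 ms pulse at U_subs = 7.5 V
prob = build_unit_cell(cell, subs["1.0um"])
m = solve_pulse(prob, U_subs=7.5)
print(round(electroporated_area_fraction(m), 3))
# 0.434                        # fraction of membrane with N > 1e13 m^-2

# onset voltage on the standard sweep grid
print(onset_voltage_sweep(prob, [1.0, 2.5, 5.0, 7.5, 10.0]))
# 2.5                          # volts across the substrate
```

Reading of the numbers: with 0.4 µm pores roughly half the applied
voltage reaches the substrate and electroporation begins near
U_subs ≈ 5 V (so U_app ≈ 10 V), staying confined to the membrane
patches above pores; 1.0 µm substrates electroporate from ≈2.5 V but at
7.5 V already 43% of the membrane is permeabilized — the window for
gentle, localized treatment is much narrower.

## Command line

```sh
localep unitcell -c config.yaml -o out/    # electroporation maps
localep insert -o out/                     # device solve
localep design -o out/                     # pore-size design sweep
localep fixture -o out/ --seed 7           # synthetic trace round-trip
localep reproduce fig2d|fig3|table1-check  # bundled scenarios
```

Configurations are YAML; quantities accept lab units (`"0.4 um"`,
`"2e6 1/cm^2"`, `"10 ms"`). Every run writes a `manifest.json` with the
fully resolved parameter set; reruns with the same configuration and
seed are bit-identical.

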