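# aerodose

Desk-scale modelling of radioactive-aerosol deposition in subject-specific
human airways, from parametrized geometry through Lagrangian particle
tracking to Monte-Carlo point-source decks for internal dosimetry.

## Who this is for

Inhalation-dosimetry and respiratory-aerosol researchers who need a fast,
fully scriptable stand-in for the heavy CFD/Monte-Carlo chain: generate a
bifurcating airway tree spanning realistic phenotypes (trachea diameter
t_d, carina angle b_a), drive it with a breathing waveform, track an
aerosol population, compute deposition-fraction metrics, and export the
deposited particles as batched point sources for a radiation-transport
code. The package also ships the two supporting procedures such studies
lean on: RBF kernel k-means phenotype clustering with Random-Forest
feature ranking, and a Richardson/GCI grid-convergence toolkit.

## The model

Airways are trees of straight circular tube segments (analytic
inside/outside tests; mm units). Airflow is reduced-order: the inlet flow
Q(t) = Qmax·sin(2πt/T) (heavy exercise: Qmax = 90 L/min, T = 2 s) is
distributed through the tree by Poiseuille conductance d⁴/L and converted
to per-segment parabolic profiles. Each parcel is one particle obeying

m_p dv_p/dt = ½ C_d ρ A_p |v_s| v_s + m_p g(1 − α_p) + f_B + f_lift + f_vm

with slip velocity v_s = u − v_p, Schiller–Naumann drag
C_d = (24/Re_p)(1 + 0.15 Re_p^0.687) (0.44 above Re_p = 1000), and
Brownian forcing of per-axis amplitude √(2 k_B T γ_f/Δt), γ_f = 3πηd_p.
Drag is integrated point-implicitly (exponential update), so the scheme
is stable at any sub-step. Walls stick on contact; particles crossing a
terminal outlet escape to the unmodelled distal airways; particles
crossing the inlet leave as exhaled. Deposition metrics:

- nDF = (n_Stick + n_Scape·ICRP_correction)/n_Total
- mDF = (m_Stick + m_Scape)/m_Total (exhaled mass excluded from the numerator)
- regional mDF/nDF_(L,R) = lobar stuck amount over the lobar total

plus deposition-efficiency curves against the impaction parameter d_p²Q
(μm²·L/min, points below 0.1 excluded) and 19-bin normalized size
histograms on [0, 10] μm. The default source term is aerosolized ¹³¹I:
log-normal sizes (count median 0.42 μm, GSD 3.5), particle density
4390 kg/m³, aerosol specific activity 0.21% × 4.6×10¹⁵ Bq/kg ≈ 10¹³ Bq/kg,
beta/gamma emission lines for the dual decay modes, and 500-sources-per-
batch decks with two sources per deposition location.

## Worked example

```python
from aerodose import (BreathingPattern, MetricsConfig, ParticleSourceConfig,
                      SimulationConfig, simulate_deposition, measure_parameters,
                      generate_airway_tree, ndf, mdf, regional_fractions)
from aerodose.geometry import cluster_spec
from aerodose.metrics import tally_from_records

tree = generate_airway_tree(cluster_spec("bb", n_generations=6, seed=1))
p = measure_parameters(tree)
print(f"t_d = {p.t_d:.1f} mm, b_a = {p.b_a:.2f} deg, "
      f"V = {p.volume/1000:.1f} cm^3, L = {p.total_length:.0f} mm")

result = simulate_deposition(
    tree,
    BreathingPattern(qmax_lpm=90.0, period_s=2.0),
    ParticleSourceConfig(kind="lognormal", median_um=0.42, gsd=3.5),
    SimulationConfig(n_particles=20_000, seed=1),
)
print(result.counts)

tally = tally_from_records(result.records, tree)
cfg = MetricsConfig(icrp_correction=0.25)
mdf_l, mdf_r, ndf_l, ndf_r = regional_fractions(tally)
print(f"nDF = {ndf(tally, cfg):.3f}, mDF = {mdf(tally, cfg):.3f}")
print(f"lobar split: mDF_L = {100*mdf_l:.1f}%, mDF_R = {100*mdf_r:.1f}%")
```

prints (exactly, for this seed):

```
t_d = 18.2 mm, b_a = 97.83 deg, V = 75.1 cm^3, L = 1308 mm
{'airborne': 2, 'stuck': 4780, 'escaped': 12202, 'exhaled': 3016}
nDF = 0.392, mDF = 0.961
lobar split: mDF_L = 35.6%, mDF_R = 64.4%
```

Read: on the large-t_d/large-b_a phenotype under heavy-exercise breathing,
24% of injected particles stick to the modelled walls, 61% escape to the
deeper lung (credited at the chosen ICRP factor of 0.25 in nDF), and 15%
are exhaled; the escaped-mass credit of the printed mDF convention pushes
the mass fraction to 0.96, and deposited mass favours the right lung.

The same run is available from the shell:

```bash
aerodose run --config run.toml        # full pipeline + source decks
aerodose geom generate --cluster bb --out tree.json
aerodose gci study.csv                # grid-convergence report
```

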