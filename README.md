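# foilyield

Activation analysis and production planning for accelerator-made medical
radionuclides, built around the proton irradiation of isotopically
enriched ⁴⁸Ti targets for theranostic ⁴⁷Sc.

⁴⁷Sc (t½ = 3.35 d) pairs SPECT-compatible γ emission with β⁻ therapy,
but no production route currently delivers it at scale. One candidate
route bombards enriched ⁴⁸Ti with 18–70 MeV protons. Assessing it needs
two linked computations, both implemented here:

* **Inverse (measurement):** stacked foils — thin ⁴⁸Ti deposits
  interleaved with natNi monitor foils, Al catchers and degraders — are
  irradiated in one beam pass so each foil samples a different proton
  energy. From the net counts of a γ peak, the end-of-bombardment (EOB)
  activity of each product follows from

  `A_EOB = C·λ·(t_real/t_live) / (ε·I_γ·e^(−λt_c)·(1−e^(−λt_real)))`,

  the proton flux φ from the IAEA-recommended natNi(p,x)⁵⁷Ni monitor
  cross-section, and the production cross-section from
  `σ = A_EOB / (φ·N_t·(1−e^(−λt_irr)))`, rescaled to a 100% enriched
  target. Per-foil proton energies come from a Bethe stopping-power
  model with Bohr straggling; uncertainties (counting, efficiency, γ
  intensity, monitor σ, areal density) combine in quadrature.

* **Forward (planning):** excitation functions σ(E) — shape-preserving
  interpolants through measured points, anchored to zero at the reaction
  threshold — feed the thick-target activation integral

  `A = (I/e)·(N_A/M)·(1−e^(−λt_irr)) ∫ σ(E)/S(E) dE`,

  giving EOB yields (MBq/µA) per scenario, and the post-EOB activity
  sets evolve by radioactive decay with ⁴⁴ᵐSc → ⁴⁴ᵍSc isomeric feeding
  (Bateman) to track the radionuclidic purity (RNP) of ⁴⁷Sc — the share
  of ⁴⁷Sc in the total scandium activity.

A forward simulator generates complete synthetic campaigns with known
ground truth (Poisson counting noise, realistic stack and counting
geometry), so the whole inverse pipeline is testable end to end: a
noise-free campaign inverts to the true cross-sections at machine
precision.

## Worked example

The measured ⁴⁸Ti(p,x) cross-section table, the natNi(p,x)⁵⁷Ni monitor
curve, the decay data and reaction thresholds ship as package fixtures,
so planning questions run out of the box:

```python
from foilyield import Scenario, default_registry, yield_table
from foilyield.io import fitted_excitations

table = yield_table(fitted_excitations(),
                    [Scenario(e_entry_mev=30.0, t_irr_h=24.0),
                     Scenario(e_entry_mev=40.0, t_irr_h=24.0)],
                    default_registry())
```

`python examples/plan_yields.py` prints (MBq per µA at EOB, 24 h rows):

```
      scenario  Sc-47 [MBq]  Sc-46 [MBq]  Sc-44g [MBq]  Sc-44m [MBq]  Sc-43 [MBq]
E<25 MeV, 24 h         67.1        -             335.0          24.2        -
E<30 MeV, 24 h        179.7          0.0        1643.1         125.0        -
E<35 MeV, 24 h        331.2          4.6        3110.3         268.5         14.9
E<40 MeV, 24 h        480.1         19.6        4035.8         383.2        310.6
```

Reading: irradiating a thick ⁴⁸Ti target for 24 h with protons entering
at 30 MeV makes ~180 MBq of ⁴⁷Sc per µA; pushing the entry energy to
40 MeV nearly triples the ⁴⁷Sc but opens the ⁴⁶Sc channel — and that
contaminant, with its 83.8 d half-life, outlives ⁴⁷Sc. The purity
consequences (`python examples/purity_evolution.py`):

```
scenario: 24 h irradiation, protons below 30 MeV
  time to 99% purity: 1582 h
scenario: 24 h irradiation, protons below 35 MeV
  maximum RNP 56.0% at 340 h, then 46Sc takes over
scenario: 24 h irradiation, protons below 40 MeV
  maximum RNP 51.0% at 246 h, then 46Sc takes over
```

Below 30 MeV the purity climbs monotonically and crosses 99% about
1 580 h (≈ 20 half-lives) after EOB; at 35–40 MeV it peaks near 50–56%
a couple of weeks after EOB and then decays away — ⁴⁶Sc caps it forever.

The other examples show the energy bookkeeping through a 70 → 18 MeV
stack (`stack_energy_profile.py`) and a full synthetic
measurement-to-cross-section extraction (`extract_cross_sections.py`).

A thin CLI wraps the same functions: `foilyield stack energies`,
`foilyield xs extract`, `foilyield yield plan`, `foilyield rnp curve`,
`foilyield rnp solve`, `foilyield simulate campaign`.

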