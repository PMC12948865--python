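# rhizotrace

Tracer mass-balance analysis of ¹³CO₂ pulse-labelling field experiments:
from per-compartment δ¹³C and carbon measurements to net rhizodeposition
carbon, root carbon corrected for extraneous organic matter, and whole-plant
carbon-allocation coefficients.

Rhizodeposition — the carbon that living roots release into soil — is hard to
measure because it is chemically indistinguishable from native soil organic
matter. Labelling a crop repeatedly with ¹³CO₂ makes root-derived carbon
traceable: at harvest, the excess ¹³C found in each compartment (grain, straw,
roots by soil layer, bulk soil) partitions the plant's assimilated carbon.
`rhizotrace` is for agro- and soil ecologists running such campaigns (e.g.
wheat under different cropping systems and water regimes) who want a tested,
reproducible calculation chain plus a forward simulator with known ground
truth for validating it end to end.

## The mass balance

With χ the ¹³C atom fraction (from δ¹³C via R = R_VPDB·(δ/1000 + 1),
χ = R/(1+R)) and χᴱ = χ_labelled − χ_reference the atom excess against the
natural-abundance sample of the same treatment and soil layer, the excess ¹³C
mass of a pool holding m(C) grams of carbon per m² is

    mᴱ(¹³C) = χᴱ · m(C) · M¹³ / (χ¹² · M¹² + χ¹³ · M¹³)

Fine-root samples from the topsoil are corrected for extraneous organic
matter (EOM, δ¹³C = −29.3 ‰) with a two-pool mixing model,

    f_RBC = (χᴱ_sample − χᴱ_EOM) / (χᴱ_root − χᴱ_EOM)

Mass-based root C is scaled to area with RC_S = RC_M · ρ · z. Per soil layer,
the carbon derived from rhizodeposition follows from the soil and root excess
masses under two assumptions — homogeneous root enrichment, and equal
enrichment of roots and rhizodeposits:

    %CdfR = mᴱ_soil / (mᴱ_soil + mᴱ_root) · 100
    qCdfR = %CdfR · RC_S / (100 − %CdfR)

Relative rhizodeposition is qCdfR / (qCdfR + RC_S); allocation coefficients
express grain, straw, root and rhizodeposition C as proportions of whole-plant
C; root:shoot = root C / straw C and belowground:aboveground =
(root + rhizodeposition C) / (straw + grain C). A small companion module
classifies prokaryotic taxa into copiotrophs (rrn copy number ≥ 5) and
oligotrophs (< 5) and computes community read-count ratios.

## Worked example

Simulate a labelled campaign (3 cropping systems × control/drought × 4 plots,
default study conditions) and run the pipeline:

```python
from rhizotrace import SimConfig, simulate_experiment, analyze

sim = simulate_experiment(SimConfig(seed=1))
res = analyze(sim.measurements, sim.references, sim.geometry)
print(res.summary)      # means ± SE per treatment and pooled
```

Pooled rows of the treatment summary (seed 1):

```
system  regime                 variable  n       mean       se  pct_change_vs_control
   all control relative_rhizodeposition 12   0.705171 0.003319                    NaN
   all drought relative_rhizodeposition 12   0.700624 0.002003              -0.644729
   all control             rhizo_c_g_m2 12 237.169994 2.679678              14.387914 (drought row)
   all control              root_c_g_m2 12  99.083883 0.956253              16.942399 (drought row)
```

Under rainfed control the pipeline recovers ≈ 99 g C m⁻² of root C and
≈ 237 g C m⁻² of rhizodeposition C — about 71 % of belowground C input — and
the simulated drought raises both, the configured treatment effect. The same
chain is available from the shell:

```bash
rhizotrace simulate -o sim/ --seed 1
rhizotrace run --measurements sim/measurements.csv \
               --references sim/references.csv \
               --geometry sim/geometry.csv -o results/
rhizotrace recover --reps 100 -n 0.0 -n 0.2 -o recovery.csv   # bias/RMSE vs truth
```

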