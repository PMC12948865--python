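# Methods

## Model and procedure

`rhizotrace` implements the end-of-season tracer mass balance for a
multi-pulse ¹³CO₂ labelling experiment. The calculation chain is:

1. **Atom excess.** Every labelled measurement is paired with the
   natural-abundance reference of its own treatment (cropping system × water
   regime), soil layer and material (plant vs soil). δ¹³C is converted to the
   ¹³C atom fraction with R = R_VPDB·(δ/1000 + 1), χ = R/(1+R), assuming a
   binary ¹²C/¹³C system; the excess is the difference of labelled and
   reference fractions. Negative excesses (sample below its reference, a
   noise phenomenon) are retained and logged at this stage — clipping here
   would bias sums.
2. **Excess mass.** mᴱ = χᴱ·m(C)·M¹³ / (χ¹²·M¹² + χ¹³·M¹³), where the
   denominator uses the *measured sample's* atom fractions, i.e. it is the
   sample's mean atomic mass of carbon; mᴱ is linear in χᴱ and m(C).
3. **Root carbon.** Mass-based root C (g C kg⁻¹ dry soil) is scaled to area
   with RC_S = RC_M·ρ·z. The topsoil (0–0.25 m) fine-root sample is corrected
   for extraneous organic matter (EOM) with the two-pool mixing fraction
   f_RBC; the corrected carbon is sample C × f_RBC. Crown and coarse root C
   of the topsoil are summed into one coarse pool; within-row and between-row
   cores of the two deeper layers are averaged per layer and class.
4. **Partitioning.** Per layer, %CdfR = mᴱ_soil/(mᴱ_soil + mᴱ_root)·100 with
   the root excess summed over the classes sampled in that layer (crown +
   coarse + fine in the topsoil; coarse + fine below), and
   qCdfR = %CdfR·RC_S/(100 − %CdfR). Profile totals are built layer-wise:
   excess masses and qCdfR are summed, and the profile %CdfR is recomputed
   from the summed excess masses rather than averaged across layers — mass
   balance is additive, percentages are not.
5. **Allocation.** Grain, straw, root and rhizodeposition C as fractions of
   their sum (they close to 1 by construction), root:shoot = root/straw,
   belowground:aboveground = (root + rhizo)/(straw + grain).
6. **Summaries.** Group means and SE = sd/√n over plot replicates per system
   × regime and pooled, with the drought-vs-control percent change. No
   inferential statistics are computed here; mixed-model inference belongs to
   downstream tools.

The two scientific assumptions behind step 4 — homogeneous ¹³C enrichment of
the root system, and equal enrichment of roots and rhizodeposits — are also
the construction rule of the simulator, which is what makes exact
forward/inverse testing possible.

### Choice of the clean-root endmember

The EOM correction needs the atom excess of clean root material. The package
uses the same plot's topsoil *coarse-root* excess: under the
homogeneous-enrichment assumption all root classes share one enrichment, and
coarse roots are hand-sorted and effectively free of EOM. If a dedicated
clean-fine-root measurement exists it can be supplied as an extra
`coarse_root` topsoil row.

### Numerical and degenerate-input policy

* f_RBC outside [0, 1] (noise pushing the sample outside its endmembers) is
  clamped with a warning; the raw value is kept in the `f_rbc.csv` output.
  Coinciding endmembers raise a degenerate-mixing error.
* Negative soil or root excess masses are clamped to zero when entering the
  layer bundles (logged). A layer with zero excess in both pools, or zero
  root excess with positive soil excess (singular partition), is flagged,
  excluded from that layer's summary and logged.
* δ ≤ −1000 ‰ and atom fractions outside (0, 1) are rejected as unphysical.
* Allocation closure is asserted to 1 ± 1e−9; the partition identity
  qCdfR/(qCdfR + RC) = %CdfR/100 holds to 1e−12 by construction.

## Constants and tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| R_VPDB | 0.0111802 | – | VPDB ¹³C/¹²C ratio in the Coplen framework; overridable (e.g. 0.011180), results differ in the 5th significant figure |
| M¹², M¹³ | 12.0, 13.0033548 | g mol⁻¹ | exact ¹²C definition; CODATA ¹³C |
| δ¹³C_EOM | −29.3 | ‰ | EOM endmember measured on the same field in prior work |
| bulk density ρ | 1300/1450/1500 | kg m⁻³ | typical loamy arable profile; per-layer config input, never hard-coded |
| layer thickness z | 0.25 each | m | three sampled layers to 0.75 m |

## The synthetic-data generator

`simulate.SimConfig` defaults encode the study conditions: 3 cropping
systems × 2 water regimes × 4 plots; 1060 g C m⁻² total assimilated C;
36.5 g ¹³C m⁻² applied tracer with net recovery 46 % (control) and 32 %
(drought); natural-abundance δ¹³C ≈ −28 ‰ (plant) and −26 ‰ (soil); soil
background C 4500/2000/1000 g C m⁻² per layer; EOM contamination 20 % of
topsoil fine-root sample C; δ-noise 0.2 ‰ (IRMS precision) and 5 %
multiplicative lognormal mass noise (field sampling). The rainfed allocation
(grain 0.383, straw 0.300, root 0.0934, rhizodeposition 0.2236) reproduces
the rainfed profile means of ≈ 99 g C m⁻² root C and ≈ 237 g C m⁻²
rhizodeposition C; the drought scheme shifts allocation belowground (larger
fine-root and rhizodeposition shares) so treatment summaries are
sign-consistent with the observed drought response — all effect sizes are
configuration, not code.

The forward model distributes the recovered tracer over all compartments in
proportion to carbon mass (one common enrichment per plot), which *enforces*
the two mass-balance assumptions; rhizodeposit excess is diluted into the
natural-abundance soil background, EOM is mixed into the topsoil fine-root
sample as a carbon-mass-weighted ("χ-weighted") two-pool mixture, and
synthetic δ values are obtained by exact algebraic inversion of the
excess-mass equation. Consequences used by the test suite: with noise and
contamination off, the pipeline recovers true qCdfR, root C and allocation
coefficients to floating-point precision, and f_RBC equals 1 − φ exactly for
contamination fraction φ.

What the generator does **not** emulate — and what passing tests therefore do
not show about real data: per-event labelling dynamics (the 11 pulses are
summarised by the recovery fraction), root-enrichment heterogeneity or
root–rhizodeposit enrichment differences (the very biases the mass-balance
assumptions introduce in the field), lateral tracer movement, carbonate or
priming effects in soil, plot-level biological variability beyond measurement
noise, and mole- vs mass-based mixing differences (O(1e−6) at these
enrichments). The Monte-Carlo recovery study (`recovery_study`) quantifies
noise-driven bias/RMSE only under the generator's own assumptions; at the
default 0.2 ‰ δ-noise the relative bias of whole-profile qCdfR is ≈ 0.1–0.2 %
(100 replicates, problem size 24 plots per replicate — sizes chosen so the
full suite runs in well under a minute apart from the Monte-Carlo check).

## Known limitations

* %CdfR uses the *measured* fine-root excess mass; when EOM contamination is
  present its (slightly negative) excess against the plant reference leaves a
  relative error of order 1e−4 in qCdfR at φ = 0.2 — far below measurement
  noise, but not identically zero.
* The treatment summary is descriptive (means, SE, percent change); no
  mixed-effects inference or multiple-comparison adjustment is provided.
* The trophic classifier expects pre-computed rrn copy numbers per taxon; it
  does not re-implement rrnDB lookups or amplicon processing. Whether ratios
  should be read- or ASV-based is study-specific; both weightings are
  offered (`weight="reads"` default, `weight="asv"`).
* Single-timepoint simulation: no within-season dynamics of allocation.
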