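# fatlabel

**¹³C isotopologue analysis of fatty acids from negative-ion CI GC-MS of
pentafluorobenzyl esters.**

When a culture (e.g. a microalga growing on ¹³C-bicarbonate) incorporates a
stable-isotope tracer into its lipids, each fatty acid appears in the mass
spectrum as a ladder of isotopologues M+0 … M+n, one per acyl carbon.
Derivatising the free fatty acids as pentafluorobenzyl (PFB) esters and
ionising by negative-ion chemical ionisation (NCI) leaves the intact
carboxylate anion [M−H]⁻, so the whole ladder is measured on a single,
unfragmented ion series — e.g. m/z 277 (M+0) to 295 (M+18) for 18:3.
`fatlabel` turns the per-isotopologue peak areas into tracer enrichment:

1. **Peak integration** that honours the chromatographic isotope effect:
   heavy isotopologues elute a few seconds earlier (≈ 4.2 s across the 18
   labels of an 18-carbon acid on a 100 m FAME-phase column), so each
   channel is integrated as a whole-peak area over a shared window, which
   cancels the elution bias by construction. QC covers co-elution,
   blank contamination, peak truncation and sampling density.
2. **Natural-abundance correction.** The measured mass distribution vector
   (MDV) **m** mixes tracer labelling with natural ¹³C, ²H, ¹⁷O and ¹⁸O.
   A lower-triangular correction matrix **C** is built whose column *j* is
   the isotope pattern of the anion with *j* carbons fixed as ¹³C (natural
   abundance elsewhere, each element's pattern obtained by self-convolution
   of its abundance vector, carbon = [0.9893, 0.0107]); solving
   **C x = m** yields the corrected vector **x** (the MDV*).
3. **Fractional labelling.** The enrichment statistic is the
   position-weighted mean of the corrected MDV,
   FL = Σᵢ *i·xᵢ* / (*n*·Σᵢ *xᵢ*), i.e. the mean fraction of carbon
   positions carrying ¹³C; multiplied by the pool size it gives the amount
   of ¹³C incorporated into the pool.
4. **Quantification.** Pool sizes from the isotopologue-summed area
   (labelling-invariant by construction) against a deuterated internal
   standard (myristic-d27, 50 µM default) with linear external calibration
   and linear-range flags; extraction-recovery tables compare methods as
   percentages of a reference protocol.
5. **A forward simulator** generating measured MDVs and full chromatograms
   (Gaussian peaks, per-label RT shift, noise, contamination) from a
   two-pool enrichment model with known ground truth, so every stage is
   testable without instrument data.

## Worked example

```python
from fatlabel import (
    EnrichmentModel, build_correction_matrix, carboxylate_anion_formula,
    correct_mdv, parse_fatty_acid_name, simulate_mdv,
)

fa = parse_fatty_acid_name("C18:3n3")
anion = carboxylate_anion_formula(fa)
print("anion:", anion, "-> nominal m/z", anion.nominal_mass())

# a pool whose labelled half carries 95% 13C per carbon
em = EnrichmentModel(kind="two_pool", labeled_fraction=0.526, p_per_carbon=0.95)
measured = simulate_mdv(fa, em)          # forward model incl. natural abundance
result = correct_mdv(measured, build_correction_matrix(anion))
print(f"fraction labelled: {result.fraction_labeled:.4f}")
print(f"corrected M+0:     {result.corrected_mdv.values[0]:.4f}")
print(f"corrected M+18:    {result.corrected_mdv.values[18]:.4f}")
```

prints

```
anion: C18H29O2- -> nominal m/z 277
fraction labelled: 0.4997
corrected M+0:     0.4740
corrected M+18:    0.2089
```

The corrected vector is bimodal — an unlabelled residue at M+0 and a
near-fully-labelled cohort peaking toward M+18 — and the fractional
labelling recovers the ground truth 0.526 × 0.95 ≈ 0.50: half of all acyl
carbon positions in the pool carry ¹³C.

The same analysis runs from the shell over chromatogram CSVs
(`time_min,mz,intensity`):

```sh
fatlabel simulate --out fixtures --seed 0
fatlabel extract fixtures/t96h.csv -f C18:3n3 --rt-window 29.5:30.4 --out run
fatlabel correct run/peak_table.csv --out run
```

`run/summary.csv` then reports `fraction_labeled ≈ 0.50` for the simulated
96 h scenario, with clip-count and residual diagnostics, and every run
writes a `manifest.json` (config echo, input hashes, version).

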