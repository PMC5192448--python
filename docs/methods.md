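# Methods

## Measurement model

A fatty acid with *n* acyl carbons detected as its carboxylate anion
[M−H]⁻ yields *n*+1 isotopologue channels M+0 … M+n. The measured mass
distribution vector (MDV) **m** ∈ ℝⁿ⁺¹ is modelled as

  **m** = **C t**,

where **t** is the tracer distribution (fraction of molecules with exactly
*j* ¹³C tracer atoms) and **C** is the natural-abundance correction matrix.
Column *j* of **C** is the isotope pattern of the anion formula with *j*
carbons fixed as ¹³C: the convolution of the per-element patterns, where
each element's pattern is the atom-count-fold self-convolution of its
abundance vector over mass offsets (+0, +1, +2 u). The matrix is lower
triangular (an isotopologue can only gain mass), has a positive diagonal,
and its columns sum to slightly less than one because mass beyond M+n is
truncated; restoring headroom rows makes each column sum to 1 to 1e−9
(verified by test). The vector must span all *n* carbons of the parent
species — shorter vectors alias heavy isotopologues into the truncation.

Natural ¹³C on the *non-fixed* carbons is included in each column (the
convention of the flux-analysis correction literature); setting
`carbon_natural=False` excludes it for comparison with tracer-purity-style
corrections. Tracer purity defaults to 1.0 and is configurable on the
enrichment model; no purity correction is applied to measured data unless
the isotope table is edited to encode it.

Default abundances: C [0.9893, 0.0107]; H [0.999885, 0.000115];
O [0.99757, 0.00038, 0.00205] (standard terrestrial values; carbon's pair
is the one the correction is most sensitive to). The table ships as
editable YAML (`src/fatlabel/data/isotopes.yaml`).

## Correction and the labelling statistic

`correct_mdv` solves **C x = m** by forward substitution (exactly the
matrix-inverse multiplication, but numerically tighter). Measurement noise
can push entries of **x** slightly negative; these are clipped to zero and
the vector renormalised, with the clip count, clipped mass and residual
‖**C x̂** − **m**‖ kept as diagnostics rather than hidden — dynamic-range
problems (saturation, out-of-linear-range areas) show up here first. A
non-negative least-squares solve (`method="nnls"`) is available for noisy
data; on clean data it agrees with the triangular solve to 1e−8.

Fractional labelling of the corrected vector is the position-weighted mean

  FL = Σᵢ *i·xᵢ* / (*n* · Σᵢ *xᵢ*).

The divisor is the carbon count *n*, not the number of isotopologues
*n*+1: only with *n* does a fully labelled pool read exactly 1 (100%),
which is the behaviour the fully-labelled-ion limit requires. The *n*+1
convention is exposed as `divisor="n_isotopologues"` for comparison.
Positional isotopomer information is out of scope — a unit-resolution
isotopologue ladder cannot resolve *which* carbons are labelled — and so is
natural-variation isotope-ratio work (the method measures exogenous
enrichment, not per-mil shifts).

## Peak integration

Heavy isotopologues elute earlier (weaker London dispersion from the
smaller molecular volume); across the 18 labels of an 18-carbon acid the
apex moves ≈ 4.2 s (0.07 min). Apex heights are therefore biased; whole
peak areas are not. All channels are integrated over one shared window —
the union of the per-channel peak extents — so the within-peak spectral
skew (heavy-rich leading edge, light-rich tail) integrates out by
construction, and enlarging the window further changes areas only at the
noise floor (property-tested).

Concrete choices, all configurable on `IntegrationConfig`:

- **XIC**: summed intensity of channels within ±0.5 u (unit-resolution
  quadrupole, 100–400 m/z scan range, 2 scans/s defaults).
- **Baseline**: moving median, default window 60 s. The window must
  exceed roughly three peak base-widths; at 1.5× the base width the median
  tracks the flanks and clips a few percent of the area, which is why the
  default is twice the peak base (~20 s for σ = 2.5 s Gaussians).
- **Apex**: maximum of the baseline-subtracted trace with parabolic
  three-point sub-sample refinement (at 2 scans/s the raw grid is 0.5 s,
  too coarse for a 0.23 s-per-label shift).
- **Bounds**: walk from the apex to 0.1% of apex height or the first
  valley, whichever comes first.
- **QC flags**: truncation when the shared-window edge intensity exceeds
  1% of apex; undersampling when fewer than 10 points span a peak
  (area ratios need adequate sampling across the peak); co-elution when a
  secondary maximum above 10% of apex lies in the window or the
  apex-aligned peak-shape correlation against the area-weighted consensus
  falls below 0.9; blank contamination when the blank's M+0 area exceeds
  10% of the sample's (contamination biases labelling low). QC is a pure
  function of (chromatogram, config): re-running reproduces flags exactly.
- **RT-shift estimate**: area-weighted least-squares slope of apex RT vs
  label count; the weights keep near-empty channels, whose apexes are
  noise, from driving the fit. Reported per label (s, signed) and as the
  implied M+0→M+n separation (s, positive = heavy earlier).

The integration algorithm and baseline model are this package's declared
defaults; instrument vendor software does not document its own.

## Quantification

Pool size uses the sum of all isotopologue areas — invariant under any
redistribution of signal across the ladder, so labelling cannot change the
apparent concentration (property-tested) — as a response ratio against the
myristic-d27 internal standard (default 50 µM; its anion channel, nominal
m/z 254, never enters the ¹³C arithmetic). Calibration is linear per fatty
acid with the fitted concentration range as the linear-range bounds;
out-of-range results are flagged. Recovery tables report each method's
concentrations as percentages of a reference method, rounded half-up to
integers for presentation with raw ratios retained. Recomputing published
recovery rows from published (already rounded) concentrations reproduces
most cells exactly and the rest within ±1 — the residue of rounding the
concentrations before the ratio.

## Simulator

Ground truth is a two-pool enrichment model: a fraction *f* of molecules
belongs to a labelled pool in which each carbon is ¹³C independently with
probability *p* (× purity); the rest are unlabelled. The tracer
distribution is (1−*f*)·δ₀ + *f*·Binomial(*n*, *p*·purity), giving overall
labelling *f·p·*purity. With *p* near 1 this reproduces the bimodal
unlabelled/fully-labelled spectra of partly turned-over pools on a ¹³C
carbon source and supports reading partially- vs fully-labelled ratios as
elongation vs de novo synthesis; a single-pool binomial mode exists for
simpler tests. The measured-space MDV is the exact forward model **C t**;
chromatograms render each channel as a Gaussian (constant σ = 2.5 s
default) at apex − *k*·shift, with per-point multiplicative noise,
additive baseline noise, and optional unlabelled contamination, all behind
one seeded generator (fixed seed ⇒ byte-identical files).

Canonical fixtures: an unlabelled control, 48 h and 96 h scenarios with
ground-truth labelling 0.43 and 0.50 for 18:3 (*p* = 0.95 — near-complete
labelling of de-novo acyl carbons from a ¹³C inorganic-carbon source —
with *f* = target/*p*), a co-elution fixture (interferent on the M+2
channel at 50% apex height, 8 s after the apex), and a contamination
fixture with its blank. Problem sizes are kept small — one fatty acid,
a 4 min acquisition window at 2 scans/s (480 points × 19 channels),
200 replicates for noise calibration — which is ample for the sub-percent
tolerances tested.

What the simulator does *not* emulate: ionisation-efficiency or
electron-capture physics, peak-shape asymmetry (tailing), drifting
baselines, co-eluting fatty acids of different species (a 100 m column
resolves them), or real enrichment kinetics. Passing tests therefore
demonstrate correctness of the arithmetic and the integration under the
modelled distortions, not robustness to every instrument artefact.

## Numerical and design notes

- Nominal integer m/z is the default axis (unit-resolution instrument);
  exact-mass mode uses the monoisotopic anion m/z and the 1.0033548 u
  ¹³C spacing with a ±0.5 u window.
- The PFB moiety never appears in any formula: it is lost on ionisation,
  so all mass arithmetic is on the bare anion. Only straight-chain CₓHᵧO₂
  stoichiometry is modelled (y = 2x − 2·double bonds; anion y−1).
- Degenerate inputs: all-zero MDVs, vectors of length 1, empty XIC
  selections, gapped peak tables, zero reference-concentration cells and
  out-of-bounds enrichment parameters all raise (or warn, where the spec
  of the operation is a trace) with messages naming the offending item.
- Geometry (cis/trans) and omega position are parsed and carried as
  metadata only; they never affect mass arithmetic. Double-bond positional
  isomers are a chromatographic, not computational, distinction.
- Retention times are minutes internally; seconds appear only in reports
  where the quantity is conventionally quoted in seconds.
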