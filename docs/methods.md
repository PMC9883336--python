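# Methods

## The screening problem

Furan fatty acids (FuFAs) are potent radical scavengers present at trace
levels (< 1% of lipids) in fish oils, mushrooms and plant oils, almost
entirely esterified into triacylglycerols (TAGs). In positive-mode
LC-ESI-HRMS, FuFA-containing TAGs are buried under far more abundant
conventional TAGs, and MS¹ exact masses alone are equivocal: an MS¹ peak
window around a FuFA-TAG precursor typically contains many unrelated ions.
`fufatag` implements the MS²-level solution — identify FuFA-TAGs by the
simultaneous presence of FuFA-diagnostic fragment ions.

## Exact-mass model

All m/z values are monoisotopic atomic-mass sums (C = 12 exactly,
H = 1.00782503207, O = 15.9949146196, N = 14.0030740048 Da). Positive-ion
m/z is by default the plain atom-inventory sum — [M+H]⁺ adds one H atom,
[M+NH₄]⁺ adds NH₄ — with no electron-mass subtraction, because that
convention reproduces published 4-decimal lipid tables. An
`electron_correction` flag subtracts 0.000549 Da per charge for physically
correct cation masses; at m/z 100–1000 the difference (0.5–5 ppm-scale on
light fragments, < 0.001 on heavy ones) never moves a peak across the 4 ppm
matching tolerance for the ions that matter here. Display rounding is
half-up to 4 decimals for m/z and 3 for ppm; all internal computation is
full precision.

## Building blocks and TAG assembly

* Conventional fatty acid `n:d` → CₙH₂ₙ₋₂dO₂. Double-bond positions and
  geometry are not modeled; MS² cannot resolve them.
* FuFA `pXq` (p = carboxyalkyl length, X ∈ {M, D} = one or two ring
  methyls, q = alkyl length) → CₙH₂ₙ₋₆O₃ with n = p + q + 4 + methyls
  (furan ring + two ring double bonds + carboxyl = 4 unsaturation
  equivalents). The hydrogen count comes from this structural rule, not a
  per-compound lookup, so any p/q/methylation combination is supported.
* TAG = glycerol (C₃H₈O₃) + 3 FA − 3 H₂O. Compositions are multisets; the
  canonical display name lists conventional FAs in ascending molecular
  weight, FuFAs last ("sn-3" by convention only — positional isomers
  co-elute and are not resolved, and every annotation carries that caveat).
  A `-` separates `15:0`-style tokens (`15:0-Ln9D5`); three identical FuFAs
  collapse to `tri9M5`.

The default building-block set holds 11 conventional fatty acids (P, Pn, S,
O, L, Ln, Ep, Dp, Dh, 15:0, 17:0) and 12 FuFAs: the eight most relevant
species (9M3, 9D3, 9M5, 11M3, 9D5, 11D3, 11M5, 11D5) plus the four
acylium-isomer partners 7M5, 7D5, 13M3, 13D3. 13M3 is included although it
is the rarest partner, so that every [FCO]⁺ mass is shared by exactly two
set members. A "core" subset (6 food-relevant FuFAs × 7 characteristic
conventional FAs) reproduces the published one-FuFA candidate list
(6 × 7·8/2 = 168 entries); the annotation default enumerates the full set
with one and two FuFA moieties per TAG (1650 candidates), which trace-level
samples require (they contribute two-FuFA TAGs and minor FAs like 15:0).

## Diagnostic fragments

* Diacyl [M−RCOO]⁺: precursor minus one fatty acid as RCOOH; one ion per
  distinct leaving acid; m/z conserves mass exactly (checked to 1e-9 Da).
* [FCO]⁺: the FuFA acylium (acid − OH), base peak of clean FuFA-TAG MS²
  spectra. Six m/z values (263.2011 … 333.2794) cover all twelve default
  FuFAs; each value is shared by a positional-isomer pair.
* Furan core: allylic [CH₂(furan)alkyl]⁺, CₙH₂ₙ₋₅O with
  n = 5 + methyls + alkyl length. It differs within every [FCO]⁺ pair and
  is what makes the third filter step decisive.
* McLafferty ion: a hard two-outcome rule — M-type → C₇H₉O (109.0653),
  D-type → C₈H₁₁O (123.0810) — independent of both chain lengths. A
  general rearrangement engine is not warranted: the rule is validated
  against every published value and chain-length independence is confirmed
  by the mushroom data.
* The +74 u/+128 u satellite series is exposed only as unit-mass report
  labels; its elemental composition is not modeled and it never enters the
  filter. Conventional-FA acylium ions are predicted but carry no
  identification weight.

## The filter flow

For each MS² spectrum (default tolerance 4 ppm, configurable):

1. **Precursor.** Candidates whose [M+H]⁺ (optionally [M+NH₄]⁺) lies within
   tolerance of the declared precursor. An in-spectrum precursor peak is
   recorded as corroborating evidence but not required — fragmentation can
   consume it.
2. **[FCO]⁺** must be present → FuFA narrowed to an isomer pair.
3. **Furan core** selects the concrete FuFA; the **McLafferty** ion must
   match the methylation degree. Multi-FuFA candidates need the trio once
   per distinct FuFA species.
4. **Diacyl ions** assign the conventional fatty acids.

Candidates sharing a protonated formula (true isomers, e.g. LO9D5 vs
PLn11D5, or LL9D5 vs OLn9D5) are arbitrated by support: the candidate(s)
with the most matched distinct diacyl ions win, with the number of distinct
explained diagnostic peaks as tie-break (a composition whose two furan
cores collapse onto one m/z explains fewer peaks than one accounting for
every observed core). Remaining ties are genuinely indistinguishable ion
sets and are all emitted flagged `AMBIGUOUS` rather than guessed. The
tie-break matters only for pathological two-FuFA mixtures; all published
annotations are decided at the diacyl step.

Tiers: `FULL` requires precursor + trio + ≥ 1 consistent diacyl ion;
`FUFA_ONLY` (name prefix `XY`) is the fallback when no candidate in a
precursor group has diacyl support — the FuFA is identified, the
conventional fatty acids are not (the co-elution case in the mushroom
data). A strict mode additionally requires the matched [FCO]⁺ to be the
spectrum base peak; it is off by default because co-eluting TAGs share
spectra in which at most one [FCO]⁺ can be the base peak.

Runs are deduplicated by TAG name keeping the occurrence with the highest
[FCO]⁺ intensity (one row per TAG, no chromatographic model); retention
time is carried for reporting only. The reported intensity of an
annotation is the matched [FCO]⁺ peak height.

## Reporting computations

* **Relative abundances** across replicate injections: within each class
  (FuFA vs conventional) the most abundant TAG of run 1 is the reference;
  every run's intensities are expressed as % of that run's reference
  intensity, and the per-TAG relative standard deviation across runs
  quantifies reproducibility. Runs missing the reference are flagged, not
  dropped.
* **Indirect content estimation**: a known total FuFA content (e.g. from an
  independent FAME determination) is allocated proportionally to [FCO]⁺
  intensities — contentᵢ = total · Iᵢ/ΣI — assuming similar MS² response of
  all FuFA-TAGs. The total is conserved exactly; the smallest allocated
  content is the indirect detection-limit estimate, convertible from a
  dry-weight to a per-lipid basis by dividing by the lipid fraction.

## Synthetic data

`simulate_spectrum` generates what the filter assumes a clean FuFA-TAG MS²
spectrum looks like: every predicted fragment, Gaussian m/z error (default
σ = 1 ppm, matching sub-2-ppm instrument accuracy — at σ = 1 the 4 ppm
window captures > 99.99% of peaks), an intensity hierarchy headed by
[FCO]⁺ (= 1.0; diacyl 0.4, furan core 0.12, McLafferty 0.1, surviving
precursor 0.1), and by default 15 uniformly placed decoy peaks
(60–1000 Th, 0.5–5% of base) emulating chemical background. It does not
model chromatographic peak shape, isotope envelopes, detector noise or
ion suppression by co-eluting abundant TAGs — so passing tests demonstrate
the selectivity and soundness of the mass-based filter, not robustness to
poor chromatography, which is a known failure mode of this method class.
"Noise-free" in the recall/soundness property means σ = 0 **and** zero
decoys. All generators are deterministic under a seed, which is part of
the public contract.

The mushroom fixture rebuilds the 18 identified FuFA-TAG spectra row by
row from the published observed values: the precursor from the [M+H]⁺
column, the McLafferty/furan-core/[FCO]⁺ ions and the diacyl ions from the
fragment column (the published fragment list interleaves the diagnostic
ions on the left with the diacyl ions on the right, and the fixture encodes
that assignment explicitly per row), and the [FCO]⁺ height from the
intensity column × 1000 (the table's scaling). The heights of the other
ions are unpublished and set to fixed sub-maximal constants. One row
(`15:0-Ln9D5`) lists a diacyl value ~2800 ppm from any fragment of its own
composition (601.4830; likely a printing artefact or chimeric peak); the
fixture keeps it as printed and the row still annotates via its two
consistent diacyl ions. The co-eluting `XY9D5`/`LL7D5` rows (both at
20.80 min, same precursor) are kept as two spectra as published.

## Numerical choices and edge cases

* Peak matching returns the most intense peak within tolerance, ties by
  smallest |ppm|; base-peak ties take the lower m/z.
* ppm errors are signed, (measured − calculated)/calculated × 10⁶;
  published tables print magnitudes.
* Required resolution is plain m/Δm; FWHM peak width m/R is the collision
  criterion in isobar-conflict scans. The published fragment-pair
  resolution figures (16,680 / 11,190) are not reproducible by m/Δm from
  the quoted fragment masses (the reference mass used there is unclear)
  and are deliberately not asserted.
* Two published diacyl values ([OO]⁺ 603.5353, [EpEp]⁺ 643.4727) sit
  1 × 10⁻⁴ Da above the direct atomic sums — consistent with intermediate
  rounding in the source table; the package reports the direct sums.
* Empty spectra, empty candidate databases, zero-annotation runs and
  missing precursors are all non-fatal (empty results, logged skips);
  formula subtraction below zero, profile-mode input and malformed
  nomenclature raise.

## Known limitations

Absolute quantification, retention-time identity, sn-position assignment,
isotope-pattern checks and negative-mode adducts are out of scope. The
screen inherits the method's chemistry-level degeneracies: two-FuFA TAGs
whose FuFA pair swaps acylium-isomer partners (e.g. A·7M5·11M3 vs
A·9M3·9M5) produce identical diagnostic ion sets and are reported together
as `AMBIGUOUS` (132 of the 1650 default candidates; none involve the
published identifications).
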