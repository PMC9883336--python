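# fufatag

Screening of **furan-fatty-acid triacylglycerols (FuFA-TAGs)** in
centroided LC-Orbitrap MS² spectra.

Furan fatty acids (FuFAs) are trace-level antioxidant fatty acids — a furan
ring carrying a carboxyalkyl chain (α), an alkyl chain (α′) and one (M) or
two (D) ring methyls, written in number-letter-number short form (9M5 =
9-(3-methyl-5-pentylfuran-2-yl)-nonanoic acid). They are esterified into
triacylglycerols, where conventional lipidomics overlooks them: MS¹ exact
masses are equivocal, and nominal isobars (O vs CH₄, Δm = 0.0364 Da; C₂ vs
H₈O, Δm = 0.0575 Da) crowd the precursor space. `fufatag` is for lipidomics
practitioners who want to find these species in their MS² data — it builds
exact-mass candidate databases, predicts the diagnostic fragment ions, and
runs the multi-step identification filter:

1. **[M+H]⁺** precursor match (4 ppm default),
2. **[FCO]⁺** — the FuFA acylium (acid − OH), base peak of FuFA-TAG MS²
   spectra; narrows the FuFA to a positional-isomer pair,
3. **furan-core ion** ([CH₂(furan)alkyl]⁺) + **McLafferty ion**
   (m/z 109.0653 for M-, 123.0810 for D-type) — pin down the FuFA,
4. **diacyl [M−RCOO]⁺ ions** — assign the conventional fatty acids.

All mass arithmetic is monoisotopic (TAG = glycerol + 3 FA − 3 H₂O;
FuFA `pXq` → CₙH₂ₙ₋₆O₃ with n = p + q + 4 + methyls). See
`docs/methods.md` for the model, filter arbitration and noise assumptions.

## Worked example

Screen the built-in deterministic mushroom spectra (18 FuFA-TAGs rebuilt
from published observed values) end to end:

```bash
fufatag simulate --fixture --format mgf -o sim
fufatag annotate sim/spectra.mgf -o annotations
```

which prints

```
wrote 18 spectra to sim/spectra.mgf
annotated 18 TAG(s) from 18 spectra -> annotations.tsv
```

`annotations.tsv` holds one row per identified TAG; the first rows are

```
name        tier       rt_min  formula_mh  mz_mh_obs  mz_mh_calc  precursor_ppm  fufa  carbon_number  intensity
LL7D5       FULL       20.8    C57H97O7    893.7233   893.7234    -0.146         7D5   54             284000.0
XY9D5       FUFA_ONLY  20.8    C57H97O7    893.7233   893.7234    -0.146         9D5   54             570000.0
15:0-Ln9D5  FULL       21.65   C56H97O7    881.7230   881.7234    -0.488         9D5   53             1010000.0
```

Reading: `LL7D5` was fully assigned — precursor within 0.15 ppm of the
calculated [M+H]⁺, the 7D5 acylium/core/McLafferty trio present, and the
diacyl ions identifying two linoleic acids. `XY9D5` co-elutes at the same
precursor but shows no usable diacyl ions, so only the FuFA (9D5) is
identified (`FUFA_ONLY`, `XY` = unassigned conventional pair). The
`intensity` column is the [FCO]⁺ base-peak height; `carbon_number` sums the
acyl carbons. `annotations.json` carries the full matched-ion evidence
(every theoretical vs observed m/z with its ppm error).

The same API is available from Python:

```python
from fufatag import (default_building_blocks, enumerate_candidates,
                     annotate_run, mushroom_fixture)

db = enumerate_candidates(default_building_blocks(), fufa_per_tag=(1, 2))
table = annotate_run(mushroom_fixture(), db, tol_ppm=4.0)   # 18 rows
```

Other entry points: `fufatag enumerate` (candidate [M+H]⁺/[M+NH₄]⁺ tables,
168 one-FuFA candidates for the core 6 × 7 set), `fufatag predict LL9M5`
(transition lists), `fufatag report` (replicate relative abundances and
indirect content/LOD estimation from a known total FuFA content).

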