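# sparselabel

Tools for quantifying **sparse (selective) isotope labels** in peptides from
high-resolution mass spectra:

- simulate isotope patterns of peptides carrying enforced ¹⁵N/¹³C labels —
  at unit resolution or down to **isotopic fine structure** — by treating
  each label as its own single-isotope pseudo-element;
- enumerate every **intermediate labeling state** arising from incomplete
  incorporation and metabolic scrambling (independently omittable label
  units per amino acid, e.g. `[1, 5]` for [¹⁵N,¹³C₅]-Val), with
  added-neutron collision detection;
- determine **percent incorporation per state** by fitting linear
  combinations of simulated patterns to an observed spectrum: a two-state
  RMSE grid fit and a greedy nearest-neighbor multi-state fit whose
  normalized coefficients sum to 100;
- discriminate isobaric label compositions (e.g. [¹⁵N₃] vs [¹⁵N,¹³C₂]) by
  **isotopic mass defect** after single-point internal calibration;
- run label-aware **peptide-mass-fingerprint** searches and **B/Y fragment**
  matching (CID) to localize labels;
- generate **synthetic FTICR-like spectra** with known mixing weights, noise
  and seed, so every fitting path is testable without instrument data.

The Val/Ile/Leu (`VIL`) and Lys/Gly/Ser (`KGS`) labeling schemes and the
GFP-CD16a example construct are bundled in `sparselabel.data`.

## CLI

```bash
# enumerate labeling states (45 for this peptide under VIL)
sparselabel enumerate GEELFTGVVPILVELDGDVNGHK --scheme VIL

# simulate a fully labeled isotope pattern, write an .xy profile
sparselabel simulate SAMPEGYVQER --scheme VIL --mode fine --out sim.xy

# synthesize a spectrum with known truth, then fit it back
sparselabel synth EEDPIHLR --scheme VIL --weights 40,43,17 --seed 5 --out spec.xy
sparselabel fit spec.xy EEDPIHLR --scheme VIL

# PMF search of an .asc masslist / fragment matching
sparselabel pmf peaks.asc EEDPIHLR,SAMPEGYVQER --scheme VIL --tol-ppm 5
sparselabel fragments TISFKDDGTYK --scheme VIL --charge 2 --masslist ms2.asc
```

Custom schemes are JSON files:

```json
{"V": {"n15N": 1, "n13C": 5, "units": [1, 5]},
 "L": {"n15N": 1, "n13C": 0, "units": [1]},
 "extras": [{"n15N": 2, "n13C": 5}]}
```

`units` are independently omittable label blocks; `extras` declares
additional states (e.g. scrambling routes) beyond the reachable set.

## Library sketch

```python
from sparselabel import *
from sparselabel import data
from sparselabel.states import LabelScheme
from sparselabel.synth import SynthSpec, generate_spectrum, state_patterns

vil = LabelScheme.from_dict(data.VIL_SCHEME)
states = enumerate_states("EEDPIHLR", vil)          # (0,0), (1,0), (2,0)
obs, truth = generate_spectrum(SynthSpec("EEDPIHLR", vil, (40., 43., 17.)))
fit = fit_multi_state(obs, states, state_patterns("EEDPIHLR", states),
                      fwhm=truth["fwhm"])
print(dict(zip(fit.descriptors, fit.weights)))      # ≈ {…: 40, …: 43, …: 17}
```
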