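# synfibre

Hierarchical fibre-assembly modelling for coiled-coil self-assembling
systems (SYCE2–TEX12), with small-angle X-ray scattering (SAXS) analysis,
electron-micrograph quantification and fully reproducible synthetic data.

The package implements:

- **Assembly model** — the discrete fibre-length rule `L(n) = 20 + 15(n−1)` nm,
  width taxonomy (2:2 / 4:4 / 10-nm / bundled classes), synaptonemal-complex
  mass estimates, and heptad-register analysis of coiled-coil interface motifs.
- **Bead models & lattice** — coarse bead models of 2:2 and 4:4 building
  blocks and their end-to-end fibres, PDB export, and general triclinic
  d-spacings (d(001) of the 4:4 crystal form = 156.49 Å).
- **SAXS analysis** — Debye and cylinder forward models, Guinier and
  cross-sectional Guinier fits, regularised indirect Fourier transform
  (P(r), Dmax) with Shannon-channel reliability flagging, and SEC-SAXS
  series analysis.
- **EM quantification** — ridge detection, per-fibre length/width
  measurement, width histograms and Gaussian-mixture width populations.
- **Synthetic data** — seeded, byte-reproducible SAXS curves, micrographs
  with ground truth, and SEC elution sweeps.

See `docs/methods.md` for the scientific methods, calibrations and limits
of validity.

## Worked example

Predict the allowed assembly states:

```sh
$ synfibre predict-assembly --n-max 4
$ cat assembly.json
{
  "allowed_lengths_nm": [20.0, 35.0, 50.0, 65.0],
  "width_classes": [
    {"label": "2:2-fibre",     "nominal_nm": 2.0,  "lower_nm": 0.0,  "upper_nm": 3.0},
    {"label": "4:4-fibre",     "nominal_nm": 4.0,  "lower_nm": 3.0,  "upper_nm": 7.0},
    {"label": "10-nm fibre",   "nominal_nm": 10.0, "lower_nm": 7.0,  "upper_nm": 20.0},
    {"label": "bundled fibre", "nominal_nm": 40.0, "lower_nm": 20.0, "upper_nm": 40.0}
  ],
  "sc_mass_GDa_per_um": 4.004723601188799
}
```

Simulate a noisy SAXS curve for a two-block 2:2 fibre (true length 35 nm)
and analyse it:

```sh
$ synfibre --seed 11 simulate-saxs --kind 2:2 --n-subunits 2 --out demo.dat
$ synfibre analyze-saxs demo.dat
$ cat saxs_analysis.json
{
  "input": "demo.dat",
  "Rg_nm": 9.910900433431348,
  "I0": 1251246.750882135,
  "Rc_nm": 0.809859424979231,
  "Dmax_nm": 35.0,
  "shannon_channels": 27.685002350835195,
  "shannon_reliable": true
}
```

The recovered Dmax is the true 35 nm; Rg ≈ 9.9 nm matches the rod
expectation √(35²/12 + R²/2) ≈ 10.1 nm, and Rc ≈ 0.81 nm gives a
cross-sectional radius R = Rc·√2 ≈ 1.1 nm — a thin 2:2 fibre.

Simulate and analyse an SEC elution sweep (long thin fibres elute first):

```sh
$ synfibre --seed 0 simulate-sec --out-prefix sec_frame
$ synfibre analyze-sec sec_frame_*.dat
$ cat sec_series.csv
frame,I0,Rg_nm,Rc_nm,Dmax_nm,shannon_channels,shannon_reliable,status
0,4282934.1519549545,17.497276750425666,0.8212518747939844,70.0,55.37000470167039,True,ok
1,2184239.7475808817,11.987861287932882,0.9893320775522001,45.0,35.59500302250239,True,ok
2,1521719.7407546402,6.903790663654124,1.1363089985701362,25.0,19.775001679167996,True,ok
3,1634879.705801794,5.792530503817872,1.215892626872942,20.0,15.820001343334395,True,ok
```

Dmax falls monotonically while Rc rises — the thinner the species, the
longer the fibre, the signature of the assembly hierarchy.

Simulate a micrograph and quantify the fibres in it:

```sh
$ synfibre --seed 7 simulate-em --out em.tif --truth-out truth.csv
$ synfibre quantify-em em.tif
INFO synfibre: detected 12 fibres
$ cat em_quant_populations.json
[
  {"label": "population-1", "mean_nm": 2.692987110572603, "sd_nm": 0.17553447112312237, "n": 9},
  {"label": "population-2", "mean_nm": 3.8069882872967806, "sd_nm": 0.14532641876861999, "n": 3}
]
```

Two width populations are resolved, corresponding to the 2:2 (~2–3 nm) and
4:4 (~4 nm) fibre classes.

Every command also writes a `*.manifest.json` recording inputs, outputs,
the effective configuration and the seed, so any result can be regenerated
byte-for-byte.

## Python API

```python
import numpy as np
from synfibre import (
    FibreModelSpec, TWO_TWO, build_fibre_beads, model_dmax,
    cylinder_intensity, guinier_fit, ift_pofr,
)

model = build_fibre_beads(FibreModelSpec(TWO_TWO, n_subunits=2))
print(model_dmax(model))          # ~35 nm

curve = cylinder_intensity(length=35.0, radius=1.0, q=np.geomspace(2e-3, 0.25, 400))
print(guinier_fit(curve).Rg)      # ~10.1 nm
print(ift_pofr(curve, np.arange(10.0, 85.0, 2.5)).dmax)
```

## Tests

```sh
python -m pytest -q tests/
```
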