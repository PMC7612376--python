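# Methods

This document records the scientific choices behind `synfibre`: the models it
implements, the numerical methods it uses, how each analysis was calibrated,
and the known limits of validity. All calibrations were performed against
closed-form oracles or against the package's own synthetic ground truth; no
default was adjusted against experimental data.

## 1. Discrete assembly model (`synfibre.assembly`)

SYCE2–TEX12 fibres grow by end-to-end addition of rod-like building blocks.
A single block spans 20 nm; each additional block adds 15 nm because adjacent
blocks overlap by 5 nm at their junctions. The allowed length series is
therefore

```
L(n) = 20 + 15 (n − 1)   nm,   n = 1, 2, 3, …
```

giving 20, 35, 50, 65, … nm. `predict_fibre_length` implements the rule and
rejects non-positive or non-integer `n`; `enumerate_allowed_lengths` expands
the series.

Two building-block stoichiometries are supported: the 2:2 SYCE2:TEX12
heterotetramer (thin, ~2 nm fibres) and the 4:4 hetero-octamer (~4 nm
fibres). `classify_fibre_width` bins measured widths into the 2:2, 4:4,
10-nm intermediate and bundled (~40 nm) classes using fixed boundaries at
3, 7 and 20 nm.

### SC mass model

The mass-per-length of the synaptonemal complex (SC) is estimated from its
cross-section treated as a solvated protein volume: a 100 nm × 50 nm
cross-section, protein density 1.33 g/cm³, and a solvent fraction between
0.8 (loosely packed) and 0.2 (densely packed). This yields 1.6–6.4 GDa/µm,
and 154 GDa for a 24-µm chromosome-length SC at the dense limit. The model
is linear in length and in (1 − solvent fraction); both linearities are
property-tested.

### Heptad-register analysis

Coiled-coil interface residues were analysed by mod-7 congruence.
`congruence_classes` groups residue numbers by their heptad class;
`heptad_register` finds the register offset that places a residue set on the
core *a*/*d* positions. Invariants established by exhaustive search over all
seven offsets: the FFV motif residues fall in a single mod-7 class; the LFIL
motif residues fall in exactly two classes with successive gaps (4, 3, 4),
the signature of alternating *a*/*d* core packing; and the register search
places all LFIL residues on core positions.

## 2. Bead models and lattice geometry (`synfibre.beads`, `synfibre.lattice`)

Building blocks are represented as coarse bead models: a rigid core (a
14 × 4 × 2 nm box of beads) flanked by extended termini, with lateral copies
for the 4:4 form. Fibres are assembled by translating blocks along the fibre
axis with the 5-nm junction overlap and de-duplicating overlapping junction
beads. The model maximum dimension (`model_dmax`, brute-force over bead
pairs plus bead radii) reproduces the 20/35/50/65-nm series to within
rounding, which ties the geometric model to the assembly rule.

d-spacings of a crystal form are computed from the general triclinic metric
tensor (`dspacing`). The implementation is verified two independent ways:
against a brute-force reciprocal-lattice-vector construction (build real
axes, invert, take |h **a*** + k **b*** + l **c***|⁻¹) on random cells, and
against the `gemmi` crystallographic library. For the 4:4 crystal form the
(001) spacing is 156.49 Å — the molecular repeat along the fibre axis.

## 3. SAXS forward models and analysis (`synfibre.saxs`)

Units: momentum transfer `q` is in Å⁻¹ in all I/O and public curve objects;
real-space lengths are nm internally (conversion factor 10).

**Forward models.** `debye_intensity` evaluates the Debye formula over bead
models with per-bead weights and Gaussian form factors; I(0) equals
(Σ weights)² exactly. `cylinder_intensity` integrates the classical
orientationally averaged cylinder form factor by fixed-order Gauss–Legendre
quadrature; it matches the two-point Debye closed form and the thin-rod
(sine-integral) limit in tests.

**Guinier analysis.** `guinier_fit` performs the standard ln I vs q² fit,
scanning windows with `q·Rg ≤ window_qRg` (default 0.8) and requiring a
minimum point count and linearity. Truncation bias on rod-like particles:
for a 35-nm rod at `window_qRg = 0.8` the fitted Rg is biased −2%; at 0.5
the bias is −0.8%. The default stays at 0.8 (conventional, more noise
robust); use 0.5 on low-noise data when accuracy matters more than
precision.

**Cross-sectional Guinier.** `cross_section_fit` fits ln(qI) vs q² in the
plateau region above the overall-Guinier knee (the window start scales with
`plateau_factor = 1.6` over 1/Rg; the value was calibrated against the
closed-form rod oracle Rc = R/√2). An exactly flat ln(qI) window (ideal
1/q rod scattering) is clamped to slope 0 → Rc = 0 to avoid float round-off
producing a spurious rejection. **Domain of validity: rods with aspect
ratio L/2R ≳ 3.** Across the studied size regime (L = 15–65 nm,
R = 1.0–2.7 nm, aspect ≥ 3) recovered Rg and Rc are within 3% of the
closed-form values. At aspect 2.8 the factorization itself breaks down and
Rc carries an intrinsic −3.2% bias that is insensitive to window placement;
this regime is characterised (bias bounded in (−5%, 0)) but excluded from
the accuracy claim.

**Indirect Fourier transform.** `ift_pofr` inverts I(q) to P(r) on a
candidate-Dmax grid: for each candidate, a smoothness-regularised
least-squares inversion with a non-negativity bias; the regularisation
weight is chosen by an L-curve knee criterion with a normalised smoothness
penalty. The support estimate within each candidate comes from the
flank intercept of P(r), refined on a finer r-grid. Candidate selection
uses reduced χ²: feasible candidates satisfy
`χ² ≤ max(best_χ² · slack, 1.0)` — the floor at 1 encodes that any fit
within the noise is statistically indistinguishable, and prevents
meaningless ratio comparisons of near-zero χ² on (nearly) noiseless data;
the smallest feasible Dmax is reported. Recovery is within 5% of the true
Dmax (√(L² + 4R²)) at point-wise SNR ≥ 20 across the 15–65-nm series.
Limitation: with coarse grids (~300 points) and long rods near the Shannon
limit, recovery degrades; `shannon_channels` reports the channel count and
flags Dmax > π/qmin as unreliable.

**SEC series.** `analyze_sec_series` applies Guinier, cross-section and IFT
per frame and returns a table with a per-frame `status` column; frames where
any step fails are marked rather than raising. On the default simulated
elution sweep (65-nm 2:2 fibres eluting first, ending at the 4:4 block)
Dmax decreases and Rc increases strictly monotonically — thinner species
are longer, the defining signature of the assembly hierarchy.

## 4. Electron-micrograph quantification (`synfibre.emquant`)

**Preprocessing** removes the mean, suppresses slow background with a
Gaussian-blur subtraction, and band-passes in frequency space. Gradient
suppression is verified on synthetic ramps (interior residual < 5% of the
ramp amplitude; FFT wraparound confines the remainder to the borders).

**Ridge detection** uses Hessian-eigenvalue ridge filtering with hysteresis
thresholding, skeletonisation and trace extraction. Width at each trace
point is measured from the intensity profile perpendicular to the local
tangent, using eigenvector orientation with a dual-formula fallback for the
degenerate cases; fibre ends are extended along the tangent while intensity
support persists, so that `min_length` filtering acts on the detected core,
not the extension.

**Calibration** (against noise-free unit-contrast synthetic ridges of known
width w, rendered by the package's own generator): detection scale
`sigma = max(1.0, w/(2√3))` (the second-derivative optimum for a flat-top
ridge), hysteresis thresholds 0.12/0.05, `min_length = 0.75·w·aspect`
terms in pixels. With these settings, single straight fibres at widths
4–20 px and arbitrary orientation are recovered with length error < 5% and
mean width error < 10%; the residual width bias is largest (+7.4%) at
w = 4 px where the PSF σ is comparable to the half-width.

**Detection reliability.** On the default micrograph recipe
(contrast/noise = 20) the detected fibre count equals the ground-truth
count in 49/50 fixed-seed repeats (98%). The default `min_length_px = 20`
(half the shortest real fibre in the default recipe, 40 px) suppresses
short spurious background-noise ridges; at 10 px three spurious 12–24-px
ridges appeared across the 50 repeats.

**Width populations.** `fit_width_populations` fits a Gaussian mixture
(scikit-learn, fixed seed → deterministic) and reports per-class mean, sd
and count sorted by mean. On a 140/70 two-class synthetic mixture
(means 2.3/3.6 nm, sd 0.4/1.0 nm) the responsibility-based hard assignment
is 88% correct (criterion: ≥ 85%) with means recovered within 2%.

## 5. Synthetic data (`synfibre.simulate`)

All generators take explicit seeds and are byte-reproducible. SAXS noise is
Gaussian with `sd = relative_sd · I + floor_sd`, reported per point in the
`.dat` files. Micrographs render fibres as anti-aliased flat-ended bright
ridges on a mid-grey background with Gaussian PSF blur, linear background
gradient and white noise; ground truth (polylines, widths, lengths) is
returned alongside. SEC frames are convex mixtures of species curves; the
default sweep runs from pure 65-nm 2:2 fibres to the pure 4:4 block. The
generator defaults are the study conditions and were not adjusted against
analysis outcomes; the single analysis default changed after a study
(`min_length_px`, above) is an analysis-side threshold calibrated against
generator ground truth.

## 6. Known fidelity gaps

- Bead models have no hydration shell and uniform contrast; absolute
  intensities are on an arbitrary scale.
- The cylinder oracle ignores flexibility and polydispersity.
- Cross-sectional Guinier is undefined below aspect ~3 (see §3).
- Micrographs model negative-stain-like contrast only; no CTF.
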