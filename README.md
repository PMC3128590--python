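# neuritemap

Voxel-wise neurite-density mapping from multi-shell diffusion-weighted MRI,
with a synthetic layered-hippocampus phantom and exact small-sample group
statistics.

The signal in each voxel is modeled as two non-exchanging water pools: an
isotropic Gaussian pool (effective diffusivity `d_eff`) and a pool of
impermeable, cylindrically symmetric neurites (axial/transverse diffusivities
`d_long`/`d_trans`) whose orientations follow an even-order real
spherical-harmonic ODF. The Funk–Hecke theorem reduces the orientation
integral to per-order kernel coefficients

```
k_l(alpha) = 2*pi * ∫_{-1}^{1} exp(-alpha t^2) P_l(t) dt,   alpha = b (d_long - d_trans)
```

so the predicted signal is

```
S(b, g) = s0 [ (1 - nu) e^{-b d_eff} + nu e^{-b d_trans} Σ_lm f_lm k_l(alpha) Y_lm(g) ]
```

with `f_00` pinned to `1/sqrt(4*pi)` (unit-mass ODF). The neurite signal
fraction `nu` is the "neurite density" mapped across the volume. Fitting uses
variable projection: the model is linear in `s0(1-nu)` and `s0*nu*f_lm`, so
only the three diffusivities are optimized nonlinearly (bound-constrained
least squares, DTI-based initialization, seeded multi-start). b-values are in
s/mm², diffusivities in mm²/s.

The default acquisition is 9 shells (b = 0, 2000, 3000, 4000, 5000, 6000,
8000, 10000, 15000 s/mm²) × 6 directions from a packaged 54-point
near-uniform antipodal set (degree-4 quadrature error ≈ 2e-8), Δ/δ = 8/2 ms,
4 averages.

Because no acquisition data are distributed, the pipeline runs on a phantom:
a banded slab with one band per hippocampal subregion (CA1/CA3 × SO, CL, SR,
LM and DG × GL, ML), per-subject layer densities drawn from published
group-level mean ± SD (n = 4 per group), signals from the forward model, and
Rician noise `sqrt((S+e1)^2 + e2^2)` with `sigma = s0/SNR/sqrt(n_averages)`.
Group comparisons per ROI use an exact two-sided Wilcoxon rank-sum test (full
enumeration of all 70 assignments at n = 4+4; mid-ranks for ties) plus the
relative reduction `100*(control - stressed)/control`.

## Command-line pipeline

```bash
neuritemap simulate --out study/ [--config config.yaml] [--seed N] [--noise-free] [--quiet]
neuritemap fit      --study study/ --out maps/  [--config config.yaml] [--seed N] [--quiet]
neuritemap stats    --maps maps/ --study study/ --out stats/ [--config config.yaml] [--quiet]
```

`simulate` writes per-subject NIfTI + FSL-style bval/bvec, the shared label
map, ground-truth CSV and a provenance record; `fit` writes per-subject
`neurite_density.nii.gz`, `md.nii.gz`, `converged.nii.gz` and a fit log;
`stats` writes per-subject ROI summaries, the per-ROI comparison CSV and a
rendered text table. Every stage records config hash, seed and version in
`provenance.json`; reruns with the same config are bit-identical.

Config file schema (all keys optional):

```yaml
simulate:
  n_per_group: 4      # subjects per group
  snr_b0: 50          # Rician SNR at b=0 ('--noise-free' overrides)
  seed: 0
  band_width: 2       # voxels per layer band
  n_cols: 16          # slab width
fit:
  l_max: 4
  n_starts: 5
  seed: 0
stats:
  alpha: 0.05
  holm: false         # Holm correction off by default (uncorrected tests)
```

## Caveats

* The objective is Gaussian least squares on magnitude data; the Rician
  noise floor at b = 15000 s/mm² biases `nu` upward at finite SNR. This is
  deliberate (matching 4-average magnitude data handling) and is exercised,
  not corrected, by the tests.
* In isotropic cell layers (CL, GL) the two compartments are nearly
  indistinguishable, so per-voxel `nu` is weakly identified at finite SNR;
  the model separates compartments reliably only where the ODF is
  anisotropic.
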