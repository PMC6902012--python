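# Methods

## The comparison

Two processing orders for resting-state fMRI temporal features are contrasted
on identical inputs:

- **Prenorm**: warp the (preprocessed) 4D time series into standard space
  with a per-subject deformation field, then compute tSNR, ALFF, ReHo and
  seed FC on the warped series (seed used directly in standard space).
- **Postnorm**: compute the same features in native space (the seed sphere is
  inverse-normalized into native space first), then warp each 3D feature map.

Both branches share identical preprocessing — confound regression, when
enabled — before the branch point; the 0.01–0.08 Hz band-pass for FC/ReHo
runs inside each branch, so Prenorm filters the warped series and Postnorm
the native series. This is the only ordering consistent with warping every
timepoint of the series.

The mechanism under study is purely algorithmic. Pull-resampling with
trilinear weights $w_c \ge 0$, $\sum w_c = 1$ replaces each output sample by
$\sum_c w_c x_c$ over the 8 lattice corners. For i.i.d. noise the output
variance shrinks by $\prod_{d}\big[(1-t_d)^2 + t_d^2\big]$, where $t_d$ is
the fractional sampling offset along axis $d$: 1 on-lattice, $1/8$ at
half-voxel offsets, and $(2/3)^3 \approx 0.296$ in expectation for uniform
offsets. Applied to a time series (Prenorm) this suppresses temporal noise —
tSNR rises by $\approx 1/\sqrt{0.296} \approx 1.9$ in the uniform-offset
regime, ALFF falls, neighbours become correlated so ReHo rises. Applied to a
finished scalar map (Postnorm) it merely smooths values; a constant map stays
constant. Because the offsets $t_d$ depend on each subject's warp, Prenorm
converts warp variability into feature variability.

## Synthetic study conditions

**Constant-tSNR phantom.** Every in-mask voxel receives an independent
Gaussian series standardized to zero *sample* mean and unit *sample* SD
(denominator $n-1$), then rescaled to
$\mu + (\mu/\text{tSNR})\,z$. Sample mean and sample tSNR therefore equal
their targets exactly (to float round-off, ~1e-13), not just in expectation.
Defaults: mean 1000, tSNR 100, 190 timepoints, TR 2 s. The same SD convention
(ddof = 1) is used by the tSNR feature, which is what makes the constancy
end-to-end exact.

**Brain mask.** An axis-aligned ellipsoid inscribed in the grid box
(π/6 ≈ 52 % fill). It leaves genuine out-of-mask edge voxels so the
resampler's boundary policy is exercised; whether a phantom should cover the
whole box or only a brain-like region is a free choice, made here in favour
of testing edges.

**Grids.** Default "desk" grid: 20×24×18 voxels at 3 mm (seconds-scale
studies); the full standard-space bounding box
[−90, −126, −72; 90, 90, 108] at 3 mm (61×73×61) is available via
`GridSpec.mni_3mm()`. Bounding-box corners are voxel *centers*; the
voxel-to-world affine is diagonal, indices are 0-based.

**Deformation fields.** I.i.d. Gaussian 3-vector fields smoothed to a stated
FWHM and rescaled so the RMS displacement magnitude equals the requested
amplitude exactly. Defaults: per-subject amplitude drawn uniformly from
2–4 mm RMS, smoothness 25 mm FWHM — magnitudes representative of the
nonlinear component of anatomical normalization, smooth at the centimetre
scale as regularized warps are, and comfortably diffeomorphic (steeper
combinations can fold, which the inversion detects and reports). At 2–4 mm
the per-axis fractional offsets are already near-uniform, which is why the
simulated Prenorm tSNR inflation lands near the uniform-offset prediction.

**Cohorts.** One root seed; subject and session seeds are spawned via
`numpy.random.SeedSequence`, so cohorts are bit-reproducible and subjects
independent. Sessions of a subject share the amplitude (anatomy) but draw
independent field realizations by default, emulating normalization
parameters re-estimated per scan with the head repositioned;
`share_session_warp=True` reuses one field. Optional subject/session offsets
to the target tSNR (`between_subject_sd`, `within_subject_sd`, default 0)
plant genuine individual differences for reliability experiments; the
reliability preset uses 15 and 3 tSNR units (~15 % and ~3 % of the mean,
plausible for empirical between-subject spread and scan-rescan drift).

**Network signal.** `embed_network_signal` adds one shared zero-mean
band-limited (0.01–0.08 Hz) unit-SD source, scaled by `signal_sd`, to every
voxel of each ROI. The preset uses signal SD 5 on noise SD 10 (temporal
SNR 0.5). Voxel means are untouched; temporal SD rises as expected for added
signal. The true design is recorded on the image for recovery tests.

**What the phantom does *not* emulate:** head motion, slice-timing effects,
physiological noise, spatially autocorrelated scanner noise, anatomical
variability in the mask, and any genuine neural signal outside the embedded
ROIs. Passing tests therefore demonstrate the *algorithmic* consequences of
the normalization order, not the full behaviour of empirical data — for real
data the package reads 4D NIfTI plus displacement-field NIfTI inputs, and the
empirical magnitudes will differ.

## Numerical choices

- **Resampling** is pull (backward) only, trilinear or nearest-neighbour; an
  output voxel is *valid* only if its full interpolation support (all 8
  corners, or the single nearest voxel) lies in the source mask. Invalid
  voxels are zeroed and excluded from every statistic — masking, rather than
  zero-filling, keeps edge artifacts out of whole-brain means.
- **Nearest-neighbour rounding** is half-up (`floor(x + 0.5)`), used
  identically for values and masks, which is what makes
  feature∘warp ≡ warp∘feature *exact* for voxelwise features (tSNR, ALFF)
  under nearest-neighbour resampling. The commutation is deliberately not
  asserted for ReHo (neighbourhoods differ between spaces) or FC (the seed
  time course differs).
- **Warp inversion** solves $v(y) = -u(y + v(y))$ by fixed-point iteration at
  source-lattice nodes, with the update step halved whenever the residual
  grows; failure to reach tolerance raises with diagnostics (it indicates a
  non-diffeomorphic field). The solver runs to 0.005 voxel at the nodes so
  that the *composition* guarantee — forward∘inverse within 0.05 voxel —
  holds at arbitrary interior points (at least 2 voxels from the box faces,
  forward image inside the grid), where off-node interpolation error enters.
  Displacement fields are sampled off-node with cubic splines; linear
  interpolation of the fields would by itself exceed the composition budget.
  Images are never resampled cubically.
- **Band-pass** is an ideal rectangular DFT-domain filter, inclusive at both
  quantized bin edges; DC is retained so mean-dependent quantities stay
  defined (FC/ReHo are mean-invariant, so this is inert for them). ALFF uses
  the regressed-but-unfiltered series, per the fixed processing order.
- **ALFF scaling** is pinned to the one-sided amplitude spectrum
  $(2/N)\,|X_k|$ averaged over in-band bins. Any fixed constant only rescales
  maps and cancels from every comparison; fixing one makes runs
  bit-reproducible.
- **ReHo** uses Kendall's $W$ without tie correction (continuous data; ties
  have measure zero) and requires ≥ 14 of the 27 cube voxels in-mask, else
  the voxel is masked.
- **Confound regression** is OLS on [intercept, confounds, optional linear
  trend] with the fitted intercept added back so tSNR stays defined;
  collinear columns are dropped with a warning. It is *off* by default for
  phantom studies: the phantom's contract is exact constancy, and regressing
  random covariates would perturb the sample SD.
- **Degenerate statistics**: zero-SD voxels are masked rather than emitting
  infinities; an identically-zero paired difference (or a stack exactly equal
  to the null value) reports t = 0 as a valid "no evidence" outcome, while
  zero variance around a nonzero mean is masked (the infinite-t guard).
- **Multiple comparisons**: Benjamini–Hochberg FDR across in-mask voxels.
  Cluster-level Gaussian-random-field correction would require smoothness
  estimation disproportionate to this package and affects only which voxels
  are flagged, not any summary this package reports.
- **CV floor**: voxels with |across-subject mean| below 1e-6 of the map scale
  are masked; CV is ill-defined near zero mean.

## ICC

With two sessions, a one-way random-effects decomposition gives the
between-subject mean square (MSB) and within-subject mean square (MSW). The
reliability index is ICC = (Vb − Vw)/(Vb + Vw) with two exposed readings of
the "variabilities" Vb, Vw:

- `method="components"` (default): Vb = (MSB − MSW)/2 and Vw = MSW, the
  ANOVA estimates of the between- and within-subject *variance components*;
  population value $(\sigma_b^2-\sigma_w^2)/(\sigma_b^2+\sigma_w^2)$ (0.6 for
  σ_b = 2, σ_w = 1).
- `method="ms"`: Vb = MSB, Vw = MSW, which is the classical ICC(1,1) at
  k = 2; population value $\sigma_b^2/(\sigma_b^2+\sigma_w^2)$.

Both are monotone transforms of MSB/MSW, so medians, orderings, and every
Prenorm-vs-Postnorm comparison agree between them; the default follows the
variance-component reading of the formula. Negative estimates are reported,
not clamped. The two readings behave differently under a pure-noise null
(σ_b = 0): the "ms" form centers near 0, while the component form
concentrates near −1 (its Vb estimate vanishes) and can fall below −1 for
individual voxels — negative values simply mean "no reliable between-subject
signal". Conventional display bands (fair/moderate/substantial/almost
perfect) are emitted in summaries for orientation only and carry no
inferential weight. The paired t-test comparing ICC maps between orders
treats voxels as samples; with tens of thousands of correlated voxels its
p-value is descriptive, not inferential — the package reproduces the
computation and this caveat.

Why Prenorm loses reliability here: each scan's warp differs (re-estimated
parameters, repositioned head), so the warp-dependent noise-suppression
factor differs *between a subject's sessions*, loading the within-subject
variance Vw; Postnorm's feature values are computed before any resampling and
are untouched. With session-shared warps the factor would instead load Vb and
the effect reverses — which is why per-scan fields are the default.

## Desk-scale problem sizes

The default study uses 20 subjects, a 20×24×18 grid (4552 in-mask voxels),
190 timepoints, and 5–10 seeded replicates for replicate-based properties —
sizes chosen so a full study runs in seconds-to-minutes while keeping
thousands of voxels for voxelwise statistics. All sizes scale up through
`StudyConfig` (including the full standard-space grid).

## Known limitations

- Only axis-aligned, positive, diagonal NIfTI affines are accepted; oblique
  acquisitions must be resampled upstream.
- Warp estimation is out of scope; fields are inputs.
- B-spline and sinc image interpolation are not implemented (the
  `Interpolator` abstraction leaves room); trilinear and nearest-neighbour
  cover the comparison of interest.
- The phantom's noise is white; empirical autocorrelation would attenuate
  (not remove) the variance-suppression effect.
- fALFF and 7/19-voxel ReHo neighbourhoods are deliberate non-goals.
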