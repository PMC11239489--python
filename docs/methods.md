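# Methods

This note documents the models, algorithms and numerical choices behind the
package, and what the desk-scale synthetic studies do and do not show about
real cryo-EM data.

## Problem setting

Single-particle cryo-EM reconstruction alternates between estimating each
particle image's orientation against a pair of reference maps (one per
random half of the dataset) and reconstructing new references from the
images. Because the images are extremely noisy, the references must be
regularized between iterations; the classical choice is a per-Fourier-shell
Wiener filter whose gains derive from the half-map Fourier shell
correlation (FSC). This package implements the denoiser-prior alternative:
a convolutional denoiser, trained on pairs of half-maps by a noise2noise
objective, replaces the Wiener filter as the source of prior information,
with *spectral trailing* as the safeguard that keeps denoiser-injected
information away from the frequencies used to report resolution.

## Training-pair construction

A half-map pair `(x0, x1)` shares signal and carries independent noise.
From one pair, a training example for target half `k` is

    y    = H_{C,A}[ x_{1-k} + e ]                          (input)
    ybar = H_{C-bar,A}[ x_k * M + h(x_k) * (1 - M) ]       (target)

where `e` is colored noise, `M` is a smooth molecule mask, `h` is a 15 A
low-pass, and `H_{C,A}` applies an anisotropic Gaussian filter with
covariance `C`, a rigid transform `A` (rotation uniform over SO(3),
translation in voxels), a crop to a cubic patch and standardization to zero
mean / unit standard deviation. Outside the mask the target is filled with
the low-passed map rather than zeroed, so disordered-but-dense regions
(detergent micelles, flexible domains) keep plausible smooth density.

Choices the source material leaves open, decided here:

* **Covariance sampling.** Resolution cutoffs for `C` and `C-bar` are drawn
  uniformly from 4–20 A and ordered so the input is never *sharper* than
  the target (equality allowed) — the network is never trained to sharpen,
  a guard against hallucinated high-resolution features. Per-axis
  anisotropy factors are drawn in 0.7–1.4 with a random orientation.
  A cutoff `R` maps to an isotropic covariance with Fourier gain 0.5 at
  frequency `1/R`.
* **Interpolation under `A`**: trilinear, with volume-mean fill outside the
  grid. Crops are drawn interior so fill values rarely matter.
* **Standardization** is computed over the full patch in double precision;
  zero-variance crops are redrawn up to a retry limit.
* **Operation order** in `H` is filter → transform → crop → standardize.

## The denoiser

A residual volumetric U-net: `f(v) = v + g(v)` with encoder blocks
(3x3x3 convolution → instance normalization → SiLU) each followed by 2x
average pooling, a bottleneck block, and decoder blocks (2x nearest
upsampling → skip concatenation → convolution → normalization → SiLU →
channel dropout). The final trunk convolution is zero-initialized, so a
freshly built network is the exact identity — the natural residual-learning
start, and the anchor for several reduction tests. Instance normalization
is used because mini-batches are small; a norm-free variant is available.
The reference full-size ladder (depth 5, channels 26–416) has ~12.9 M
parameters; all studies here use depth-2 toys of a few thousand parameters.

The network and its training are implemented on a small reverse-mode
autodiff engine in `blush.nn` (numpy arrays, static per-pass graphs, Adam
with cosine decay). Every layer's backward pass is tested against central
finite differences.

**Recycling.** `R_r[f, y]` applies `f` to its own output `r` times
(`r` uniform in {0..5}, drawn per example); the loss then differentiates a
single further application:

    L = 1/(2b) * sum_pairs sum_k || ybar_k - f(R_r[f, y_k]) ||^2

Recycled passes run in inference mode and are not differentiated
(stop-gradient): this bounds memory, matches common recycling practice,
and is verified by a dedicated gradient test. Because each of the `b`
pairs contributes both half-directions, the normalization equals the mean
per-example summed squared error, which is how it is computed.

**Whole-volume inference** tiles the map into overlapping cubic patches,
standardizes each, applies the network once, de-standardizes with the
patch's own pre-filter statistics (amplitude restoration is otherwise
undefined for a network trained on standardized data), and recombines with
separable raised-cosine blend weights normalized per voxel to an exact
partition of unity.

## Fourier-shell machinery

One shell convention everywhere: a Fourier voxel with integer-rounded
radius `s` belongs to shell `s`; shell `s` on an `n`-grid with voxel size
`v` corresponds to `n*v/s` Angstrom. Resolution→shell conversions round
down (never passing frequencies beyond the stated resolution). The
solvent-corrected FSC masks both maps, phase-randomizes both beyond a
chosen shell, and applies `(FSC_t - FSC_n)/(1 - FSC_n)` above the
randomization shell plus a 2-shell margin, averaging `FSC_n` over a
configurable number of randomization draws. The resolution shell `rho` is
the largest shell up to which the corrected FSC stays at or above 0.143
(first-crossing rule); a curve that never crosses supports Nyquist, one
below threshold at shell 1 yields `rho = 1`.

Phase randomization replaces phases with those of a real white-noise
field's transform, which preserves Hermitian symmetry exactly (output stays
real, amplitudes untouched).

## Refinement with spectral trailing

The toy refinement loop is deliberately minimal plumbing around the
contribution: hard-assignment projection matching by normalized
cross-correlation over a fixed quasi-uniform orientation grid, and direct
Fourier reconstruction by central-slice insertion. The insertion uses
2x-oversampled trilinear gridding with Friedel-mate insertion, per-voxel
weight normalization, decimation back to the map grid and Hermitian
symmetrization; its adjoint extracts slices from the same oversampled
transform. On dense noiseless data this pair reaches FSC > 0.95 to the
phantom out to 80% of Nyquist.

Per iteration: align each half-set against its own reference; backproject;
estimate `rho` from the masked, solvent-corrected half-map FSC; build new
references. In `baseline` mode the reference is the half-map under the
gold-standard per-shell weight `2*FSC/(1+FSC)` (clamped to [0,1]). In
`blush` mode the *Wiener-filtered* half-map passes through the denoiser
(at its native 1.5 A scale, rescaling by Fourier crop/pad when the grid
differs) and a trailing filter composes the reference: denoised shells up
to `rho - 2`, zero above, except that when `rho` exceeds the denoiser's own
3 A Nyquist the shells above that limit are taken unchanged from the
Wiener-filtered map. Feeding the denoiser the filtered map makes the
identity-denoiser case reduce exactly to the baseline below the trailing
cutoff, and matches the classification-mode contract where the filtered
map is the denoiser input. The trailing edge is a hard cutoff (a soft-edge
option exists); the final iteration never sees the denoiser — the output
is the Wiener-filtered average of the last half-maps.

Because shells at and above `rho - 2` are never populated from the
denoiser, resolution estimated from the final half-maps cannot have been
inflated by it; the suite asserts `trail < rho` at every iteration and
runs a phase-randomization guard (refining data randomized beyond a shell
must leave the corrected FSC at noise level beyond it, in both modes).

## Synthetic data

Phantoms are sums of anisotropic 3D Gaussian blobs — deliberately not
atomic models, mirroring a prior that is trained without atomic-model
supervision and avoiding implied atomic realism. Default blob radii are
2–5 A on a 1.5 A grid so the spectrum carries usable power into the shells
the studies interrogate. The optional disordered sub-box is filled with
band-limited (>= 20 A) random texture, excluded from the soft molecule
mask; particle datasets can additionally draw, per particle, one of
several independent texture volumes so the disordered density is present
in every image but inconsistent between particles — the synthetic analogue
of a detergent micelle. Half-map pairs add independent colored noise
(power ~ `1/(1+(s/s0)^2)`, knee at shell 4) to a shared phantom; particle
images are central-slice projections with independent 2D colored noise and
alternating half-set labels. All generators are pure functions of their
spec and seed.

## Frozen study conditions (blush.experiments)

Sized for single-CPU runtimes; all seeds explicit.

* **Corpus**: 32-cube maps at 1.5 A, 8-blob phantoms with a 14-voxel
  disordered box, masks included; base noise scale 0.4 (map SNR ~ 1).
* **Toy denoiser (noise2noise study)**: depth 2, channels (4, 8), 16-cube
  patches, batch of 4 pairs, 200 Adam steps at 3e-3 (cosine decay), toy
  dropout 0.25 — at a few thousand parameters, the reference 0.5 rate
  destroys too much capacity. Gentle input-noise augmentation (0–0.2).
* **Refinement-facing denoiser**: channels (8, 16), 400 steps, 24 pairs
  whose noise scales span 0.4–2.5, input-noise augmentation 0–1.0 —
  reconstruction intermediates are far noisier than archive-quality maps.
* **Refinement studies**: 64-cube micelle phantom (16 blobs + 28-voxel
  disordered box), 128-orientation grid, 320 particles, 3 iterations;
  low-SNR noise scale 60 (baseline misassigns ~30–40% of orientations).
* **Learning-curve probe**: the raw training-loss trace carries an
  irreducible target-noise floor that varies with each batch's crop
  content by more than the learnable trend, so learning is verified on a
  frozen probe batch (untrained vs trained loss) rather than on trace
  windows.

## What the studies show — and what they cannot

The noise2noise study shows the package's central statistical mechanism:
a denoiser trained purely on noisy pairs moves held-out noisy maps closer
to the clean phantom than they started (all ten seeds). The trailing
contract, reduction property and overfitting guard show the safeguard
logic is exact.

The low-SNR refinement comparison deserves candor. At desk-scale grids the
usable band is 5–10 shells whenever the baseline misassigns >= 30% of
orientations, so the two-shell trailing cutoff discards 25–40% of it —
at publication scale `rho` spans on the order of a hundred shells and the
same two shells cost ~2%. Under that strict precondition the trailing
handicap exceeds what a toy prior recovers, and the baseline wins most
seeds; control experiments show an oracle prior (the true phantom as
denoiser output) does overcome the handicap, and at moderate SNR
(misassignment 10–15%) the denoiser-regularized mode beats the baseline on
the micelle phantom. The package reports both operating points honestly
rather than tuning either.

Passing tests here demonstrate internal correctness and the method's
statistical mechanisms on blob phantoms with stationary colored noise.
They do not demonstrate performance on real micrographs: no CTF, no
beam-induced motion, no structural heterogeneity, no atomic-scale density,
and a hard-assignment E-step rather than marginalization.

## Numerical choices

* Fourier rescaling crops/pads the centered spectrum; output edge
  `round(n * v_in / v_out)` floored to even; the physical density integral
  is preserved exactly (values scale with the voxel-volume ratio).
* MRC I/O goes through gemmi; axis order is canonicalized to `(z, y, x)`
  on read regardless of header axis-order words; files are written mode-2.
* FSC power terms are computed with the same complex expression as the
  cross term so a self-FSC is exactly 1 at every populated shell.
* Shell filters extend beyond-Nyquist corner voxels with the Nyquist gain;
  the trailing filter treats corners as above-Nyquist territory.
* Ties in projection matching break to the lowest orientation index;
  zero-norm templates score zero against everything.
* Degenerate inputs: zero-variance patches pass through inference
  unchanged; training aborts (restoring the last finite state) if the loss
  becomes non-finite.

## Known limitations

* The autodiff engine is single-threaded numpy; the full-size reference
  network is constructible but not practically trainable here.
* The orientation grid is global and fixed; there is no local/translational
  search, no CTF, and no per-particle scale estimation.
* `NoiseSpectrum` families are radially symmetric; astigmatic or
  ice-gradient noise is out of scope.
* Checkpoints store raw float arrays with an embedded config and format
  version; cross-version compatibility is not promised beyond that check.
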