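"""Canonical desk-scale study recipes.

These functions freeze the package's reference experimental conditions —
grid sizes, noise levels, corpus composition, network size and training
length — so the test suite and the reproduction script exercise exactly the
same protocols.  The conditions are sized for single-CPU runtimes; see
docs/methods.md for the rationale behind each choice.

Three protocols:

* :func:`noise2noise_study` — train a depth-2 toy denoiser on synthetic
  half-map pairs and check that it moves a held-out noisy map closer to its
  clean phantom than the input was (the signal-recovery property of
  noise2noise training: the network never sees a clean map, yet learns to
  estimate one).
* :func:`overfitting_guard_study` — refine particles whose images were
  phase-randomized beyond a chosen shell and verify the solvent-corrected
  half-map FSC stays at noise level beyond that shell in both refinement
  modes (no spurious resolution).
* :func:`low_snr_benefit_study` — compare denoiser-regularized refinement
  against the Wiener baseline on membrane-protein-like phantoms (ordered
  blobs plus per-particle disordered "micelle" texture) at low SNR, scoring
  shell-integrated FSC to the ordered phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume
from .spectral import compute_fsc
from .augment import AugmentationPolicy
from .denoiser import DenoiserConfig, DenoiserModel, build_model, denoise_volume
from .training import TrainingConfig, train
from .synthetic import (
    NoiseModel,
    PhantomSpec,
    make_disorder_volumes,
    make_halfmap_pair,
    make_orientation_grid,
    make_particle_dataset,
    make_phantom,
    make_training_corpus,
    randomize_dataset_phases,
)
from .reconstruct import RefinementConfig, refine

__all__ = [
    "CORPUS_TEMPLATE",
    "toy_policy",
    "train_toy_denoiser",
    "noise2noise_study",
    "overfitting_guard_study",
    "low_snr_benefit_study",
    "refinement_phantom",
]

# ---------------------------------------------------------------------------
# reference conditions

# Training corpus: 32^3 maps at the denoiser's native 1.5 A voxel size.
# Blob phantoms with a micelle-like disordered box; per-pair noise scale
# spans map qualities from clean (0.4, map SNR ~ 1) to heavily degraded
# (2.5), the way a curated archive of deposited half-maps spans resolutions.
CORPUS_TEMPLATE = PhantomSpec(
    n=32,
    voxel_size=1.5,
    n_blobs=8,
    blob_radius_range=(2.0, 5.0),
    disorder_region=((8, 8, 8), 14),
    disorder_amplitude=0.8,
)
CORPUS_NOISE_SCALE = 0.4
CORPUS_NOISE_SCALE_RANGE = (0.4, 2.5)

# Toy network: depth 2, trained on 16^3 patches.  Dropout is reduced from
# the full-size reference 0.5 — at a few thousand parameters, dropping half
# of 4-8 channels destroys too much capacity.
TOY_PATCH_EDGE = 16
TOY_CHANNELS = (4, 8)
TOY_CHANNELS_STRONG = (8, 16)
TOY_DROPOUT = 0.25
TOY_LEARNING_RATE = 3e-3


def toy_policy(noise_hi: float = 0.2) -> AugmentationPolicy:
    """Augmentation policy for toy training (16^3 patches).

    ``noise_hi`` caps the amplitude of the extra colored noise injected on
    the input side; the gentle default suits the clean-corpus noise2noise
    study, while the refinement-facing denoiser trains with a wider range.
    """
    return AugmentationPolicy(patch_edge=TOY_PATCH_EDGE,
                              noise_scale_range=(0.0, noise_hi))


def train_toy_denoiser(seed: int, steps: int = 200, n_pairs: int = 16,
                       channels: tuple[int, ...] = TOY_CHANNELS,
                       batch_pairs: int = 4,
                       noise_scale_range: tuple[float, float] | None = None,
                       augment_noise_hi: float = 0.2,
                       ):
    """Train a depth-2 toy denoiser on a synthetic half-map corpus."""
    rng = np.random.default_rng(seed)
    noise = NoiseModel.colored(CORPUS_TEMPLATE.n, CORPUS_NOISE_SCALE)
    corpus = make_training_corpus(n_pairs, CORPUS_TEMPLATE, noise, rng,
                                  noise_scale_range=noise_scale_range)
    cfg = TrainingConfig(batch_pairs=batch_pairs, steps=steps,
                         learning_rate=TOY_LEARNING_RATE, seed=seed)
    mcfg = DenoiserConfig(base_channels=channels, dropout_rate=TOY_DROPOUT)
    return train(corpus, cfg, toy_policy(augment_noise_hi),
                 model_config=mcfg)


def train_refinement_denoiser(seed: int):
    """The stronger toy denoiser used inside refinement studies: wider
    channels, longer training, corpus and augmentation spanning the heavier
    degradation levels reconstruction intermediates exhibit."""
    return train_toy_denoiser(seed, steps=400, n_pairs=24,
                              channels=TOY_CHANNELS_STRONG,
                              noise_scale_range=CORPUS_NOISE_SCALE_RANGE,
                              augment_noise_hi=1.0)


# ---------------------------------------------------------------------------
# noise2noise recovery


@dataclass
class Noise2NoiseOutcome:
    mse_noisy: float
    mse_denoised: float
    loss_first: float
    loss_last: float
    probe_loss_untrained: float
    probe_loss_trained: float

    @property
    def ratio(self) -> float:
        return self.mse_denoised / self.mse_noisy

    @property
    def improved(self) -> bool:
        return self.mse_denoised < self.mse_noisy

    @property
    def loss_decreased(self) -> bool:
        """Training lowered the loss on a frozen probe batch.

        The raw per-step training loss carries an irreducible target-noise
        floor that varies with each batch's crop content by more than the
        learnable trend, so the learning signal is read off a fixed batch
        instead of trace windows.
        """
        return self.probe_loss_trained < self.probe_loss_untrained


def noise2noise_study(seed: int, steps: int = 200,
                      n_pairs: int = 16) -> Noise2NoiseOutcome:
    """Train on noisy pairs only; measure held-out MSE to the clean phantom.

    The held-out phantom is disjoint from the corpus (different seed
    stream) and the evaluation map carries fresh noise.
    """
    from .training import compute_loss

    # frozen probe batch for the learning-curve comparison
    probe_rng = np.random.default_rng(seed + 50001)
    noise = NoiseModel.colored(CORPUS_TEMPLATE.n, CORPUS_NOISE_SCALE)
    probe_corpus = make_training_corpus(4, CORPUS_TEMPLATE, noise, probe_rng)
    probe_batch = []
    for pair in probe_corpus:
        for k in (0, 1):
            probe_batch.append(build_example_for_probe(pair, k, probe_rng))
    untrained = build_model(
        DenoiserConfig(base_channels=TOY_CHANNELS, dropout_rate=TOY_DROPOUT))
    probe_untrained = float(compute_loss(untrained, probe_batch).data)

    result = train_toy_denoiser(seed, steps=steps, n_pairs=n_pairs)
    probe_trained = float(compute_loss(result.model, probe_batch).data)
    eval_spec = PhantomSpec(
        n=CORPUS_TEMPLATE.n,
        voxel_size=CORPUS_TEMPLATE.voxel_size,
        n_blobs=CORPUS_TEMPLATE.n_blobs,
        blob_radius_range=CORPUS_TEMPLATE.blob_radius_range,
        seed=seed + 90001,
    )
    phantom, _ = make_phantom(eval_spec)
    noise = NoiseModel.colored(CORPUS_TEMPLATE.n, CORPUS_NOISE_SCALE)
    ev_rng = np.random.default_rng(seed + 70001)
    pair = make_halfmap_pair(phantom, None, noise, ev_rng)
    den = denoise_volume(result.model, pair.x0, TOY_PATCH_EDGE,
                         TOY_PATCH_EDGE // 2)
    mse_noisy = float(np.mean((pair.x0.grid - phantom.grid) ** 2))
    mse_den = float(np.mean((den.grid - phantom.grid) ** 2))
    k = max(1, min(20, len(result.loss_trace) // 10))
    return Noise2NoiseOutcome(
        mse_noisy=mse_noisy,
        mse_denoised=mse_den,
        loss_first=float(np.mean(result.loss_trace[:k])),
        loss_last=float(np.mean(result.loss_trace[-k:])),
        probe_loss_untrained=probe_untrained,
        probe_loss_trained=probe_trained,
    )


def build_example_for_probe(pair, k, rng):
    """One probe example under the toy policy (helper for the frozen
    learning-curve batch)."""
    from .augment import build_example

    return build_example(pair, k, rng, toy_policy())


# ---------------------------------------------------------------------------
# refinement studies

REFINE_N = 64
REFINE_BLOBS = 16
REFINE_DISORDER = (((20, 12, 12)), 28)
REFINE_DISORDER_AMPLITUDE = 0.8
REFINE_ORIENTATIONS = 128
REFINE_PARTICLES = 320
REFINE_NOISE_SCALE_LOW_SNR = 60.0
REFINE_ITERATIONS = 3


def refinement_phantom(seed: int = 2):
    """The membrane-protein-like refinement phantom: ordered blobs plus a
    disordered micelle-like box.  Returns (phantom_with_disorder, mask,
    ordered_only_phantom) — the last is the scoring target, since the
    disordered density is not reproducible signal."""
    spec = PhantomSpec(
        n=REFINE_N, voxel_size=1.5, n_blobs=REFINE_BLOBS,
        blob_radius_range=(2.0, 5.0),
        disorder_region=(REFINE_DISORDER[0], REFINE_DISORDER[1]),
        disorder_amplitude=REFINE_DISORDER_AMPLITUDE, seed=seed,
    )
    phantom, mask = make_phantom(spec)
    clean_spec = PhantomSpec(
        n=REFINE_N, voxel_size=1.5, n_blobs=REFINE_BLOBS,
        blob_radius_range=(2.0, 5.0), seed=seed,
    )
    ordered, _ = make_phantom(clean_spec)
    return spec, phantom, mask, ordered


def _integrated_fsc(vol: Volume, target: Volume) -> float:
    f = compute_fsc(vol, target)
    return float(f.values[1:].sum())


@dataclass
class RefinePairOutcome:
    int_fsc_baseline: float
    int_fsc_blush: float
    acc_baseline: float
    acc_blush: float
    rho_baseline: list
    rho_blush: list


def low_snr_benefit_study(model: DenoiserModel, seed: int,
                          noise_scale: float = REFINE_NOISE_SCALE_LOW_SNR,
                          n_particles: int = REFINE_PARTICLES,
                          iterations: int = REFINE_ITERATIONS,
                          ) -> RefinePairOutcome:
    """One seed of the low-SNR comparison: baseline vs denoiser-regularized
    refinement on the micelle phantom, scored by shell-integrated FSC to
    the ordered phantom."""
    spec, _, mask, ordered = refinement_phantom()
    grid = make_orientation_grid(REFINE_ORIENTATIONS)
    texs = make_disorder_volumes(spec, 12, np.random.default_rng(55))
    noise = NoiseModel.colored(REFINE_N, noise_scale)
    data = make_particle_dataset(ordered, n_particles, grid, noise,
                                 np.random.default_rng(seed),
                                 disorder_volumes=texs)
    out = {}
    for mode, m in (("baseline", None), ("blush", model)):
        cfg = RefinementConfig(iterations=iterations, mode=mode, seed=0,
                               mask=mask)
        r = refine(data, m, cfg, grid, patch_edge=32, overlap=16)
        acc = float((r.assignments == data.grid_indices).mean())
        out[mode] = (_integrated_fsc(r.volume, ordered), acc, r.rho_trace)
    return RefinePairOutcome(
        int_fsc_baseline=out["baseline"][0],
        int_fsc_blush=out["blush"][0],
        acc_baseline=out["baseline"][1],
        acc_blush=out["blush"][1],
        rho_baseline=out["baseline"][2],
        rho_blush=out["blush"][2],
    )


@dataclass
class OverfitGuardOutcome:
    mean_fsc_beyond: dict  # mode -> mean corrected FSC beyond the shell
    rand_shell: int


def overfitting_guard_study(model: DenoiserModel, seed: int = 0,
                            rand_shell: int | None = None,
                            n_particles: int = 256,
                            iterations: int = 3) -> OverfitGuardOutcome:
    """Refine phase-randomized particles and measure the solvent-corrected
    half-map FSC beyond the randomization shell, in both modes.

    A mean near zero certifies that neither the Wiener baseline nor the
    denoiser path manufactures correlation where the data carry none.
    """
    n = 32
    spec = PhantomSpec(n=n, voxel_size=1.5, n_blobs=8,
                       blob_radius_range=(2.0, 5.0), seed=3)
    phantom, mask = make_phantom(spec)
    if rand_shell is None:
        rand_shell = n // 4  # 6 A on this grid
    grid = make_orientation_grid(96)
    noise = NoiseModel.colored(n, 4.0)
    rng = np.random.default_rng(seed)
    data = make_particle_dataset(phantom, n_particles, grid, noise, rng)
    data = randomize_dataset_phases(data, rand_shell, rng)
    means = {}
    for mode, m in (("baseline", None), ("blush", model)):
        cfg = RefinementConfig(iterations=iterations, mode=mode, seed=seed,
                               mask=mask, rand_shell=rand_shell)
        r = refine(data, m, cfg, grid, patch_edge=16, overlap=8)
        vals = r.fsc_trace[-1].values
        beyond = vals[rand_shell + 3:]  # past the correction margin
        means[mode] = float(beyond.mean())
    return OverfitGuardOutcome(mean_fsc_beyond=means, rand_shell=rand_shell)
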