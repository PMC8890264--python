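"""Conditional variational autoencoder over atomic density grids.

The model learns p(lig | rec) for ligand density grids conditioned on
receptor density grids.  Three networks share a multi-resolution 3D
convolutional topology:

* an **input encoder** mapping the (receptor, ligand) grid pair to the
  parameters (mu, sigma) of a diagonal-Gaussian approximate posterior
  q(z | rec, lig);
* a **conditional encoder** mapping the receptor grid to a conditioning
  vector c, exposing its per-level feature maps as U-Net skip connections;
* a **decoder** mapping the concatenation [z, c] (plus skip features) to a
  nonnegative generated ligand grid via nearest-neighbor upsampling and
  convolutions, with a softplus output activation.

Training minimizes

    L = lambda_recon * L_recon + lambda_KL(t) * L_KL + lambda_steric * L_steric

where L_recon is the summed squared voxel error, L_KL the closed-form
diagonal-Gaussian KL divergence to the standard-normal prior, and L_steric
the channel-summed receptor x generated-ligand density overlap.  The KL
weight follows a linear ramp: 0.1 until iteration 450 000, rising to 1.6
over the next 200 000 iterations.  Optimization uses RMSprop (reference
settings: learning rate 1e-5, batch size 8).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .atom_types import TypedStruct
from .grids import DensityGrid, GridSpec, RigidTransform, molecule_to_grid, random_transform, steric_overlap

__all__ = [
    "ModelConfig", "TrainConfig", "LossWeights", "LatentDistribution",
    "ConditionalCode", "GridCVAE", "kl_divergence", "reconstruction_loss",
    "kl_weight", "total_loss", "train", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    grid_points: int = 48
    lig_channels: int = 18
    rec_channels: int = 18
    latent_dim: int = 128
    block_widths: tuple = (32, 64, 128)
    use_skip_connections: bool = True
    spectral_norm: bool = True
    rng_seed: int = 0

    @property
    def n_levels(self) -> int:
        return len(self.block_widths)

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.grid_points % (2**self.n_levels) != 0:
            raise ValueError("grid_points must be divisible by 2^n_levels")


@dataclass(frozen=True)
class LossWeights:
    recon: float = 4.0
    kl_initial: float = 0.1
    kl_final: float = 1.6
    kl_ramp_start: int = 450_000
    kl_ramp_length: int = 200_000
    steric: float = 1.0

    def __post_init__(self):
        if min(self.recon, self.kl_initial, self.kl_final, self.steric) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.kl_ramp_length <= 0:
            raise ValueError("ramp length must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 8
    max_iterations: int = 1_000_000
    rng_seed: int = 0
    augment: bool = True
    max_translation: float = 2.0
    log_every: int = 100
    checkpoint_path: str | None = None
    log_path: str | None = None


@dataclass
class LatentDistribution:
    """Diagonal Gaussian latent parameters."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            raise ValueError("latent std must be strictly positive")


@dataclass
class ConditionalCode:
    vector: np.ndarray
    skip_features: list


def kl_divergence(latent: LatentDistribution) -> float:
    """KL( N(mu, sigma) || N(0, 1) ) = sum 1/2 (mu^2 + sigma^2 - 2 ln sigma - 1)."""
    mu, sigma = latent.mean, latent.std
    return float(np.sum(0.5 * (mu**2 + sigma**2 - 2.0 * np.log(sigma) - 1.0)))


def reconstruction_loss(lig_gen, lig, form: str = "sum") -> float:
    """Squared error over all voxels and channels ('sum', or 'mean' per voxel)."""
    a = lig_gen.values if isinstance(lig_gen, DensityGrid) else np.asarray(lig_gen)
    b = lig.values if isinstance(lig, DensityGrid) else np.asarray(lig)
    if a.shape != b.shape:
        raise ValueError("grid shapes differ")
    sq = (a - b) ** 2
    return float(sq.sum() if form == "sum" else sq.mean())


def kl_weight(weights: LossWeights, iteration: int) -> float:
    """Linear ramp from kl_initial to kl_final over the configured window."""
    if iteration < 0:
        raise ValueError("iteration must be nonnegative")
    if iteration < weights.kl_ramp_start:
        return weights.kl_initial
    frac = (iteration - weights.kl_ramp_start) / weights.kl_ramp_length
    frac = min(frac, 1.0)
    return weights.kl_initial + frac * (weights.kl_final - weights.kl_initial)


def total_loss(lig, lig_gen, rec, latent: LatentDistribution, weights: LossWeights, iteration: int):
    """Weighted loss and per-term breakdown at a training iteration."""
    recon = reconstruction_loss(lig_gen, lig)
    kl = kl_divergence(latent)
    steric = steric_overlap(rec, lig_gen) if isinstance(rec, DensityGrid) else float(
        np.sum(np.asarray(rec).sum(0) * np.asarray(lig_gen.values if isinstance(lig_gen, DensityGrid) else lig_gen).sum(0))
    )
    lam_kl = kl_weight(weights, iteration)
    value = weights.recon * recon + lam_kl * kl + weights.steric * steric
    return value, {"recon": recon, "kl": kl, "steric": steric, "lambda_kl": lam_kl}


class _Encoder(nn.Module):
    def __init__(self, c_in, cfg: ModelConfig, out_dim, rng, two_heads):
        sn = cfg.spectral_norm
        self.blocks = []
        c = c_in
        for w in cfg.block_widths:
            self.blocks.append(nn.ConvBlock(c, w, rng, spectral_norm=sn))
            c = w
        bottom = cfg.grid_points // (2**cfg.n_levels)
        flat = cfg.block_widths[-1] * bottom**3
        self.head = nn.Dense(flat, out_dim, rng, spectral_norm=sn)
        self.head2 = nn.Dense(flat, out_dim, rng, spectral_norm=sn) if two_heads else None

    def forward(self, x: nn.Tensor):
        skips = []
        for blk in self.blocks:
            x = blk(x)
            skips.append(x)
            x = nn.avg_pool2(x)
        flat = x.reshape(x.shape[0], -1)
        if self.head2 is None:
            return self.head(flat), skips
        return (self.head(flat), self.head2(flat)), skips


class _Decoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        sn = cfg.spectral_norm
        w = cfg.block_widths
        self.bottom = cfg.grid_points // (2**cfg.n_levels)
        self.w_top = w[-1]
        self.fc = nn.Dense(2 * cfg.latent_dim, w[-1] * self.bottom**3, rng, spectral_norm=sn)
        self.blocks = []
        c = w[-1]
        for i in reversed(range(cfg.n_levels)):
            c_in = c + (w[i] if cfg.use_skip_connections else 0)
            c_out = w[i - 1] if i > 0 else w[0]
            self.blocks.append(nn.ConvBlock(c_in, c_out, rng, spectral_norm=sn))
            c = c_out
        self.out_conv = nn.Conv3d(c, cfg.lig_channels, rng, spectral_norm=sn)
        self.use_skips = cfg.use_skip_connections

    def forward(self, zc: nn.Tensor, skips):
        x = nn.leaky_relu(self.fc(zc))
        x = x.reshape(x.shape[0], self.w_top, self.bottom, self.bottom, self.bottom)
        for lvl, blk in enumerate(self.blocks):
            x = nn.upsample2(x)
            if self.use_skips:
                skip = skips[len(self.blocks) - 1 - lvl]
                x = nn.concat([x, skip], axis=1)
            x = blk(x)
        return nn.softplus(self.out_conv(x))


class GridCVAE(nn.Module):
    """Input encoder + conditional encoder + decoder over density grids."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        c = config
        self.input_encoder = _Encoder(
            c.rec_channels + c.lig_channels, c, c.latent_dim, rng, two_heads=True
        )
        self.cond_encoder = _Encoder(c.rec_channels, c, c.latent_dim, rng, two_heads=False)
        self.decoder = _Decoder(c, rng)

    # ---- batched tensor-level passes (training) -----------------------
    def _encode_input_t(self, rec: np.ndarray, lig: np.ndarray):
        x = nn.Tensor(np.concatenate([rec, lig], axis=1))
        (mu, log_std), _ = self.input_encoder.forward(x)
        return mu, log_std

    def _encode_cond_t(self, rec: np.ndarray):
        x = nn.Tensor(rec)
        cvec, skips = self.cond_encoder.forward(x)
        return cvec, skips

    def _decode_t(self, z: nn.Tensor, cvec: nn.Tensor, skips):
        return self.decoder.forward(nn.concat([z, cvec], axis=1), skips)

    # ---- public single-example API ------------------------------------
    def _check(self, grid: DensityGrid, channels: int):
        if grid.values.shape != (channels,) + (self.config.grid_points,) * 3:
            raise ValueError(
                f"grid shape {grid.values.shape} does not match model config"
            )

    def encode_input(self, rec: DensityGrid, lig: DensityGrid) -> LatentDistribution:
        """Approximate posterior q(z | rec, lig)."""
        if not rec.spec.same_geometry(lig.spec):
            raise ValueError("receptor and ligand grids have different geometry")
        self._check(rec, self.config.rec_channels)
        self._check(lig, self.config.lig_channels)
        with nn.frozen_power_iteration():
            mu, log_std = self._encode_input_t(rec.values[None], lig.values[None])
        return LatentDistribution(mu.data[0], np.exp(log_std.data[0]))

    def encode_condition(self, rec: DensityGrid) -> ConditionalCode:
        """Conditional code c plus per-level skip feature maps."""
        self._check(rec, self.config.rec_channels)
        with nn.frozen_power_iteration():
            cvec, skips = self._encode_cond_t(rec.values[None])
        return ConditionalCode(cvec.data[0], [s.data[0] for s in skips])

    def decode(self, z: np.ndarray, cond: ConditionalCode, spec: GridSpec | None = None) -> DensityGrid:
        """Generated (nonnegative) ligand density for latent z and condition c."""
        z = np.asarray(z, dtype=float)
        if z.shape != (self.config.latent_dim,):
            raise ValueError(f"latent vector must have length {self.config.latent_dim}")
        zt = nn.Tensor(z[None])
        cvec = nn.Tensor(cond.vector[None])
        skips = [nn.Tensor(s[None]) for s in cond.skip_features]
        with nn.frozen_power_iteration():
            out = self._decode_t(zt, cvec, skips)
        spec = spec or GridSpec(
            side=(self.config.grid_points - 1) * 0.5,
            n_channels=self.config.lig_channels,
        )
        return DensityGrid(out.data[0], spec)


def train(dataset, model: GridCVAE, train_config: TrainConfig = TrainConfig(),
          weights: LossWeights = LossWeights(), grid_spec: GridSpec | None = None,
          max_iterations: int | None = None):
    """Train on (receptor TypedStruct, ligand TypedStruct) pairs.

    Grids are rendered on the fly, centered on each ligand's heavy-atom
    centroid, with optional random rigid-pose augmentation shared by the
    receptor/ligand pair.  Returns the per-iteration loss history.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    cfg = model.config
    rng = np.random.default_rng(train_config.rng_seed)
    n_iter = max_iterations if max_iterations is not None else train_config.max_iterations

    def render(pair):
        rec_s, lig_s = pair
        center = tuple(lig_s.centroid)
        spec_r = grid_spec or GridSpec(n_channels=cfg.rec_channels)
        side = spec_r.side
        res = spec_r.resolution
        rspec = GridSpec(center=center, side=side, resolution=res,
                         n_channels=cfg.rec_channels, atomic_radius=spec_r.atomic_radius)
        lspec = GridSpec(center=center, side=side, resolution=res,
                         n_channels=cfg.lig_channels, atomic_radius=spec_r.atomic_radius)
        if train_config.augment:
            tf = random_transform(rng, train_config.max_translation, pivot=center)
        else:
            tf = RigidTransform()
        rec = molecule_to_grid(rec_s, rspec, tf).values
        lig = molecule_to_grid(lig_s, lspec, tf).values
        return rec, lig

    cache = None
    if not train_config.augment:
        cache = [render(p) for p in dataset]

    params = model.parameters()
    opt = nn.RMSprop(params, lr=train_config.learning_rate)
    history = []
    for it in range(n_iter):
        idx = rng.integers(len(dataset), size=train_config.batch_size)
        if cache is not None:
            batch = [cache[i] for i in idx]
        else:
            batch = [render(dataset[i]) for i in idx]
        rec = np.stack([b[0] for b in batch])
        lig = np.stack([b[1] for b in batch])
        B = rec.shape[0]

        mu, log_std = model._encode_input_t(rec, lig)
        sigma = nn.exp(log_std)
        eps = rng.standard_normal(mu.shape)
        z = mu + sigma * nn.Tensor(eps)
        cvec, skips = model._encode_cond_t(rec)
        gen = model._decode_t(z, cvec, skips)

        lig_t = nn.Tensor(lig)
        diff = gen - lig_t
        recon = (diff * diff).sum() * (1.0 / B)
        klt = (
            (mu * mu + sigma * sigma - 2.0 * log_std + (-1.0)).sum() * (0.5 / B)
        )
        rec_sum = nn.Tensor(rec.sum(axis=1, keepdims=True))
        steric = (gen.sum_axis(1) * rec_sum).sum() * (1.0 / B)
        lam_kl = kl_weight(weights, it)
        loss = weights.recon * recon + lam_kl * klt + weights.steric * steric

        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"divergent loss at iteration {it}: recon={recon.data}, "
                f"kl={klt.data}, steric={steric.data}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append({
            "iteration": it, "loss": float(loss.data), "recon": float(recon.data),
            "kl": float(klt.data), "steric": float(steric.data), "lambda_kl": lam_kl,
        })
    if train_config.log_path:
        with open(train_config.log_path, "w", newline="") as fh:
            wtr = csv.DictWriter(fh, fieldnames=list(history[0]))
            wtr.writeheader()
            wtr.writerows(history)
    if train_config.checkpoint_path:
        save_checkpoint(model, train_config.checkpoint_path, iteration=n_iter)
    return history


def save_checkpoint(model: GridCVAE, path, iteration: int = 0) -> None:
    """Weights + ModelConfig + iteration counter in one .npz archive."""
    arrays = model.state_arrays()
    meta = {"config": asdict(model.config), "iteration": iteration}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple:
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = meta["config"]
    cfg["block_widths"] = tuple(cfg["block_widths"])
    model = GridCVAE(ModelConfig(**cfg))
    model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta["iteration"]
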