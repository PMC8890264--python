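"""Latent-space sampling controls and end-to-end generation.

Two sampling modes exist: *posterior* (encode a real receptor-ligand complex
and draw latents around its posterior) and *prior* (draw from the standard
normal).  Two scalar controls shape the draw:

* variability factor lambda_var scales the standard deviation:
      z' = mu + lambda_var * sigma * eps,   eps ~ N(0, I)
* bias factor lambda_bias in [0, 1] linearly interpolates the sampling
  distribution's parameters between the prior (0) and the posterior (1):
      mu'    = lambda_bias * mu_post
      sigma' = lambda_bias * sigma_post + (1 - lambda_bias)

Latent trajectories between encoded ligands use spherical interpolation:
directions rotate at constant angular speed in the plane of the two
endpoints while vector norms interpolate linearly, so the trajectory passes
exactly through every endpoint.

``generate`` runs the full pipeline: grid the inputs, encode, sample,
decode with the receptor's conditional code, then atom fitting and bond
inference turn each generated density into a molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atom_types import TypedStruct, default_scheme
from .bonds import BondRules, make_molecule
from .cvae import ConditionalCode, GridCVAE, LatentDistribution
from .fitting import FitConfig, fit_atoms
from .grids import DensityGrid, GridSpec, molecule_to_grid

__all__ = [
    "SampleSpec", "sample_latent", "interpolate_distribution",
    "slerp", "slerp_trajectory", "interpolation_grid_centers", "generate",
]


@dataclass(frozen=True)
class SampleSpec:
    mode: str = "posterior"
    var_factor: float = 1.0
    bias_factor: float | None = None
    n_samples: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("posterior", "prior"):
            raise ValueError("mode must be 'posterior' or 'prior'")
        if self.var_factor < 0:
            raise ValueError("variability factor must be nonnegative")
        if self.bias_factor is not None and not (0.0 <= self.bias_factor <= 1.0):
            raise ValueError("bias factor must lie in [0, 1]")


def sample_latent(latent: LatentDistribution | None, spec: SampleSpec, latent_dim: int | None = None) -> np.ndarray:
    """Draw n_samples latent vectors z' = mu + lambda_var * sigma * eps.

    ``latent=None`` (or prior mode) uses the standard-normal prior.  Each
    sample index gets its own RNG stream derived from the master seed, so
    individual samples are reproducible independently of batch order.
    """
    if latent is None or spec.mode == "prior":
        if latent_dim is None and latent is None:
            raise ValueError("latent_dim required for prior sampling")
        dim = latent_dim if latent is None else latent.mean.shape[0]
        latent = LatentDistribution(np.zeros(dim), np.ones(dim))
    if spec.bias_factor is not None:
        latent = interpolate_distribution(latent, spec.bias_factor)
    out = np.empty((spec.n_samples, latent.mean.shape[0]))
    for k in range(spec.n_samples):
        rng = np.random.default_rng((spec.rng_seed, k))
        eps = rng.standard_normal(latent.mean.shape[0])
        out[k] = latent.mean + spec.var_factor * latent.std * eps
    return out


def interpolate_distribution(posterior: LatentDistribution, bias_factor: float) -> LatentDistribution:
    """Linear parameter interpolation between prior (0) and posterior (1)."""
    if not (0.0 <= bias_factor <= 1.0):
        raise ValueError("bias factor must lie in [0, 1]")
    mu = bias_factor * posterior.mean
    sigma = bias_factor * posterior.std + (1.0 - bias_factor)
    return LatentDistribution(mu, sigma)


def slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Spherical interpolation: rotate the direction, interpolate the norm.

    Falls back to linear interpolation (with a warning) for antiparallel
    endpoints, where the rotation plane is undefined.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("slerp endpoints must be nonzero")
    ua, ub = a / na, b / nb
    dot = float(np.clip(ua @ ub, -1.0, 1.0))
    norm = (1.0 - t) * na + t * nb
    if dot > 1.0 - 1e-12:
        direction = ua
    elif dot < -1.0 + 1e-12:
        import warnings

        warnings.warn("antiparallel slerp endpoints; falling back to linear interpolation")
        v = (1.0 - t) * a + t * b
        return v
    else:
        omega = np.arccos(dot)
        direction = (np.sin((1.0 - t) * omega) * ua + np.sin(t * omega) * ub) / np.sin(omega)
    return norm * direction


def slerp_trajectory(endpoints, steps_per_segment: int) -> np.ndarray:
    """Piecewise spherical trajectory passing through every endpoint.

    With E endpoints and s steps per segment, returns (E-1)*s + 1 vectors;
    endpoints sit at indices 0, s, 2s, ...
    """
    endpoints = [np.asarray(e, float) for e in endpoints]
    if len(endpoints) < 2:
        raise ValueError("need at least two endpoints")
    if steps_per_segment < 1:
        raise ValueError("steps_per_segment must be >= 1")
    out = [endpoints[0]]
    for a, b in zip(endpoints[:-1], endpoints[1:]):
        for k in range(1, steps_per_segment + 1):
            t = k / steps_per_segment
            out.append(b if t == 1.0 else slerp(a, b, t))
    return np.array(out)


def interpolation_grid_centers(endpoint_centers, steps_per_segment: int) -> np.ndarray:
    """Grid centers along a latent trajectory: linear interpolation of the
    segment endpoints' (real ligand) centers, aligned with slerp_trajectory."""
    centers = [np.asarray(c, float) for c in endpoint_centers]
    if len(centers) < 2:
        raise ValueError("need at least two centers")
    out = [centers[0]]
    for a, b in zip(centers[:-1], centers[1:]):
        for k in range(1, steps_per_segment + 1):
            t = k / steps_per_segment
            out.append((1.0 - t) * a + t * b)
    return np.array(out)


def generate(
    receptor: TypedStruct,
    model: GridCVAE,
    spec: SampleSpec = SampleSpec(),
    ligand: TypedStruct | None = None,
    grid_spec: GridSpec | None = None,
    fit_config: FitConfig | None = None,
    bond_rules: BondRules = BondRules(),
):
    """Sample molecules for a receptor (grid -> encode -> sample -> decode ->
    fit -> bond inference).  Returns a list of per-sample dicts with the
    latent vector, generated grid, fitted structure, molecule and fit loss.
    """
    if spec.mode == "posterior" and ligand is None:
        raise ValueError("posterior sampling requires the reference ligand")
    cfg = model.config
    center = tuple((ligand or receptor).centroid)
    res = grid_spec.resolution if grid_spec else 0.5
    side = grid_spec.side if grid_spec else (cfg.grid_points - 1) * 0.5
    rspec = GridSpec(center=center, side=side, resolution=res, n_channels=cfg.rec_channels)
    lspec = GridSpec(center=center, side=side, resolution=res, n_channels=cfg.lig_channels)
    rec_grid = molecule_to_grid(receptor, rspec)
    cond = model.encode_condition(rec_grid)
    if spec.mode == "posterior":
        lig_grid = molecule_to_grid(ligand, lspec)
        latent = model.encode_input(rec_grid, lig_grid)
    else:
        latent = None
    zs = sample_latent(latent, spec, latent_dim=cfg.latent_dim)
    lig_scheme = default_scheme("ligand")
    fit_config = fit_config or FitConfig()
    results = []
    for k, z in enumerate(zs):
        grid = model.decode(z, cond, spec=lspec)
        fit = fit_atoms(grid, lig_scheme, fit_config)
        mol = make_molecule(fit.struct, bond_rules)
        results.append(
            {
                "index": k,
                "z": z,
                "grid": grid,
                "struct": fit.struct,
                "molecule": mol,
                "fit_loss": fit.final_loss,
                "valid": mol.valid,
            }
        )
    return results
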