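"""Atom fitting: invert a density grid back into typed atoms.

Fitting solves  min_{T,C} || g(T, C) - G_ref ||^2  by alternating two steps:

1. *Detection* — local maxima of the residual density (reference minus the
   density of atoms placed so far), restricted to element channels and above
   a threshold, seed new atoms.  Non-element properties (aromaticity, H-bond
   roles, charge) are read off the property channels at the peak voxel.
2. *Refinement* — gradient descent on the squared-error objective moves all
   atom coordinates off-lattice, with backtracking step halving and the best
   iterate kept.

Rounds are accepted while the L2 objective keeps improving by more than a
relative tolerance; a beam search over candidate peaks generalizes the greedy
default.  The residual grid and objective are updated incrementally over each
atom's compact kernel support, so a fit costs far less than re-rendering the
full grid at every step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .atom_types import TypedAtom, TypedStruct, TypeScheme, type_atom
from .grids import DensityGrid, GridSpec, coordinate_gradient, molecule_to_grid

__all__ = ["FitConfig", "FitResult", "grid_l2", "detect_next_atoms", "refine_coordinates", "fit_atoms"]

# 26-neighbor offsets, excluding the origin
_OFFSETS = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]


@dataclass(frozen=True)
class FitConfig:
    peak_threshold: float = 0.25
    max_atoms: int = 80
    gd_steps: int = 100
    gd_step_size: float = 0.1
    beam_width: int = 1
    atoms_per_round: int = 1
    convergence_tol: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self):
        if self.peak_threshold <= 0:
            raise ValueError("peak_threshold must be positive")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")


@dataclass
class FitResult:
    struct: TypedStruct
    final_loss: float
    loss_trace: list
    n_rounds: int


def grid_l2(struct: TypedStruct, ref: DensityGrid) -> float:
    """Sum over channels and voxels of (grid(struct) - ref)^2."""
    if struct.scheme.total_width != ref.spec.n_channels:
        raise ValueError("scheme width does not match grid channels")
    model = molecule_to_grid(struct, ref.spec)
    return float(np.sum((model.values - ref.values) ** 2))


class _State:
    """A candidate structure plus its residual grid and cached L2 loss.

    residual = grid(struct) - ref, so loss = sum(residual^2).
    """

    def __init__(self, ref: DensityGrid, scheme: TypeScheme):
        self.spec = ref.spec
        self.scheme = scheme
        self.residual = -ref.values.copy()
        self.loss = float(np.sum(self.residual**2))
        self.coords = np.zeros((0, 3))
        self.tvs = np.zeros((0, scheme.total_width))

    def copy(self) -> "_State":
        new = object.__new__(_State)
        new.spec, new.scheme = self.spec, self.scheme
        new.residual = self.residual.copy()
        new.loss = self.loss
        new.coords = self.coords.copy()
        new.tvs = self.tvs.copy()
        return new

    def _apply(self, coord, tv, sign):
        """Add/remove one atom's density, updating the cached loss locally."""
        from .grids import _atom_density

        res = _atom_density(self.spec, np.asarray(coord, float))
        if res is None:
            return
        sl, k = res
        for c in np.nonzero(tv)[0]:
            window = self.residual[(c,) + sl]
            self.loss -= float(np.sum(window**2))
            window += sign * tv[c] * k
            self.loss += float(np.sum(window**2))

    def add_atom(self, coord, tv):
        self._apply(coord, tv, +1.0)
        self.coords = np.vstack([self.coords, np.asarray(coord, float)[None]])
        self.tvs = np.vstack([self.tvs, np.asarray(tv, float)[None]])

    def move_atoms(self, new_coords):
        for a in range(len(self.coords)):
            if not np.array_equal(new_coords[a], self.coords[a]):
                self._apply(self.coords[a], self.tvs[a], -1.0)
                self._apply(new_coords[a], self.tvs[a], +1.0)
        self.coords = new_coords.copy()

    def struct(self) -> TypedStruct:
        atoms = [TypedAtom(c, t) for c, t in zip(self.coords, self.tvs)]
        return TypedStruct(atoms=atoms, scheme=self.scheme)


def _residual_peaks(residual: np.ndarray, spec: GridSpec, scheme: TypeScheme, threshold: float):
    """Strict 26-neighbor local maxima of ``-residual`` on element channels.

    Ties are broken by (value, then lexicographic voxel index): an equal-valued
    plateau keeps only its lexicographically first voxel.
    """
    density = -residual[: scheme.n_element_channels]
    cand = np.argwhere(density >= threshold)
    if len(cand) == 0:
        return []
    padded = np.pad(density, ((0, 0), (1, 1), (1, 1), (1, 1)), constant_values=-np.inf)
    c, i, j, k = cand.T
    vals = density[c, i, j, k]
    keep = np.ones(len(cand), dtype=bool)
    for off in _OFFSETS:
        nb = padded[c, i + 1 + off[0], j + 1 + off[1], k + 1 + off[2]]
        later = off > (0, 0, 0)  # neighbor has larger lexicographic index
        ok = (vals > nb) | ((vals == nb) & later)
        keep &= ok
    peaks = [(float(v), tuple(map(int, idx))) for v, idx in zip(vals[keep], cand[keep])]
    peaks.sort(key=lambda p: (-p[0], p[1]))
    return peaks


def detect_next_atoms(ref: DensityGrid, current: TypedStruct, config: FitConfig):
    """Candidate atoms at residual peaks, sorted by residual value descending."""
    model = molecule_to_grid(current, ref.spec)
    residual = model.values - ref.values
    return _candidates_from_residual(residual, ref.spec, current.scheme, config)


def _candidates_from_residual(residual, spec: GridSpec, scheme: TypeScheme, config: FitConfig):
    peaks = _residual_peaks(residual, spec, scheme, config.peak_threshold)
    elements = scheme.get_property("element").values
    origin, res = spec.origin, spec.resolution
    density = -residual
    out = []
    taken = set()
    for value, (c, i, j, k) in peaks:
        if (i, j, k) in taken:  # one atom per voxel: best element channel wins
            continue
        taken.add((i, j, k))
        coord = origin + res * np.array([i, j, k], dtype=float)
        aromatic = acceptor = donor = False
        charge = 0
        if scheme.has_property("aromatic"):
            aromatic = density[scheme.block_slice("aromatic").start + 1, i, j, k] >= 0.5
        if scheme.has_property("acceptor"):
            acceptor = density[scheme.block_slice("acceptor").start, i, j, k] >= 0.5
        if scheme.has_property("donor"):
            donor = density[scheme.block_slice("donor").start, i, j, k] >= 0.5
        if scheme.has_property("charge"):
            cb = density[scheme.block_slice("charge"), i, j, k]
            charge_vals = scheme.get_property("charge").values
            charge = charge_vals[int(np.argmax(cb))] if np.any(cb >= 0.5) else 0
        tv = type_atom(elements[c], bool(aromatic), bool(acceptor), bool(donor), charge, scheme)
        out.append(TypedAtom(coord, tv))
    return out


def _refine_state(state: _State, config: FitConfig) -> None:
    """Gradient descent with backtracking halving; keeps the best iterate."""
    if len(state.coords) == 0:
        return
    step = config.gd_step_size
    for _ in range(config.gd_steps):
        grad = coordinate_gradient(state.residual, state.spec, state.coords, state.tvs)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite coordinate gradient")
        gnorm = np.max(np.abs(grad))
        if gnorm < 1e-12:
            break
        prev_loss = state.loss
        prev_coords = state.coords.copy()
        accepted = False
        for _ in range(8):
            state.move_atoms(prev_coords - step * grad)
            if state.loss < prev_loss:
                accepted = True
                break
            state.move_atoms(prev_coords)
            step *= 0.5
        if not accepted:
            break
        step *= 1.1
        if prev_loss - state.loss < 1e-9 * max(prev_loss, 1.0):
            break


def refine_coordinates(struct: TypedStruct, ref: DensityGrid, config: FitConfig = FitConfig()) -> TypedStruct:
    """Refine atom coordinates by gradient descent on the L2 objective.

    Types are unchanged; the returned structure's loss never exceeds the input's.
    """
    state = _State(ref, struct.scheme)
    for atom in struct.atoms:
        state.add_atom(atom.coordinate, atom.type_vector)
    _refine_state(state, config)
    return state.struct()


def fit_atoms(ref: DensityGrid, scheme: TypeScheme, config: FitConfig = FitConfig()) -> FitResult:
    """Iterative atom detection + gradient-descent refinement (greedy or beam)."""
    if scheme.total_width != ref.spec.n_channels:
        raise ValueError("scheme width does not match grid channels")
    root = _State(ref, scheme)
    beam = [root]
    best = root
    trace = [best.loss]
    n_rounds = 0
    while True:
        if len(best.coords) >= config.max_atoms:
            break
        children = []
        for state in beam:
            cands = _candidates_from_residual(state.residual, ref.spec, scheme, config)
            if not cands:
                continue
            if config.beam_width == 1:
                chosen = [cands[: config.atoms_per_round]]
            else:
                chosen = [[c] for c in cands[: config.beam_width]]
            for group in chosen:
                child = state.copy()
                for atom in group:
                    if len(child.coords) >= config.max_atoms:
                        break
                    child.add_atom(atom.coordinate, atom.type_vector)
                _refine_state(child, config)
                children.append(child)
        if not children:
            break
        children.sort(key=lambda s: s.loss)
        improved = children[0].loss < best.loss - config.convergence_tol * best.loss
        if not improved:
            break
        beam = children[: config.beam_width]
        best = children[0]
        trace.append(best.loss)
        n_rounds += 1
    return FitResult(struct=best.struct(), final_loss=best.loss, loss_trace=trace, n_rounds=n_rounds)
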