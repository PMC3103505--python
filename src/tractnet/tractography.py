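"""Deterministic fiber tracking on diffusion-tensor fields.

Implements three classic deterministic streamline families on a voxel grid of
3x3 diffusion tensors:

* ``FACT`` — follow the principal eigenvector of the tensor in the current
  voxel (fiber assignment by continuous tracking);
* ``TEND`` — tensor deflection, propagate ``v_out ∝ D @ v_in``;
* ``TL``   — tensorline, blend the eigenvector and the deflected incoming
  direction by the local fractional anisotropy,
  ``v_out ∝ FA * e1 + (1 - FA) * D @ v_in``.

Direction fields are sampled by nearest-neighbor voxel lookup (FACT is defined
voxel-wise); the same lookup is used for TL/TEND so that the three trackers
coincide on spatially constant, axially symmetric fields. Default stopping
parameters are those typical of high-resolution mouse DTI: 25 µm steps,
200 mm maximum trace length, ±80° per-step curvature threshold, and an FA
stopping threshold of 0.12 with brute-force seeding (one bidirectional
streamline per supra-threshold voxel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TensorField",
    "TrackParams",
    "Trajectory",
    "compute_fa",
    "compute_md",
    "select_seeds",
    "track",
]

_MODES = ("FACT", "TL", "TEND")


def compute_fa(tensor: np.ndarray) -> float:
    """Fractional anisotropy of a symmetric 3x3 diffusion tensor.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, clipped to
    [0, 1]. Tiny negative eigenvalues are clamped to zero; the all-zero
    tensor is defined to have FA = 0.
    """
    lam = _eigvals(tensor)
    return _fa_from_eigvals(lam)


def compute_md(tensor: np.ndarray) -> float:
    """Mean diffusivity, the mean of the three eigenvalues (= trace / 3)."""
    lam = _eigvals(tensor)
    return float(lam.sum() / 3.0)


def _eigvals(tensor: np.ndarray) -> np.ndarray:
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3):
        raise ValueError(f"expected a 3x3 tensor, got shape {tensor.shape}")
    if not np.allclose(tensor, tensor.T, atol=1e-10):
        raise ValueError("tensor is not symmetric")
    lam = np.linalg.eigvalsh(tensor)
    return np.clip(lam, 0.0, None)


def _fa_from_eigvals(lam: np.ndarray) -> float:
    norm = np.linalg.norm(lam)
    if norm == 0.0:
        return 0.0
    dev = lam - lam.mean()
    fa = np.sqrt(1.5) * np.linalg.norm(dev) / norm
    return float(np.clip(fa, 0.0, 1.0))


@dataclass
class TensorField:
    """Voxel grid of symmetric diffusion tensors with a physical voxel size.

    Parameters
    ----------
    tensors
        Array of shape ``(nx, ny, nz, 3, 3)``; units mm²/s.
    voxel_size
        Edge length of a voxel along each axis, in mm (scalar or length-3).
    """

    tensors: np.ndarray
    voxel_size: np.ndarray

    _fa: np.ndarray | None = field(default=None, repr=False, compare=False)
    _md: np.ndarray | None = field(default=None, repr=False, compare=False)
    _e1: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, 3, 4), atol=1e-10):
            raise ValueError("tensor field contains non-symmetric tensors")
        vs = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        if np.any(vs <= 0):
            raise ValueError("voxel_size must be positive")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def _decompose(self) -> None:
        lam, vec = np.linalg.eigh(self.tensors)
        lam = np.clip(lam, 0.0, None)
        norm = np.linalg.norm(lam, axis=-1)
        dev = lam - lam.mean(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / norm
        self._fa = np.clip(np.where(norm > 0, fa, 0.0), 0.0, 1.0)
        self._md = lam.sum(axis=-1) / 3.0
        # eigh sorts ascending: last eigenvector is the principal axis
        self._e1 = vec[..., :, 2]

    def fa_map(self) -> np.ndarray:
        """Fractional anisotropy at every voxel."""
        if self._fa is None:
            self._decompose()
        return self._fa

    def md_map(self) -> np.ndarray:
        """Mean diffusivity at every voxel."""
        if self._md is None:
            self._decompose()
        return self._md

    def principal_axis_map(self) -> np.ndarray:
        """Unit principal eigenvector at every voxel, shape (nx, ny, nz, 3)."""
        if self._e1 is None:
            self._decompose()
        return self._e1


@dataclass(frozen=True)
class TrackParams:
    """Streamline integration and stopping parameters.

    step in mm (default 0.025 = 25 µm); max_length in mm; max_angle the
    per-step curvature threshold in degrees; fa_threshold the FA stopping /
    seeding threshold; mode one of FACT, TL, TEND.
    """

    step: float = 0.025
    max_length: float = 200.0
    max_angle: float = 80.0
    fa_threshold: float = 0.12
    mode: str = "FACT"

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not 0 < self.max_angle < 180:
            raise ValueError("max_angle must lie in (0, 180) degrees")
        if not 0 <= self.fa_threshold < 1:
            raise ValueError("fa_threshold must lie in [0, 1)")
        if self.max_length <= 0:
            raise ValueError("max_length must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")


@dataclass
class Trajectory:
    """One fiber path: ordered 3-D points (mm) plus per-step scalar samples.

    ``samples`` maps a map name (e.g. ``"md"``, ``"fa"``) to one scalar per
    point, sampled from the voxel containing that point.
    """

    points: np.ndarray
    samples: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        for name, vals in self.samples.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (len(self.points),):
                raise ValueError(f"sample map {name!r} must have one value per point")
            self.samples[name] = vals

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Arc length in mm (sum of inter-point distances)."""
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def select_seeds(field: TensorField, fa_threshold: float = 0.12) -> np.ndarray:
    """Brute-force seed selection: all voxels with FA strictly above threshold.

    Returns an integer array of voxel indices, shape (n_seeds, 3).
    """
    fa = field.fa_map()
    return np.argwhere(fa > fa_threshold)


def _voxel_of(point: np.ndarray, field: TensorField) -> np.ndarray | None:
    idx = np.floor(point / field.voxel_size).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(field.shape)):
        return None
    return idx


def _propagate(
    field: TensorField,
    voxel: np.ndarray,
    v_in: np.ndarray,
    mode: str,
) -> np.ndarray:
    """One direction update; sign chosen so that dot(v_out, v_in) >= 0."""
    i, j, k = voxel
    e1 = field.principal_axis_map()[i, j, k]
    if np.dot(e1, v_in) < 0:
        e1 = -e1
    if mode == "FACT":
        v = e1
    elif mode == "TEND":
        v = field.tensors[i, j, k] @ v_in
    else:  # TL: anisotropy-weighted blend of eigenvector and deflection
        fa = field.fa_map()[i, j, k]
        v = fa * e1 + (1.0 - fa) * (field.tensors[i, j, k] @ v_in)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return e1
    v = v / norm
    if np.dot(v, v_in) < 0:
        v = -v
    return v


def _half_track(
    field: TensorField,
    start: np.ndarray,
    v0: np.ndarray,
    params: TrackParams,
    budget: float,
) -> np.ndarray:
    """Integrate one direction from `start`; returns points after the seed."""
    fa = field.fa_map()
    cos_limit = np.cos(np.radians(params.max_angle))
    pos = start.copy()
    v = v0.copy()
    pts: list[np.ndarray] = []
    length = 0.0
    while length + params.step <= budget + 1e-12:
        voxel = _voxel_of(pos, field)
        if voxel is None or fa[tuple(voxel)] < params.fa_threshold:
            break
        v_new = _propagate(field, voxel, v, params.mode)
        if np.dot(v_new, v) < cos_limit:
            break
        nxt = pos + params.step * v_new
        if _voxel_of(nxt, field) is None:
            break
        pts.append(nxt)
        pos, v = nxt, v_new
        length += params.step
    return np.array(pts).reshape(-1, 3)


def track(
    field: TensorField,
    seeds: Iterable[Sequence[int]],
    params: TrackParams | None = None,
    scalar_maps: dict[str, np.ndarray] | None = None,
) -> list[Trajectory]:
    """Bidirectional deterministic tracking from seed voxels.

    Parameters
    ----------
    field
        The diffusion tensor field.
    seeds
        Voxel indices (iterable of int triples); one bidirectional streamline
        is launched from each seed voxel center. Seeds outside the volume are
        rejected with an error.
    params
        Integration and stopping parameters (defaults: 25 µm step, 200 mm
        maximum length, ±80° curvature, FA threshold 0.12, FACT).
    scalar_maps
        Optional named voxel maps (e.g. ``{"md": md_map}``); each trajectory
        records one sample per point from the voxel containing it.

    Returns
    -------
    list of Trajectory
        Termination: sub-threshold FA, per-step turn above ``max_angle``,
        leaving the volume, or reaching ``max_length``.
    """
    params = params or TrackParams()
    scalar_maps = scalar_maps or {}
    shape = np.asarray(field.shape)
    for name, vol in scalar_maps.items():
        if vol.shape != field.shape:
            raise ValueError(f"scalar map {name!r} shape {vol.shape} != field {field.shape}")
    e1_map = field.principal_axis_map()
    out: list[Trajectory] = []
    half_budget = params.max_length / 2.0
    for seed in seeds:
        seed = np.asarray(seed, dtype=int)
        if np.any(seed < 0) or np.any(seed >= shape):
            raise ValueError(f"seed voxel {tuple(seed)} lies outside the volume")
        center = (seed + 0.5) * field.voxel_size
        v0 = e1_map[tuple(seed)]
        fwd = _half_track(field, center, v0, params, half_budget)
        bwd = _half_track(field, center, -v0, params, half_budget)
        pts = np.vstack([bwd[::-1], center[None, :], fwd])
        samples = {}
        for name, vol in scalar_maps.items():
            idx = np.floor(pts / field.voxel_size).astype(int)
            idx = np.clip(idx, 0, shape - 1)
            samples[name] = vol[idx[:, 0], idx[:, 1], idx[:, 2]]
        out.append(Trajectory(points=pts, samples=samples))
    return out
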