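"""Synthetic two-group connectome cohorts and diffusion-tensor phantoms.

The cohort generator emulates the statistical design of a control vs.
dysmyelinated (shiverer-like) mouse study: two groups of ``n_per_group``
subjects, each subject described by three correlated connectivity networks
(standing in for the FACT / TL / TEND tractography variants) on a common
modular small-world base graph. The case group receives

* a uniform multiplicative weight attenuation (1 - attenuation), emulating
  reduced fiber integrity (raises path length, lowers efficiency), and
* degree-preserving rewiring of a fraction of edges, emulating network
  randomization (lowers clustering, modularity and small-worldness).

All randomness flows from a single integer seed through a documented
``numpy.random.SeedSequence`` spawning scheme, so cohorts are bit-for-bit
reproducible.

The phantom generator builds small tensor volumes containing anisotropic
fiber bundles in an isotropic background, with the two end-caps of each
bundle labeled as distinct parcellation regions — a complete fixture for the
tracking → network stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from tractnet.metrics import _double_edge_swaps, _edge_list, _matrix_from_edges
from tractnet.network import ConnectivityNetwork, Parcellation
from tractnet.tractography import TensorField

__all__ = [
    "ALGORITHM_NAMES",
    "BundleSpec",
    "GroupDesign",
    "SubjectSample",
    "emulate_algorithm_variants",
    "generate_group_connectomes",
    "generate_tensor_phantom",
]

ALGORITHM_NAMES = ("FACT", "TL", "TEND")


@dataclass(frozen=True)
class GroupDesign:
    """Design of a synthetic two-group connectome cohort.

    Defaults follow the study design this generator emulates: 6 subjects per
    group, 150 network nodes in 6 modules, a 30% case-group weight
    attenuation, 10% of edges rewired in cases, 5% per-subject and
    per-algorithm multiplicative log-normal jitter.
    """

    n_per_group: int = 6
    n_nodes: int = 150
    n_modules: int = 6
    base_weight: float = 1.0
    attenuation: float = 0.3
    rewire_frac: float = 0.1
    subject_noise: float = 0.05
    algo_jitter: float = 0.05
    p_within: float = 0.3
    p_between: float = 0.02
    weight_sigma: float = 0.25
    within_weight_boost: float = 2.0
    projection_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be at least 4")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        if not (1 <= self.n_modules <= self.n_nodes):
            raise ValueError("n_modules must lie in [1, n_nodes]")
        if not (0 <= self.attenuation < 1):
            raise ValueError("attenuation must lie in [0, 1)")
        if not (0 <= self.rewire_frac < 1):
            raise ValueError("rewire_frac must lie in [0, 1)")
        if self.subject_noise < 0 or self.algo_jitter < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.base_weight <= 0:
            raise ValueError("base_weight must be positive")
        if not (0 < self.p_within <= 1 and 0 <= self.p_between <= 1):
            raise ValueError("edge probabilities must lie in (0, 1] / [0, 1]")


@dataclass
class SubjectSample:
    """One synthetic subject: id, group, and three algorithm-variant networks."""

    subject_id: str
    group: str  # "control" or "case"
    networks: list[ConnectivityNetwork]

    def __post_init__(self) -> None:
        if self.group not in ("control", "case"):
            raise ValueError("group must be 'control' or 'case'")
        if len(self.networks) != len(ALGORITHM_NAMES):
            raise ValueError(f"expected {len(ALGORITHM_NAMES)} networks per subject")


def _module_labels(n_nodes: int, n_modules: int) -> np.ndarray:
    return np.arange(n_nodes) * n_modules // n_nodes


def _edge_weight(
    design: GroupDesign, within: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal weights around base_weight with realistic topology coupling.

    Within-module edges are boosted (stronger intra-community than
    inter-community connections, as in real structural connectomes), and a
    fraction ``projection_frac`` of between-module edges receives the same
    boost, emulating the strong long-range projection tracts (e.g. callosal
    fibers) that keep healthy brains topologically short-pathed.
    """
    within = np.asarray(within)
    w = design.base_weight * np.exp(
        design.weight_sigma * rng.standard_normal(within.shape)
    )
    strong = within | (rng.random(within.shape) < design.projection_frac)
    return w * np.where(strong, design.within_weight_boost, 1.0)


def _planted_partition_base(design: GroupDesign, rng: np.random.Generator) -> np.ndarray:
    """Weighted planted-partition graph; connected by construction (patched)."""
    n = design.n_nodes
    modules = _module_labels(n, design.n_modules)
    same = modules[:, None] == modules[None, :]
    prob = np.where(same, design.p_within, design.p_between)
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < prob[iu, ju]
    w = _edge_weight(design, same[iu, ju], rng)
    W = np.zeros((n, n))
    W[iu[present], ju[present]] = w[present]
    W += W.T
    # patch rare disconnection by bridging components with base-weight edges
    ncomp, labels = connected_components(csr_array(W), directed=False)
    while ncomp > 1:
        a = rng.choice(np.flatnonzero(labels == 0))
        b = rng.choice(np.flatnonzero(labels != 0))
        W[a, b] = W[b, a] = design.base_weight
        ncomp, labels = connected_components(csr_array(W), directed=False)
    return W


def _rewire(
    W: np.ndarray,
    frac: float,
    rng: np.random.Generator,
    design: GroupDesign | None = None,
    require_connected: bool = True,
) -> np.ndarray:
    """Degree-preserving rewiring of ~frac of the edges.

    When ``design`` is given, edges moved to a new position receive a fresh
    weight drawn for that position (within-module edges boosted, cross-module
    edges not), keeping the weight model consistent with the rewired
    topology; otherwise weights simply travel with their edges.
    """
    if frac == 0:
        return W.copy()
    edges, weights = _edge_list(W)
    original = {(min(a, b), max(a, b)) for a, b in edges}
    n_swaps = int(np.ceil(frac * len(edges) / 2.0))  # each swap rewires 2 edges
    modules = _module_labels(W.shape[0], design.n_modules) if design else None
    for _ in range(50):
        new_edges, new_weights, _, _ = _double_edge_swaps(edges, weights, n_swaps, rng)
        if design is not None:
            new_weights = new_weights.copy()
            for pos, (a, b) in enumerate(new_edges):
                if (min(a, b), max(a, b)) not in original:
                    within = modules[a] == modules[b]
                    new_weights[pos] = _edge_weight(design, within, rng)
        R = _matrix_from_edges(W.shape[0], new_edges, new_weights)
        if not require_connected or connected_components(csr_array(R), directed=False)[0] == 1:
            return R
    raise RuntimeError("could not produce a connected rewired network")


def _jitter(W: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric per-edge multiplicative log-normal jitter (keeps weights > 0)."""
    if sigma == 0:
        return W.copy()
    n = W.shape[0]
    factors = np.exp(sigma * rng.standard_normal((n, n)))
    factors = np.triu(factors, k=1)
    factors += factors.T
    out = W * factors
    return out


def emulate_algorithm_variants(
    base: ConnectivityNetwork | np.ndarray,
    algo_jitter: float,
    seed,
) -> list[ConnectivityNetwork]:
    """Three correlated perturbations of one network, one per tracking variant.

    Each variant multiplies every edge weight by an independent log-normal
    factor exp(algo_jitter * N(0, 1)); the edge support is shared with the
    base and ``algo_jitter = 0`` returns three exact copies.
    """
    if algo_jitter < 0:
        raise ValueError("algo_jitter must be nonnegative")
    if isinstance(base, ConnectivityNetwork):
        net = base
    else:
        W = np.asarray(base, dtype=float)
        net = ConnectivityNetwork(nodes=[f"R{i+1}" for i in range(W.shape[0])], weights=W)
    rng = np.random.default_rng(seed)
    return [
        net.copy(weights=_jitter(net.weights, algo_jitter, rng), algorithm=name)
        for name in ALGORITHM_NAMES
    ]


def generate_group_connectomes(design: GroupDesign) -> list[SubjectSample]:
    """Generate the full two-group cohort (2 * n_per_group subjects).

    Seed scheme: ``SeedSequence(design.seed)`` spawns one child for the
    control base graph, one for the case-group rewiring, and one per subject;
    each subject child spawns streams for subject jitter and
    algorithm-variant jitter, in that order.

    The control group perturbs the base graph directly. The case group
    shares one altered base — ``rewire_frac`` of the edges rewired by
    degree-preserving double-edge swaps and all weights attenuated by
    (1 - attenuation) — emulating a genetically homogeneous mutant line
    whose subjects differ only by individual (jitter) variation.
    """
    root = np.random.SeedSequence(design.seed)
    n_subjects = 2 * design.n_per_group
    base_ss, rewire_ss, *subject_ss = root.spawn(2 + n_subjects)
    base = _planted_partition_base(design, np.random.default_rng(base_ss))
    case_base = _rewire(base, design.rewire_frac, np.random.default_rng(rewire_ss))
    case_base *= 1.0 - design.attenuation
    nodes = [f"R{i+1}" for i in range(design.n_nodes)]
    samples: list[SubjectSample] = []
    for s, ss in enumerate(subject_ss):
        group = "control" if s < design.n_per_group else "case"
        noise_ss, algo_ss = ss.spawn(2)
        if group == "control":
            W = base.copy()
            sid = f"Ctl{s + 1}"
        else:
            W = case_base.copy()
            sid = f"Case{s - design.n_per_group + 1}"
        W = _jitter(W, design.subject_noise, np.random.default_rng(noise_ss))
        net = ConnectivityNetwork(
            nodes=nodes, weights=W, metadata={"subject": sid, "group": group}
        )
        samples.append(
            SubjectSample(
                subject_id=sid,
                group=group,
                networks=emulate_algorithm_variants(net, design.algo_jitter, algo_ss),
            )
        )
    return samples


# --------------------------------------------------------------------------
# tensor phantoms


@dataclass(frozen=True)
class BundleSpec:
    """A fiber bundle defined by a polyline of mm-space waypoints.

    ``points`` is a sequence of >= 2 waypoints; a voxel belongs to the bundle
    if its center lies within ``radius`` mm of the polyline. The bundle's two
    end-caps (the first and last ``cap_length`` mm along the polyline) are
    labeled as distinct parcellation regions.
    """

    points: tuple
    radius: float
    cap_length: float = 0.2

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("points must be a sequence of >= 2 mm-space 3-D points")
        object.__setattr__(self, "points", tuple(map(tuple, pts)))
        if self.radius <= 0 or self.cap_length <= 0:
            raise ValueError("radius and cap_length must be positive")


def _axial_eigvals(fa: float, md: float) -> tuple[float, float]:
    """(axial, radial) eigenvalues of an axially symmetric tensor with given
    FA and MD.

    For lambda = (x, 1, 1) * c the FA reduces to (x - 1) / sqrt(x**2 + 2), so
    x = (1 + fa * sqrt(3 - 2 fa**2)) / (1 - fa**2); the pair is then scaled
    to trace/3 = md.
    """
    if not 0 <= fa < 1:
        raise ValueError("fa must lie in [0, 1)")
    if md <= 0:
        raise ValueError("md must be positive")
    if fa == 0:
        return md, md
    x = (1.0 + fa * np.sqrt(3.0 - 2.0 * fa**2)) / (1.0 - fa**2)
    radial = 3.0 * md / (x + 2.0)
    return x * radial, radial


def _nearest_on_polyline(p: np.ndarray, verts: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(distance, arc position, unit tangent) of the point nearest to p."""
    best = (np.inf, 0.0, np.array([1.0, 0.0, 0.0]))
    arc = 0.0
    for a, b in zip(verts[:-1], verts[1:]):
        seg = b - a
        seg_len = np.linalg.norm(seg)
        if seg_len == 0:
            continue
        t = np.clip(np.dot(p - a, seg) / seg_len**2, 0.0, 1.0)
        proj = a + t * seg
        d = np.linalg.norm(p - proj)
        if d < best[0]:
            best = (d, arc + t * seg_len, seg / seg_len)
        arc += seg_len
    return best


def generate_tensor_phantom(
    shape: Sequence[int],
    bundles: Sequence[BundleSpec],
    fa_inside: float = 0.8,
    voxel_size=0.08,
    md_inside: float = 7e-4,
    md_background: float = 7e-4,
    seed=None,
) -> tuple[TensorField, np.ndarray, Parcellation]:
    """Tensor phantom: anisotropic bundles in an isotropic background.

    Inside each bundle, tensors are axially symmetric with the principal axis
    along the local bundle tangent and FA equal to ``fa_inside``; background
    tensors are isotropic (FA = 0). MD is ``md_inside`` / ``md_background``
    (mm²/s), positive everywhere. The two end-caps of each bundle are labeled
    as distinct regions (bundle k gets region ids 2k+1 and 2k+2); overlapping
    end-cap regions are rejected.

    Returns ``(TensorField, md_map, Parcellation)``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must have 3 dimensions")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    tensors = np.zeros(shape + (3, 3))
    tensors[..., 0, 0] = tensors[..., 1, 1] = tensors[..., 2, 2] = md_background
    labels = np.zeros(shape, dtype=int)
    ax, rad = _axial_eigvals(fa_inside, md_inside)
    centers = (np.indices(shape).reshape(3, -1).T + 0.5) * vs
    extent = np.asarray(shape) * vs
    for b_idx, bundle in enumerate(bundles):
        verts = np.asarray(bundle.points, dtype=float)
        if np.any(verts < 0) or np.any(verts > extent):
            raise ValueError(f"bundle {b_idx} waypoints lie outside the volume")
        total_arc = np.linalg.norm(np.diff(verts, axis=0), axis=1).sum()
        for flat, c in enumerate(centers):
            d, arc, tangent = _nearest_on_polyline(c, verts)
            if d > bundle.radius:
                continue
            ijk = np.unravel_index(flat, shape)
            D = rad * np.eye(3) + (ax - rad) * np.outer(tangent, tangent)
            tensors[ijk] = D
            near_start = arc <= bundle.cap_length
            near_end = arc >= total_arc - bundle.cap_length
            if near_start and near_end:
                raise ValueError(
                    f"end-cap regions of bundle {b_idx} overlap at voxel {ijk}: "
                    f"cap_length exceeds half the bundle length"
                )
            cap = (2 * b_idx + 1) if near_start else (2 * b_idx + 2) if near_end else 0
            if cap:
                if labels[ijk] not in (0, cap):
                    raise ValueError(
                        f"end-cap regions overlap at voxel {ijk} "
                        f"(regions {labels[ijk]} and {cap})"
                    )
                labels[ijk] = cap
    field = TensorField(tensors=tensors, voxel_size=vs)
    md_map = field.md_map()
    parc = Parcellation.from_label_volume(labels, vs)
    return field, md_map, parc
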