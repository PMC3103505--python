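"""Region-to-region connectivity networks and backbone extraction.

An undirected arc between gray-matter regions i and j receives the weight

    w(a_ij) = [1 / (n_i + n_j)] * sum_{f in F_ij} (1/N_f) * sum_steps g(step)

where F_ij is the set of fiber trajectories whose two endpoints lie in
regions i and j, N_f the number of steps of fiber f, n_i and n_j the number
of superficial (surface) voxels of the regions, and g(step) depends on the
weighting mode:

* ``inv_md``  — 1 / MD(step), the inverse local mean diffusivity (default;
  weights each fiber by an indirect measure of its integrity);
* ``mean_fa`` — FA(step), mean fractional anisotropy along the fiber;
* ``count``   — 1 per fiber, i.e. w = |F_ij| / (n_i + n_j).

The connectivity backbone keeps the maximum spanning tree and then adds the
remaining edges in decreasing weight order until the average node degree
reaches a target (default 4, i.e. 2n edges on n nodes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from tractnet.tractography import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityNetwork",
    "Parcellation",
    "build_network",
    "extract_backbone",
    "modified_whs_node_count",
]

WEIGHT_MODES = ("inv_md", "mean_fa", "count")


def modified_whs_node_count(
    n_gray_structures: int = 26,
    cortical_subregions: int = 50,
    hemispheres: int = 2,
) -> int:
    """Node count of the modified Waxholm-Space mouse parcellation.

    Of the selected gray-matter structures, the cerebral cortex (one
    structure) is re-parcellated into ``cortical_subregions`` subregions of
    approximately equal volume per hemisphere; hemispheres are kept separate.
    With the defaults (26 structures, 50 cortical subregions, 2 hemispheres)
    this yields (26 - 1 + 50) * 2 = 150 network nodes, 75 per hemisphere.
    """
    if n_gray_structures < 1:
        raise ValueError("need at least one gray-matter structure (the cortex)")
    return (n_gray_structures - 1 + cortical_subregions) * hemispheres


@dataclass
class ConnectivityNetwork:
    """Node labels plus a symmetric nonnegative weight matrix (zero diagonal)."""

    nodes: list[str]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = [str(x) for x in self.nodes]
        W = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if W.shape != (n, n):
            raise ValueError(f"weight matrix shape {W.shape} != ({n}, {n})")
        if not np.allclose(W, W.T, atol=1e-9):
            raise ValueError("weight matrix must be symmetric")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    @property
    def average_degree(self) -> float:
        """2 |E| / n: each undirected edge contributes 2 to the degree sum."""
        return 2.0 * self.n_edges / self.n_nodes

    def to_graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        iu, ju = np.nonzero(np.triu(self.weights, k=1))
        G.add_weighted_edges_from(
            (int(i), int(j), float(self.weights[i, j])) for i, j in zip(iu, ju)
        )
        return G

    def copy(self, weights: np.ndarray | None = None, **meta) -> "ConnectivityNetwork":
        return ConnectivityNetwork(
            nodes=list(self.nodes),
            weights=self.weights.copy() if weights is None else weights,
            metadata={**self.metadata, **meta},
        )


@dataclass
class Parcellation:
    """Gray-matter region definition used to map fiber endpoints to nodes.

    Either a voxel label volume (integer region id per voxel, 0 = background,
    ids contiguous from 1) with a physical voxel size, or — for matrix-only
    pipelines — a plain node-label list. ``surface_counts[i]`` is n_{i+1},
    the number of superficial voxels of region i+1 (6-connected boundary
    voxels when computed from a label volume; defaults to 1 per region for
    matrix-only parcellations).
    """

    labels: list[str]
    surface_counts: np.ndarray
    volume: np.ndarray | None = None
    voxel_size: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.surface_counts = np.asarray(self.surface_counts, dtype=int)
        if len(self.surface_counts) != len(self.labels):
            raise ValueError("one surface count per region required")

    @classmethod
    def from_nodes(cls, labels, surface_counts=None) -> "Parcellation":
        labels = [str(x) for x in labels]
        if surface_counts is None:
            surface_counts = np.ones(len(labels), dtype=int)
        return cls(labels=labels, surface_counts=surface_counts)

    @classmethod
    def from_label_volume(cls, volume: np.ndarray, voxel_size) -> "Parcellation":
        volume = np.asarray(volume)
        if not np.issubdtype(volume.dtype, np.integer):
            raise ValueError("label volume must be integer-valued")
        n_regions = int(volume.max())
        present = np.unique(volume)
        if np.any(present < 0):
            raise ValueError("negative region ids are not allowed")
        return cls(
            labels=[f"R{i}" for i in range(1, n_regions + 1)],
            surface_counts=_surface_voxel_counts(volume, n_regions),
            volume=volume,
            voxel_size=np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy(),
        )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def region_of_point(self, point: np.ndarray) -> int:
        """Region id (1-based) of an mm-space point; 0 if background/outside."""
        if self.volume is None:
            raise ValueError("this parcellation has no label volume")
        idx = np.floor(np.asarray(point) / self.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.volume.shape)):
            return 0
        return int(self.volume[tuple(idx)])


def _surface_voxel_counts(volume: np.ndarray, n_regions: int) -> np.ndarray:
    """n_i = number of 6-connected boundary voxels of each region."""
    counts = np.zeros(n_regions, dtype=int)
    padded = np.pad(volume, 1, constant_values=0)
    core = padded[1:-1, 1:-1, 1:-1]
    boundary = np.zeros(volume.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            nbr = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
            boundary |= nbr != core
    for r in range(1, n_regions + 1):
        counts[r - 1] = int(np.count_nonzero(boundary & (core == r)))
    return counts


def build_network(
    trajectories: list[Trajectory],
    parcellation: Parcellation,
    weight_mode: str = "inv_md",
) -> ConnectivityNetwork:
    """Build the weighted connectome from fiber trajectories.

    A trajectory connects the two regions containing its endpoints; fibers
    with an endpoint in background (region 0) or with both endpoints in the
    same region are skipped (logged). In ``inv_md`` mode each fiber
    contributes the arithmetic mean of 1/MD over its steps, in ``mean_fa``
    mode the mean FA, in ``count`` mode 1; sums over F_ij are divided by
    n_i + n_j.
    """
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
    n = parcellation.n_regions
    W = np.zeros((n, n))
    skipped = 0
    for t_idx, traj in enumerate(trajectories):
        ri = parcellation.region_of_point(traj.points[0])
        rj = parcellation.region_of_point(traj.points[-1])
        if ri == 0 or rj == 0 or ri == rj:
            skipped += 1
            continue
        if weight_mode == "count":
            contrib = 1.0
        elif weight_mode == "inv_md":
            md = traj.samples.get("md")
            if md is None:
                raise ValueError("inv_md mode requires per-step 'md' samples")
            if np.any(md <= 0):
                raise ValueError(
                    f"trajectory {t_idx} has non-positive MD at a used step"
                )
            contrib = float(np.mean(1.0 / md))
        else:  # mean_fa
            fa = traj.samples.get("fa")
            if fa is None:
                raise ValueError("mean_fa mode requires per-step 'fa' samples")
            contrib = float(np.mean(fa))
        W[ri - 1, rj - 1] += contrib
        W[rj - 1, ri - 1] += contrib
    if skipped:
        logger.info("build_network: skipped %d trajectories without two distinct "
                    "labeled endpoint regions", skipped)
    ns = parcellation.surface_counts.astype(float)
    norm = ns[:, None] + ns[None, :]
    W = W / norm
    np.fill_diagonal(W, 0.0)
    return ConnectivityNetwork(
        nodes=list(parcellation.labels),
        weights=W,
        metadata={"weight_mode": weight_mode, "skipped_trajectories": skipped},
    )


def extract_backbone(
    network: ConnectivityNetwork, target_avg_degree: float = 4.0
) -> ConnectivityNetwork:
    """Connectivity backbone: maximum spanning tree plus strongest edges.

    The maximum spanning tree (maximal total weight) is extracted first; the
    remaining edges are then added in strictly decreasing weight order (ties
    broken by ascending (i, j) node-index order) until the average node
    degree 2|E|/n first reaches ``target_avg_degree``. Edge weights are
    preserved and the result is connected whenever the input is.

    A disconnected input is reduced to its largest connected component with a
    warning; if the input runs out of edges before the target degree is
    reached, all edges are returned with a warning.
    """
    if target_avg_degree <= 0:
        raise ValueError("target_avg_degree must be positive")
    full = network.weights
    ncomp, comp = connected_components(csr_array(full), directed=False)
    nodes = np.arange(network.n_nodes)
    if ncomp > 1:
        sizes = np.bincount(comp)
        keep = int(np.argmax(sizes))
        warnings.warn(
            f"input network is disconnected; extracting the backbone of the "
            f"largest component ({sizes[keep]} of {network.n_nodes} nodes)"
        )
        nodes = np.flatnonzero(comp == keep)
    Wfull = full[np.ix_(nodes, nodes)]
    n = len(nodes)
    # maximum spanning tree = minimum spanning tree of the negated weights
    mst = minimum_spanning_tree(csr_array(-Wfull)).tocoo()
    in_tree = np.zeros((n, n), dtype=bool)
    in_tree[mst.row, mst.col] = in_tree[mst.col, mst.row] = True
    W = np.where(in_tree, Wfull, 0.0)
    n_kept = len(mst.row)
    needed = int(np.ceil(target_avg_degree * n / 2.0))
    iu, ju = np.triu_indices(n, k=1)
    rest = (Wfull[iu, ju] > 0) & ~in_tree[iu, ju]
    ri, rj, rw = iu[rest], ju[rest], Wfull[iu[rest], ju[rest]]
    # strictly decreasing weight; ties broken by ascending (i, j) order
    order = np.lexsort((rj, ri, -rw))
    for k in order[: max(0, needed - n_kept)]:
        W[ri[k], rj[k]] = W[rj[k], ri[k]] = rw[k]
        n_kept += 1
    if n_kept < needed:
        warnings.warn(
            f"only {n_kept} edges available; target average degree "
            f"{target_avg_degree} not reachable"
        )
    return ConnectivityNetwork(
        nodes=[network.nodes[i] for i in nodes],
        weights=W,
        metadata={**network.metadata, "backbone_target_avg_degree": target_avg_degree},
    )
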