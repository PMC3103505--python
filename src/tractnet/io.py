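"""File formats: connectivity matrices, cohort manifests, trajectories, NIfTI.

Connectivity matrices are CSV/TSV with a header row of node labels and a
square numeric body; symmetry is validated on read (tolerance 1e-9).
Cohorts are written as one matrix file per subject-variant plus a JSON
manifest recording subject ids, groups, algorithm ordering and design
parameters. Trajectories use a plain-text format: one line per point
(``x y z [sample...]``), a blank line between trajectories. Phantom volumes
can be exported as NIfTI (tensor as a 6-component lower-triangle image)
when nibabel is available.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from tractnet.network import ConnectivityNetwork
from tractnet.synthetic import ALGORITHM_NAMES, GroupDesign, SubjectSample
from tractnet.tractography import TensorField, Trajectory

__all__ = [
    "read_cohort",
    "read_matrix",
    "read_trajectories",
    "write_cohort",
    "write_matrix",
    "write_phantom_nifti",
    "write_trajectories",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def write_matrix(network: ConnectivityNetwork, path) -> None:
    """Write a connectivity matrix as CSV/TSV with a node-label header row."""
    path = Path(path)
    df = pd.DataFrame(network.weights, columns=network.nodes)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_matrix(path) -> ConnectivityNetwork:
    """Read a CSV/TSV connectivity matrix; validates squareness and symmetry."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: file is empty")
    df = pd.read_csv(path, sep=_sep_for(path))
    W = df.to_numpy(dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError(
            f"{path}: matrix body is {W.shape[0]}x{W.shape[1]}, not square"
        )
    asym = np.abs(W - W.T)
    if asym.max() > 1e-9:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path}: matrix is asymmetric at indices ({i}, {j}): "
            f"{W[i, j]!r} vs {W[j, i]!r}"
        )
    return ConnectivityNetwork(nodes=[str(c) for c in df.columns], weights=W)


def write_cohort(samples: list[SubjectSample], outdir, design: GroupDesign | None = None) -> Path:
    """Write a cohort as per-subject-variant CSV matrices plus manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sample in samples:
        for net in sample.networks:
            algo = net.metadata.get("algorithm", "NA")
            fname = f"{sample.subject_id}_{algo}.csv"
            write_matrix(net, outdir / fname)
            entries.append(
                {
                    "subject": sample.subject_id,
                    "group": sample.group,
                    "algorithm": algo,
                    "file": fname,
                }
            )
    manifest = {
        "algorithms": list(ALGORITHM_NAMES),
        "networks": entries,
        "design": dataclasses.asdict(design) if design is not None else None,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(manifest_path) -> list[SubjectSample]:
    """Read a cohort written by :func:`write_cohort`.

    Subject and algorithm ordering follows the manifest, never the
    filesystem.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    outdir = manifest_path.parent
    by_subject: dict[str, dict] = {}
    for entry in manifest["networks"]:
        rec = by_subject.setdefault(
            entry["subject"], {"group": entry["group"], "networks": {}}
        )
        net = read_matrix(outdir / entry["file"])
        net.metadata.update(
            {"algorithm": entry["algorithm"], "subject": entry["subject"],
             "group": entry["group"]}
        )
        rec["networks"][entry["algorithm"]] = net
    samples = []
    for sid, rec in by_subject.items():
        nets = [rec["networks"][a] for a in manifest["algorithms"]]
        samples.append(SubjectSample(subject_id=sid, group=rec["group"], networks=nets))
    return samples


def write_trajectories(trajectories: list[Trajectory], path, sample_names=None) -> None:
    """Plain-text trajectories: one ``x y z [samples...]`` line per point,
    blank line between trajectories; sample column names in a ``#`` header."""
    path = Path(path)
    if trajectories and sample_names is None:
        sample_names = sorted(trajectories[0].samples)
    sample_names = list(sample_names or [])
    lines = ["# columns: x y z " + " ".join(sample_names)]
    for traj in trajectories:
        for p_idx, pt in enumerate(traj.points):
            vals = [f"{v:.9g}" for v in pt]
            vals += [f"{traj.samples[s][p_idx]:.9g}" for s in sample_names]
            lines.append(" ".join(vals))
        lines.append("")
    path.write_text("\n".join(lines))


def read_trajectories(path) -> list[Trajectory]:
    """Read trajectories written by :func:`write_trajectories`."""
    path = Path(path)
    sample_names: list[str] = []
    out: list[Trajectory] = []
    block: list[list[float]] = []

    def _flush():
        if block:
            arr = np.array(block)
            samples = {
                name: arr[:, 3 + k] for k, name in enumerate(sample_names)
            }
            out.append(Trajectory(points=arr[:, :3], samples=samples))
            block.clear()

    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("#"):
            parts = line.split()
            sample_names = parts[parts.index("z") + 1:] if "z" in parts else []
            continue
        if not line:
            _flush()
            continue
        block.append([float(v) for v in line.split()])
    _flush()
    return out


def write_phantom_nifti(field: TensorField, md_map, labels, outdir) -> dict[str, Path]:
    """Export a phantom as NIfTI volumes (requires nibabel).

    The tensor field is stored as a 6-component lower-triangle image
    (Dxx, Dyx, Dyy, Dzx, Dzy, Dzz); MD and region labels as scalar images.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(np.append(field.voxel_size, 1.0))
    t = field.tensors
    lower = np.stack(
        [t[..., 0, 0], t[..., 1, 0], t[..., 1, 1],
         t[..., 2, 0], t[..., 2, 1], t[..., 2, 2]],
        axis=-1,
    )
    paths = {
        "tensor": outdir / "tensor.nii.gz",
        "md": outdir / "md.nii.gz",
        "labels": outdir / "labels.nii.gz",
    }
    nib.save(nib.Nifti1Image(lower.astype(np.float64), affine), paths["tensor"])
    nib.save(nib.Nifti1Image(np.asarray(md_map, dtype=np.float64), affine), paths["md"])
    nib.save(
        nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), paths["labels"]
    )
    return paths
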