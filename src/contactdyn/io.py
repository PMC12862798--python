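"""Readers and writers.

Coordinate input goes through MDAnalysis (topology: PDB/GRO; trajectories:
XTC/TRR/DCD or multi-model PDB) and is converted to the package's
nm/ns-based containers.  Tabular formats are plain text (TSV/CSV/JSON) or
HDF5 so synthetic data and real data are interchangeable downstream.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .contacts import (
    ContactCriteria,
    ContactSet,
    DistanceSeries,
    ResidueLabel,
    Topology,
    Trajectory,
)
from .mosaic import ClusterPartition, CorrelationModel
from .timescales import DynamicalContentProfile, RelaxationSpectrum, ResponseEnsemble, TimescaleGrid

__all__ = [
    "load_trajectories",
    "write_structure_pdb",
    "write_distance_csv",
    "read_distance_csv",
    "write_distance_h5",
    "read_distance_h5",
    "write_contact_set_tsv",
    "write_contact_set_json",
    "read_contact_set_json",
    "write_partition_json",
    "write_partition_tsv",
    "read_partition_json",
    "write_matrix_csv",
    "plot_matrix_heatmap",
    "write_response_csv",
    "read_response_csv",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_content_csv",
    "plot_content_profile",
]

_NM_PER_ANGSTROM = 0.1


def _label_from_resid(resid: int) -> ResidueLabel:
    return ResidueLabel(resid, "protein" if resid >= 1 else "ligand")


def load_trajectories(
    topology_path: str | Path,
    trajectory_paths: Sequence[str | Path] | None = None,
    frame_interval_ns: float | None = None,
) -> list[Trajectory]:
    """Read coordinate trajectories via MDAnalysis into nm/ns containers.

    Residues with resid >= 1 are treated as protein, resid <= 0 as ligand
    (the numbering convention of the photoswitchable PDZ systems).  If
    ``frame_interval_ns`` is not given it is taken from the trajectory
    metadata (MDAnalysis dt, ps).
    """
    import MDAnalysis as mda

    trajectory_paths = [str(p) for p in (trajectory_paths or [])]
    out: list[Trajectory] = []
    for i, traj_path in enumerate(trajectory_paths or [None]):
        if traj_path is None:
            u = mda.Universe(str(topology_path))
        else:
            u = mda.Universe(str(topology_path), traj_path)
        labels = [_label_from_resid(int(r.resid)) for r in u.residues]
        top = Topology(
            labels=labels,
            atom_names=[a.name for a in u.atoms],
            atom_resindex=np.asarray(u.atoms.resindices, dtype=int),
        )
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        dt_ns = frame_interval_ns
        if dt_ns is None:
            dt_ns = float(u.trajectory.dt) / 1000.0  # MDAnalysis dt is ps
        out.append(
            Trajectory(
                topology=top,
                coordinates=coords * _NM_PER_ANGSTROM,
                frame_interval_ns=dt_ns,
                trajectory_id=Path(traj_path or topology_path).stem,
            )
        )
    return out


def write_structure_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB via MDAnalysis."""
    import warnings

    import MDAnalysis as mda

    top = traj.topology
    n_res = top.n_residues
    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=n_res,
        atom_resindex=top.atom_resindex,
        residue_segindex=[0 if l.chain_role == "protein" else 1 for l in top.labels],
        n_segments=2,
        trajectory=True,
    )
    u.add_TopologyAttr("names", top.atom_names)
    u.add_TopologyAttr("resids", [l.index for l in top.labels])
    u.add_TopologyAttr("resnames", ["GLY"] * n_res)
    u.add_TopologyAttr("segids", ["A", "B"])
    u.load_new(traj.coordinates / _NM_PER_ANGSTROM, format="memory", order="fac")
    with warnings.catch_warnings():
        # toy structures have no unit cell or occupancy metadata; the PDB
        # writer's defaults are exactly what we want
        warnings.simplefilter("ignore", UserWarning)
        with mda.Writer(str(path), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# distance tables


def _group_by_trajectory(series: Sequence[DistanceSeries]) -> dict[str, list[DistanceSeries]]:
    groups: dict[str, list[DistanceSeries]] = {}
    for s in series:
        groups.setdefault(s.trajectory_id, []).append(s)
    return groups


def write_distance_csv(series: Sequence[DistanceSeries], path: str | Path) -> None:
    """One trajectory's series as CSV: time_ns plus one column per contact."""
    groups = _group_by_trajectory(series)
    if len(groups) != 1:
        raise ValueError("CSV holds one trajectory; use write_distance_h5 for ensembles")
    (tid, group), = groups.items()
    df = pd.DataFrame({"time_ns": group[0].times})
    for s in sorted(group, key=lambda s: s.name):
        df[s.name] = s.values
    df.to_csv(path, index=False, float_format="%.10g")


def read_distance_csv(
    path: str | Path, trajectory_id: str | None = None, transform: str = "distance"
) -> list[DistanceSeries]:
    df = pd.read_csv(path)
    if "time_ns" not in df.columns:
        raise ValueError(f"{path}: expected a time_ns column")
    tid = trajectory_id or Path(path).stem
    times = df["time_ns"].to_numpy()
    out = []
    for col in df.columns:
        if col == "time_ns":
            continue
        out.append(
            DistanceSeries(
                contact=_contact_from_column(col),
                trajectory_id=tid,
                times=times,
                values=df[col].to_numpy(),
                transform=transform,
            )
        )
    return out


def _contact_from_column(col: str) -> tuple[ResidueLabel, ResidueLabel]:
    try:
        a, b = (int(x) for x in col.split("_"))
    except ValueError as e:
        raise ValueError(f"contact column {col!r} is not of the form 'a_b'") from e
    return (_label_from_resid(a), _label_from_resid(b))


def write_distance_h5(series: Sequence[DistanceSeries], path: str | Path) -> None:
    """Ensemble distance tables: one HDF5 group per trajectory.

    Each group holds ``times`` (ns) and ``values`` (frames x contacts) with
    the contact names stored as a ``contacts`` attribute.
    """
    groups = _group_by_trajectory(series)
    with h5py.File(path, "w") as f:
        for tid in sorted(groups):
            group = sorted(groups[tid], key=lambda s: s.name)
            g = f.create_group(tid)
            g.create_dataset("times", data=group[0].times)
            g.create_dataset("values", data=np.column_stack([s.values for s in group]))
            g.attrs["contacts"] = [s.name for s in group]
            g.attrs["transform"] = group[0].transform


def read_distance_h5(path: str | Path) -> list[DistanceSeries]:
    out = []
    with h5py.File(path, "r") as f:
        for tid in sorted(f):
            g = f[tid]
            times = g["times"][()]
            values = g["values"][()]
            names = [c if isinstance(c, str) else c.decode() for c in g.attrs["contacts"]]
            transform = str(g.attrs.get("transform", "distance"))
            for j, name in enumerate(names):
                out.append(
                    DistanceSeries(
                        contact=_contact_from_column(name),
                        trajectory_id=tid,
                        times=times,
                        values=values[:, j],
                        transform=transform,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# contact sets


def write_contact_set_tsv(cs: ContactSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "res_a": [a.index for a, _ in cs.pairs],
            "res_b": [b.index for _, b in cs.pairs],
            "population": cs.population,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_contact_set_json(cs: ContactSet, path: str | Path) -> None:
    doc = {
        "criteria": {
            "heavy_atom_cutoff": cs.criteria.heavy_atom_cutoff,
            "population_threshold": cs.criteria.population_threshold,
            "neighbor_exclusion": cs.criteria.neighbor_exclusion,
            "mode": cs.criteria.mode,
            "c_alpha_cutoff": cs.criteria.c_alpha_cutoff,
            "feature_transform": cs.criteria.feature_transform,
        },
        "contacts": [
            {"res_a": a.index, "res_b": b.index, "population": float(p)}
            for (a, b), p in zip(cs.pairs, cs.population)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_contact_set_json(path: str | Path) -> ContactSet:
    doc = json.loads(Path(path).read_text())
    criteria = ContactCriteria(**doc["criteria"])
    pairs = [
        (_label_from_resid(c["res_a"]), _label_from_resid(c["res_b"]))
        for c in doc["contacts"]
    ]
    population = np.array([c["population"] for c in doc["contacts"]])
    return ContactSet(pairs=pairs, criteria=criteria, population=population)


# ---------------------------------------------------------------------------
# partitions and matrices


def write_partition_json(part: ClusterPartition, path: str | Path) -> None:
    names = part.features or [str(j) for j in range(len(part.labels))]
    doc = {
        "gamma": part.gamma,
        "objective": part.objective,
        "clusters": {
            str(cid): [names[j] for j in members]
            for cid, members in enumerate(part.clusters)
        },
        "noise": [names[j] for j in part.noise],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def write_partition_tsv(part: ClusterPartition, path: str | Path) -> None:
    names = part.features or [str(j) for j in range(len(part.labels))]
    rows = [(names[j], cid) for cid, members in enumerate(part.clusters) for j in members]
    rows += [(names[j], -1) for j in part.noise]
    pd.DataFrame(rows, columns=["contact", "cluster"]).to_csv(path, sep="\t", index=False)


def read_partition_json(path: str | Path) -> dict[str, object]:
    """Partition as feature name -> cluster id ('noise' for noise)."""
    doc = json.loads(Path(path).read_text())
    out: dict[str, object] = {}
    for cid, members in doc["clusters"].items():
        for name in members:
            out[name] = int(cid)
    for name in doc.get("noise", []):
        out[name] = "noise"
    return out


def write_matrix_csv(model: CorrelationModel, path: str | Path) -> None:
    pd.DataFrame(model.matrix, index=model.features, columns=model.features).to_csv(
        path, float_format="%.8g"
    )


def plot_matrix_heatmap(model: CorrelationModel, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(model.matrix, vmin=0, vmax=1, cmap="viridis", interpolation="nearest")
    ax.set_title(f"contact-distance similarity ({model.method})")
    fig.colorbar(im, ax=ax, label="similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# responses, spectra, dynamical content


def write_response_csv(resp: ResponseEnsemble, path: str | Path) -> None:
    pd.DataFrame(
        {"time_ns": resp.times, "mean": resp.mean, "sem": resp.sem, "n_traj": resp.n_traj}
    ).to_csv(path, index=False, float_format="%.10g")


def read_response_csv(path: str | Path, feature: str | None = None) -> ResponseEnsemble:
    df = pd.read_csv(path)
    for col in ("time_ns", "mean"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected a {col} column")
    n = len(df)
    return ResponseEnsemble(
        feature=feature or Path(path).stem,
        times=df["time_ns"].to_numpy(),
        mean=df["mean"].to_numpy(),
        sem=df["sem"].to_numpy() if "sem" in df else np.zeros(n),
        n_traj=df["n_traj"].to_numpy() if "n_traj" in df else np.ones(n, dtype=int),
    )


def write_spectra_csv(spectra: Sequence[RelaxationSpectrum], path: str | Path) -> None:
    """Amplitude spectra on a shared tau grid: tau_ns plus one column per feature."""
    spectra = list(spectra)
    df = pd.DataFrame({"tau_ns": spectra[0].grid.taus})
    for s in spectra:
        if not np.allclose(s.grid.taus, spectra[0].grid.taus):
            raise ValueError("spectra must share one tau grid")
        df[s.feature] = s.amplitudes
    df.to_csv(path, index=False, float_format="%.10g")


def read_spectra_csv(path: str | Path) -> list[RelaxationSpectrum]:
    df = pd.read_csv(path)
    taus = df["tau_ns"].to_numpy()
    grid = TimescaleGrid(taus=taus, per_decade=_infer_per_decade(taus))
    out = []
    for col in df.columns:
        if col == "tau_ns":
            continue
        out.append(
            RelaxationSpectrum(
                feature=col,
                grid=grid,
                amplitudes=df[col].to_numpy(),
                offset=0.0,
                chi2=float("nan"),
                entropy=float("nan"),
                lam=float("nan"),
                prior=float("nan"),
            )
        )
    return out


def _infer_per_decade(taus: np.ndarray) -> int:
    if taus.size < 2:
        return 10
    return max(int(round(1.0 / np.log10(taus[1] / taus[0]))), 1)


def write_spectrum_json(spec: RelaxationSpectrum, path: str | Path) -> None:
    doc = {
        "feature": spec.feature,
        "tau_ns": spec.grid.taus.tolist(),
        "amplitudes": spec.amplitudes.tolist(),
        "offset": spec.offset,
        "chi2": spec.chi2,
        "entropy": spec.entropy,
        "lam": spec.lam,
        "prior": spec.prior,
        "converged": spec.converged,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def write_content_csv(profile: DynamicalContentProfile, path: str | Path) -> None:
    """Dynamical content as CSV suited to log-axis plotting."""
    df = pd.DataFrame({"tau_ns": profile.grid.taus, "total": profile.total})
    for cid in sorted(profile.per_cluster):
        df[f"cluster_{cid}"] = profile.per_cluster[cid]
    df.to_csv(path, index=False, float_format="%.10g")


def plot_content_profile(profile: DynamicalContentProfile, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.grid.taus, profile.total, "r-", lw=2.5, label="all clusters")
    for cid, values in sorted(profile.per_cluster.items()):
        if cid == "noise":
            continue
        ax.plot(profile.grid.taus, values, lw=1, label=f"C{cid}")
    for tau, height in profile.peaks:
        ax.axvline(tau, color="gray", ls=":", lw=0.5)
    ax.set_xscale("log")
    ax.set_xlabel(r"$\tau$ (ns)")
    ax.set_ylabel(r"dynamical content $D(\tau)$")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
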