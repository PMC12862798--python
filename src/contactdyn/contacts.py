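"""Inter-residue contact identification and distance monitoring.

Contacts are defined on the shortest heavy-atom distance between two
residues: a residue pair counts as a contact if that distance drops below a
cutoff (default 0.45 nm) in at least a minimum fraction of frames (default
10%), excluding sequence neighbors (|i - j| <= 2 within a chain).  A cheaper
variant monitors the single C-alpha--C-alpha distance against a wider cutoff
(default 0.8 nm).  Distances may be reported directly (nm) or as inverse
distances (1/nm), which emphasize short-range changes.

Residue numbering follows the convention of photoswitchable PDZ-domain
studies: protein residues are numbered from 1 upward, ligand residues from
0 downward (0, -1, -2, ...), so the two chains can never collide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ResidueLabel",
    "ContactCriteria",
    "ContactSet",
    "DistanceSeries",
    "Topology",
    "Trajectory",
    "min_residue_distance",
    "identify_contacts",
    "extract_series",
    "subsample",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class ResidueLabel:
    """A residue identified by number and chain role.

    Protein residues have index >= 1, ligand residues index <= 0; the index
    alone is therefore unique within a system.
    """

    index: int
    chain_role: str = "protein"  # "protein" | "ligand"

    def __post_init__(self) -> None:
        if self.chain_role not in ("protein", "ligand"):
            raise ValueError(f"unknown chain_role {self.chain_role!r}")
        if self.chain_role == "protein" and self.index < 1:
            raise ValueError(f"protein residue index must be >= 1, got {self.index}")
        if self.chain_role == "ligand" and self.index > 0:
            raise ValueError(f"ligand residue index must be <= 0, got {self.index}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return str(self.index)


@dataclass(frozen=True)
class ContactCriteria:
    """Parameters of the contact definition.

    heavy_atom_cutoff : nm, threshold on the shortest heavy-atom distance.
    population_threshold : minimum fraction of (pooled) frames below cutoff.
    neighbor_exclusion : require |i - j| > this within a chain (default 2).
    mode : "heavy_atom" or "c_alpha"; the latter uses c_alpha_cutoff (nm).
    feature_transform : "distance" or "inverse_distance" for reported series.
    minimum_image : apply an orthorhombic minimum-image convention when the
        trajectory carries a box; off by default, inputs are expected to be
        whole-molecule / PBC-corrected.
    """

    heavy_atom_cutoff: float = 0.45
    population_threshold: float = 0.10
    neighbor_exclusion: int = 2
    mode: str = "heavy_atom"
    c_alpha_cutoff: float = 0.8
    feature_transform: str = "distance"
    minimum_image: bool = False

    def __post_init__(self) -> None:
        if self.heavy_atom_cutoff <= 0 or self.c_alpha_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.population_threshold <= 1:
            raise ValueError("population_threshold must be in (0, 1]")
        if self.neighbor_exclusion < 0:
            raise ValueError("neighbor_exclusion must be >= 0")
        if self.mode not in ("heavy_atom", "c_alpha"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.feature_transform not in ("distance", "inverse_distance"):
            raise ValueError(f"unknown feature_transform {self.feature_transform!r}")

    @property
    def cutoff(self) -> float:
        return self.heavy_atom_cutoff if self.mode == "heavy_atom" else self.c_alpha_cutoff


@dataclass
class ContactSet:
    """Identified contact pairs with their observed populations."""

    pairs: list[tuple[ResidueLabel, ResidueLabel]]
    criteria: ContactCriteria
    population: np.ndarray  # fraction of pooled frames below cutoff, per pair

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=float)
        if len(self.pairs) != self.population.size:
            raise ValueError("pairs and population length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)

    def names(self) -> list[str]:
        """Feature names in the ``a_b`` dialect used by the table writers."""
        return [f"{a.index}_{b.index}" for a, b in self.pairs]


@dataclass
class DistanceSeries:
    """One contact's distance time series in one trajectory.

    ``values`` are distances (nm) or inverse distances (1/nm) depending on
    the transform recorded with the series; ``times`` is a uniform grid in ns
    starting at the trajectory origin (t = 0 at the perturbation).
    """

    contact: tuple[ResidueLabel, ResidueLabel]
    trajectory_id: str
    times: np.ndarray
    values: np.ndarray
    transform: str = "distance"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal shape")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def name(self) -> str:
        a, b = self.contact
        return f"{a.index}_{b.index}"


# ---------------------------------------------------------------------------
# topology / trajectory containers


def _is_hydrogen(name: str) -> bool:
    """Classify an atom as hydrogen from its PDB-style name.

    Hydrogen names start with 'H' or with a digit followed by 'H'
    (e.g. '1HB2'); everything else counts as heavy.
    """
    s = name.strip()
    if not s:
        return False
    if s[0] in "Hh":
        return True
    return s[0].isdigit() and len(s) > 1 and s[1] in "Hh"


@dataclass
class Topology:
    """Minimal per-atom topology shared by all trajectories of an ensemble."""

    labels: list[ResidueLabel]
    atom_names: list[str]
    atom_resindex: np.ndarray  # index into ``labels`` per atom

    def __post_init__(self) -> None:
        self.atom_resindex = np.asarray(self.atom_resindex, dtype=int)
        if len(self.atom_names) != self.atom_resindex.size:
            raise ValueError("atom_names and atom_resindex length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("residue labels must be unique")

    @property
    def n_residues(self) -> int:
        return len(self.labels)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([not _is_hydrogen(n) for n in self.atom_names])

    def label_index(self, label: ResidueLabel) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"residue {label} not in topology") from None

    def atoms_of(self, res: int, heavy_only: bool = True) -> np.ndarray:
        """Atom indices of residue ``res`` (positional index into labels)."""
        sel = self.atom_resindex == res
        if heavy_only:
            sel &= self.heavy_mask
        return np.flatnonzero(sel)

    def c_alpha_of(self, res: int) -> int:
        sel = np.flatnonzero(
            (self.atom_resindex == res)
            & np.array([n.strip() == "CA" for n in self.atom_names])
        )
        if sel.size == 0:
            raise ValueError(f"residue {self.labels[res]} has no CA atom")
        return int(sel[0])


@dataclass
class Trajectory:
    """Coordinates (nm) of one run: shape (n_frames, n_atoms, 3)."""

    topology: Topology
    coordinates: np.ndarray
    frame_interval_ns: float
    trajectory_id: str = "traj"
    box_nm: np.ndarray | None = None  # orthorhombic box lengths, optional

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate atom count does not match topology")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ns


# ---------------------------------------------------------------------------
# operations


def _pair_key(pair: tuple[ResidueLabel, ResidueLabel]) -> tuple[int, int]:
    a, b = pair
    return (a.index, b.index) if a.index <= b.index else (b.index, a.index)


def _ordered(pair: tuple[ResidueLabel, ResidueLabel]) -> tuple[ResidueLabel, ResidueLabel]:
    a, b = pair
    return (a, b) if a.index <= b.index else (b, a)


def _minimum_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def min_residue_distance(
    frame_coordinates: np.ndarray,
    topology: Topology,
    pair: tuple[ResidueLabel, ResidueLabel],
    mode: str = "heavy_atom",
    box_nm: np.ndarray | None = None,
) -> float:
    """Shortest inter-residue distance (nm) in a single frame.

    In ``heavy_atom`` mode the minimum over all heavy-atom pairs is returned;
    in ``c_alpha`` mode the single CA--CA distance.  Symmetric in pair order.
    """
    coords = np.asarray(frame_coordinates, dtype=float)
    ia = topology.label_index(pair[0])
    ib = topology.label_index(pair[1])
    if mode == "c_alpha":
        pa = coords[topology.c_alpha_of(ia)]
        pb = coords[topology.c_alpha_of(ib)]
        diff = pa - pb
        if box_nm is not None:
            diff = _minimum_image(diff, np.asarray(box_nm))
        return float(np.linalg.norm(diff))
    if mode != "heavy_atom":
        raise ValueError(f"unknown mode {mode!r}")
    aa = topology.atoms_of(ia)
    ab = topology.atoms_of(ib)
    if aa.size == 0:
        raise ValueError(f"residue {pair[0]} has no heavy atoms")
    if ab.size == 0:
        raise ValueError(f"residue {pair[1]} has no heavy atoms")
    if box_nm is not None:
        diff = coords[aa][:, None, :] - coords[ab][None, :, :]
        diff = _minimum_image(diff, np.asarray(box_nm))
        return float(np.sqrt((diff**2).sum(-1)).min())
    return float(cdist(coords[aa], coords[ab]).min())


def candidate_pairs(
    topology: Topology, neighbor_exclusion: int = 2
) -> list[tuple[ResidueLabel, ResidueLabel]]:
    """All residue pairs passing the sequence-neighbor exclusion.

    The |i - j| > n rule applies within a chain only; protein--ligand pairs
    are never sequence-excluded since they live on different chains.
    """
    labels = sorted(topology.labels, key=lambda l: l.index)
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if a.chain_role == b.chain_role and abs(a.index - b.index) <= neighbor_exclusion:
                continue
            out.append((a, b))
    out.sort(key=_pair_key)
    return out


def _pair_min_distances(
    traj: Trajectory, pairs: Sequence[tuple[ResidueLabel, ResidueLabel]], mode: str,
    use_box: bool = False,
) -> np.ndarray:
    """Per-frame minimum distance for each pair: shape (n_frames, n_pairs).

    Vectorized over atoms through a full heavy-atom distance matrix per
    frame, reduced with a residue-pair index map; adequate for the system
    sizes this package targets (up to a few hundred residues).
    """
    top = traj.topology
    n_res = top.n_residues
    pair_pos = np.array(
        [(top.label_index(a), top.label_index(b)) for a, b in pairs], dtype=int
    ).reshape(-1, 2)
    box = traj.box_nm if (use_box and traj.box_nm is not None) else None

    if mode == "c_alpha":
        ca = np.array([top.c_alpha_of(r) for r in range(n_res)])
        xyz = traj.coordinates[:, ca, :]  # (F, R, 3)
        diff = xyz[:, pair_pos[:, 0], :] - xyz[:, pair_pos[:, 1], :]
        if box is not None:
            diff = _minimum_image(diff, np.asarray(box))
        return np.sqrt((diff**2).sum(-1))

    heavy = np.flatnonzero(top.heavy_mask)
    for r in range(n_res):
        if top.atoms_of(r).size == 0:
            raise ValueError(f"residue {top.labels[r]} has no heavy atoms")
    res_of_heavy = top.atom_resindex[heavy]
    out = np.empty((traj.n_frames, len(pairs)))
    # map each heavy-atom pair to a flattened residue-pair slot
    flat_idx = res_of_heavy[:, None] * n_res + res_of_heavy[None, :]
    pair_flat = pair_pos[:, 0] * n_res + pair_pos[:, 1]
    pair_flat_t = pair_pos[:, 1] * n_res + pair_pos[:, 0]
    for f in range(traj.n_frames):
        xyz = traj.coordinates[f, heavy]
        if box is not None:
            diff = xyz[:, None, :] - xyz[None, :, :]
            diff = _minimum_image(diff, np.asarray(box))
            dmat = np.sqrt((diff**2).sum(-1))
        else:
            dmat = cdist(xyz, xyz)
        mins = np.full(n_res * n_res, np.inf)
        np.minimum.at(mins, flat_idx.ravel(), dmat.ravel())
        out[f] = np.minimum(mins[pair_flat], mins[pair_flat_t])
    return out


def identify_contacts(
    ensemble: Sequence[Trajectory], criteria: ContactCriteria | None = None
) -> ContactSet:
    """Identify contact pairs across an ensemble of trajectories.

    The population of a pair is the fraction of frames, pooled over all
    trajectories, in which its minimum distance is below the cutoff; pairs
    at or above ``population_threshold`` are kept.  Pair order is
    deterministic (lexicographic by residue indices).
    """
    criteria = criteria or ContactCriteria()
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    top = ensemble[0].topology
    for t in ensemble[1:]:
        if t.topology.labels != top.labels or t.topology.atom_names != top.atom_names:
            raise ValueError("all trajectories must share one topology")
    total_frames = sum(t.n_frames for t in ensemble)
    if total_frames == 0:
        raise ValueError("ensemble contains zero frames")

    pairs = candidate_pairs(top, criteria.neighbor_exclusion)
    below = np.zeros(len(pairs))
    for traj in ensemble:
        d = _pair_min_distances(traj, pairs, criteria.mode, criteria.minimum_image)
        below += (d < criteria.cutoff).sum(axis=0)
    population = below / total_frames
    keep = population >= criteria.population_threshold
    return ContactSet(
        pairs=[p for p, k in zip(pairs, keep) if k],
        criteria=criteria,
        population=population[keep],
    )


def extract_series(
    ensemble: Sequence[Trajectory], contact_set: ContactSet
) -> list[DistanceSeries]:
    """Monitor each contact's minimum distance in every trajectory.

    Returns one series per (contact, trajectory), with the feature transform
    from the contact criteria applied and times in ns from the trajectory
    frame interval.
    """
    crit = contact_set.criteria
    out: list[DistanceSeries] = []
    for traj in ensemble:
        for p in contact_set.pairs:
            for lab in p:
                traj.topology.label_index(lab)  # raises KeyError if absent
        d = _pair_min_distances(traj, contact_set.pairs, crit.mode, crit.minimum_image)
        for j, pair in enumerate(contact_set.pairs):
            values = d[:, j]
            if crit.feature_transform == "inverse_distance":
                values = 1.0 / values
            out.append(
                DistanceSeries(
                    contact=_ordered(pair),
                    trajectory_id=traj.trajectory_id,
                    times=traj.times_ns,
                    values=values,
                    transform=crit.feature_transform,
                )
            )
    return out


def subsample(series: DistanceSeries, stride: int) -> DistanceSeries:
    """Keep every ``stride``-th frame (0, stride, 2*stride, ...).

    Correlation analysis is robust to sparse data, so a stride of 5 is the
    conventional choice there; time-scale fitting always uses full series.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return replace(series, times=series.times[::stride], values=series.values[::stride])
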