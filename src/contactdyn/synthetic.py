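"""Synthetic ensembles with known ground truth.

Three generators make every pipeline stage testable without MD data:

* ``generate_clustered_series`` -- feature time series with planted
  block-correlation structure (latent-factor construction, analytically
  exact target Pearson correlations in expectation);
* ``generate_response_ensemble`` -- trajectory ensembles whose mean follows
  a known multiexponential relaxation, the forward model of the max-ent
  fit, with Gaussian observation noise and the mixed short/long run-length
  design typical of nonequilibrium MD campaigns (e.g. 90 x 1 us plus
  22 x 10 us);
* ``generate_toy_structure_ensemble`` -- tiny multi-residue structures with
  frames engineered so each designated residue pair is in contact in a
  prescribed fraction of frames, together with the exactly expected
  contact table.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contacts import (
    ContactCriteria,
    ContactSet,
    DistanceSeries,
    ResidueLabel,
    Topology,
    Trajectory,
    candidate_pairs,
)

__all__ = [
    "PlantedClusterSpec",
    "PlantedResponseSpec",
    "ToyStructureSpec",
    "generate_clustered_series",
    "generate_response_ensemble",
    "generate_toy_structure_ensemble",
]


# ---------------------------------------------------------------------------
# planted correlation blocks


@dataclass(frozen=True)
class PlantedClusterSpec:
    """Block-correlation design: sizes per cluster, target intra/inter rho.

    Defaults mimic the block structure of a contact-distance correlation
    matrix with a handful of clusters of a few to a dozen contacts each.
    """

    sizes: tuple[int, ...] = (8, 6, 5)
    rho_in: float = 0.8
    rho_out: float = 0.05
    n_noise_features: int = 0

    def __post_init__(self) -> None:
        if not self.sizes or any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be >= 1")
        if not 0 < self.rho_in <= 1:
            raise ValueError("rho_in must be in (0, 1]")
        if not 0 <= self.rho_out < 1:
            raise ValueError("rho_out must be in [0, 1)")
        if self.rho_in <= self.rho_out:
            raise ValueError("need rho_in > rho_out")


def generate_clustered_series(
    spec: PlantedClusterSpec, n_frames: int = 5000, seed: int = 0
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Standardized series with planted block correlations.

    Construction: x = sqrt(rho_out) g + sqrt(rho_in - rho_out) z_c
    + sqrt(1 - rho_in) eps with iid standard-normal latent components
    (g global, z_c per cluster, eps per feature), giving expected Pearson
    correlation rho_in within and rho_out between clusters.  Returns
    (feature names, features-by-frames matrix, ground-truth labels with -1
    for noise features).
    """
    rng = np.random.default_rng(seed)
    n_feat = sum(spec.sizes) + spec.n_noise_features
    g = rng.standard_normal(n_frames)
    X = np.empty((n_feat, n_frames))
    labels = np.empty(n_feat, dtype=int)
    row = 0
    for c, size in enumerate(spec.sizes):
        z = rng.standard_normal(n_frames)
        for _ in range(size):
            eps = rng.standard_normal(n_frames)
            X[row] = (
                math.sqrt(spec.rho_out) * g
                + math.sqrt(spec.rho_in - spec.rho_out) * z
                + math.sqrt(1.0 - spec.rho_in) * eps
            )
            labels[row] = c
            row += 1
    for _ in range(spec.n_noise_features):
        X[row] = rng.standard_normal(n_frames)
        labels[row] = -1
        row += 1
    names = [f"f{j}" for j in range(n_feat)]
    return names, X, labels


# ---------------------------------------------------------------------------
# planted multiexponential responses


@dataclass(frozen=True)
class PlantedResponseSpec:
    """Forward model of the relaxation fit for one feature.

    components : (tau_ns, amplitude_nm) terms of the multiexponential mean;
        amplitudes are signed (a contact distance may rise or fall).
    offset : long-time plateau (nm).
    noise_sd : per-frame Gaussian observation noise (nm).
    n_traj / long_traj_fraction / t_max / frame_interval : the run design;
        a ``long_traj_fraction`` of trajectories extends to ``t_max``, the
        rest stop at ``t_max/10`` -- the mixed-length pattern of
        nonequilibrium MD campaigns (defaults: 112 runs of which 22 long,
        10 us maximum, 20 ps write-out).
    ar1_phi : optional AR(1) coefficient for temporally correlated noise.
    """

    components: tuple[tuple[float, float], ...] = ((30.0, 0.3), (800.0, -0.2))
    offset: float = 1.0
    noise_sd: float = 0.1
    n_traj: int = 112
    long_traj_fraction: float = 22 / 112
    t_max: float = 10_000.0  # ns
    frame_interval: float = 0.02  # ns
    ar1_phi: float = 0.0

    def __post_init__(self) -> None:
        if any(tau <= 0 for tau, _ in self.components):
            raise ValueError("time constants must be positive")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.frame_interval <= 0 or self.t_max <= 0:
            raise ValueError("t_max and frame_interval must be positive")
        if not 0 <= self.long_traj_fraction <= 1:
            raise ValueError("long_traj_fraction must be in [0, 1]")
        if not -1 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in (-1, 1)")

    def mean_curve(self, times: np.ndarray) -> np.ndarray:
        """Closed-form ensemble mean at ``times`` (ns)."""
        t = np.asarray(times, dtype=float)
        out = np.full(t.shape, self.offset)
        for tau, amp in self.components:
            out = out + amp * np.exp(-t / tau)
        return out


def generate_response_ensemble(
    spec: PlantedResponseSpec, seed: int = 0, feature: str = "1_4"
) -> tuple[list[DistanceSeries], dict]:
    """Trajectories of one feature: planted mean plus Gaussian noise.

    Returns the list of DistanceSeries (long trajectories to t_max, short
    ones to t_max/10) and the ground truth: components, offset, and the
    closed-form mean function.
    """
    rng = np.random.default_rng(seed)
    n_long = int(round(spec.long_traj_fraction * spec.n_traj))
    n_frames_long = int(round(spec.t_max / spec.frame_interval)) + 1
    n_frames_short = int(round(spec.t_max / 10.0 / spec.frame_interval)) + 1
    t_long = np.arange(n_frames_long) * spec.frame_interval
    mean_long = spec.mean_curve(t_long)

    out: list[DistanceSeries] = []
    for i in range(spec.n_traj):
        n = n_frames_long if i < n_long else n_frames_short
        noise = rng.standard_normal(n) * spec.noise_sd
        if spec.ar1_phi != 0.0:
            # AR(1) with stationary marginal variance noise_sd^2
            phi = spec.ar1_phi
            innov = noise * math.sqrt(1 - phi**2)
            noise = np.empty(n)
            noise[0] = innov[0] / math.sqrt(1 - phi**2)
            for k in range(1, n):
                noise[k] = phi * noise[k - 1] + innov[k]
        out.append(
            DistanceSeries(
                contact=_contact_from_name(feature),
                trajectory_id=f"traj{i:03d}",
                times=t_long[:n],
                values=mean_long[:n] + noise,
            )
        )
    truth = {
        "components": list(spec.components),
        "offset": spec.offset,
        "mean_curve": spec.mean_curve,
        "n_long": n_long,
        "n_short": spec.n_traj - n_long,
    }
    return out, truth


def _contact_from_name(name: str) -> tuple[ResidueLabel, ResidueLabel]:
    try:
        a, b = (int(x) for x in name.split("_"))
        return (
            ResidueLabel(a, "protein" if a >= 1 else "ligand"),
            ResidueLabel(b, "protein" if b >= 1 else "ligand"),
        )
    except ValueError:
        return (ResidueLabel(1), ResidueLabel(4))


# ---------------------------------------------------------------------------
# toy structures


@dataclass(frozen=True)
class ToyStructureSpec:
    """Layout of a small synthetic structure with plantable contacts.

    ``n_residues`` protein residues (numbered 1..n) and optionally
    ``n_ligand_residues`` ligand residues (numbered down from 0) sit on a
    coarse 3-D lattice (2 nm spacing), far outside any contact cutoff.
    ``contact_plan`` maps residue-index pairs to the fraction of frames in
    which the pair is placed in contact (0.3 nm apart); each residue may
    appear in at most one planted pair so populations stay independent.
    """

    n_residues: int = 8
    atoms_per_residue: int = 3
    n_ligand_residues: int = 0
    contact_plan: tuple[tuple[tuple[int, int], float], ...] = (((1, 5), 1.0), ((2, 7), 0.5))
    spacing_nm: float = 2.0
    contact_distance_nm: float = 0.3

    def __post_init__(self) -> None:
        if self.n_residues < 2 or self.atoms_per_residue < 1:
            raise ValueError("need >= 2 residues with >= 1 atom")
        if not 0 < self.contact_distance_nm < 0.45 < self.spacing_nm:
            raise ValueError("contact distance must be below the cutoff, spacing above")
        seen: set[int] = set()
        lo = -(self.n_ligand_residues - 1) if self.n_ligand_residues else 1
        for (a, b), frac in self.contact_plan:
            if not 0 <= frac <= 1:
                raise ValueError("contact fractions must be in [0, 1]")
            for r in (a, b):
                if not lo <= r <= self.n_residues or (self.n_ligand_residues == 0 and r < 1):
                    raise ValueError(f"planted residue {r} outside the structure")
                if r in seen:
                    raise ValueError(f"residue {r} appears in more than one planted pair")
                seen.add(r)

    def labels(self) -> list[ResidueLabel]:
        prot = [ResidueLabel(i, "protein") for i in range(1, self.n_residues + 1)]
        lig = [
            ResidueLabel(-i, "ligand") for i in range(self.n_ligand_residues - 1, -1, -1)
        ]
        return lig + prot


_ATOM_NAMES = ["CA", "CB", "CG", "CD", "CE", "CZ", "NZ", "OD"]


def generate_toy_structure_ensemble(
    spec: ToyStructureSpec,
    n_frames: int = 50,
    seed: int = 0,
    criteria: ContactCriteria | None = None,
) -> tuple[Trajectory, ContactSet]:
    """A toy trajectory plus the exactly expected contact table.

    Residues rest on a wide lattice; in a seeded random subset of
    round(fraction * n_frames) frames each planted pair's second residue is
    moved next to the first (closest atoms ``contact_distance_nm`` apart).
    The expected ContactSet contains every planted pair that passes the
    neighbor exclusion and whose realized population meets the threshold.
    """
    criteria = criteria or ContactCriteria()
    rng = np.random.default_rng(seed)
    labels = spec.labels()
    index_of = {l.index: i for i, l in enumerate(labels)}
    n_res = len(labels)
    napr = spec.atoms_per_residue

    atom_names = []
    atom_resindex = []
    for r in range(n_res):
        for a in range(napr):
            atom_names.append(_ATOM_NAMES[a % len(_ATOM_NAMES)])
            atom_resindex.append(r)
    top = Topology(labels=labels, atom_names=atom_names, atom_resindex=np.array(atom_resindex))

    # home positions: coarse 3-D lattice, atoms jittered within 0.08 nm
    side = int(np.ceil(n_res ** (1 / 3)))
    centers = np.array(
        [(r % side, (r // side) % side, r // side**2) for r in range(n_res)],
        dtype=float,
    ) * spec.spacing_nm
    local = rng.uniform(-0.08, 0.08, size=(n_res, napr, 3))
    local[:, 0, :] = 0.0  # CA exactly at the center, so CA-CA >= heavy min

    coords = np.empty((n_frames, n_res * napr, 3))
    base = (centers[:, None, :] + local).reshape(n_res * napr, 3)
    coords[:] = base

    expected_pairs: list[tuple[ResidueLabel, ResidueLabel]] = []
    expected_pop: list[float] = []
    allowed = set()
    for a, b in candidate_pairs(top, criteria.neighbor_exclusion):
        allowed.add((a.index, b.index))

    for (ia, ib), frac in spec.contact_plan:
        ra, rb = index_of[ia], index_of[ib]
        n_contact = int(round(frac * n_frames))
        frames = rng.choice(n_frames, size=n_contact, replace=False)
        # place residue b so its first atom sits contact_distance from a's first atom
        target = centers[ra] + np.array([spec.contact_distance_nm, 0.0, 0.0])
        shift = target - centers[rb]
        sl = slice(rb * napr, (rb + 1) * napr)
        for f in frames:
            coords[f, sl] = base[sl] + shift
        population = n_contact / n_frames
        key = (min(ia, ib), max(ia, ib))
        if key in allowed and population >= criteria.population_threshold:
            la = labels[index_of[key[0]]]
            lb = labels[index_of[key[1]]]
            expected_pairs.append((la, lb))
            expected_pop.append(population)

    order = sorted(range(len(expected_pairs)), key=lambda i: (expected_pairs[i][0].index, expected_pairs[i][1].index))
    expected = ContactSet(
        pairs=[expected_pairs[i] for i in order],
        criteria=criteria,
        population=np.array([expected_pop[i] for i in order]),
    )
    traj = Trajectory(
        topology=top,
        coordinates=coords,
        frame_interval_ns=0.02,
        trajectory_id=f"toy{seed}",
    )
    return traj, expected
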