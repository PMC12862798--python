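import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import contactdyn as cd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_ensemble():
    """Small toy-structure trajectory with its exactly expected contacts."""
    spec = cd.ToyStructureSpec(
        n_residues=8,
        atoms_per_residue=3,
        contact_plan=(((1, 5), 1.0), ((2, 7), 0.5), ((3, 8), 0.05)),
    )
    return cd.generate_toy_structure_ensemble(spec, n_frames=40, seed=11)


@pytest.fixture
def two_block_model():
    """Correlation model with two planted 6-feature blocks."""
    spec = cd.PlantedClusterSpec(sizes=(6, 6), rho_in=0.8, rho_out=0.05)
    names, X, labels = cd.generate_clustered_series(spec, n_frames=5000, seed=1)
    return cd.correlation_matrix(X, features=names), labels


def planted_pipeline_ensemble(tmp_path, seed=7, taus=(10.0, 200.0, 3000.0)):
    """HDF5 distance tables for 12 features in 3 planted clusters.

    Cluster membership is carried both by shared (latent-factor) noise and
    by a cluster-specific relaxation time constant, so the clustering and
    timescale stages each see their own planted ground truth.
    """
    from contactdyn import io as cio

    rng = np.random.default_rng(seed)
    taus = dict(enumerate(taus))
    n_traj, t_max, dt, n_long = 24, 10_000.0, 2.0, 6
    sd, rho = 0.6, 0.85
    names = [f"{10 * c + 1}_{10 * c + 5 + j}" for c in range(3) for j in range(4)]
    series = []
    for itraj in range(n_traj):
        n = int(t_max / dt) + 1 if itraj < n_long else int(t_max / 10 / dt) + 1
        t = np.arange(n) * dt
        latent = {c: rng.standard_normal(n) for c in range(3)}
        for i, name in enumerate(names):
            c = i // 4
            sign = 1.0 if i % 2 == 0 else -1.0
            noise = sd * (np.sqrt(rho) * latent[c] + np.sqrt(1 - rho) * rng.standard_normal(n))
            values = 2.0 + sign * np.exp(-t / taus[c]) + noise
            series.append(
                cd.DistanceSeries(
                    contact=cio._contact_from_column(name),
                    trajectory_id=f"t{itraj:02d}",
                    times=t,
                    values=values,
                )
            )
    h5 = tmp_path / "distances.h5"
    cio.write_distance_h5(series, h5)
    return h5, taus, names


def write_pipeline_config(tmp_path, h5, out_name="run"):
    cfg = f"""
seed = 42

[input]
distances_h5 = "{h5}"

[output]
directory = "{tmp_path / out_name}"

[mosaic]
gamma = 0.4

[maxent]
lam = 10.0
"""
    p = tmp_path / f"{out_name}.toml"
    p.write_text(cfg)
    return p


def scaled_response_spec(**overrides):
    """Desk-scale version of the mixed short/long run design.

    30 trajectories (1/4 long), 10 us window at 1 ns write-out, per-frame
    noise sized so the ensemble SEM is ~5% of a unit amplitude.
    """
    params = dict(
        components=((30.0, 0.3), (800.0, -0.2)),
        offset=1.0,
        noise_sd=0.05 * np.sqrt(30),
        n_traj=30,
        long_traj_fraction=0.25,
        t_max=10_000.0,
        frame_interval=1.0,
    )
    params.update(overrides)
    return cd.PlantedResponseSpec(**params)
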