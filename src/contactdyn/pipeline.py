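"""End-to-end orchestration: contacts -> cluster -> fit -> content.

A run is described by a TOML config and produces file intermediates per
stage plus a manifest with checksums, so runs are reproducible and can be
resumed from any stage whose inputs are unchanged.  All randomness (the
Leiden restarts) is seeded from the config; two runs with the same config
and inputs produce byte-identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from . import io as cio
from .contacts import ContactCriteria, ContactSet, DistanceSeries, identify_contacts, extract_series
from .mosaic import MosaicConfig, correlation_matrix, leiden_cpm, reorder_block_diagonal, stack_series
from .timescales import (
    MaxEntConfig,
    build_tau_grid,
    dynamical_content,
    ensemble_average,
    maxent_fit,
    preprocess,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("contacts", "cluster", "fit", "content")


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    output_dir: Path
    seed: int = 42
    log_level: str = "INFO"
    # input: either coordinates (topology + trajectories) or distance tables
    topology: Path | None = None
    trajectories: list[Path] = field(default_factory=list)
    frame_interval_ns: float | None = None
    distances_h5: Path | None = None
    distances_csv: list[Path] = field(default_factory=list)
    criteria: ContactCriteria = field(default_factory=ContactCriteria)
    mosaic: MosaicConfig = field(default_factory=MosaicConfig)
    method: str = "pearson_abs"
    stride: int = 5
    maxent: MaxEntConfig = field(default_factory=MaxEntConfig)
    per_decade: int = 10
    tau_min_ns: float | None = None  # default: 2 x frame interval
    plots: bool = False
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as f:
            doc = tomllib.load(f)
        base = path.parent

        def _p(v):
            p = Path(v)
            return p if p.is_absolute() else base / p

        inp = doc.get("input", {})
        out = doc.get("output", {})
        cfg = cls(
            output_dir=_p(out.get("directory", "run_output")),
            seed=int(doc.get("seed", 42)),
            log_level=str(doc.get("log_level", "INFO")),
            topology=_p(inp["topology"]) if "topology" in inp else None,
            trajectories=[_p(t) for t in inp.get("trajectories", [])],
            frame_interval_ns=inp.get("frame_interval_ns"),
            distances_h5=_p(inp["distances_h5"]) if "distances_h5" in inp else None,
            distances_csv=[_p(t) for t in inp.get("distances_csv", [])],
            criteria=ContactCriteria(**doc.get("contacts", {})),
            mosaic=MosaicConfig(
                gamma=doc.get("mosaic", {}).get("gamma", 0.5),
                min_cluster_size=doc.get("mosaic", {}).get("min_cluster_size", 2),
                n_restarts=doc.get("mosaic", {}).get("n_restarts", 10),
                seed=int(doc.get("seed", 42)),
            ),
            method=doc.get("mosaic", {}).get("method", "pearson_abs"),
            stride=int(doc.get("mosaic", {}).get("stride", 5)),
            maxent=MaxEntConfig(**doc.get("maxent", {})),
            per_decade=int(doc.get("grid", {}).get("per_decade", 10)),
            tau_min_ns=doc.get("grid", {}).get("tau_min_ns"),
            plots=bool(out.get("plots", False)),
            raw=doc,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        has_coords = self.topology is not None
        has_tables = self.distances_h5 is not None or bool(self.distances_csv)
        if not has_coords and not has_tables:
            raise ValueError("config must provide coordinates or distance tables")
        for p in [self.topology, self.distances_h5, *self.trajectories, *self.distances_csv]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


@dataclass
class RunManifest:
    """Record of a completed (or failed) run: config, versions, checksums."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)  # stage -> {outputs: {path: sha256}, ...}
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "stages": self.stages,
                "warnings": self.warnings,
                "failed_stage": self.failed_stage,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def load(cls, path: Path) -> "RunManifest | None":
        if not path.exists():
            return None
        doc = json.loads(path.read_text())
        return cls(
            config=doc.get("config", {}),
            version=doc.get("version", ""),
            stages=doc.get("stages", {}),
            warnings=doc.get("warnings", []),
            failed_stage=doc.get("failed_stage"),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _outputs_valid(stage_record: dict | None, out_dir: Path) -> bool:
    if not stage_record:
        return False
    outputs = stage_record.get("outputs", {})
    if not outputs:
        return False
    for rel, digest in outputs.items():
        p = out_dir / rel
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def _load_series(config: RunConfig) -> list[DistanceSeries]:
    if config.distances_h5 is not None:
        return cio.read_distance_h5(config.distances_h5)
    series: list[DistanceSeries] = []
    for p in config.distances_csv:
        series.extend(cio.read_distance_csv(p, trajectory_id=Path(p).stem))
    return series


def run_pipeline(
    config: RunConfig,
    resume: bool = False,
    stages: Sequence[str] | None = None,
) -> RunManifest:
    """Execute the analysis chain, persisting every intermediate.

    Stages run in the fixed order contacts -> cluster -> fit -> content;
    with ``resume=True`` a stage whose recorded outputs still exist with
    matching checksums is skipped and later stages read the persisted
    intermediates.  On a stage failure the manifest records the failed
    stage; outputs of earlier stages remain valid.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    wanted = set(stages or STAGES)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    manifest_path = out_dir / "manifest.json"
    previous = RunManifest.load(manifest_path) if resume else None
    manifest = RunManifest(config=_config_snapshot(config))
    if previous is not None:
        manifest.stages = dict(previous.stages)

    for stage in STAGES:
        if stage not in wanted:
            continue
        record = manifest.stages.get(stage)
        if resume and _outputs_valid(record, out_dir) and record.get("config_hash") == _config_hash(config):
            logger.info("stage %s: outputs valid, skipping", stage)
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, out_dir)
        except Exception as e:  # noqa: BLE001 - recorded, then re-raised
            manifest.failed_stage = stage
            manifest.warnings.append(f"stage {stage} failed: {e}")
            manifest_path.write_text(manifest.to_json() + "\n")
            raise
        manifest.stages[stage] = {
            "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "config_hash": _config_hash(config),
        }
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)
    manifest_path.write_text(manifest.to_json() + "\n")
    return manifest


def _config_snapshot(config: RunConfig) -> dict:
    snap = dict(config.raw) if config.raw else {}
    snap.setdefault("seed", config.seed)
    return json.loads(json.dumps(snap, default=str))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(_config_snapshot(config), sort_keys=True).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# stages


def _stage_contacts(config: RunConfig, out_dir: Path) -> list[Path]:
    """Identify contacts (coordinate input) or ingest distance tables."""
    dist_path = out_dir / "distances.h5"
    contacts_path = out_dir / "contacts.json"
    contacts_tsv = out_dir / "contacts.tsv"
    if config.topology is not None:
        ensemble = cio.load_trajectories(
            config.topology, config.trajectories, config.frame_interval_ns
        )
        cs = identify_contacts(ensemble, config.criteria)
        logger.info("contacts: %d pairs pass the criteria", len(cs))
        series = extract_series(ensemble, cs)
    else:
        series = _load_series(config)
        names = sorted({s.name for s in series})
        n_traj = len({s.trajectory_id for s in series})
        logger.info("contacts: ingested %d features x %d trajectories", len(names), n_traj)
        pairs = [cio._contact_from_column(n) for n in names]
        cs = ContactSet(pairs=pairs, criteria=config.criteria, population=np.ones(len(pairs)))
    cio.write_contact_set_json(cs, contacts_path)
    cio.write_contact_set_tsv(cs, contacts_tsv)
    cio.write_distance_h5(series, dist_path)
    return [contacts_path, contacts_tsv, dist_path]


def _stage_cluster(config: RunConfig, out_dir: Path) -> list[Path]:
    series = cio.read_distance_h5(out_dir / "distances.h5")
    names, X = stack_series(series, stride=config.stride)
    model = correlation_matrix(X, method=config.method, features=names)
    part = leiden_cpm(model, config.mosaic)
    logger.info(
        "cluster: %d clusters + %d noise features at gamma=%.2f (objective %.4f)",
        part.n_clusters, len(part.noise), config.mosaic.gamma, part.objective,
    )
    reordered, _ = reorder_block_diagonal(model, part)
    out = [out_dir / "partition.json", out_dir / "partition.tsv", out_dir / "correlation.csv"]
    cio.write_partition_json(part, out[0])
    cio.write_partition_tsv(part, out[1])
    cio.write_matrix_csv(reordered, out[2])
    if config.plots:
        p = out_dir / "correlation.png"
        cio.plot_matrix_heatmap(reordered, p)
        out.append(p)
    return out


def _stage_fit(config: RunConfig, out_dir: Path) -> list[Path]:
    series = cio.read_distance_h5(out_dir / "distances.h5")
    by_feature: dict[str, list[DistanceSeries]] = {}
    for s in series:
        by_feature.setdefault(s.name, []).append(s)
    names = sorted(by_feature)

    any_series = by_feature[names[0]][0]
    dt = float(any_series.times[1] - any_series.times[0])
    t_max = max(float(s.times[-1]) for s in series)
    t_min = config.tau_min_ns if config.tau_min_ns is not None else 2.0 * dt
    grid = build_tau_grid(t_min, t_max, per_decade=config.per_decade)

    resp_dir = out_dir / "responses"
    resp_dir.mkdir(exist_ok=True)
    outputs = []
    spectra = []
    diagnostics = {}
    for name in names:
        resp = ensemble_average(by_feature[name])
        rp = resp_dir / f"{name}.csv"
        cio.write_response_csv(resp, rp)
        outputs.append(rp)
        pre = preprocess(resp, config.maxent)
        spec = maxent_fit(pre, grid, config.maxent)
        spectra.append(spec)
        diagnostics[name] = {
            "chi2": spec.chi2,
            "entropy": spec.entropy,
            "offset": spec.offset,
            "converged": spec.converged,
            "n_iter": spec.n_iter,
        }
    logger.info("fit: %d features on a %d-point tau grid", len(names), grid.n)
    sp = out_dir / "spectra.csv"
    cio.write_spectra_csv(spectra, sp)
    dg = out_dir / "fit_diagnostics.json"
    dg.write_text(json.dumps(diagnostics, indent=1, sort_keys=True) + "\n")
    return outputs + [sp, dg]


def _stage_content(config: RunConfig, out_dir: Path) -> list[Path]:
    spectra = cio.read_spectra_csv(out_dir / "spectra.csv")
    partition = cio.read_partition_json(out_dir / "partition.json")
    profile = dynamical_content(spectra, partition)
    logger.info(
        "content: %d peaks at tau = %s ns",
        len(profile.peaks), [round(t, 3) for t, _ in profile.peaks],
    )
    out = [out_dir / "content.csv", out_dir / "peaks.json"]
    cio.write_content_csv(profile, out[0])
    out[1].write_text(
        json.dumps(
            {"peaks": [{"tau_ns": t, "height": h} for t, h in profile.peaks]},
            indent=1, sort_keys=True,
        )
        + "\n"
    )
    if config.plots:
        p = out_dir / "content.png"
        cio.plot_content_profile(profile, p)
        out.append(p)
    return out


_STAGE_FUNCS = {
    "contacts": _stage_contacts,
    "cluster": _stage_cluster,
    "fit": _stage_fit,
    "content": _stage_content,
}
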