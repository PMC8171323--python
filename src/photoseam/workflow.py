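"""End-to-end workflow: discovery cascade plus refinement.

The pipeline mirrors the six-step protocol: seam metadynamics on the top
state pair, harvesting of near-degenerate frames, clustering and MECI
optimization, branching-plane cone sampling — then either recursion
(cone points of an upper seam seed metadynamics on the next pair down, the
cascade protocol) or, at the lowest pair, the photoproduct census and
string-method refinement paths.

Determinism: a single global seed deterministically spawns per-stage seeds
(splittable counter scheme), so identical configurations give
byte-identical reports and individual stages can be rerun in isolation.
Stage outputs are checkpointed as JSON so an interrupted run resumes
without recomputation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, fileio
from .cone import DEFAULTS as CONE_DEFAULTS
from .cone import sample_cone
from .metadynamics import (BiasPotential, MDParams, SeamConstraint,
                           propagate_seam_md)
from .models import make_model
from .paths import barrier_table, find_path, profile_along_path
from .products import census, retally
from .selection import (cluster_frames, dedupe_mecis, harvest_seam_frames,
                        optimize_meci)

logger = logging.getLogger("photoseam")

__all__ = ["WorkflowConfig", "run_workflow", "stage_seed", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def stage_seed(global_seed: int, *key: int) -> int:
    """Deterministic per-stage seed spawned from the global seed."""
    ss = np.random.SeedSequence((int(global_seed),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class WorkflowConfig:
    """Full parameterization of one workflow run.

    ``ladder`` lists the state pairs explored top-down, e.g.
    ``[[2, 1], [1, 0]]`` for an S2/S1 seam cascading into S0/S1; adjacent
    pairs must step down by exactly one state.  Unset sections inherit the
    documented defaults of the corresponding module.
    """

    model: dict = field(default_factory=lambda: {"name": "two_state_photo",
                                                 "params": {}})
    start: list | None = None
    ladder: list = field(default_factory=lambda: [[1, 0]])
    md: dict = field(default_factory=dict)          # MDParams overrides
    cascade_md: dict = field(default_factory=dict)  # lower-level overrides
    constraint: dict = field(default_factory=dict)  # SeamConstraint fields
    bias: dict = field(default_factory=dict)        # BiasPotential fields
    harvest_gap_max: float = 0.1
    cluster_k_max: int = 6
    meci: dict = field(default_factory=dict)        # tolerances
    cone: dict = field(default_factory=dict)        # per-role overrides
    product: dict = field(default_factory=dict)     # census tolerances
    paths: dict = field(default_factory=dict)       # n_images etc.
    profile_paths: bool = False
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        pairs = [tuple(int(s) for s in p) for p in self.ladder]
        if not pairs:
            raise ValueError("ladder must contain at least one state pair")
        for p in pairs:
            if len(p) != 2 or p[0] <= p[1]:
                raise ValueError(
                    f"ladder pair {list(p)} must be [upper, lower] with "
                    "upper > lower")
            if p[0] - p[1] != 1:
                raise ValueError(f"ladder pair {list(p)} must be adjacent states")
        for a, b in zip(pairs, pairs[1:]):
            if not (b[0] == a[0] - 1 and b[1] == a[1] - 1):
                raise ValueError(
                    f"ladder must descend one state per level, got "
                    f"{list(a)} -> {list(b)}")
        self.ladder = [list(p) for p in pairs]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _md_params(config: WorkflowConfig, pair, seed, cascade_level: bool) -> MDParams:
    base = dict(config.md)
    if cascade_level:
        base.update(config.cascade_md)
    base.setdefault("n_steps", 4000)
    base["state_pair"] = (min(pair), max(pair))
    base["seed"] = seed
    return MDParams(**base)


def _cone_params(config: WorkflowConfig, role: str) -> dict:
    p = dict(CONE_DEFAULTS[role])
    p.update(config.cone.get(role, {}))
    p["gap_window"] = tuple(p["gap_window"])
    return p


class _Checkpoints:
    def __init__(self, out_dir: str | None, resume: bool):
        self.dir = Path(out_dir) / "checkpoints" if out_dir else None
        self.resume = resume
        if self.dir:
            self.dir.mkdir(parents=True, exist_ok=True)

    def load(self, name: str):
        if self.resume and self.dir and (self.dir / f"{name}.json").exists():
            return fileio.load_report(self.dir / f"{name}.json")
        return None

    def save(self, name: str, payload: dict):
        if self.dir:
            fileio.write_report(payload, self.dir / f"{name}.json")


def run_workflow(config: WorkflowConfig, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the report as a plain dict.

    Raises :class:`StageError` naming the failed stage; a partial report
    and per-stage checkpoints are written to ``config.out_dir`` (when set)
    before the error propagates, so the run can be resumed.
    """
    model = make_model(config.model["name"], **config.model.get("params", {}))
    if config.start is not None:
        start = model.geometry(np.array(config.start, dtype=float))
    elif hasattr(model, "franck_condon"):
        start = model.franck_condon()
    else:
        raise ValueError("config.start is required for this model")

    ck = _Checkpoints(config.out_dir, resume)
    report: dict = {"config": config.to_dict(), "seed": config.seed,
                    "version": __version__, "levels": [], "log": []}
    gseed = config.seed

    def log_stage(stage: str, **counts):
        entry = {"stage": stage}
        entry.update(counts)
        report["log"].append(entry)
        logger.info("%s %s", stage,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    def fail(stage, exc):
        if config.out_dir:
            Path(config.out_dir).mkdir(parents=True, exist_ok=True)
            fileio.write_report(report,
                               Path(config.out_dir) / "partial_report.json")
        raise StageError(stage, str(exc)) from exc

    pairs = [tuple(sorted(p)) for p in config.ladder]  # (lower, upper)
    starts = [start]
    mecis_by_level = []

    for li, pair in enumerate(pairs):
        level_name = f"level{li}_s{pair[1]}s{pair[0]}"
        cached = ck.load(level_name)
        if cached is not None:
            mecis = [fileio.meci_from_dict(d) for d in cached["mecis"]]
            level_entry = {k: v for k, v in cached.items()
                           if k != "schema_version"}
            log_stage(f"{level_name}/seam_md",
                      runs=level_entry["n_starts"],
                      harvested=level_entry["n_frames_harvested"])
            log_stage(f"{level_name}/cluster",
                      chosen_k=level_entry["chosen_k"])
            log_stage(f"{level_name}/meci",
                      optimized=level_entry["n_optimized"],
                      converged=level_entry["n_converged"],
                      unique=len(mecis))
        else:
            try:
                frames, frame_energies = [], []
                for si, s in enumerate(starts):
                    params = _md_params(config, pair,
                                        stage_seed(gseed, li, si),
                                        cascade_level=li > 0)
                    bias = BiasPotential(**config.bias)
                    constraint = SeamConstraint(**config.constraint)
                    traj = propagate_seam_md(model, s, params, constraint,
                                             bias)
                    kept = harvest_seam_frames(traj, config.harvest_gap_max)
                    kept_e = [e for e, g in zip(
                        traj.state_energies.mean(axis=1), traj.gaps)
                        if g < config.harvest_gap_max]
                    frames.extend(kept)
                    frame_energies.extend(kept_e)
                log_stage(f"{level_name}/seam_md", runs=len(starts),
                          harvested=len(frames))
                if not frames:
                    raise RuntimeError("no seam frames harvested")
            except Exception as exc:
                fail(f"{level_name}/seam_md", exc)
            try:
                k_max = min(config.cluster_k_max, len(frames))
                clus = cluster_frames(frames, k_max,
                                      seed=stage_seed(gseed, li, 900),
                                      energies=np.array(frame_energies))
                log_stage(f"{level_name}/cluster", chosen_k=clus.chosen_k)
            except Exception as exc:
                fail(f"{level_name}/cluster", exc)
            try:
                meci_kw = dict(config.meci)
                records = [optimize_meci(model, pair, c, **meci_kw)
                           for c in clus.centroids]
                records = [r for r in records if r.converged]
                mecis = dedupe_mecis(records)
                for k, r in enumerate(mecis):
                    r.meci_id = f"s{pair[1]}s{pair[0]}_meci_{k}"
                log_stage(f"{level_name}/meci", optimized=len(clus.centroids),
                          converged=len(records), unique=len(mecis))
                if not mecis:
                    raise RuntimeError("no converged MECI at this level")
            except Exception as exc:
                fail(f"{level_name}/meci", exc)
            level_entry = {
                "pair": list(pair), "n_starts": len(starts),
                "n_frames_harvested": len(frames),
                "n_optimized": len(clus.centroids),
                "n_converged": len(records),
                "chosen_k": clus.chosen_k,
                "inertia_by_k": {str(k): v
                                 for k, v in clus.inertia_by_k.items()},
                "mecis": [fileio.meci_to_dict(r) for r in mecis],
            }
            ck.save(level_name, level_entry)
        report["levels"].append(level_entry)
        mecis_by_level.append(mecis)

        if li < len(pairs) - 1:
            # cascade: cone points of this seam seed the next level's MD
            try:
                cp = _cone_params(config, "cascade")
                starts = []
                cone_log = {}
                for mi, rec in enumerate(mecis):
                    samples = sample_cone(model, rec, R=cp["R"], n=cp["n"],
                                          gap_window=cp["gap_window"],
                                          seed=stage_seed(gseed, li, 500 + mi))
                    starts.extend(s.geometry for s in samples)
                    cone_log[rec.meci_id] = len(samples)
                log_stage(f"{level_name}/cone_seed", seeds=len(starts))
                report["levels"][-1]["cascade_seeds"] = cone_log
            except Exception as exc:
                fail(f"{level_name}/cone_seed", exc)

    # ------------------------------------------------------------------
    # lowest level: cone sampling, product census, refinement paths
    final_pair = pairs[-1]
    final_mecis = mecis_by_level[-1]
    cached = ck.load("products")
    if cached is not None:
        report["censuses"] = cached["censuses"]
        report["products"] = cached["products"]
        report["cone"] = cached["cone"]
        registry = [fileio.stationary_from_dict(d) for d in cached["products"]]
        log_stage("products", mecis=len(final_mecis),
                  products=len(registry))
    else:
        try:
            cp = _cone_params(config, "lower_seam")
            registry = []
            censuses = []
            cone_log = {}
            for mi, rec in enumerate(final_mecis):
                samples = sample_cone(model, rec, R=cp["R"], n=cp["n"],
                                      gap_window=cp["gap_window"],
                                      seed=stage_seed(gseed, 800, mi))
                cens, registry = census(model, samples,
                                        state_index=final_pair[0],
                                        registry=registry, **config.product)
                censuses.append(cens)
                cone_log[rec.meci_id] = {"n": len(samples)}
            censuses = [retally(c, registry) for c in censuses]
            report["censuses"] = [fileio.census_to_dict(c) for c in censuses]
            report["products"] = [fileio.stationary_to_dict(p)
                                  for p in registry]
            report["cone"] = cone_log
            log_stage("products", mecis=len(final_mecis),
                      products=len(registry))
            ck.save("products", {"censuses": report["censuses"],
                                 "products": report["products"],
                                 "cone": report["cone"]})
        except Exception as exc:
            fail("products", exc)

    cached = ck.load("paths")
    if cached is not None:
        report["paths"] = cached["paths"]
        report["barrier_table"] = cached["barrier_table"]
        log_stage("paths", seam_paths=len(cached["paths"]),
                  table_cells=len(cached["barrier_table"]))
    else:
        try:
            path_kw = dict(config.paths)
            n_images_gs = path_kw.pop("n_images_ground", 21)
            n_images_seam = path_kw.pop("n_images_seam", 11)
            paths_out = []
            table_out = {}
            good_products = [p for p in registry if p.converged]
            if len(good_products) >= 2:
                table = barrier_table(model, good_products,
                                      n_images=n_images_gs,
                                      state=final_pair[0])
                table_out = {f"{a}->{b}": cell
                             for (a, b), cell in sorted(table.items())}
            if len(final_mecis) >= 2:
                sp = find_path(model,
                               (final_mecis[0].geometry,
                                final_mecis[1].geometry),
                               ("seam", final_pair), n_images=n_images_seam)
                entry = {
                    "endpoints": [final_mecis[0].meci_id,
                                  final_mecis[1].meci_id],
                    "objective": "seam",
                    "barrier_forward": sp.barrier_forward,
                    "barrier_reverse": sp.barrier_reverse,
                    "barrierless": sp.barrierless,
                    "converged": sp.converged,
                    "max_gap": float(sp.gaps.max()),
                    "profile_energy": [float(e) for e in sp.path_energy()],
                    "arc_length": [float(s) for s in sp.arc_length],
                }
                if config.profile_paths and sp.converged:
                    prof = profile_along_path(
                        model, sp, cone_params=None,
                        seed=stage_seed(gseed, 950), registry=registry)
                    entry["profile"] = [
                        {"index": p.index, "sigma": p.sigma,
                         "e_mean": p.e_mean,
                         "fractions": dict(sorted(p.fractions.items())),
                         "skipped": p.skipped} for p in prof]
                paths_out.append(entry)
            report["paths"] = paths_out
            report["barrier_table"] = table_out
            log_stage("paths", seam_paths=len(paths_out),
                      table_cells=len(table_out))
            ck.save("paths", {"paths": paths_out,
                              "barrier_table": table_out})
        except Exception as exc:
            fail("paths", exc)

    if config.out_dir:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        fileio.write_report(report, Path(config.out_dir) / "report.json")
    return report
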