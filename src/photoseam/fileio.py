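"""Trajectory, geometry and report serialization.

Particle geometries (dim = 3) travel as standard multi-frame XYZ with
energies and gap recorded on the comment line; abstract coordinate-vector
models use a one-line whitespace-separated format with the same metadata
after a ``#``.  Reports are JSON with an explicit schema version.

All floats are written with ``repr`` round-trip precision, so a
write-then-read cycle reproduces coordinates exactly and reports are
byte-stable for identical runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import Geometry
from .products import ProductCensus, StationaryPoint
from .selection import MECIRecord

SCHEMA_VERSION = 1

__all__ = ["write_frames", "read_frames", "write_report", "load_report",
           "SCHEMA_VERSION"]


def _fmt(x: float) -> str:
    return repr(float(x))


def _meta_str(meta: dict) -> str:
    return " ".join(f"{k}={_fmt(v) if isinstance(v, float) else v}"
                    for k, v in meta.items())


def _parse_meta(s: str) -> dict:
    out = {}
    for tok in s.split():
        if "=" not in tok:
            continue
        k, v = tok.split("=", 1)
        try:
            out[k] = int(v)
        except ValueError:
            try:
                out[k] = float(v)
            except ValueError:
                out[k] = v
    return out


def write_frames(path, frames: list[Geometry],
                 metadata: list[dict] | None = None) -> None:
    """Write frames as multi-frame XYZ (3-D particles) or coordinate lines.

    ``metadata`` is an optional per-frame dict (e.g. step, E_i, E_j, gap,
    E_bias) recorded on the comment line.
    """
    path = Path(path)
    metadata = metadata or [{}] * len(frames)
    lines = []
    for g, meta in zip(frames, metadata):
        if g.n_particles > 1 and g.dim == 3:
            lines.append(str(g.n_particles))
            lines.append(_meta_str(meta))
            for lab, row in zip(g.labels, g.as_matrix()):
                lines.append(f"{lab} " + " ".join(_fmt(c) for c in row))
        else:
            coord_str = " ".join(_fmt(c) for c in g.coords)
            meta_str = _meta_str(meta)
            lines.append(coord_str + (f" # {meta_str}" if meta_str else ""))
    path.write_text("\n".join(lines) + "\n")


def read_frames(path, n_particles: int = 1, dim: int = 0,
                labels: tuple[str, ...] = ()
                ) -> tuple[list[Geometry], list[dict]]:
    """Round-trip counterpart of :func:`write_frames`.

    For the abstract one-line dialect the caller supplies the geometry
    signature; for XYZ it is read from the file.  Raises ``ValueError``
    naming the frame on malformed atom counts or line arity.
    """
    text = Path(path).read_text().splitlines()
    frames: list[Geometry] = []
    metas: list[dict] = []
    i = 0
    frame_no = 0
    while i < len(text):
        line = text[i].strip()
        if not line:
            i += 1
            continue
        tokens = line.split()
        is_xyz = len(tokens) == 1 and tokens[0].isdigit()
        if is_xyz:
            nat = int(tokens[0])
            if i + 2 + nat > len(text):
                raise ValueError(f"frame {frame_no}: truncated XYZ block "
                                 f"(declared {nat} atoms)")
            meta = _parse_meta(text[i + 1])
            labs, rows = [], []
            for k in range(nat):
                parts = text[i + 2 + k].split()
                if len(parts) != 4:
                    raise ValueError(
                        f"frame {frame_no}: atom line {k} has "
                        f"{len(parts)} fields, expected 4")
                labs.append(parts[0])
                rows.append([float(p) for p in parts[1:]])
            frames.append(Geometry(np.array(rows).ravel(), nat, 3,
                                   tuple(labs)))
            metas.append(meta)
            i += 2 + nat
        else:
            if "#" in line:
                coord_part, meta_part = line.split("#", 1)
                meta = _parse_meta(meta_part)
            else:
                coord_part, meta = line, {}
            coords = np.array([float(t) for t in coord_part.split()])
            np_eff = n_particles or 1
            d_eff = dim or coords.size // np_eff
            if coords.size != np_eff * d_eff:
                raise ValueError(
                    f"frame {frame_no}: {coords.size} coordinates do not "
                    f"match {np_eff} x {d_eff}")
            frames.append(Geometry(coords, np_eff, d_eff,
                                   labels or ("X",) * np_eff))
            metas.append(meta)
            i += 1
        frame_no += 1
    return frames, metas


# ---------------------------------------------------------------------------
# JSON (de)serialization of record types


def geometry_to_dict(g: Geometry) -> dict:
    return {"coords": list(map(float, g.coords)), "n_particles": g.n_particles,
            "dim": g.dim, "labels": list(g.labels)}


def geometry_from_dict(d: dict) -> Geometry:
    return Geometry(np.array(d["coords"]), d["n_particles"], d["dim"],
                    tuple(d["labels"]))


def meci_to_dict(r: MECIRecord) -> dict:
    return {"geometry": geometry_to_dict(r.geometry),
            "state_pair": list(r.state_pair), "e_mean": r.e_mean,
            "gap_at_convergence": r.gap_at_convergence,
            "g_vec": list(map(float, r.g_vec)),
            "h_vec": list(map(float, r.h_vec)), "sigma": r.sigma,
            "converged": r.converged, "n_iterations": r.n_iterations,
            "h_is_fallback": r.h_is_fallback, "meci_id": r.meci_id}


def meci_from_dict(d: dict) -> MECIRecord:
    return MECIRecord(geometry=geometry_from_dict(d["geometry"]),
                      state_pair=tuple(d["state_pair"]), e_mean=d["e_mean"],
                      gap_at_convergence=d["gap_at_convergence"],
                      g_vec=np.array(d["g_vec"]), h_vec=np.array(d["h_vec"]),
                      sigma=d["sigma"], converged=d["converged"],
                      n_iterations=d["n_iterations"],
                      h_is_fallback=d["h_is_fallback"],
                      meci_id=d["meci_id"])


def stationary_to_dict(p: StationaryPoint) -> dict:
    return {"geometry": geometry_to_dict(p.geometry),
            "state_index": p.state_index, "energy": p.energy,
            "gradient_norm": p.gradient_norm,
            "product_label": p.product_label,
            "support_count": p.support_count, "converged": p.converged}


def stationary_from_dict(d: dict) -> StationaryPoint:
    return StationaryPoint(geometry=geometry_from_dict(d["geometry"]),
                           state_index=d["state_index"], energy=d["energy"],
                           gradient_norm=d["gradient_norm"],
                           product_label=d["product_label"],
                           support_count=d["support_count"],
                           converged=d["converged"])


def census_to_dict(c: ProductCensus) -> dict:
    return {"fractions": dict(sorted(c.fractions.items())),
            "counts": dict(sorted(c.counts.items())), "total": c.total,
            "meci_id": c.meci_id, "hit_indices": list(c.hit_indices)}


def census_from_dict(d: dict) -> ProductCensus:
    return ProductCensus(fractions=d["fractions"], counts=d["counts"],
                         total=d["total"], meci_id=d["meci_id"],
                         hit_indices=list(d["hit_indices"]))


def path_to_dict(p) -> dict:
    return {"images": [geometry_to_dict(g) for g in p.images],
            "energies": [[float(e) for e in row] for row in p.energies],
            "gaps": [float(g) for g in p.gaps], "objective": p.objective,
            "state": p.state,
            "state_pair": list(p.state_pair) if p.state_pair else None,
            "barrier_forward": p.barrier_forward,
            "barrier_reverse": p.barrier_reverse,
            "barrierless": p.barrierless, "converged": p.converged,
            "arc_length": [float(s) for s in p.arc_length]}


def path_from_dict(d: dict):
    from .paths import PathResult
    return PathResult(images=[geometry_from_dict(g) for g in d["images"]],
                      energies=np.array(d["energies"]),
                      gaps=np.array(d["gaps"]), objective=d["objective"],
                      state=d["state"],
                      state_pair=tuple(d["state_pair"])
                      if d["state_pair"] else None,
                      barrier_forward=d["barrier_forward"],
                      barrier_reverse=d["barrier_reverse"],
                      barrierless=d["barrierless"], converged=d["converged"],
                      arc_length=np.array(d["arc_length"]))


def _np_default(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(report_dict: dict, path) -> None:
    """Serialize a report dict as schema-versioned, byte-stable JSON."""
    doc = {"schema_version": SCHEMA_VERSION}
    doc.update(report_dict)
    Path(path).write_text(
        json.dumps(doc, indent=1, sort_keys=True, default=_np_default) + "\n")


def load_report(path) -> dict:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema version {version!r}, "
                         f"expected {SCHEMA_VERSION}")
    return doc
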