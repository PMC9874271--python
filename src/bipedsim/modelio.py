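"""Model-directory I/O and validation.

A model directory holds a versioned YAML model document (segments,
joints, d.f., muscle paths per estimation method, actuator layout),
OBJ meshes per segment, and CSV tables (architecture, per-method muscle
parameters, postures).  Angles are degrees, lengths metres, forces
newtons; CSV headers carry the units.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .mesh import MeshBody, MeshError, mesh_mass_properties
from .model import DoF, JointSpec, SegmentSpec, SkeletonModel, count_dofs
from .muscles import (ArchitectureRow, MuscleParameters, MusclePath,
                      ESTIMATION_METHODS, MUSCLE_GROUPS)
from .synth import HindlimbModel, SynthConfig

SCHEMA_VERSION = 1


def _load_mesh_file(path: Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), process=False, force="mesh")
    return mesh


def write_model_dir(bundle: HindlimbModel, out_dir: str | Path) -> Path:
    """Write a complete model directory for a generated bundle."""
    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)

    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": bundle.model.name,
        "body_mass_kg": bundle.config.body_mass,
        "stance_segment": bundle.stance_segment,
        "cop_m": [float(v) for v in bundle.cop],
        "constrained_dofs": list(bundle.constrained_dofs),
        "reserve_dofs": list(bundle.reserve_dofs),
        "body_group": list(bundle.model.body_group),
        "tail_group": list(bundle.model.tail_group),
        "body_pivot_joint": bundle.model.body_pivot_joint,
        "tail_pivot_joint": bundle.model.tail_pivot_joint,
        "segments": [],
        "joints": [],
        "muscles": {},
    }
    for seg in bundle.model.segments.values():
        meshes = []
        for i, mb in enumerate(seg.body_meshes + seg.cavity_meshes):
            fname = f"meshes/{seg.name}_{mb.role}_{i}.obj"
            mb.as_trimesh().export(str(out / fname))
            meshes.append({"file": fname, "role": mb.role,
                           "density_kg_m3": mb.density, "name": mb.name})
        doc["segments"].append({
            "name": seg.name, "parent_joint": seg.parent_joint,
            "mass_override_kg": seg.mass_override, "meshes": meshes})
    for joint in bundle.model.joints.values():
        doc["joints"].append({
            "name": joint.name, "parent_segment": joint.parent_segment,
            "child_segment": joint.child_segment,
            "location_in_parent_m": [float(v) for v in joint.location_in_parent],
            "dofs": [{"name": d.name, "axis": [float(v) for v in d.axis],
                      "kind": d.kind, "locked": bool(d.locked),
                      "locked_value": float(d.locked_value)} for d in joint.dofs]})
    for method, paths in bundle.muscle_sets.items():
        doc["muscles"][method] = [
            {"name": p.name, "group": p.group,
             "via_points": [{"segment": s, "location_m": [float(v) for v in pt]}
                            for s, pt in p.via_points]}
            for p in paths]
    with open(out / "model.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)

    arch = pd.DataFrame([{
        "muscle": r.muscle, "muscle_mass_kg": r.muscle_mass,
        "optimal_fibre_length_m": r.optimal_fibre_length,
        "pennation_deg": r.pennation, "source_body_mass_kg": r.source_body_mass,
    } for r in bundle.architecture])
    arch.to_csv(out / "architecture.csv", index=False)

    params = pd.DataFrame([{
        "muscle": p.muscle, "method": p.method, "f_max_n": p.f_max,
        "optimal_fibre_length_m": p.optimal_fibre_length,
    } for method in bundle.parameters for p in bundle.parameters[method].values()])
    params.to_csv(out / "muscle_parameters.csv", index=False)
    return out


def read_model_dir(model_dir: str | Path) -> HindlimbModel:
    """Load a model directory back into a HindlimbModel bundle."""
    root = Path(model_dir)
    with open(root / "model.yaml") as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {doc.get('schema_version')!r}")

    segments = []
    for s in doc["segments"]:
        bodies, cavities = [], []
        for mdesc in s["meshes"]:
            tm = _load_mesh_file(root / mdesc["file"])
            mb = MeshBody(tm.vertices, tm.faces, mdesc["density_kg_m3"],
                          mdesc["role"], mdesc.get("name", ""))
            (bodies if mb.role == "body" else cavities).append(mb)
        segments.append(SegmentSpec(s["name"], s["parent_joint"], bodies,
                                    cavities, s.get("mass_override_kg")))
    joints = []
    for j in doc["joints"]:
        dofs = [DoF(d["name"], np.array(d["axis"]), d["kind"], d["locked"],
                    d.get("locked_value", 0.0)) for d in j["dofs"]]
        joints.append(JointSpec(j["name"], j["parent_segment"],
                                j["child_segment"],
                                np.array(j["location_in_parent_m"]), dofs))
    model = SkeletonModel(segments, joints,
                          body_group=tuple(doc.get("body_group", ())),
                          tail_group=tuple(doc.get("tail_group", ())),
                          body_pivot_joint=doc.get("body_pivot_joint"),
                          tail_pivot_joint=doc.get("tail_pivot_joint"),
                          name=doc.get("name", "model"))

    muscle_sets = {}
    for method, paths in doc["muscles"].items():
        muscle_sets[method] = [
            MusclePath(p["name"],
                       [(vp["segment"], np.array(vp["location_m"]))
                        for vp in p["via_points"]], p.get("group", ""))
            for p in paths]

    arch_frame = pd.read_csv(root / "architecture.csv")
    architecture = [ArchitectureRow(r.muscle, r.muscle_mass_kg,
                                    r.optimal_fibre_length_m, r.pennation_deg,
                                    r.source_body_mass_kg)
                    for r in arch_frame.itertuples()]
    params_frame = pd.read_csv(root / "muscle_parameters.csv")
    parameters: dict[str, dict[str, MuscleParameters]] = {}
    for r in params_frame.itertuples():
        parameters.setdefault(r.method, {})[r.muscle] = MuscleParameters(
            r.muscle, r.method, r.f_max_n, r.optimal_fibre_length_m)

    groups: dict[str, list[str]] = {}
    for p in next(iter(muscle_sets.values())):
        groups.setdefault(p.group, []).append(p.name)

    config = SynthConfig(seed=0, body_mass=doc["body_mass_kg"],
                         muscle_set="full" if len(groups) and sum(
                             len(v) for v in groups.values()) > 10 else "reduced")
    return HindlimbModel(model, muscle_sets, parameters, architecture, groups,
                         list(doc["constrained_dofs"]),
                         list(doc["reserve_dofs"]),
                         np.array(doc["cop_m"]), doc["stance_segment"], config)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def validate_model(bundle: HindlimbModel) -> dict:
    """Structural validation: mesh closure, tree topology, d.f. counts,
    muscle-group partition, architecture completeness.

    Returns ``{"ok": bool, "checks": [...], "errors": [...]}``; problems
    are reported, never silently fixed.
    """
    checks, errors = [], []

    for seg in bundle.model.segments.values():
        for mb in seg.body_meshes + seg.cavity_meshes:
            try:
                mesh_mass_properties(mb)
                checks.append(f"mesh {mb.name or seg.name}: closed and oriented")
            except (MeshError, ValueError) as exc:
                errors.append(str(exc))

    try:
        counts = count_dofs(bundle.model)
        checks.append(f"d.f. counts: {counts['active']} active, "
                      f"{counts['locked']} locked")
        if set(bundle.constrained_dofs) - {
                d.name for _, d in bundle.model.active_dofs()}:
            errors.append("constrained d.f. not among the active d.f.")
    except (ValueError, KeyError) as exc:
        errors.append(f"kinematic tree: {exc}")

    arch_names = {r.muscle for r in bundle.architecture}
    for method, paths in bundle.muscle_sets.items():
        names = [p.name for p in paths]
        if len(set(names)) != len(names):
            errors.append(f"{method}: duplicate muscle names")
        missing = [n for n in names if n not in arch_names]
        if missing and method != "model4_volumetric":
            errors.append(f"{method}: no architecture row for {missing}")
        bad_group = [p.name for p in paths if p.group not in MUSCLE_GROUPS]
        if bad_group:
            errors.append(f"{method}: muscles with unknown group {bad_group}")
        for p in paths:
            for seg, _pt in p.via_points:
                if seg not in bundle.model.segments:
                    errors.append(f"muscle {p.name}: unknown segment {seg!r}")
        if method not in ESTIMATION_METHODS:
            errors.append(f"unknown estimation method {method!r}")
        missing_params = [n for n in names
                          if n not in bundle.parameters.get(method, {})]
        if missing_params:
            errors.append(f"{method}: no parameters for {missing_params}")
    checks.append(f"muscle sets: {', '.join(bundle.muscle_sets)}")

    groups_seen = {p.group for p in next(iter(bundle.muscle_sets.values()))}
    checks.append(f"groups present: {len(groups_seen)}")

    return {"ok": not errors, "checks": checks, "errors": errors}
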