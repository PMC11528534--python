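"""Self-describing JSON tissue snapshots (full precision round-trip)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ..glucose_transport import GlucoseField
from ..tissue_mech import TissueDomain, TissueState

__all__ = ["SCHEMA_VERSION", "write_snapshot", "read_snapshot", "snapshot_dict"]

SCHEMA_VERSION = 1


def _floats(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def snapshot_dict(
    tissue: TissueState,
    field: GlucoseField | None = None,
    time: float = 0.0,
    extra: dict | None = None,
) -> dict:
    tess = tissue.tessellation()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "time": time,
        "domain": dataclasses.asdict(tissue.domain),
        "next_id": tissue.next_id,
        "cells": {
            "ids": tissue.ids.tolist(),
            "positions": _floats(tissue.positions),
            "velocities": _floats(tissue.velocities),
            "masses": _floats(tissue.masses),
            "preferred_areas": _floats(tissue.preferred_areas),
            "birth_areas": _floats(tissue.birth_areas),
            "basal_areas": _floats(tissue.basal_areas),
            "mature": tissue.mature.tolist(),
            "glucose": _floats(tissue.glucose),
            "clocks": _floats(tissue.clocks),
            "ages": _floats(tissue.ages),
            "lineages": tissue.lineages.tolist(),
            "polygons": [_floats(v) for v in tess.vertices],
            "areas": _floats(tess.areas),
            "perimeters": _floats(tess.perimeters),
        },
    }
    if field is not None:
        doc["glucose_field"] = {
            "concentrations": _floats(field.concentrations),
            "source_mask": field.source_mask.astype(int).tolist(),
            "diffusivity": field.diffusivity,
            "uptake": field.uptake,
        }
    if extra:
        doc["extra"] = extra
    return doc


def write_snapshot(tissue: TissueState, path, field: GlucoseField | None = None,
                   time: float = 0.0, extra: dict | None = None) -> None:
    Path(path).write_text(json.dumps(snapshot_dict(tissue, field, time, extra)))


def read_snapshot(path) -> tuple[TissueState, GlucoseField | None, dict]:
    """Load a snapshot; refuses files written under a different schema."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"snapshot schema {version!r} incompatible with {SCHEMA_VERSION}")
    dom = TissueDomain(**doc["domain"])
    c = doc["cells"]
    tissue = TissueState(
        dom,
        np.array(c["positions"]),
        velocities=np.array(c["velocities"]),
        masses=np.array(c["masses"]),
        preferred_areas=np.array(c["preferred_areas"]),
        glucose=np.array(c["glucose"]),
        clocks=np.array(c["clocks"]),
        ages=np.array(c["ages"]),
        lineages=np.array(c["lineages"]),
        ids=np.array(c["ids"]),
        next_id=doc["next_id"],
        birth_areas=np.array(c["birth_areas"]),
        mature=np.array(c["mature"]),
        basal_areas=np.array(c["basal_areas"]),
    )
    gf = None
    if "glucose_field" in doc:
        g = doc["glucose_field"]
        gf = GlucoseField(
            np.array(g["concentrations"]),
            np.array(g["source_mask"], dtype=bool),
            diffusivity=g["diffusivity"],
            uptake=g["uptake"],
        )
    return tissue, gf, doc
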