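"""Readers and writers for the pipeline's on-disk formats.

Frames: numbered PNG/TIFF images in a directory (or one multi-page TIFF).
Mosaics: single-image TIFF with a JSON sidecar of offsets and retained frame
indices.  Label masks: 16-bit TIFF with a JSON sidecar of flags/provenance.
Vesicle tables: CSV.  Summaries, manifests, edit lists: JSON.  Everything a
stage writes can be read back by the matching reader.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .morphometry import VesicleRecord, records_to_dataframe
from .mosaic import Mosaic
from .popstats import PopulationSummary, SampleSummary
from .segmentation import CorrectionEdit, LabelMask
from .synthgen import Track

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


def read_track(directory, pixel_size_um: float = 0.25) -> Track:
    """Read a frame directory (or a multi-page TIFF file) as a Track."""
    import imageio.v3 as iio

    path = Path(directory)
    if not path.exists():
        raise InputError(f"track input {path} does not exist")
    if path.is_file():
        stack = tifffile.imread(path)
        frames = [np.asarray(f) for f in stack]
    else:
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise InputError(f"no frame images found in {path}")
        frames = [np.asarray(iio.imread(p)) for p in files]
    return Track(frames=frames, pixel_size_um=pixel_size_um)


def write_mosaic(path, mosaic: Mosaic) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mosaic.image)
    sidecar = {
        "pixel_size_um": mosaic.pixel_size_um,
        "offsets": np.asarray(mosaic.offsets).tolist(),
        "retained_frame_indices": [int(i) for i in mosaic.retained_frame_indices],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_mosaic(path) -> Mosaic:
    path = Path(path)
    if not path.exists():
        raise InputError(f"mosaic {path} does not exist")
    image = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        return Mosaic(
            image=image,
            offsets=np.asarray(meta["offsets"], dtype=float),
            retained_frame_indices=list(meta["retained_frame_indices"]),
            pixel_size_um=float(meta["pixel_size_um"]),
        )
    return Mosaic(image=image, offsets=np.zeros((1, 2)), retained_frame_indices=[0], pixel_size_um=0.25)


def write_label_mask(path, mask: LabelMask) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.labels.astype(np.uint16))
    sidecar = {
        "pixel_size_um": mask.pixel_size_um,
        "provenance": mask.provenance,
        "flags": {str(k): sorted(v) for k, v in mask.flags.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_label_mask(path) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise InputError(f"label mask {path} does not exist")
    labels = tifffile.imread(path).astype(np.int32)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        flags = {int(k): frozenset(v) for k, v in meta.get("flags", {}).items()}
        return LabelMask(labels, float(meta["pixel_size_um"]), meta.get("provenance", "auto"), flags)
    return LabelMask(labels, 0.25)


def write_records_csv(path, records: list[VesicleRecord], sample_id: str = "sample") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_dataframe(records, sample_id).to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"vesicle table {path} does not exist")
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def write_edits(path, edits: list[CorrectionEdit]) -> None:
    payload = []
    for e in edits:
        p = e.payload
        if isinstance(p, np.ndarray):
            p = p.tolist()
        elif isinstance(p, tuple) and len(p) == 2 and not np.isscalar(p[1]):
            p = [p[0], np.asarray(p[1]).tolist()]
        payload.append({"kind": e.kind, "payload": p})
    Path(path).write_text(json.dumps(payload, indent=2))


def read_edits(path) -> list[CorrectionEdit]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"edit list {path} does not exist")
    raw = json.loads(path.read_text())
    return [CorrectionEdit(kind=e["kind"], payload=e["payload"]) for e in raw]


def _summary_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in d.items()}


def write_summaries(path, samples: list[SampleSummary], population: PopulationSummary | None = None) -> None:
    doc = {"samples": [_summary_dict(s) for s in samples]}
    if population is not None:
        doc["population"] = _summary_dict(population)
    Path(path).write_text(json.dumps(doc, indent=2))


def read_summaries(path) -> tuple[list[SampleSummary], PopulationSummary | None]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary file {path} does not exist")
    doc = json.loads(path.read_text())

    def fix(d):
        return {k: (math.nan if v is None else v) for k, v in d.items()}

    samples = [SampleSummary(**fix(s)) for s in doc["samples"]]
    population = PopulationSummary(**fix(doc["population"])) if "population" in doc else None
    return samples, population
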