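"""End-to-end orchestration: stitch -> segment -> correct -> measure -> summarize.

One chamber sample is the union of its (typically two) recorded tracks; the
pipeline stitches each track into a mosaic, segments it, optionally applies
an expert edit list, measures every accepted vesicle, pools the tracks'
records, and writes per-sample tables and summaries plus a run manifest
(config hash, seed, versions, per-stage counts) so a rerun with the same
config and inputs is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import InputError, PipelineError
from .io import (
    read_edits,
    read_track,
    write_label_mask,
    write_mosaic,
    write_records_csv,
    write_summaries,
)
from .morphometry import measure_sample
from .mosaic import StitchParams, stitch_track
from .popstats import summarize_population, summarize_sample
from .segmentation import FilterRules, MrfParams, segment_mosaic

logger = logging.getLogger("vesiclepop")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; round-trips losslessly through JSON."""

    pixel_size_um: float = 0.25
    stitch: StitchParams = field(default_factory=StitchParams)
    mrf: MrfParams = field(default_factory=MrfParams)
    filter_rules: FilterRules = field(default_factory=FilterRules)
    output_dir: str = "vesiclepop_out"
    seed: int = 0
    log_level: str = "INFO"
    time_min: float = 30.0

    def validate(self) -> None:
        self.mrf.validate()
        self.filter_rules.validate()
        if self.pixel_size_um <= 0:
            from .errors import ParameterError

            raise ParameterError("pixel_size_um must be > 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        raw["stitch"] = StitchParams(**raw.get("stitch", {}))
        raw["mrf"] = MrfParams(**raw.get("mrf", {}))
        raw["filter_rules"] = FilterRules(**raw.get("filter_rules", {}))
        return cls(**raw)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    input_tracks: dict[str, list],
    edits_files: dict[str, str] | None = None,
) -> dict:
    """Run the full pipeline and return the run manifest.

    ``input_tracks`` maps a sample (chamber) id to a list of track input
    directories (or multi-page TIFFs); ``edits_files`` optionally maps a
    sample id to a JSON correction-edit list applied to that sample's masks.
    All inputs are validated before any computation; any stage error aborts
    with the stage name.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    if not input_tracks:
        raise InputError("no input tracks given")
    for sample_id, tracks in input_tracks.items():
        if not tracks:
            raise InputError(f"sample {sample_id}: needs at least one track")
        for t in tracks:
            if not Path(t).exists():
                raise InputError(f"sample {sample_id}: track input {t} does not exist")
    edits_files = edits_files or {}
    for sample_id, path in edits_files.items():
        if not Path(path).exists():
            raise InputError(f"sample {sample_id}: edits file {path} does not exist")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "samples": {},
    }
    summaries = []

    for sample_id, tracks in input_tracks.items():
        sample_dir = out / sample_id
        sample_dir.mkdir(parents=True, exist_ok=True)
        sample_records = []
        sample_info: dict = {"tracks": []}
        edits = read_edits(edits_files[sample_id]) if sample_id in edits_files else None

        for t_idx, track_path in enumerate(tracks):
            stage = "stitch"
            try:
                track = read_track(track_path, config.pixel_size_um)
                mosaic = stitch_track(track, config.stitch)
                write_mosaic(sample_dir / f"track{t_idx}_mosaic.tif", mosaic)
                logger.info(
                    "sample=%s track=%d stage=stitch frames_in=%d frames_retained=%d",
                    sample_id, t_idx, len(track.frames), len(mosaic.retained_frame_indices),
                )

                stage = "segment"
                label_mask, report = segment_mosaic(
                    mosaic.image, config.pixel_size_um, config.mrf, config.filter_rules, edits
                )
                write_label_mask(sample_dir / f"track{t_idx}_mask.tif", label_mask)
                (sample_dir / f"track{t_idx}_rejections.json").write_text(
                    json.dumps(report.as_dict(), indent=2)
                )
                logger.info(
                    "sample=%s track=%d stage=segment found=%d accepted=%d "
                    "too_small=%d too_large=%d border=%d clump=%d",
                    sample_id, t_idx, report.total_found, report.accepted,
                    report.too_small, report.too_large, report.border_touching,
                    report.flagged_clump,
                )

                stage = "measure"
                records = measure_sample(label_mask)
                sample_records.extend(records)
                logger.info(
                    "sample=%s track=%d stage=measure records=%d", sample_id, t_idx, len(records)
                )
                sample_info["tracks"].append(
                    {
                        "input": str(track_path),
                        "frames_in": len(track.frames),
                        "frames_retained": len(mosaic.retained_frame_indices),
                        "labels_found": report.total_found,
                        "labels_accepted": report.accepted,
                        "rejections": report.as_dict(),
                        "records": len(records),
                    }
                )
            except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
                raise PipelineError(
                    f"sample {sample_id}, track {t_idx}: stage '{stage}' failed: {exc}"
                ) from exc

        write_records_csv(sample_dir / "vesicles.csv", sample_records, sample_id)
        summary = summarize_sample(sample_records, config.time_min, sample_id)
        summaries.append(summary)
        sample_info["quantity"] = summary.quantity
        manifest["samples"][sample_id] = sample_info
        logger.info("sample=%s stage=summarize quantity=%d", sample_id, summary.quantity)

    population = summarize_population(summaries) if len(summaries) >= 2 else None
    write_summaries(out / "summaries.json", summaries, population)
    manifest["n_samples"] = len(summaries)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
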