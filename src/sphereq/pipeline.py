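"""End-to-end per-image orchestration: segment, classify, summarize, export.

A run produces a structured run directory::

    out/
      config_echo.yaml    # every effective parameter
      run.log             # versions, per-image progress, errors
      per_nucleus.csv     # one row per nucleus across all images
      per_neurosphere.csv # one row per neurosphere per image
      overlays/<image>.png

Images that fail are logged and skipped; the remaining inputs are still
processed and the failure list is returned to the caller.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .classification import classify_stack
from .config import PipelineConfig
from .io_formats import (
    read_roi_file,
    read_stack,
    write_nucleus_csv,
    write_qc_overlay,
    write_summary_csv,
)
from .quantification import summarize_roi
from .segmentation import manual_rois_from_file, segment_neurospheres, segment_nuclei_in_roi

__all__ = ["run_pipeline", "process_image"]


def _versions() -> dict[str, str]:
    import scipy
    import skimage
    import tifffile

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "tifffile": tifffile.__version__,
    }


def process_image(config: PipelineConfig, path) -> tuple:
    """Run segmentation, classification and summarization on one image.

    Returns ``(rois, nuclei, records, summaries)``.
    """
    path = Path(path)
    stack = read_stack(path, config.channels)
    if config.roi_source == "manual":
        pairs = read_roi_file(config.roi_file, stack.shape)
        rois = manual_rois_from_file(pairs, stack.shape)
    else:
        rois = segment_neurospheres(
            stack.channel(config.neurosphere_channel),
            config.neurosphere_stage.params,
            config.neurosphere_stage.gate,
        )
    dapi = stack.channel(config.dapi_channel)
    nuclei = []
    for roi in rois:
        nuclei.extend(
            segment_nuclei_in_roi(
                dapi, roi, config.nucleus_stage.params, config.nucleus_stage.gate
            )
        )
    records = classify_stack(
        stack,
        rois,
        nuclei,
        config.markers,
        rolling_radius=config.marker_rolling_radius,
        subtract_marker_background=config.subtract_marker_background,
    )
    summaries = []
    for roi in rois:
        roi_records = [r for r in records if r.roi_id == roi.roi_id]
        summaries.append(
            summarize_roi(
                roi_records, roi.roi_id, config.combinations, image_id=path.stem
            )
        )
    return stack, rois, nuclei, records, summaries


def run_pipeline(config: PipelineConfig, inputs, out_dir) -> tuple[Path, list[str]]:
    """Process every input image and write the run directory.

    Returns ``(run_dir, failed_image_names)``; the caller decides the exit
    status.  Outputs are deterministic for fixed config, inputs and seed.
    """
    out_dir = Path(out_dir)
    overlays = out_dir / "overlays"
    overlays.mkdir(parents=True, exist_ok=True)
    log_lines = [f"sphereq run: {len(list(inputs))} input(s)"]
    for lib, ver in _versions().items():
        log_lines.append(f"version {lib}={ver}")
    with open(out_dir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.effective, fh, sort_keys=True)
    log_lines.append("config echoed to config_echo.yaml")

    all_records, all_ids, all_summaries = [], [], []
    failed = []
    for path in inputs:
        path = Path(path)
        try:
            stack, rois, nuclei, records, summaries = process_image(config, path)
        except Exception as exc:  # keep processing the remaining images
            failed.append(path.name)
            log_lines.append(f"ERROR {path.name}: {exc}")
            continue
        all_records.extend(records)
        all_ids.extend([path.stem] * len(records))
        all_summaries.extend(summaries)
        write_qc_overlay(
            stack, rois, records, overlays / f"{path.stem}.png",
            base_channel=config.dapi_channel,
        )
        log_lines.append(
            f"processed {path.name}: {len(rois)} neurosphere(s), "
            f"{len(records)} nuclei"
        )
    write_nucleus_csv(all_records, out_dir / "per_nucleus.csv", image_id=all_ids)
    write_summary_csv(all_summaries, out_dir / "per_neurosphere.csv")
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return out_dir, failed
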