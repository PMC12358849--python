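"""End-to-end measurement pipeline over TIFF inputs.

Chains masking, orientation estimation, nematic order, correlation
length, smectic order, domain segmentation and defect detection per
frame, and writes one results row per (image, frame) plus the derived
maps.  Reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fileio
from .angstats import fold_axial
from .config import RunConfig
from .domains import domain_metrics, high_order_domains
from .nematic import (
    angle_autocorrelation,
    correlation_length,
    detect_defects,
    local_order_parameter,
    mean_order,
)
from .orientation import Image2D, Mask, estimate_orientation, tissue_mask
from .smectic import aggregate_smectic, local_smectic

log = logging.getLogger("fiberorder")

RESULT_COLUMNS = [
    "image",
    "frame",
    "mean_S",
    "corr_length_um",
    "corr_length_norm",
    "corr_censored",
    "mean_tau",
    "mean_d_um",
    "n_smectic_windows",
    "n_domains",
    "mean_domain_diameter_um",
    "high_order_fraction",
    "n_defects_total",
    "defect_charge_sum",
    "mask_equivalent_diameter_um",
    "mask_area_px",
]

SCHEMA = {
    "mean_S": "spatial mean of the windowed nematic order parameter, dimensionless [0,1]",
    "corr_length_um": "first crossing of the angle autocorrelation below the threshold, μm",
    "corr_length_norm": "corr_length_um / mask equivalent diameter, dimensionless",
    "corr_censored": "1 if the autocorrelation never reached the threshold within r_max",
    "mean_tau": "spatial mean smectic order parameter, dimensionless [0,1]",
    "mean_d_um": "mean characteristic fiber distance over reliable windows, μm",
    "n_smectic_windows": "number of evaluated smectic windows",
    "n_domains": "number of high-order domains (S >= threshold)",
    "mean_domain_diameter_um": "mean equivalent-circle domain diameter, μm",
    "high_order_fraction": "fraction of mask area above the order threshold",
    "n_defects_total": "number of detected topological defects",
    "defect_charge_sum": "sum of detected defect charges (half-integer units)",
    "mask_equivalent_diameter_um": "2·px·sqrt(mask area/π), μm",
    "mask_area_px": "tissue mask area, pixels",
}


@dataclass
class FrameResult:
    row: dict
    defects: list[tuple[int, float, float, float]]  # (frame, row, col, charge)


def measure_frame(
    image: Image2D,
    config: RunConfig,
    mask: Mask | None = None,
    frame_index: int = 0,
) -> FrameResult:
    """Run every measurement stage on a single frame."""
    if mask is None:
        mask = tissue_mask(image, min_hole_area_px=config.mask_min_hole_area_px)
    orient = estimate_orientation(image, config.sigma_grad_um, config.sigma_window_um)
    order = local_order_parameter(orient, mask, config.op_window_um)
    m_s = mean_order(order, mask)
    profile = angle_autocorrelation(
        orient,
        mask,
        dr_um=config.corr_dr_um,
        r_max_um=config.corr_r_max_um,
        n_pairs_max=config.corr_n_pairs_max,
        seed=config.stage_seed(frame_index, 1),
    )
    clen, cnorm, censored = correlation_length(
        profile, config.corr_threshold, mask.equivalent_diameter_um
    )
    smec = local_smectic(
        image, orient, mask, config.smectic_window_um, config.smectic_band_um
    )
    if smec.defined.any():
        mean_tau, mean_d = aggregate_smectic(smec)
    else:
        mean_tau, mean_d = float("nan"), float("nan")
    label_map = high_order_domains(
        order, mask, config.domain_threshold, config.domain_min_area_px
    )
    _, dsummary = domain_metrics(label_map, mask)
    defects = detect_defects(orient, mask, config.loop_radius_px, config.merge_radius_px)
    row = {
        "frame": frame_index,
        "mean_S": m_s,
        "corr_length_um": clen,
        "corr_length_norm": cnorm,
        "corr_censored": int(censored),
        "mean_tau": mean_tau,
        "mean_d_um": mean_d,
        "n_smectic_windows": int(smec.defined.sum()),
        "n_domains": dsummary["n_domains"],
        "mean_domain_diameter_um": dsummary["mean_diameter_um"],
        "high_order_fraction": dsummary["total_high_order_fraction"],
        "n_defects_total": len(defects.defects),
        "defect_charge_sum": defects.total_charge,
        "mask_equivalent_diameter_um": mask.equivalent_diameter_um,
        "mask_area_px": mask.area_px,
    }
    return FrameResult(
        row=row,
        defects=[(frame_index, r, c, s) for r, c, s in defects.defects],
    )


def run_pipeline(
    config: RunConfig,
    inputs: list[str | Path],
    mask_paths: list[str | Path] | None = None,
) -> pd.DataFrame:
    """Measure every frame of every input TIFF and write all artifacts.

    Unreadable inputs produce an error record and the run continues.
    An empty input list yields an empty table (with a warning).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    fileio.write_json(out / "results_schema.json", SCHEMA)
    tag = config.config_hash()

    rows: list[dict] = []
    defect_rows: list[dict] = []
    errors: list[dict] = []
    if not inputs:
        log.warning("empty input list: writing an empty results table")
    for i, path in enumerate(inputs):
        path = Path(path)
        try:
            frames = fileio.read_frames(path, config.pixel_size_um, config.channel)
        except Exception as exc:  # record and continue with remaining files
            log.error("failed to read %s: %s", path, exc)
            errors.append({"image": str(path), "error": str(exc)})
            continue
        mask = None
        if mask_paths is not None:
            marr = fileio.read_frames(mask_paths[i], config.pixel_size_um)[0]
            mask = Mask(marr.intensity > 0, config.pixel_size_um)
        for f, img in enumerate(frames):
            try:
                res = measure_frame(img, config, mask=mask, frame_index=f)
            except Exception as exc:
                log.error("failed on %s frame %d: %s", path, f, exc)
                errors.append({"image": str(path), "frame": f, "error": str(exc)})
                continue
            res.row["image"] = path.name
            rows.append(res.row)
            for fr, r, c, s in res.defects:
                defect_rows.append(
                    {"image": path.name, "frame": fr, "row": r, "col": c, "charge": s}
                )

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table.to_csv(out / f"results_{tag}.csv", index=False)
    pd.DataFrame(
        defect_rows, columns=["image", "frame", "row", "col", "charge"]
    ).to_csv(out / f"defects_{tag}.csv", index=False)
    if errors:
        fileio.write_json(out / f"errors_{tag}.json", errors)
    return table


def setup_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fiberorder")
    root.handlers[:] = [handler]
    root.setLevel(level)
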