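"""Run configuration: validated parameters for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Every tunable of the measurement pipeline, with units in the names.

    The resolved config is echoed verbatim into the output directory of
    each run; all stochastic choices (pair subsampling) derive from
    ``seed`` via per-stage substreams.
    """

    pixel_size_um: float = 0.5
    channel: int | None = None
    # orientation
    sigma_grad_um: float | None = None  # None -> 1 px equivalent
    sigma_window_um: float | None = None  # None -> 4 px equivalent
    # nematic
    op_window_um: float = 20.0
    corr_dr_um: float = 2.0
    corr_r_max_um: float = 100.0
    corr_n_pairs_max: int = 200_000
    corr_threshold: float = 0.2
    # smectic
    smectic_window_um: float = 25.0
    smectic_band_um: tuple[float, float] = (1.5, 10.0)
    # domains
    domain_threshold: float = 0.6
    domain_min_area_px: int = 25
    track_overlap_frac: float = 0.3
    # defects
    loop_radius_px: float = 3.0
    merge_radius_px: float = 4.0
    # misc
    mask_min_hole_area_px: int = 64
    seed: int = 0
    output_dir: str = "fiberorder_out"

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.op_window_um / self.pixel_size_um < 5:
            raise ValueError("op_window_um must span at least 5 pixels")
        if self.corr_dr_um <= 0 or self.corr_r_max_um <= 0:
            raise ValueError("correlation binning must be positive")
        if not 0 < self.domain_threshold < 1:
            raise ValueError("domain_threshold must lie in (0, 1)")
        if self.smectic_window_um < 4 * self.smectic_band_um[0]:
            raise ValueError("smectic window must hold >= 4 band-minimum periods")
        if self.loop_radius_px < 1:
            raise ValueError("loop_radius_px must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["smectic_band_um"] = list(self.smectic_band_um)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir")  # destination does not affect the measurement
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "smectic_band_um" in d:
            d = {**d, "smectic_band_um": tuple(d["smectic_band_um"])}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def stage_seed(self, *key: int) -> int:
        """Deterministic per-stage substream seed below 2^31."""
        import numpy as np

        ss = np.random.SeedSequence([self.seed, *key])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
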