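"""Run configuration: every threshold and criterion used by a pipeline run."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults follow the published analysis: five thresholds 0.100-0.200 in
    steps of 0.025, a bilateral product cut-off of 0.05 squared, peak
    detectability cut-offs 0.15/0.08 with a 0.01 ROI-mean floor, a symmetry
    band of 1 +/- 0.5 with an adjusted-R2 floor of 0.7, and alpha 0.05.
    """

    data_dir: str = ""
    out_dir: str = ""
    thresholds: tuple[float, ...] = (0.100, 0.125, 0.150, 0.175, 0.200)
    bilateral_threshold: float = 0.05 ** 2
    peak_high: float = 0.15
    peak_low: float = 0.08
    mean_min: float = 0.01
    slope_band: tuple[float, float] = (0.5, 1.5)
    r2_min: float = 0.7
    lme_terms: tuple[str, ...] = ("sex", "age")
    alpha: float = 0.05
    seed: int = 0
    sample_unit: str = "scan"
    field_size_mode: str = "per_scan"
    voxelwise_areas: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["slope_band"] = list(self.slope_band)
        d["lme_terms"] = list(self.lme_terms)
        if self.voxelwise_areas is not None:
            d["voxelwise_areas"] = list(self.voxelwise_areas)
        return d

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def save(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: Path | str, **overrides) -> RunConfig:
    """Load a YAML/JSON config file, applying keyword overrides on top."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("thresholds", "slope_band", "lme_terms", "voxelwise_areas"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
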