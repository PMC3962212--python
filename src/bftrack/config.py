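"""Pipeline configuration: one YAML file holding every working parameter."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .filtering import FilterParams
from .segmentation import SegmentationParams
from .tracking import LinkParams

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs, serializable to/from YAML.

    Segmentation settings are tuned on the first and last frame only;
    intervening frames are interpolated (threshold linearly, cutoff as the
    endpoint mean).
    """

    input: str = ""
    output_dir: str = "bftrack_out"
    pixel_size: float = 0.977  # µm per pixel
    dt: float = 2.0  # minutes per frame
    filter: FilterParams = field(default_factory=FilterParams)
    seg_first: SegmentationParams = field(default_factory=SegmentationParams)
    seg_last: SegmentationParams = field(default_factory=SegmentationParams)
    link: LinkParams = field(default_factory=LinkParams)
    rmsd_threshold: float = 15.0  # px; 0 disables the non-motile filter
    exclusions: str | None = None  # path to manual exclusion list
    acov_fit_range: tuple[float, float] | None = None  # minutes
    n_boot: int = 200
    seed: int = 0
    write_overlays: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("filter", FilterParams), ("seg_first", SegmentationParams),
                         ("seg_last", SegmentationParams), ("link", LinkParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if d.get("acov_fit_range") is not None:
            d["acov_fit_range"] = tuple(d["acov_fit_range"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
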