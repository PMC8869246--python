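"""Pipeline configuration.

The defaults reproduce the published processing parameters: an 800x600
working frame, a 3-tap Gaussian pre-blur, 3x3 square SE for edge
extraction, 9x9 rectangular SE for cluster detection, a 3x3 noise-removal
opening, a 1% gap-area ceiling and a 20-px debris floor.  Every field is
serializable, and a flat key-value (TOML) config file can override any of
them; CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

from .exceptions import ParameterError


@dataclass
class PipelineConfig:
    #: Working frame as (width, height); ``None`` keeps the native size.
    resize_target: tuple[int, int] | None = (800, 600)
    #: Where the resize happens: "input" (before any filtering) or
    #: "after_sharpen" (on the sharpened edge image and the gray reference).
    resize_stage: str = "input"
    #: Odd kernel size of the Gaussian pre-blur (and of the edge-image blur).
    pre_blur_kernel: int = 3
    #: Override for the Gaussian sigma; ``None`` uses the size-to-sigma rule.
    gaussian_sigma: float | None = None
    #: Side of the square SE used for the grayscale edge morphology.
    edge_se_size: int = 3
    #: Side of the rectangular SE used for cluster close/open.
    cluster_se_size: int = 9
    #: Apply the Laplacian sharpening to the combined edge image.
    sharpen: bool = True
    #: Blur the combined edge image before sharpening (False: after).
    blur_before_sharpen: bool = True
    #: Holes up to this fraction of the image area qualify for the
    #: intensity-conditional gap classification; larger holes stay open.
    gap_area_ceiling: float = 0.01
    #: Filled components smaller than this pixel count are dropped as debris.
    debris_floor: int = 20
    #: Side of the square SE of the noise-removal binary morphology.
    noise_open_se_size: int = 3
    #: Noise-removal operator pair applied to the binarized edge image
    #: before contour filling: "close_open" (bridge ring gaps, then drop
    #: specks), "open" (specks only), or "none".
    noise_morphology: str = "close_open"
    #: "population" (divide by n) or "sample" (divide by n-1) std reporting.
    std_mode: str = "population"
    #: Keep named intermediate stage images on the result.
    debug_dump: bool = False

    def __post_init__(self) -> None:
        if self.resize_target is not None:
            w, h = self.resize_target
            if w < 1 or h < 1:
                raise ParameterError(f"resize_target must be positive, got {self.resize_target}")
            self.resize_target = (int(w), int(h))
        if self.resize_stage not in ("input", "after_sharpen"):
            raise ParameterError(f"unknown resize_stage {self.resize_stage!r}")
        for name in ("pre_blur_kernel", "edge_se_size", "cluster_se_size", "noise_open_se_size"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ParameterError(f"{name} must be odd and >= 1, got {v}")
        if not 0 <= self.gap_area_ceiling <= 1:
            raise ParameterError(f"gap_area_ceiling must be a fraction in [0, 1], got {self.gap_area_ceiling}")
        if self.debris_floor < 0:
            raise ParameterError(f"debris_floor must be >= 0, got {self.debris_floor}")
        if self.noise_morphology not in ("close_open", "open", "none"):
            raise ParameterError(f"unknown noise_morphology {self.noise_morphology!r}")
        if self.std_mode not in ("population", "sample"):
            raise ParameterError(f"std_mode must be 'population' or 'sample', got {self.std_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["resize_target"] is not None:
            d["resize_target"] = list(d["resize_target"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if data.get("resize_target") is not None:
            data["resize_target"] = tuple(data["resize_target"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Load overrides from a flat TOML key-value file."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if data.get("resize_target") == "none":
            data["resize_target"] = None
        return cls.from_dict(data)
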