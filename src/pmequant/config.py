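"""Validated analysis configuration.

All tunable parameters of the quantification pipelines live in one flat,
validated record. Defaults are the published values of the original
assays: the 1200 (or 250, on the alternate microscope) raw-scale MD
intensity cutoff, 15 px egg-mask erosion, 35 px rolling-ball radius,
ten 1 µm distance shells, the smallest-40% object filter, the 15 µm³
vesicle volume floor, and the guard/background envelope thicknesses
(0.2 / 0.3 µm for the vesicle assay, 0.5 / 1.0 µm for the MD-proximal
assay). Unknown keys in a config file are hard errors: a silent typo in
a threshold name would corrupt the science.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

from pydantic import BaseModel, ConfigDict, Field


class AnalysisConfig(BaseModel):
    """Flat configuration shared by all pipelines.

    Lengths are µm unless the name says px; intensity thresholds are on
    the raw camera scale (16-bit class).
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # 2D kinetics
    threshold_md: float = Field(default=1200.0, gt=0)
    erosion_px: int = Field(default=15, ge=0)
    rolling_ball_radius_px: int = Field(default=35, ge=1)
    rolling_ball_presmooth_sigma: float = Field(default=0.0, ge=0)
    min_component_area_px: int | None = Field(default=None, ge=0)

    # 3D shell analysis
    shell_count: int = Field(default=10, ge=1)
    shell_width_um: float = Field(default=1.0, gt=0)
    object_filter_fraction: float = Field(default=0.40, ge=0, lt=1)

    # vesicle colocalization
    vesicle_min_volume_um3: float = Field(default=15.0, gt=0)
    vesicle_guard_um: float = Field(default=0.2, gt=0)
    vesicle_background_um: float = Field(default=0.3, gt=0)

    # MD-proximal envelope measurement
    md_guard_um: float = Field(default=0.5, gt=0)
    md_background_um: float = Field(default=1.0, gt=0)

    # axoneme "touching" distance for the membrane assay; None = one voxel
    touch_distance_um: float | None = Field(default=None, gt=0)

    seed: int = Field(default=0, ge=0)

    def config_hash(self) -> str:
        """Short stable hash of the configuration, for provenance columns."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a flat JSON file.

    Unspecified keys take the published defaults; ``overrides`` win over
    file values. Unknown keys and out-of-range values raise.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        if text.strip():
            loaded = json.loads(text)
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a flat JSON object")
            data.update(loaded)
    if overrides:
        data.update(overrides)
    return AnalysisConfig(**data)
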