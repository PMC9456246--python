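"""Validated run configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["SegmentationSettings", "FishRunConfig", "FourCRunConfig", "RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationSettings(_Strict):
    """Detector thresholds; every constant the detection text leaves open."""

    stop_fraction: float = 0.3
    init_radius_vox: float = 10.0
    beta: float = 0.5
    nucleus_min_vox: int = 1000
    nucleus_max_vox: int = 1_000_000
    locus_top_k: int = 80
    territory_top_k: int = 3000
    locus_min_vox: int = 3
    locus_max_vox: int = 500
    territory_min_vox: int = 100
    territory_max_vox: int = 50_000
    connectivity: int = 26


class FishRunConfig(_Strict):
    spacing_nm: tuple[float, float, float] = (400.0, 200.0, 200.0)  # (dz, dy, dx)
    channel_map: dict[str, int] = Field(
        default_factory=lambda: {"dna": 0, "probe1": 1, "probe2": 2, "paint": 3}
    )
    segmentation: SegmentationSettings = Field(default_factory=SegmentationSettings)
    cutoff_nm: float = 2000.0
    quantile_q: float = 0.99
    k_sigma: float = 3.0


class FourCRunConfig(_Strict):
    site: str = "AAGCTT"
    cut_offset: int = 1
    end_tolerance: int = 4
    map_min_len: int = 20
    window: int = 500_000
    scale: float = 1e6
    mask_flank: int = 1
    include_site: bool = False


class RunConfig(_Strict):
    fish: FishRunConfig = Field(default_factory=FishRunConfig)
    fourc: FourCRunConfig = Field(default_factory=FourCRunConfig)
    seed: int = 0

    def digest_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
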