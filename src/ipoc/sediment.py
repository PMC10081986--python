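"""Sediment-stored sea-ice carbon: per-layer iPOC, age model, inventory.

Converts a layered sediment core (TOC plus either HBI intensities or a
precomputed sediment H-Print) into a theoretical-maximum iPOC
concentration per gram of dry sediment, assigns calendar ages to layer
boundaries with a constant-sedimentation-rate age model, and summarizes
the iPOC range accessible to burrowing infauna within a bioturbation
horizon (default 70 mm).

"Theoretical maximum" is implemented literally: the full TOC share
attributed to the sea-ice fraction, with no degradation, mixing, or
burial-efficiency discount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ipoc.hprint import Calibration, compute_hprint, hprint_to_ipoc


@dataclass(frozen=True)
class SedimentLayer:
    """One depth interval of a core.

    Provide either the three HBI intensities or a precomputed
    ``hprint_pct`` (mutually exclusive).  ``toc_mg_per_g`` is total
    organic carbon in mg per g dry sediment.
    """

    depth_top_mm: float
    depth_bottom_mm: float
    toc_mg_per_g: float
    ip25: Optional[float] = None
    hbi2: Optional[float] = None
    hbi3: Optional[float] = None
    hprint_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.depth_top_mm < self.depth_bottom_mm:
            raise ValueError(
                f"layer depths must satisfy top < bottom, got "
                f"[{self.depth_top_mm}, {self.depth_bottom_mm}]"
            )
        if self.toc_mg_per_g < 0:
            raise ValueError("TOC must be non-negative")
        has_intensities = any(
            v is not None for v in (self.ip25, self.hbi2, self.hbi3)
        )
        if has_intensities and self.hprint_pct is not None:
            raise ValueError(
                "provide intensities or hprint_pct, not both"
            )
        if not has_intensities and self.hprint_pct is None:
            raise ValueError("layer needs intensities or an explicit H-Print")
        if self.hprint_pct is not None and not (0 <= self.hprint_pct <= 100):
            raise ValueError("hprint_pct must be in [0, 100]")


@dataclass(frozen=True)
class SedimentProfile:
    """An ordered, non-overlapping stack of layers with an age model."""

    layers: tuple[SedimentLayer, ...]
    sedimentation_rate_mm_per_y: float = 1.0
    sampling_year: int = 2008
    station_meta: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sedimentation_rate_mm_per_y <= 0:
            raise ValueError("sedimentation rate must be positive")
        layers = tuple(self.layers)
        for a, b in zip(layers, layers[1:]):
            if b.depth_top_mm < a.depth_bottom_mm:
                raise ValueError(
                    f"layers overlap or are unsorted at depth "
                    f"{b.depth_top_mm} mm"
                )
        object.__setattr__(self, "layers", layers)

    def age_at(self, depth_mm: float) -> float:
        """Calendar age at a depth: sampling_year - depth / rate."""
        return self.sampling_year - depth_mm / self.sedimentation_rate_mm_per_y


@dataclass(frozen=True)
class LayerResult:
    layer: SedimentLayer
    hprint_pct: Optional[float]
    ipoc_fraction: Optional[float]  # unitless, clamped to [0, 1]
    ipoc_mg_per_g: Optional[float]
    age_top: float
    age_bottom: float

    @property
    def defined(self) -> bool:
        return self.ipoc_mg_per_g is not None


@dataclass(frozen=True)
class SedimentResult:
    profile: SedimentProfile
    layers: tuple[LayerResult, ...]
    accessible_horizon_mm: float
    ipoc_min_mg_per_g: float
    ipoc_max_mg_per_g: float
    oldest_accessible_age: float


def layer_ipoc(
    layer: SedimentLayer, cal: Calibration = Calibration()
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(H-Print %, iPOC fraction, iPOC mg/g) for one layer.

    The iPOC fraction is the clamped calibration output divided by 100;
    mg/g is TOC times that fraction.  A layer whose intensities are all
    zero (H-Print undefined) yields ``(None, None, None)`` and is flagged
    by callers rather than silently dropped.
    """
    if layer.hprint_pct is not None:
        h: Optional[float] = layer.hprint_pct
    else:
        h = compute_hprint(
            layer.ip25 or 0.0, layer.hbi2 or 0.0, layer.hbi3 or 0.0
        )
    if h is None:
        return None, None, None
    _, ipoc = hprint_to_ipoc(h, cal)
    frac = min(1.0, max(0.0, ipoc / 100.0))
    return h, frac, layer.toc_mg_per_g * frac


def age_model(profile: SedimentProfile) -> list[tuple[float, float]]:
    """(age_top, age_bottom) calendar years per layer; linear, no compaction."""
    return [
        (profile.age_at(l.depth_top_mm), profile.age_at(l.depth_bottom_mm))
        for l in profile.layers
    ]


def evaluate_profile(
    profile: SedimentProfile,
    cal: Calibration = Calibration(),
    horizon_mm: float = 70.0,
) -> SedimentResult:
    """Per-layer iPOC plus the bioturbation-accessible inventory summary."""
    ages = age_model(profile)
    layer_results = []
    for layer, (a_top, a_bot) in zip(profile.layers, ages):
        h, frac, mg = layer_ipoc(layer, cal)
        layer_results.append(
            LayerResult(layer, h, frac, mg, a_top, a_bot)
        )
    lo, hi, oldest = accessible_inventory(
        profile, layer_results, horizon_mm=horizon_mm
    )
    return SedimentResult(
        profile=profile,
        layers=tuple(layer_results),
        accessible_horizon_mm=horizon_mm,
        ipoc_min_mg_per_g=lo,
        ipoc_max_mg_per_g=hi,
        oldest_accessible_age=oldest,
    )


def accessible_inventory(
    profile: SedimentProfile,
    layer_results: Sequence[LayerResult],
    horizon_mm: float = 70.0,
) -> tuple[float, float, float]:
    """(min, max mg iPOC/g; oldest accessible age) within the horizon.

    A layer counts when any part of it overlaps [0, horizon]; partially
    overlapping layers contribute their whole value (conservative for a
    maximum estimate).  The oldest accessible age is the age at the
    horizon depth itself.
    """
    if horizon_mm <= 0:
        raise ValueError("bioturbation horizon must be positive")
    vals = [
        r.ipoc_mg_per_g
        for r in layer_results
        if r.defined and r.layer.depth_top_mm < horizon_mm
    ]
    if not vals:
        raise ValueError(
            f"no defined layers intersect the upper {horizon_mm} mm"
        )
    return min(vals), max(vals), profile.age_at(horizon_mm)
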