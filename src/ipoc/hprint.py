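"""H-Print index, iPOC calibration, and HBI source classification.

The H-Print expresses the phytoplankton-derived HBI III intensity as a
percentage of the summed intensities of the three monitored HBIs
(IP25, HBI II, HBI III):

    H-Print (%) = 100 * HBI_III / (IP25 + HBI_II + HBI_III)

0% is a fully sympagic (sea-ice) signal, 100% fully pelagic.  A linear
calibration from a controlled ice-algae feeding experiment maps H-Print to
the sea-ice particulate organic carbon share (iPOC) of marine-origin carbon:

    iPOC (%) = 101.08 - 1.02 * H-Print

The calibration line exceeds 100% at H-Print 0 and drops below 0% at
H-Print 100, so calibrated values are clamped to [0, 100] by default; the
raw (unclamped) value is always retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence


class HPrintDomainError(ValueError):
    """Raised when an intensity or H-Print value is outside its domain."""


@dataclass(frozen=True)
class Calibration:
    """Linear H-Print -> iPOC calibration.

    Parameters
    ----------
    intercept : float
        iPOC (%) at H-Print 0. Default 101.08.
    slope : float
        Change in iPOC (%) per H-Print unit; must be negative.
        Default -1.02.
    r_squared, df : float, int
        Fit quality of the source feeding-experiment regression;
        informational only (defaults 0.97 and 23).
    clamp : bool
        If True (default), calibrated iPOC is clamped to [0, 100].
    """

    intercept: float = 101.08
    slope: float = -1.02
    r_squared: float = 0.97
    df: int = 23
    clamp: bool = True

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError(f"calibration slope must be negative, got {self.slope}")
        if not self.intercept > 0:
            raise ValueError(
                f"calibration intercept must be positive, got {self.intercept}"
            )


class Classification(str, Enum):
    """HBI carbon-source classification of a consumer sample."""

    BOTH_SOURCES = "both_sources"
    PELAGIC_ONLY = "pelagic_only"
    EXCLUDED_NO_HBIS = "excluded_no_hbis"


@dataclass(frozen=True)
class SampleResult:
    """Per-sample pipeline output.

    ``hprint_pct``/``ipoc_*`` are None exactly when the sample has no
    measurable HBIs (classification ``excluded_no_hbis``): the H-Print
    denominator is zero and no iPOC value can be calculated.
    """

    sample_id: str
    hprint_pct: Optional[float]
    ipoc_raw_pct: Optional[float]
    ipoc_pct: Optional[float]
    classification: Classification

    @property
    def included(self) -> bool:
        return self.classification is not Classification.EXCLUDED_NO_HBIS


def _check_intensities(ip25: float, hbi2: float, hbi3: float) -> None:
    for name, v in (("ip25", ip25), ("hbi2", hbi2), ("hbi3", hbi3)):
        if not math.isfinite(v):
            raise HPrintDomainError(f"intensity {name} is not finite: {v!r}")
        if v < 0:
            raise HPrintDomainError(f"intensity {name} is negative: {v!r}")


def compute_hprint(ip25: float, hbi2: float, hbi3: float) -> Optional[float]:
    """H-Print (%) from the three HBI intensities, or None if undefined.

    Returns ``100 * hbi3 / (ip25 + hbi2 + hbi3)``; the index is undefined
    (None) when all three intensities are zero.  Raises
    :class:`HPrintDomainError` for negative or non-finite intensities.
    """
    _check_intensities(ip25, hbi2, hbi3)
    denom = ip25 + hbi2 + hbi3
    if denom == 0:
        return None
    # the ratio is bounded in [0, 100]; clip floating-point overshoot only
    return min(100.0, max(0.0, 100.0 * hbi3 / denom))


def hprint_to_ipoc(
    h: float, cal: Calibration = Calibration()
) -> tuple[float, float]:
    """Map an H-Print value to (raw iPOC %, reported iPOC %).

    The raw value is the calibration line evaluated at ``h``; the reported
    value is clamped to [0, 100] when ``cal.clamp`` is set, else equal to
    the raw value.  ``h`` must lie in [0, 100].
    """
    if not (0.0 <= h <= 100.0):
        raise HPrintDomainError(f"H-Print must be in [0, 100], got {h!r}")
    raw = cal.intercept + cal.slope * h
    ipoc = min(100.0, max(0.0, raw)) if cal.clamp else raw
    return raw, ipoc


def classify_sample(ip25: float, hbi2: float, hbi3: float) -> Classification:
    """Classify a sample's carbon sources from its HBI zero pattern.

    ``excluded_no_hbis`` when all three intensities are zero (no index can
    be computed); ``pelagic_only`` when only the phytoplankton marker
    HBI III is present; ``both_sources`` whenever any sea-ice HBI (IP25 or
    HBI II) is present.
    """
    _check_intensities(ip25, hbi2, hbi3)
    if ip25 == 0 and hbi2 == 0:
        return (
            Classification.EXCLUDED_NO_HBIS
            if hbi3 == 0
            else Classification.PELAGIC_ONLY
        )
    return Classification.BOTH_SOURCES


def process_sample(
    sample_id: str,
    ip25: float,
    hbi2: float,
    hbi3: float,
    cal: Calibration = Calibration(),
) -> SampleResult:
    """Run H-Print, calibration, and classification for one sample."""
    cls = classify_sample(ip25, hbi2, hbi3)
    h = compute_hprint(ip25, hbi2, hbi3)
    if h is None:
        return SampleResult(sample_id, None, None, None, cls)
    raw, ipoc = hprint_to_ipoc(h, cal)
    return SampleResult(sample_id, h, raw, ipoc, cls)


def run_pipeline(
    samples: Sequence,
    cal: Calibration = Calibration(),
) -> tuple[list[SampleResult], list[str]]:
    """Process a batch of samples; return (results, exclusion log).

    ``samples`` is any sequence of objects with ``sample_id``, ``ip25``,
    ``hbi2`` and ``hbi3`` attributes (e.g. ``BiomarkerSample``).  One
    :class:`SampleResult` is returned per input sample; the exclusion log
    lists the ids of every sample with no measurable HBIs.  Included
    results all carry finite iPOC values.
    """
    if len(samples) == 0:
        raise ValueError("run_pipeline requires at least one sample")
    results: list[SampleResult] = []
    excluded: list[str] = []
    for s in samples:
        r = process_sample(s.sample_id, s.ip25, s.hbi2, s.hbi3, cal)
        results.append(r)
        if r.classification is Classification.EXCLUDED_NO_HBIS:
            excluded.append(r.sample_id)
    return results, excluded
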