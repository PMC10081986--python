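"""Tabular I/O and validation for consumer samples and sediment cores.

The pipeline aggregates heterogeneous legacy datasets with no single
schema, so column names are mapped to canonical fields through a small
(YAML-serializable) config.  Validation is total: every input row becomes
either a validated :class:`BiomarkerSample` or an entry in the error
report — rows are never silently dropped.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from ipoc.hprint import Classification, SampleResult


class TaxonGroup(str, Enum):
    BENTHIC_INVERTEBRATE = "benthic_invertebrate"
    ZOOPLANKTON = "zooplankton"
    ICE_ASSOCIATED_INVERTEBRATE = "ice_associated_invertebrate"
    FISH = "fish"
    SEABIRD = "seabird"
    MARINE_MAMMAL = "marine_mammal"


class Habitat(str, Enum):
    BENTHIC = "benthic"
    MIXED = "mixed"
    PELAGIC = "pelagic"
    SYMPAGIC = "sympagic"


class FeedingStrategy(str, Enum):
    SURFACE_DEPOSIT = "surface_deposit"
    SUBSURFACE_DEPOSIT = "subsurface_deposit"
    SUSPENSION = "suspension"
    PREDATOR_SCAVENGER = "predator_scavenger"


#: Observed latitude range of the aggregated datasets; values outside it
#: trigger a validation *warning*, not a hard error (it is an observed
#: range, not a format rule).
LATITUDE_RANGE = (55.0, 82.0)


class BiomarkerSample(BaseModel):
    """One organism's HBI intensities plus ecological metadata.

    Intensities are response-normalized GC-MS SIM peak areas (arbitrary
    units); no response-factor correction is applied downstream.  ``month``
    is None when no collection month was recorded — this is distinct from
    any valid month and such samples are excluded from monthly summaries
    and regressions, never coerced to 0 or 13.
    """

    model_config = ConfigDict(frozen=True)

    sample_id: str
    species: str
    taxon_group: TaxonGroup
    habitat: Habitat
    feeding_strategy: Optional[FeedingStrategy] = None
    latitude: float
    longitude: Optional[float] = None
    year: int
    month: Optional[int] = None
    tissue: Optional[str] = None
    ip25: float
    hbi2: float
    hbi3: float

    @field_validator("ip25", "hbi2", "hbi3")
    @classmethod
    def _nonneg_finite(cls, v: float) -> float:
        if not (v == v and abs(v) != float("inf")):
            raise ValueError("intensity must be finite")
        if v < 0:
            raise ValueError("intensity must be non-negative")
        return v

    @field_validator("year")
    @classmethod
    def _year_range(cls, v: int) -> int:
        if not (1982 <= v <= 2019):
            raise ValueError(f"year {v} outside [1982, 2019]")
        return v

    @field_validator("month")
    @classmethod
    def _month_range(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and not (1 <= v <= 12):
            raise ValueError(f"month {v} outside [1, 12]")
        return v

    @field_validator("latitude")
    @classmethod
    def _latitude_warn(cls, v: float) -> float:
        lo, hi = LATITUDE_RANGE
        if not (lo <= v <= hi):
            warnings.warn(
                f"latitude {v} outside observed range [{lo}, {hi}]",
                stacklevel=2,
            )
        return v


@dataclass
class RowError:
    """Validation failure for one input row."""

    row: int  # 0-based data-row index (excluding header)
    sample_id: Optional[str]
    message: str


@dataclass
class IOConfig:
    """Delimited-text dialect and column mapping.

    ``columns`` maps canonical field names to file header names; omitted
    optional fields are read as missing.  Loadable from YAML via
    :meth:`from_yaml`.
    """

    delimiter: str = ","
    columns: dict[str, str] = field(default_factory=dict)

    MANDATORY = (
        "sample_id",
        "species",
        "taxon_group",
        "habitat",
        "latitude",
        "year",
        "ip25",
        "hbi2",
        "hbi3",
    )
    OPTIONAL = ("feeding_strategy", "longitude", "month", "tissue")

    def header_for(self, fld: str) -> str:
        return self.columns.get(fld, fld)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "IOConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            delimiter=raw.get("delimiter", ","),
            columns=raw.get("columns", {}) or {},
        )


class MissingColumnError(ValueError):
    """A mandatory column is absent from the input file."""


def _cell(row: pd.Series, header: str) -> Any:
    v = row.get(header)
    if v is None or (isinstance(v, float) and v != v) or v == "":
        return None
    return v


def read_samples(
    path: Union[str, Path], config: Optional[IOConfig] = None
) -> tuple[list[BiomarkerSample], list[RowError]]:
    """Read and validate consumer samples from a delimited-text file.

    Returns ``(samples, errors)``.  Every data row contributes to exactly
    one of the two lists.  A missing mandatory column raises
    :class:`MissingColumnError` naming the column; row-level problems
    (out-of-vocabulary habitat, negative intensity, bad month, ...) are
    collected as :class:`RowError` records.
    """
    config = config or IOConfig()
    df = pd.read_csv(path, sep=config.delimiter, dtype=str, keep_default_na=False)
    for fld in IOConfig.MANDATORY:
        if config.header_for(fld) not in df.columns:
            raise MissingColumnError(
                f"mandatory column {config.header_for(fld)!r} (field {fld!r}) "
                f"missing from {path}"
            )

    samples: list[BiomarkerSample] = []
    errors: list[RowError] = []
    for i, row in df.iterrows():
        record: dict[str, Any] = {}
        for fld in IOConfig.MANDATORY + IOConfig.OPTIONAL:
            record[fld] = _cell(row, config.header_for(fld))
        try:
            samples.append(BiomarkerSample(**record))
        except Exception as exc:  # pydantic ValidationError or coercion error
            msg = str(exc).splitlines()
            # keep the first informative line plus the offending field line
            summary = "; ".join(line.strip() for line in msg[:3] if line.strip())
            errors.append(RowError(int(i), record.get("sample_id"), summary))
    return samples, errors


#: Value written for an undefined (excluded-sample) numeric field.
MISSING = "NA"
_FLOAT_FMT = "%.4f"


def write_results(
    results: Sequence[SampleResult],
    path: Union[str, Path],
    samples: Optional[Sequence[BiomarkerSample]] = None,
) -> None:
    """Write per-sample pipeline results as CSV.

    One row per sample: id, species, habitat, month, H-Print %, clamped
    iPOC %, classification.  Undefined values (samples excluded for having
    no measurable HBIs) are emitted as an explicit ``NA`` marker, never 0.
    Numeric values are written to 4 decimals and round-trip losslessly at
    that precision.  Species/habitat/month columns are filled from
    ``samples`` when provided (matched by id), else left as ``NA``.

    Raises ``ValueError`` for an empty result list (no file is created).
    """
    if len(results) == 0:
        raise ValueError("write_results requires a non-empty result list")
    meta = {s.sample_id: s for s in samples} if samples else {}
    rows = []
    for r in results:
        s = meta.get(r.sample_id)
        rows.append(
            {
                "sample_id": r.sample_id,
                "species": s.species if s else MISSING,
                "habitat": s.habitat.value if s else MISSING,
                "month": (
                    MISSING if s is None or s.month is None else int(s.month)
                ),
                "hprint_pct": r.hprint_pct,
                "ipoc_pct": r.ipoc_pct,
                "classification": r.classification.value,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep=MISSING)


def read_results(path: Union[str, Path]) -> list[SampleResult]:
    """Read back a :func:`write_results` file as :class:`SampleResult` rows.

    The raw (unclamped) iPOC is reconstructed as None; only the reported
    columns survive the round trip.
    """
    df = pd.read_csv(path, na_values=[MISSING], keep_default_na=False)
    out: list[SampleResult] = []
    for _, row in df.iterrows():
        h = row["hprint_pct"]
        ip = row["ipoc_pct"]
        out.append(
            SampleResult(
                sample_id=str(row["sample_id"]),
                hprint_pct=None if pd.isna(h) else float(h),
                ipoc_raw_pct=None,
                ipoc_pct=None if pd.isna(ip) else float(ip),
                classification=Classification(row["classification"]),
            )
        )
    return out


def write_samples(
    samples: Sequence[BiomarkerSample], path: Union[str, Path]
) -> None:
    """Write samples in the canonical column layout (identity IOConfig)."""
    rows = [s.model_dump() for s in samples]
    df = pd.DataFrame(rows)
    for col in ("taxon_group", "habitat", "feeding_strategy"):
        df[col] = df[col].map(lambda v: v.value if v is not None else "")
    df["month"] = df["month"].map(
        lambda v: "" if v is None or pd.isna(v) else int(v)
    )
    df.to_csv(path, index=False)
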