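"""Synthetic consumer datasets and sediment cores with known ground truth.

The generator emulates the statistical structure the analysis assumes in
Arctic consumer HBI data: habitat-structured iPOC distributions (benthic >
sympagic > mixed > pelagic reliance on ice-derived carbon), seasonal
drops of iPOC in pelagic consumers after the May and September
phytoplankton blooms (HBI lipid turnover in tissue is days to weeks, so
the pulse decays quickly), a positive latitude gradient, lognormal
total-HBI intensity, and detection-limit corruption — samples with no
measurable HBIs at all (dropouts) and samples containing only the
phytoplankton marker HBI III.

True per-sample iPOC is drawn on the percent scale and perturbed with
noise on the logit of iPOC/100, which keeps simulated values inside
(0, 100) without truncation artifacts.  The true value is inverted through
the calibration line to an H-Print, a lognormal total intensity is
partitioned into HBI III = (H-Print/100) x total, and the remainder is
split between IP25 and HBI II by a configurable ratio — so running the
measurement pipeline on a noise-free dataset recovers the truth exactly.

Two mean structures are available: the default categorical structure
above, and an explicit linear-coefficient structure
(:class:`LinearEffects`) in which the mean is linear in the fitted design
(ordered habitat score, numeric month, latitude, month x habitat).  The
linear mode is the right tool for estimator-validation studies, where
"the coefficient of the generating model" must be well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit, logit

from ipoc.foodweb_stats import DEFAULT_HABITAT_SCORES
from ipoc.hprint import Calibration
from ipoc.sample_io import BiomarkerSample, FeedingStrategy, Habitat, TaxonGroup
from ipoc.sediment import SedimentLayer

# (species, taxon group, feeding strategy) pools per habitat; drawn from
# commonly sampled Arctic shelf taxa.
SPECIES_POOL: dict[str, list[tuple[str, TaxonGroup, Optional[FeedingStrategy]]]] = {
    "benthic": [
        ("Macoma calcarea", TaxonGroup.BENTHIC_INVERTEBRATE, FeedingStrategy.SURFACE_DEPOSIT),
        ("Nuculana pernula", TaxonGroup.BENTHIC_INVERTEBRATE, FeedingStrategy.SUBSURFACE_DEPOSIT),
        ("Serripes groenlandicus", TaxonGroup.BENTHIC_INVERTEBRATE, FeedingStrategy.SUSPENSION),
        ("Buccinum glaciale", TaxonGroup.BENTHIC_INVERTEBRATE, FeedingStrategy.PREDATOR_SCAVENGER),
        ("Ophiura sarsii", TaxonGroup.BENTHIC_INVERTEBRATE, FeedingStrategy.PREDATOR_SCAVENGER),
        ("Myoxocephalus scorpius", TaxonGroup.FISH, None),
    ],
    "pelagic": [
        ("Calanus hyperboreus", TaxonGroup.ZOOPLANKTON, None),
        ("Pseudocalanus spp.", TaxonGroup.ZOOPLANKTON, None),
        ("Themisto libellula", TaxonGroup.ZOOPLANKTON, None),
        ("Mallotus villosus", TaxonGroup.FISH, None),
        ("Uria lomvia", TaxonGroup.SEABIRD, None),
    ],
    "mixed": [
        ("Boreogadus saida", TaxonGroup.FISH, None),
        ("Gadus chalcogrammus", TaxonGroup.FISH, None),
        ("Odobenus rosmarus divergens", TaxonGroup.MARINE_MAMMAL, None),
        ("Erignathus barbatus", TaxonGroup.MARINE_MAMMAL, None),
    ],
    "sympagic": [
        ("Apherusa glacialis", TaxonGroup.ICE_ASSOCIATED_INVERTEBRATE, None),
        ("Gammarus wilkitzkii", TaxonGroup.ICE_ASSOCIATED_INVERTEBRATE, None),
        ("Onisimus nanseni", TaxonGroup.ICE_ASSOCIATED_INVERTEBRATE, None),
    ],
}

_WEEKS_PER_MONTH = 365.25 / 12 / 7


class LinearEffects(BaseModel):
    """Generating coefficients for the linear mean structure.

    The true mean iPOC (%) is
    ``intercept + habitat*score + latitude*(lat - lat_ref) + month*m +
    month_habitat*m*score`` with the ordered habitat score
    pelagic 0 / mixed 1 / sympagic 2 / benthic 3 and numeric month 1-12.
    """

    model_config = ConfigDict(frozen=True)

    intercept: float = 55.0
    habitat: float = 8.0
    latitude: float = 0.5
    month: float = -0.5
    month_habitat: float = -0.4
    lat_ref: float = 65.0


class SyntheticConfig(BaseModel):
    """Study-shaped generator settings.

    Defaults emulate the aggregated Arctic consumer dataset: habitat mean
    iPOC of 70/65/55/40% for benthic/sympagic/mixed/pelagic, a ~20%
    post-bloom iPOC drop in pelagic consumers in May and September decaying
    over ~3-week lipid turnover, +0.5% iPOC per degree latitude, ~3% of
    samples with no measurable HBIs and ~4% with only phytoplankton HBIs.
    """

    model_config = ConfigDict(frozen=True)

    n_samples: int = Field(gt=0)
    seed: int = 0
    habitat_base_ipoc: dict[str, float] = {
        "benthic": 70.0,
        "mixed": 55.0,
        "sympagic": 65.0,
        "pelagic": 40.0,
    }
    habitat_weights: dict[str, float] = {
        "benthic": 0.45,
        "pelagic": 0.25,
        "mixed": 0.20,
        "sympagic": 0.10,
    }
    pelagic_seasonal_amplitude: float = 20.0
    bloom_months: tuple[int, ...] = (5, 9)
    turnover_weeks: float = 3.0
    latitude_effect: float = 0.5
    latitude_ref: float = 68.5  # midpoint of the sampled range: the
    # configured habitat means are then the marginal group means
    latitude_range: tuple[float, float] = (55.0, 82.0)
    year_range: tuple[int, int] = (1982, 2019)
    noise_sd: float = 0.35  # SD of the logit-scale perturbation
    intensity_log_mean: float = 3.0  # lognormal params of total HBI intensity
    intensity_log_sd: float = 1.0
    ip25_to_hbi2_mean: float = 1.0
    ip25_to_hbi2_cv: float = 0.3
    dropout_rate: float = Field(default=0.03, ge=0, le=1)
    pelagic_only_rate: float = Field(default=0.04, ge=0, le=1)
    missing_month_rate: float = Field(default=0.03, ge=0, le=1)
    linear_effects: Optional[LinearEffects] = None

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if set(self.habitat_base_ipoc) != {h.value for h in Habitat}:
            raise ValueError("habitat_base_ipoc must cover the four habitats")
        if set(self.habitat_weights) != {h.value for h in Habitat}:
            raise ValueError("habitat_weights must cover the four habitats")
        if any(w < 0 for w in self.habitat_weights.values()):
            raise ValueError("habitat weights must be non-negative")
        return self


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside the samples, never consumed by the
    pipeline under test."""

    table: pd.DataFrame  # sample_id, habitat, month, latitude, true_ipoc, ...
    params: dict
    exceedance_50: float  # share of non-dropout samples with true iPOC > 50


def _seasonal_dip(month: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Post-bloom iPOC suppression factor in [0, 1] per sample month."""
    dip = np.zeros(month.shape, dtype=float)
    turnover = max(cfg.turnover_weeks, 1e-9)
    for b in cfg.bloom_months:
        lag_months = np.mod(month - b, 12)
        dip = np.maximum(
            dip, np.exp(-lag_months * _WEEKS_PER_MONTH / turnover)
        )
    return dip


def _true_mean(
    habitat: np.ndarray,
    month: np.ndarray,
    latitude: np.ndarray,
    cfg: SyntheticConfig,
) -> np.ndarray:
    if cfg.linear_effects is not None:
        eff = cfg.linear_effects
        score = np.array([DEFAULT_HABITAT_SCORES[h] for h in habitat])
        return (
            eff.intercept
            + eff.habitat * score
            + eff.latitude * (latitude - eff.lat_ref)
            + eff.month * month
            + eff.month_habitat * month * score
        )
    base = np.array([cfg.habitat_base_ipoc[h] for h in habitat])
    dip_weight = np.where(
        habitat == "pelagic", 1.0, np.where(habitat == "mixed", 0.5, 0.0)
    )
    return (
        base
        - cfg.pelagic_seasonal_amplitude * dip_weight * _seasonal_dip(month, cfg)
        + cfg.latitude_effect * (latitude - cfg.latitude_ref)
    )


def generate_samples(
    config: SyntheticConfig, cal: Calibration = Calibration()
) -> tuple[list[BiomarkerSample], SyntheticTruth]:
    """Generate a consumer dataset plus its ground truth.

    Deterministic for a fixed ``config.seed``.  Raises ``ValueError`` when
    the configured mean structure leaves (0, 100) anywhere on the sampled
    covariates (infeasible true iPOC).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    habitats = list(config.habitat_weights)
    w = np.array([config.habitat_weights[h] for h in habitats], dtype=float)
    habitat = rng.choice(habitats, size=n, p=w / w.sum())
    month = rng.integers(1, 13, size=n)
    lat_lo, lat_hi = config.latitude_range
    latitude = rng.uniform(lat_lo, lat_hi, size=n)
    year = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)

    mu = _true_mean(habitat, month.astype(float), latitude, config)
    if np.any(mu <= 0) or np.any(mu >= 100):
        raise ValueError(
            f"infeasible config: true mean iPOC outside (0, 100) "
            f"(range {mu.min():.1f}..{mu.max():.1f})"
        )
    p = mu / 100.0
    z = logit(p)
    if config.noise_sd > 0:
        # first-order bias correction keeps E[expit(z + eps)] ~= p, so the
        # configured means are the means of the simulated values
        z = z - 0.5 * config.noise_sd**2 * (1.0 - 2.0 * p)
        z = z + rng.normal(0.0, config.noise_sd, size=n)
    true_ipoc = 100.0 * expit(z)

    # invert the calibration line (restricted to H-Print in [0, 100])
    h = (cal.intercept - true_ipoc) / (-cal.slope)
    if np.any(h < 0) or np.any(h > 100):
        raise ValueError("true iPOC maps outside the calibrated H-Print range")

    total = rng.lognormal(config.intensity_log_mean, config.intensity_log_sd, n)
    hbi3 = h / 100.0 * total
    rem = total - hbi3
    cv = config.ip25_to_hbi2_cv
    sig2 = math.log1p(cv * cv)
    ratio = rng.lognormal(
        math.log(config.ip25_to_hbi2_mean) - sig2 / 2.0, math.sqrt(sig2), n
    )
    ip25 = rem * ratio / (1.0 + ratio)
    hbi2 = rem - ip25

    dropout = rng.random(n) < config.dropout_rate
    pelagic_only = (~dropout) & (rng.random(n) < config.pelagic_only_rate)
    ip25[dropout] = 0.0
    hbi2[dropout] = 0.0
    hbi3[dropout] = 0.0
    ip25[pelagic_only] = 0.0
    hbi2[pelagic_only] = 0.0

    month_missing = rng.random(n) < config.missing_month_rate

    samples: list[BiomarkerSample] = []
    rows = []
    for i in range(n):
        pool = SPECIES_POOL[habitat[i]]
        species, taxon, feeding = pool[rng.integers(0, len(pool))]
        sid = f"SYN{i:05d}"
        samples.append(
            BiomarkerSample(
                sample_id=sid,
                species=species,
                taxon_group=taxon,
                habitat=Habitat(habitat[i]),
                feeding_strategy=feeding,
                latitude=float(latitude[i]),
                longitude=None,
                year=int(year[i]),
                month=None if month_missing[i] else int(month[i]),
                tissue=None,
                ip25=float(ip25[i]),
                hbi2=float(hbi2[i]),
                hbi3=float(hbi3[i]),
            )
        )
        rows.append(
            {
                "sample_id": sid,
                "habitat": habitat[i],
                "month": None if month_missing[i] else int(month[i]),
                "month_true": int(month[i]),
                "latitude": float(latitude[i]),
                "year": int(year[i]),
                "true_ipoc": float(true_ipoc[i]),
                "dropout": bool(dropout[i]),
                "pelagic_only": bool(pelagic_only[i]),
            }
        )
    table = pd.DataFrame(rows)
    included = table.loc[~table["dropout"], "true_ipoc"]
    truth = SyntheticTruth(
        table=table,
        params={
            "habitat_base_ipoc": dict(config.habitat_base_ipoc),
            "latitude_effect": config.latitude_effect,
            "pelagic_seasonal_amplitude": config.pelagic_seasonal_amplitude,
            "linear_effects": (
                config.linear_effects.model_dump()
                if config.linear_effects
                else None
            ),
            "noise_sd": config.noise_sd,
            "seed": config.seed,
        },
        exceedance_50=float((included > 50.0).mean()),
    )
    return samples, truth


def generate_core(
    n_layers: int,
    layer_thickness_mm: float = 10.0,
    toc_mg_per_g: Union[float, Sequence[float]] = 20.0,
    hprint_pct: Union[float, Sequence[float]] = 30.0,
    toc_noise_cv: float = 0.0,
    hprint_jitter_sd: float = 0.0,
    seed: Optional[int] = None,
) -> list[SedimentLayer]:
    """Generate a layered sediment core with configurable depth trends.

    ``toc_mg_per_g`` and ``hprint_pct`` are scalars or per-layer
    sequences; optional lognormal TOC noise and Gaussian H-Print jitter
    (clipped to [0, 100]) are seeded and reproducible.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    toc = np.broadcast_to(
        np.asarray(toc_mg_per_g, dtype=float), (n_layers,)
    ).copy()
    hp = np.broadcast_to(
        np.asarray(hprint_pct, dtype=float), (n_layers,)
    ).copy()
    rng = np.random.default_rng(seed)
    if toc_noise_cv > 0:
        sig2 = math.log1p(toc_noise_cv**2)
        toc *= rng.lognormal(-sig2 / 2.0, math.sqrt(sig2), n_layers)
    if hprint_jitter_sd > 0:
        hp = np.clip(rng.normal(hp, hprint_jitter_sd), 0.0, 100.0)
    return [
        SedimentLayer(
            depth_top_mm=i * layer_thickness_mm,
            depth_bottom_mm=(i + 1) * layer_thickness_mm,
            toc_mg_per_g=float(toc[i]),
            hprint_pct=float(hp[i]),
        )
        for i in range(n_layers)
    ]
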