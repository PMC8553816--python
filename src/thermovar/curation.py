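"""Curation of published CTmax records into a per-species trait table.

The source compilations of critical thermal maximum (CTmax) measurements
carry several observations per species (different acclimation
temperatures, endpoints and habitats).  The analysis needs exactly one
row per species with the response log10(S.D. CTmax) and its covariates.
Curation applies a three-step selection:

1. drop records whose endpoint was death rather than loss of equilibrium
   (death overshoots the critical threshold);
2. drop polar-zone and brackish-habitat records (too few polar species;
   brackish habitat type is ambiguous in the sources);
3. per species, keep one record chosen by acclimation temperature and
   sample size, then derive delta-T = CTmax - T_a and the response.

Every excluded record lands in exactly one exclusion list, so the
bookkeeping identity input = output + sum(exclusions) always holds.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import pandas as pd

logger = logging.getLogger(__name__)

Endpoint = Literal["loss_of_equilibrium", "death"]
ClimateZone = Literal["tropical", "temperate", "polar"]
Habitat = Literal["freshwater", "marine", "brackish"]
Hemisphere = Literal["northern", "southern"]

VALID_ENDPOINTS = {"loss_of_equilibrium", "death"}
VALID_ZONES = {"tropical", "temperate", "polar"}
VALID_HABITATS = {"freshwater", "marine", "brackish"}
VALID_HEMISPHERES = {"northern", "southern"}

#: latitude (degrees, absolute) separating tropical from temperate
TROPICS_BOUNDARY_DEG = 23.0

SelectionMode = Literal[
    "lowest_then_largest_n", "midpoint_then_largest_n", "largest_n_then_lowest"
]


class CurationError(ValueError):
    pass


@dataclass
class CTmaxRecord:
    """One published CTmax observation at one acclimation temperature.

    ``ctmax_sd`` may be absent when ``ctmax_se`` and ``n_individuals``
    allow reconstruction (sd = se * sqrt(n)).  Temperatures are degrees
    Celsius throughout; ``heating_rate`` is degrees C per minute.
    """

    species: str
    ctmax_mean: float
    t_acclim: float
    n_individuals: int
    endpoint: str
    climate_zone: str
    habitat: str
    hemisphere: str | None = None
    ctmax_sd: float | None = None
    ctmax_se: float | None = None
    heating_rate: float | None = None
    record_id: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise CurationError(
                f"record {self.record_id} ({self.species}): "
                f"n_individuals must be >= 1, got {self.n_individuals}"
            )
        if self.ctmax_sd is not None and self.ctmax_sd < 0:
            raise CurationError(
                f"record {self.record_id} ({self.species}): negative SD"
            )
        if self.ctmax_mean <= self.t_acclim:
            logger.warning(
                "record %s (%s): CTmax %.2f <= acclimation %.2f "
                "(delta-T <= 0 is physically suspect)",
                self.record_id, self.species, self.ctmax_mean, self.t_acclim,
            )


@dataclass
class SpeciesTrait:
    """One curated species: response plus model covariates."""

    species: str
    log10_sd_ctmax: float
    ctmax: float
    delta_t: float
    group: str               # temperate | tropical
    habitat: str             # freshwater | marine
    hemisphere: str          # northern | southern
    n_individuals: int
    heating_rate: float | None = None


@dataclass
class CurationReport:
    """Counts at each filter stage plus per-reason exclusion lists."""

    n_input: int = 0
    n_after_endpoint: int = 0
    n_after_zone_habitat: int = 0
    n_species_output: int = 0
    selection_mode: str = "lowest_then_largest_n"
    sd_reconstructed_from_se: int = 0
    exclusions: dict[str, list[int]] = field(default_factory=dict)

    def exclude(self, reason: str, record: CTmaxRecord) -> None:
        self.exclusions.setdefault(reason, []).append(record.record_id)

    @property
    def n_excluded(self) -> int:
        return sum(len(v) for v in self.exclusions.values())

    def validate(self) -> None:
        if not (
            self.n_input
            >= self.n_after_endpoint
            >= self.n_after_zone_habitat
            >= self.n_species_output
        ):
            raise CurationError("stage counts must be non-increasing")
        if self.n_input != self.n_species_output + self.n_excluded:
            raise CurationError(
                f"bookkeeping mismatch: input {self.n_input} != output "
                f"{self.n_species_output} + excluded {self.n_excluded}"
            )
        ids = [i for lst in self.exclusions.values() for i in lst]
        if len(ids) != len(set(ids)):
            raise CurationError("a record appears in more than one exclusion list")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class CurationConfig:
    selection_mode: SelectionMode = "lowest_then_largest_n"
    allow_se_reconstruction: bool = True


# ---------------------------------------------------------------------------
# Filters


def filter_endpoint(
    records: list[CTmaxRecord], report: CurationReport | None = None
) -> tuple[list[CTmaxRecord], list[CTmaxRecord]]:
    """Keep loss-of-equilibrium records; exclude death-endpoint ones."""
    kept, excluded = [], []
    for rec in records:
        if rec.endpoint not in VALID_ENDPOINTS:
            raise CurationError(
                f"record {rec.record_id} ({rec.species}): "
                f"unknown endpoint {rec.endpoint!r}"
            )
        if rec.endpoint == "death":
            excluded.append(rec)
            if report is not None:
                report.exclude("death_endpoint", rec)
        else:
            kept.append(rec)
    return kept, excluded


def filter_zone_habitat(
    records: list[CTmaxRecord], report: CurationReport | None = None
) -> tuple[list[CTmaxRecord], list[CTmaxRecord]]:
    """Exclude polar-zone and brackish-habitat records (separate reasons)."""
    kept, excluded = [], []
    for rec in records:
        if rec.climate_zone not in VALID_ZONES:
            raise CurationError(
                f"record {rec.record_id}: unknown climate zone "
                f"{rec.climate_zone!r}"
            )
        if rec.habitat not in VALID_HABITATS:
            raise CurationError(
                f"record {rec.record_id}: unknown habitat {rec.habitat!r}"
            )
        if rec.climate_zone == "polar":
            excluded.append(rec)
            if report is not None:
                report.exclude("polar", rec)
        elif rec.habitat == "brackish":
            excluded.append(rec)
            if report is not None:
                report.exclude("brackish", rec)
        else:
            kept.append(rec)
    return kept, excluded


def select_acclimation(
    records: list[CTmaxRecord],
    mode: SelectionMode = "lowest_then_largest_n",
) -> CTmaxRecord:
    """Pick the single representative record for one species.

    The published rule — the lowest or mid-point tested acclimation
    temperature with the largest sample size — admits several readings,
    so the mode is explicit:

    * ``lowest_then_largest_n`` (default): lowest T_a; ties broken by
      largest n, then by input order.
    * ``midpoint_then_largest_n``: the median of the distinct tested T_a
      values (lower of the two middles for an even count); among records
      at that T_a, largest n then input order.
    * ``largest_n_then_lowest``: largest n; ties broken by lowest T_a,
      then input order.
    """
    if not records:
        raise CurationError("select_acclimation called with no records")
    order = {id(r): i for i, r in enumerate(records)}
    if mode == "lowest_then_largest_n":
        return min(
            records,
            key=lambda r: (r.t_acclim, -r.n_individuals, order[id(r)]),
        )
    if mode == "largest_n_then_lowest":
        return min(
            records,
            key=lambda r: (-r.n_individuals, r.t_acclim, order[id(r)]),
        )
    if mode == "midpoint_then_largest_n":
        levels = sorted({r.t_acclim for r in records})
        mid = levels[(len(levels) - 1) // 2]
        at_mid = [r for r in records if r.t_acclim == mid]
        return min(
            at_mid, key=lambda r: (-r.n_individuals, order[id(r)])
        )
    raise CurationError(f"unknown selection mode {mode!r}")


# ---------------------------------------------------------------------------
# Response and covariates


def compute_delta_t(ctmax: float, t_acclim: float) -> float:
    """delta-T = CTmax - T_a, the acute-warming buffer above acclimation."""
    if not (math.isfinite(ctmax) and math.isfinite(t_acclim)):
        raise CurationError("delta-T requires finite temperatures")
    dt = ctmax - t_acclim
    if dt <= 0:
        logger.warning("delta-T = %.3f <= 0 (CTmax at or below acclimation)", dt)
    return dt


def build_response(
    record: CTmaxRecord, allow_se: bool = True
) -> tuple[float, bool]:
    """log10 of the within-species SD of CTmax.

    Returns (value, reconstructed_from_se).  When the SD is missing but a
    standard error and n are available, sd = se * sqrt(n).  An SD of zero,
    or an SE-only record with n < 2, has no defined response and raises
    ``DegenerateSD`` so the caller can exclude the record with a logged
    reason rather than propagate a NaN.
    """
    sd = record.ctmax_sd
    reconstructed = False
    if sd is None or (isinstance(sd, float) and math.isnan(sd)):
        if not allow_se or record.ctmax_se is None:
            raise DegenerateSD("no SD and no SE to reconstruct from")
        if record.n_individuals < 2:
            raise DegenerateSD("SE-only record with n < 2")
        sd = record.ctmax_se * math.sqrt(record.n_individuals)
        reconstructed = True
    if sd <= 0:
        raise DegenerateSD(f"SD = {sd} has no log")
    return math.log10(sd), reconstructed


class DegenerateSD(CurationError):
    pass


def classify_group(latitude: float) -> tuple[str, str]:
    """Latitudinal group and hemisphere from a signed latitude.

    |lat| < 23 degrees -> tropical, otherwise temperate (the boundary
    itself is classed temperate); the sign gives the hemisphere (0 is
    treated as northern).
    """
    if not math.isfinite(latitude) or abs(latitude) > 90:
        raise CurationError(f"latitude {latitude!r} out of range")
    group = "tropical" if abs(latitude) < TROPICS_BOUNDARY_DEG else "temperate"
    hemisphere = "southern" if latitude < 0 else "northern"
    return group, hemisphere


# ---------------------------------------------------------------------------
# Pipeline


def curate(
    records: list[CTmaxRecord], config: CurationConfig | None = None
) -> tuple[list[SpeciesTrait], CurationReport]:
    """Full curation: endpoint filter -> zone/habitat filter -> per-species
    selection -> response construction.  One SpeciesTrait per surviving
    species; the report reconciles every input record."""
    config = config or CurationConfig()
    report = CurationReport(selection_mode=config.selection_mode)

    # ensure stable ids
    for i, rec in enumerate(records):
        if rec.record_id is None:
            rec.record_id = i
    report.n_input = len(records)

    kept, _ = filter_endpoint(records, report)
    report.n_after_endpoint = len(kept)

    kept, _ = filter_zone_habitat(kept, report)
    report.n_after_zone_habitat = len(kept)

    by_species: dict[str, list[CTmaxRecord]] = {}
    for rec in kept:
        by_species.setdefault(rec.species, []).append(rec)

    traits: list[SpeciesTrait] = []
    for species in sorted(by_species):
        recs = by_species[species]
        # records that cannot carry the response are out before selection
        usable = []
        for rec in recs:
            if rec.n_individuals < 2:
                report.exclude("n_below_2", rec)
            elif rec.hemisphere not in VALID_HEMISPHERES:
                report.exclude("unknown_hemisphere", rec)
            else:
                usable.append(rec)
        if not usable:
            continue
        chosen = select_acclimation(usable, config.selection_mode)
        try:
            log10_sd, reconstructed = build_response(
                chosen, allow_se=config.allow_se_reconstruction
            )
        except DegenerateSD as exc:
            logger.warning("species %s excluded: %s", species, exc)
            report.exclude("degenerate_sd", chosen)
            for rec in usable:
                if rec is not chosen:
                    report.exclude("acclimation_not_selected", rec)
            continue
        if reconstructed:
            report.sd_reconstructed_from_se += 1
        for rec in usable:
            if rec is not chosen:
                report.exclude("acclimation_not_selected", rec)
        group = "tropical" if chosen.climate_zone == "tropical" else "temperate"
        traits.append(
            SpeciesTrait(
                species=species,
                log10_sd_ctmax=log10_sd,
                ctmax=chosen.ctmax_mean,
                delta_t=compute_delta_t(chosen.ctmax_mean, chosen.t_acclim),
                group=group,
                habitat=chosen.habitat,
                hemisphere=chosen.hemisphere,
                n_individuals=chosen.n_individuals,
                heating_rate=chosen.heating_rate,
            )
        )
    report.n_species_output = len(traits)
    if not traits:
        raise CurationError("no species survived curation")
    report.validate()
    return traits, report


# ---------------------------------------------------------------------------
# I/O

RECORD_COLUMNS = {
    "species": str,
    "ctmax_mean": float,
    "ctmax_sd": float,
    "ctmax_se": float,
    "n_individuals": int,
    "t_acclim": float,
    "endpoint": str,
    "climate_zone": str,
    "habitat": str,
    "hemisphere": str,
    "heating_rate": float,
}

REQUIRED_COLUMNS = (
    "species", "ctmax_mean", "n_individuals", "t_acclim",
    "endpoint", "climate_zone", "habitat",
)


def read_records(path) -> list[CTmaxRecord]:
    """Read CTmax records from delimited text (comma or tab, sniffed).

    Extra columns are preserved in the frame but ignored here; missing
    optional values may be empty cells.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[CTmaxRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurationError(f"input table lacks columns: {', '.join(missing)}")

    def opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return v

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        hemi = opt(row, "hemisphere")
        records.append(
            CTmaxRecord(
                species=str(row["species"]),
                ctmax_mean=float(row["ctmax_mean"]),
                t_acclim=float(row["t_acclim"]),
                n_individuals=int(row["n_individuals"]),
                endpoint=str(row["endpoint"]),
                climate_zone=str(row["climate_zone"]),
                habitat=str(row["habitat"]),
                hemisphere=str(hemi) if hemi is not None else None,
                ctmax_sd=_maybe_float(opt(row, "ctmax_sd")),
                ctmax_se=_maybe_float(opt(row, "ctmax_se")),
                heating_rate=_maybe_float(opt(row, "heating_rate")),
                record_id=i,
            )
        )
    return records


def _maybe_float(v):
    return None if v is None else float(v)


def records_to_frame(records: list[CTmaxRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def traits_to_frame(traits: list[SpeciesTrait]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in traits])
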