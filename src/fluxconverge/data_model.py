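"""Domain types, site-table schema and I/O for the EC-BM convergence pipeline.

The central exchange format is a flat CSV "site table": one row per forest
site carrying eddy-covariance (EC) fluxes, biometric (BM) component fluxes,
the methodological profile of the BM measurements, environmental covariates
and (optionally) repeated carbon-stock inventories.  All fluxes are annual
sums in gC m-2 y-1.

Empty cells and the literal string "NA" are missing values.  Unknown extra
columns are preserved on read and written back unchanged.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ClimateZone", "DataQuality", "Fertility", "LeafType", "LeafHabit",
    "FluxKind", "FineRootNppMethod", "AllometryQuality", "LeafNppMethod",
    "SoilChamber", "RhSoilMethod", "RsoilDrivers", "RDrivers",
    "RleafParameterization", "RwoodScaling", "EcPartitioning",
    "SiteRecord", "MethodProfile", "BmComponents", "FluxPair",
    "StockInventory", "EcFluxes", "ParsedSite",
    "SchemaError", "RowParseError", "ValidationError",
    "ValidationIssue", "ValidationReport",
    "read_site_table", "write_site_table", "parse_dataframe", "validate_dataset",
    "REQUIRED_COLUMNS", "OPTIONAL_COLUMNS",
]

RSOIL_PARTITION_TOL = 1.0  # gC m-2 y-1 slack allowed in Rsoil = Rroot + Rh-soil

# Plausibility windows (warnings only), wider than the observed study ranges
PLAUSIBILITY_WINDOWS = {
    "NEP": (-500.0, 1200.0),
    "Reco": (200.0, 4000.0),
    "GPP": (300.0, 4500.0),
}

TROPICAL_LATITUDE_BAND = 23.5  # |lat| below which a site defaults to tropical


class SchemaError(ValueError):
    """The site table is missing a required column or has a malformed header."""


class RowParseError(ValueError):
    """A numeric cell could not be parsed; carries the offending row index."""

    def __init__(self, row: int, column: str, value: Any):
        self.row = row
        self.column = column
        super().__init__(f"row {row}: column {column!r}: cannot parse {value!r} as a number")


class ValidationError(ValueError):
    """A parsed value violates a hard invariant (bad enum level, broken identity)."""


class _CIEnum(str, enum.Enum):
    """String enum parsed case-insensitively."""

    @classmethod
    def parse(cls, raw: str) -> "_CIEnum":
        token = str(raw).strip().lower().replace("-", "_").replace(" ", "_")
        for member in cls:
            if member.value.lower() == token:
                return member
        raise ValidationError(
            f"unknown {cls.__name__} level {raw!r}; expected one of "
            f"{[m.value for m in cls]}"
        )

    def __str__(self) -> str:  # serialize as the bare level name
        return self.value


class ClimateZone(_CIEnum):
    BOREAL = "boreal"
    TEMPERATE = "temperate"
    TROPICAL = "tropical"


class DataQuality(_CIEnum):
    HIGH = "high"
    FAIR = "fair"


class Fertility(_CIEnum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class LeafType(_CIEnum):
    NEEDLELEAVED = "needleleaved"
    BROADLEAVED = "broadleaved"
    MIXED = "mixed"


class LeafHabit(_CIEnum):
    EVERGREEN = "evergreen"
    DECIDUOUS = "deciduous"
    MIXED = "mixed"


class FluxKind(_CIEnum):
    NEP = "nep"
    RECO = "reco"
    GPP = "gpp"


class FineRootNppMethod(_CIEnum):
    SEQUENTIAL_CORING = "sequential_coring"
    INGROWTH_CORES = "ingrowth_cores"
    MINIRHIZOTRON = "minirhizotron"
    OTHER = "other"


class AllometryQuality(_CIEnum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class LeafNppMethod(_CIEnum):
    LITTER_TRAP = "litter_trap"
    ALLOMETRY = "allometry"


class SoilChamber(_CIEnum):
    NSNF = "nsnf"   # closed static (non-steady-state non-through-flow)
    NSF = "nsf"     # closed dynamic (non-steady-state through-flow)
    OTHER = "other"


class RhSoilMethod(_CIEnum):
    ROOT_EXCLUSION = "root_exclusion"
    ROOT_RESPIRATION = "root_respiration"
    COMPONENT_INTEGRATION = "component_integration"
    OTHER = "other"


class RsoilDrivers(_CIEnum):
    TEMPERATURE = "temperature"
    TEMPERATURE_AND_WATER = "temperature_and_water"


class RDrivers(_CIEnum):
    TEMPERATURE = "temperature"
    TEMPERATURE_PLUS_OTHER = "temperature_plus_other"


class RleafParameterization(_CIEnum):
    SITE_SPECIFIC = "site_specific"
    GENERIC = "generic"


class RwoodScaling(_CIEnum):
    WOOD_VOLUME = "wood_volume"
    WOOD_AREA = "wood_area"


class EcPartitioning(_CIEnum):
    NIGHTTIME = "nighttime"
    DAYTIME = "daytime"
    SUNDOWN = "sundown"


@dataclass
class SiteRecord:
    """Metadata and environmental covariates for one site."""

    site_id: str
    latitude: float
    longitude: float
    climate_zone: ClimateZone
    years_measured: int        # replicate measurement years, l >= 1
    data_quality: DataQuality
    mean_annual_temperature: Optional[float] = None   # degC
    mean_annual_precipitation: Optional[float] = None  # mm y-1
    fertility: Optional[Fertility] = None
    leaf_type: Optional[LeafType] = None
    leaf_habit: Optional[LeafHabit] = None
    lai: Optional[float] = None                        # m2 m-2
    elevation_variability: Optional[float] = None      # m, SD within DEM quadrat
    topographical_slope: Optional[float] = None        # percent
    years_measured_ec: Optional[int] = None            # method-specific overrides
    years_measured_bm: Optional[int] = None

    def check(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValidationError(f"{self.site_id}: latitude {self.latitude} outside [-90, 90]")
        if self.years_measured < 1:
            raise ValidationError(f"{self.site_id}: years_measured must be >= 1")
        if self.lai is not None and self.lai < 0:
            raise ValidationError(f"{self.site_id}: lai must be >= 0")

    def ec_years(self) -> int:
        return self.years_measured_ec if self.years_measured_ec is not None else self.years_measured

    def bm_years(self) -> int:
        return self.years_measured_bm if self.years_measured_bm is not None else self.years_measured


@dataclass
class MethodProfile:
    """Categorical profile of the BM (and EC-partitioning) methodology at a site.

    One field per methodological variant screened in the analysis; every
    field is optional because few studies report the full protocol.
    """

    fine_root_npp_method: Optional[FineRootNppMethod] = None
    allometry_quality: Optional[AllometryQuality] = None
    leaf_npp_method: Optional[LeafNppMethod] = None
    soil_chamber: Optional[SoilChamber] = None
    co2_scrubbing: Optional[bool] = None       # only meaningful for NSF chambers
    rh_soil_method: Optional[RhSoilMethod] = None
    rh_cwd_considered: Optional[bool] = None
    rsoil_model_drivers: Optional[RsoilDrivers] = None
    rleaf_model_drivers: Optional[RDrivers] = None
    rleaf_parameterization: Optional[RleafParameterization] = None
    rleaf_variable_q10: Optional[bool] = None
    light_inhibition_considered: Optional[bool] = None
    leaf_growth_respiration: Optional[bool] = None
    wood_growth_respiration: Optional[bool] = None
    rwood_model_drivers: Optional[RDrivers] = None
    rwood_scaling: Optional[RwoodScaling] = None
    branch_stem_separated: Optional[bool] = None
    ec_partitioning: Optional[EcPartitioning] = None
    npp_branch_turnover_measured: Optional[bool] = None
    npp_mycorrhiza_measured: Optional[bool] = None

    def check(self, site_id: str = "?") -> None:
        if self.co2_scrubbing is not None and self.soil_chamber != SoilChamber.NSF:
            raise ValidationError(
                f"{site_id}: co2_scrubbing may only be set for NSF soil chambers"
            )


# (field name, kind) for the BM component fluxes; all in gC m-2 y-1
_BM_FIELDS = (
    "npp_wood_aboveground", "npp_foliage", "npp_fineroot", "npp_coarseroot",
    "npp_understory", "npp_branch_turnover", "npp_reproductive", "npp_other",
    "ra_leaf", "ra_wood", "ra_understory",
    "rsoil", "rroot", "rh_soil", "rh_cwd",
)


@dataclass
class BmComponents:
    """Biometric component fluxes for one site (gC m-2 y-1; None = not measured)."""

    npp_wood_aboveground: Optional[float] = None
    npp_foliage: Optional[float] = None
    npp_fineroot: Optional[float] = None
    npp_coarseroot: Optional[float] = None
    npp_understory: Optional[float] = None
    npp_branch_turnover: Optional[float] = None
    npp_reproductive: Optional[float] = None
    npp_other: Optional[float] = None
    ra_leaf: Optional[float] = None
    ra_wood: Optional[float] = None
    ra_understory: Optional[float] = None
    rsoil: Optional[float] = None
    rroot: Optional[float] = None
    rh_soil: Optional[float] = None
    rh_cwd: Optional[float] = None

    def check(self, site_id: str = "?") -> None:
        for name in _BM_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{site_id}: {name} = {v} must be >= 0")
        if self.rsoil is not None and self.rroot is not None and self.rh_soil is not None:
            gap = self.rsoil - (self.rroot + self.rh_soil)
            if abs(gap) > RSOIL_PARTITION_TOL:
                raise ValidationError(
                    f"{site_id}: Rsoil partition violated by {gap:+.1f} gC m-2 y-1 "
                    f"(rsoil={self.rsoil}, rroot={self.rroot}, rh_soil={self.rh_soil})"
                )


@dataclass
class EcFluxes:
    """Eddy-covariance fluxes for one site (gC m-2 y-1)."""

    nep: float
    reco: Optional[float] = None
    gpp: Optional[float] = None
    reco_daytime: Optional[float] = None  # daytime-partitioned variant, if dual-reported
    gpp_daytime: Optional[float] = None


@dataclass
class FluxPair:
    """Matched EC and BM estimates of one flux with half-range uncertainties."""

    flux_kind: FluxKind
    ec_value: float
    bm_value: float
    ec_uncertainty: Optional[float] = None
    bm_uncertainty: Optional[float] = None

    def check(self) -> None:
        if self.flux_kind in (FluxKind.RECO, FluxKind.GPP):
            if self.ec_value <= 0 or self.bm_value <= 0:
                raise ValidationError(f"{self.flux_kind}: Reco/GPP values must be > 0")
        for u in (self.ec_uncertainty, self.bm_uncertainty):
            if u is not None and u <= 0:
                raise ValidationError("uncertainties must be > 0")


@dataclass
class StockInventory:
    """Two-date carbon-stock inventory (wood + soil) with lateral export losses."""

    time_start: float
    time_end: float
    wood_stock_start: float
    wood_stock_end: float
    soil_stock_start: float
    soil_stock_end: float
    lateral_losses: float = 0.0  # gC m-2 y-1 exported (harvest, DOC leaching)

    def check(self, site_id: str = "?") -> None:
        if self.time_end <= self.time_start:
            raise ValidationError(f"{site_id}: stock inventory interval must be positive")
        for name in ("wood_stock_start", "wood_stock_end", "soil_stock_start", "soil_stock_end"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{site_id}: {name} must be >= 0")


@dataclass
class ParsedSite:
    """One fully parsed site-table row."""

    site: SiteRecord
    methods: MethodProfile
    bm: BmComponents
    ec: EcFluxes
    stocks: Optional[StockInventory] = None
    extra: dict = field(default_factory=dict)  # unknown columns, preserved verbatim


# ---------------------------------------------------------------------------
# Column dictionary

REQUIRED_COLUMNS = (
    "site_id", "latitude", "longitude", "climate_zone", "years_measured",
    "data_quality", "nep_ec", "reco_ec", "gpp_ec", "ec_partitioning",
)

_SITE_NUMERIC = (
    "mean_annual_temperature", "mean_annual_precipitation", "lai",
    "elevation_variability", "topographical_slope",
)
_SITE_ENUM = {"fertility": Fertility, "leaf_type": LeafType, "leaf_habit": LeafHabit}
_SITE_INT = ("years_measured_ec", "years_measured_bm")

_METHOD_ENUM = {
    "fine_root_npp_method": FineRootNppMethod,
    "allometry_quality": AllometryQuality,
    "leaf_npp_method": LeafNppMethod,
    "soil_chamber": SoilChamber,
    "rh_soil_method": RhSoilMethod,
    "rsoil_model_drivers": RsoilDrivers,
    "rleaf_model_drivers": RDrivers,
    "rleaf_parameterization": RleafParameterization,
    "rwood_model_drivers": RDrivers,
    "rwood_scaling": RwoodScaling,
    "ec_partitioning": EcPartitioning,
}
_METHOD_BOOL = (
    "co2_scrubbing", "rh_cwd_considered", "rleaf_variable_q10",
    "light_inhibition_considered", "leaf_growth_respiration",
    "wood_growth_respiration", "branch_stem_separated",
    "npp_branch_turnover_measured", "npp_mycorrhiza_measured",
)

_STOCK_COLUMNS = (
    "time_start", "time_end", "wood_stock_start", "wood_stock_end",
    "soil_stock_start", "soil_stock_end", "lateral_losses",
)

OPTIONAL_COLUMNS = (
    tuple(_BM_FIELDS)
    + _SITE_NUMERIC + tuple(_SITE_ENUM) + _SITE_INT
    + tuple(k for k in _METHOD_ENUM if k != "ec_partitioning") + _METHOD_BOOL
    + _STOCK_COLUMNS
    + ("reco_ec_daytime", "gpp_ec_daytime")
)

_MISSING_TOKENS = {"", "na", "nan", "none"}


def _is_missing(v: Any) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip().lower() in _MISSING_TOKENS


def _to_float(v: Any, row: int, column: str) -> Optional[float]:
    if _is_missing(v):
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise RowParseError(row, column, v) from None


def _to_int(v: Any, row: int, column: str) -> Optional[int]:
    f = _to_float(v, row, column)
    if f is None:
        return None
    if abs(f - round(f)) > 1e-9:
        raise RowParseError(row, column, v)
    return int(round(f))


_TRUE_TOKENS = {"true", "yes", "y", "1", "1.0"}
_FALSE_TOKENS = {"false", "no", "n", "0", "0.0"}


def _to_bool(v: Any, row: int, column: str) -> Optional[bool]:
    if _is_missing(v):
        return None
    if isinstance(v, bool):
        return v
    token = str(v).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValidationError(f"row {row}: column {column!r}: {v!r} is not a boolean")


def _to_enum(cls, v: Any) -> Optional[_CIEnum]:
    if _is_missing(v):
        return None
    return cls.parse(v)


def infer_climate_zone(latitude: float, band: float = TROPICAL_LATITUDE_BAND) -> ClimateZone:
    """Latitude-band fallback when the site table does not state the zone."""
    if abs(latitude) < band:
        return ClimateZone.TROPICAL
    return ClimateZone.BOREAL if abs(latitude) >= 55.0 else ClimateZone.TEMPERATE


def read_site_table(
    path: str | Path,
    schema_config: Optional[Mapping[str, str]] = None,
) -> list[ParsedSite]:
    """Read and validate a site table CSV.

    Parameters
    ----------
    path
        CSV file, UTF-8, header row, one site per row.
    schema_config
        Optional mapping ``canonical column name -> column name in the file``
        used to re-map non-standard layouts.

    Raises
    ------
    SchemaError
        if a required column is absent (the message names it).
    RowParseError
        for unparseable numeric cells (carries the row index).
    ValidationError
        for unknown enum levels or broken hard invariants.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = dict(schema_config or {})
    if rename:
        # canonical <- file; invert for DataFrame.rename(columns=file->canonical)
        df = df.rename(columns={v: k for k, v in rename.items()})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path.name}")
    return [_parse_row(i, row) for i, row in enumerate(df.to_dict(orient="records"))]


def parse_dataframe(df: pd.DataFrame) -> list[ParsedSite]:
    """Parse an in-memory site table with the canonical column layout."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from DataFrame")
    return [_parse_row(i, row) for i, row in enumerate(df.to_dict(orient="records"))]


def _parse_row(i: int, row: Mapping[str, Any]) -> ParsedSite:
    site_id = str(row["site_id"]).strip()
    latitude = _to_float(row["latitude"], i, "latitude")
    if latitude is None:
        raise ValidationError(f"row {i}: latitude is required")
    zone_raw = row.get("climate_zone")
    zone = _to_enum(ClimateZone, zone_raw) or infer_climate_zone(latitude)
    years = _to_int(row["years_measured"], i, "years_measured")
    if years is None:
        raise ValidationError(f"row {i}: years_measured is required")
    quality = _to_enum(DataQuality, row["data_quality"])
    if quality is None:
        raise ValidationError(f"row {i}: data_quality is required")

    site = SiteRecord(
        site_id=site_id,
        latitude=latitude,
        longitude=_to_float(row["longitude"], i, "longitude") or 0.0,
        climate_zone=zone,
        years_measured=years,
        data_quality=quality,
    )
    for name in _SITE_NUMERIC:
        setattr(site, name, _to_float(row.get(name), i, name))
    for name, cls in _SITE_ENUM.items():
        setattr(site, name, _to_enum(cls, row.get(name)))
    for name in _SITE_INT:
        setattr(site, name, _to_int(row.get(name), i, name))
    site.check()

    methods = MethodProfile()
    for name, cls in _METHOD_ENUM.items():
        setattr(methods, name, _to_enum(cls, row.get(name)))
    for name in _METHOD_BOOL:
        setattr(methods, name, _to_bool(row.get(name), i, name))
    methods.check(site_id)

    bm = BmComponents(**{name: _to_float(row.get(name), i, name) for name in _BM_FIELDS})
    bm.check(site_id)

    nep_ec = _to_float(row["nep_ec"], i, "nep_ec")
    if nep_ec is None:
        raise ValidationError(f"row {i}: nep_ec is required")
    ec = EcFluxes(
        nep=nep_ec,
        reco=_to_float(row.get("reco_ec"), i, "reco_ec"),
        gpp=_to_float(row.get("gpp_ec"), i, "gpp_ec"),
        reco_daytime=_to_float(row.get("reco_ec_daytime"), i, "reco_ec_daytime"),
        gpp_daytime=_to_float(row.get("gpp_ec_daytime"), i, "gpp_ec_daytime"),
    )

    stocks = None
    stock_vals = {c: _to_float(row.get(c), i, c) for c in _STOCK_COLUMNS}
    if any(v is not None for c, v in stock_vals.items() if c != "lateral_losses"):
        core = {c: stock_vals[c] for c in _STOCK_COLUMNS if c != "lateral_losses"}
        if any(v is None for v in core.values()):
            missing = [c for c, v in core.items() if v is None]
            raise ValidationError(f"{site_id}: incomplete stock inventory (missing {missing})")
        stocks = StockInventory(**core, lateral_losses=stock_vals["lateral_losses"] or 0.0)
        stocks.check(site_id)

    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    extra = {k: v for k, v in row.items() if k not in known}
    return ParsedSite(site=site, methods=methods, bm=bm, ec=ec, stocks=stocks, extra=extra)


def write_site_table(records: Sequence[ParsedSite], path: str | Path) -> None:
    """Write records back to the canonical CSV layout (round-trip safe)."""
    rows = []
    for rec in records:
        row: dict[str, Any] = {}
        s = rec.site
        row.update(
            site_id=s.site_id, latitude=s.latitude, longitude=s.longitude,
            climate_zone=str(s.climate_zone), years_measured=s.years_measured,
            data_quality=str(s.data_quality),
        )
        row.update(nep_ec=rec.ec.nep, reco_ec=rec.ec.reco, gpp_ec=rec.ec.gpp,
                   reco_ec_daytime=rec.ec.reco_daytime, gpp_ec_daytime=rec.ec.gpp_daytime)
        for name in _SITE_NUMERIC + _SITE_INT:
            row[name] = getattr(s, name)
        for name in _SITE_ENUM:
            v = getattr(s, name)
            row[name] = str(v) if v is not None else None
        for name in _METHOD_ENUM:
            v = getattr(rec.methods, name)
            row[name] = str(v) if v is not None else None
        for name in _METHOD_BOOL:
            row[name] = getattr(rec.methods, name)
        for name in _BM_FIELDS:
            row[name] = getattr(rec.bm, name)
        if rec.stocks is not None:
            for f in dc_fields(rec.stocks):
                row[f.name] = getattr(rec.stocks, f.name)
        row.update(rec.extra)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)


@dataclass
class ValidationIssue:
    site_id: str
    severity: str  # "warning" | "error"
    field: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps([vars(i) for i in self.issues], indent=2)


def validate_dataset(records: Iterable[ParsedSite]) -> ValidationReport:
    """Plausibility screen of parsed records; returns a report, never raises.

    Values outside the study-wide plausibility windows are flagged as
    warnings; hard invariant violations (negative components, impossible
    Rsoil partition) are reported as errors.
    """
    report = ValidationReport()

    def add(site_id, severity, fld, msg):
        report.issues.append(ValidationIssue(site_id, severity, fld, msg))

    for rec in records:
        sid = rec.site.site_id
        for kind, value, fld in (
            ("NEP", rec.ec.nep, "nep_ec"),
            ("Reco", rec.ec.reco, "reco_ec"),
            ("GPP", rec.ec.gpp, "gpp_ec"),
        ):
            if value is None:
                continue
            lo, hi = PLAUSIBILITY_WINDOWS[kind]
            if not (lo <= value <= hi):
                add(sid, "warning", fld,
                    f"{kind} = {value} gC m-2 y-1 outside plausibility window [{lo}, {hi}]")
        try:
            rec.bm.check(sid)
        except ValidationError as e:
            add(sid, "error", "bm_components", str(e))
        bm = rec.bm
        if bm.rsoil is not None and bm.rroot is not None and bm.rh_soil is None:
            if bm.rsoil < bm.rroot - RSOIL_PARTITION_TOL:
                add(sid, "error", "rsoil",
                    f"rsoil ({bm.rsoil}) < rroot ({bm.rroot}): partition impossible")
        try:
            rec.site.check()
        except ValidationError as e:
            add(sid, "error", "site", str(e))
        try:
            rec.methods.check(sid)
        except ValidationError as e:
            add(sid, "error", "methods", str(e))
        if rec.stocks is not None:
            try:
                rec.stocks.check(sid)
            except ValidationError as e:
                add(sid, "error", "stocks", str(e))
    return report
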