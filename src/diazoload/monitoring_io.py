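"""Reading, validation and genus-level harmonisation of plankton monitoring tables.

National marine monitoring programmes distribute phytoplankton observations as
long-format delimited text: one row per taxon per depth-integrated tube sample,
with biovolume (mm³ L⁻¹) computed from cell counts and cell geometry, and
optionally carbon biomass (µg C L⁻¹) and an autotroph-group label. This module
turns such exports into a tidy internal table with exactly one row per
(station, sampling event, genus), where species- and size-class-level records
of the three diazotrophic genera (*Aphanizomenon*, *Dolichospermum*,
*Nodularia*) are rolled up by summation and everything else is retained under
the catch-all label ``other``.

It also applies the per-station tube-depth correction: stations sampled with a
0–20 m integrating tube underestimate the 0–10 m biovolume of near-surface
filamentous cyanobacteria by roughly a factor of two, so their biovolumes (and
carbon) are multiplied by a configured factor (2 for 0–20 m tubes, 1 for
0–10 m tubes).
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: The three heterocystous, bloom-forming genera that dominate pelagic N2
#: fixation in the Baltic Sea.
DIAZOTROPH_GENERA = ("Aphanizomenon", "Dolichospermum", "Nodularia")

#: Canonical label for every taxon that is not one of the diazotroph genera.
OTHER_TAXON = "other"

#: Autotroph group labels used by the carbon-fraction summaries.
GROUP_CYANO = "cyanobacteria_filamentous"
GROUP_DIATOMS = "diatoms"
GROUP_FLAGELLATES = "flagellates_other"

# Genus-level aliases, lower-cased first word of the scientific name.
# Dolichospermum was split out of Anabaena, and older exports still use the
# latter name.
_GENUS_ALIASES = {
    "aphanizomenon": "Aphanizomenon",
    "dolichospermum": "Dolichospermum",
    "anabaena": "Dolichospermum",
    "nodularia": "Nodularia",
}

#: Default column-name mapping (internal field -> export header). Matches the
#: headers written by :func:`write_monitoring_table`; SHARK-style exports with
#: different headers are handled by passing a custom ``schema``.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "station": "station_name",
    "date": "sample_date",
    "depth_top": "sample_min_depth_m",
    "depth_bottom": "sample_max_depth_m",
    "taxon": "scientific_name",
    "biovolume": "biovolume_mm3_per_l",
    "carbon": "carbon_ug_per_l",
    "group": "trophic_group",
}

_REQUIRED_FIELDS = ("station", "date", "depth_top", "depth_bottom", "taxon", "biovolume")
_OPTIONAL_FIELDS = ("carbon", "group")

#: Canonical column order of the tidy internal table.
CANONICAL_COLUMNS = list(_REQUIRED_FIELDS) + list(_OPTIONAL_FIELDS)


@dataclasses.dataclass(frozen=True)
class MonitoringSample:
    """One genus' biovolume in one depth-integrated tube sample.

    ``biovolume_raw``/``carbon_raw`` hold the pre-correction values after
    :func:`apply_depth_correction` so the adjustment stays auditable.
    """

    station: str
    date: datetime.date
    depth_top: float
    depth_bottom: float
    taxon: str
    biovolume: float
    carbon: float | None = None
    group: str | None = None
    biovolume_raw: float | None = None
    carbon_raw: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.biovolume) or self.biovolume < 0:
            raise ValidationError(
                f"biovolume must be finite and >= 0, got {self.biovolume!r}"
            )
        if not self.depth_bottom > self.depth_top:
            raise ValidationError(
                f"depth_bottom ({self.depth_bottom}) must exceed depth_top ({self.depth_top})"
            )
        if self.carbon is not None and self.carbon < 0:
            raise ValidationError(f"carbon must be >= 0, got {self.carbon!r}")


@dataclasses.dataclass(frozen=True)
class StationConfig:
    """Station metadata: basin membership, tube interval and depth correction.

    When ``depth_correction`` is not given it defaults to 2 for a 0–20 m tube
    and 1 otherwise, encoding the convention that filamentous cyanobacteria
    occur almost entirely above ~10 m, so a 0–20 m integrated concentration is
    about half the 0–10 m one.
    """

    station: str
    basin: str
    tube_top: float = 0.0
    tube_bottom: float = 10.0
    depth_correction: float | None = None

    def __post_init__(self):
        if self.depth_correction is None:
            corr = 2.0 if (self.tube_top, self.tube_bottom) == (0.0, 20.0) else 1.0
            object.__setattr__(self, "depth_correction", corr)
        if not self.depth_correction > 0:
            raise ConfigurationError(
                f"depth_correction must be > 0, got {self.depth_correction}"
            )
        if not self.tube_bottom > self.tube_top:
            raise ConfigurationError(
                f"tube interval ({self.tube_top}, {self.tube_bottom}) is empty"
            )


def canonical_genus(name: str) -> str:
    """Map a scientific name to its canonical diazotroph genus, or ``other``.

    Matching is on the lower-cased first word, so species- and size-class
    labels like ``"Nodularia spumigena"`` or ``"Aphanizomenon flos-aquae"``
    roll up to their genus. Unrecognised taxa become :data:`OTHER_TAXON`.
    """
    if not isinstance(name, str) or not name.strip():
        return OTHER_TAXON
    first = name.strip().split()[0].lower()
    return _GENUS_ALIASES.get(first, OTHER_TAXON)


def _coerce_dataframe(raw: pd.DataFrame, schema: Mapping[str, str]) -> pd.DataFrame:
    """Rename export headers to internal names and coerce dtypes, collecting
    per-row validation issues."""
    missing = [schema[f] for f in _REQUIRED_FIELDS if schema[f] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"monitoring table is missing mandatory column(s): {missing}"
        )
    inverse = {v: k for k, v in schema.items() if v in raw.columns}
    df = raw.rename(columns=inverse)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]].copy()
    for opt in _OPTIONAL_FIELDS:
        if opt not in df.columns:
            df[opt] = np.nan

    issues: list[tuple[int, str]] = []

    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    for idx in df.index[dates.isna() & df["date"].notna()]:
        issues.append((int(idx), f"unparseable date {df.loc[idx, 'date']!r}"))
    for idx in df.index[df["date"].isna()]:
        issues.append((int(idx), "missing date"))
    df["date"] = dates

    for col in ("depth_top", "depth_bottom", "biovolume", "carbon"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        for idx in df.index[bad]:
            issues.append((int(idx), f"non-numeric {col} {df.loc[idx, col]!r}"))
        df[col] = vals.astype(float)

    for col in ("depth_top", "depth_bottom", "biovolume"):
        for idx in df.index[df[col].isna()]:
            issues.append((int(idx), f"missing {col}"))

    neg = df["biovolume"] < 0
    for idx in df.index[neg.fillna(False)]:
        issues.append((int(idx), f"negative biovolume {df.loc[idx, 'biovolume']}"))
    negc = df["carbon"] < 0
    for idx in df.index[negc.fillna(False)]:
        issues.append((int(idx), f"negative carbon {df.loc[idx, 'carbon']}"))
    shallow = df["depth_bottom"] <= df["depth_top"]
    for idx in df.index[shallow.fillna(False)]:
        issues.append((int(idx), "depth_bottom must exceed depth_top"))

    if issues:
        issues.sort()
        raise ValidationError("invalid monitoring rows", issues=issues)
    return df


def roll_up_genera(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate species/size-class rows to genus level.

    Biovolume (and carbon) of rows sharing (station, date, depth interval,
    genus, group) are summed — they are partitions of one and the same tube
    sample, so summation conserves total biovolume. Rows whose taxon is not a
    recognised diazotroph genus keep their group label and are pooled under
    ``other`` (the carbon-fraction summaries need them; the fixation estimate
    ignores them).
    """
    if df.empty:
        return df.reindex(columns=CANONICAL_COLUMNS)
    out = df.copy()
    out["taxon"] = out["taxon"].map(canonical_genus)
    key_group = out["group"].fillna("")
    grouped = (
        out.assign(_group=key_group)
        .groupby(["station", "date", "depth_top", "depth_bottom", "taxon", "_group"],
                 as_index=False, sort=True)
        .agg(biovolume=("biovolume", "sum"), carbon=("carbon", lambda s: s.sum(min_count=1)))
    )
    grouped["group"] = grouped.pop("_group").where(lambda s: s != "", np.nan)
    return grouped[CANONICAL_COLUMNS]


def read_monitoring_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited monitoring export into the tidy internal table.

    Parameters
    ----------
    path
        Delimited text file (comma or tab separated; autodetected when
        ``sep`` is ``None``), UTF-8, one row per taxon observation.
    schema
        Partial override of :data:`DEFAULT_SCHEMA`, mapping internal field
        names to the file's column headers.
    sep
        Explicit field separator; by default sniffed by pandas.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`CANONICAL_COLUMNS`, one row per
        (station, date, depth interval, genus, group), species rolled up.

    Raises
    ------
    ConfigurationError
        If the file or a mandatory mapped column is missing.
    ValidationError
        If any row has a negative biovolume, an unparseable date or number,
        or an empty depth interval; every offending row is reported.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"monitoring table not found: {path}")
    full_schema = dict(DEFAULT_SCHEMA)
    if schema:
        full_schema.update(schema)
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if raw.empty:
        _coerce_dataframe(raw, full_schema)  # still enforce mandatory headers
        return pd.DataFrame(columns=CANONICAL_COLUMNS)
    df = _coerce_dataframe(raw, full_schema)
    return roll_up_genera(df)


def write_monitoring_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy internal table back to CSV using the default headers,
    such that :func:`read_monitoring_table` round-trips it."""
    out = df.reindex(columns=CANONICAL_COLUMNS).copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out = out.rename(columns=DEFAULT_SCHEMA)
    out.to_csv(path, index=False)


def apply_depth_correction(sample: MonitoringSample, cfg: StationConfig) -> MonitoringSample:
    """Scale one sample's biovolume (and carbon) by the station's tube-depth
    correction, keeping the original values for audit."""
    if cfg.station != sample.station:
        raise ConfigurationError(
            f"station mismatch: sample {sample.station!r} vs config {cfg.station!r}"
        )
    return dataclasses.replace(
        sample,
        biovolume=sample.biovolume * cfg.depth_correction,
        carbon=None if sample.carbon is None else sample.carbon * cfg.depth_correction,
        biovolume_raw=sample.biovolume,
        carbon_raw=sample.carbon,
    )


def correct_depth_table(
    df: pd.DataFrame, stations: Mapping[str, StationConfig]
) -> pd.DataFrame:
    """Vectorised :func:`apply_depth_correction` over a tidy table.

    Adds ``biovolume_raw``/``carbon_raw`` columns and replaces ``biovolume``
    and ``carbon`` by their corrected values. Every station appearing in the
    table must be configured.
    """
    if df.empty:
        out = df.copy()
        out["biovolume_raw"] = pd.Series(dtype=float)
        out["carbon_raw"] = pd.Series(dtype=float)
        return out
    unknown = sorted(set(df["station"]) - set(stations))
    if unknown:
        raise ConfigurationError(f"no station configuration for: {unknown}")
    corr = df["station"].map({k: v.depth_correction for k, v in stations.items()})
    out = df.copy()
    out["biovolume_raw"] = out["biovolume"]
    out["carbon_raw"] = out["carbon"] if "carbon" in out else np.nan
    out["biovolume"] = out["biovolume"] * corr
    if "carbon" in out:
        out["carbon"] = out["carbon"] * corr
    return out


def sampling_count_table(df: pd.DataFrame, stations: Sequence[str] | None = None) -> pd.DataFrame:
    """Count distinct sampling events per station and calendar month.

    An event is a distinct (station, date) pair, pooled across all years —
    the layout used to document per-month sampling effort of a monitoring
    programme. Returns a 12-row frame indexed by month with one column per
    station (all zeros for months/stations never sampled).
    """
    if stations is None:
        stations = sorted(df["station"].unique()) if not df.empty else []
    months = pd.Index(range(1, 13), name="month")
    if df.empty:
        return pd.DataFrame(0, index=months, columns=list(stations))
    events = df[["station", "date"]].drop_duplicates()
    counts = (
        events.assign(month=pd.to_datetime(events["date"]).dt.month)
        .groupby(["month", "station"])
        .size()
        .unstack(fill_value=0)
    )
    return counts.reindex(index=months, columns=list(stations), fill_value=0).astype(int)


def samples_to_frame(samples: Sequence[MonitoringSample]) -> pd.DataFrame:
    """Convert record objects to the tidy DataFrame the pipeline operates on."""
    if not samples:
        return pd.DataFrame(columns=CANONICAL_COLUMNS)
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples])
    df["date"] = pd.to_datetime(df["date"])
    return df[CANONICAL_COLUMNS]
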