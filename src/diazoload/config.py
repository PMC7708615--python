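"""Loading and validation of the station/basin/load configuration file.

The configuration is a single YAML document mapping stations to basins and
tube intervals, basins to areas, pooling widths and allowable limits, and
basins to external nitrogen-input series. A default file for the Baltic Sea
ships with the package (``data/baltic_defaults.yaml``).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .estimation import BasinConfig
from .exceptions import ConfigurationError
from .loads import ExternalLoad
from .monitoring_io import StationConfig


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Parsed configuration: stations, basins, external loads, extra areas."""

    stations: dict[str, StationConfig]
    basins: dict[str, BasinConfig]
    external: tuple[ExternalLoad, ...]
    extrapolation_areas_km2: dict[str, float]


def default_config_path() -> Path:
    return Path(resources.files("diazoload").joinpath("data/baltic_defaults.yaml"))


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Parse a basin/station/load YAML file (package default when ``path``
    is None)."""
    path = default_config_path() if path is None else Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    for key in ("stations", "basins"):
        if key not in doc:
            raise ConfigurationError(f"configuration {path} lacks section {key!r}")

    stations: dict[str, StationConfig] = {}
    for sid, spec in doc["stations"].items():
        tube = spec.get("tube", [0, 10])
        stations[sid] = StationConfig(
            station=sid,
            basin=spec["basin"],
            tube_top=float(tube[0]),
            tube_bottom=float(tube[1]),
            depth_correction=spec.get("depth_correction"),
        )

    basins: dict[str, BasinConfig] = {}
    limits: dict[str, float | None] = {}
    for name, spec in doc["basins"].items():
        members = tuple(s for s, st in stations.items() if st.basin == name)
        if not members:
            raise ConfigurationError(f"basin {name!r} has no member stations")
        basins[name] = BasinConfig(
            name=name,
            area_km2=float(spec["area_km2"]),
            stations=members,
            pooling_years=int(spec.get("pooling_years", 1)),
        )
        limits[name] = spec.get("allowable_limit_kt")

    external: list[ExternalLoad] = []
    for basin, entries in (doc.get("external_inputs") or {}).items():
        if basin not in basins:
            raise ConfigurationError(f"external input for unknown basin {basin!r}")
        for entry in entries:
            external.append(
                ExternalLoad(
                    basin=basin,
                    period=tuple(int(y) for y in entry["period"]),
                    external_input=float(entry["total_kt_per_year"]),
                    allowable_limit=limits.get(basin),
                )
            )

    areas = {
        k: float(v) for k, v in (doc.get("extrapolation_areas_km2") or {}).items()
    }
    return PipelineConfig(
        stations=stations,
        basins=basins,
        external=tuple(external),
        extrapolation_areas_km2=areas,
    )
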