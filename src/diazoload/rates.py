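"""Genera-specific N2 fixation rates per unit biovolume.

Single-cell isotope-tracer measurements yield fixation per cell
(fmol N cell⁻¹ day⁻¹). Dividing by the genus' mean cell volume (µm³) gives a
rate per biovolume, and the unit identity

    1 fmol N cell⁻¹ day⁻¹ / 1 µm³  =  1 µmol N mm⁻³ day⁻¹

makes that number directly multiplicable with monitoring biovolumes in
mm³ L⁻¹ (the product is in µmol N L⁻¹ day⁻¹ = mmol N m⁻³ day⁻¹).

:func:`default_rates` pins the summer-mean (June–August) per-biovolume rates
for the three Baltic diazotroph genera derived from several thousand
single-cell measurements; they sit comfortably inside the 0.45–1.3
µmol mm⁻³ day⁻¹ envelope of independently published Baltic rates.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, ValidationError


@dataclasses.dataclass(frozen=True)
class GenusRate:
    """Per-biovolume fixation rate of one genus.

    rate and se are in µmol N mm⁻³ day⁻¹; n_cells is the number of
    single-cell measurements behind the mean.
    """

    taxon: str
    rate: float
    se: float
    n_cells: int

    def __post_init__(self):
        if not (math.isfinite(self.rate) and self.rate >= 0):
            raise ValidationError(f"rate must be finite and >= 0, got {self.rate!r}")
        if self.se < 0:
            raise ValidationError(f"se must be >= 0, got {self.se!r}")
        if self.n_cells <= 0:
            raise ValidationError(f"n_cells must be > 0, got {self.n_cells!r}")


@dataclasses.dataclass(frozen=True)
class CellMeasurement:
    """One single-cell fixation measurement: fmol N cell⁻¹ day⁻¹ and µm³."""

    taxon: str
    cell_rate: float
    cell_volume: float

    def __post_init__(self):
        if self.cell_rate < 0:
            raise ValidationError(f"cell_rate must be >= 0, got {self.cell_rate!r}")
        if not self.cell_volume > 0:
            raise ValidationError(f"cell_volume must be > 0, got {self.cell_volume!r}")


def normalize_cell_rate(
    cells: Sequence[CellMeasurement], mean_cell_volume: float
) -> GenusRate:
    """Convert single-cell rates to a per-biovolume genus rate.

    rate = mean(cell rates) / mean cell volume, se = SE(cell rates) / mean
    cell volume (sample standard deviation, n−1 denominator; 0 when only one
    cell was measured). Thanks to the fmol-per-µm³ unit identity the result
    is already in µmol N mm⁻³ day⁻¹.
    """
    if not cells:
        raise ValidationError("need at least one cell measurement")
    if not mean_cell_volume > 0:
        raise ValidationError(f"mean_cell_volume must be > 0, got {mean_cell_volume!r}")
    taxa = {c.taxon for c in cells}
    if len(taxa) > 1:
        raise ValidationError(f"cell measurements mix taxa: {sorted(taxa)}")
    n = len(cells)
    vals = [c.cell_rate for c in cells]
    mean = sum(vals) / n
    if n > 1:
        var = sum((v - mean) ** 2 for v in vals) / (n - 1)
        se = math.sqrt(var / n)
    else:
        se = 0.0
    return GenusRate(
        taxon=cells[0].taxon,
        rate=mean / mean_cell_volume,
        se=se / mean_cell_volume,
        n_cells=n,
    )


#: Summer-mean per-biovolume fixation rates (µmol N mm⁻³ day⁻¹, mean ± SE)
#: and single-cell sample sizes for the three Baltic genera.
_DEFAULT_RATE_ROWS = (
    ("Aphanizomenon", 0.66, 0.11, 1227),
    ("Nodularia", 0.68, 0.14, 1129),
    ("Dolichospermum", 1.20, 0.25, 1640),
)


def default_rates() -> dict[str, GenusRate]:
    """The default genus → rate mapping (exactly three genera)."""
    return {
        taxon: GenusRate(taxon=taxon, rate=r, se=se, n_cells=n)
        for taxon, r, se, n in _DEFAULT_RATE_ROWS
    }


def load_rates_csv(path: str | Path) -> dict[str, GenusRate]:
    """Load rates from a small CSV with columns taxon, rate, se, n_cells,
    so empirical rates from other campaigns can be substituted."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"rates file not found: {path}")
    df = pd.read_csv(path)
    required = {"taxon", "rate", "se", "n_cells"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"rates file {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, GenusRate] = {}
    for _, row in df.iterrows():
        gr = GenusRate(
            taxon=str(row["taxon"]),
            rate=float(row["rate"]),
            se=float(row["se"]),
            n_cells=int(row["n_cells"]),
        )
        if gr.taxon in out:
            raise ValidationError(f"duplicate taxon in rates file: {gr.taxon}")
        out[gr.taxon] = gr
    return out


def write_rates_csv(rates: Mapping[str, GenusRate], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in rates.values()]).to_csv(path, index=False)
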