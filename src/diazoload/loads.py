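"""Internal vs external nitrogen loads and cross-basin extrapolation.

Internal loads (from N2 fixation, computed by :mod:`diazoload.estimation`)
are compared against externally supplied figures: total external nitrogen
input (rivers + direct point sources + atmospheric deposition) and the
maximum allowable input per basin under the Baltic Sea Action Plan. Both are
treated strictly as configuration inputs — this package does not recompute
them.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .estimation import AnnualLoad
from .exceptions import ValidationError


@dataclasses.dataclass(frozen=True)
class ExternalLoad:
    """External nitrogen input and allowable limit for one basin and period.

    ``period`` is an inclusive (first_year, last_year) span; values in
    kt N yr⁻¹.
    """

    basin: str
    period: tuple[int, int]
    external_input: float
    allowable_limit: float | None = None

    def __post_init__(self):
        if self.external_input < 0:
            raise ValidationError(f"external input must be >= 0, got {self.external_input}")
        if self.allowable_limit is not None and self.allowable_limit < 0:
            raise ValidationError(f"allowable limit must be >= 0, got {self.allowable_limit}")
        object.__setattr__(self, "period", tuple(self.period))


@dataclasses.dataclass(frozen=True)
class LoadComparison:
    """Internal + external load against the allowable limit, kt N yr⁻¹."""

    basin: str
    internal: float
    external: float
    total: float
    allowable_limit: float | None
    ratio: float | None  # total / allowable_limit
    exceeds_limit: bool


def compare_loads(internal: AnnualLoad, external: ExternalLoad) -> LoadComparison:
    """Combine an estimated internal load with a configured external input.

    total = internal + external exactly; ``exceeds_limit`` is True when the
    total exceeds the allowable limit (False when no limit is configured).
    """
    if internal.basin != external.basin:
        raise ValidationError(
            f"basin mismatch: internal {internal.basin!r} vs external {external.basin!r}"
        )
    total = internal.load + external.external_input
    limit = external.allowable_limit
    ratio = None if limit in (None, 0) else total / limit
    return LoadComparison(
        basin=internal.basin,
        internal=internal.load,
        external=external.external_input,
        total=total,
        allowable_limit=limit,
        ratio=ratio,
        exceeds_limit=bool(limit is not None and total > limit),
    )


def extrapolate_to_area(
    source: AnnualLoad | float, source_area_km2: float, target_area_km2: float
) -> float:
    """Scale a basin load to another basin's surface area (kt N yr⁻¹).

    Assumes the source basin's areal fixation rate applies uniformly to the
    target area: load × target_area / source_area.
    """
    if not source_area_km2 > 0 or not target_area_km2 > 0:
        raise ValidationError(
            f"areas must be > 0, got source {source_area_km2}, target {target_area_km2}"
        )
    load = source.load if isinstance(source, AnnualLoad) else float(source)
    return load * target_area_km2 / source_area_km2


def pick_external(
    series: Sequence[ExternalLoad], basin: str, years: Sequence[int] | None = None
) -> ExternalLoad:
    """Select the external-load entry for a basin whose period best overlaps
    ``years`` (largest overlap; latest period on ties). With no ``years`` the
    widest period wins."""
    cands = [e for e in series if e.basin == basin]
    if not cands:
        raise ValidationError(f"no external load configured for basin {basin!r}")
    if years:
        yrs = set(int(y) for y in years)

        def score(e: ExternalLoad):
            span = set(range(e.period[0], e.period[1] + 1))
            # most overlap first, then the tightest period, then the latest
            return (len(span & yrs), -len(span - yrs), e.period[1])
    else:
        def score(e: ExternalLoad):
            return (e.period[1] - e.period[0], e.period[1])
    return max(cands, key=score)
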