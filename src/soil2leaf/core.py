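"""Measurement data model, CSV I/O, site-level and grand summaries.

The whole pipeline consumes one long-format table of records keyed by
(site, tree, compartment, analyte). Summaries keep full precision; rounding
to printed decimals happens only in report rendering.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Compartment",
    "MeasurementTable",
    "SiteSummary",
    "GrandSummary",
    "ThresholdConfig",
    "ValidationError",
    "load_measurements",
    "summarize_sites",
    "grand_summary",
    "star_code",
    "round_half_up",
]

LONG_COLUMNS = ["site_id", "tree_id", "compartment", "analyte", "value", "units"]
KEY_COLUMNS = ["site_id", "tree_id", "compartment", "analyte"]


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


class Compartment(str, enum.Enum):
    LEAF = "leaf"
    SOIL = "soil"


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, as printed tables do.

    ``round()`` uses banker's rounding (0.1875 -> 0.18 at 2 decimals), which
    disagrees with every printed mean that ends in a 5.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SiteSummary:
    """Per-site, per-analyte mean and SEM (sample sd / sqrt(n), ddof=1)."""

    site_id: str
    analyte: str
    mean: float
    sem: float | None  # None when n == 1 (SEM undefined)
    n: int
    sig_code: str = "ns"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.sem is not None and self.sem < 0:
            raise ValidationError("sem must be non-negative")


@dataclass(frozen=True)
class GrandSummary:
    """Across-site roll-up of one analyte: unweighted mean of site means."""

    analyte: str
    grand_mean: float
    min_site: tuple[str, float]
    max_site: tuple[str, float]
    n_sites: int

    def __post_init__(self) -> None:
        if not (self.min_site[1] <= self.grand_mean <= self.max_site[1]):
            raise ValidationError(
                "grand mean must lie between min and max site means"
            )


@dataclass(frozen=True)
class ThresholdConfig:
    """A named regulatory limit for an element (mg/kg dry weight)."""

    element: str
    limit: float
    basis: str = ""

    def __post_init__(self) -> None:
        if not self.limit > 0:
            raise ValidationError(f"limit must be positive, got {self.limit}")


@dataclass
class MeasurementTable:
    """Long-format measurement records with unique keys and consistent units.

    ``data`` holds columns site_id, tree_id, compartment, analyte, value,
    units.  Missing values are NaN; sentinel numbers are never used.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=LONG_COLUMNS))

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        df = df[LONG_COLUMNS].reset_index(drop=True)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        bad_compartment = set(df["compartment"]) - {c.value for c in Compartment}
        if bad_compartment:
            raise ValidationError(f"unknown compartments: {sorted(bad_compartment)}")
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, KEY_COLUMNS].drop_duplicates().to_records(index=False).tolist()
            )
            raise ValidationError(f"duplicate measurement keys: {offenders}")
        finite = df["value"].dropna()
        if not ((finite > float("-inf")) & (finite < float("inf"))).all():
            raise ValidationError("values must be finite or NaN")
        if (finite < 0).any():
            raise ValidationError("concentration values must be non-negative")
        units = df.dropna(subset=["units"]).groupby(["analyte", "compartment"])["units"].nunique()
        mixed = units[units > 1]
        if not mixed.empty:
            raise ValidationError(
                f"inconsistent units within analyte/compartment: {mixed.index.tolist()}"
            )
        self.data = df

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "MeasurementTable":
        return cls(pd.DataFrame(list(records), columns=LONG_COLUMNS))

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site_id"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self.data["analyte"].unique())

    def select(self, analyte: str | None = None, compartment: str | None = None) -> pd.DataFrame:
        df = self.data
        if analyte is not None:
            df = df[df["analyte"] == analyte]
        if compartment is not None:
            comp = Compartment(compartment).value
            df = df[df["compartment"] == comp]
        return df

    def values_for(self, analyte: str, compartment: str) -> pd.Series:
        """Tree-level values indexed by (site_id, tree_id)."""
        df = self.select(analyte, compartment)
        return df.set_index(["site_id", "tree_id"])["value"]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        # 17 significant digits: lossless float round-trip through text
        out["value"] = out["value"].map(lambda v: "" if pd.isna(v) else format(v, ".17g"))
        out.to_csv(path, index=False)

    def concat(self, other: "MeasurementTable") -> "MeasurementTable":
        return MeasurementTable(pd.concat([self.data, other.data], ignore_index=True))


def load_measurements(
    path: str | Path,
    layout: str = "long",
    units_map: Mapping[str, str] | None = None,
) -> MeasurementTable:
    """Read a CSV in long or wide layout into a validated table.

    Wide layout has one row per site x tree (columns ``site_id``, ``tree_id``,
    optionally ``compartment``, then one column per analyte) and is melted to
    long form; units come from ``units_map`` (analyte -> unit string).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "long":
        try:
            df = pd.read_csv(
                path, dtype={"site_id": str, "tree_id": str},
                float_precision="round_trip",
            )
        except ValueError as exc:
            raise ValidationError(f"parse error in {path}: {exc}") from exc
        return MeasurementTable(df)
    if layout != "wide":
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, dtype={"site_id": str, "tree_id": str})
    id_vars = [c for c in ("site_id", "tree_id", "compartment") if c in df.columns]
    if "site_id" not in id_vars or "tree_id" not in id_vars:
        raise ValidationError("wide layout requires site_id and tree_id columns")
    long = df.melt(id_vars=id_vars, var_name="analyte", value_name="value")
    for col, (i, row) in zip(long["value"], long.iterrows()):
        if not pd.isna(col) and not isinstance(col, (int, float)):
            try:
                float(col)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric cell at row {i}, analyte {row['analyte']!r}: {col!r}"
                ) from None
    long["value"] = pd.to_numeric(long["value"])
    if "compartment" not in long.columns:
        long["compartment"] = Compartment.LEAF.value
    long["units"] = long["analyte"].map(units_map or {})
    return MeasurementTable(long[LONG_COLUMNS])


def summarize_sites(
    table: MeasurementTable, analyte: str, compartment: str = "leaf"
) -> list[SiteSummary]:
    """One mean/SEM summary per site for a single analyte."""
    df = table.select(analyte, compartment).dropna(subset=["value"])
    if df.empty:
        raise ValidationError(f"no {compartment} measurements for analyte {analyte!r}")
    out: list[SiteSummary] = []
    for site, grp in df.groupby("site_id", sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sd = float(vals.std(ddof=1))
            sem = sd / math.sqrt(n)
        else:
            sem = None  # undefined, never reported as 0
        out.append(SiteSummary(site_id=str(site), analyte=analyte, mean=mean, sem=sem, n=n))
    return out


def grand_summary(summaries: Sequence[SiteSummary]) -> GrandSummary:
    """Unweighted mean of site means with min/max site identification.

    Ties for the extreme sites are broken by lexicographic site id so output
    is deterministic.
    """
    if not summaries:
        raise ValidationError("no site summaries supplied")
    analytes = {s.analyte for s in summaries}
    if len(analytes) != 1:
        raise ValidationError(f"mixed analytes in grand summary: {sorted(analytes)}")
    ordered = sorted(summaries, key=lambda s: s.site_id)
    means = [s.mean for s in ordered]
    gmean = sum(means) / len(means)
    lo = min(ordered, key=lambda s: (s.mean, s.site_id))
    max_mean = max(means)
    hi = next(s for s in ordered if s.mean == max_mean)  # first in site_id order
    return GrandSummary(
        analyte=analytes.pop(),
        grand_mean=gmean,
        min_site=(lo.site_id, lo.mean),
        max_site=(hi.site_id, hi.mean),
        n_sites=len(ordered),
    )


def star_code(p: float) -> str:
    """Map a p-value to its significance code: ``***``, ``**``, ``*`` or ``ns``.

    Boundaries are strict: p = 0.05 is ``ns``.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
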