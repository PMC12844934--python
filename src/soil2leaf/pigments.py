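"""Chlorophyll quantification from methanol-extract absorbances.

Linear two-wavelength equations (Lichtenthaler coefficients for methanol
extracts)::

    chl_a = 16.82 * A665.2 - 9.28 * A652.4
    chl_b = 36.92 * A652.4 - 16.54 * A665.2

Pigments are in ug/g FW; the a/b ratio is dimensionless and defined only for
chl_b > 0. Negative computed pigments are returned with a flag rather than
clamped — the equations are linear and clamping would hide bad readings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CHL_A_COEF",
    "CHL_B_COEF",
    "PigmentReading",
    "PigmentResult",
    "compute_pigments",
    "compute_pigments_batch",
]

# (coefficient on A665.2, coefficient on A652.4)
CHL_A_COEF = (16.82, -9.28)
CHL_B_COEF = (-16.54, 36.92)


@dataclass(frozen=True)
class PigmentReading:
    a665_2: float
    a652_4: float

    def __post_init__(self) -> None:
        for name in ("a665_2", "a652_4"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class PigmentResult:
    chl_a: float
    chl_b: float
    ratio: float | None  # None when chl_b <= 0
    implausible: bool = False  # a computed pigment was negative


def compute_pigments(reading: PigmentReading) -> PigmentResult:
    chl_a = CHL_A_COEF[0] * reading.a665_2 + CHL_A_COEF[1] * reading.a652_4
    chl_b = CHL_B_COEF[0] * reading.a665_2 + CHL_B_COEF[1] * reading.a652_4
    ratio = chl_a / chl_b if chl_b > 0 else None
    return PigmentResult(
        chl_a=chl_a,
        chl_b=chl_b,
        ratio=ratio,
        implausible=(chl_a < 0 or chl_b < 0),
    )


def compute_pigments_batch(in_csv: str | Path, out_csv: str | Path) -> pd.DataFrame:
    """CSV batch mode: sample_id,a665_2,a652_4 -> adds chl_a,chl_b,ratio,flags."""
    df = pd.read_csv(in_csv)
    required = {"sample_id", "a665_2", "a652_4"}
    if not required.issubset(df.columns):
        raise ValueError(f"input must have columns {sorted(required)}")
    results = [
        compute_pigments(PigmentReading(r.a665_2, r.a652_4)) for r in df.itertuples()
    ]
    df["chl_a"] = [r.chl_a for r in results]
    df["chl_b"] = [r.chl_b for r in results]
    df["ratio"] = [r.ratio for r in results]
    df["flags"] = ["implausible" if r.implausible else "" for r in results]
    df.to_csv(out_csv, index=False)
    return df
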