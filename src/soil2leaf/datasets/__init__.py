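"""Packaged reference tables: published site-level summary fixtures.

Two CSVs ship with the package:

* ``tables_1_2_leaf_site_summaries.csv`` — per-site mean/SEM/significance for
  17 leaf analytes (macronutrients in %, micronutrients and trace metals in
  mg/kg, SPAD index, chlorophyll a/b in ug/g FW and their ratio) across the
  20 monitored orchard sites.
* ``table_3_baf_site_summaries.csv`` — per-site mean/SEM of the leaf/soil
  bioaccumulation factor for Cd, Cu, Ni, Pb, Zn, Fe and Mn.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..core import SiteSummary

__all__ = [
    "load_leaf_site_summaries",
    "load_baf_site_summaries",
    "leaf_summaries",
    "baf_summaries",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files(__package__).joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype={"site_id": str})


def load_leaf_site_summaries() -> pd.DataFrame:
    """Leaf site summaries as a DataFrame (site_id, analyte, mean, sem, n, sig, units)."""
    return _read("tables_1_2_leaf_site_summaries.csv")


def load_baf_site_summaries() -> pd.DataFrame:
    """BAF site summaries as a DataFrame (site_id, element, mean, sem, n)."""
    return _read("table_3_baf_site_summaries.csv")


def _to_summaries(df: pd.DataFrame, analyte_col: str, analyte: str) -> list[SiteSummary]:
    sub = df[df[analyte_col] == analyte]
    if sub.empty:
        raise KeyError(f"analyte {analyte!r} not in fixture")
    return [
        SiteSummary(
            site_id=r.site_id,
            analyte=analyte,
            mean=float(r.mean),
            sem=float(r.sem),
            n=int(r.n),
            sig_code=getattr(r, "sig", "ns"),
        )
        for r in sub.itertuples(index=False)
    ]


def leaf_summaries(analyte: str) -> list[SiteSummary]:
    """Site summaries for one leaf analyte from the packaged fixture."""
    return _to_summaries(load_leaf_site_summaries(), "analyte", analyte)


def baf_summaries(element: str) -> list[SiteSummary]:
    """Site summaries for one element's BAF from the packaged fixture."""
    return _to_summaries(load_baf_site_summaries(), "element", element)
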