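"""Bite-dimension records from gelatin cubes and the strike analysis table.

Each successful strike removes an approximately elliptical divot from a
standardized 15 mm gelatin cube; its length, width and depth are measured
with calipers and volume is length x width x depth.  Strikes are typed as
``edge``, ``corner``, ``scrape`` (jaws did not fully occlude) or ``miss``
(jaw contact without a mark).  Misses carry zero dimensions by default; a
config switch treats them as missing instead, and another excludes miss and
scrape rows entirely for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STRIKE_TYPES = ("edge", "corner", "scrape", "miss")
CUBE_EDGE_MM = 15.0  # gelatin cubes are 1.5 cm per side

DIMENSION_COLS = ("length_mm", "width_mm", "depth_mm")


class BiteError(ValueError):
    pass


def bite_volume(length_mm: float, width_mm: float, depth_mm: float) -> float:
    """Bite volume in mm^3 as the product of the three caliper dimensions."""
    dims = (length_mm, width_mm, depth_mm)
    if any(d < 0 for d in dims):
        raise BiteError(f"negative bite dimension in {dims}")
    return float(length_mm * width_mm * depth_mm)


@dataclass
class ValidationReport:
    n_rows: int
    issues: pd.DataFrame  # columns: strike_id, issue

    @property
    def n_issues(self) -> int:
        return len(self.issues)


def validate_bites(
    table: pd.DataFrame, *, miss_as_missing: bool = False
) -> tuple[pd.DataFrame, ValidationReport]:
    """Normalize and validate a bite table; never silently drops rows.

    Strike types are lower-cased/stripped; dimensions are bounded by the
    15 mm cube edge; misses get volume 0 (or NaN dimensions when
    ``miss_as_missing``).  Violations are listed in the report.
    """
    df = table.copy()
    issues: list[dict] = []
    df["strike_type"] = df["strike_type"].astype(str).str.strip().str.lower()
    for sid, st in zip(df["strike_id"], df["strike_type"]):
        if st not in STRIKE_TYPES:
            issues.append({"strike_id": sid, "issue": f"unknown strike_type {st!r}"})
    for col in DIMENSION_COLS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[col] > CUBE_EDGE_MM
        for sid in df.loc[bad, "strike_id"]:
            issues.append(
                {"strike_id": sid, "issue": f"{col} exceeds {CUBE_EDGE_MM} mm cube edge"}
            )
        neg = df[col] < 0
        for sid in df.loc[neg, "strike_id"]:
            issues.append({"strike_id": sid, "issue": f"negative {col}"})
    is_miss = df["strike_type"] == "miss"
    nonzero_miss = is_miss & (
        df[list(DIMENSION_COLS)].fillna(0).gt(0).any(axis=1)
    )
    for sid in df.loc[nonzero_miss, "strike_id"]:
        issues.append(
            {"strike_id": sid, "issue": "miss with non-zero bite dimensions"}
        )
    clean_miss = is_miss & ~nonzero_miss
    if miss_as_missing:
        df.loc[clean_miss, list(DIMENSION_COLS)] = np.nan
    else:
        df.loc[clean_miss, list(DIMENSION_COLS)] = 0.0
    df["volume_mm3"] = (
        df["length_mm"] * df["width_mm"] * df["depth_mm"]
    )
    report = ValidationReport(
        n_rows=len(df),
        issues=pd.DataFrame(issues, columns=["strike_id", "issue"]),
    )
    return df, report


def join_observations(
    kinematics_table: pd.DataFrame, bite_table: pd.DataFrame
) -> pd.DataFrame:
    """Left-join bite dimensions onto kinematic strikes by strike_id.

    Kinematic strikes without bite data are retained with bite fields
    absent — the strike, not the fish, is the unit of replication, and only
    a subset of filmed strikes have measurable gel dimensions.
    """
    for name, t in (("kinematics", kinematics_table), ("bite", bite_table)):
        dup = t["strike_id"].duplicated()
        if dup.any():
            raise BiteError(
                f"duplicate strike_id in {name} table: {sorted(t.loc[dup, 'strike_id'])}"
            )
    merged = kinematics_table.merge(
        bite_table, on="strike_id", how="left", suffixes=("", "_bite")
    )
    return merged


def exclude_miss_scrape(table: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity subset: drop miss and scrape rows (edge/corner bites only)."""
    return table[~table["strike_type"].isin(["miss", "scrape"])].reset_index(drop=True)
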