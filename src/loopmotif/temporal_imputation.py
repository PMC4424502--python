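"""Least-squares imputation of expression at unmeasured time points.

The miRNA platform samples five reperfusion times (0, 2, 24, 48, 168 h) but
the mRNA platform only three (0, 24, 168 h).  To correlate mRNA and miRNA
profiles on a common grid, each mRNA profile is completed by fitting a
single ordinary-least-squares line value = a + b * time (time in raw hours)
through its measured points and predicting the missing times from the line.
Measured points are never altered; imputed points are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TemporalProfile", "fit_line", "impute_profile", "build_matched_profiles"]

DEFAULT_GRID = (0.0, 2.0, 24.0, 48.0, 168.0)


@dataclass
class TemporalProfile:
    """One entity's time series: (time_h, value, origin) with origin measured/imputed."""

    entity_id: str
    points: pd.DataFrame  # columns: time_h, value, origin

    def __post_init__(self) -> None:
        t = self.points["time_h"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.entity_id}: times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.points["time_h"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.points["value"].to_numpy(dtype=float)


def fit_line(times, values) -> tuple[float, float]:
    """OLS fit value = a + b*t; returns (intercept a, slope b)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 measured points for a least-squares line")
    if np.unique(t).size != t.size:
        raise ValueError("duplicate time points in profile")
    b, a = np.polyfit(t, v, 1)
    return float(a), float(b)


def impute_profile(entity_id: str, measured, target_times) -> TemporalProfile:
    """Complete a profile at ``target_times`` from its OLS line.

    ``measured`` is an iterable of (time_h, value).  Target times already
    measured are returned unchanged with origin ``measured``; the rest get
    the fitted line's prediction with origin ``imputed``.  Extrapolation
    outside the measured range is allowed (the line is global).
    """
    meas = sorted((float(t), float(v)) for t, v in measured)
    t_meas = np.array([t for t, _ in meas])
    v_meas = np.array([v for _, v in meas])
    a, b = fit_line(t_meas, v_meas)
    lookup = dict(meas)
    rows = []
    for t in sorted(set(float(x) for x in target_times) | set(t_meas)):
        if t in lookup:
            rows.append((t, lookup[t], "measured"))
        else:
            rows.append((t, a + b * t, "imputed"))
    return TemporalProfile(
        entity_id=entity_id,
        points=pd.DataFrame(rows, columns=["time_h", "value", "origin"]),
    )


def build_matched_profiles(
    mrna_profiles: dict[str, list[tuple[float, float]]],
    mirna_profiles: dict[str, list[tuple[float, float]]],
) -> pd.DataFrame:
    """Align mRNA and miRNA profiles on the union time grid.

    Inputs map entity id -> measured (time_h, value) points.  miRNA profiles
    are expected to already cover the union grid; mRNA profiles are completed
    by least-squares imputation.  Returns a long DataFrame with columns
    ``entity_id, time_h, value, origin``.
    """
    grid: set[float] = set()
    for prof in list(mrna_profiles.values()) + list(mirna_profiles.values()):
        grid |= {float(t) for t, _ in prof}
    if not grid:
        raise ValueError("no profiles supplied")
    mrna_times: set[float] = set()
    for prof in mrna_profiles.values():
        mrna_times |= {float(t) for t, _ in prof}
    if mrna_profiles and mirna_profiles and not (
        mrna_times & {float(t) for p in mirna_profiles.values() for t, _ in p}
    ):
        raise ValueError("mRNA and miRNA time grids do not overlap")

    frames = []
    for eid, prof in mrna_profiles.items():
        frames.append(impute_profile(eid, prof, grid).points.assign(entity_id=eid))
    for eid, prof in mirna_profiles.items():
        frames.append(impute_profile(eid, prof, grid).points.assign(entity_id=eid))
    out = pd.concat(frames, ignore_index=True)
    return out[["entity_id", "time_h", "value", "origin"]]


def profiles_to_arrays(profiles: pd.DataFrame) -> dict[str, np.ndarray]:
    """Pivot a long profile table to entity -> value vector on the sorted grid."""
    wide = profiles.pivot(index="entity_id", columns="time_h", values="value")
    wide = wide[sorted(wide.columns)]
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"profile for {missing} does not cover the full time grid")
    return {eid: row.to_numpy(dtype=float) for eid, row in wide.iterrows()}
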