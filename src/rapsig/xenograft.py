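"""Xenograft efficacy analysis: volumes, growth curves, TGI and group tests.

Tumor volume from two-dimensional caliper readings uses the standard
ellipsoid approximation V = l * w^2 / 2 (l = longest diameter, w = shortest,
both mm; volume mm^3).  Percent tumor-growth inhibition (TGI) compares
baseline-subtracted volume gains at the last day measured in both arms:

    TGI = 100 * (1 - (V_T(end) - V_T(0)) / (V_C(end) - V_C(0)))

so 100% means complete growth arrest and values above 100 indicate
regression below baseline.  Group comparisons use the two-sided Student's
t-test (pooled variance) on final volumes; P < 0.05 is called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "InhibitionResult",
    "tumor_volume",
    "add_volumes",
    "stratified_randomize",
    "growth_curves",
    "percent_inhibition",
    "compare_groups",
    "read_measurements",
]

GROUPS = ("control", "rapamycin", "CCI-779", "doxorubicin")

_MEAS_COLS = ["animal_id", "model_id", "group", "day", "l_mm", "w_mm"]


@dataclass
class InhibitionResult:
    model_id: str
    group: str
    percent_inhibition: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def tumor_volume(l, w):
    """Ellipsoid volume l * w^2 / 2 (mm^3); w must not exceed l."""
    l = np.asarray(l, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(l <= 0) or np.any(w <= 0):
        raise ValueError("diameters must be positive")
    if np.any(w > l):
        raise ValueError("shortest diameter exceeds longest; axes swapped?")
    vol = l * w**2 / 2.0
    return float(vol) if vol.ndim == 0 else vol


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"animal_id": str, "model_id": str, "group": str})
    missing = [c for c in _MEAS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement file missing columns: {missing}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown treatment groups: {sorted(bad)}")
    if df.duplicated(["animal_id", "day"]).any():
        dup = df[df.duplicated(["animal_id", "day"])].iloc[0]
        raise ValueError(
            f"duplicate measurement for animal {dup['animal_id']!r} "
            f"on day {int(dup['day'])}")
    return df


def add_volumes(measurements: pd.DataFrame) -> pd.DataFrame:
    """Append a volume_mm3 column computed from the caliper columns."""
    out = measurements.copy()
    out["volume_mm3"] = tumor_volume(out["l_mm"].to_numpy(),
                                     out["w_mm"].to_numpy())
    return out


def stratified_randomize(baselines: pd.Series, groups, seed: int,
                         group_sizes=None) -> pd.Series:
    """Assign animals to groups, stratified by baseline tumor volume.

    Animals are sorted by baseline volume and partitioned into consecutive
    blocks of one animal per group; within each block the group order is a
    uniform random permutation under ``seed``.  ``group_sizes`` caps each
    group (default: as equal as possible); animals beyond the requested
    total are labelled "unassigned".
    """
    groups = list(groups)
    n = len(baselines)
    if group_sizes is None:
        base = n // len(groups)
        group_sizes = {g: base for g in groups}
    if sum(group_sizes.values()) > n:
        raise ValueError("requested group sizes exceed the number of animals")
    rng = np.random.default_rng(seed)
    remaining = dict(group_sizes)
    order = baselines.sort_values(kind="mergesort").index
    assignment = pd.Series("unassigned", index=baselines.index, dtype=object)
    for start in range(0, n, len(groups)):
        block = list(order[start:start + len(groups)])
        open_groups = [g for g in groups if remaining[g] > 0]
        rng.shuffle(block)
        for animal, g in zip(block, open_groups):
            assignment[animal] = g
            remaining[g] -= 1
    return assignment


def growth_curves(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per (group, day) mean volume, SEM and n over the animals measured.

    SEM is the sample SD over sqrt(n); a single-animal point gets SEM 0 and
    is identifiable by its n.  Output is ordered by group then day.
    """
    df = measurements if "volume_mm3" in measurements else add_volumes(measurements)
    rows = []
    for (group, day), grp in df.groupby(["group", "day"], sort=True):
        v = grp["volume_mm3"].to_numpy()
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append({"group": group, "day": int(day),
                     "mean_volume": float(v.mean()), "sem": sem, "n": len(v)})
    return pd.DataFrame(rows)


def _mean_volume(curves: pd.DataFrame, group: str, day: int) -> float:
    sel = curves[(curves["group"] == group) & (curves["day"] == day)]
    if sel.empty:
        raise ValueError(f"group {group!r} has no measurement on day {day}")
    return float(sel["mean_volume"].iloc[0])


def percent_inhibition(curves: pd.DataFrame, treated_group: str,
                       control_group: str = "control",
                       day: int | None = None) -> float:
    """Endpoint TGI from group growth curves.

    ``day`` defaults to the last day present in both groups; both groups
    must also have a day-0 (randomization) baseline.  Control volume gain
    must be positive for the ratio to be defined.
    """
    if day is None:
        days_t = set(curves.loc[curves["group"] == treated_group, "day"])
        days_c = set(curves.loc[curves["group"] == control_group, "day"])
        common = days_t & days_c
        if not common:
            raise ValueError("groups share no measurement day")
        day = max(common)
    dv_t = _mean_volume(curves, treated_group, day) - _mean_volume(curves, treated_group, 0)
    dv_c = _mean_volume(curves, control_group, day) - _mean_volume(curves, control_group, 0)
    if dv_c <= 0:
        raise ValueError("control arm did not grow; inhibition is undefined")
    return 100.0 * (1.0 - dv_t / dv_c)


def compare_groups(a, b, welch: bool = False) -> float:
    """Two-sided two-sample Student's t-test on final volumes; returns p.

    Pooled variance by default (Welch behind the flag).  Groups need n >= 2
    and a nonzero pooled variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 animals")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0  # identical constant groups: t = 0
        raise ValueError("zero pooled variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)
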