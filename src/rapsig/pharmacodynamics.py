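"""Dose-response (EC50) fitting and its association with predicted sensitivity.

Viability plates follow the screen design of a 10-point dose ladder with a
vehicle (zero-dose) well.  The model is the constrained sigmoid

    v(d) = bottom + (top - bottom) / (1 + (d / EC50)^hill)

with the Hill coefficient fixed at 1, ``top`` anchored to the vehicle wells
and ``bottom`` constrained nonnegative — the "constrained sigmoidal
dose-response" preset of standard curve-fitting software.  Because
fluorescence noise is multiplicative, the fit minimizes residuals of log
viability (geometric mean per dose); the vehicle wells enter as the d = 0
observation and bound ``top`` rather than fixing it outright, which keeps
EC50 estimates unbiased when the vehicle mean itself is noisy.  A
deterministic multistart over a log-spaced EC50 grid avoids local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponsePlate",
    "DoseResponseFit",
    "fit_dose_response",
    "correlate_prediction_ec50",
    "read_plates",
    "write_plates",
]

# EC50 is only considered identified within [min positive dose / 10,
# max dose * 10]; fits landing on the boundary are flagged unconverged.
_EC50_BOUND_FACTOR = 10.0


@dataclass
class DoseResponsePlate:
    """Replicate background-subtracted fluorescence at each dose (molar)."""

    cell_line: str
    doses: np.ndarray
    viability: list  # one array of replicate values per dose

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = [np.atleast_1d(np.asarray(v, dtype=float))
                          for v in self.viability]
        if len(self.viability) != len(self.doses):
            raise ValueError("one replicate set per dose is required")
        if np.any(self.doses < 0):
            raise ValueError("doses must be nonnegative")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.count_nonzero(self.doses > 0) < 4:
            raise ValueError("need >= 4 distinct positive doses to fit")
        if self.doses[0] != 0:
            raise ValueError("a zero (vehicle) dose is required to anchor top")
        if any(np.any(v <= 0) for v in self.viability):
            raise ValueError("viability must be positive (check background "
                             "subtraction)")

    def mean_viability(self) -> np.ndarray:
        return np.array([v.mean() for v in self.viability])

    def geometric_mean_viability(self) -> np.ndarray:
        return np.array([float(np.exp(np.log(v).mean())) for v in self.viability])


@dataclass
class DoseResponseFit:
    cell_line: str
    ec50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool


def _sigmoid(d, top, bottom, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)


def fit_dose_response(plate: DoseResponsePlate, hill: float = 1.0,
                      n_starts: int = 25) -> DoseResponseFit:
    """Least-squares EC50 fit on log viability, geometric mean per dose.

    Free parameters are log top (bounded within a factor e of the vehicle
    geometric mean, which also enters as the d = 0 observation), ``bottom``
    (> 0, <= vehicle mean) and log10 EC50, bounded one decade beyond the
    positive dose range.  A multistart over a log-spaced EC50 grid makes the
    fit deterministic.  Fits with no resolvable inhibition (flat or
    increasing viability) are returned with ``converged=False`` and EC50 at
    the upper bound.
    """
    gm = plate.geometric_mean_viability()
    y = np.log(gm)
    d = plate.doses  # the model at d = 0 is exactly top
    lo = d[1] / _EC50_BOUND_FACTOR
    hi = d[-1] * _EC50_BOUND_FACTOR
    lb, ub = np.log10(lo), np.log10(hi)
    b_floor = 1e-9 * gm[0]

    def resid(theta):
        log_top, bottom, log_ec50 = theta
        model = _sigmoid(d, np.exp(log_top), bottom, 10.0 ** log_ec50, hill)
        return np.log(model) - y

    b0 = float(np.clip(gm.min(), b_floor, gm[0]))
    best = None
    for log_start in np.linspace(lb, ub, n_starts):
        res = optimize.least_squares(
            resid, x0=[y[0], b0, log_start],
            bounds=([y[0] - 1.0, b_floor, lb], [y[0] + 1.0, gm[0], ub]))
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    log_top, bottom, log_ec50 = best.x
    top = float(np.exp(log_top))
    ec50 = float(10.0 ** log_ec50)
    rss = float(2.0 * best.cost)
    span_ok = (top - bottom) > 0.1 * max(abs(top), 1e-12)
    interior = lb + 1e-6 < log_ec50 < ub - 1e-6
    converged = bool(span_ok and interior)
    if not span_ok:
        ec50 = float(hi)  # no resolvable inhibition
    return DoseResponseFit(cell_line=plate.cell_line, ec50=ec50, hill=hill,
                           top=top, bottom=float(bottom), rss=rss,
                           converged=converged)


def read_plates(path) -> list:
    """Read plates from a long TSV (cell_line, dose_molar, replicate, fluorescence)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str})
    need = {"cell_line", "dose_molar", "replicate", "fluorescence"}
    if not need <= set(df.columns):
        raise ValueError(f"plate file needs columns {sorted(need)}")
    plates = []
    for line, grp in df.groupby("cell_line", sort=True):
        doses = np.sort(grp["dose_molar"].unique())
        viability = [grp.loc[grp["dose_molar"] == d, "fluorescence"].to_numpy()
                     for d in doses]
        plates.append(DoseResponsePlate(cell_line=line, doses=doses,
                                        viability=viability))
    return plates


def write_plates(plates, path) -> None:
    import pandas as pd

    rows = []
    for p in plates:
        for d, reps in zip(p.doses, p.viability):
            for j, v in enumerate(reps):
                rows.append({"cell_line": p.cell_line, "dose_molar": repr(float(d)),
                             "replicate": j + 1, "fluorescence": repr(float(v))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def correlate_prediction_ec50(sensitivity, fits, use_log10: bool = True):
    """OLS of (log10) EC50 on predicted sensitivity across cell lines.

    ``sensitivity`` maps cell line -> predicted sensitivity (dict or Series);
    ``fits`` is a list of DoseResponseFit.  Only converged fits enter, and at
    least three are required.  Returns (slope, pearson_r, p_value) for the
    two-sided test of zero slope.  A negative r means higher predicted
    sensitivity goes with lower EC50, i.e. the signature tracks potency.
    """
    import pandas as pd

    sens = pd.Series(dict(sensitivity) if isinstance(sensitivity, dict)
                     else sensitivity, dtype=float)
    rows = [(f.cell_line, f.ec50) for f in fits if f.converged]
    if len(rows) < 3:
        raise ValueError("need >= 3 cell lines with converged fits")
    lines, ec50s = zip(*rows)
    missing = [ln for ln in lines if ln not in sens.index]
    if missing:
        raise ValueError(f"no predicted sensitivity for {missing[:5]}")
    x = sens.loc[list(lines)].to_numpy()
    yv = np.log10(ec50s) if use_log10 else np.asarray(ec50s, dtype=float)
    if np.ptp(x) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance in sensitivity or EC50")
    res = stats.linregress(x, yv)
    return float(res.slope), float(res.rvalue), float(res.pvalue)
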