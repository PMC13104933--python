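"""Ratiometric HPTS proton-flux assay computations.

The pH reporter HPTS (pyranine) is read out as the excitation ratio
F460/F417 (pH-dependent over pH-independent isosbestic channel).  The
calibration model maps ratio R to pH through

    pH = -log10(A * B**R - 1)

with published constants A = 8.959e-8 and B = 1.185.  The intraliposomal pH is
then converted to a *total* proton concentration, accounting for the phosphate
buffer's capacity with a single effective dissociation constant:

    [H]_total = h + P_total * h / (Ka + h),    h = 10**(-pH)

(free protons plus protons bound to monobasic phosphate; defaults
Ka = 6.31e-8 M, P_total = 0.03 M).  Initial proton-flux rates are ordinary
least-squares slopes of [H]_total over the first 60 s after valinomycin
addition, and variants are compared with a one-way fixed-effects ANOVA
followed by Tukey's honestly-significant-difference test (studentized-range
distribution).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CalibrationDomainError, PoresymError

PUBLISHED_A = 8.959e-8
PUBLISHED_B = 1.185

DEFAULT_KA = 6.31e-8
DEFAULT_P_TOTAL = 0.03


@dataclass
class CalibrationCurve:
    """Sigmoid ratio-to-pH calibration, pH = -log10(A * B**R - 1)."""

    A: float = PUBLISHED_A
    B: float = PUBLISHED_B
    fitted: bool = False
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 1):
            raise ValueError(f"require A > 0 and B > 1; got A={self.A}, B={self.B}")


@dataclass
class BufferModel:
    """Single-pKa phosphate buffering of total proton concentration."""

    Ka: float = DEFAULT_KA
    P_total: float = DEFAULT_P_TOTAL

    def __post_init__(self) -> None:
        if not (self.Ka > 0 and self.P_total >= 0):
            raise ValueError("require Ka > 0 and P_total >= 0")


def pH_to_ratio(pH, calib: CalibrationCurve | None = None) -> np.ndarray:
    """Invert the calibration: R = log((10**-pH + 1) / A) / log(B)."""
    calib = calib or CalibrationCurve()
    h = np.power(10.0, -np.asarray(pH, dtype=float))
    return np.log((h + 1.0) / calib.A) / np.log(calib.B)


def ratio_to_pH(ratio, calib: CalibrationCurve | None = None) -> np.ndarray:
    """pH = -log10(A * B**R - 1); errors when the signal is below the floor."""
    calib = calib or CalibrationCurve()
    arg = calib.A * np.power(calib.B, np.asarray(ratio, dtype=float)) - 1.0
    if np.any(arg <= 0):
        raise CalibrationDomainError(
            "ratio below calibration floor (A * B**ratio <= 1)"
        )
    return -np.log10(arg)


def fit_calibration(points: pd.DataFrame) -> CalibrationCurve:
    """Least-squares fit of (A, B) in ratio space from (pH, ratio) points.

    Requires at least 4 points spanning at least 2 pH units; initialised at
    the published constants.
    """
    if not {"pH", "ratio"}.issubset(points.columns):
        raise ValueError("calibration table needs columns pH, ratio")
    pH = points["pH"].to_numpy(dtype=float)
    ratio = points["ratio"].to_numpy(dtype=float)
    if len(pH) < 4:
        raise PoresymError(f"need >= 4 calibration points, got {len(pH)}")
    if np.ptp(pH) < 2.0:
        raise PoresymError("calibration points must span >= 2 pH units")

    def model(pH, logA, B):
        h = np.power(10.0, -pH)
        return np.log((h + 1.0) / np.exp(logA)) / np.log(B)

    try:
        popt, _ = optimize.curve_fit(
            model, pH, ratio, p0=[np.log(PUBLISHED_A), PUBLISHED_B],
            bounds=([-np.inf, 1.0 + 1e-9], [0.0, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise PoresymError(
            f"calibration fit did not converge (started at A={PUBLISHED_A}, B={PUBLISHED_B})"
        ) from exc
    A, B = float(np.exp(popt[0])), float(popt[1])
    resid = ratio - model(pH, *popt)
    return CalibrationCurve(
        A=A, B=B, fitted=True, fit_residual=float(np.sqrt(np.mean(resid**2)))
    )


def total_proton(pH, buffer: BufferModel | None = None) -> np.ndarray:
    """Total proton concentration (M): free plus phosphate-bound."""
    buffer = buffer or BufferModel()
    h = np.power(10.0, -np.asarray(pH, dtype=float))
    return h + buffer.P_total * h / (buffer.Ka + h)


@dataclass
class FluxTrace:
    """One processed well/replicate trace."""

    time: np.ndarray  # s
    ratio: np.ndarray
    pH: np.ndarray
    H_total: np.ndarray  # M
    t_valinomycin: float
    label: str = ""
    t_cccp: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def process_trace(
    time,
    F460,
    F417,
    t_valinomycin: float,
    calib: CalibrationCurve | None = None,
    buffer: BufferModel | None = None,
    label: str = "",
    t_cccp: float | None = None,
) -> FluxTrace:
    """Raw channel pair -> ratio -> pH -> total proton concentration."""
    time = np.asarray(time, dtype=float)
    ratio = np.asarray(F460, dtype=float) / np.asarray(F417, dtype=float)
    pH = ratio_to_pH(ratio, calib)
    return FluxTrace(
        time=time,
        ratio=ratio,
        pH=np.asarray(pH),
        H_total=np.asarray(total_proton(pH, buffer)),
        t_valinomycin=t_valinomycin,
        label=label,
        t_cccp=t_cccp,
    )


def delta_pH(trace: FluxTrace) -> np.ndarray:
    """pH(t) minus the mean pH over all pre-valinomycin points."""
    pre = trace.time < trace.t_valinomycin
    if pre.sum() < 2:
        raise PoresymError(
            f"need >= 2 pre-valinomycin points, found {int(pre.sum())}"
        )
    return trace.pH - trace.pH[pre].mean()


def _window_mask(time: np.ndarray, t_val: float, window: float) -> np.ndarray:
    return (time > t_val) & (time <= t_val + window)


def initial_rate(
    trace: FluxTrace, window: float = 60.0
) -> tuple[float, float]:
    """OLS slope (M/s) and standard error of H_total over (t_val, t_val+window]."""
    mask = _window_mask(trace.time, trace.t_valinomycin, window)
    if mask.sum() < 3:
        raise PoresymError(
            f"need >= 3 points in the {window}-s rate window, found {int(mask.sum())}"
        )
    res = stats.linregress(trace.time[mask], trace.H_total[mask])
    return float(res.slope), float(res.stderr)


def pooled_initial_rate(
    traces: list[FluxTrace], window: float = 60.0
) -> tuple[float, float]:
    """One OLS fit over the stacked window points of several replicate traces.

    All traces must share the same event time.  Pooling the window points of
    all technical measurements gives the rate estimator many residual degrees
    of freedom, so its 2-SE interval has close to nominal Gaussian coverage.
    """
    ts, ys = [], []
    for tr in traces:
        mask = _window_mask(tr.time, tr.t_valinomycin, window)
        ts.append(tr.time[mask])
        ys.append(tr.H_total[mask])
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    if len(t) < 3:
        raise PoresymError("pooled rate window has fewer than 3 points")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.stderr)


def anova_oneway(groups: dict[str, np.ndarray]) -> pd.Series:
    """One-way fixed-effects ANOVA from the standard sums of squares."""
    if len(groups) < 2:
        raise PoresymError("ANOVA needs >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise PoresymError(f"group {k!r} has fewer than 2 values")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    if np.ptp(all_vals) == 0:
        # all observations identical: no variance anywhere, F = 0 by definition
        k, n = len(arrays), len(all_vals)
        return pd.Series(
            {"F": 0.0, "p": 1.0, "df_between": k - 1, "df_within": n - k,
             "ss_between": 0.0, "ss_within": 0.0, "ms_within": 0.0}
        )
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_between = len(arrays) - 1
    df_within = len(all_vals) - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    F = ms_between / ms_within if ms_within > 0 else (0.0 if ms_between == 0 else np.inf)
    p = float(stats.f.sf(F, df_between, df_within)) if np.isfinite(F) else 0.0
    return pd.Series(
        {
            "F": float(F),
            "p": p,
            "df_between": df_between,
            "df_within": df_within,
            "ss_between": float(ss_between),
            "ss_within": float(ss_within),
            "ms_within": float(ms_within),
        }
    )


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons via the studentized-range distribution."""
    anova = anova_oneway(groups)
    ms_within = anova["ms_within"]
    df_within = int(anova["df_within"])
    k = len(groups)
    rows = []
    for (n1, v1), (n2, v2) in itertools.combinations(
        ((n, np.asarray(v, dtype=float)) for n, v in groups.items()), 2
    ):
        diff = v1.mean() - v2.mean()
        se = np.sqrt(ms_within / 2.0 * (1.0 / len(v1) + 1.0 / len(v2)))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_within)) if np.isfinite(q) else 0.0
        rows.append(
            {"group1": n1, "group2": n2, "diff": float(diff), "q": float(q),
             "p_adj": min(p_adj, 1.0)}
        )
    return pd.DataFrame(rows)


def compare_rates(groups: dict[str, np.ndarray]) -> tuple[pd.Series, pd.DataFrame]:
    """One-way ANOVA plus post-hoc Tukey HSD over labelled rate groups."""
    return anova_oneway(groups), tukey_hsd(groups)
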