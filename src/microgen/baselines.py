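"""Seven comparison imputers on the clr-scale tensor.

All baselines share the observed-value-passthrough contract: wherever the
mask is 1 the output equals the input exactly.  Mean/median/linear/cubic/
moving-window/LOCF operate within subject across time; MICE runs a
chained-equation regression per taxon with timepoints as columns and
subjects as rows (scikit-learn's IterativeImputer, deterministic, mean
initialized, single imputation).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression

from .datasets import ClrDataset, ImputationResult, MicrogenError

__all__ = ["BaselineSpec", "impute_baseline", "run_all_baselines", "BASELINE_METHODS"]

BASELINE_METHODS = ("mean", "median", "linear", "cubic", "moving_window",
                    "mice", "locf")


@dataclasses.dataclass
class BaselineSpec:
    method: str = "mean"
    window: int = 3
    mice_iterations: int = 10

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise MicrogenError("window must be odd and >= 1")


def _cohort_mean(x: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Per-taxon mean over every observed sample in the cohort (fallback)."""
    obs = e == 1
    if not obs.any():
        raise MicrogenError("no observed samples in the cohort")
    return x[obs].mean(axis=0)


def _poly_impute(t: np.ndarray, e_row: np.ndarray, series: np.ndarray,
                 order: int) -> np.ndarray:
    """Polynomial fit over observed (t, value) pairs; nearest value at edges."""
    obs_idx = np.flatnonzero(e_row)
    t_obs = t[obs_idx]
    out = series.copy()
    miss_idx = np.flatnonzero(e_row == 0)
    lo, hi = t_obs[0], t_obs[-1]
    interior = miss_idx[(t[miss_idx] > lo) & (t[miss_idx] < hi)]
    edges = np.setdiff1d(miss_idx, interior)
    for j in range(series.shape[1]):
        v_obs = series[obs_idx, j]
        if interior.size:
            deg = min(order, len(obs_idx) - 1)
            if deg == 0:
                out[interior, j] = v_obs[0]
            else:
                coeffs = np.polyfit(t_obs, v_obs, deg)
                out[interior, j] = np.polyval(coeffs, t[interior])
        for i in edges:
            nearest = obs_idx[np.argmin(np.abs(t_obs - t[i]))]
            out[i, j] = series[nearest, j]
    return out


def _moving_window(e_row: np.ndarray, series: np.ndarray, window: int) -> np.ndarray:
    out = series.copy()
    k = len(e_row)
    half = window // 2
    for i in np.flatnonzero(e_row == 0):
        w = half
        while True:
            lo, hi = max(0, i - w), min(k, i + w + 1)
            sel = np.flatnonzero(e_row[lo:hi]) + lo
            if sel.size:
                out[i] = series[sel].mean(axis=0)
                break
            w += 1  # empty window: expand to the nearest observed values
    return out


def _locf(e_row: np.ndarray, series: np.ndarray) -> np.ndarray:
    out = series.copy()
    obs_idx = np.flatnonzero(e_row)
    last = obs_idx[0]
    for i in range(len(e_row)):
        if e_row[i] == 1:
            last = i
        else:
            out[i] = series[last]  # leading gaps take the first observed value
    return out


def _mice(x: np.ndarray, e: np.ndarray, iterations: int) -> np.ndarray:
    s, k, n = x.shape
    out = x.copy()
    for j in range(n):
        mat = x[:, :, j].astype(float).copy()
        mat[e == 0] = np.nan
        col_all_nan = np.all(np.isnan(mat), axis=0)
        if col_all_nan.any():
            mat[:, col_all_nan] = np.nanmean(mat)
        imp = IterativeImputer(estimator=LinearRegression(), max_iter=iterations,
                               sample_posterior=False, initial_strategy="mean",
                               random_state=0, tol=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # fixed sweep count, no tol stop
            filled = imp.fit_transform(mat)
        if filled.shape[1] != k:  # a column with no observed values was dropped
            filled = mat
        out[:, :, j] = np.where(e == 0, filled, x[:, :, j])
    return out


def impute_baseline(clr: ClrDataset, mask: np.ndarray | None = None,
                    spec: BaselineSpec | None = None) -> ImputationResult:
    """Apply one baseline imputer to the clr tensor; observed entries pass through."""
    spec = spec if spec is not None else BaselineSpec()
    if spec.method not in BASELINE_METHODS:
        raise MicrogenError(f"unknown baseline method {spec.method!r}")
    x = clr.clr_values
    e = (clr.mask if mask is None else np.asarray(mask)).astype(int)
    s, k, n = x.shape
    out = x.copy()
    fallback = None

    if spec.method == "mice":
        out = _mice(x, e, spec.mice_iterations)
    else:
        for si in range(s):
            e_row = e[si]
            miss = np.flatnonzero(e_row == 0)
            if miss.size == 0:
                continue
            obs = np.flatnonzero(e_row)
            if obs.size == 0:
                if fallback is None:
                    fallback = _cohort_mean(x, e)
                out[si, miss] = fallback
                continue
            series = x[si]
            if spec.method == "mean":
                out[si, miss] = series[obs].mean(axis=0)
            elif spec.method == "median":
                out[si, miss] = np.median(series[obs], axis=0)
            elif spec.method == "linear":
                out[si] = _poly_impute(clr.source.timepoints, e_row, series, 1)
            elif spec.method == "cubic":
                out[si] = _poly_impute(clr.source.timepoints, e_row, series, 3)
            elif spec.method == "moving_window":
                out[si] = _moving_window(e_row, series, spec.window)
            elif spec.method == "locf":
                out[si] = _locf(e_row, series)
    out[e == 1] = x[e == 1]
    return ImputationResult(clr_values=out, mask=e.copy(), method=spec.method)


def run_all_baselines(clr: ClrDataset, mask: np.ndarray | None = None) -> dict:
    """Run every baseline with default settings; errors propagate per method."""
    results = {}
    errors = {}
    for method in BASELINE_METHODS:
        try:
            results[method] = impute_baseline(clr, mask, BaselineSpec(method=method))
        except MicrogenError as exc:  # pragma: no cover - defensive
            errors[method] = exc
    if errors and not results:
        raise MicrogenError(f"all baselines failed: {errors}")
    return results
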