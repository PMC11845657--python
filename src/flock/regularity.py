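"""Movement-regularity features: location/series entropy and VAR(X) forecast error.

Location entropy is the Shannon entropy of a member's 2-D occupancy
histogram in path-adapted coordinates, computed on a fixed grid of 1 m^2
bins covering roughly 100 m^2 centred on the member's mean location; frames
outside the window are clipped into the border bins so no mass is lost.
Series entropy applies the same idea to any 1-D feature series. Forecast
error comes from rolling-window vector autoregression, optionally with the
other members' movement as exogenous inputs (VARX).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LOG_BASES = {"2": 2.0, "e": math.e, 2: 2.0, math.e: math.e}


@dataclass(frozen=True)
class EntropyConfig:
    bin_size: float = 1.0        # m, side of one square bin
    window_area: float = 100.0   # m^2, total window
    log_base: float = 2.0

    def __post_init__(self):
        side = math.sqrt(self.window_area)
        n = side / self.bin_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window side must be divisible by bin size")

    @property
    def n_bins_side(self) -> int:
        return int(round(math.sqrt(self.window_area) / self.bin_size))


@dataclass(frozen=True)
class PredictabilityConfig:
    window: int = 100
    train: int = 95
    horizon: int = 5
    model_order: int = 1
    ridge: float = 1e-8          # stabilizer for (near-)singular designs

    def __post_init__(self):
        if self.train + self.horizon != self.window:
            raise ValueError("train + horizon must equal window")
        if self.model_order < 1 or self.model_order >= self.train:
            raise ValueError("invalid model order")


def _shannon(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / math.log(base))).sum())


def location_entropy(xy: np.ndarray, cfg: EntropyConfig | None = None) -> float:
    """Entropy of a member's 2-D occupancy histogram (bits by default).

    ``xy`` is (T, 2) path-adapted coordinates. The grid is ``n x n`` bins of
    ``bin_size`` metres centred on the member's mean location; outliers are
    clipped to the border bins. Bounded by ``log(n^2)``.
    """
    cfg = cfg or EntropyConfig()
    xy = np.asarray(xy, dtype=float)
    xy = xy[np.all(np.isfinite(xy), axis=1)]
    if xy.shape[0] == 0:
        raise ValueError("no finite frames")
    n = cfg.n_bins_side
    center = xy.mean(axis=0)
    lo = center - 0.5 * math.sqrt(cfg.window_area)
    idx = np.floor((xy - lo) / cfg.bin_size).astype(int)
    idx = np.clip(idx, 0, n - 1)
    counts = np.zeros((n, n))
    np.add.at(counts, (idx[:, 0], idx[:, 1]), 1.0)
    return _shannon(counts.ravel() / counts.sum(), cfg.log_base)


def series_entropy(series: np.ndarray, bins: int = 20,
                   edges: np.ndarray | None = None, log_base: float = 2.0) -> float:
    """Shannon entropy of the histogram of a 1-D feature series.

    Pass shared ``edges`` to keep entropies comparable across members and
    groups of one dataset. A constant series occupies a single bin (H = 0).
    """
    series = np.asarray(series, dtype=float)
    series = series[np.isfinite(series)]
    if series.size == 0:
        raise ValueError("empty series")
    if edges is None:
        lo, hi = float(series.min()), float(series.max())
        if hi - lo < 1e-12:
            return 0.0
        edges = np.linspace(lo, hi, bins + 1)
    counts, _ = np.histogram(np.clip(series, edges[0], edges[-1]), bins=edges)
    total = counts.sum()
    if total == 0:
        return 0.0
    return _shannon(counts / total, log_base)


# ---------------------------------------------------------------------------
# rolling VAR / VARX forecast error


def _fit_var(train_diff: np.ndarray, order: int, ridge: float,
             exog: np.ndarray | None = None):
    """Least-squares VAR(order) on differenced data; returns (coef, intercept).

    Design rows are the ``order`` lagged difference vectors (plus exogenous
    regressors at the same time step, if given). A tiny ridge keeps
    degenerate windows (e.g. perfectly constant motion) well-posed.
    """
    T, d = train_diff.shape
    rows = []
    targets = []
    for t in range(order, T):
        lags = train_diff[t - order:t][::-1].ravel()
        if exog is not None:
            lags = np.concatenate([lags, exog[t]])
        rows.append(lags)
        targets.append(train_diff[t])
    X = np.asarray(rows)
    Y = np.asarray(targets)
    X1 = np.column_stack([X, np.ones(len(X))])
    XtX = X1.T @ X1 + ridge * np.eye(X1.shape[1])
    beta = np.linalg.solve(XtX, X1.T @ Y)
    return beta[:-1], beta[-1]


def _forecast(last_lags: np.ndarray, coef: np.ndarray, intercept: np.ndarray,
              steps: int, order: int, d: int,
              exog_future: np.ndarray | None = None) -> np.ndarray:
    """Iterated multi-step forecast of differences."""
    lags = [last_lags[i] for i in range(order)]  # most recent first
    out = np.empty((steps, d))
    for h in range(steps):
        x = np.concatenate(lags[:order]).ravel()
        if exog_future is not None:
            x = np.concatenate([x, exog_future[h]])
        pred = x @ coef + intercept
        out[h] = pred
        lags.insert(0, pred)
    return out


def _rolling_error(xy: np.ndarray, cfg: PredictabilityConfig,
                   exog_xy: np.ndarray | None) -> tuple[float, int, int]:
    xy = np.asarray(xy, dtype=float)
    T = xy.shape[0]
    if T < cfg.window + 1:
        raise ValueError(f"series of length {T} shorter than window {cfg.window} + 1")
    diffs = np.diff(xy, axis=0)                       # length T-1
    ex = None
    if exog_xy is not None:
        exog_xy = np.asarray(exog_xy, dtype=float)
        if exog_xy.ndim == 2:
            exog_xy = exog_xy[:, None, :]
        ex = np.diff(exog_xy, axis=0).reshape(T - 1, -1)

    errors = []
    skipped = 0
    start = 0
    # each window covers cfg.window positions => cfg.window-1 differences
    while start + cfg.window <= T:
        d_win = diffs[start:start + cfg.window - 1]
        train_d = d_win[:cfg.train - 1]
        ex_train = ex[start:start + cfg.train - 1] if ex is not None else None
        ex_future = (ex[start + cfg.train - 1:start + cfg.window - 1]
                     if ex is not None else None)
        try:
            coef, intercept = _fit_var(train_d, cfg.model_order, cfg.ridge, ex_train)
        except np.linalg.LinAlgError:
            skipped += 1
            start += cfg.horizon
            continue
        last = train_d[-cfg.model_order:][::-1]
        pred_d = _forecast(last, coef, intercept, cfg.horizon, cfg.model_order,
                           xy.shape[1], ex_future)
        anchor = xy[start + cfg.train - 1]
        pred_pos = anchor + np.cumsum(pred_d, axis=0)
        true_pos = xy[start + cfg.train:start + cfg.window]
        errors.append(float(np.sqrt(np.mean(np.sum((pred_pos - true_pos) ** 2, axis=1)))))
        start += cfg.horizon
    if not errors:
        raise ValueError("no valid forecast windows")
    return float(np.mean(errors)), len(errors), skipped


def var_error(xy: np.ndarray, cfg: PredictabilityConfig | None = None) -> float:
    """Mean rolling-window VAR forecast RMSE (m) of one member's motion.

    The model is fit on first-differenced positions of the training segment,
    forecasts ``horizon`` steps, and errors are measured on re-integrated
    positions. Windows advance by the horizon so forecasts do not overlap.
    """
    cfg = cfg or PredictabilityConfig()
    err, _, _ = _rolling_error(xy, cfg, None)
    return err


def varx_error(xy: np.ndarray, others_xy: np.ndarray,
               cfg: PredictabilityConfig | None = None) -> float:
    """VAR forecast error with other members' differenced motion as exogenous input.

    ``others_xy`` is (T, k, 2) (or (T, 2) for a single other member). The
    exogenous values over the forecast horizon are taken as observed,
    matching the conditional-forecast protocol.
    """
    cfg = cfg or PredictabilityConfig()
    others_xy = np.asarray(others_xy, dtype=float)
    if others_xy.ndim == 2:
        others_xy = others_xy[:, None, :]
    err, _, _ = _rolling_error(xy, cfg, others_xy)
    return err
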