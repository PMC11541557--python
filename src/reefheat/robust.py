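"""Inferential machinery for the bleaching-driver analysis.

Yuen's trimmed-means test for dependent samples with a robust explanatory
effect size, predictor screening by pairwise correlation and variance
inflation factors, the Friedman-Popescu pairwise H interaction statistic,
bootstrap confidence bands for partial-dependence curves, and a spline
correlogram for spatial autocorrelation of model residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "PairedSample",
    "YuenResult",
    "trimmed_mean",
    "winsorize",
    "yuen_paired",
    "collinearity_screen",
    "vif_screen",
    "friedman_h",
    "partial_dependence",
    "partial_dependence_ci",
    "PDCurve",
    "haversine_km",
    "spline_correlogram",
    "CorrelogramResult",
]

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Trimmed / winsorized estimators and Yuen's paired test
# ---------------------------------------------------------------------------


def trimmed_mean(x, trim: float) -> float:
    """Mean after removing floor(trim*n) values at each tail (sorted order)."""
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    x = np.sort(np.asarray(x, dtype=float))
    g = int(np.floor(trim * len(x)))
    kept = x[g : len(x) - g] if g else x
    if kept.size == 0:
        raise ValueError("no values left after trimming")
    return float(kept.mean())


def winsorize(x, trim: float) -> np.ndarray:
    """Winsorized copy of x: tail values pulled to the trimming quantiles."""
    x = np.asarray(x, dtype=float)
    order = np.sort(x)
    g = int(np.floor(trim * len(x)))
    if g == 0:
        return x.copy()
    lo, hi = order[g], order[len(x) - g - 1]
    return np.clip(x, lo, hi)


def _winsorized_normal_variance(trim: float) -> float:
    """Variance of a standard normal winsorized at the trim quantiles.

    Used to rescale a winsorized variance into a consistent estimate of the
    underlying variance under normality (the usual robust-effect-size
    convention; 0.4121 at 20% trimming).
    """
    if trim == 0:
        return 1.0
    z = stats.norm.ppf(1.0 - trim)
    # E[W^2] = int_{-z}^{z} x^2 phi(x) dx + 2*trim*z^2
    inner = 1.0 - 2.0 * trim - 2.0 * z * stats.norm.pdf(z)
    return inner + 2.0 * trim * z**2


@dataclass
class PairedSample:
    """Equal-length paired measurements (same sites sampled in two years)."""

    x: np.ndarray
    y: np.ndarray
    ids: list | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length vectors")
        if len(self.x) < 5:
            raise ValueError("need at least 5 pairs")

    @classmethod
    def from_frames(cls, a: pd.Series, b: pd.Series) -> "PairedSample":
        """Pair two indexed series by id, dropping (and warning on) unpaired sites."""
        common = a.index.intersection(b.index)
        unpaired = len(a.index.union(b.index)) - len(common)
        if unpaired:
            warnings.warn(f"{unpaired} unpaired sites excluded", stacklevel=2)
        return cls(a.loc[common].to_numpy(), b.loc[common].to_numpy(), list(common))


@dataclass
class YuenResult:
    statistic: float
    df: float
    p_value: float
    effect_size: float
    trimmed_diff: float


def yuen_paired(sample: PairedSample | tuple, trim: float = 0.10) -> YuenResult:
    """Yuen's trimmed-means test for two dependent samples.

    Tests whether the trimmed means of the paired measurements differ, using
    the winsorized variances and covariance of the pairs (the
    dependent-samples form of Yuen's test). With ``trim=0`` the statistic,
    degrees of freedom and p-value reduce exactly to the classical paired
    t-test. The effect size is an explanatory measure xi: the square root of
    the between-trimmed-means variance over the total variance, the latter
    estimated from the pooled winsorized variance rescaled for consistency
    under normality.
    """
    if not isinstance(sample, PairedSample):
        sample = PairedSample(*sample)
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    x, y = sample.x, sample.y
    n = len(x)
    g = int(np.floor(trim * n))
    h = n - 2 * g
    if h < 5:
        raise ValueError(f"only {h} pairs left after trimming (need >= 5)")
    tx, ty = trimmed_mean(x, trim), trimmed_mean(y, trim)
    wx, wy = winsorize(x, trim), winsorize(y, trim)
    q1 = (n - 1) * np.var(wx, ddof=1)
    q2 = (n - 1) * np.var(wy, ddof=1)
    q3 = (n - 1) * np.cov(wx, wy, ddof=1)[0, 1]
    df = float(h - 1)
    se2 = (q1 + q2 - 2.0 * q3) / (h * (h - 1.0))
    diff = tx - ty
    if se2 <= 0:
        if np.allclose(x, y):
            return YuenResult(0.0, df, 1.0, 0.0, 0.0)
        raise ValueError("degenerate winsorized variance of the differences")
    t = diff / np.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)

    # explanatory measure xi on the paired values
    var_means = diff**2 / 4.0
    pooled = np.concatenate([wx - np.mean(wx), wy - np.mean(wy)])
    total = np.var(pooled, ddof=1) / _winsorized_normal_variance(trim)
    xi = float(np.sqrt(var_means / (var_means + total))) if total > 0 else (
        0.0 if diff == 0 else 1.0
    )
    return YuenResult(float(t), df, float(p), xi, float(diff))


# ---------------------------------------------------------------------------
# Predictor screening
# ---------------------------------------------------------------------------


def collinearity_screen(
    predictors: pd.DataFrame,
    r_max: float = 0.6,
    ranking: list[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy correlation screen in ranking order.

    Walking the predictors in ``ranking`` order (most informative first), a
    predictor is kept iff its absolute Pearson correlation with every
    already-kept predictor stays below ``r_max``. Returns the kept names and
    the dropped (candidate, kept, r) pairs. Constant columns are dropped with
    a warning (their correlation is undefined).
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    order = list(ranking) if ranking is not None else list(predictors.columns)
    unknown = set(order) - set(predictors.columns)
    if unknown:
        raise KeyError(f"ranking names not in predictors: {sorted(unknown)}")
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for name in order:
        col = predictors[name].to_numpy(dtype=float)
        if np.std(col) == 0:
            warnings.warn(f"constant predictor {name!r} dropped", stacklevel=2)
            continue
        clash = None
        for other in kept:
            r = float(np.corrcoef(col, predictors[other].to_numpy(dtype=float))[0, 1])
            if abs(r) >= r_max:
                clash = (name, other, r)
                break
        if clash is None:
            kept.append(name)
        else:
            dropped.append(clash)
    return kept, dropped


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1-R2_j) regressing column j on the others (with intercept)."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot <= 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(
    predictors: pd.DataFrame, vif_max: float = 4.0
) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop the predictor with the largest variance inflation factor.

    Repeats until every remaining VIF is below ``vif_max``. Perfectly
    collinear predictors show infinite VIF and are dropped first. Returns the
    kept names and the (name, vif) pairs dropped, in drop order.
    """
    cols = list(predictors.columns)
    if predictors.shape[0] <= len(cols):
        raise ValueError("need more rows than predictors for VIF screening")
    dropped: list[tuple[str, float]] = []
    while len(cols) >= 2:
        vifs = _vif_values(predictors[cols].to_numpy(dtype=float))
        worst = int(np.argmax(vifs))
        if vifs[worst] < vif_max:
            break
        dropped.append((cols[worst], float(vifs[worst])))
        cols.pop(worst)
    return cols, dropped


# ---------------------------------------------------------------------------
# Partial dependence and the Friedman-Popescu H statistic
# ---------------------------------------------------------------------------


def partial_dependence(
    predict, X: pd.DataFrame, predictor: str, grid: np.ndarray | int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence curve of a fitted predictor over an evaluation grid.

    ``PD(v)`` is the mean prediction with the chosen column forced to ``v``,
    averaging over the empirical distribution of the other columns. An
    integer ``grid`` spans the observed range with that many points.
    """
    if predictor not in X.columns:
        raise KeyError(f"predictor {predictor!r} not in data")
    if isinstance(grid, (int, np.integer)):
        col = X[predictor].to_numpy(dtype=float)
        grid = np.linspace(col.min(), col.max(), int(grid))
    grid = np.asarray(grid, dtype=float)
    n = len(X)
    stacked = pd.concat([X] * len(grid), ignore_index=True)
    stacked[predictor] = np.repeat(grid, n)
    preds = np.asarray(predict(stacked), dtype=float).reshape(len(grid), n)
    return grid, preds.mean(axis=1)


def friedman_h(
    predict,
    X: pd.DataFrame,
    pair: tuple[str, str],
    max_background: int = 100,
    seed: int = 0,
) -> float:
    """Friedman-Popescu pairwise H statistic in [0, 1].

    Measures how far the model's joint partial dependence on two predictors
    departs from the sum of their one-dimensional partial dependences:
    ``H = sqrt( sum (PD_jk - PD_j - PD_k)^2 / sum PD_jk^2 )`` over the
    empirical joint grid, with every component centered. Zero-variance joint
    dependence returns 0 by convention. For speed the empirical background is
    subsampled to ``max_background`` rows (deterministic given ``seed``).
    """
    j, k = pair
    for name in (j, k):
        if name not in X.columns:
            raise KeyError(f"predictor {name!r} not in data")
    if len(X) > max_background:
        rng = np.random.default_rng(seed)
        X = X.iloc[np.sort(rng.choice(len(X), max_background, replace=False))]
    X = X.reset_index(drop=True)
    n = len(X)

    def pd_at_data(cols: list[str]) -> np.ndarray:
        # PD evaluated at each observation's own value(s) of `cols`
        stacked = pd.concat([X] * n, ignore_index=True)  # blocks: grid point i
        for c in cols:
            stacked[c] = np.repeat(X[c].to_numpy(), n)
        preds = np.asarray(predict(stacked), dtype=float).reshape(n, n)
        vals = preds.mean(axis=1)
        return vals - vals.mean()

    pd_j = pd_at_data([j])
    pd_k = pd_at_data([k])
    pd_jk = pd_at_data([j, k])
    denom = float(np.sum(pd_jk**2))
    if denom < 1e-12:
        return 0.0
    h2 = float(np.sum((pd_jk - pd_j - pd_k) ** 2)) / denom
    return float(np.sqrt(np.clip(h2, 0.0, 1.0)))


@dataclass
class PDCurve:
    """Partial-dependence curve with a bootstrap confidence band."""

    predictor: str
    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray | None
    upper: np.ndarray | None
    rug: np.ndarray
    n_boot: int = 0
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        d = {"predictor": self.predictor, "grid": self.grid, "estimate": self.estimate}
        if self.lower is not None:
            d["lower"], d["upper"] = self.lower, self.upper
        return pd.DataFrame(d)


def partial_dependence_ci(
    model_refitter,
    X: pd.DataFrame,
    y: np.ndarray,
    predictor: str,
    n_boot: int = 1000,
    seed: int = 0,
    grid_points: int = 50,
    base_predict=None,
) -> PDCurve:
    """Partial dependence with a 95% percentile bootstrap band.

    ``model_refitter(Xb, yb)`` must return a prediction callable fitted to
    the bootstrap sample; replicates are drawn by case resampling. The point
    curve comes from ``base_predict`` (or a refit on the full data).
    Replicates whose refit fails are skipped and counted, with a warning when
    more than 5% fail. The observed predictor values are returned as the rug.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    col = X[predictor].to_numpy(dtype=float)
    grid = np.linspace(col.min(), col.max(), grid_points)
    y = np.asarray(y, dtype=float)
    if base_predict is None:
        base_predict = model_refitter(X, y)
    _, est = partial_dependence(base_predict, X, predictor, grid)
    rng = np.random.default_rng(seed)
    curves, failed = [], 0
    n = len(X)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            pred = model_refitter(X.iloc[idx].reset_index(drop=True), y[idx])
            _, c = partial_dependence(pred, X, predictor, grid)
        except Exception:
            failed += 1
            continue
        curves.append(c)
    if failed > 0.05 * n_boot:
        warnings.warn(
            f"{failed}/{n_boot} bootstrap refits failed for {predictor!r}",
            stacklevel=2,
        )
    band = np.percentile(np.vstack(curves), [2.5, 97.5], axis=0)
    return PDCurve(
        predictor=predictor,
        grid=grid,
        estimate=est,
        lower=band[0],
        upper=band[1],
        rug=col.copy(),
        n_boot=len(curves),
        n_failed=failed,
    )


# ---------------------------------------------------------------------------
# Spline correlogram
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in kilometers between WGS-84 coordinate pairs."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class CorrelogramResult:
    """Spatial correlation as a smooth function of inter-site distance."""

    distance_km: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int


def _moran_cloud(z: np.ndarray, dist: np.ndarray, iu) -> tuple[np.ndarray, np.ndarray]:
    sim = np.outer(z, z)[iu]
    return dist[iu], sim


def _fit_spline(d: np.ndarray, s: np.ndarray, grid: np.ndarray) -> np.ndarray:
    order = np.argsort(d)
    d, s = d[order], s[order]
    # GCV spline needs strictly increasing x: average duplicate distances
    uniq, inverse = np.unique(d, return_inverse=True)
    if len(uniq) < len(d):
        sums = np.bincount(inverse, weights=s)
        counts = np.bincount(inverse)
        d, s = uniq, sums / counts
    if len(d) < 10:
        raise ValueError("too few distinct pair distances for a spline fit")
    spl = make_smoothing_spline(d, s, lam=None)
    return np.asarray(spl(grid), dtype=float)


def spline_correlogram(
    coords: np.ndarray | pd.DataFrame,
    residuals: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
    grid_points: int = 100,
) -> CorrelogramResult:
    """Nonparametric spatial correlogram with a bootstrap envelope.

    Residuals are standardized and every site pair contributes a Moran-type
    similarity (the product of standardized values) at its great-circle
    distance; a cubic smoothing spline (GCV-selected smoothing) of similarity
    against distance estimates the correlation function on a 100-point grid
    from 0 to the 75th percentile of pairwise distances. The pointwise 95%
    envelope comes from bootstrap resampling of sites (self-pairs excluded).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2): latitude, longitude")
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 sites")
    if coords.shape[0] != n:
        raise ValueError("coords and residuals length mismatch")
    lat, lon = coords[:, 0], coords[:, 1]
    dist = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    iu = np.triu_indices(n, k=1)
    if dist[iu].max() <= 0:
        raise ValueError("all sites are colocated")
    sd = z.std()
    if sd == 0:
        raise ValueError("residuals are constant")
    z = (z - z.mean()) / sd
    grid = np.linspace(0.0, np.percentile(dist[iu], 75), grid_points)
    d_all, s_all = _moran_cloud(z, dist, iu)
    estimate = np.clip(_fit_spline(d_all, s_all, grid), -1.0, 1.0)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, grid_points))
    b = 0
    attempts = 0
    while b < n_boot and attempts < 4 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, n)
        zb = z[idx]
        zb = (zb - zb.mean()) / (zb.std() or 1.0)
        db = dist[np.ix_(idx, idx)]
        pairs = np.triu_indices(n, k=1)
        same = idx[pairs[0]] == idx[pairs[1]]  # same original site: distance 0, sim z^2
        d_b = db[pairs][~same]
        s_b = np.outer(zb, zb)[pairs][~same]
        try:
            boots[b] = _fit_spline(d_b, s_b, grid)
        except Exception:
            continue
        b += 1
    if b < n_boot:
        boots = boots[:b]
    lower, upper = np.percentile(boots, [2.5, 97.5], axis=0)
    lower = np.minimum(lower, estimate)
    upper = np.maximum(upper, estimate)
    return CorrelogramResult(
        distance_km=grid, estimate=estimate, lower=lower, upper=upper, n_boot=b
    )
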