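"""Six normalization strategies for two-channel regulation microarrays.

Transcriptomics-style normalization assumes that most probe signals are
unchanged between channels; on regulation arrays the red (enriched) and
green (input) channels genuinely differ, so that assumption fails for
methods which normalize the channels together.  The six methods here span
both families:

* :func:`lowess_normalize` — per-array local regression of M on A
  (assumes the log-ratio distribution is centered around zero);
* :func:`quantile_normalize` — equalizes the distributions of all
  channels, green and red pooled together;
* :func:`vsn_normalize` — VSN-style variance stabilization: per-channel
  affine calibration followed by a generalized-log transform, fitted by
  least-trimmed squares across channels;
* :func:`tquantile_normalize` — quantile normalization within subgroups:
  the green channels are equalized across arrays and the red channels are
  equalized across arrays, separately;
* :func:`tbw_scale` — per-array subtraction of the Tukey-biweight robust
  location of M (rank-preserving, hence ROC curves identical to raw);
* :func:`peng_normalize` — rotation of the MA cloud to flatten the major
  dye trend, followed by LOWESS.

All methods consume an :class:`~regnorm.core.ExperimentSet` or
:class:`~regnorm.core.MAMatrix` and return a :class:`NormalizationResult`
whose ``M_norm``/``A_norm`` align with the input.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import minimize
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .core import ExperimentSet, MAMatrix, compute_ma

__all__ = [
    "NormalizationMethod",
    "NormalizationResult",
    "lowess_normalize",
    "quantile_normalize",
    "tquantile_normalize",
    "vsn_normalize",
    "tukey_biweight",
    "tbw_scale",
    "peng_normalize",
    "normalize",
    "VsnConvergenceError",
]

LN2 = np.log(2.0)


class NormalizationMethod(enum.Enum):
    LOWESS = "lowess"
    QUANTILE = "quantile"
    VSN = "vsn"
    TQUANTILE = "tquantile"
    TBW = "tbw"
    PENG = "peng"


@dataclass
class NormalizationResult:
    method: NormalizationMethod
    M_norm: np.ndarray
    A_norm: np.ndarray
    array_ids: list[str]
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def as_ma(self) -> MAMatrix:
        return MAMatrix(M=self.M_norm, A=self.A_norm, array_ids=self.array_ids)


class VsnConvergenceError(RuntimeError):
    """VSN-style calibration failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


def _as_ma(data: ExperimentSet | MAMatrix) -> MAMatrix:
    return data if isinstance(data, MAMatrix) else compute_ma(data)


# ---------------------------------------------------------------------------
# (i) LOWESS
# ---------------------------------------------------------------------------


def _lowess_fit(m: np.ndarray, a: np.ndarray, span: float, iterations: int) -> np.ndarray:
    """Robust local-regression fit of m on a, evaluated at each a."""
    span_range = float(a.max() - a.min())
    # delta collapses near-duplicate abscissae; linear interpolation between
    # fitted anchors, which is what makes n ~ 1e5 tractable
    return _sm_lowess(
        m, a, frac=span, it=iterations, delta=0.01 * span_range, return_sorted=False
    )


def lowess_normalize(
    data: ExperimentSet | MAMatrix, span: float = 0.3, iterations: int = 4
) -> NormalizationResult:
    """LOWESS normalization applied to each microarray individually.

    Fits a robust locally weighted regression of M on A per array and
    subtracts the fitted intensity-dependent trend; assumes the log-ratio
    distribution is centered around zero at every intensity.  A is
    unchanged.
    """
    ma = _as_ma(data)
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if ma.n_probes < 10:
        raise ValueError("lowess_normalize needs at least 10 probes per array")
    if ma.n_probes * span < 2:
        raise ValueError("span too small for the number of probes")
    M_norm = np.empty_like(ma.M)
    trends = []
    for j in range(ma.n_arrays):
        fit = _lowess_fit(ma.M[:, j], ma.A[:, j], span, iterations)
        M_norm[:, j] = ma.M[:, j] - fit
        trends.append(
            {"fit_min": float(fit.min()), "fit_max": float(fit.max()), "fit_mean": float(fit.mean())}
        )
    return NormalizationResult(
        NormalizationMethod.LOWESS,
        M_norm,
        ma.A.copy(),
        ma.array_ids,
        {"span": span, "iterations": iterations, "trend": trends},
    )


# ---------------------------------------------------------------------------
# (ii) quantile / (iv) T-quantile
# ---------------------------------------------------------------------------


def _channel_intensities(
    experiment: ExperimentSet | MAMatrix,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Raw green/red intensity matrices (probes x arrays) of the input."""
    if isinstance(experiment, MAMatrix):
        ma = experiment
        return (
            2.0 ** (ma.A - ma.M / 2.0),
            2.0 ** (ma.A + ma.M / 2.0),
            list(ma.array_ids),
        )
    return (
        np.column_stack([a.green for a in experiment.arrays]),
        np.column_stack([a.red for a in experiment.arrays]),
        list(experiment.array_ids),
    )


def _quantile_columns(X: np.ndarray) -> np.ndarray:
    """Classic quantile normalization of the columns of X.

    Each value is replaced by the mean of same-rank values across columns;
    tied values within a column receive the mean of the scores their
    positions would get, keeping the map well defined and deterministic.
    """
    n, _ = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_X = np.take_along_axis(X, order, axis=0)
    target = sorted_X.mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[order[:, j], j] = target
        uniq, inverse, counts = np.unique(X[:, j], return_inverse=True, return_counts=True)
        if len(uniq) < n:  # average scores over ties
            sums = np.bincount(inverse, weights=out[:, j])
            out[:, j] = (sums / counts)[inverse]
    return out


def quantile_normalize(experiment: ExperimentSet | MAMatrix) -> NormalizationResult:
    """Quantile normalization of all channels — green and red — together.

    All 2·n_arrays raw-intensity channel vectors are pooled and each value
    is replaced by the mean of same-rank values across channels, so after
    the transform every channel has an identical distribution; M and A are
    recomputed from the normalized channels.
    """
    greens, reds, array_ids = _channel_intensities(experiment)
    J = greens.shape[1]
    if 2 * J < 2:
        raise ValueError("quantile normalization needs at least two channels")
    X = np.column_stack([greens, reds])
    Xn = _quantile_columns(X)
    lg_n, lr_n = np.log2(Xn[:, :J]), np.log2(Xn[:, J:])
    return NormalizationResult(
        NormalizationMethod.QUANTILE,
        lr_n - lg_n,
        (lr_n + lg_n) / 2.0,
        list(array_ids),
        {"n_channels": 2 * J},
    )


def tquantile_normalize(experiment: ExperimentSet | MAMatrix) -> NormalizationResult:
    """T-quantile normalization: quantile normalization within subgroups,
    here applied to the red and the green channels separately.

    The green channels of all arrays are equalized among themselves and
    likewise the red channels, so within-array within-channel probe ranks
    are preserved exactly while the red and green distributions remain
    free to differ — the property that preserves the enriched component.
    Requires >= 2 arrays (it is a between-array method).
    """
    greens, reds, array_ids = _channel_intensities(experiment)
    if greens.shape[1] < 2:
        raise ValueError("tquantile_normalize needs at least 2 arrays")
    lg_n = np.log2(_quantile_columns(greens))
    lr_n = np.log2(_quantile_columns(reds))
    return NormalizationResult(
        NormalizationMethod.TQUANTILE,
        lr_n - lg_n,
        (lr_n + lg_n) / 2.0,
        list(array_ids),
        {"n_arrays": greens.shape[1]},
    )


# ---------------------------------------------------------------------------
# (iii) VSN-style calibrated glog
# ---------------------------------------------------------------------------


def _glog2(y: np.ndarray) -> np.ndarray:
    """glog2(y) = log2(y + sqrt(y**2 + 1)) = arcsinh(y) / ln 2."""
    return np.arcsinh(y) / LN2


def vsn_normalize(
    experiment: ExperimentSet,
    trim_fraction: float = 0.10,
    max_outer: int = 30,
    subsample: int = 2000,
) -> NormalizationResult:
    """VSN-style variance stabilizing normalization between arrays and channels.

    Each channel c is calibrated by an affine map and transformed by the
    generalized log, h_c(x) = glog2((x - a_c) / b_c).  Parameters are
    estimated by a trimmed Gaussian profile likelihood: the squared
    deviations of each probe's transformed values from their
    across-channel mean are summed over the (1 - trim_fraction) majority
    of probes with the smallest deviations — the "most probes are
    un-enriched" assumption — and the log-Jacobian of the transforms
    keeps the calibration identifiable (without it, compressing a channel
    toward a constant would trivially minimize the disagreement).  The
    fit alternates (retained set | parameter optimization) until the
    retained set is stable; parameters are estimated on a deterministic
    intensity-stratified subsample (``subsample`` probes) and the
    transform applied to every probe.

    Returns M = h_red - h_green, A = (h_red + h_green)/2; each h_c is
    monotone increasing, so within-channel ranks are preserved, but the
    joint calibration pulls the channel distributions together.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    greens = np.column_stack([a.green for a in experiment.arrays])
    reds = np.column_stack([a.red for a in experiment.arrays])
    X = np.column_stack([greens, reds])  # n x C raw intensities
    n, C = X.shape
    if C < 2:
        raise ValueError("vsn_normalize needs at least 2 channels")

    # deterministic stratified subsample along mean log-intensity
    if n > subsample:
        order = np.argsort(np.log2(X).mean(axis=1), kind="stable")
        idx = order[np.linspace(0, n - 1, subsample).astype(int)]
    else:
        idx = np.arange(n)
    Xs = X[idx]
    ns = len(idx)
    n_keep = int(np.ceil((1.0 - trim_fraction) * ns))

    a0 = np.zeros(C)
    log_b0 = np.log(np.median(np.abs(Xs - np.median(Xs, axis=0)), axis=0) + 1e-9)
    params = np.concatenate([a0, log_b0])

    def transform(P: np.ndarray, x: np.ndarray) -> np.ndarray:
        a, b = P[:C], np.exp(P[C:])
        return _glog2((x - a) / b)

    def residuals(P: np.ndarray) -> np.ndarray:
        H = transform(P, Xs)
        return ((H - H.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)

    trace: list[dict] = []
    keep = np.argsort(residuals(params), kind="stable")[:n_keep]
    converged = False
    scale_span = float(np.ptp(Xs))
    bounds = [(-2.0 * scale_span, 2.0 * scale_span)] * C + [
        (lb - 8.0, lb + 8.0) for lb in log_b0
    ]
    prev_obj = np.inf
    for outer in range(max_outer):
        Xk = Xs[keep]
        n_obs = Xk.size

        def objective(P: np.ndarray) -> tuple[float, np.ndarray]:
            # trimmed Gaussian profile likelihood (negative, up to constants):
            # (n/2) log RSS minus the summed log-Jacobian of the glog maps,
            # with its analytic gradient in (a_c, log b_c)
            a, b = P[:C], np.exp(P[C:])
            u = Xk - a
            q = u * u + b * b
            H = _glog2(u / b)
            R = H - H.mean(axis=1, keepdims=True)
            rss = float((R * R).sum())
            f = (n_obs / 2.0) * np.log(rss + 1e-300) + 0.5 * float(np.log(q).sum())
            s = 1.0 / (LN2 * np.sqrt(q))
            d_a = (n_obs / rss) * (R * -s).sum(axis=0) - (u / q).sum(axis=0)
            d_logb = (n_obs / rss) * (R * (-u * s)).sum(axis=0) + (
                b * b / q
            ).sum(axis=0)
            return f, np.concatenate([d_a, d_logb])

        res = minimize(
            objective, params, method="L-BFGS-B", jac=True, bounds=bounds,
            options={"maxiter": 300},
        )
        params = res.x
        new_keep = np.argsort(residuals(params), kind="stable")[:n_keep]
        trace.append({"outer": outer, "objective": float(res.fun)})
        if np.array_equal(new_keep, keep) or abs(prev_obj - res.fun) < 1e-8 * (
            1.0 + abs(res.fun)
        ):
            converged = True
            break
        keep = new_keep
        prev_obj = res.fun
    if not converged:
        raise VsnConvergenceError(
            f"VSN-style calibration did not stabilize in {max_outer} outer iterations",
            trace,
        )

    H = transform(params, X)
    hg, hr = H[:, : C // 2], H[:, C // 2 :]
    a_fit, b_fit = params[:C], np.exp(params[C:])
    return NormalizationResult(
        NormalizationMethod.VSN,
        hr - hg,
        (hr + hg) / 2.0,
        list(experiment.array_ids),
        {
            "offsets": a_fit.tolist(),
            "scales": b_fit.tolist(),
            "trim_fraction": trim_fraction,
            "n_outer": len(trace),
            "trace": trace,
        },
    )


# ---------------------------------------------------------------------------
# (v) Tukey's biweight scaling
# ---------------------------------------------------------------------------


def tukey_biweight(
    values: np.ndarray, c: float = 5.0, max_iter: int = 50, tol: float = 1e-6
) -> float:
    """Tukey-biweight robust location estimate of a vector.

    Starts at the median with scale MAD = median(|x - median|); iterates
    weighted means with bisquare weights w = (1 - u**2)**2 for |u| < 1 and
    0 otherwise, u = (x - current) / (c * MAD), until the step is below
    ``tol`` or ``max_iter`` is reached.  Weights fall off with distance
    from the center, so outliers barely influence the estimate.  If MAD is
    zero (all values equal up to a majority) the median is returned.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("tukey_biweight needs >= 1 finite value")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        return med
    est = med
    for _ in range(max_iter):
        u = (x - est) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        new = float(np.sum(w * x) / np.sum(w))
        if abs(new - est) < tol:
            return new
        est = new
    return est


def tbw_scale(
    data: ExperimentSet | MAMatrix,
    c: float = 5.0,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> NormalizationResult:
    """Tukey's biweight scaling: per-array centering of the log-ratios.

    Subtracts from each array's M vector its Tukey-biweight location (the
    robust estimate of the median).  Since each array is only shifted by a
    constant, all rank-based statistics — ROC curves in particular — are
    identical to those of the raw data within each array.
    """
    ma = _as_ma(data)
    centers = [tukey_biweight(ma.M[:, j], c=c, max_iter=max_iter, tol=tol) for j in range(ma.n_arrays)]
    M_norm = ma.M - np.asarray(centers)[None, :]
    return NormalizationResult(
        NormalizationMethod.TBW,
        M_norm,
        ma.A.copy(),
        ma.array_ids,
        {"scale_factors": [float(v) for v in centers], "c": c},
    )


# ---------------------------------------------------------------------------
# (vi) Peng's method
# ---------------------------------------------------------------------------


def _principal_slope(a: np.ndarray, m: np.ndarray) -> float:
    """Total-least-squares (major-axis) slope of the (a, m) cloud."""
    ac, mc = a - a.mean(), m - m.mean()
    cov = np.cov(np.vstack([ac, mc]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]  # first principal direction
    if abs(v[0]) < 1e-12:
        raise ValueError("degenerate MA cloud: zero variance along A")
    return float(v[1] / v[0])


def peng_normalize(
    data: ExperimentSet | MAMatrix, span: float = 0.3, iterations: int = 4
) -> NormalizationResult:
    """Peng's method: MA-cloud rotation followed by LOWESS.

    Per array: (1) estimate the major-axis slope of the (A, M) point cloud
    by total least squares (first principal direction); (2) rotate the
    cloud about its centroid by -atan(slope) so the dominant dye trend is
    horizontal; (3) LOWESS-detrend the rotated coordinates.  Makes strong
    assumptions about the shape of the MA plot; the rotation angle per
    array is reported in the diagnostics.
    """
    ma = _as_ma(data)
    if ma.n_probes < 10:
        raise ValueError("peng_normalize needs at least 10 probes per array")
    if np.any(ma.A.std(axis=0) < 1e-12):
        raise ValueError("degenerate input: zero-variance A column")
    M_norm = np.empty_like(ma.M)
    A_norm = np.empty_like(ma.A)
    angles = []
    for j in range(ma.n_arrays):
        a, m = ma.A[:, j], ma.M[:, j]
        slope = _principal_slope(a, m)
        theta = np.arctan(slope)
        ca, sa = np.cos(-theta), np.sin(-theta)
        a0, m0 = a.mean(), m.mean()
        a_rot = a0 + ca * (a - a0) - sa * (m - m0)
        m_rot = m0 + sa * (a - a0) + ca * (m - m0)
        fit = _lowess_fit(m_rot, a_rot, span, iterations)
        M_norm[:, j] = m_rot - fit
        A_norm[:, j] = a_rot
        angles.append(float(theta))
    return NormalizationResult(
        NormalizationMethod.PENG,
        M_norm,
        A_norm,
        ma.array_ids,
        {"rotation_angles": angles, "estimator": "total-least-squares", "span": span},
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def normalize(
    experiment: ExperimentSet,
    method: NormalizationMethod | str,
    **kwargs,
) -> NormalizationResult:
    """Apply one of the six normalization methods to an experiment."""
    method = NormalizationMethod(method) if isinstance(method, str) else method
    if method is NormalizationMethod.LOWESS:
        return lowess_normalize(experiment, **kwargs)
    if method is NormalizationMethod.QUANTILE:
        return quantile_normalize(experiment, **kwargs)
    if method is NormalizationMethod.VSN:
        return vsn_normalize(experiment, **kwargs)
    if method is NormalizationMethod.TQUANTILE:
        return tquantile_normalize(experiment, **kwargs)
    if method is NormalizationMethod.TBW:
        return tbw_scale(experiment, **kwargs)
    if method is NormalizationMethod.PENG:
        return peng_normalize(experiment, **kwargs)
    raise ValueError(f"unknown method {method!r}")
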