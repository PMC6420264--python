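"""Cumulative-Gaussian psychometric function fitting for 2AFC data.

The model for the probability of judging a comparison of intensity ``x``
greater than the standard is

    P(x) = lambda/2 + (1 - lambda) * Phi((x - pse) / sigma)

where ``pse`` is the point of subjective equality (50% point for
lambda = 0), ``sigma`` the spread of the underlying Gaussian, and
``lambda`` an optional lapse rate compressing the asymptotes.
Parameters are estimated by binomial maximum likelihood; the classic
least-squares "function deviation" (sum of squared distances between
observed proportions and the fitted curve) is retained purely as a
fit-quality metric.

The JND is extracted as half the distance between the 25% and 75% points
of the fitted curve, by numerical inversion, so lapse-enabled fits remain
correct; for a lapse-free fit it equals ``Phi^{-1}(0.75) * sigma``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: z-score of the 75th percentile; JND/sigma for a lapse-free fit
Z75 = float(norm.ppf(0.75))

_EPS = 1e-12


class FitError(ValueError):
    """Raised when a psychometric fit is impossible or non-identifiable."""


def aggregate_binomial(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse binary 2AFC trials into per-cell counts.

    Groups by (standard, brightness, comparison) and returns one row per
    cell with ``n_heavier`` (responses == 1) and ``n_total``.  The
    brightness column is carried through when present (NaN-safe).
    Returns an empty frame for empty input.
    """
    cols = ["standard", "brightness", "comparison"]
    keys = [c for c in cols if c in trials.columns]
    if "standard" not in keys or "comparison" not in keys:
        raise ValueError("trial table needs 'standard' and 'comparison' columns")
    out_cols = keys + ["n_heavier", "n_total"]
    if trials.empty:
        return pd.DataFrame(columns=out_cols)
    g = trials.groupby(keys, dropna=False, sort=True)["response"]
    out = g.agg(n_heavier="sum", n_total="count").reset_index()
    out["n_heavier"] = out["n_heavier"].astype(int)
    out["n_total"] = out["n_total"].astype(int)
    return out[out_cols]


def _as_counts(X, y, sample_weight):
    """Normalise inputs to (levels x, successes k, totals n) arrays.

    Accepts per-trial binary ``y`` (sample_weight = trial multiplicity) or
    per-level proportions in [0, 1] with sample_weight = trial counts.
    """
    x = np.asarray(X, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError("X and y must have matching lengths")
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("responses must be binary or proportions in [0, 1]")
    levels, inv = np.unique(x, return_inverse=True)
    k = np.zeros(levels.size)
    n = np.zeros(levels.size)
    np.add.at(k, inv, y * w)
    np.add.at(n, inv, w)
    return levels, k, n


def _psychometric_p(x, pse, sigma, lapse):
    return lapse / 2.0 + (1.0 - lapse) * norm.cdf((x - pse) / sigma)


class CumulativeGaussianPsychometric(BaseEstimator):
    """Maximum-likelihood cumulative-Gaussian psychometric function.

    A scikit-learn style estimator: ``fit(X, y)`` takes comparison
    intensities (n_trials,) or (n_trials, 1) and binary "judged greater"
    responses (or per-level proportions with ``sample_weight`` giving the
    trial counts); ``predict_proba`` returns the fitted choice
    probabilities.

    Parameters
    ----------
    fit_lapse : bool, default False
        Estimate the lapse rate (bounded by `lapse_max`) instead of
        holding it fixed at `lapse`.
    lapse : float, default 0.0
        Fixed lapse rate when `fit_lapse` is False.
    lapse_max : float, default 0.2
        Upper bound for an estimated lapse rate.
    n_grid : int, default 13
        Coarse-grid resolution per axis for the multi-start search.

    Attributes
    ----------
    pse_ : float
        Point of subjective equality (location).
    sigma_ : float
        Spread of the cumulative Gaussian.
    lapse_ : float
        Lapse rate used by the fitted curve.
    loglik_ : float
        Binomial log-likelihood at the optimum.
    deviation_ : float
        Sum of squared distances between observed proportions and the
        fitted curve (fit-quality metric).
    converged_ : bool
        False when no optimiser start converged; never silent (logged).
    """

    def __init__(self, fit_lapse=False, lapse=0.0, lapse_max=0.2, n_grid=13):
        self.fit_lapse = fit_lapse
        self.lapse = lapse
        self.lapse_max = lapse_max
        self.n_grid = n_grid

    # -- likelihood ----------------------------------------------------
    @staticmethod
    def _nll(params, x, k, n, fixed_lapse):
        pse, log_sigma = params[0], params[1]
        lapse = params[2] if fixed_lapse is None else fixed_lapse
        p = _psychometric_p(x, pse, np.exp(log_sigma), lapse)
        p = np.clip(p, _EPS, 1.0 - _EPS)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    def fit(self, X, y, sample_weight=None):
        """Fit by binomial MLE with a probit-regression start plus a
        coarse-grid multi-start; sets the fitted attributes."""
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")
        x, k, n = _as_counts(X, y, sample_weight)
        if x.size < 3:
            raise FitError(f"need >= 3 distinct comparison levels, got {x.size}")
        total_k, total_n = k.sum(), n.sum()
        if total_k == 0 or total_k == total_n:
            raise FitError(
                "responses are all identical (all 0 or all 1): "
                "psychometric parameters are not identifiable"
            )

        span = float(x.max() - x.min())
        # probit-regression initialisation on clipped proportions
        p_obs = np.clip(k / n, 1.0 / (2.0 * n.max() + 2), 1.0 - 1.0 / (2.0 * n.max() + 2))
        z = norm.ppf(p_obs)
        slope, intercept = np.polyfit(x, z, 1)
        starts = []
        if slope > 0:
            starts.append((-intercept / slope, np.log(1.0 / slope)))
        # best point of a coarse (pse, sigma) grid under the same likelihood
        pse_grid = np.linspace(x.min(), x.max(), self.n_grid)
        sig_grid = np.geomspace(span / 50.0, span * 2.0, self.n_grid)
        P, S = np.meshgrid(pse_grid, sig_grid)
        lapse0 = self.lapse if not self.fit_lapse else 0.02
        pm = _psychometric_p(x[None, None, :], P[..., None], S[..., None], lapse0)
        pm = np.clip(pm, _EPS, 1.0 - _EPS)
        nll_grid = -np.sum(k * np.log(pm) + (n - k) * np.log1p(-pm), axis=-1)
        j = np.unravel_index(np.argmin(nll_grid), nll_grid.shape)
        starts.append((float(P[j]), float(np.log(S[j]))))

        fixed_lapse = None if self.fit_lapse else self.lapse
        log_sig_lo, log_sig_hi = np.log(span / 200.0), np.log(span * 20.0)
        bounds = [(x.min() - 2 * span, x.max() + 2 * span), (log_sig_lo, log_sig_hi)]
        if self.fit_lapse:
            bounds.append((0.0, self.lapse_max))

        best = None
        converged = False
        for s in starts:
            theta0 = list(s) + ([lapse0] if self.fit_lapse else [])
            theta0[1] = float(np.clip(theta0[1], log_sig_lo, log_sig_hi))
            res = minimize(
                self._nll,
                theta0,
                args=(x, k, n, fixed_lapse),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)

        self.pse_ = float(best.x[0])
        self.sigma_ = float(np.exp(best.x[1]))
        self.lapse_ = float(best.x[2]) if self.fit_lapse else float(self.lapse)
        self.loglik_ = -float(best.fun)
        self.converged_ = converged
        if not converged:
            logger.warning(
                "psychometric fit did not converge (pse=%.3g, sigma=%.3g)",
                self.pse_,
                self.sigma_,
            )
        self.levels_ = x
        self.deviation_ = float(np.sum((k / n - self.proportion(x)) ** 2))
        return self

    # -- fitted-curve queries ------------------------------------------
    def proportion(self, X) -> np.ndarray:
        """Fitted P("judged greater") at the given comparison intensities."""
        x = np.asarray(X, dtype=float).reshape(-1)
        return _psychometric_p(x, self.pse_, self.sigma_, self.lapse_)

    def predict_proba(self, X) -> np.ndarray:
        p = self.proportion(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.proportion(X) >= 0.5).astype(int)

    def inverse(self, p: float, tol: float = 1e-6) -> float:
        """Comparison intensity at which the fitted curve attains ``p``.

        Bisection on the full fitted curve (lapse included); raises when
        the asymptotes exclude ``p``.
        """
        lo_asym, hi_asym = self.lapse_ / 2.0, 1.0 - self.lapse_ / 2.0
        if not lo_asym < p < hi_asym:
            raise FitError(
                f"fitted curve spans ({lo_asym:.3f}, {hi_asym:.3f}); cannot attain p={p}"
            )
        q = (p - self.lapse_ / 2.0) / (1.0 - self.lapse_)
        half = max(abs(norm.ppf(q)) + 1.0, 2.0) * self.sigma_
        f = lambda v: float(_psychometric_p(v, self.pse_, self.sigma_, self.lapse_)) - p
        return float(brentq(f, self.pse_ - half, self.pse_ + half, xtol=tol))

    def jnd(self, lower: float = 0.25, upper: float = 0.75) -> float:
        """Half the span between the lower and upper response quantiles."""
        return 0.5 * (self.inverse(upper) - self.inverse(lower))


def fit_cumulative_gaussian(
    points: pd.DataFrame, **options
) -> CumulativeGaussianPsychometric:
    """Fit one psychometric function to a table of binomial points.

    ``points`` must carry columns comparison / n_heavier / n_total for a
    single (participant, standard, brightness) cell.
    """
    est = CumulativeGaussianPsychometric(**options)
    return est.fit(
        points["comparison"].to_numpy(dtype=float),
        points["n_heavier"].to_numpy(dtype=float) / points["n_total"].to_numpy(dtype=float),
        sample_weight=points["n_total"].to_numpy(dtype=float),
    )


def jnd_quartile(fit: CumulativeGaussianPsychometric) -> float:
    """JND = (x75 − x25)/2 from the fitted curve by numerical inversion."""
    return fit.jnd(0.25, 0.75)


def weber_fraction_fit(fit: CumulativeGaussianPsychometric, standard: float) -> dict:
    """Weber fractions of a fitted function: JND normalised to the
    perceived (PSE) and the physical (standard) intensity."""
    if fit.pse_ <= 0:
        raise ValueError(f"nonpositive PSE {fit.pse_}; cannot form JND/PSE fraction")
    if standard <= 0:
        raise ValueError(f"nonpositive standard {standard}")
    j = jnd_quartile(fit)
    return {"jnd_over_pse": j / fit.pse_, "jnd_over_standard": j / standard}


def function_deviation(
    fit: CumulativeGaussianPsychometric, points: pd.DataFrame
) -> float:
    """Sum of squared distances between observed proportions and the
    fitted curve; zero iff the curve interpolates every point."""
    p_obs = points["n_heavier"].to_numpy(dtype=float) / points["n_total"].to_numpy(dtype=float)
    p_fit = fit.proportion(points["comparison"].to_numpy(dtype=float))
    return float(np.sum((p_obs - p_fit) ** 2))


def fit_participants(trials: pd.DataFrame, **options) -> pd.DataFrame:
    """Fit one psychometric function per (participant, standard[, brightness]).

    Returns a tidy frame with pse, sigma, lapse, jnd, both Weber
    fractions, deviation and a convergence flag.  Non-identifiable cells
    (all responses identical) are reported with ``converged = False`` and
    NaN parameters, with the reason logged — never silently dropped.
    """
    rows = []
    keys = ["participant", "group", "standard"]
    has_brightness = "brightness" in trials.columns and trials["brightness"].notna().any()
    if has_brightness:
        keys.append("brightness")
    for key, sub in trials.groupby(keys, dropna=False, sort=True):
        rec = dict(zip(keys, key))
        points = aggregate_binomial(sub)
        try:
            fit = fit_cumulative_gaussian(points, **options)
            j = jnd_quartile(fit)
            std = float(rec["standard"])
            rec.update(
                pse=fit.pse_,
                sigma=fit.sigma_,
                lapse=fit.lapse_,
                jnd=j,
                jnd_over_pse=j / fit.pse_ if fit.pse_ > 0 else np.nan,
                jnd_over_standard=j / std if std > 0 else np.nan,
                deviation=fit.deviation_,
                converged=fit.converged_,
            )
        except FitError as exc:
            logger.warning("fit failed for %s: %s", rec, exc)
            rec.update(
                pse=np.nan,
                sigma=np.nan,
                lapse=np.nan,
                jnd=np.nan,
                jnd_over_pse=np.nan,
                jnd_over_standard=np.nan,
                deviation=np.nan,
                converged=False,
            )
        rows.append(rec)
    return pd.DataFrame(rows)
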