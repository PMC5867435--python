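"""Cumulative-logit ordinal regression with threshold-specific slopes.

The model relates a continuous predictor x (here, the collective judgement
score at inspection start) to an ordinal outcome with K ordered categories
(here, K=4 inspection ratings, Inadequate < Requires improvement < Good <
Outstanding) through

    P(rating <= k | x) = sigmoid(theta_k + beta_k * x),   k = 1..K-1.

With ``proportional=True`` the slopes are constrained equal (beta_k == beta,
the proportional-odds model); the default leaves one slope per threshold, so
each boundary between "worse" and "better" categories gets its own odds
ratio exp(beta_k).  Negative slopes mean a higher score lowers the odds of a
worse-or-equal rating.

Estimation is maximum likelihood: quasi-Newton (BFGS) started from the
proportional-odds solution, followed by Newton refinement with a
finite-difference Hessian of the analytic gradient; standard errors come
from the inverse observed information.

Usage follows the Model/Results convention::

    model = CumulativeLogitModel.from_dataframe(paired, score_col="cjs")
    res = model.fit()
    print(res.summary())
    res.odds_ratios(); res.conf_int(); res.predict(4.0)
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .types import RATING_LEVELS, ValidationError, rating_index

logger = logging.getLogger("carevoice")

Z_975 = norm.ppf(0.975)  # 1.959964

_PARAM_BOUND = 80.0  # |parameter| beyond this is treated as (quasi-)separation


class ConvergenceError(RuntimeError):
    """Raised when the likelihood is unbounded (separation) or the optimiser fails."""


def odds_ratio(beta: float) -> float:
    """Odds ratio for a one-unit increase of the predictor: exp(beta)."""
    return float(np.exp(beta))


def wald_interval(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for exp(beta): exp(beta -/+ z * se)."""
    if se <= 0:
        raise ValidationError(f"standard error must be positive, got {se}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must lie in (0, 1), got {level}")
    z = norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _encode_ratings(ratings: Sequence) -> np.ndarray:
    out = np.empty(len(ratings), dtype=np.int64)
    for i, r in enumerate(ratings):
        if isinstance(r, str):
            out[i] = rating_index(r)
        else:
            out[i] = int(r)
    if out.size and (out.min() < 0 or out.max() >= len(RATING_LEVELS)):
        raise ValidationError("rating codes must lie in 0..3")
    return out


class CumulativeLogitModel:
    """Ordinal outcome model built from (score, rating) pairs.

    Parameters
    ----------
    score : array-like of float
        Continuous predictor, one value per observation.
    rating : array-like
        Ordinal outcomes as rating strings or 0-based integer codes
        (0 = Inadequate ... 3 = Outstanding).
    proportional : bool
        Constrain the slopes to a common beta (proportional odds).
    """

    def __init__(self, score, rating, proportional: bool = False):
        self.x = np.asarray(score, dtype=float)
        y_full = _encode_ratings(list(rating))
        if self.x.shape != y_full.shape:
            raise ValidationError("score and rating must have equal length")
        if self.x.size == 0:
            raise ValidationError("empty data")
        present = np.unique(y_full)
        if present.size < 2:
            raise ValidationError("at least 2 rating categories must be present")
        counts = np.bincount(y_full, minlength=len(RATING_LEVELS))
        for k, c in enumerate(counts):
            if c == 0:
                logger.warning(
                    "category %r has zero observations; fit proceeds but the adjacent "
                    "thresholds are weakly identified", RATING_LEVELS[k],
                )
        # Empty *extreme* categories leave their boundary threshold without a
        # maximum-likelihood estimate (it drifts to +/- infinity); collapse
        # them so the fit runs over the observed category range only.
        lo = int(present.min())
        hi = int(present.max())
        if lo > 0 or hi < len(RATING_LEVELS) - 1:
            logger.warning(
                "empty extreme categories collapsed; thresholds fitted for %s",
                RATING_LEVELS[lo:hi],
            )
        self.cat_offset = lo
        self.n_categories = hi - lo + 1
        self.y = y_full - lo
        self.proportional = proportional
        self.n_thresholds = self.n_categories - 1
        self.nobs = self.x.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, score_col: str = "cjs", rating_col: str = "rating",
                       proportional: bool = False) -> "CumulativeLogitModel":
        return cls(df[score_col].to_numpy(), df[rating_col].to_numpy(), proportional=proportional)

    # -- likelihood ---------------------------------------------------------

    def _unpack(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = self.n_thresholds
        thetas = params[:m]
        betas = np.full(m, params[m]) if self.proportional else params[m:]
        return thetas, betas

    def _cell_probs(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-observation category probability p_i, plus F and f=F(1-F) matrices."""
        thetas, betas = self._unpack(params)
        eta = thetas[None, :] + betas[None, :] * self.x[:, None]  # (n, m)
        F = expit(eta)
        n = self.nobs
        m = self.n_thresholds
        Fpad = np.concatenate([np.zeros((n, 1)), F, np.ones((n, 1))], axis=1)
        idx = np.arange(n)
        p = Fpad[idx, self.y + 1] - Fpad[idx, self.y]
        return p, F, F * (1.0 - F)

    def loglike(self, params: np.ndarray) -> float:
        p, _, _ = self._cell_probs(np.asarray(params, dtype=float))
        return float(np.sum(np.log(np.clip(p, 1e-300, None))))

    def _nll_grad(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        params = np.asarray(params, dtype=float)
        p, F, f = self._cell_probs(params)
        pc = np.clip(p, 1e-12, None)
        nll = -np.sum(np.log(pc))
        n = self.nobs
        m = self.n_thresholds
        G = np.zeros((n, m))
        idx = np.arange(n)
        upper = self.y <= m - 1  # F_{y+1} term exists unless y is the top category
        iu = idx[upper]
        G[iu, self.y[upper]] += f[iu, self.y[upper]] / pc[upper]
        lower = self.y >= 1
        il = idx[lower]
        G[il, self.y[lower] - 1] -= f[il, self.y[lower] - 1] / pc[lower]
        g_theta = -G.sum(axis=0)
        gx = -(G * self.x[:, None])
        if self.proportional:
            grad = np.concatenate([g_theta, [gx.sum()]])
        else:
            grad = np.concatenate([g_theta, gx.sum(axis=0)])
        return float(nll), grad

    def score(self, params: np.ndarray) -> np.ndarray:
        """Gradient of the log-likelihood."""
        return -self._nll_grad(params)[1]

    def _hessian_nll(self, params: np.ndarray) -> np.ndarray:
        """Observed information: central finite differences of the analytic gradient."""
        params = np.asarray(params, dtype=float)
        k = params.size
        H = np.zeros((k, k))
        for j in range(k):
            h = 1e-5 * max(1.0, abs(params[j]))
            up = params.copy(); up[j] += h
            dn = params.copy(); dn[j] -= h
            H[:, j] = (self._nll_grad(up)[1] - self._nll_grad(dn)[1]) / (2 * h)
        return 0.5 * (H + H.T)

    def _start_params(self) -> np.ndarray:
        cum = np.cumsum(np.bincount(self.y, minlength=self.n_categories))[:-1] / self.nobs
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        thetas = np.log(cum / (1 - cum))
        if self.proportional:
            return np.concatenate([thetas, [0.0]])
        return np.concatenate([thetas, np.zeros(self.n_thresholds)])

    # -- fitting ------------------------------------------------------------

    def fit(self, start_params: Optional[np.ndarray] = None, gtol: float = 1e-6,
            maxiter: int = 500) -> "CumulativeLogitResults":
        """Maximise the likelihood and return a results object.

        Raises :class:`ConvergenceError` on (quasi-)separation — parameter
        estimates running away while the likelihood stays unbounded.
        """
        if start_params is None:
            if self.proportional:
                start = self._start_params()
            else:
                # start the threshold-specific fit from the proportional-odds optimum
                prop = CumulativeLogitModel(self.x, self.y, proportional=True)
                try:
                    prop_res = prop.fit(gtol=max(gtol, 1e-5))
                    start = np.concatenate([prop_res.thetas, prop_res.betas])
                except ConvergenceError:
                    start = self._start_params()
        else:
            start = np.asarray(start_params, dtype=float)

        res = minimize(self._nll_grad, start, jac=True, method="BFGS",
                       options={"gtol": gtol * 1e-2, "maxiter": maxiter})
        params = res.x

        # Newton refinement: quadratic convergence to gradient norms BFGS
        # alone rarely reaches, plus the Hessian we need for the covariance.
        H = None
        for _ in range(50):
            nll, grad = self._nll_grad(params)
            if np.max(np.abs(params)) > _PARAM_BOUND:
                raise ConvergenceError(
                    "parameter estimates diverged: data are (quasi-)separated and the "
                    "likelihood is unbounded"
                )
            if np.max(np.abs(grad)) < gtol:
                break
            H = self._hessian_nll(params)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            scale = 1.0
            for _ in range(30):  # backtrack until the objective improves
                trial = params - scale * step
                if self._nll_grad(trial)[0] <= nll + 1e-12:
                    break
                scale *= 0.5
            params = params - scale * step

        nll, grad = self._nll_grad(params)
        gnorm = float(np.max(np.abs(grad)))
        if np.max(np.abs(params)) > _PARAM_BOUND:
            raise ConvergenceError(
                "parameter estimates diverged: data are (quasi-)separated and the "
                "likelihood is unbounded"
            )
        # a (near-)perfect fit means the data are separated and the MLE sits at
        # infinity: the likelihood plateaus, so the gradient check alone would
        # wrongly report convergence
        p_fit, _, _ = self._cell_probs(params)
        if p_fit.min() > 0.999:
            raise ConvergenceError(
                "fitted probabilities are all ~1: data are separated and the "
                "likelihood is unbounded"
            )
        converged = gnorm < gtol
        if not converged:
            logger.warning("fit did not reach gradient tolerance: |grad|_inf = %.3g", gnorm)

        H = self._hessian_nll(params)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            logger.warning("observed information is singular; using pseudo-inverse")
            cov = np.linalg.pinv(H)
        if np.any(np.diag(cov) <= 0):
            logger.warning("non-positive variance estimate; covariance may be unreliable")
        return CumulativeLogitResults(self, params, cov, -nll, converged, gnorm)


class CumulativeLogitResults:
    """Estimates, uncertainties and inference for a fitted cumulative-logit model."""

    def __init__(self, model: CumulativeLogitModel, params: np.ndarray, cov: np.ndarray,
                 llf: float, converged: bool, gnorm: float):
        self.model = model
        self._params = np.asarray(params, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.gnorm = float(gnorm)
        self.nobs = model.nobs
        m = model.n_thresholds
        off = model.cat_offset
        self.threshold_labels = list(RATING_LEVELS[off : off + m])
        names = [f"theta[{lab}]" for lab in self.threshold_labels]
        if model.proportional:
            names += ["beta"]
        else:
            names += [f"beta[{lab}]" for lab in self.threshold_labels]
        self.param_names = names

    # -- parameter views ----------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.param_names)

    @property
    def thetas(self) -> np.ndarray:
        return self._params[: self.model.n_thresholds].copy()

    @property
    def betas(self) -> np.ndarray:
        m = self.model.n_thresholds
        if self.model.proportional:
            return np.full(m, self._params[m])
        return self._params[m:].copy()

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self.cov), 0, None)), index=self.param_names)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov, index=self.param_names, columns=self.param_names)

    @property
    def pvalues(self) -> pd.Series:
        se = self.bse.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self._params / se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.param_names)

    def _require_converged(self) -> None:
        if not self.converged:
            raise ConvergenceError("inference requested on a non-converged fit")

    # -- inference on the odds-ratio scale ----------------------------------

    def odds_ratios(self) -> pd.Series:
        """exp(beta_k): multiplicative change in the odds of a worse-or-equal
        rating per unit of the predictor, one per threshold."""
        self._require_converged()
        labels = self.threshold_labels if not self.model.proportional else ["(all)"]
        betas = self._params[self.model.n_thresholds:]
        return pd.Series([odds_ratio(b) for b in betas], index=labels)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald confidence intervals for the slope odds ratios."""
        self._require_converged()
        m = self.model.n_thresholds
        labels = self.threshold_labels if not self.model.proportional else ["(all)"]
        rows = []
        for i, lab in enumerate(labels):
            b = self._params[m + i]
            se = float(self.bse.iloc[m + i])
            lo, hi = wald_interval(b, se, level)
            rows.append({"threshold": lab, "or_low": lo, "or": odds_ratio(b), "or_high": hi})
        return pd.DataFrame(rows).set_index("threshold")

    def inference_table(self, level: float = 0.95) -> pd.DataFrame:
        """One row per parameter: beta, SE, OR with CI (slopes only), p-value."""
        self._require_converged()
        m = self.model.n_thresholds
        pv = self.pvalues
        se = self.bse
        rows = []
        for i, lab in enumerate(self.threshold_labels):
            rows.append({"term": f"{lab} (intercept)", "beta": self._params[i],
                         "se": se.iloc[i], "or_low": np.nan, "or": np.nan,
                         "or_high": np.nan, "p": pv.iloc[i]})
        slope_labels = self.threshold_labels if not self.model.proportional else ["(all)"]
        for i, lab in enumerate(slope_labels):
            b = self._params[m + i]
            s = float(se.iloc[m + i])
            if s > 0:
                lo, hi = wald_interval(b, s, level)
            else:  # degenerate information (e.g. a near-empty category)
                lo = hi = np.nan
            rows.append({"term": f"{lab} (score)", "beta": b, "se": s,
                         "or_low": lo, "or": odds_ratio(b), "or_high": hi,
                         "p": pv.iloc[m + i]})
        return pd.DataFrame(rows).set_index("term")

    def summary(self, level: float = 0.95) -> str:
        """Plain-text fit summary with Beta (SE), OR and CI bounds, and p."""
        self._require_converged()
        tab = self.inference_table(level)
        lines = [
            "Cumulative-logit ordinal regression"
            + (" (proportional odds)" if self.model.proportional else " (threshold-specific slopes)"),
            f"N = {self.nobs}    log-likelihood = {self.llf:.3f}    converged = {self.converged}",
            "",
            f"{'':34s}{'Beta (SE)':>16s}{'2.5%':>8s}{'OR':>8s}{'97.5%':>8s}{'p':>9s}",
        ]
        for term, row in tab.iterrows():
            beta_se = f"{row['beta']:.2f} ({row['se']:.2f})"
            if np.isnan(row["or"]):
                lines.append(f"{term:34s}{beta_se:>16s}{'':>8s}{'':>8s}{'':>8s}{row['p']:>9.3f}")
            else:
                lines.append(
                    f"{term:34s}{beta_se:>16s}{row['or_low']:>8.2f}{row['or']:>8.2f}"
                    f"{row['or_high']:>8.2f}{row['p']:>9.3f}"
                )
        return "\n".join(lines)

    # -- prediction ---------------------------------------------------------

    def predict(self, score) -> np.ndarray:
        """Category probabilities at the given score(s): shape (4,) or (n, 4).

        For threshold-specific slopes the cumulative curves can cross far
        from the data; negative cell probabilities are clamped at zero and
        the vector renormalised (the event is logged).  Categories collapsed
        for being empty get probability zero.
        """
        self._require_converged()
        probs = predict_probs(self, score)
        off = self.model.cat_offset
        n_full = len(RATING_LEVELS)
        if off == 0 and self.model.n_categories == n_full:
            return probs
        probs2 = np.atleast_2d(probs)
        full = np.zeros((probs2.shape[0], n_full))
        full[:, off : off + self.model.n_categories] = probs2
        return full[0] if np.asarray(score).ndim == 0 else full

    def to_dict(self) -> dict:
        return {
            "proportional": self.model.proportional,
            "params": dict(zip(self.param_names, self._params.tolist())),
            "bse": dict(zip(self.param_names, self.bse.tolist())),
            "llf": self.llf,
            "converged": self.converged,
            "nobs": int(self.nobs),
        }


def fit_cumulative_logit(pairs, proportional: bool = False) -> CumulativeLogitResults:
    """Fit the ordinal model from a (score, rating) DataFrame or pair of arrays."""
    if isinstance(pairs, pd.DataFrame):
        model = CumulativeLogitModel.from_dataframe(pairs, proportional=proportional)
    else:
        score, rating = pairs
        model = CumulativeLogitModel(score, rating, proportional=proportional)
    return model.fit()


def predict_probs(fit, score) -> np.ndarray:
    """Category probabilities under fitted (or explicit) parameters.

    ``fit`` is a :class:`CumulativeLogitResults`, or any object with
    ``thetas`` and ``betas`` arrays of length 3.
    """
    thetas = np.asarray(fit.thetas, dtype=float)
    betas = np.asarray(fit.betas, dtype=float)
    x = np.atleast_1d(np.asarray(score, dtype=float))
    F = expit(thetas[None, :] + betas[None, :] * x[:, None])
    Fpad = np.concatenate([np.zeros((x.size, 1)), F, np.ones((x.size, 1))], axis=1)
    probs = np.diff(Fpad, axis=1)
    if (probs < 0).any():
        logger.info(
            "predict_probs: cumulative curves cross at %d score(s); clamping negative "
            "cell probabilities and renormalising", int((probs < 0).any(axis=1).sum()),
        )
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
    return probs[0] if np.isscalar(score) or np.asarray(score).ndim == 0 else probs


def simulate_ordinal(score, thetas, betas, rng: np.random.Generator) -> np.ndarray:
    """Draw 0-based ordinal categories from the cumulative-logit model."""
    x = np.asarray(score, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    cum = expit(thetas[None, :] + betas[None, :] * x[:, None])
    cum = np.maximum.accumulate(cum, axis=1)  # guard tiny non-monotonicity
    u = rng.uniform(size=x.shape[0])
    return (u[:, None] > cum).sum(axis=1)
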