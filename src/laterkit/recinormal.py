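"""The recinormal (reciprocal-normal) distribution and single-condition fits.

In the LATER race model a decision signal rises linearly from baseline at a
rate drawn afresh on each trial from a normal distribution, and a response is
triggered when the signal reaches a fixed threshold.  The interval ``T`` to
threshold then has normally distributed *promptness* ``P = 1/T``; the induced
distribution of ``T`` is called recinormal.  This module provides the density
and distribution function, the closed-form maximum-likelihood fit on the
promptness scale, the reciprobit transform (reciprocal-time abscissa against
probit ordinate, under which recinormal samples are linear), and a
two-component normal mixture on the promptness scale for datasets that
contain a minor population of unusually fast "early" responses.

The promptness normal is left untruncated: the small mass at non-positive
promptness corresponds to trials that never reach threshold and is ignored in
the likelihood, which keeps the MLE closed-form.  A reliability flag on the
parameters warns when ``mu_p / sigma_p < 2``, i.e. when more than ~2.3% of
promptness mass lies at or below zero and the untruncated approximation
starts to bite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, InsufficientDataError

__all__ = [
    "RecinormalParams",
    "RaceParams",
    "RecinormalFit",
    "ReciprobitPoints",
    "MixtureFit",
    "recinormal_pdf",
    "recinormal_cdf",
    "recinormal_ppf",
    "recinormal_loglik",
    "fit_recinormal",
    "reciprobit_transform",
    "theoretical_reciprobit",
    "fit_early_mixture",
]


@dataclass(frozen=True)
class RecinormalParams:
    """Parameters of a recinormal interval distribution on the promptness scale.

    Parameters
    ----------
    mu_p : float
        Mean promptness (1/s).  For self-paced movement this is the mean
        instantaneous event frequency.
    sigma_p : float
        Standard deviation of promptness (1/s).
    """

    mu_p: float
    sigma_p: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_p) or self.mu_p <= 0:
            raise ValueError(f"mu_p must be finite and > 0, got {self.mu_p}")
        if not np.isfinite(self.sigma_p) or self.sigma_p <= 0:
            raise ValueError(f"sigma_p must be finite and > 0, got {self.sigma_p}")

    @property
    def reliable(self) -> bool:
        """False when mu_p/sigma_p < 2, i.e. >~2.3% promptness mass at or below zero."""
        return self.mu_p / self.sigma_p >= 2.0

    @property
    def intercept(self) -> float:
        """Reciprobit ordinate-intercept at infinite time, mu_p / sigma_p."""
        return self.mu_p / self.sigma_p

    def scaled(self, c: float) -> "RecinormalParams":
        """Parameters after multiplying all intervals by ``c > 0``."""
        return RecinormalParams(self.mu_p / c, self.sigma_p / c)


@dataclass(frozen=True)
class RaceParams:
    """Mechanistic LATER race parameters.

    theta is the baseline-to-threshold distance (arbitrary units), mu_r and
    sigma_r the mean and SD of the linear rate of rise (units/s).  The
    interval distribution depends on these only through the promptness
    parameters ``mu_p = mu_r / theta`` and ``sigma_p = sigma_r / theta``, so
    only two of the three are identifiable from interval data; the package
    convention fixes ``theta = 1`` when converting from promptness parameters.
    """

    theta: float
    mu_r: float
    sigma_r: float

    def __post_init__(self) -> None:
        for name in ("theta", "mu_r", "sigma_r"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    def to_recinormal(self) -> RecinormalParams:
        return RecinormalParams(self.mu_r / self.theta, self.sigma_r / self.theta)

    @classmethod
    def from_recinormal(cls, params: RecinormalParams, theta: float = 1.0) -> "RaceParams":
        return cls(theta=theta, mu_r=params.mu_p * theta, sigma_r=params.sigma_p * theta)


def _validate_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("intervals must be finite and strictly positive")
    return t


def recinormal_pdf(t, params: RecinormalParams):
    """Density of the recinormal distribution at interval(s) ``t`` (1/s units).

    ``f(t) = t^-2 * phi((1/t - mu_p)/sigma_p) / sigma_p`` by change of
    variables from the promptness normal.  Integrates over (0, inf) to
    ``Phi(mu_p/sigma_p)`` (the untruncated normal leaves its negative-
    promptness mass out of the positive time axis).
    """
    scalar = np.isscalar(t)
    t = _validate_times(t)
    z = (1.0 / t - params.mu_p) / params.sigma_p
    out = stats.norm.pdf(z) / (params.sigma_p * t**2)
    return float(out) if scalar else out


def recinormal_cdf(t, params: RecinormalParams):
    """P(T <= t) = P(promptness >= 1/t) = 1 - Phi((1/t - mu_p)/sigma_p).

    Monotone nondecreasing in t with limit ``Phi(mu_p/sigma_p)`` as t -> inf.
    """
    scalar = np.isscalar(t)
    t = _validate_times(t)
    z = (1.0 / t - params.mu_p) / params.sigma_p
    out = stats.norm.sf(z)
    return float(out) if scalar else out


def recinormal_ppf(q, params: RecinormalParams):
    """Quantile function: t such that recinormal_cdf(t) = q.

    Valid for ``0 < q < Phi(mu_p/sigma_p)`` (the attainable probability range).
    """
    scalar = np.isscalar(q)
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= stats.norm.cdf(params.intercept))):
        raise ValueError("q outside the attainable probability range")
    # 1 - Phi((1/t - mu)/sigma) = q  =>  1/t = mu + sigma * Phi^-1(1 - q)
    p = params.mu_p + params.sigma_p * stats.norm.isf(q)
    out = 1.0 / p
    return float(out) if scalar else out


def _normal_loglik_suff(n: int, m: float, s2: float, mu: float, sigma: float) -> float:
    """Gaussian log-likelihood from sufficient statistics (n, mean, ML variance)."""
    return -0.5 * n * np.log(2.0 * np.pi) - n * np.log(sigma) - n * (
        s2 + (m - mu) ** 2
    ) / (2.0 * sigma**2)


def recinormal_loglik(intervals, params: RecinormalParams) -> float:
    """Recinormal log-likelihood, including the -2*sum(log t) Jacobian term."""
    t = _validate_times(intervals)
    p = 1.0 / t
    n = t.size
    return float(
        _normal_loglik_suff(n, float(p.mean()), float(p.var()), params.mu_p, params.sigma_p)
        - 2.0 * np.log(t).sum()
    )


@dataclass(frozen=True)
class RecinormalFit:
    """Result of a single-condition maximum-likelihood fit."""

    params: RecinormalParams
    loglik: float
    n: int


def fit_recinormal(intervals) -> RecinormalFit:
    """Closed-form MLE of the recinormal distribution.

    On the promptness scale ``p_i = 1/t_i`` the MLE is the sample mean and
    the ML (divisor n) standard deviation.  Requires n >= 3 strictly positive
    intervals that are not all identical.
    """
    t = _validate_times(intervals)
    if t.size < 3:
        raise InsufficientDataError(f"need at least 3 intervals, got {t.size}")
    p = 1.0 / t
    mu = float(p.mean())
    var = float(p.var())  # divisor n: the ML estimator
    if var <= 0 or np.isclose(var, 0.0, atol=1e-30):
        raise DegenerateDataError("all intervals identical: variance is zero")
    params = RecinormalParams(mu, float(np.sqrt(var)))
    return RecinormalFit(params=params, loglik=recinormal_loglik(t, params), n=t.size)


@dataclass(frozen=True)
class ReciprobitPoints:
    """Empirical reciprobit coordinates.

    abscissa holds negated promptness (-1/t, units 1/s) sorted ascending so
    that longer intervals sit to the right and infinite time is at 0;
    ordinate holds the probit (standard-normal quantile) of the Hazen
    plotting position.  Under a true recinormal the points fall on a line of
    slope ``1/sigma_p`` with ordinate-intercept ``mu_p/sigma_p`` at abscissa 0.
    """

    abscissa: np.ndarray
    ordinate: np.ndarray
    n: int

    def line_fit(self) -> tuple[float, float, float]:
        """Least-squares (slope, intercept, R^2) of ordinate on abscissa."""
        res = stats.linregress(self.abscissa, self.ordinate)
        return float(res.slope), float(res.intercept), float(res.rvalue**2)


def reciprobit_transform(intervals) -> ReciprobitPoints:
    """Empirical reciprobit coordinates of an interval sample.

    Plotting position is Hazen's ``(i - 0.5)/n``; tied abscissa values (exact
    duplicates, as produced by frame quantization) are collapsed to a single
    point at the mean of their plotting positions.
    """
    t = _validate_times(intervals)
    if t.size < 3:
        raise InsufficientDataError(f"need at least 3 intervals, got {t.size}")
    n = t.size
    x = np.sort(-1.0 / t)
    pos = (np.arange(1, n + 1) - 0.5) / n
    # collapse exact ties to the mean of their plotting positions
    ux, inverse = np.unique(x, return_inverse=True)
    upos = np.bincount(inverse, weights=pos) / np.bincount(inverse)
    return ReciprobitPoints(abscissa=ux, ordinate=stats.norm.ppf(upos), n=n)


def theoretical_reciprobit(params: RecinormalParams, n: int) -> ReciprobitPoints:
    """Reciprobit points of the exact recinormal quantiles at Hazen positions.

    These are exactly linear: ordinate = (abscissa + mu_p) / sigma_p.
    """
    pos = (np.arange(1, n + 1) - 0.5) / n
    t = recinormal_ppf(pos, params)
    x = np.sort(-1.0 / t)
    return ReciprobitPoints(abscissa=x, ordinate=stats.norm.ppf(pos), n=n)


@dataclass(frozen=True)
class MixtureFit:
    """Two-component promptness-normal mixture fit.

    The component with the larger mean promptness is labelled *early* (the
    fast sub-population); ``weight_early`` is its mixing proportion.  When
    the data carry no second component the fit degrades to the single
    recinormal fit with ``weight_early = 0`` and ``single_component = True``.
    ``early_is_minor`` records whether the early component is genuinely minor
    (weight < 0.5), which the scientific reading assumes.
    """

    main: RecinormalParams
    early: RecinormalParams | None
    weight_early: float
    loglik: float
    responsibilities: np.ndarray
    converged: bool
    n_iter: int
    single_component: bool = False
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def early_is_minor(self) -> bool:
        return self.weight_early < 0.5


def fit_early_mixture(
    intervals,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
    init_quantile: float = 0.85,
) -> MixtureFit:
    """EM fit of a two-component normal mixture on the promptness scale.

    Initialization splits the promptness sample at ``init_quantile`` (the
    early component is expected to be a minor fast tail).  The EM loglik is
    nondecreasing across iterations; convergence is declared when the gain
    drops below ``tol`` or after ``max_iter`` iterations.  If the mixture
    fails to improve on the single-component fit by any positive amount the
    single-component result is returned flagged.
    """
    t = _validate_times(intervals) if np.size(intervals) else np.empty(0)
    if t.size < 20:
        raise InsufficientDataError(f"mixture fit needs n >= 20, got {t.size}")
    p = 1.0 / t
    n = p.size
    single = fit_recinormal(t)

    # initialize from a split at the upper promptness quantile
    cut = np.quantile(p, init_quantile)
    hi = p >= cut
    if hi.sum() < 2 or (~hi).sum() < 2:
        hi = p >= np.median(p)
    mus = np.array([p[~hi].mean(), p[hi].mean()])
    sds = np.array([max(p[~hi].std(), 1e-6), max(p[hi].std(), 1e-6)])
    w = np.array([1.0 - hi.mean(), hi.mean()])

    loglik_path = []
    prev = -np.inf
    resp = np.full((n, 2), 0.5)
    converged = False
    it = 0
    degenerate = False
    for it in range(1, max_iter + 1):
        # E-step
        logdens = stats.norm.logpdf(p[:, None], mus[None, :], sds[None, :]) + np.log(w)[None, :]
        norm = np.logaddexp(logdens[:, 0], logdens[:, 1])
        ll = float(norm.sum())
        resp = np.exp(logdens - norm[:, None])
        loglik_path.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            degenerate = True
            break
        w = nk / n
        mus = (resp * p[:, None]).sum(axis=0) / nk
        var = (resp * (p[:, None] - mus[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < 1e-12):
            degenerate = True
            break
        sds = np.sqrt(var)

    # loglik in full recinormal terms (Jacobian shared by both components)
    jac = -2.0 * float(np.log(t).sum())
    ll_mix = (loglik_path[-1] if loglik_path else -np.inf) + jac

    if degenerate or ll_mix <= single.loglik:
        return MixtureFit(
            main=single.params,
            early=None,
            weight_early=0.0,
            loglik=single.loglik,
            responsibilities=np.zeros(n),
            converged=True,
            n_iter=it,
            single_component=True,
            loglik_path=np.asarray(loglik_path) + jac,
        )

    early_idx = int(np.argmax(mus))  # faster component = larger mean promptness
    main_idx = 1 - early_idx
    return MixtureFit(
        main=RecinormalParams(float(mus[main_idx]), float(sds[main_idx])),
        early=RecinormalParams(float(mus[early_idx]), float(sds[early_idx])),
        weight_early=float(w[early_idx]),
        loglik=ll_mix,
        responsibilities=resp[:, early_idx],
        converged=converged,
        n_iter=it,
        loglik_path=np.asarray(loglik_path) + jac,
    )
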