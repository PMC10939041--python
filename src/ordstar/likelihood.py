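"""Cumulative-link ordinal likelihood.

The 3-level outcome is a categorized latent variable D = eta + eps with
thresholds theta_1 < theta_2:  Y <= r  iff  D <= theta_r, so
P(Y <= r) = F(theta_r - eta) with F the standard normal CDF (probit
link, eps ~ N(0, 1)) or the standard logistic CDF (logit link).
Category probabilities are differences of consecutive cumulative
probabilities.

Log-probabilities are evaluated by log-CDF differences with
complementary-CDF switching so that deep-tail observations
(|theta - eta| large) do not suffer catastrophic cancellation.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy.stats import norm

__all__ = ["category_probs", "log_category_probs", "ordinal_loglik", "ordinal_deviance"]

_LINKS = ("probit", "logit")


def _check_link(link):
    if link not in _LINKS:
        raise ValueError(f"link must be one of {_LINKS}, got {link!r}")


def _cdf(c, link):
    return norm.cdf(c) if link == "probit" else special.expit(c)


def _pdf(c, link):
    if link == "probit":
        return norm.pdf(c)
    p = special.expit(c)
    return p * (1.0 - p)


def _logcdf(c, link):
    return norm.logcdf(c) if link == "probit" else special.log_expit(c)


def _logsf(c, link):
    return norm.logsf(c) if link == "probit" else special.log_expit(-c)


def _check_thresholds(thresholds):
    t1, t2 = float(thresholds[0]), float(thresholds[1])
    if not (np.isfinite(t1) and np.isfinite(t2) and t1 < t2):
        raise ValueError(f"thresholds must be finite with theta1 < theta2, got {thresholds}")
    return t1, t2


def category_probs(eta, thresholds, link: str = "probit"):
    """Category probabilities (pi0, pi1, pi2) at predictor value(s) eta.

    pi_r = F(theta_r - eta) - F(theta_{r-1} - eta) with theta_0 = -inf
    and theta_3 = +inf; the three probabilities are positive and sum
    to one.  ``eta`` may be scalar or array; the result has one more
    leading probability axis of length 3 stacked last.
    """
    _check_link(link)
    t1, t2 = _check_thresholds(thresholds)
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    F1 = _cdf(t1 - eta, link)
    F2 = _cdf(t2 - eta, link)
    return np.stack([F1, F2 - F1, 1.0 - F2], axis=-1)


def _log_diff_cdf(c1, c2, link):
    """log(F(c2) - F(c1)) for c1 < c2, numerically stable in both tails."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    lower_tail = (c1 + c2) < 0
    # lower tail: work with log F; upper tail: with log survival
    lF1, lF2 = _logcdf(c1, link), _logcdf(c2, link)
    lS1, lS2 = _logsf(c1, link), _logsf(c2, link)
    with np.errstate(divide="ignore", invalid="ignore"):
        low = lF2 + np.log1p(-np.exp(np.minimum(lF1 - lF2, -1e-300)))
        high = lS1 + np.log1p(-np.exp(np.minimum(lS2 - lS1, -1e-300)))
    return np.where(lower_tail, low, high)


def log_category_probs(eta, thresholds, link: str = "probit"):
    """log (pi0, pi1, pi2), stacked on the last axis, tail-stable."""
    _check_link(link)
    t1, t2 = _check_thresholds(thresholds)
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    c1, c2 = t1 - eta, t2 - eta
    return np.stack(
        [_logcdf(c1, link), _log_diff_cdf(c1, c2, link), _logsf(c2, link)], axis=-1
    )


def ordinal_loglik(y, eta, thresholds, link: str = "probit") -> float:
    """Multinomial log-likelihood sum_i log pi_{y_i}(eta_i).

    ``y`` holds levels coded 0..2 (insecurity-ascending canonical
    coding); ``eta`` is the latent predictor per record.
    """
    y = np.asarray(y)
    if y.min() < 0 or y.max() > 2:
        raise ValueError("levels must be coded 0..2")
    lp = log_category_probs(eta, thresholds, link)
    return float(lp[np.arange(len(y)), y.astype(int)].sum())


def ordinal_deviance(y, eta, thresholds, link: str = "probit") -> float:
    """-2 x log-likelihood (the saturated multinomial constant is omitted)."""
    return -2.0 * ordinal_loglik(y, eta, thresholds, link)


def _score_info_weights(y, c1, c2, link, floor: float = 1e-12):
    """Per-record score and expected-information weights in (c1, c2).

    Returns ``(u1, u2, m11, m12, m22)`` where u_k = d log pi_y / d c_k
    and M is the 2x2 expected information of one record with respect
    to (c1, c2) = (theta_1 - eta, theta_2 - eta).  Used by the
    penalized Fisher-scoring fitter.
    """
    f1, f2 = _pdf(c1, link), _pdf(c2, link)
    F1, F2 = _cdf(c1, link), _cdf(c2, link)
    p0 = np.maximum(F1, floor)
    p1 = np.maximum(F2 - F1, floor)
    p2 = np.maximum(1.0 - F2, floor)
    y = np.asarray(y).astype(int)
    u1 = np.where(y == 0, f1 / p0, np.where(y == 1, -f1 / p1, 0.0))
    u2 = np.where(y == 2, -f2 / p2, np.where(y == 1, f2 / p1, 0.0))
    m11 = f1 * f1 * (1.0 / p0 + 1.0 / p1)
    m12 = -f1 * f2 / p1
    m22 = f2 * f2 * (1.0 / p1 + 1.0 / p2)
    return u1, u2, m11, m12, m22
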