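"""Weibull accelerated-failure-time probability machinery.

Parameterization used throughout the package (scale form):

    S(t) = exp(-(t / lam)^k),   h(t) = (k / lam) * (t / lam)^(k - 1)

with shape ``k > 0`` shared across subjects and a per-subject scale
``lam_i = exp(eta_i)``, where ``eta_i = log lam_i`` is the linear predictor
or network output.  ``k > 1`` corresponds to a hazard that rises with time,
the regime expected for age-at-onset outcomes such as Alzheimer's disease.

The censored negative log-likelihood is

    NLL = -sum_i [ d_i * log f(t_i) + (1 - d_i) * log S(t_i) ]

with ``d_i`` the event indicator; right-censored subjects contribute only
the survival term.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "weibull_log_survival",
    "weibull_log_hazard",
    "weibull_log_density",
    "weibull_median",
    "censored_neg_log_likelihood",
    "nll_and_eta_gradient",
]


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return arr


def weibull_log_survival(t, shape, scale):
    """log S(t) = -(t / scale)^shape.

    Non-positive everywhere; exactly 0 at ``t = 0`` (S(0) = 1).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("t must be non-negative and finite")
    k = _check_positive("shape", shape)
    lam = _check_positive("scale", scale)
    return -((t / lam) ** k)


def weibull_log_hazard(t, shape, scale):
    """log h(t) = log k - log scale + (k - 1) * (log t - log scale)."""
    t = np.asarray(t, dtype=float)
    k = _check_positive("shape", shape)
    lam = _check_positive("scale", scale)
    if np.any(t <= 0):
        raise ValueError("t must be strictly positive for the hazard")
    return np.log(k) - np.log(lam) + (k - 1.0) * (np.log(t) - np.log(lam))


def weibull_log_density(t, shape, scale):
    """log f(t) = log h(t) + log S(t) for the scale-form Weibull.

    Raises for ``t = 0``: the density diverges there when ``shape < 1`` and
    is 0 when ``shape > 1``, so the log is never finite and informative.
    """
    return weibull_log_hazard(t, shape, scale) + weibull_log_survival(t, shape, scale)


def weibull_median(shape, scale):
    """Median event time ``scale * (ln 2)^(1/shape)`` (monotone in scale)."""
    k = _check_positive("shape", shape)
    lam = _check_positive("scale", scale)
    return lam * np.log(2.0) ** (1.0 / k)


def _prepare(time, event, log_scale):
    t = np.asarray(time, dtype=float)
    d = np.asarray(event)
    eta = np.asarray(log_scale, dtype=float)
    if t.ndim != 1:
        t = t.ravel()
    if t.size == 0:
        raise ValueError("empty cohort: no subjects")
    if d.shape != t.shape or eta.shape != t.shape:
        raise ValueError(
            f"length mismatch: time {t.shape}, event {d.shape}, log_scale {eta.shape}"
        )
    if not np.all(np.isin(d, (0, 1))):
        raise ValueError("event indicators must be 0 or 1")
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("times must be non-negative and finite")
    d = d.astype(float)
    if np.any((t == 0) & (d == 1)):
        raise ValueError("event at t=0 is not supported (density not finite)")
    return t, d, eta


def censored_neg_log_likelihood(time, event, shape, log_scale):
    """Right-censored Weibull negative log-likelihood.

    Events contribute ``-log f(t_i)``; censored subjects ``-log S(t_i)``.
    A censored subject at ``t = 0`` contributes exactly 0 (S(0) = 1).
    """
    nll, _, _ = nll_and_eta_gradient(time, event, shape, log_scale)
    return nll


def nll_and_eta_gradient(time, event, shape, log_scale):
    """NLL plus its gradients w.r.t. eta_i = log lam_i and w.r.t. k.

    Writing ``u_i = log t_i - eta_i`` and ``w_i = exp(k * u_i) = (t_i/lam_i)^k``:

        NLL      = sum_i [ w_i - d_i * (log k + (k-1) log t_i - k * eta_i) ]
        dNLL/deta_i = k * (d_i - w_i)
        dNLL/dk  = sum_i [ u_i * w_i - d_i * (1/k + u_i) ]

    Returns ``(nll, grad_eta, grad_k)``.  Used by both the linear model and
    the network trainer (the eta-gradient is the quantity backpropagated).
    """
    k = float(_check_positive("shape", shape))
    t, d, eta = _prepare(time, event, log_scale)
    pos = t > 0
    logt = np.where(pos, np.log(np.where(pos, t, 1.0)), 0.0)
    u = np.where(pos, logt - eta, 0.0)
    w = np.where(pos, np.exp(k * u), 0.0)  # (t/lam)^k; 0 at t=0
    nll = float(np.sum(w - d * (np.log(k) + (k - 1.0) * logt - k * eta)))
    grad_eta = k * (d - w)
    grad_k = float(np.sum(u * w - d * (1.0 / k + u)))
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite likelihood; check scales/times")
    return nll, grad_eta, grad_k
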