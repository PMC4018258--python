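"""Per-probe two-component normal mixture fits on M-values.

Each probe is modelled independently across samples as a mixture of two
normal components with a common variance: an unmethylated component with
mean ``mu_u`` and a methylated component with mean ``mu_m >= mu_u``, mixed
with prior weight ``pi`` on the methylated component.  The fit is by EM
from a single deterministic start (median split of the sample values), and
posterior methylation probabilities follow from Bayes' rule.

The engine operates on a whole probe x sample matrix at once; all probes
are iterated in lockstep with converged rows dropped from the active set,
which is what makes genome-scale matrices (tens of thousands of probes)
practical in pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .io import IntensityMatrix

__all__ = [
    "MixtureFit",
    "PosteriorMatrix",
    "fit_probe_mixture",
    "posterior_probabilities",
    "fit_all",
    "em_fit_matrix",
]

#: relative log-likelihood change below which a probe is declared converged
EM_TOL = 1e-8
#: hard cap on EM sweeps
EM_MAX_ITER = 500
#: sigma^2 is floored at this multiple of the per-probe sample variance
VARIANCE_FLOOR_SCALE = 1e-6
#: minimum number of samples for a mixture fit to be attempted
MIN_SAMPLES = 4

_PI_CLIP = 1e-12


@dataclass
class MixtureFit:
    """Maximum-likelihood estimates for one probe.

    Attributes
    ----------
    pi : float
        Prior probability of the methylated (higher-mean) component.
    mu_u, mu_m : float
        Component means on the M scale, with ``mu_m >= mu_u``.
    sigma2 : float
        Common within-component variance.
    loglik : float
        Maximised observed-data log-likelihood.
    converged : bool
        Whether the relative log-likelihood change fell below tolerance.
    degenerate : bool
        True when one component is effectively empty (``pi`` within
        ``1/(2n)`` of 0 or 1) or the input had zero variance; posterior
        probabilities are then the constant ``pi``.
    n_iter : int
        Number of EM sweeps performed.
    """

    pi: float
    mu_u: float
    mu_m: float
    sigma2: float
    loglik: float
    converged: bool
    degenerate: bool
    n_iter: int = 0

    @property
    def mixture_mean(self) -> float:
        """pi * mu_m + (1 - pi) * mu_u, the weighted component mean."""
        return self.pi * self.mu_m + (1.0 - self.pi) * self.mu_u


@dataclass
class PosteriorMatrix:
    """Posterior methylation probabilities, probes x samples."""

    probe_ids: np.ndarray
    chrom: np.ndarray
    samples: list
    p: np.ndarray
    pos: np.ndarray = None

    @property
    def shape(self):
        return self.p.shape


def _log_odds(values: np.ndarray, pi, mu_u, mu_m, sigma2) -> np.ndarray:
    """Log posterior odds of the methylated component, vectorised.

    ``pi``/``mu_u``/``mu_m``/``sigma2`` are broadcast against the leading
    axis of ``values``.
    """
    pi_c = np.clip(pi, _PI_CLIP, 1.0 - _PI_CLIP)
    delta = mu_m - mu_u
    mid = 0.5 * (mu_m + mu_u)
    return np.log(pi_c / (1.0 - pi_c)) + (values - mid) * (delta / sigma2)


def em_fit_matrix(
    values: np.ndarray,
    *,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    return_history: bool = False,
    accelerate: bool = True,
) -> dict:
    """Fit the two-component equal-variance mixture to every row of ``values``.

    Parameters
    ----------
    values : (t, n) array
        M-values, one probe per row, no missing entries, n >= 4.
    return_history : bool
        If True, also return the per-iteration log-likelihood trajectory of
        each row (list of arrays); intended for small inputs only.  Forces
        the plain (unaccelerated) sweep.
    accelerate : bool
        Use the compiled SQUAREM-accelerated engine (same E/M updates and
        fixed points, monotone accepted log-likelihoods, far fewer sweeps).
        The pure-numpy plain EM is kept as the reference path.

    Returns
    -------
    dict with keys ``pi, mu_u, mu_m, sigma2, loglik, converged, degenerate,
    n_iter, posteriors`` (all per-row arrays; ``posteriors`` is (t, n)),
    plus ``history`` when requested.
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    t, n = V.shape
    if n < MIN_SAMPLES:
        raise ValueError(f"mixture fit needs at least {MIN_SAMPLES} samples, got {n}")
    if not np.all(np.isfinite(V)):
        raise ValueError("mixture fit requires finite values")

    if accelerate and not return_history:
        from ._em_numba import em_fit_rows

        pi, mu_u, mu_m, sigma2, loglik, converged, n_iter = em_fit_rows(
            np.ascontiguousarray(V), tol, max_iter, VARIANCE_FLOOR_SCALE
        )
        return _finalize(V, n, pi, mu_u, mu_m, sigma2, loglik, converged, n_iter)

    # deterministic start: split each row at its median, means of the halves
    Vs = np.sort(V, axis=1)
    half = n // 2
    mu_u = Vs[:, :half].mean(axis=1)
    mu_m = Vs[:, half:].mean(axis=1)
    pi = np.full(t, 0.5)
    sigma2 = (
        np.sum((Vs[:, :half] - mu_u[:, None]) ** 2, axis=1)
        + np.sum((Vs[:, half:] - mu_m[:, None]) ** 2, axis=1)
    ) / n
    rowvar = V.var(axis=1)
    floor = VARIANCE_FLOOR_SCALE * (rowvar + 1e-12)
    sigma2 = np.maximum(sigma2, floor)

    loglik = np.full(t, -np.inf)
    converged = np.zeros(t, dtype=bool)
    n_iter = np.zeros(t, dtype=int)
    history: list[list[float]] = [[] for _ in range(t)] if return_history else None

    active = np.arange(t)
    for _ in range(max_iter):
        if active.size == 0:
            break
        Va = V[active]
        pia = pi[active]
        mua_u = mu_u[active]
        mua_m = mu_m[active]
        s2a = sigma2[active]

        logit = _log_odds(Va, pia[:, None], mua_u[:, None], mua_m[:, None], s2a[:, None])
        g = expit(logit)

        # observed-data log-likelihood at the current parameters:
        # log[(1-pi) phi_u] + log(1 + exp(logit)) summed over samples
        pi_c = np.clip(pia, _PI_CLIP, 1.0 - _PI_CLIP)
        du2 = (Va - mua_u[:, None]) ** 2
        ll = (
            np.log(1.0 - pi_c)
            - 0.5 * np.log(2.0 * np.pi * s2a)
        ) * n + np.sum(-du2 / (2.0 * s2a[:, None]) + np.logaddexp(0.0, logit), axis=1)

        if history is not None:
            for row, val in zip(active, ll):
                history[row].append(float(val))

        done = np.abs(ll - loglik[active]) <= tol * np.maximum(1.0, np.abs(ll))
        loglik[active] = ll
        n_iter[active] += 1

        # M-step on all active rows (freezing only affects bookkeeping)
        sg = g.sum(axis=1)
        s1g = n - sg
        new_mu_m = np.where(sg > 0, (g * Va).sum(axis=1) / np.maximum(sg, 1e-300), mua_m)
        new_mu_u = np.where(
            s1g > 0, ((1.0 - g) * Va).sum(axis=1) / np.maximum(s1g, 1e-300), mua_u
        )
        new_s2 = (
            g * (Va - new_mu_m[:, None]) ** 2 + (1.0 - g) * (Va - new_mu_u[:, None]) ** 2
        ).sum(axis=1) / n
        pi[active] = sg / n
        mu_m[active] = new_mu_m
        mu_u[active] = new_mu_u
        sigma2[active] = np.maximum(new_s2, floor[active])

        converged[active[done]] = True
        active = active[~done]

    out = _finalize(V, n, pi, mu_u, mu_m, sigma2, loglik, converged, n_iter)
    if history is not None:
        out["history"] = [np.asarray(h) for h in history]
    return out


def _finalize(V, n, pi, mu_u, mu_m, sigma2, loglik, converged, n_iter) -> dict:
    """Relabel components, flag degeneracy and assemble posteriors."""
    flip = mu_m < mu_u
    if np.any(flip):
        mu_u[flip], mu_m[flip] = mu_m[flip].copy(), mu_u[flip].copy()
        pi[flip] = 1.0 - pi[flip]

    rowvar = V.var(axis=1)
    degenerate = (pi < 1.0 / (2 * n)) | (pi > 1.0 - 1.0 / (2 * n)) | (rowvar == 0)

    posteriors = expit(
        _log_odds(V, pi[:, None], mu_u[:, None], mu_m[:, None], sigma2[:, None])
    )
    if np.any(degenerate):
        posteriors[degenerate] = pi[degenerate, None]

    return {
        "pi": pi,
        "mu_u": mu_u,
        "mu_m": mu_m,
        "sigma2": sigma2,
        "loglik": loglik,
        "converged": converged,
        "degenerate": degenerate,
        "n_iter": n_iter,
        "posteriors": posteriors,
    }


def fit_probe_mixture(values: np.ndarray, **kwargs) -> MixtureFit:
    """Fit the mixture for a single probe's sample values."""
    res = em_fit_matrix(np.asarray(values, dtype=float)[None, :], **kwargs)
    return MixtureFit(
        pi=float(res["pi"][0]),
        mu_u=float(res["mu_u"][0]),
        mu_m=float(res["mu_m"][0]),
        sigma2=float(res["sigma2"][0]),
        loglik=float(res["loglik"][0]),
        converged=bool(res["converged"][0]),
        degenerate=bool(res["degenerate"][0]),
        n_iter=int(res["n_iter"][0]),
    )


def posterior_probabilities(fit: MixtureFit, values: np.ndarray) -> np.ndarray:
    """Posterior probability that each sample is methylated under ``fit``.

    For a degenerate fit (one component empty) the posterior carries no
    information and is the constant ``fit.pi``.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("posterior_probabilities requires finite values")
    if fit.degenerate:
        return np.full(v.shape, fit.pi)
    return expit(_log_odds(v, fit.pi, fit.mu_u, fit.mu_m, fit.sigma2))


def fit_all(matrix: IntensityMatrix, **kwargs) -> tuple[list, PosteriorMatrix]:
    """Fit every probe of an intensity matrix independently.

    Returns the per-probe :class:`MixtureFit` list (in probe order) and the
    assembled :class:`PosteriorMatrix`.  Probes are independent, so the
    result does not depend on evaluation order.
    """
    res = em_fit_matrix(matrix.values, **kwargs)
    fits = [
        MixtureFit(
            pi=float(res["pi"][d]),
            mu_u=float(res["mu_u"][d]),
            mu_m=float(res["mu_m"][d]),
            sigma2=float(res["sigma2"][d]),
            loglik=float(res["loglik"][d]),
            converged=bool(res["converged"][d]),
            degenerate=bool(res["degenerate"][d]),
            n_iter=int(res["n_iter"][d]),
        )
        for d in range(matrix.n_probes)
    ]
    post = PosteriorMatrix(
        probe_ids=matrix.probe_ids,
        chrom=matrix.chrom,
        samples=list(matrix.samples),
        p=res["posteriors"],
        pos=matrix.pos,
    )
    return fits, post
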