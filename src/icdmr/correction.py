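"""Removal of non-biological (spatial) correlation between neighbouring probes.

Tiling-array intensities of adjacent probes are correlated for two distinct
reasons: shared methylation status of the underlying fragment (discrete,
biologically meaningful) and experimental spatial effects such as probe
overlap and fragment size (continuous, a nuisance).  This module removes
only the continuous part, pair by pair along the chromosome:

1. centralise both probes by their fitted mixture means,
2. strip the discrete component from the left probe by shifting its
   methylated samples down by an adjustment constant ``kappa`` (the
   no-intercept regression coefficient of the RAW intensity on the
   posterior; the raw scale anchors the unmethylated state at M ~ 0),
   giving the predictor ``r``,
3. regress the right probe's centralised intensity on ``r`` by weighted
   least squares, weighting each sample by its clustering certainty
   max(p, 1-p); the residuals are the corrected intensity.

The first probe of each chromosome has no left neighbour and passes
through unchanged.  The correction is one-pass: the predictor for probe i
is always built from the raw probe i-1, never from an already corrected
row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IntensityMatrix, chrom_slices
from .mixture import MixtureFit, PosteriorMatrix

__all__ = [
    "CorrectionIntermediates",
    "centralize",
    "adjustment_constant",
    "remove_discrete",
    "certainty_weights",
    "wls_residuals",
    "correct_matrix",
    "correction_diagnostics",
]

#: below this weighted predictor variance the WLS slope is forced to zero
PREDICTOR_VARIANCE_EPS = 1e-12


@dataclass
class CorrectionIntermediates:
    """Per-pair diagnostics of one correction step."""

    centralized_d: np.ndarray
    centralized_d1: np.ndarray
    kappa: float
    r: np.ndarray
    w: np.ndarray
    beta0: float
    beta1: float
    residuals: np.ndarray


def _mixture_shift(fit: MixtureFit) -> float:
    """Scalar the row is shifted by when centralising.

    The weighted component mean pi*mu_m + (1-pi)*mu_u; for a degenerate fit
    the mean of the single surviving component.
    """
    if fit.degenerate:
        return fit.mu_m if fit.pi > 0.5 else fit.mu_u
    return fit.mixture_mean


def centralize(values: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Shift a probe's values by its fitted weighted component mean.

    A scalar shift, so it leaves the clustering and the posterior
    probabilities unchanged.
    """
    return np.asarray(values, dtype=float) - _mixture_shift(fit)


def adjustment_constant(values: np.ndarray, posteriors: np.ndarray) -> float:
    """No-intercept regression coefficient of raw intensity on the posterior.

    kappa = sum(p * m) / sum(p^2), computed on the RAW (uncentralised)
    intensities; with binary posteriors this is exactly the arithmetic mean
    of the methylated group's intensity.  The raw scale matters: on
    enrichment arrays (log2 treated/untreated) the unmethylated state sits
    at M ~ 0, so subtracting p * kappa lowers the methylated group onto the
    unmethylated level and removes the discrete component completely at
    differential probes, while at non-differential probes (centred at 0,
    fitted component means straddling it) the subtraction removes only
    about half of the fitted split and the predictor keeps enough of the
    shared continuous noise for the downstream regression to work.
    Computing kappa on centralised values instead would leave a residual
    group gap of pi * (mu_m - mu_u) and let the regression eat the
    biological signal.  Zero when no sample carries methylated mass.
    """
    m = np.asarray(values, dtype=float)
    p = np.asarray(posteriors, dtype=float)
    if m.shape != p.shape:
        raise ValueError("values and posteriors must have equal length")
    denom = np.sum(p * p)
    if denom == 0.0:
        return 0.0
    return float(np.sum(p * m) / denom)


def remove_discrete(
    centralized: np.ndarray, posteriors: np.ndarray, kappa: float
) -> np.ndarray:
    """Strip the methylation-status component: r = m~ - p * kappa.

    With binary posteriors this lowers the methylated group onto the
    unmethylated level, so only the continuous variation remains.
    """
    m = np.asarray(centralized, dtype=float)
    p = np.asarray(posteriors, dtype=float)
    if m.shape != p.shape:
        raise ValueError("centralized values and posteriors must have equal length")
    return m - p * kappa


def certainty_weights(posteriors: np.ndarray) -> np.ndarray:
    """Clustering-certainty weights w = max(p, 1 - p), in [0.5, 1]."""
    p = np.asarray(posteriors, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("posteriors must lie in [0, 1]")
    return np.maximum(p, 1.0 - p)


def wls_residuals(
    response: np.ndarray, predictor: np.ndarray, weights: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Weighted least squares of response on predictor with an intercept.

    Returns (beta0, beta1, residuals).  When the weighted variance of the
    predictor is (near) zero the slope is set to zero and the intercept to
    the weighted mean.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (y.shape == x.shape == w.shape):
        raise ValueError("response, predictor and weights must have equal length")
    if y.size < 3:
        raise ValueError("weighted regression needs at least 3 points")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with positive total mass")
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum() / sw
    if sxx < PREDICTOR_VARIANCE_EPS:
        beta1 = 0.0
        beta0 = ybar
    else:
        sxy = (w * (x - xbar) * (y - ybar)).sum() / sw
        beta1 = sxy / sxx
        beta0 = ybar - beta1 * xbar
    residuals = y - beta0 - beta1 * x
    return float(beta0), float(beta1), residuals


def _correct_values(
    values: np.ndarray,
    chrom: np.ndarray,
    pi: np.ndarray,
    mu_u: np.ndarray,
    mu_m: np.ndarray,
    degenerate: np.ndarray,
    posteriors: np.ndarray,
) -> np.ndarray:
    """Vectorised one-pass correction of a whole matrix (array backend)."""
    shift = pi * mu_m + (1.0 - pi) * mu_u
    if np.any(degenerate):
        shift = np.where(degenerate, np.where(pi > 0.5, mu_m, mu_u), shift)
    centered = values - shift[:, None]

    corrected = values.copy()
    for sl in chrom_slices(chrom):
        block = centered[sl]
        if block.shape[0] < 2:
            continue
        P = posteriors[sl][:-1]
        md = block[:-1]
        raw_d = values[sl][:-1]
        y = block[1:]

        # kappa from the RAW left-neighbour row (see adjustment_constant)
        denom = np.sum(P * P, axis=1)
        kappa = np.divide(
            np.sum(P * raw_d, axis=1), denom, out=np.zeros_like(denom), where=denom > 0
        )
        r = md - P * kappa[:, None]
        w = np.maximum(P, 1.0 - P)

        sw = w.sum(axis=1)
        xbar = (w * r).sum(axis=1) / sw
        ybar = (w * y).sum(axis=1) / sw
        xc = r - xbar[:, None]
        yc = y - ybar[:, None]
        sxx = (w * xc * xc).sum(axis=1) / sw
        sxy = (w * xc * yc).sum(axis=1) / sw
        ok = sxx >= PREDICTOR_VARIANCE_EPS
        beta1 = np.divide(sxy, sxx, out=np.zeros_like(sxy), where=ok)
        beta0 = ybar - beta1 * xbar
        corrected[sl][1:] = y - beta0[:, None] - beta1[:, None] * r
        # first probe of the chromosome passes through raw (no left neighbour)
    return corrected


def correct_matrix(
    matrix: IntensityMatrix, fits: list[MixtureFit], posteriors: PosteriorMatrix
) -> IntensityMatrix:
    """Return a matrix whose rows 2..t per chromosome are WLS residuals.

    ``fits`` and ``posteriors`` must come from fitting ``matrix`` itself.
    The corrected matrix is meant to be refitted with the mixture module
    before scoring concordance.
    """
    if len(fits) != matrix.n_probes:
        raise ValueError("one mixture fit per probe is required")
    pi = np.array([f.pi for f in fits])
    mu_u = np.array([f.mu_u for f in fits])
    mu_m = np.array([f.mu_m for f in fits])
    degenerate = np.array([f.degenerate for f in fits], dtype=bool)
    corrected = _correct_values(
        matrix.values, matrix.chrom, pi, mu_u, mu_m, degenerate, posteriors.p
    )
    return IntensityMatrix(
        probe_ids=matrix.probe_ids,
        chrom=matrix.chrom,
        pos=matrix.pos,
        samples=list(matrix.samples),
        values=corrected,
        validate=False,
    )


def correction_diagnostics(
    matrix: IntensityMatrix, fits: list[MixtureFit], posteriors: PosteriorMatrix
):
    """Per-pair diagnostics table of the correction step.

    One row per within-chromosome adjacent probe pair with the adjustment
    constant, the WLS coefficients and the lag-1 correlation between the
    pair's rows before and after correction.
    """
    import pandas as pd

    corrected = correct_matrix(matrix, fits, posteriors)
    rows = []
    for sl in chrom_slices(matrix.chrom):
        for d in range(sl.start, sl.stop - 1):
            raw_d, raw_d1 = matrix.values[d], matrix.values[d + 1]
            p = posteriors.p[d]
            md = centralize(raw_d, fits[d])
            md1 = centralize(raw_d1, fits[d + 1])
            kappa = adjustment_constant(raw_d, p)
            r = remove_discrete(md, p, kappa)
            beta0, beta1, _ = wls_residuals(md1, r, certainty_weights(p))
            rows.append(
                {
                    "probe_id_left": matrix.probe_ids[d],
                    "probe_id_right": matrix.probe_ids[d + 1],
                    "chrom": matrix.chrom[d],
                    "kappa": kappa,
                    "beta0": beta0,
                    "beta1": beta1,
                    "lag1_corr_before": float(np.corrcoef(raw_d, raw_d1)[0, 1]),
                    "lag1_corr_after": float(
                        np.corrcoef(corrected.values[d], corrected.values[d + 1])[0, 1]
                    ),
                }
            )
    return pd.DataFrame(rows)
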