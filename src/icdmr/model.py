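"""Model/results interface tying the pipeline together.

:class:`ICDMR` is constructed from an intensity matrix and ``fit()`` runs
the full procedure — per-probe mixture fits, one-pass spatial correction,
mixture refit on the corrected intensities, concordance scoring, mirrored
empirical-null thresholding and run aggregation — returning an
:class:`ICDMRResults` carrying per-probe estimates, the concordance track,
the threshold and the called regions, with a text ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as _io
from .concordance import DMRSet, NullModel, call_dmrs, concordance_track, estimate_null_threshold
from .correction import _correct_values
from .io import IntensityMatrix
from .mixture import PosteriorMatrix, em_fit_matrix

__all__ = ["ICDMR", "ICDMRResults"]


class ICDMR:
    """Unsupervised consistently-DMR caller for one intensity matrix.

    Parameters
    ----------
    data : IntensityMatrix
        Probe x sample M-values with ordered genomic coordinates.
    correct : bool
        Apply the spatial-correlation correction (and mixture refit)
        before scoring concordance.  Disabling it reproduces the naive
        analysis whose threshold drifts with the background correlation.
    """

    def __init__(self, data: IntensityMatrix, correct: bool = True):
        if not isinstance(data, IntensityMatrix):
            raise TypeError("data must be an IntensityMatrix")
        self.data = data
        self.correct = bool(correct)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, beta_input: bool = False, **kwargs) -> "ICDMR":
        """Build from a dataframe with probe_id/chrom/pos + sample columns."""
        return cls(IntensityMatrix.from_frame(df, beta_input=beta_input), **kwargs)

    @classmethod
    def from_table(cls, path, beta_input: bool = False, **kwargs) -> "ICDMR":
        """Build from a tab-delimited intensity table on disk."""
        return cls(_io.read_intensity_table(path, beta_input=beta_input), **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        min_scores: int = 3,
        min_sub_half: int = 20,
    ) -> "ICDMRResults":
        """Run the full pipeline and return the results object.

        ``alpha`` is the type-I error level of the mirrored-null threshold,
        ``min_scores`` the minimum run length of significant concordances
        for a region (a run of k scores spans k + 1 probes) and
        ``min_sub_half`` the minimum number of sub-0.5 scores required for
        the null to be estimable.
        """
        m = self.data
        raw = em_fit_matrix(m.values)
        if self.correct:
            corrected_values = _correct_values(
                m.values,
                m.chrom,
                raw["pi"],
                raw["mu_u"],
                raw["mu_m"],
                raw["degenerate"],
                raw["posteriors"],
            )
            final = em_fit_matrix(corrected_values)
        else:
            corrected_values = m.values
            final = raw

        posteriors = PosteriorMatrix(
            probe_ids=m.probe_ids,
            chrom=m.chrom,
            samples=list(m.samples),
            p=final["posteriors"],
            pos=m.pos,
        )
        track = concordance_track(posteriors, corrected=self.correct)
        null = estimate_null_threshold(track.scores, alpha, min_sub_half=min_sub_half)
        dmrs = call_dmrs(
            track, null, posteriors, final["pi"], min_scores=min_scores, pos=m.pos
        )
        return ICDMRResults(
            model=self,
            raw_fit=raw,
            final_fit=final,
            posteriors=posteriors,
            track=track,
            null=null,
            dmrs=dmrs,
            alpha=alpha,
            min_scores=min_scores,
        )


class ICDMRResults:
    """Fitted-pipeline results.

    Attributes
    ----------
    params : pandas.DataFrame
        Per-probe mixture estimates after correction (pi, mu_u, mu_m,
        sigma2, loglik, converged, degenerate).
    posteriors : PosteriorMatrix
        Posterior methylation probabilities from the corrected fit.
    track : ConcordanceTrack
        Concordance scores of adjacent within-chromosome probe pairs.
    null : NullModel
        Mirrored empirical null; ``threshold`` is its (1 - alpha) quantile.
    dmrs : DMRSet
        Called regions with summaries.
    """

    def __init__(self, model, raw_fit, final_fit, posteriors, track, null, dmrs, alpha, min_scores):
        self.model = model
        self.raw_fit = raw_fit
        self.final_fit = final_fit
        self.posteriors = posteriors
        self.track = track
        self.null: NullModel = null
        self.dmrs: DMRSet = dmrs
        self.alpha = alpha
        self.min_scores = min_scores

    @property
    def threshold(self) -> float:
        return self.null.threshold

    @property
    def significant(self) -> np.ndarray:
        """Boolean flags: concordance strictly above the threshold."""
        return self.track.scores > self.null.threshold

    @property
    def params(self) -> pd.DataFrame:
        m = self.model.data
        f = self.final_fit
        return pd.DataFrame(
            {
                "probe_id": m.probe_ids,
                "chrom": m.chrom,
                "pos": m.pos,
                "pi": f["pi"],
                "mu_u": f["mu_u"],
                "mu_m": f["mu_m"],
                "sigma2": f["sigma2"],
                "loglik": f["loglik"],
                "converged": f["converged"],
                "degenerate": f["degenerate"],
            }
        )

    def dmr_frame(self) -> pd.DataFrame:
        return self.dmrs.to_frame()

    def to_bed(self, path, header_lines=()) -> None:
        _io.write_dmr_bed(self.dmrs, path, header_lines=header_lines)

    def write_track(self, path, header_lines=()) -> None:
        _io.write_concordance_track(
            self.track, self.posteriors, self.null.threshold, path, header_lines=header_lines
        )

    def write_params(self, path) -> None:
        self.params.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        m = self.model.data
        n_sig = int(np.sum(self.significant))
        n_high = sum(1 for r in self.dmrs if r.differentiation_class == "high")
        lines = [
            "ICDMR results",
            "=" * 60,
            f"probes:                  {m.n_probes}",
            f"samples:                 {m.n_samples}",
            f"chromosomes:             {len(m.chromosome_slices())}",
            f"correction applied:      {self.model.correct}",
            f"concordance scores:      {len(self.track)}",
            f"alpha:                   {self.alpha}",
            f"null sample size:        {self.null.null_sample_size}",
            f"threshold T_alpha:       {self.null.threshold:.4f}",
            f"significant scores:      {n_sig} ({n_sig / max(len(self.track), 1):.2%})",
            f"min significant run:     {self.min_scores} scores "
            f"({self.min_scores + 1} probes)",
            f"DMRs called:             {len(self.dmrs)}",
            f"  high differentiation:  {n_high}",
            f"  low differentiation:   {len(self.dmrs) - n_high}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ICDMRResults: {len(self.dmrs)} DMRs at threshold "
            f"{self.null.threshold:.4f} (alpha={self.alpha})>"
        )
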