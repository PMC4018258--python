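"""Data containers and readers/writers for methylation intensity tables.

The central object is :class:`IntensityMatrix`: a probe x sample matrix of
M-values (log2 methylated/unmethylated intensity ratios) with per-probe
genomic coordinates, sorted by chromosome and position.  Beta-values
(fraction methylated, in (0,1)) are supported on input through the logit2
link M = log2(beta / (1 - beta)).

Formats are deliberately plain: tab-delimited text for intensity tables
and concordance tracks, BED6+3 for called regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeAnnotation",
    "IntensityMatrix",
    "beta_to_m",
    "m_to_beta",
    "read_intensity_table",
    "write_intensity_table",
    "write_dmr_bed",
    "write_concordance_track",
    "chrom_slices",
]

META_COLUMNS = ("probe_id", "chrom", "pos")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic annotation of one probe (1-based start coordinate)."""

    probe_id: str
    chrom: str
    pos: int


def beta_to_m(beta):
    """logit2 link: M = log2(beta / (1 - beta)).

    Strictly increasing on (0, 1); raises for values outside the open
    interval rather than clipping silently.
    """
    b = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(b <= 0.0) or np.any(b >= 1.0):
        raise ValueError("beta values must lie strictly inside (0, 1)")
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out


def m_to_beta(m):
    """Inverse logit2 link: beta = 2^M / (1 + 2^M), in (0, 1)."""
    x = np.asarray(m, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("M values must be finite")
    # expit formulated in base 2 for numerical symmetry
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp2(-x)), np.exp2(x) / (1.0 + np.exp2(x)))
    return float(out) if np.isscalar(m) else out


def chrom_slices(chrom: np.ndarray) -> list[slice]:
    """Contiguous row slices per chromosome of a sorted chromosome vector."""
    if len(chrom) == 0:
        return []
    change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(chrom)]])
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass
class IntensityMatrix:
    """Probe x sample matrix of M-values with ordered genomic coordinates.

    ``probe_ids``, ``chrom`` and ``pos`` are parallel per-probe arrays;
    rows are sorted by (chrom, pos) with strictly increasing positions
    inside each chromosome.  Missing values are rejected outright — the
    downstream model has no missing-data mechanism.
    """

    probe_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    samples: list
    values: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.validate:
            self._check()

    def _check(self):
        t = len(self.probe_ids)
        if self.values.shape != (t, len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{t} probes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity matrix contains missing or non-finite values")
        if len(set(self.probe_ids)) != t:
            raise ValueError("probe_id values must be unique")
        for sl in chrom_slices(self.chrom):
            p = self.pos[sl]
            if np.any(np.diff(p) <= 0):
                bad = self.probe_ids[sl][1:][np.diff(p) <= 0][0]
                raise ValueError(
                    f"positions must be strictly increasing within a chromosome "
                    f"(violated at probe {bad!r})"
                )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def probes(self) -> list[ProbeAnnotation]:
        return [
            ProbeAnnotation(str(i), str(c), int(p))
            for i, c, p in zip(self.probe_ids, self.chrom, self.pos)
        ]

    def chromosome_slices(self) -> list[slice]:
        return chrom_slices(self.chrom)

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {"probe_id": self.probe_ids, "chrom": self.chrom, "pos": self.pos}
        )
        vals = pd.DataFrame(self.values, columns=self.samples)
        return pd.concat([meta, vals], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, beta_input: bool = False) -> "IntensityMatrix":
        """Build a matrix from a dataframe with probe_id/chrom/pos + sample columns."""
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        samples = [c for c in df.columns if c not in META_COLUMNS]
        if not samples:
            raise ValueError("no sample columns found")
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        values = df[samples].to_numpy(dtype=float)
        if beta_input:
            values = beta_to_m(values)
        return cls(
            probe_ids=df["probe_id"].to_numpy(),
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            samples=samples,
            values=values,
        )


def read_intensity_table(path, beta_input: bool = False) -> IntensityMatrix:
    """Read a tab-delimited intensity table.

    Expected header: ``probe_id  chrom  pos  <sample> ...``.  Rows are
    sorted by (chrom, pos) on read.  With ``beta_input=True`` the sample
    cells are beta-values in (0,1) and are converted through the logit2
    link.  Errors name the offending probe or line where possible.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "chrom": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        first = dup.iloc[0]
        line = int(dup.index[0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: duplicated probe_id {first!r} (line {line})")
    samples = [c for c in df.columns if c not in META_COLUMNS]
    for col in samples:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            line = int(bad[0]) + 2
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r} (line {line})"
            )
        df[col] = numeric
    try:
        return IntensityMatrix.from_frame(df, beta_input=beta_input)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_intensity_table(matrix: IntensityMatrix, path, header_lines=()) -> None:
    """Write a matrix in the tab-delimited format read_intensity_table accepts."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_dmr_bed(dmrs, path, header_lines=()) -> None:
    """Write called regions as BED6+3 (0-based half-open coordinates).

    Columns: chrom, start(pos of first probe - 1), end(pos of last probe),
    name, score = round(1000 * mean concordance), strand '.', n_probes,
    mean methylation frequency, differentiation class.  An empty region
    set produces an empty file.
    """
    regions = list(dmrs)
    with open(path, "w") as fh:
        if not regions:
            return
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "# BED6+3; end = start coordinate of the last probe "
            "(probe length not modelled)\n"
        )
        for i, r in enumerate(regions, start=1):
            fh.write(
                "\t".join(
                    [
                        str(r.chrom),
                        str(int(r.start_pos) - 1),
                        str(int(r.end_pos)),
                        f"DMR_{i:05d}",
                        str(int(round(1000 * r.mean_concordance))),
                        ".",
                        str(int(r.n_probes)),
                        f"{r.mean_methylation_frequency:.4f}",
                        r.differentiation_class,
                    ]
                )
                + "\n"
            )


def write_concordance_track(track, posteriors, threshold, path, header_lines=()) -> None:
    """Write per-pair concordance scores as a tab-delimited track.

    Columns: probe_id_left, probe_id_right, chrom, pos_left, pos_right,
    score, significant (score strictly above ``threshold``).
    """
    ids = posteriors.probe_ids if hasattr(posteriors, "probe_ids") else posteriors
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "probe_id_left\tprobe_id_right\tchrom\tpos_left\tpos_right\tscore\tsignificant\n"
        )
        for li, ri, score in zip(track.left_index, track.right_index, track.scores):
            fh.write(
                "\t".join(
                    [
                        str(track.matrix_probe_ids[li]),
                        str(track.matrix_probe_ids[ri]),
                        str(track.matrix_chrom[li]),
                        str(track.matrix_pos[li]),
                        str(track.matrix_pos[ri]),
                        f"{score:.6f}",
                        str(int(score > threshold)),
                    ]
                )
                + "\n"
            )
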