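"""AR(1) tiling-array simulator with planted DMRs and known truth.

Background intensities along the chromosome follow a stationary first-order
autoregressive process per sample: N_i = rho * N_{i-1} + e_i with a fixed
innovation standard deviation ``noise_sd`` (default 0.4 on the M scale,
i.e. a beta-scale replicate noise of ~0.07 at the unmethylated state) and
a stationary start, so the marginal background variance grows with rho as
noise_sd^2 / (1 - rho^2).  With the default scale, an effect of E = 2
(beta 0.5 -> 0.8) produces the clearly bimodal M-value distributions the
mixture model presumes.  The alternative convention with a rho-independent
marginal variance is available via ``stationary_unit_variance=True``.

DMRs are intervals of ``dmr_length`` consecutive probes placed uniformly
at random without overlap and with at least one non-DMR probe between
regions.  Within a DMR, a randomly drawn subset of the case samples (a
fraction ``mf`` of the cases, the methylation frequency) has the effect
``E`` added to its background; controls are always unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import IntensityMatrix

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_dataset", "pair_labels"]

PROBE_SPACING = 50  # bp between probe starts; tiling arrays are near-evenly spaced


@dataclass
class SimulationConfig:
    """Study-design parameters of one simulated dataset.

    Defaults mirror the simulation design the method was characterised on:
    30,000 probes, 25 cases + 25 controls, 10-probe DMRs, effect size
    ``effect`` on the M scale (2 corresponds to a beta-value of 0.8 against
    an unmethylated 0.5).
    """

    n_probes: int = 30_000
    n_cases: int = 25
    n_controls: int = 25
    rho: float = 0.0
    effect: float = 2.0
    mf: float = 1.0
    dmr_length: int = 10
    dmr_proportion: float = 0.2
    seed: int = 0
    noise_sd: float = 0.4
    chrom: str = "chr1"
    stationary_unit_variance: bool = False

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 <= self.dmr_proportion <= 1.0):
            raise ValueError("dmr_proportion must lie in [0, 1]")
        if self.dmr_proportion > 0 and not (0.0 < self.mf <= 1.0):
            raise ValueError("mf must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_dmrs(self) -> int:
        return int(round(self.dmr_proportion * self.n_probes / self.dmr_length))


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset.

    ``dmr_intervals`` are (start, end) probe indices, 0-based inclusive;
    ``methylated_samples_per_dmr`` holds, per DMR, the indices of the case
    columns carrying the methylated state.
    """

    dmr_intervals: list
    probe_is_dmr: np.ndarray
    methylated_samples_per_dmr: list
    n_cases: int
    pair_label: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.pair_label is None:
            self.pair_label = pair_labels(self)


def _place_dmrs(n_probes: int, n_dmrs: int, length: int, rng) -> list[tuple[int, int]]:
    """Uniformly random non-overlapping intervals with >= 1 probe gap.

    Sampled exactly (uniform over all valid placements) through the usual
    gap-composition bijection: nondecreasing offsets drawn as a
    combination-with-repetition, then spread by the mandatory footprint.
    """
    if n_dmrs == 0:
        return []
    slack = n_probes - n_dmrs * length - (n_dmrs - 1)
    if slack < 0:
        raise ValueError(
            f"cannot place {n_dmrs} DMRs of length {length} with gaps in "
            f"{n_probes} probes"
        )
    # K-combination without replacement from range(slack + K), sorted, minus
    # its index, yields a uniform nondecreasing K-tuple over range(slack + 1)
    draw = np.sort(rng.choice(slack + n_dmrs, size=n_dmrs, replace=False))
    offsets = draw - np.arange(n_dmrs)
    starts = offsets + np.arange(n_dmrs) * (length + 1)
    return [(int(s), int(s) + length - 1) for s in starts]


def simulate_dataset(config: SimulationConfig) -> tuple[IntensityMatrix, SimulationTruth]:
    """Generate one intensity matrix plus its ground truth.

    All randomness flows from ``config.seed``; the same configuration is
    bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    t, n = config.n_probes, config.n_samples

    # stationary AR(1) background, one chain per sample (columns)
    if config.stationary_unit_variance:
        marginal_sd = config.noise_sd
        innov_sd = config.noise_sd * np.sqrt(1.0 - config.rho**2)
    else:
        innov_sd = config.noise_sd
        marginal_sd = config.noise_sd / np.sqrt(1.0 - config.rho**2)
    noise = rng.standard_normal((t, n))
    background = np.empty((t, n))
    background[0] = marginal_sd * noise[0]
    if config.rho == 0.0:
        background[1:] = innov_sd * noise[1:]
    else:
        for i in range(1, t):
            background[i] = config.rho * background[i - 1] + innov_sd * noise[i]

    intervals = _place_dmrs(t, config.n_dmrs, config.dmr_length, rng)
    probe_is_dmr = np.zeros(t, dtype=bool)
    # half-way counts round up: MF=0.1 of 25 cases means 3 methylated
    n_meth = int(np.floor(config.mf * config.n_cases + 0.5))
    methylated_sets = []
    values = background
    for start, end in intervals:
        probe_is_dmr[start : end + 1] = True
        cases = np.sort(rng.choice(config.n_cases, size=n_meth, replace=False))
        methylated_sets.append(cases)
        values[start : end + 1, cases] += config.effect

    samples = [f"case_{j + 1}" for j in range(config.n_cases)] + [
        f"control_{j + 1}" for j in range(config.n_controls)
    ]
    matrix = IntensityMatrix(
        probe_ids=np.array([f"probe_{i + 1:06d}" for i in range(t)], dtype=object),
        chrom=np.full(t, config.chrom, dtype=object),
        pos=1 + PROBE_SPACING * np.arange(t, dtype=np.int64),
        samples=samples,
        values=values,
        validate=False,
    )
    truth = SimulationTruth(
        dmr_intervals=intervals,
        probe_is_dmr=probe_is_dmr,
        methylated_samples_per_dmr=methylated_sets,
        n_cases=config.n_cases,
    )
    return matrix, truth


def pair_labels(truth: SimulationTruth) -> np.ndarray:
    """Label each adjacent probe pair as 'dmr', 'non_dmr' or 'boundary'.

    A pair is 'dmr' when both probes lie inside the same DMR, 'non_dmr'
    when both lie outside every DMR, and 'boundary' otherwise.  Because
    regions are separated by at least one gap probe, no pair can span two
    distinct DMRs.
    """
    flags = truth.probe_is_dmr
    left, right = flags[:-1], flags[1:]
    labels = np.where(
        left & right, "dmr", np.where(~left & ~right, "non_dmr", "boundary")
    )
    return labels.astype(object)
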