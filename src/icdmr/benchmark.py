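"""Simulation benchmark: the unsupervised caller vs supervised probe tests.

For each simulated scenario the pipeline is run end to end (per-dataset
mirrored-null threshold) and compared against probe-wise two-sample tests
that are allowed to see the case/control labels: the pooled-variance
Student's t-test and the Wilcoxon rank-sum test (normal approximation
with tie and continuity corrections).

Sensitivity is the fraction of truly differential units called
significant and the false positive rate (1 - specificity) the fraction of
truly non-differential units called.  Units are probes for the supervised
tests and adjacent-probe pairs for the concordance-based caller; pairs
straddling a region edge ('boundary') enter neither denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ICDMR
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "BenchmarkResult",
    "t_test_probe",
    "wrst_probe",
    "evaluate_calls",
    "run_benchmark",
    "null_threshold_study",
    "results_frame",
    "plot_benchmark",
]

METHODS = ("icdmr", "t_test", "wrst")


@dataclass
class BenchmarkResult:
    """Mean operating characteristics of one method in one scenario."""

    method: str
    rho: float
    effect: float
    mf: float
    dmr_proportion: float
    n_repeats: int
    sensitivity: float
    fpr: float
    threshold_used: float = float("nan")
    region_fpr_by_min_scores: dict = field(default_factory=dict)
    per_repeat: pd.DataFrame = field(default=None, repr=False)


def t_test_probe(case_values, control_values) -> float:
    """Two-sided pooled-variance two-sample t-test p-value.

    With zero pooled variance the test is vacuous: p = 1 when the group
    means agree, p = 0 otherwise.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def wrst_probe(case_values, control_values) -> float:
    """Two-sided Wilcoxon rank-sum p-value (normal approximation).

    Uses the Mann-Whitney U formulation with tie correction and
    continuity correction; fully tied data give p = 1.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    return float(
        stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def evaluate_calls(calls: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Sensitivity and FPR of boolean calls against dmr/non_dmr labels.

    ``labels`` entries are 'dmr', 'non_dmr' or 'boundary'; boundary units
    are excluded from both denominators.  An empty stratum makes the
    corresponding metric undefined and raises.
    """
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels, dtype=object)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    is_dmr = labels == "dmr"
    is_null = labels == "non_dmr"
    if not np.any(is_dmr):
        raise ValueError("sensitivity undefined: no dmr-labelled units")
    if not np.any(is_null):
        raise ValueError("FPR undefined: no non_dmr-labelled units")
    sensitivity = float(np.mean(calls[is_dmr]))
    fpr = float(np.mean(calls[is_null]))
    return sensitivity, fpr


def _region_probe_fpr(results, truth, min_scores: int) -> float:
    """Fraction of truly non-DMR probes covered by regions of >= min_scores runs."""
    from .concordance import call_dmrs

    dmrs = call_dmrs(
        results.track,
        results.null,
        results.posteriors,
        results.final_fit["pi"],
        min_scores=min_scores,
        pos=results.model.data.pos,
    )
    covered = np.zeros(truth.probe_is_dmr.size, dtype=bool)
    for r in dmrs:
        covered[r.start_probe : r.end_probe + 1] = True
    non_dmr = ~truth.probe_is_dmr
    return float(np.mean(covered[non_dmr]))


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def run_benchmark(
    scenarios,
    n_repeats: int = 10,
    alpha: float = 0.05,
    methods=METHODS,
    seed: int = 0,
    region_min_scores=(),
    min_sub_half: int = 20,
) -> list[BenchmarkResult]:
    """Run every scenario x repeat and average the operating characteristics.

    ``scenarios`` is an iterable of :class:`SimulationConfig`; each repeat
    draws a fresh seed from ``seed``, shared across methods so all methods
    see identical data.  ``region_min_scores`` additionally records, for
    the concordance caller, the fraction of non-DMR probes covered by
    called regions at each of the given minimum run lengths.
    """
    scenarios = list(scenarios)
    seeds = _child_seeds(seed, len(scenarios) * n_repeats).reshape(
        len(scenarios), n_repeats
    )
    out = []
    for si, scenario in enumerate(scenarios):
        rows = []
        for rep in range(n_repeats):
            cfg = SimulationConfig(
                **{
                    **scenario.__dict__,
                    "seed": int(seeds[si, rep]),
                }
            )
            matrix, truth = simulate_dataset(cfg)
            probe_labels = np.where(truth.probe_is_dmr, "dmr", "non_dmr").astype(object)
            cases = matrix.values[:, : cfg.n_cases]
            controls = matrix.values[:, cfg.n_cases :]

            if "icdmr" in methods:
                res = ICDMR(matrix).fit(alpha=alpha, min_sub_half=min_sub_half)
                sens, fpr = evaluate_calls(res.significant, truth.pair_label)
                row = {
                    "method": "icdmr",
                    "repeat": rep,
                    "sensitivity": sens,
                    "fpr": fpr,
                    "threshold": res.threshold,
                }
                for ms in region_min_scores:
                    row[f"region_fpr_min{ms}"] = _region_probe_fpr(res, truth, ms)
                rows.append(row)
            if "t_test" in methods:
                p = stats.ttest_ind(cases, controls, axis=1, equal_var=True).pvalue
                sens, fpr = evaluate_calls(p < alpha, probe_labels)
                rows.append(
                    {"method": "t_test", "repeat": rep, "sensitivity": sens, "fpr": fpr}
                )
            if "wrst" in methods:
                p = stats.mannwhitneyu(
                    cases,
                    controls,
                    axis=1,
                    alternative="two-sided",
                    method="asymptotic",
                    use_continuity=True,
                ).pvalue
                sens, fpr = evaluate_calls(p < alpha, probe_labels)
                rows.append(
                    {"method": "wrst", "repeat": rep, "sensitivity": sens, "fpr": fpr}
                )
        detail = pd.DataFrame(rows)
        for method in methods:
            sub = detail[detail["method"] == method]
            region_fpr = {
                ms: float(sub[f"region_fpr_min{ms}"].mean())
                for ms in region_min_scores
                if f"region_fpr_min{ms}" in sub
            }
            out.append(
                BenchmarkResult(
                    method=method,
                    rho=scenario.rho,
                    effect=scenario.effect,
                    mf=scenario.mf,
                    dmr_proportion=scenario.dmr_proportion,
                    n_repeats=n_repeats,
                    sensitivity=float(sub["sensitivity"].mean()),
                    fpr=float(sub["fpr"].mean()),
                    threshold_used=float(sub["threshold"].mean())
                    if "threshold" in sub
                    else float("nan"),
                    region_fpr_by_min_scores=region_fpr,
                    per_repeat=sub.reset_index(drop=True),
                )
            )
    return out


def null_threshold_study(
    rhos=(0.0, 0.3, 0.5, 0.7),
    n_repeats: int = 10,
    alpha: float = 0.05,
    n_probes: int = 30_000,
    n_cases: int = 25,
    n_controls: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Thresholds (and score symmetry) under pure-noise simulations.

    For each background correlation, simulate datasets with no DMRs, run
    the corrected pipeline and record the mirrored-null threshold along
    with the median of the corrected concordance scores.
    """
    rhos = list(rhos)
    seeds = _child_seeds(seed, len(rhos) * n_repeats).reshape(len(rhos), n_repeats)
    rows = []
    for ri, rho in enumerate(rhos):
        for rep in range(n_repeats):
            cfg = SimulationConfig(
                n_probes=n_probes,
                n_cases=n_cases,
                n_controls=n_controls,
                rho=rho,
                dmr_proportion=0.0,
                seed=int(seeds[ri, rep]),
            )
            matrix, _ = simulate_dataset(cfg)
            res = ICDMR(matrix).fit(alpha=alpha)
            scores = res.track.scores
            rows.append(
                {
                    "rho": rho,
                    "repeat": rep,
                    "threshold": res.threshold,
                    "median_score": float(np.median(scores)),
                    "mean_score": float(np.mean(scores)),
                    "frac_below_half": float(np.mean(scores < 0.5)),
                }
            )
    return pd.DataFrame(rows)


def results_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Long-format table of benchmark results (one row per method x scenario)."""
    rows = []
    for r in results:
        row = {
            "method": r.method,
            "rho": r.rho,
            "effect": r.effect,
            "mf": r.mf,
            "dmr_proportion": r.dmr_proportion,
            "n_repeats": r.n_repeats,
            "sensitivity": r.sensitivity,
            "fpr": r.fpr,
            "threshold_used": r.threshold_used,
        }
        for ms, v in r.region_fpr_by_min_scores.items():
            row[f"region_fpr_min{ms}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def plot_benchmark(frame: pd.DataFrame, path, methods=METHODS) -> None:
    """Sensitivity (left axis) and FPR (right axis) against MF, one panel
    per method x correlation level, mirroring the usual benchmark layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rhos = sorted(frame["rho"].unique())
    methods = [m for m in methods if m in set(frame["method"])]
    fig, axes = plt.subplots(
        len(methods), len(rhos), figsize=(3 * len(rhos), 2.5 * len(methods)),
        squeeze=False, sharex=True,
    )
    for i, method in enumerate(methods):
        for j, rho in enumerate(rhos):
            sub = frame[(frame.method == method) & (frame.rho == rho)].sort_values("mf")
            ax = axes[i][j]
            ax.plot(sub["mf"], sub["sensitivity"], "r-o", ms=3, label="sensitivity")
            ax.set_ylim(0, 1.05)
            twin = ax.twinx()
            twin.plot(sub["mf"], sub["fpr"], "b--s", ms=3, label="FPR")
            twin.set_ylim(0, max(0.2, sub["fpr"].max() * 1.3))
            if i == 0:
                ax.set_title(f"rho = {rho}")
            if j == 0:
                ax.set_ylabel(f"{method}\nsensitivity", color="r")
            if j == len(rhos) - 1:
                twin.set_ylabel("FPR", color="b")
            if i == len(methods) - 1:
                ax.set_xlabel("MF")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
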