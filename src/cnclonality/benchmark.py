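"""Calibration and power studies of the full pipeline on synthetic cohorts,
plus an exhaustive reference implementation of the single-change scan.

These routines are the package's built-in validation surface: they
regenerate study-scale synthetic cohorts, run the production pipeline end
to end, and summarise operating characteristics (null calibration of the
p-values, sensitivity on clonal pairs, false-clonal rate on independent
pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pipeline import analyze_cohort
from .segmentation import SegmentationConfig, segment_arm
from .simulate import SimConfig, evaluate_recovery, simulate_cohort


def exhaustive_single_change(values: np.ndarray, sigma: float,
                             min_markers: int) -> tuple[int, int, float]:
    """Reference scan: enumerate every interval directly.

    Slow but transparent; used to validate the production ``segment_arm``
    on small arms.
    """
    x = np.asarray(values, dtype=np.float64)
    m = x.size
    sigma = max(sigma, 1e-6)
    total = x.sum()
    stats_all = []
    for i in range(m):
        inner = np.cumsum(x[i:])
        for j in range(i + min_markers - 1, m):
            L = j - i + 1
            s_in = inner[j - i]
            if L == m:
                T = (total / m) / (sigma / np.sqrt(m))
            else:
                mean_in = s_in / L
                mean_out = (total - s_in) / (m - L)
                T = (mean_in - mean_out) / (sigma * np.sqrt(1.0 / L + 1.0 / (m - L)))
            stats_all.append((i, j, T))
    vmax = max(abs(t) for _, _, t in stats_all)
    tol = 1e-10 * max(vmax, 1.0)
    # complements of an interval are exact ties in |T|: first (i, j) wins
    for i, j, T in stats_all:
        if abs(T) >= vmax - tol:
            return i, j, T
    raise RuntimeError("unreachable")


def segmentation_oracle_agreement(n_arms: int = 200, max_markers: int = 200,
                                  seed: int = 0) -> float:
    """Fraction of random arms where the production scan matches the
    exhaustive reference exactly (interval and |T| to 1e-9)."""
    rng = np.random.default_rng(seed)
    config = SegmentationConfig()
    agree = 0
    for _ in range(n_arms):
        m = int(rng.integers(2 * config.min_segment_markers, max_markers + 1))
        x = rng.normal(0, 1, m)
        if rng.random() < 0.5:
            a = int(rng.integers(0, m - 2))
            b = int(rng.integers(a + 1, m))
            x[a:b + 1] += rng.normal(0, 1.5)
        i, j, T = segment_arm(x, 1.0, config)
        oi, oj, oT = exhaustive_single_change(x, 1.0, config.min_segment_markers)
        if (i, j) == (oi, oj) and abs(abs(T) - abs(oT)) < 1e-9:
            agree += 1
    return agree / n_arms


@dataclass
class CalibrationResult:
    p_values: np.ndarray
    positive_rate: float     # clonal-or-equivocal fraction at alpha
    ks_p: float              # KS test of p-value uniformity
    n_pairs: int
    n_null: int
    analysis: object = None  # the underlying CohortAnalysis


def calibration_study(n_test_pairs: int = 500, null_pairs: int = 200,
                      seed: int = 0,
                      config: SimConfig | None = None) -> CalibrationResult:
    """Null behaviour of the test on a cohort of only independent pairs.

    Every within-patient pair is truly independent, so p-values should be
    approximately uniform and the clonal-or-equivocal rate close to alpha.
    """
    config = config or SimConfig()
    track, profiles, _ = simulate_cohort(config, n_patients=n_test_pairs,
                                         fraction_clonal=0.0, seed=seed)
    analysis = analyze_cohort(track, profiles, null_max_pairs=null_pairs,
                              seed=seed)
    pvals = np.array([r.p_value for r in analysis.pair_results])
    positive = np.mean([r.classification in ("clonal", "equivocal")
                        for r in analysis.pair_results])
    ks_p = stats.kstest(pvals, "uniform").pvalue
    return CalibrationResult(pvals, float(positive), float(ks_p),
                             len(pvals), analysis.null.n_pairs, analysis)


@dataclass
class PowerResult:
    sensitivity: float       # clonal-or-equivocal rate on truly clonal pairs
    false_clonal_rate: float  # strict clonal rate on independent pairs
    n_clonal: int
    n_independent: int
    per_seed: list


def power_study(n_replicates: int = 10, n_patients: int = 20,
                fraction_clonal: float = 0.5, null_pairs: int = 200,
                seed: int = 0,
                config: SimConfig | None = None) -> PowerResult:
    """Detection performance on mixed cohorts, averaged over replicates.

    Each replicate simulates ``n_patients`` two-sample patients with the
    generator defaults (shared-event fraction 0.8, shift 0.45, noise 0.25),
    runs the full pipeline, and scores classifications against truth.
    """
    config = config or SimConfig()
    per_seed = []
    n_clonal = n_indep = 0
    for k in range(n_replicates):
        rep_seed = seed + 1000 * k
        track, profiles, truths = simulate_cohort(
            config, n_patients=n_patients, fraction_clonal=fraction_clonal,
            seed=rep_seed)
        analysis = analyze_cohort(track, profiles, null_max_pairs=null_pairs,
                                  seed=rep_seed)
        metrics = evaluate_recovery(analysis.pair_results, truths)
        per_seed.append(metrics)
        n_clonal += sum(metrics.confusion["clonal"].values())
        n_indep += sum(metrics.confusion["independent"].values())
    sens = float(np.mean([m.sensitivity for m in per_seed]))
    fcr = float(np.mean([m.false_clonal_rate for m in per_seed]))
    return PowerResult(sens, fcr, n_clonal, n_indep, per_seed)


def arm_event_frequencies(segmentations: dict, arm_index: int) -> tuple[float, float]:
    """(gain fraction, loss fraction) of samples carrying any call on an arm."""
    from .segmentation import ArmCall

    n = len(segmentations)
    gains = sum(segs[arm_index].call is ArmCall.GAIN
                for segs in segmentations.values())
    losses = sum(segs[arm_index].call is ArmCall.LOSS
                 for segs in segmentations.values())
    return gains / n, losses / n
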