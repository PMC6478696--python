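"""Simulation of the unadjusted sequential t-test strategy.

The strategy under study: start with n = 2 observations per group, run a
pooled two-sided t-test, stop if p < alpha, otherwise add one observation
to each group and test again, up to a per-group cap.  Under a true null
this "optional stopping" inflates the false-positive probability far above
alpha and biases the effect estimate conditional on stopping (the winner's
curse).  This module simulates the strategy many times, records where each
run first crosses the threshold, builds the resulting false-positive curve
as a function of the stopping cap, and summarizes the effect-size bias.

All sample sizes are per group.  Group A is drawn from Normal(0, sigma),
group B from Normal(delta, sigma); delta = 0 is the null.  Each replicate
runs on its own spawned RNG substream, so results are reproducible
bit-for-bit for a given master seed and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ttest import t_and_p

__all__ = [
    "NEVER",
    "SequentialConfig",
    "Trajectory",
    "CrossingResult",
    "FDRCurve",
    "EffectSummary",
    "simulate_trajectory",
    "first_crossing_distribution",
    "fdr_curve",
    "fwer_independent",
    "effect_size_at_stop",
]

#: Sentinel in crossing arrays for replicates that never reach p < alpha.
NEVER = -1


@dataclass(frozen=True)
class SequentialConfig:
    """Full specification of one batch of simulated sequential strategies.

    Parameters
    ----------
    n_start : first per-group sample size tested (2 is the smallest for
        which a within-group variance exists).
    n_max : per-group cap; data collection stops here regardless.
    alpha : significance threshold compared against p strictly (p < alpha).
    delta : true mean difference between the groups; 0 under the null.
    sigma : common standard deviation of both groups.
    reps : number of independent simulated strategies.
    seed : master seed; every replicate gets a spawned substream.
    """

    n_start: int = 2
    n_max: int = 150
    alpha: float = 0.05
    delta: float = 0.0
    sigma: float = 1.0
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_start < 2:
            raise ValueError("n_start must be >= 2")
        if self.n_max < self.n_start:
            raise ValueError("n_max must be >= n_start")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """One simulated run: the running test at every per-group n.

    ``p_values[i]`` and ``t_stats[i]`` belong to per-group size
    ``n[i] = n_start + i``.  The trajectory is always computed all the way
    to ``n_max`` — crossing the threshold does not truncate the record, so
    later re-crossings back above alpha remain observable.
    """

    n: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    first_crossing: int | None
    effect_at_stop: float | None
    effect_at_cap: float

    def recrosses(self, alpha: float) -> bool:
        """True if p >= alpha at some n after the first crossing."""
        if self.first_crossing is None:
            return False
        i = self.first_crossing - self.n[0]
        return bool(np.any(self.p_values[i + 1 :] >= alpha))


@dataclass(frozen=True)
class CrossingResult:
    """First-crossing outcomes for a batch of replicates.

    ``crossings`` holds the smallest per-group n with p < alpha for each
    replicate, or :data:`NEVER`.  Effect sizes are Cohen's d
    (mean_B - mean_A) / pooled sd: ``effect_at_stop`` at the crossing n
    (NaN when never crossed) and ``effect_at_cap`` at n_max for every
    replicate.
    """

    crossings: np.ndarray
    effect_at_stop: np.ndarray
    effect_at_cap: np.ndarray
    config: SequentialConfig

    @property
    def reps(self) -> int:
        return self.crossings.size

    @property
    def never_fraction(self) -> float:
        return float(np.mean(self.crossings == NEVER))


@dataclass(frozen=True)
class FDRCurve:
    """False-positive probability of the stopping rule vs the cap.

    ``rates[i]`` is the fraction of replicates whose first crossing is at
    or below ``caps[i]``; ``se`` the binomial Monte-Carlo standard error.
    Under a true null this is the familywise type-I error of stopping at
    cap c (the quantity the optional-stopping literature plots as a
    "false discovery rate").
    """

    caps: np.ndarray
    rates: np.ndarray
    se: np.ndarray
    reps: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"cap": self.caps, "rate": self.rates, "se": self.se})


@dataclass(frozen=True)
class EffectSummary:
    """Effect-size bias of optional stopping under one configuration.

    ``mean_abs_d_stopped`` averages |d| at the stopping n over replicates
    that stopped; ``mean_d_at_cap`` is the unconditional mean d at n_max
    over all replicates (unbiased for delta/sigma); the nonstopped column
    gives |d| at n_max among runs that never crossed, for contrast.
    """

    n_stopped: int
    n_total: int
    mean_abs_d_stopped: float | None
    se_abs_d_stopped: float | None
    mean_d_at_cap: float
    se_d_at_cap: float
    mean_abs_d_nonstopped: float | None
    se_abs_d_nonstopped: float | None


def _trajectory_arrays(a: np.ndarray, b: np.ndarray, n_start: int):
    """Running pooled t and p for per-group sizes n_start..len(a).

    Cumulative-moment formulation of the O(1)-per-step accumulator update;
    also returns running Cohen's d.  Inputs are the full per-group draws.
    """
    n = np.arange(1, a.size + 1, dtype=float)
    ca, cb = np.cumsum(a), np.cumsum(b)
    ca2, cb2 = np.cumsum(a * a), np.cumsum(b * b)
    mean_a, mean_b = ca / n, cb / n
    lo = n_start - 1
    nn = n[lo:]
    with np.errstate(invalid="ignore"):
        var_a = np.maximum(ca2[lo:] - nn * mean_a[lo:] ** 2, 0.0) / (nn - 1)
        var_b = np.maximum(cb2[lo:] - nn * mean_b[lo:] ** 2, 0.0) / (nn - 1)
    t, p = t_and_p(nn, mean_a[lo:], var_a, nn, mean_b[lo:], var_b)
    sp2 = 0.5 * (var_a + var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sp2 > 0, (mean_b[lo:] - mean_a[lo:]) / np.sqrt(sp2), 0.0)
    return t, p, d


def simulate_trajectory(config: SequentialConfig, rng: np.random.Generator) -> Trajectory:
    """Simulate one full sequential run and record the whole p trajectory."""
    a = rng.normal(0.0, config.sigma, size=config.n_max)
    b = rng.normal(config.delta, config.sigma, size=config.n_max)
    t, p, d = _trajectory_arrays(a, b, config.n_start)
    n = np.arange(config.n_start, config.n_max + 1)
    below = p < config.alpha
    if below.any():
        i = int(np.argmax(below))
        first = int(n[i])
        effect = float(d[i])
    else:
        first, effect = None, None
    return Trajectory(n, t, p, first, effect, float(d[-1]))


def first_crossing_distribution(config: SequentialConfig) -> CrossingResult:
    """Run ``config.reps`` independent sequential strategies.

    Each replicate runs on an independent substream spawned from the
    master seed, so the batch is reproducible and may be reordered or
    parallelized without changing any outcome.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.reps)
    crossings = np.full(config.reps, NEVER, dtype=np.int64)
    eff_stop = np.full(config.reps, np.nan)
    eff_cap = np.empty(config.reps)
    for i, ss in enumerate(seeds):
        traj = simulate_trajectory(config, np.random.Generator(np.random.PCG64(ss)))
        if traj.first_crossing is not None:
            crossings[i] = traj.first_crossing
            eff_stop[i] = traj.effect_at_stop
        eff_cap[i] = traj.effect_at_cap
    return CrossingResult(crossings, eff_stop, eff_cap, config)


def fdr_curve(result: CrossingResult, caps=None) -> FDRCurve:
    """Cumulative first-crossing fraction at each stopping cap.

    Default caps are every integer per-group n from n_start to n_max.
    """
    cfg = result.config
    if caps is None:
        caps = np.arange(cfg.n_start, cfg.n_max + 1)
    caps = np.asarray(caps, dtype=np.int64)
    if caps.size and (caps.min() < cfg.n_start or caps.max() > cfg.n_max):
        raise ValueError(
            f"caps must lie within the simulated range [{cfg.n_start}, {cfg.n_max}]"
        )
    crossed = result.crossings[result.crossings != NEVER]
    counts = np.searchsorted(np.sort(crossed), caps, side="right")
    rates = counts / result.reps
    se = np.sqrt(rates * (1.0 - rates) / result.reps)
    return FDRCurve(caps, rates, se, result.reps)


def fwer_independent(k: int, alpha: float) -> float:
    """Familywise error rate of k independent level-alpha tests: 1-(1-a)^k."""
    if k < 1 or int(k) != k:
        raise ValueError("k must be a positive integer")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - (1.0 - alpha) ** k


def effect_size_at_stop(config_or_result) -> EffectSummary:
    """Summarize effect-size inflation conditional on early stopping.

    Accepts a :class:`SequentialConfig` (simulates) or an existing
    :class:`CrossingResult` (reuses the batch).
    """
    if isinstance(config_or_result, SequentialConfig):
        result = first_crossing_distribution(config_or_result)
    else:
        result = config_or_result
    stopped = result.crossings != NEVER
    k = int(stopped.sum())

    def _mstats(x):
        if x.size == 0:
            return None, None
        return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0

    abs_stop = np.abs(result.effect_at_stop[stopped])
    abs_non = np.abs(result.effect_at_cap[~stopped])
    mean_stop, se_stop = _mstats(abs_stop)
    mean_non, se_non = _mstats(abs_non)
    return EffectSummary(
        n_stopped=k,
        n_total=result.reps,
        mean_abs_d_stopped=mean_stop,
        se_abs_d_stopped=se_stop,
        mean_d_at_cap=float(np.mean(result.effect_at_cap)),
        se_d_at_cap=float(np.std(result.effect_at_cap, ddof=1) / np.sqrt(result.reps))
        if result.reps > 1
        else 0.0,
        mean_abs_d_nonstopped=mean_non,
        se_abs_d_nonstopped=se_non,
    )
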