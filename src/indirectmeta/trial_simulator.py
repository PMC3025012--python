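"""Generative model for two-arm trials feeding an indirect comparison.

Each simulated trial of treatment T (B or C) against the common
comparator A is drawn as follows:

1. total size N ~ discrete uniform on [20, 500]; both arms get floor(N/2)
   participants (equal allocation);
2. the trial's comparator event rate p_Aj ~ Uniform(p_A - delta, p_A + delta),
   jittering trials around the true average comparator rate p_A;
3. the trial's own log odds ratio ~ Normal(log OR_TA, tau^2), where tau is
   the between-study standard deviation;
4. the treatment-arm event rate follows from p_Aj and the trial's OR via
   the odds transformation;
5. event counts are Binomial(arm size, arm rate) in each arm.

Setting tau = 0 and delta = 0 removes all between-trial variation, leaving
only binomial sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .meta_engine import TwoArmTrial

__all__ = [
    "ScenarioConfig",
    "SimulatedComparison",
    "derived_event_rate",
    "simulate_trial",
    "simulate_replicate",
    "replicate_streams",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design.

    Parameters
    ----------
    k_ba, k_ca : int
        Number of trials directly comparing B vs A and C vs A.
    p_a : float
        True average event rate in the common comparator arm A.
    or_ba, or_ca : float
        True odds ratios of B vs A and C vs A.
    tau : float
        Between-study standard deviation of the trial-specific log-ORs
        (shared by both comparisons).
    jitter_halfwidth : float
        Half-width delta of the uniform support for the trial-level
        comparator rate, Uniform(p_a - delta, p_a + delta).
    n_total_range : (int, int)
        Inclusive range of the total trial size (both arms combined).
    reps : int
        Monte-Carlo replicates to run for this scenario.
    seed : int or None
        Root seed of the scenario's random stream.
    """

    k_ba: int
    k_ca: int
    p_a: float
    or_ba: float
    or_ca: float
    tau: float
    jitter_halfwidth: float = 0.05
    n_total_range: tuple[int, int] = (20, 500)
    reps: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_ba < 1 or self.k_ca < 1:
            raise ValueError("each comparison needs at least one trial")
        if not 0.0 < self.p_a < 1.0:
            raise ValueError("p_a must lie strictly in (0, 1)")
        delta = self.jitter_halfwidth
        if delta < 0 or self.p_a - delta <= 0.0 or self.p_a + delta >= 1.0:
            raise ValueError("uniform support for the baseline rate must stay inside (0, 1)")
        if self.or_ba <= 0 or self.or_ca <= 0:
            raise ValueError("true odds ratios must be positive")
        if self.tau < 0:
            raise ValueError("tau is a standard deviation and must be >= 0")
        low, high = self.n_total_range
        if not (isinstance(low, (int, np.integer)) and isinstance(high, (int, np.integer))):
            raise TypeError("n_total_range bounds must be integers")
        if low < 2 or high < low:
            raise ValueError("n_total_range must be an increasing range of totals >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def true_or_cb(self) -> float:
        """True C-vs-B odds ratio, OR_CA / OR_BA."""
        return self.or_ca / self.or_ba

    @property
    def is_null(self) -> bool:
        """True when the indirect null holds (OR_BA = OR_CA)."""
        return self.or_ba == self.or_ca

    def label(self) -> str:
        return (
            f"kca={self.k_ca}_kba={self.k_ba}_pa={self.p_a:g}"
            f"_orba={self.or_ba:g}_orca={self.or_ca:g}_tau={self.tau:g}"
        )


@dataclass(frozen=True)
class SimulatedComparison:
    """All trials of one direct comparison within one replicate."""

    trials: tuple[TwoArmTrial, ...]
    comparison: str  # "BA" or "CA"
    truth: ScenarioConfig


def derived_event_rate(or_: float, p_ctrl: float) -> float:
    """Event probability whose odds are ``or_`` times the control odds.

    p = OR * p0 / (1 - p0 + OR * p0). The identity OR = [p/(1-p)] /
    [p0/(1-p0)] inverts to this closed form.
    """
    if not 0.0 < p_ctrl < 1.0:
        raise ValueError("p_ctrl must lie strictly in (0, 1)")
    if or_ <= 0:
        raise ValueError("odds ratio must be positive")
    return or_ * p_ctrl / (1.0 - p_ctrl + or_ * p_ctrl)


def _true_or(config: ScenarioConfig, which: str) -> float:
    if which == "BA":
        return config.or_ba
    if which == "CA":
        return config.or_ca
    raise ValueError(f"comparison must be 'BA' or 'CA', got {which!r}")


def _draw_comparison(
    config: ScenarioConfig, which: str, rng: np.random.Generator, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized draw of k trials: (arm sizes, control events, treatment events)."""
    true_or = _true_or(config, which)
    low, high = config.n_total_range
    total = rng.integers(low, high + 1, size=k)
    n_arm = total // 2
    delta = config.jitter_halfwidth
    p_ctrl = rng.uniform(config.p_a - delta, config.p_a + delta, size=k)
    log_or = rng.normal(math.log(true_or), config.tau, size=k)
    p_trt = np.exp(log_or) * p_ctrl / (1.0 - p_ctrl + np.exp(log_or) * p_ctrl)
    events_ctrl = rng.binomial(n_arm, p_ctrl)
    events_trt = rng.binomial(n_arm, p_trt)
    return n_arm, events_ctrl, events_trt


def simulate_trial(
    config: ScenarioConfig, which: str, rng: np.random.Generator
) -> TwoArmTrial:
    """Draw a single trial for the given comparison from the generative model."""
    n_arm, events_ctrl, events_trt = _draw_comparison(config, which, rng, k=1)
    return TwoArmTrial(
        study_id=f"{which}-1",
        events_trt=int(events_trt[0]),
        n_trt=int(n_arm[0]),
        events_ctrl=int(events_ctrl[0]),
        n_ctrl=int(n_arm[0]),
    )


def _build_comparison(
    config: ScenarioConfig, which: str, rng: np.random.Generator, k: int
) -> SimulatedComparison:
    n_arm, events_ctrl, events_trt = _draw_comparison(config, which, rng, k)
    trials = tuple(
        TwoArmTrial(
            study_id=f"{which}-{j + 1}",
            events_trt=int(events_trt[j]),
            n_trt=int(n_arm[j]),
            events_ctrl=int(events_ctrl[j]),
            n_ctrl=int(n_arm[j]),
        )
        for j in range(k)
    )
    return SimulatedComparison(trials=trials, comparison=which, truth=config)


def simulate_replicate(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[SimulatedComparison, SimulatedComparison]:
    """Draw one replicate: k_ba B-vs-A trials and k_ca C-vs-A trials."""
    ba = _build_comparison(config, "BA", rng, config.k_ba)
    ca = _build_comparison(config, "CA", rng, config.k_ca)
    return ba, ca


def replicate_streams(config: ScenarioConfig) -> Iterator[np.random.Generator]:
    """Independent per-replicate random streams for one scenario.

    All streams derive deterministically from the scenario seed, so any
    execution order (or parallel split) of the replicates reproduces the
    same trials.
    """
    root = np.random.SeedSequence(config.seed)
    for child in root.spawn(config.reps):
        yield np.random.default_rng(child)


def with_seed(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    """Copy of the scenario with its root seed replaced."""
    return replace(config, seed=seed)
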