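"""Per-trial log-odds-ratio effects and DerSimonian-Laird random-effects pooling.

This module turns 2x2 trial count tables into log-odds-ratio effect
estimates and pools them with the classic closed-form DerSimonian-Laird
(DL) moment estimator: fixed-effect inverse-variance weights give
Cochran's Q, the between-study variance tau^2 is estimated from Q and
truncated at zero, and the pooled effect is the inverse-variance average
under the random-effects weights 1/(se_i^2 + tau^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwoArmTrial",
    "EffectEstimate",
    "MetaResult",
    "DegenerateTrialError",
    "trial_log_or",
    "dl_pool",
    "pool_trials",
    "read_trials_csv",
]

#: Continuity-correction policies for zero cells in a 2x2 table.
#:   "halves"           -- add 0.5 to all four cells of any table with a zero
#:                         cell; all trials are retained (default).
#:   "drop-double-zero" -- same correction, but trials with zero events in
#:                         both arms, or all events in both arms, are dropped
#:                         from the pool instead of being retained.
CONTINUITY_POLICIES = ("halves", "drop-double-zero")


class DegenerateTrialError(ValueError):
    """Raised when a trial cannot contribute a usable effect estimate."""


def _check_count(name: str, value: object) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise TypeError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return int(value)


@dataclass(frozen=True)
class TwoArmTrial:
    """Event counts and arm sizes for one randomized two-arm trial.

    The "treatment" arm is the experimental treatment (B or C); the
    "control" arm is the common comparator A.
    """

    study_id: str
    events_trt: int
    n_trt: int
    events_ctrl: int
    n_ctrl: int

    def __post_init__(self) -> None:
        for name in ("events_trt", "n_trt", "events_ctrl", "n_ctrl"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.n_trt <= 0 or self.n_ctrl <= 0:
            raise ValueError("arm sizes must be positive")
        if self.events_trt > self.n_trt or self.events_ctrl > self.n_ctrl:
            raise ValueError("event count exceeds arm size")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """The 2x2 table (a, b, c, d) = (events_trt, non-events_trt, events_ctrl, non-events_ctrl)."""
        return (
            self.events_trt,
            self.n_trt - self.events_trt,
            self.events_ctrl,
            self.n_ctrl - self.events_ctrl,
        )


@dataclass(frozen=True)
class EffectEstimate:
    """A natural-log odds ratio and its standard error."""

    log_or: float
    se: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValueError("log_or must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError("se must be finite and strictly positive")


@dataclass(frozen=True)
class MetaResult:
    """DerSimonian-Laird pooled effect for one direct comparison.

    Attributes
    ----------
    pooled : EffectEstimate
        Random-effects pooled log-OR and its standard error.
    tau2_hat : float
        DL moment estimate of the between-study variance, truncated at 0.
    q_stat : float
        Cochran's Q heterogeneity statistic (0 for a single study).
    k : int
        Number of trials actually pooled.
    n_dropped : int
        Trials excluded as degenerate before pooling.
    """

    pooled: EffectEstimate
    tau2_hat: float
    q_stat: float
    k: int
    n_dropped: int = 0


def trial_log_or(trial: TwoArmTrial, correction: str = "halves") -> EffectEstimate:
    """Log-odds-ratio and SE for one trial from its 2x2 table.

    log(OR) = log[(a/b) / (c/d)] and SE = sqrt(1/a + 1/b + 1/c + 1/d)
    where (a, b, c, d) are the table cells. If any cell is zero, 0.5 is
    added to all four cells (the usual continuity correction) and the
    ``corrected`` flag is set on the result.

    Raises
    ------
    DegenerateTrialError
        If an arm has <= 1 participant (the corrected table carries no
        usable information), or, under the ``"drop-double-zero"`` policy,
        if both arms have zero events or both arms have all events.
    """
    if correction not in CONTINUITY_POLICIES:
        raise ValueError(f"unknown continuity policy {correction!r}")
    if trial.n_trt <= 1 or trial.n_ctrl <= 1:
        raise DegenerateTrialError(f"{trial.study_id}: arm with <= 1 participant")

    a, b, c, d = (float(x) for x in trial.cells)
    if correction == "drop-double-zero" and ((a == 0 and c == 0) or (b == 0 and d == 0)):
        raise DegenerateTrialError(f"{trial.study_id}: no information on the odds ratio")
    corrected = False
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate(log_or=log_or, se=se, corrected=corrected)


def dl_pool(effects: Sequence[EffectEstimate], n_dropped: int = 0) -> MetaResult:
    """Pool effect estimates with the DerSimonian-Laird random-effects model.

    With fixed-effect weights w_i = 1/se_i^2 and the fixed-effect mean
    y_FE, Cochran's Q = sum w_i (y_i - y_FE)^2 and

        tau2 = max(0, (Q - (k - 1)) / (sum w_i - sum w_i^2 / sum w_i)).

    The pooled estimate uses random-effects weights w*_i = 1/(se_i^2 + tau2)
    with SE = 1/sqrt(sum w*_i). A single study is returned unchanged with
    tau2 = Q = 0.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("cannot pool an empty list of effects")
    if len(effects) == 1:
        return MetaResult(pooled=effects[0], tau2_hat=0.0, q_stat=0.0, k=1,
                          n_dropped=n_dropped)

    y = np.array([e.log_or for e in effects], dtype=float)
    v = np.array([e.se for e in effects], dtype=float) ** 2
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite effect estimate")

    w = 1.0 / v
    sw = w.sum()
    y_fe = float(w @ y) / sw
    q = float(w @ (y - y_fe) ** 2)
    denom = sw - float(w @ w) / sw
    tau2 = max(0.0, (q - (len(y) - 1)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (v + tau2)
    sws = w_star.sum()
    pooled_y = float(w_star @ y) / sws
    pooled_se = 1.0 / math.sqrt(sws)
    return MetaResult(
        pooled=EffectEstimate(log_or=pooled_y, se=pooled_se,
                              corrected=any(e.corrected for e in effects)),
        tau2_hat=tau2,
        q_stat=q,
        k=len(y),
        n_dropped=n_dropped,
    )


def pool_trials(trials: Iterable[TwoArmTrial], correction: str = "halves") -> MetaResult:
    """Map trials through :func:`trial_log_or` and pool with :func:`dl_pool`.

    Degenerate trials are excluded and tallied in ``n_dropped``; pooling
    every remaining trial. Raises :class:`DegenerateTrialError` if no
    trial survives.
    """
    effects: list[EffectEstimate] = []
    n_dropped = 0
    for trial in trials:
        try:
            effects.append(trial_log_or(trial, correction=correction))
        except DegenerateTrialError:
            n_dropped += 1
    if not effects:
        raise DegenerateTrialError("all trials degenerate; nothing to pool")
    return dl_pool(effects, n_dropped=n_dropped)


#: Required columns of the flat trial-count CSV.
CSV_COLUMNS = ("study_id", "comparison", "events_trt", "n_trt", "events_ctrl", "n_ctrl")
COMPARISON_LABELS = ("BA", "CA")


def read_trials_csv(path) -> dict[str, list[TwoArmTrial]]:
    """Read a flat trial-count CSV into trials grouped by comparison label.

    The file must have a header with columns ``study_id, comparison,
    events_trt, n_trt, events_ctrl, n_ctrl``; ``comparison`` is ``BA``
    (treatment B vs comparator A) or ``CA``. Counts must be integers --
    a fractional count is an error, never rounded.
    """
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in trial CSV: {sorted(missing)}")
    bad = set(df["comparison"].astype(str)) - set(COMPARISON_LABELS)
    if bad:
        raise ValueError(f"unknown comparison labels {sorted(bad)}; expected BA or CA")

    out: dict[str, list[TwoArmTrial]] = {label: [] for label in COMPARISON_LABELS}
    for row in df.itertuples(index=False):
        counts = {}
        for field in ("events_trt", "n_trt", "events_ctrl", "n_ctrl"):
            value = getattr(row, field)
            if float(value) != int(value):
                raise ValueError(f"non-integer count {value!r} in column {field}")
            counts[field] = int(value)
        out[str(row.comparison)].append(TwoArmTrial(study_id=str(row.study_id), **counts))
    return out
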