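"""Performance measures over replicate estimates of the log risk ratio.

For replicate estimates theta_m of theta = log(true RR):

    relative bias (%) = 100 * mean((theta_m - theta) / theta)
    empirical SE      = sample standard deviation of theta_m  (n-1 denominator)
    MSE               = (mean(theta_m) - theta)^2 + sample variance

so MSE = bias^2 + variance holds as an identity.  The sample (n-1) variance
is used throughout; at 1000 replicates the difference from the population
form is far below Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReplicateRecord",
    "ScenarioMetrics",
    "relative_bias",
    "empirical_se",
    "mse",
    "summarize_replicates",
]


def _validated(theta_hats, true_rr: float | None = None, min_len: int = 1) -> np.ndarray:
    theta = np.asarray(theta_hats, dtype=float).ravel()
    if theta.size < min_len:
        raise ValueError(f"need at least {min_len} estimates, got {theta.size}")
    if true_rr is not None:
        if true_rr <= 0:
            raise ValueError("true_rr must be positive")
        if true_rr == 1.0:
            raise ValueError("true_rr = 1 makes relative bias undefined (log 1 = 0)")
    return theta


def relative_bias(theta_hats, true_rr: float) -> float:
    """100 * mean((theta_m - log RR) / log RR), in percent."""
    theta = _validated(theta_hats, true_rr)
    log_rr = np.log(true_rr)
    return float(100.0 * np.mean((theta - log_rr) / log_rr))


def empirical_se(theta_hats) -> float:
    """Across-replicate sample standard deviation of the log-RR estimates."""
    theta = _validated(theta_hats, min_len=2)
    return float(np.std(theta, ddof=1))


def mse(theta_hats, true_rr: float) -> float:
    """Squared bias plus sample variance of the log-RR estimates."""
    theta = _validated(theta_hats, true_rr, min_len=2)
    bias = float(np.mean(theta)) - np.log(true_rr)
    return float(bias**2 + np.var(theta, ddof=1))


@dataclass(frozen=True)
class ReplicateRecord:
    """One (scenario, replicate, model) estimate of the log risk ratio."""

    scenario_id: str
    replicate: int
    model: str
    theta_hat: float
    se: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class ScenarioMetrics:
    """Per-(scenario, model) summary: the machine twin of one results-table cell."""

    scenario_id: str
    model: str
    true_rr: float
    n: int
    reps_used: int
    n_excluded: int
    relative_bias_pct: float
    empirical_se: float
    mse: float


def summarize_replicates(
    scenario_id: str,
    model: str,
    theta_hats,
    true_rr: float,
    n: int,
    n_excluded: int = 0,
) -> ScenarioMetrics:
    theta = _validated(theta_hats, true_rr, min_len=2)
    return ScenarioMetrics(
        scenario_id=scenario_id,
        model=model,
        true_rr=true_rr,
        n=n,
        reps_used=int(theta.size),
        n_excluded=int(n_excluded),
        relative_bias_pct=relative_bias(theta, true_rr),
        empirical_se=empirical_se(theta),
        mse=mse(theta, true_rr),
    )
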