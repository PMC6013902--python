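"""Simulation scenarios for comparing risk-ratio estimators.

The study design: two independent covariates, Z1 ~ Bernoulli(0.5) and
Z2 ~ Uniform[0, 1]; a binary exposure X drawn from
``logit(P(X=1 | Z1, Z2)) = -1.0 + Z1 + Z2`` (population mean exposure 0.5);
and a binary outcome Y whose probability for *unexposed* subjects is

    g(P(Y=1 | X=0, Z1, Z2)) = alpha - max(Z1 + b*Z2, t)

with g one of {log, logit, probit}, b the Z2 coefficient, and t a truncation
floor on the linear index (t = 0 gives the untruncated, perfectly linear
model, since Z1 + b*Z2 >= 0 always).  Exposed subjects carry a constant
multiplicative risk ratio: P(Y=1 | X=1, ...) = RR * P(Y=1 | X=0, ...).

Truncation puts a spike of subjects at the maximum outcome probability, a
misspecification of any fitted *linear* predictor; a non-log generating link
misspecifies the link of a fitted log-link model.  The 28-scenario registry
(7 families x 4 truncation variants) spans maximum exposed probabilities
{0.75, 0.85, 0.95}, Z2 coefficients {2, 3, 4}, and the three links.
Intercepts are stored exactly as designed (2 decimal places), chosen so the
maximum unexposed probability is max_p_exposed / RR.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "REGISTRY",
    "ScenarioConstructionError",
    "get_scenario",
    "rr2_scenarios",
    "select_scenarios",
    "registry_frame",
    "export_registry_csv",
    "draw_covariates",
    "exposure_probability",
    "unexposed_probability",
    "outcome_probability",
    "simulate_dataset",
    "derive_intercept",
    "fraction_exposed_at_max",
    "p_distribution_summary",
]

LINKS = ("log", "logit", "probit")


class ScenarioConstructionError(ValueError):
    """A scenario's parameters yield an outcome probability outside [0, 1]."""


def _apply_link(link: str, p):
    if link == "log":
        return np.log(p)
    if link == "logit":
        return logit(p)
    if link == "probit":
        return norm.ppf(p)
    raise ValueError(f"unknown link {link!r}; expected one of {LINKS}")


def _apply_inverse_link(link: str, eta):
    if link == "log":
        return np.exp(eta)
    if link == "logit":
        return expit(eta)
    if link == "probit":
        return norm.cdf(eta)
    raise ValueError(f"unknown link {link!r}; expected one of {LINKS}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario registry.

    Parameters are those of the generating model for unexposed subjects,
    ``g(p0) = intercept - max(z1 + beta_z2 * z2, threshold)``, plus the
    design quantities used for bookkeeping: the intended maximum outcome
    probability among the exposed and the design percentage of exposed
    subjects sitting at that maximum.
    """

    family: str
    variant: int
    link: str
    intercept: float
    beta_z2: float
    threshold: float
    max_p_exposed: float
    true_rr: float
    pct_at_max: float

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}; expected one of {LINKS}")
        if self.variant == 1 and self.threshold != 0:
            raise ValueError("variant 1 scenarios are untruncated (threshold 0)")

    @property
    def scenario_id(self) -> str:
        return f"{self.family}-{self.variant}"

    @property
    def truncated(self) -> bool:
        return self.threshold > 0

    @property
    def misspecified(self) -> bool:
        """True when a fitted log-link linear model is misspecified."""
        return self.link != "log" or self.truncated

    def with_true_rr(self, true_rr: float) -> "ScenarioSpec":
        """Same generating model with a different exposure risk ratio."""
        return dataclasses.replace(self, true_rr=float(true_rr))


# family -> (max_p_exposed, beta_z2, link, intercepts for variants 1-4,
#            thresholds for variants 1-4)
_TABLE: dict[str, tuple[float, float, str, tuple[float, ...], tuple[float, ...]]] = {
    "I": (0.75, 3, "log", (-1.38, -1.23, -1.08, -0.78), (0.0, 0.15, 0.30, 0.60)),
    "II": (0.85, 3, "log", (-1.26, -1.11, -0.96, -0.66), (0.0, 0.15, 0.30, 0.60)),
    "III": (0.95, 3, "log", (-1.15, -1.00, -0.85, -0.55), (0.0, 0.15, 0.30, 0.60)),
    "IV": (0.95, 2, "log", (-1.15, -1.05, -0.95, -0.75), (0.0, 0.10, 0.20, 0.40)),
    "V": (0.95, 4, "log", (-1.15, -0.95, -0.75, -0.35), (0.0, 0.20, 0.40, 0.80)),
    "VI": (0.95, 3, "logit", (-0.76, -0.61, -0.46, -0.16), (0.0, 0.15, 0.30, 0.60)),
    "VII": (0.95, 3, "probit", (-0.48, -0.33, -0.18, -0.12), (0.0, 0.15, 0.30, 0.60)),
}

_PCT_AT_MAX = (0.0, 1.4, 2.8, 5.8)

REGISTRY: tuple[ScenarioSpec, ...] = tuple(
    ScenarioSpec(
        family=family,
        variant=variant,
        link=link,
        intercept=intercepts[variant - 1],
        beta_z2=beta,
        threshold=thresholds[variant - 1],
        max_p_exposed=max_p,
        true_rr=3.0,
        pct_at_max=_PCT_AT_MAX[variant - 1],
    )
    for family, (max_p, beta, link, intercepts, thresholds) in _TABLE.items()
    for variant in (1, 2, 3, 4)
)

_BY_ID = {spec.scenario_id: spec for spec in REGISTRY}

#: Families for which the weaker-association (RR = 2) arm is defined.
RR2_FAMILIES = ("III", "VII")


def get_scenario(scenario_id: str, true_rr: float = 3.0) -> ScenarioSpec:
    """Look up a registry scenario, optionally as its RR=2 variant.

    The RR=2 arm reuses the unexposed generating models unchanged and is
    defined only for families III and VII.
    """
    try:
        spec = _BY_ID[scenario_id]
    except KeyError:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; known ids: {sorted(_BY_ID)}"
        ) from None
    if true_rr == 3.0:
        return spec
    if true_rr == 2.0:
        if spec.family not in RR2_FAMILIES:
            raise ValueError(
                f"RR=2 variants exist only for families {RR2_FAMILIES}, "
                f"not {spec.family}"
            )
        return spec.with_true_rr(2.0)
    raise ValueError(f"registry scenarios exist for RR in (2.0, 3.0), not {true_rr}")


def rr2_scenarios() -> tuple[ScenarioSpec, ...]:
    """The eight weaker-association scenarios (families III and VII, RR=2)."""
    return tuple(
        spec.with_true_rr(2.0) for spec in REGISTRY if spec.family in RR2_FAMILIES
    )


def select_scenarios(selection: str | Sequence[str]) -> tuple[ScenarioSpec, ...]:
    """Resolve a selection like ``"all"``, ``"III-*,VII-1"`` or a list of ids."""
    if isinstance(selection, str):
        if selection.strip().lower() == "all":
            return REGISTRY
        tokens = [tok.strip() for tok in selection.split(",") if tok.strip()]
    else:
        tokens = list(selection)
    out: list[ScenarioSpec] = []
    for tok in tokens:
        if tok.endswith("-*"):
            family = tok[:-2]
            matches = [s for s in REGISTRY if s.family == family]
            if not matches:
                raise KeyError(f"unknown scenario family {family!r}")
            out.extend(matches)
        else:
            out.append(get_scenario(tok))
    return tuple(out)


def registry_frame() -> pd.DataFrame:
    """The registry as a DataFrame (one row per scenario)."""
    rows = [dataclasses.asdict(spec) | {"scenario": spec.scenario_id} for spec in REGISTRY]
    frame = pd.DataFrame(rows)
    cols = ["scenario"] + [c for c in frame.columns if c != "scenario"]
    return frame[cols]


def export_registry_csv(path) -> None:
    registry_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Data generation
# ---------------------------------------------------------------------------


def draw_covariates(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw Z1 ~ Bernoulli(0.5) and Z2 ~ Uniform[0, 1], independent."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    z1 = rng.binomial(1, 0.5, size=n)
    z2 = rng.random(size=n)
    return z1, z2


def exposure_probability(z1, z2):
    """P(X=1 | Z1, Z2) = expit(-1.0 + Z1 + Z2); population mean 0.5."""
    return expit(-1.0 + np.asarray(z1) + np.asarray(z2))


def unexposed_probability(spec: ScenarioSpec, z1, z2):
    """P(Y=1 | X=0, Z1, Z2) = g^{-1}(alpha - max(z1 + b*z2, threshold)).

    With threshold 0 this is the untruncated linear model, since the index
    z1 + b*z2 is non-negative.
    """
    index = np.maximum(np.asarray(z1) + spec.beta_z2 * np.asarray(z2), spec.threshold)
    return _apply_inverse_link(spec.link, spec.intercept - index)


def outcome_probability(spec: ScenarioSpec, x, z1, z2):
    """P(Y=1 | X, Z1, Z2): the unexposed probability times RR when exposed."""
    p0 = unexposed_probability(spec, z1, z2)
    p = np.where(np.asarray(x) == 1, spec.true_rr * p0, p0)
    if np.any(p > 1.0):
        raise ScenarioConstructionError(
            f"scenario {spec.scenario_id} with RR={spec.true_rr} yields "
            f"P(Y=1) = {float(np.max(p)):.4f} > 1"
        )
    return p


def derive_intercept(link: str, max_p_exposed: float, true_rr: float, threshold: float) -> float:
    """Intercept that puts the maximum exposed probability at its design value.

    The maximum of the unexposed probability is attained where the (floored)
    linear index equals the threshold, so alpha = g(max_p_exposed / RR) +
    threshold.  Used as a consistency check against the registry's stored
    intercepts, which are kept exactly as designed (printed to 2 dp).
    """
    p_max_unexposed = max_p_exposed / true_rr
    if not 0.0 < p_max_unexposed < 1.0:
        raise ValueError(
            f"max_p_exposed/true_rr = {p_max_unexposed} outside (0, 1)"
        )
    return float(_apply_link(link, p_max_unexposed) + threshold)


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated cohort: covariates, exposure, outcome and true risks."""

    z1: np.ndarray
    z2: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p_true: np.ndarray
    scenario: ScenarioSpec
    seed: int

    def __post_init__(self) -> None:
        n = len(self.y)
        if n == 0:
            raise ValueError("empty dataset")
        for name in ("z1", "z2", "x", "p_true"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in field {name}")

    @property
    def n(self) -> int:
        return len(self.y)

    def design_matrix(self) -> np.ndarray:
        """n x 4 design [1, x, z1, z2] used by both fitted models."""
        return np.column_stack(
            [np.ones(self.n), self.x, self.z1, self.z2]
        ).astype(float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"y": self.y, "x": self.x, "z1": self.z1, "z2": self.z2, "p_true": self.p_true}
        )

    def to_csv(self, path) -> None:
        header = (
            f"# scenario={self.scenario.scenario_id} n={self.n} "
            f"seed={self.seed} true_rr={self.scenario.true_rr}\n"
        )
        buf = io.StringIO()
        self.to_dataframe().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(buf.getvalue())

    @staticmethod
    def from_csv(path) -> "SimulatedDataset":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing scenario front-matter comment line")
            meta = dict(tok.split("=", 1) for tok in first[1:].split())
            frame = pd.read_csv(fh)
        spec = get_scenario(meta["scenario"], true_rr=float(meta.get("true_rr", 3.0)))
        return SimulatedDataset(
            z1=frame["z1"].to_numpy(),
            z2=frame["z2"].to_numpy(),
            x=frame["x"].to_numpy(),
            y=frame["y"].to_numpy(),
            p_true=frame["p_true"].to_numpy(),
            scenario=spec,
            seed=int(meta["seed"]),
        )


def simulate_dataset(spec: ScenarioSpec, n: int, seed: int) -> SimulatedDataset:
    """Simulate one cohort: covariates, then exposure, then outcome.

    One random stream per dataset; (spec, n, seed) fully determines the data.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    z1, z2 = draw_covariates(n, rng)
    x = (rng.random(n) < exposure_probability(z1, z2)).astype(int)
    p_true = outcome_probability(spec, x, z1, z2)
    y = (rng.random(n) < p_true).astype(int)
    return SimulatedDataset(z1=z1, z2=z2, x=x, y=y, p_true=p_true, scenario=spec, seed=int(seed))


def fraction_exposed_at_max(spec: ScenarioSpec, n: int = 1_000_000, seed: int = 0) -> float:
    """Percentage of exposed subjects whose index sits at the truncation floor.

    Subjects with z1 + b*z2 <= threshold all share the maximum outcome
    probability; the design targets 1.4 / 2.8 / 5.8 % for variants 2/3/4.
    Estimated by simulation of covariates and exposure only.
    """
    if not spec.truncated:
        return 0.0
    rng = np.random.default_rng(seed)
    z1, z2 = draw_covariates(n, rng)
    x = rng.random(n) < exposure_probability(z1, z2)
    at_max = (z1 + spec.beta_z2 * z2) <= spec.threshold
    n_exposed = int(x.sum())
    if n_exposed == 0:
        return 0.0
    return 100.0 * float(np.count_nonzero(at_max & x)) / n_exposed


@dataclass(frozen=True)
class PDistributionSummary:
    """Histogram of true outcome probabilities by exposure group.

    ``spike_pct`` is the percentage of each group sitting exactly at the
    group's maximum probability (the truncation spike); bin counts include
    the spike and sum to the group sizes.
    """

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]
    group_sizes: dict[str, int]
    p_max: dict[str, float]
    spike_pct: dict[str, float]


def p_distribution_summary(
    spec: ScenarioSpec, n: int, seed: int = 0, bins: int = 50
) -> PDistributionSummary:
    """Summarise the distribution of P(Y=1) for exposed and unexposed subjects."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    data = simulate_dataset(spec, n, seed)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    p_max: dict[str, float] = {}
    spike: dict[str, float] = {}
    for label, mask in (("exposed", data.x == 1), ("unexposed", data.x == 0)):
        p = data.p_true[mask]
        sizes[label] = int(mask.sum())
        counts[label], _ = np.histogram(p, bins=edges)
        if sizes[label]:
            pm = float(p.max())
            p_max[label] = pm
            at_max = np.isclose(p, pm, rtol=0.0, atol=1e-12)
            # only a truncated design produces a genuine spike (positive mass)
            spike[label] = (
                100.0 * float(at_max.sum()) / sizes[label] if spec.truncated else 0.0
            )
        else:
            p_max[label] = float("nan")
            spike[label] = 0.0
    return PDistributionSummary(
        bin_edges=edges, counts=counts, group_sizes=sizes, p_max=p_max, spike_pct=spike
    )
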