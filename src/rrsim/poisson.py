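"""Modified (robust) Poisson regression for binary outcomes.

Applying the Poisson score equations with a log link to Bernoulli data,

    S_j(beta) = sum_i (y_i - mu_i) x_ij = 0,   mu_i = exp(x_i' beta),

gives a consistent quasi-likelihood estimate of the log risk ratio without
the boundary constraint that plagues the log-binomial MLE (the dispersion
parameter cancels from the estimating equations).  Because the Poisson
variance function is wrong for Bernoulli responses, standard errors come
from the classical sandwich estimator

    cov(beta) = B^{-1} M B^{-1},
    B = sum_i mu_i x_i x_i'        (summed information, "bread"),
    M = sum_i (y_i - mu_i)^2 x_i x_i'   (summed score outer products, "meat"),

evaluated at the estimate.  Raw residuals, no small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logbinomial import RankDeficiencyError

__all__ = ["RobustPoisson", "RobustPoissonResults", "SandwichPieces", "sandwich_variance"]


@dataclass(frozen=True)
class SandwichPieces:
    """Bread, meat and the assembled sandwich covariance."""

    bread: np.ndarray
    meat: np.ndarray
    covariance: np.ndarray


def sandwich_variance(beta, y, X) -> SandwichPieces:
    """Classical sandwich covariance for log-link Poisson scores on binary data.

    For the log link the observed and expected information coincide
    (I_i = mu_i x_i x_i'), so the bread needs no expectation approximation.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = np.exp(X @ beta)
    bread = (X * mu[:, None]).T @ X
    resid2 = (y - mu) ** 2
    meat = (X * resid2[:, None]).T @ X
    try:
        binv = np.linalg.inv(bread)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(str(exc)) from exc
    cov = binv @ meat @ binv
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry
    return SandwichPieces(bread=bread, meat=meat, covariance=cov)


class RobustPoisson:
    """Poisson working model for a binary outcome, log link, sandwich SEs.

    Same constructor conventions as :class:`rrsim.logbinomial.LogBinomial`.
    """

    def __init__(self, endog, exog, exog_names: list[str] | None = None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("exog must be n x k with n matching endog")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficiencyError("exog is rank deficient")
        self.endog = y
        self.exog = X
        self.nobs, self.k = X.shape
        self.exog_names = list(exog_names) if exog_names else [
            f"x{j}" for j in range(self.k)
        ]

    @classmethod
    def from_dataframe(cls, data, response: str = "y", predictors=("x", "z1", "z2")):
        y = data[response].to_numpy()
        X = np.column_stack(
            [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in predictors]
        )
        return cls(y, X, exog_names=["intercept", *predictors])

    @classmethod
    def from_formula(cls, formula: str, data):
        lhs, rhs = (side.strip() for side in formula.split("~"))
        predictors = [term.strip() for term in rhs.split("+") if term.strip() != "1"]
        return cls.from_dataframe(data, response=lhs, predictors=predictors)

    def score(self, params) -> np.ndarray:
        mu = np.exp(self.exog @ np.asarray(params, dtype=float))
        return self.exog.T @ (self.endog - mu)

    def _quasi_loglik(self, params) -> float:
        # Poisson quasi log-likelihood up to a beta-free constant
        eta = self.exog @ params
        return float(np.sum(self.endog * eta - np.exp(eta)))

    def fit(self, max_iter: int = 100, tol: float = 1e-10) -> "RobustPoissonResults":
        """Fisher scoring on the quasi-score equations.

        The quasi-likelihood is globally concave in beta, so starting values
        are immaterial; intercept log(mean y), slopes zero.  Divergence (a
        degenerate all-zero or all-one response drives the intercept to the
        boundary) is reported via ``converged``.
        """
        beta = np.zeros(self.k)
        ybar = float(self.endog.mean())
        const = self._const_index()
        beta[const] = np.log(ybar) if ybar > 0 else -10.0

        converged = False
        n_iter = 0
        ql = self._quasi_loglik(beta)
        for n_iter in range(1, max_iter + 1):
            mu = np.exp(self.exog @ beta)
            info = (self.exog * mu[:, None]).T @ self.exog
            score = self.exog.T @ (self.endog - mu)
            try:
                delta = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(delta)):
                break
            # step-halving keeps the concave quasi-likelihood non-decreasing
            step = 1.0
            for _ in range(30):
                candidate = beta + step * delta
                ql_new = self._quasi_loglik(candidate)
                if np.isfinite(ql_new) and ql_new >= ql - 1e-12:
                    break
                step *= 0.5
            else:
                break
            beta, ql = candidate, ql_new
            if float(np.max(np.abs(step * delta))) < tol:
                converged = True
                break

        mu = np.exp(self.exog @ beta)
        try:
            pieces = sandwich_variance(beta, self.endog, self.exog)
            bse = np.sqrt(np.diag(pieces.covariance))
        except (ValueError, RankDeficiencyError):
            pieces = None
            bse = np.full(self.k, np.nan)
        return RobustPoissonResults(
            model=self,
            params=beta,
            bse=bse,
            sandwich=pieces,
            converged=converged,
            n_iter=n_iter,
            max_fitted_mu=float(mu.max()),
        )

    def _const_index(self) -> int:
        const_cols = np.flatnonzero(
            np.all(self.exog == self.exog[0, :], axis=0) & (self.exog[0, :] != 0)
        )
        if const_cols.size == 0:
            raise ValueError("exog must include an intercept (constant) column")
        return int(const_cols[0])


@dataclass
class RobustPoissonResults:
    """Quasi-likelihood point estimates with sandwich standard errors."""

    model: RobustPoisson
    params: np.ndarray
    bse: np.ndarray
    sandwich: SandwichPieces | None
    converged: bool
    n_iter: int
    max_fitted_mu: float

    @property
    def risk_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm as _norm

        zcrit = _norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - zcrit * self.bse, self.params + zcrit * self.bse]
        )

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Robust (modified) Poisson regression",
            f"  n = {self.model.nobs}, converged = {self.converged} "
            f"({self.n_iter} iterations)",
            f"  max fitted mean = {self.max_fitted_mu:.4f}  (sandwich SEs)",
            f"  {'term':<12}{'coef':>10}{'robust se':>12}{'RR':>10}{'95% CI':>22}",
        ]
        for name, b, se, rr, (lo, hi) in zip(
            self.model.exog_names, self.params, self.bse, self.risk_ratios, ci
        ):
            lines.append(
                f"  {name:<12}{b:>10.4f}{se:>12.4f}{rr:>10.4f}"
                f"      [{np.exp(lo):>7.4f}, {np.exp(hi):>7.4f}]"
            )
        return "\n".join(lines)
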