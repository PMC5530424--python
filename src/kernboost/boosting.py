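"""Component-wise functional gradient boosting with pathway-kernel base-learners.

The disease status y in {0, 1} is modelled on the logit scale by an additive
predictor eta = X beta + sum_p f_p(Z), where each f_p is a kernel-machine
effect of one pathway.  Boosting minimizes the empirical binomial risk by
repeatedly fitting every pathway's penalized kernel base-learner to the
negative gradient u = y - expit(eta) and updating only the best-fitting one
by a small step nu.  Early stopping (the number of iterations m_stop) is the
actual regularization and is tuned by stratified subsampling; environmental
covariates enter as a fixed logistic-regression offset.

Each base-learner solves a ridge problem in the transformed design
Ktilde = K K^(-1/2), whose penalty is the identity; the penalty weight
lambda is calibrated so that every base-learner spends the same degrees of
freedom (default 4), which keeps selection between pathways unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit, logit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .kernel import TOL_REL, GenotypeMatrix, KernelMatrix, ensure_psd_kernel, kernel_sqrt_inv

DF_TARGET = 4.0  # equal degrees of freedom for every base-learner
NU = 0.1  # default step length


# ---------------------------------------------------------------------------
# offset model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateOffsetModel:
    """Logistic regression on environmental covariates, used as start model."""

    beta: np.ndarray
    covariate_names: tuple[str, ...] = ()
    fitted: bool = True

    def linear_predictor(self, n: int | None = None, X: np.ndarray | None = None) -> np.ndarray:
        if self.covariate_names:
            if X is None:
                raise ValueError(
                    f"offset model requires covariates {list(self.covariate_names)}"
                )
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(self.covariate_names):
                raise ValueError("covariate matrix has wrong number of columns")
            return self.beta[0] + X @ self.beta[1:]
        if n is None and X is not None:
            n = len(X)
        if n is None:
            raise ValueError("n is required for an intercept-only offset")
        return np.full(n, self.beta[0])


def fit_offset_logistic(
    y: np.ndarray,
    X: np.ndarray | None = None,
    covariate_names: tuple[str, ...] | None = None,
) -> CovariateOffsetModel:
    """Maximum-likelihood logistic offset for the environmental covariates.

    Without covariates this is the intercept-only model beta_0 = logit(ybar).
    Perfect separation is raised as an error (add regularization or drop the
    offending covariate upstream; nothing is silently penalized here).
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class; cannot fit a logistic model")
    if X is None:
        return CovariateOffsetModel(beta=np.array([logit(y.mean())]))
    X = np.asarray(X, dtype=float)
    if covariate_names is None:
        covariate_names = tuple(f"x{j}" for j in range(X.shape[1]))
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ValueError(
                "perfect separation in the covariate offset model; consider a "
                "penalized fit or removing the separating covariate"
            ) from exc
    beta = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3:
        raise ValueError(
            "offset coefficients diverged (quasi-separation); consider a "
            "penalized fit or removing the separating covariate"
        )
    return CovariateOffsetModel(beta=beta, covariate_names=tuple(covariate_names))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def negative_gradient(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """u = y - expit(eta): negative gradient of the binomial loss in eta."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta contains non-finite values")
    return np.asarray(y, dtype=float) - expit(eta)


def empirical_risk(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean negative binomial log-likelihood, computed stably."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


# ---------------------------------------------------------------------------
# base-learner
# ---------------------------------------------------------------------------

class KernelBaseLearner:
    """One pathway's penalized kernel base-learner.

    Holds the repaired kernel's eigen-factors (V, d), from which the ridge
    fit in the Ktilde = K K^(-1/2) basis and the effective degrees of freedom
    follow in closed form: Ktilde' Ktilde shares the eigenvalues d of K, so
    df(lambda) = sum_i d_i / (d_i + lambda).
    """

    def __init__(
        self,
        pathway_id: str,
        K_raw: np.ndarray,
        df_target: float = DF_TARGET,
        tol_rel: float = TOL_REL,
        max_rank: int | None = None,
        df_method: str = "trace_S",
    ) -> None:
        self.pathway_id = pathway_id
        self.K_raw = np.asarray(K_raw, dtype=float)
        self.df_target = float(df_target)
        self.tol_rel = float(tol_rel)
        self.max_rank = max_rank
        self.df_method = df_method
        repaired = ensure_psd_kernel(KernelMatrix(self.K_raw, pathway_id))
        self.rho_applied = repaired.rho_applied
        sq = kernel_sqrt_inv(repaired, tol_rel=tol_rel, max_rank=max_rank)
        self.d = sq.eigenvalues  # retained eigenvalues of K (= of Ktilde'Ktilde)
        self.V = sq.eigenvectors  # n x rank
        self.rank = sq.rank
        self.lam = calibrate_lambda(self, self.df_target)
        # genotype-side pieces for out-of-sample prediction (set by pipeline)
        self.snp_ids: list[str] | None = None
        self.snp_weight_matrix: np.ndarray | None = None  # A N A'
        self.Z_train: np.ndarray | None = None
        self.gamma_agg = np.zeros(self.K_raw.shape[0])

    @property
    def n(self) -> int:
        return self.K_raw.shape[0]

    def attach_genotype_map(
        self, snp_ids: list[str], snp_weight_matrix: np.ndarray, Z_train: np.ndarray
    ) -> None:
        """Store A N A' and the training genotypes for prediction kernels."""
        self.snp_ids = list(snp_ids)
        self.snp_weight_matrix = np.asarray(snp_weight_matrix, dtype=float)
        self.Z_train = np.asarray(Z_train, dtype=float)

    def subsample(self, rows: np.ndarray) -> "KernelBaseLearner":
        """Base-learner restricted to a subset of individuals.

        K restricted to rows/columns of a subsample equals the kernel built
        from the subsampled genotypes, so no genotype access is needed.
        """
        K_sub = self.K_raw[np.ix_(rows, rows)]
        return KernelBaseLearner(
            self.pathway_id, K_sub, self.df_target, self.tol_rel,
            self.max_rank, self.df_method,
        )

    def degrees_of_freedom(self, lam: float) -> float:
        h = self.d / (self.d + lam)
        if self.df_method == "trace_2S_SS":
            return float(np.sum(2 * h - h * h))
        return float(np.sum(h))


def calibrate_lambda(
    base_learner: KernelBaseLearner, df_target: float, tol: float = 1e-6
) -> float:
    """Solve df(lambda) = df_target by bisection on log(lambda).

    df is strictly decreasing in lambda, from rank(Ktilde) at lambda -> 0 to
    0 at lambda -> infinity, so a root exists iff 0 < df_target < rank.
    """
    d = base_learner.d
    r_eff = base_learner.degrees_of_freedom(0.0)
    if not 0 < df_target < r_eff:
        raise ValueError(
            f"df_target {df_target} infeasible for rank {base_learner.rank} "
            f"(attainable range (0, {r_eff:g}))"
        )

    def gap(log_lam: float) -> float:
        return base_learner.degrees_of_freedom(np.exp(log_lam)) - df_target

    d_max = float(d.max())
    lo, hi = np.log(d_max) - 40.0, np.log(d_max) + 40.0
    while gap(lo) < 0:
        lo -= 20.0
    while gap(hi) > 0:
        hi += 20.0
    log_lam = brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16)
    lam = float(np.exp(log_lam))
    if abs(base_learner.degrees_of_freedom(lam) - df_target) > tol:
        raise RuntimeError("lambda calibration did not reach the df tolerance")
    return lam


def fit_base_learner(
    base_learner: KernelBaseLearner, u: np.ndarray
) -> tuple[np.ndarray, float]:
    """Penalized least-squares fit of one base-learner to the gradient u.

    Returns the ridge coefficients gamma_hat in the Ktilde basis,
    gamma_hat = (Ktilde'Ktilde + lambda I)^(-1) Ktilde' u, and the residual
    sum of squares of the fitted values Ktilde gamma_hat.  On full-rank
    kernels this is algebraically identical to the direct kernel-penalized
    form gamma = (K'K + lambda K)^(-1) K' u mapped through K^(1/2).
    """
    u = np.asarray(u, dtype=float)
    V, d, lam = base_learner.V, base_learner.d, base_learner.lam
    t = V.T @ u
    gamma_hat = V @ (np.sqrt(d) / (d + lam) * t)
    fitted = V @ (d / (d + lam) * t)
    rss = float(np.sum((u - fitted) ** 2))
    return gamma_hat, rss


# ---------------------------------------------------------------------------
# boosting loop
# ---------------------------------------------------------------------------

@dataclass
class BoostFit:
    """A fitted kernel boosting model."""

    offset: CovariateOffsetModel
    nu: float
    m_stop: int
    pathway_ids: list[str]
    selection_path: list[int]
    f_hat: np.ndarray  # P x n per-pathway aggregated function estimates
    gamma_agg: np.ndarray  # P x n accumulated coefficients in the Ktilde basis
    eta_offset: np.ndarray
    eta_train: np.ndarray
    risk_path: list[float]
    base_learners: list[KernelBaseLearner] = field(repr=False, default_factory=list)
    cv: "CVResult | None" = None

    @property
    def n_selected(self) -> np.ndarray:
        counts = np.zeros(len(self.pathway_ids), dtype=int)
        for j in self.selection_path:
            counts[j] += 1
        return counts

    def fitted_proba(self) -> np.ndarray:
        return expit(self.eta_train)


def boost(
    y: np.ndarray,
    base_learners: list[KernelBaseLearner],
    offset: CovariateOffsetModel,
    nu: float = NU,
    m_stop: int = 200,
    X: np.ndarray | None = None,
) -> BoostFit:
    """Run m_stop iterations of component-wise kernel boosting.

    Each iteration fits every base-learner to the current negative gradient,
    selects the one with minimal residual sum of squares (smallest index on
    ties, for reproducible paths) and moves the additive predictor by nu
    times its fit.  m_stop = 0 returns the offset-only model.
    """
    if not 0 < nu <= 1:
        raise ValueError("nu must be in (0, 1]")
    if m_stop < 0:
        raise ValueError("m_stop must be non-negative")
    y = np.asarray(y, dtype=float)
    n = len(y)
    for bl in base_learners:
        if bl.n != n:
            raise ValueError(
                f"base-learner {bl.pathway_id!r} built for {bl.n} individuals, got {n}"
            )
    eta_offset = offset.linear_predictor(n, X)
    eta = eta_offset.copy()
    P = len(base_learners)
    f_hat = np.zeros((P, n))
    gamma_agg = np.zeros((P, n))
    path: list[int] = []
    risks = [empirical_risk(y, eta)]
    for _ in range(m_stop):
        u = y - expit(eta)
        best_j, best_rss, best_fit, best_t = -1, np.inf, None, None
        for j, bl in enumerate(base_learners):
            t = bl.V.T @ u
            fit = bl.V @ (bl.d / (bl.d + bl.lam) * t)
            rss = float(np.sum((u - fit) ** 2))
            if rss < best_rss:
                best_j, best_rss, best_fit, best_t = j, rss, fit, t
        bl = base_learners[best_j]
        gamma = bl.V @ (np.sqrt(bl.d) / (bl.d + bl.lam) * best_t)
        f_hat[best_j] += nu * best_fit
        gamma_agg[best_j] += nu * gamma
        eta += nu * best_fit
        path.append(best_j)
        risks.append(empirical_risk(y, eta))
    return BoostFit(
        offset=offset,
        nu=nu,
        m_stop=m_stop,
        pathway_ids=[bl.pathway_id for bl in base_learners],
        selection_path=path,
        f_hat=f_hat,
        gamma_agg=gamma_agg,
        eta_offset=eta_offset,
        eta_train=eta,
        risk_path=risks,
        base_learners=list(base_learners),
    )


def selected_pathways(fit: BoostFit) -> set[str]:
    """Pathways entering the model at least once within the tuned m_stop."""
    return {fit.pathway_ids[j] for j in fit.selection_path}


# ---------------------------------------------------------------------------
# tuning by subsampling
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_risks: np.ndarray  # n_folds x (m_max + 1) out-of-subsample risks
    mean_risk: np.ndarray
    m_stop_opt: int
    folds: list[np.ndarray]
    seed: int


def select_mstop(mean_risk: np.ndarray) -> int:
    """Argmin of the mean out-of-sample risk curve; smallest m on ties."""
    return int(np.argmin(mean_risk))


def _stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    n_case = int(np.floor(fraction * len(cases)))
    n_ctrl = int(np.floor(fraction * len(controls)))
    if n_case < 1 or n_ctrl < 1:
        raise ValueError("subsample would lack one of the classes; "
                         "increase the fraction or the sample size")
    pick = np.concatenate([
        rng.choice(cases, size=n_case, replace=False),
        rng.choice(controls, size=n_ctrl, replace=False),
    ])
    return np.sort(pick)


def tune_mstop(
    y: np.ndarray,
    base_learners: list[KernelBaseLearner],
    offset: CovariateOffsetModel | None = None,
    nu: float = NU,
    m_max: int = 200,
    n_folds: int = 20,
    subsample_fraction: float = 0.5,
    seed: int = 0,
    X: np.ndarray | None = None,
) -> CVResult:
    """Choose m_stop by stratified subsampling.

    For each fold, a case-status-stratified subsample of floor(fraction * n)
    individuals is drawn without replacement, the boosting path is fitted on
    it to m_max, and the mean negative log-likelihood on the left-out
    individuals is recorded at every m in {0, ..., m_max}.  m = 0 (the
    offset-only model) is part of the grid, so an entirely empty model can
    win.  The fold-mean risk curve is minimized; the offset is refitted on
    every subsample.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if not 0 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    fold_risks = np.empty((n_folds, m_max + 1))
    folds: list[np.ndarray] = []
    for f in range(n_folds):
        sub = _stratified_subsample(y, subsample_fraction, rng)
        folds.append(sub)
        test = np.setdiff1d(np.arange(n), sub)
        y_sub, y_test = y[sub], y[test]
        X_sub = X[sub] if X is not None else None
        X_test = X[test] if X is not None else None
        offset_f = fit_offset_logistic(
            y_sub, X_sub,
            covariate_names=offset.covariate_names if offset is not None else None,
        )
        sub_learners = [bl.subsample(sub) for bl in base_learners]
        eta = offset_f.linear_predictor(len(sub), X_sub)
        eta_test = offset_f.linear_predictor(len(test), X_test)
        # K*[test, sub] V maps Ktilde-basis coefficient updates to the test set
        bridges = [
            bl.K_raw[np.ix_(test, sub)] @ sl.V
            for bl, sl in zip(base_learners, sub_learners)
        ]
        fold_risks[f, 0] = empirical_risk(y_test, eta_test)
        for m in range(1, m_max + 1):
            u = y_sub - expit(eta)
            best_j, best_rss, best_fit, best_t = -1, np.inf, None, None
            for j, sl in enumerate(sub_learners):
                t = sl.V.T @ u
                fit = sl.V @ (sl.d / (sl.d + sl.lam) * t)
                rss = float(np.sum((u - fit) ** 2))
                if rss < best_rss:
                    best_j, best_rss, best_fit, best_t = j, rss, fit, t
            sl = sub_learners[best_j]
            eta += nu * best_fit
            # K* K^(-1/2) gamma_hat reduces to bridge @ (t / (d + lambda))
            eta_test += nu * bridges[best_j] @ (best_t / (sl.d + sl.lam))
            fold_risks[f, m] = empirical_risk(y_test, eta_test)
    mean_risk = fold_risks.mean(axis=0)
    return CVResult(
        fold_risks=fold_risks,
        mean_risk=mean_risk,
        m_stop_opt=select_mstop(mean_risk),
        folds=folds,
        seed=seed,
    )


def kernel_boost(
    y: np.ndarray,
    base_learners: list[KernelBaseLearner],
    X: np.ndarray | None = None,
    nu: float = NU,
    m_max: int = 200,
    n_folds: int = 20,
    subsample_fraction: float = 0.5,
    seed: int = 0,
    covariate_names: tuple[str, ...] | None = None,
) -> BoostFit:
    """Offset fit, subsampling-tuned m_stop, and the final boosting model."""
    offset = fit_offset_logistic(y, X, covariate_names)
    cv = tune_mstop(
        y, base_learners, offset, nu=nu, m_max=m_max, n_folds=n_folds,
        subsample_fraction=subsample_fraction, seed=seed, X=X,
    )
    fit = boost(y, base_learners, offset, nu=nu, m_stop=cv.m_stop_opt, X=X)
    fit.cv = cv
    return fit


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def pathway_effects(
    fit: BoostFit, Z_new: GenotypeMatrix | None = None
) -> np.ndarray:
    """Per-pathway effect contributions f_p for new (or training) data.

    For new genotypes the effect is K* K^(-1/2) gamma_agg, realized through
    the stored SNP weight matrix A N A' of each pathway; with ``Z_new=None``
    the in-sample estimates are returned.
    """
    if Z_new is None:
        return fit.f_hat.copy()
    P = len(fit.pathway_ids)
    out = np.zeros((P, Z_new.n))
    for j, bl in enumerate(fit.base_learners):
        if not np.any(fit.gamma_agg[j]):
            continue
        if bl.snp_ids is None:
            raise ValueError(
                f"base-learner {bl.pathway_id!r} lacks genotype data needed "
                "for prediction (attach_genotype_map was never called)"
            )
        alpha = bl.V @ ((bl.V.T @ fit.gamma_agg[j]) / np.sqrt(bl.d))
        Z_p = Z_new.subset_snps(bl.snp_ids).Z
        k_star = Z_p @ bl.snp_weight_matrix @ bl.Z_train.T
        out[j] = k_star @ alpha
    return out


def predict_proba(
    fit: BoostFit,
    Z_new: GenotypeMatrix | None = None,
    X_new: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted case probabilities expit(eta*) for new individuals."""
    if Z_new is None:
        return fit.fitted_proba()
    effects = pathway_effects(fit, Z_new)
    eta = fit.offset.linear_predictor(Z_new.n, X_new) + effects.sum(axis=0)
    return expit(eta)
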