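"""Linear genomic-prediction models: Bayesian GBLUP, BayesB, elastic net.

GBLUP samples the animal-effect mixed model ``y* = 1mu + a + e`` with
``a ~ N(0, G sigma_a^2)`` by Gibbs on the reference block and predicts
validation animals through the conditional expectation
``G_vr (G_rr)^-1 a_hat``. BayesB runs single-site Gibbs with a
point-mass/scaled-t mixture prior per marker. The elastic net minimizes
``||y - Xb||^2 + lambda2 ||b||^2 + lambda1 |b|_1`` by cyclic coordinate
descent; note the mixing convention used throughout: ``alpha = 1`` is pure
ridge and ``alpha = 0`` pure lasso (the reverse of several common
implementations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from ._tuning import TuneResult, reference_split
from .exceptions import McmcError, NumericalError, ParameterError
from .pheno import GibbsSettings, RelationshipMatrix, _gibbs_mixed_model, _psd_eigh

__all__ = [
    "GblupConfig",
    "BayesBConfig",
    "EnetConfig",
    "LinearFit",
    "fit_gblup",
    "backsolve_snp_effects",
    "fit_bayesb",
    "fit_enet",
    "tune_enet",
    "default_lambda_path",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class GblupConfig:
    """Gibbs settings for GBLUP: 150k iterations / 50k burn-in / thin 10
    keep 10,000 posterior samples. Use :meth:`desk` for a fast chain."""

    n_iter: int = 150_000
    burn_in: int = 50_000
    thin: int = 10
    df: float = 5.0
    residual_df: float = 5.0
    scale_u: float | None = None
    scale_e: float | None = None

    @classmethod
    def desk(cls) -> "GblupConfig":
        return cls(n_iter=6000, burn_in=1500, thin=5)

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class BayesBConfig:
    """BayesB chain and prior settings.

    ``pi`` is the prior probability of a null marker effect; a non-null
    effect has a scaled-t prior with ``nu`` degrees of freedom and scale
    ``s2`` (``None`` = solve ``s2`` so the prior expected total marker
    variance is half the phenotypic variance).
    """

    n_iter: int = 120_000
    burn_in: int = 20_000
    thin: int = 100
    pi: float = 0.95
    nu: float = 5.0
    s2: float | None = None
    residual_df: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.pi < 1.0:
            raise ParameterError("pi must be in [0, 1)")
        if self.nu <= 2.0:
            raise ParameterError("nu must exceed 2 for a finite prior variance")

    @classmethod
    def desk(cls, **kw) -> "BayesBConfig":
        kw.setdefault("n_iter", 3000)
        kw.setdefault("burn_in", 1000)
        kw.setdefault("thin", 5)
        return cls(**kw)


@dataclass
class EnetConfig:
    """Elastic-net penalty in the (alpha, lambda_total) parameterization.

    ``alpha = lambda2 / (lambda1 + lambda2)``: alpha=1 is pure ridge,
    alpha=0 pure lasso. ``lambda1 + lambda2 = lambda_total * n`` so the
    penalty path is comparable across sample sizes. Explicit ``lambda1`` /
    ``lambda2`` override the mapping when set.
    """

    alpha: float = 0.5
    lambda_total: float = 0.1
    standardize: bool = True
    lambda1: float | None = None
    lambda2: float | None = None
    tol: float = 1e-7
    max_sweeps: int = 10_000

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError("alpha must be in [0, 1]")
        if self.lambda_total < 0:
            raise ParameterError("lambda_total must be non-negative")

    def penalties(self, n: int) -> tuple[float, float]:
        """Resolve (lambda1, lambda2) for a reference set of size n."""
        if self.lambda1 is not None or self.lambda2 is not None:
            return float(self.lambda1 or 0.0), float(self.lambda2 or 0.0)
        total = self.lambda_total * n
        return (1.0 - self.alpha) * total, self.alpha * total


def default_lambda_path(start: float = 1.0, stop: float = 0.01, n_steps: int = 20):
    """Exponentially decreasing penalty path from ``start`` down to ``stop``."""
    if not (start > stop > 0) or n_steps < 2 or n_steps > 20:
        raise ParameterError("path must decrease over 2..20 steps")
    return np.geomspace(start, stop, n_steps)


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Fitted state of a linear predictor.

    ``predict`` uses ``mu + Z beta`` when marker effects are available;
    GBLUP fits predict through stored per-animal genetic values instead
    (marker effects appear after :func:`backsolve_snp_effects`).
    """

    model: str
    mu: float
    beta: np.ndarray | None = None
    snp_ids: np.ndarray | None = None
    genetic_values: pd.Series | None = None
    inclusion_prob: np.ndarray | None = None
    variance_components: dict = field(default_factory=dict)
    config: object = None
    details: dict = field(default_factory=dict)

    def predict(self, Z: np.ndarray | None = None, ids=None) -> np.ndarray:
        if Z is not None and self.beta is not None:
            Z = np.asarray(Z, dtype=float)
            if Z.shape[1] != self.beta.size:
                raise ParameterError(
                    f"predictor matrix has {Z.shape[1]} columns, fit has {self.beta.size}"
                )
            return self.mu + Z @ self.beta
        if ids is not None and self.genetic_values is not None:
            return self.mu + self.genetic_values.loc[list(ids)].to_numpy()
        raise ParameterError("predict requires Z (marker fits) or ids (GBLUP fits)")

    def snp_scores(self) -> np.ndarray:
        """Squared marker effects, the ranking score for linear models."""
        if self.beta is None:
            raise ParameterError(f"{self.model} fit has no marker effects yet")
        return self.beta ** 2


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def fit_gblup(
    ystar,
    G: RelationshipMatrix,
    reference_ids,
    cfg: GblupConfig | None = None,
    seed: int = 0,
    jitter: float = 1e-8,
) -> LinearFit:
    """Fit Bayesian GBLUP on the reference block of ``G`` and predict the rest.

    ``ystar`` is aligned with ``reference_ids`` (a pandas Series indexed by
    animal id also works). Posterior means of ``mu``, the variances and the
    reference genetic values are stored; animals of ``G`` outside the
    reference get ``g_hat = G_vr (G_rr + jitter I)^-1 a_hat``.
    """
    cfg = cfg or GblupConfig()
    reference_ids = list(reference_ids)
    if isinstance(ystar, pd.Series):
        y = ystar.loc[reference_ids].to_numpy(float)
    else:
        y = np.asarray(ystar, dtype=float)
    if y.size != len(reference_ids):
        raise ParameterError("ystar length does not match reference_ids")
    if np.isnan(y).any():
        raise ParameterError("reference phenotypes contain missing values")

    ref_idx = G.index_of(reference_ids)
    ref_mask = np.zeros(len(G.animal_ids), dtype=bool)
    ref_mask[ref_idx] = True
    val_idx = np.flatnonzero(~ref_mask)

    g_rr = G.values[np.ix_(ref_idx, ref_idx)]
    eig = _psd_eigh(g_rr, jitter=jitter)
    settings = GibbsSettings(
        n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin,
        df=cfg.df, residual_df=cfg.residual_df,
        scale_u=cfg.scale_u, scale_e=cfg.scale_e,
    )
    out = _gibbs_mixed_model(y, [eig], settings, seed)
    a_ref = out["u_mean"][0]

    gv = pd.Series(0.0, index=pd.Index(G.animal_ids))
    gv.iloc[ref_idx] = a_ref
    if val_idx.size:
        g_vr = G.values[np.ix_(val_idx, ref_idx)]
        try:
            c, low = scipy.linalg.cho_factor(g_rr + jitter * np.eye(len(ref_idx)))
            sol = scipy.linalg.cho_solve((c, low), a_ref)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(f"reference G block is singular: {exc}")
        gv.iloc[val_idx] = g_vr @ sol

    s2a = float(out["s2_mean"][0])
    s2e = out["s2e_mean"]
    return LinearFit(
        model="gblup",
        mu=float(out["mu_mean"]),
        genetic_values=gv,
        variance_components={
            "sigma2_a": s2a,
            "sigma2_e": s2e,
            "h2": s2a / (s2a + s2e),
        },
        config=cfg,
        details={"reference_ids": reference_ids, "n_kept": out["n_kept"]},
    )


def backsolve_snp_effects(
    fit: LinearFit,
    Z: np.ndarray,
    G: RelationshipMatrix,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Back-solve per-SNP effects from GBLUP genetic values.

    With ``G = ZZ'/m`` built from this ``Z`` (rows aligned with
    ``G.animal_ids``), ``beta = Z' G^-1 a_hat / m`` satisfies
    ``Z beta = a_hat`` on the range of G. The effects are stored on the
    fit and returned.
    """
    if fit.genetic_values is None:
        raise ParameterError("fit has no genetic values to back-solve")
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if G.values.shape[0] != n:
        raise ParameterError("Z rows do not match relationship matrix")
    ahat = fit.genetic_values.loc[list(G.animal_ids)].to_numpy(float)
    try:
        c, low = scipy.linalg.cho_factor(G.values + jitter * np.eye(n))
        sol = scipy.linalg.cho_solve((c, low), ahat)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"G is singular beyond jitter: {exc}")
    beta = Z.T @ sol / m
    fit.beta = beta
    return beta


# ---------------------------------------------------------------------------
# BayesB
# ---------------------------------------------------------------------------

def fit_bayesb(
    ystar,
    Z: np.ndarray,
    cfg: BayesBConfig | None = None,
    seed: int = 0,
) -> LinearFit:
    """Single-site Gibbs sampler for the BayesB mixture prior.

    Each marker carries an inclusion indicator (null with prior
    probability ``pi``); conditional on inclusion its effect is normal
    with a marker-specific variance drawn from a scaled inverse
    chi-square(``nu``, ``s2``), which marginally is the scaled-t prior.
    Returns posterior-mean effects and per-marker inclusion frequencies.
    """
    cfg = cfg or BayesBConfig()
    rng = np.random.default_rng(seed)
    y = np.asarray(ystar, dtype=float)
    Z = np.asfortranarray(Z, dtype=float)
    n, m = Z.shape
    if y.size != n:
        raise ParameterError("ystar length does not match Z rows")
    if np.isnan(y).any() or np.isnan(Z).any():
        raise ParameterError("inputs contain missing values")

    vary = y.var()
    ckk = np.einsum("ij,ij->j", Z, Z)
    active = ckk > 0
    m_eff = int(active.sum())
    if m_eff == 0:
        raise ParameterError("all predictor columns are constant")
    col_var = Z.var(axis=0)[active].mean()
    if cfg.s2 is None:
        s2 = 0.5 * vary * (cfg.nu - 2.0) / (
            cfg.nu * m_eff * max(1.0 - cfg.pi, 1e-3) * max(col_var, 1e-12)
        )
    else:
        s2 = cfg.s2

    df_e = cfg.residual_df
    s0_e = 0.5 * vary * (df_e + 2.0) / df_e

    mu = y.mean()
    b = np.zeros(m)
    sig2g = np.full(m, cfg.nu * s2 / max(cfg.nu - 2.0, 0.1))
    sig2e = 0.5 * vary if vary > 0 else 1.0
    e = y - mu

    log_prior_odds = np.log1p(-cfg.pi) - np.log(cfg.pi) if cfg.pi > 0 else np.inf
    active_idx = np.flatnonzero(active)

    b_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    n_kept = 0

    for it in range(cfg.n_iter):
        # intercept
        mu_new = (e.mean() + mu) + np.sqrt(sig2e / n) * rng.standard_normal()
        e += mu - mu_new
        mu = mu_new

        normals = rng.standard_normal(m)
        unifs = rng.random(m)
        chi_in = rng.chisquare(cfg.nu + 1.0, size=m)
        chi_out = rng.chisquare(cfg.nu, size=m)
        for k in active_idx:
            zk = Z[:, k]
            b_old = b[k]
            rhs = zk @ e + ckk[k] * b_old
            prec = ckk[k] / sig2e + 1.0 / sig2g[k]
            v = 1.0 / prec
            bhat = v * rhs / sig2e
            if cfg.pi > 0:
                log_odds = log_prior_odds + 0.5 * (
                    np.log(v) - np.log(sig2g[k])
                ) + 0.5 * bhat * bhat / v
                log_odds = min(max(log_odds, -700.0), 700.0)  # exp overflow guard
                include = unifs[k] < 1.0 / (1.0 + np.exp(-log_odds))
            else:
                include = True
            if include:
                b_new = bhat + np.sqrt(v) * normals[k]
                sig2g[k] = (b_new * b_new + cfg.nu * s2) / chi_in[k]
            else:
                b_new = 0.0
                sig2g[k] = cfg.nu * s2 / chi_out[k]
            if b_new != b_old:
                e += zk * (b_old - b_new)
            b[k] = b_new

        sse = float(e @ e)
        sig2e = (sse + df_e * s0_e) / rng.chisquare(df_e + n)
        if not np.isfinite(sig2e) or sig2e <= 0:
            raise McmcError("residual variance diverged", iteration=it)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            b_sum += b
            incl_sum += b != 0.0
            mu_sum += mu
            n_kept += 1

    return LinearFit(
        model="bayesb",
        mu=mu_sum / n_kept,
        beta=b_sum / n_kept,
        inclusion_prob=incl_sum / n_kept,
        variance_components={"sigma2_e": sig2e, "s2_prior": s2},
        config=cfg,
        details={"n_kept": n_kept},
    )


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _coordinate_descent(X, y, lam1, lam2, tol, max_sweeps, b0=None):
    n, m = X.shape
    b = np.zeros(m) if b0 is None else b0.copy()
    colsq = np.einsum("ij,ij->j", X, X)
    denom = colsq + lam2
    r = y - X @ b
    order = np.flatnonzero(colsq > 0)
    half_l1 = lam1 / 2.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in order:
            bj = b[j]
            zj = X[:, j] @ r + colsq[j] * bj
            bn = _soft(zj, half_l1) / denom[j]
            if bn != bj:
                r += X[:, j] * (bj - bn)
                b[j] = bn
                max_delta = max(max_delta, abs(bn - bj))
        if max_delta < tol:
            return b, True
    return b, False


def fit_enet(ystar, Z: np.ndarray, cfg: EnetConfig | None = None) -> LinearFit:
    """Elastic net by cyclic coordinate descent with soft-thresholding.

    The intercept is unpenalized (handled by centering); with
    ``cfg.standardize`` columns are scaled to unit variance internally and
    coefficients are reported on the input scale.
    """
    cfg = cfg or EnetConfig()
    y = np.asarray(ystar, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if y.size != n:
        raise ParameterError("ystar length does not match Z rows")
    lam1, lam2 = cfg.penalties(n)

    ybar = y.mean()
    yc = y - ybar
    xbar = Z.mean(axis=0)
    Xc = Z - xbar
    if cfg.standardize:
        scale = Xc.std(axis=0)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    else:
        scale = np.ones(m)

    b, converged = _coordinate_descent(
        np.asfortranarray(Xc), yc, lam1, lam2, cfg.tol, cfg.max_sweeps
    )
    if not converged:
        warnings.warn(
            f"elastic net did not converge in {cfg.max_sweeps} sweeps; "
            "returning best iterate",
            RuntimeWarning,
        )
    beta = b / scale
    mu = ybar - float(xbar @ beta)
    return LinearFit(
        model="enet",
        mu=mu,
        beta=beta,
        config=cfg,
        details={"converged": converged, "lambda1": lam1, "lambda2": lam2},
    )


def tune_enet(
    ystar,
    Z: np.ndarray,
    alpha_grid=None,
    lambda_path=None,
    test_fraction: float = 0.2,
    seed: int = 0,
    standardize: bool = True,
) -> TuneResult:
    """Two-step elastic-net grid search on a single seeded 80-20 split.

    Alphas run 0..1 in steps of 0.05 by default; for each alpha the
    penalty path decreases exponentially from 1 to 0.01 in 20 steps (warm
    starts along the path). The winner minimizes test-set MSE, ties broken
    by smaller lambda then larger alpha; the winning configuration is
    refit on the full reference set.
    """
    y = np.asarray(ystar, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    if lambda_path is None:
        lambda_path = default_lambda_path()
    lambda_path = np.sort(np.asarray(lambda_path, dtype=float))[::-1]

    train, test = reference_split(len(y), test_fraction, seed, y=y)
    ytr, yte = y[train], y[test]
    Xtr, Xte = Z[train], Z[test]

    # precompute the transformed training design once
    ybar = ytr.mean()
    ytr_c = ytr - ybar
    xbar = Xtr.mean(axis=0)
    Xtr_c = Xtr - xbar
    if standardize:
        scale = Xtr_c.std(axis=0)
        scale[scale == 0] = 1.0
        Xtr_c = Xtr_c / scale
    else:
        scale = np.ones(Z.shape[1])
    Xtr_c = np.asfortranarray(Xtr_c)
    n_tr = len(train)

    rows = []
    best = None  # (mse, lam, alpha)
    for alpha in alpha_grid:
        b = None
        for lam in lambda_path:
            total = lam * n_tr
            lam1, lam2 = (1.0 - alpha) * total, alpha * total
            b, _ = _coordinate_descent(Xtr_c, ytr_c, lam1, lam2, 1e-7, 10_000, b0=b)
            beta = b / scale
            mu = ybar - float(xbar @ beta)
            mse = float(np.mean((yte - (mu + Xte @ beta)) ** 2))
            rows.append({"alpha": float(alpha), "lambda": float(lam), "test_mse": mse})
            if (
                best is None
                or mse < best[0]
                or (mse == best[0] and (lam < best[1] or (lam == best[1] and alpha > best[2])))
            ):
                best = (mse, float(lam), float(alpha))

    cfg = EnetConfig(alpha=best[2], lambda_total=best[1], standardize=standardize)
    fit = fit_enet(y, Z, cfg)
    fit.details["tune_test_mse"] = best[0]
    return TuneResult(config=cfg, fit=fit, grid=pd.DataFrame(rows))
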