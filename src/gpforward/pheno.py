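"""Phenotype precorrection, genomic relationship matrices, variance components.

Precorrection removes categorical fixed effects (diet, generation, litter,
sex) by ordinary least squares; downstream models consume the residual
``y*``. Relationship matrices follow the centered/standardized marker
cross-product construction ``G = ZZ'/m``; the additive-by-additive matrix
is its Hadamard square. Variance components are estimated by a Gibbs
sampler on ``y* = 1mu + u_1 (+ u_2) + e`` with scaled-inverse-chi-square
priors on every variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfoundingError, NumericalError, ParameterError
from .qc import GenotypePanel

__all__ = [
    "TraitTable",
    "RelationshipMatrix",
    "VarianceComponents",
    "GibbsSettings",
    "COVARIATES",
    "precorrect",
    "standardize_genotypes",
    "build_g_additive",
    "build_g_epistatic",
    "estimate_variance_components",
]

COVARIATES = ("diet", "generation", "litter", "sex")


@dataclass
class TraitTable:
    """Per-animal covariates and trait values.

    ``data`` holds one row per animal with at least ``animal_id`` plus the
    categorical covariates; raw trait values live in ``trait_names``
    columns. Precorrected values are stored in ``ystar`` (same row order,
    one column per precorrected trait) after :func:`precorrect`.
    """

    data: pd.DataFrame
    trait_names: list = field(default_factory=list)
    ystar: pd.DataFrame | None = None
    fitted_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if "animal_id" not in self.data.columns:
            raise ParameterError("trait table requires an 'animal_id' column")
        missing = [t for t in self.trait_names if t not in self.data.columns]
        if missing:
            raise ParameterError(f"trait columns absent from table: {missing}")

    @property
    def animal_ids(self) -> np.ndarray:
        return np.asarray(self.data["animal_id"], dtype=object)

    def ystar_vector(self, trait: str, animal_ids=None) -> pd.Series:
        """Precorrected values for one trait, optionally ordered by ids."""
        if self.ystar is None or trait not in self.ystar.columns:
            raise ParameterError(f"trait {trait!r} has not been precorrected")
        s = pd.Series(np.asarray(self.ystar[trait]), index=self.animal_ids)
        if animal_ids is not None:
            s = s.loc[list(animal_ids)]
        return s


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an ordered set of animal ids."""

    animal_ids: np.ndarray
    values: np.ndarray
    kind: str = "additive"

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ParameterError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ParameterError("relationship matrix must be symmetric")
        if self.kind not in ("additive", "additive_by_additive"):
            raise ParameterError(f"unknown relationship kind {self.kind!r}")

    def index_of(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.array([lookup[a] for a in ids])
        except KeyError as exc:
            raise ParameterError(f"animal id not in relationship matrix: {exc}")

    def block(self, row_ids, col_ids) -> np.ndarray:
        return self.values[np.ix_(self.index_of(row_ids), self.index_of(col_ids))]


@dataclass
class VarianceComponents:
    """Posterior summaries of a variance-component fit."""

    components: dict          # kind -> posterior mean variance
    components_sd: dict
    sigma2_e: float
    sigma2_e_sd: float
    h2: float
    h2_sd: float
    n_samples: int

    @property
    def sigma2_a(self) -> float:
        return self.components.get("additive", 0.0)

    @property
    def sigma2_aa(self) -> float:
        return self.components.get("additive_by_additive", 0.0)


@dataclass
class GibbsSettings:
    """Chain-length and prior settings for the variance-component sampler.

    Priors are scaled inverse chi-square with ``df`` degrees of freedom;
    scales are set so the prior mode equals half the phenotypic variance,
    split equally across the fitted genetic components.
    """

    n_iter: int = 15000
    burn_in: int = 5000
    thin: int = 10
    df: float = 5.0
    residual_df: float = 5.0
    scale_u: float | None = None   # override the automatic prior scale
    scale_e: float | None = None

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ParameterError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ParameterError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# precorrection
# ---------------------------------------------------------------------------

def _dummy_design(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list]:
    """Full-rank dummy design (intercept + drop-first dummies)."""
    cols = [np.ones(len(df))]
    names = ["(intercept)"]
    for cov in covariates:
        levels = sorted(map(str, pd.unique(df[cov])))
        if len(levels) < 2:
            continue  # constant covariate carries no contrast
        for lev in levels[1:]:
            cols.append((df[cov].astype(str) == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    return X, names


def precorrect(traits: TraitTable, covariates=COVARIATES) -> TraitTable:
    """Fit ``y ~ covariates`` (categorical main effects) per trait; store residuals.

    The precorrected value ``y*`` is the OLS residual (mean zero by
    construction). Animals with a missing trait value get ``NaN`` in
    ``ystar``. A rank-deficient covariate design raises
    :class:`~gpforward.exceptions.ConfoundingError` naming the aliased
    columns.
    """
    df = traits.data
    for cov in covariates:
        if cov not in df.columns:
            raise ParameterError(f"covariate column {cov!r} missing from trait table")
    ystar = pd.DataFrame(index=df.index, dtype=float)
    effects: dict = {}
    for trait in traits.trait_names:
        y = pd.to_numeric(df[trait], errors="coerce")
        obs = y.notna()
        if obs.sum() < 3:
            raise ParameterError(f"trait {trait!r} has fewer than 3 observations")
        sub = df.loc[obs]
        X, names = _dummy_design(sub, covariates)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify aliased columns via pivoted QR
            _, r = np.linalg.qr(X)
            diag = np.abs(np.diag(r))
            aliased = [names[j] for j in np.flatnonzero(diag < 1e-8 * diag.max())]
            raise ConfoundingError(
                f"rank-deficient covariate design for trait {trait!r}", aliased or names
            )
        beta, *_ = np.linalg.lstsq(X, y[obs].to_numpy(), rcond=None)
        resid = y[obs].to_numpy() - X @ beta
        resid -= resid.mean()
        col = np.full(len(df), np.nan)
        col[np.flatnonzero(obs.to_numpy())] = resid
        ystar[trait] = col
        effects[trait] = dict(zip(names, beta))
    return TraitTable(
        data=df, trait_names=list(traits.trait_names), ystar=ystar, fitted_effects=effects
    )


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def standardize_genotypes(dosages: np.ndarray, freqs: np.ndarray | None = None):
    """Center and scale dosages: ``z = (x - 2p) / sqrt(2p(1-p))``.

    Frequencies default to the sample allele frequencies of the matrix
    itself. Monomorphic SNPs make the scale zero and raise.
    Returns ``(Z, p)``.
    """
    x = np.asarray(dosages, dtype=float)
    if np.isnan(x).any():
        raise ParameterError("dosages contain missing values; impute first")
    p = x.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        bad = int(((p <= 0) | (p >= 1)).sum())
        raise ParameterError(f"{bad} monomorphic SNP(s); cannot standardize")
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return z, p


def build_g_additive(panel: GenotypePanel) -> RelationshipMatrix:
    """Additive genomic relationship matrix ``G = ZZ'/m``."""
    z, _ = standardize_genotypes(panel.dosages)
    g = z @ z.T / panel.n_snps
    g = (g + g.T) / 2.0  # kill asymmetric rounding noise
    return RelationshipMatrix(animal_ids=panel.animal_ids, values=g, kind="additive")


def build_g_epistatic(g: RelationshipMatrix) -> RelationshipMatrix:
    """Additive-by-additive matrix: the Hadamard square of additive G."""
    if g.kind != "additive":
        raise ParameterError("epistatic matrix must be built from an additive G")
    return RelationshipMatrix(
        animal_ids=g.animal_ids, values=g.values * g.values, kind="additive_by_additive"
    )


# ---------------------------------------------------------------------------
# variance components (Gibbs)
# ---------------------------------------------------------------------------

def _psd_eigh(values: np.ndarray, jitter: float = 1e-8):
    """Eigendecomposition with a PSD check; eigenvalues floored at jitter."""
    d, u = np.linalg.eigh(values)
    if d.min() < -1e-6 * max(1.0, abs(d.max())):
        raise NumericalError(
            f"relationship matrix is not PSD (min eigenvalue {d.min():.3e})"
        )
    return np.maximum(d, jitter), u


def _sample_scaled_inv_chi2(rng, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def _gibbs_mixed_model(y, eig_list, settings: GibbsSettings, seed: int):
    """Gibbs sampler for ``y = 1mu + sum_c u_c + e``, ``u_c ~ N(0, K_c s2_c)``.

    ``eig_list`` holds ``(d, U)`` eigenpairs for each K_c. Returns a dict
    with posterior-mean variances, their SDs, posterior-mean ``u_c`` and
    ``mu``, and the kept variance samples.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = y.size
    n_comp = len(eig_list)
    vary = y.var()
    if vary <= 0:
        raise ParameterError("response is constant; variance components undefined")

    df_u, df_e = settings.df, settings.residual_df
    mode_u = 0.5 * vary / n_comp
    s0_u = settings.scale_u if settings.scale_u is not None else mode_u * (df_u + 2.0) / df_u
    s0_e = settings.scale_e if settings.scale_e is not None else 0.5 * vary * (df_e + 2.0) / df_e

    mu = y.mean()
    s2 = np.full(n_comp, mode_u)
    s2e = 0.5 * vary
    u = [np.zeros(n) for _ in range(n_comp)]
    alpha = [np.zeros(n) for _ in range(n_comp)]

    kept_s2 = []
    kept_s2e = []
    u_sum = [np.zeros(n) for _ in range(n_comp)]
    mu_sum = 0.0
    n_kept = 0

    for it in range(settings.n_iter):
        for c, (d, umat) in enumerate(eig_list):
            r = y - mu
            for c2 in range(n_comp):
                if c2 != c:
                    r -= u[c2]
            w = umat.T @ r
            post_var = 1.0 / (1.0 / s2e + 1.0 / (d * s2[c]))
            post_mean = post_var * w / s2e
            alpha[c] = post_mean + np.sqrt(post_var) * rng.standard_normal(n)
            u[c] = umat @ alpha[c]
            quad = float(np.sum(alpha[c] ** 2 / d))
            s2[c] = (quad + df_u * s0_u) / rng.chisquare(df_u + n)

        resid = y - sum(u)
        mu = resid.mean() + np.sqrt(s2e / n) * rng.standard_normal()
        e = resid - mu
        s2e = (float(e @ e) + df_e * s0_e) / rng.chisquare(df_e + n)
        if not np.isfinite(s2e) or s2e <= 0:
            from .exceptions import McmcError

            raise McmcError("residual variance became non-finite", iteration=it)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            kept_s2.append(s2.copy())
            kept_s2e.append(s2e)
            for c in range(n_comp):
                u_sum[c] += u[c]
            mu_sum += mu
            n_kept += 1

    kept_s2 = np.asarray(kept_s2)
    kept_s2e = np.asarray(kept_s2e)
    return {
        "s2_mean": kept_s2.mean(axis=0),
        "s2_sd": kept_s2.std(axis=0),
        "s2e_mean": float(kept_s2e.mean()),
        "s2e_sd": float(kept_s2e.std()),
        "u_mean": [us / n_kept for us in u_sum],
        "mu_mean": mu_sum / n_kept,
        "s2_samples": kept_s2,
        "s2e_samples": kept_s2e,
        "n_kept": n_kept,
    }


def estimate_variance_components(
    ystar,
    matrices,
    settings: GibbsSettings | None = None,
    seed: int = 0,
) -> VarianceComponents:
    """Estimate variance components for one or two relationship matrices.

    ``matrices`` is a single :class:`RelationshipMatrix` or a list of them
    (typically additive, or additive + additive-by-additive). Heritability
    is ``s2_additive / (sum of genetic variances + s2_e)``: the denominator
    includes the additive-by-additive variance whenever it is fitted.
    """
    if settings is None:
        settings = GibbsSettings()
    if isinstance(matrices, RelationshipMatrix):
        matrices = [matrices]
    if not matrices:
        raise ParameterError("at least one relationship matrix required")
    y = np.asarray(ystar, dtype=float)
    if np.isnan(y).any():
        raise ParameterError("ystar contains missing values")
    for m in matrices:
        if m.values.shape[0] != y.size:
            raise ParameterError("relationship matrix does not conform to ystar")

    eig_list = [_psd_eigh(m.values) for m in matrices]
    out = _gibbs_mixed_model(y, eig_list, settings, seed)

    kinds = [m.kind for m in matrices]
    if len(set(kinds)) != len(kinds):
        raise ParameterError("duplicate relationship-matrix kinds")
    comp = dict(zip(kinds, map(float, out["s2_mean"])))
    comp_sd = dict(zip(kinds, map(float, out["s2_sd"])))

    s2_samples, s2e_samples = out["s2_samples"], out["s2e_samples"]
    denom = s2_samples.sum(axis=1) + s2e_samples
    a_idx = kinds.index("additive") if "additive" in kinds else 0
    h2_samples = s2_samples[:, a_idx] / denom
    return VarianceComponents(
        components=comp,
        components_sd=comp_sd,
        sigma2_e=out["s2e_mean"],
        sigma2_e_sd=out["s2e_sd"],
        h2=float(h2_samples.mean()),
        h2_sd=float(h2_samples.std()),
        n_samples=out["n_kept"],
    )
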