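"""Bayesian multivariate animal model fitted by Gibbs sampling.

The model for the t = 4 color traits of individual ``i`` is

    y_i = X_i beta + a_i + c_nest(i) + m_mother(i) + e_i,

with breeding values ``a`` ~ MVN(0, G (x) A) for the pedigree-derived
additive relationship matrix A, nest effects ``c`` ~ MVN(0, C), maternal
effects ``m`` ~ MVN(0, M), residuals ``e`` ~ MVN(0, R), and
inverse-Wishart priors on each t x t covariance matrix. Total phenotypic
variance per trait is V_P = V_A + V_CE (+ V_ME) + V_R, giving the
variance ratios h2 = V_A/V_P, ce2 = V_CE/V_P, me2 = V_ME/V_P, computed
per posterior sample so that the uncertainty in each component carries
over into the ratio estimates.

Sampling strategy
-----------------
Location effects are updated in blocks from their exact Gaussian full
conditionals. The additive block is reparametrized through the Cholesky
factor L of A (``a = L u`` with u ~ MVN(0, I (x) G)): writing W for the
record rows of L, the conditional precision of u is
``(W'W) (x) R^-1 + I (x) G^-1``. W'W is constant across iterations, so
one upfront eigendecomposition W'W = Q Lam Q' turns every update into
independent t x t problems — the whole additive block is drawn jointly
at O(n q) cost per iteration. Nest and maternal blocks have diagonal
incidence crossproducts and factor the same way. Covariance matrices are
drawn from their inverse-Wishart full conditionals (the whitened
crossproduct u'u equals a' A^-1 a, the usual quadratic form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .pedigree import additive_relationship

__all__ = [
    "MCMCSettings",
    "PriorSpec",
    "PosteriorChain",
    "AnimalModel",
    "standardize",
    "posterior_mode",
    "hpd_interval",
    "effective_sample_size",
    "variance_ratios",
    "genetic_correlations",
    "fixed_effect_report",
    "summarize",
    "dic",
]

DEFAULT_TRAITS = ("theta", "phi", "r_A", "brightness")
COMPONENT_LABEL = {"additive": "V_A", "nest": "V_CE", "maternal": "V_ME", "residual": "V_R"}
RATIO_LABEL = {"additive": "h2", "nest": "ce2", "maternal": "me2"}


@dataclass
class MCMCSettings:
    """Chain settings. The full-run defaults are the documented reference
    settings (1,002,000 iterations, burn-in 2000, thin 500 -> 2000 stored
    samples); desk-scale fits use far fewer iterations."""

    n_iter: int = 1_002_000
    burn_in: int = 2_000
    thin: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must lie in [0, n_iter)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PriorSpec:
    """Inverse-Wishart prior (scale matrix V, degrees of freedom nu) per
    random term and for the residual. ``scale = V * nu`` enters the full
    conditional, so V is the prior's location on the covariance scale."""

    V: dict[str, np.ndarray]
    nu: dict[str, float]

    @classmethod
    def default(cls, terms: tuple[str, ...], t: int, total_variance: float = 1.0) -> "PriorSpec":
        """Weakly informative default: V = I * (V_P / #components),
        nu = t + 0.002 for every component."""
        k = len(terms)
        V = {term: np.eye(t) * (total_variance / k) for term in terms}
        nu = {term: t + 0.002 for term in terms}
        return cls(V=V, nu=nu)

    def validate(self, t: int) -> None:
        for term, V in self.V.items():
            V = np.asarray(V, dtype=float)
            if V.shape != (t, t) or not np.allclose(V, V.T, atol=1e-12):
                raise ValueError(f"prior V for {term} must be symmetric {t}x{t}")
            if np.linalg.eigvalsh(V).min() <= 0:
                raise ValueError(f"prior V for {term} must be positive definite")
            if self.nu[term] <= t - 1:
                raise ValueError(f"prior nu for {term} must exceed t - 1")


@dataclass
class PosteriorChain:
    """Stored posterior samples and the bookkeeping needed downstream."""

    traits: tuple[str, ...]
    random_terms: tuple[str, ...]
    fixed_names: tuple[str, ...]
    covariance: dict[str, np.ndarray]   # term -> (S, t, t); includes "residual"
    fixed: np.ndarray                   # (S, p, t)
    deviance: np.ndarray                # (S,)
    deviance_at_mean: float
    n_records: int
    settings: MCMCSettings

    @property
    def n_stored(self) -> int:
        return self.deviance.shape[0]


def standardize(data: pd.DataFrame, traits: tuple[str, ...]) -> pd.DataFrame:
    """Z-score each trait column (idempotent up to numerical noise)."""
    out = data.copy()
    for tr in traits:
        v = out[tr].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"trait {tr} has zero variance; cannot standardize")
        out[tr] = (v - v.mean()) / sd
    return out


def build_design(
    data: pd.DataFrame,
    fixed_terms: tuple[str, ...],
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Fixed-effect design matrix: intercept, year factor, date nested
    within year (year-specific centered slopes), mass, sex (+-1/2)."""
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    if "year" in fixed_terms:
        years = sorted(data["year"].unique())
        for y in years[1:]:
            cols.append((data["year"] == y).to_numpy(dtype=float))
            names.append(f"year_{y}")
    if "date" in fixed_terms:
        d = data["date"].to_numpy(dtype=float)
        dz = (d - d.mean()) / (d.std(ddof=1) if d.std(ddof=1) > 0 else 1.0)
        for y in sorted(data["year"].unique()):
            mask = (data["year"] == y).to_numpy(dtype=float)
            cols.append(dz * mask)
            names.append(f"date_{y}")
    if "mass" in fixed_terms:
        m = data["mass"].to_numpy(dtype=float)
        sd = m.std(ddof=1)
        cols.append((m - m.mean()) / (sd if sd > 0 else 1.0))
        names.append("mass")
    if "sex" in fixed_terms:
        cols.append(np.where(data["sex"].to_numpy() == "M", 0.5, -0.5))
        names.append("sex")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    return X, tuple(names)


def _sample_blocks(
    lam: np.ndarray,
    b: np.ndarray,
    Rinv: np.ndarray,
    Tinv: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw x_j ~ N(P_j^-1 b_j, P_j^-1) with P_j = lam_j R^-1 + T^-1,
    batched over blocks j. ``b`` is (q, t)."""
    t = b.shape[1]
    z = rng.standard_normal(b.shape)
    if t == 1:
        prec = lam * Rinv[0, 0] + Tinv[0, 0]
        var = 1.0 / prec
        return (b[:, 0] * var + np.sqrt(var) * z[:, 0])[:, None]
    P = lam[:, None, None] * Rinv[None] + Tinv[None]
    mean = np.linalg.solve(P, b[:, :, None])[:, :, 0]
    L = np.linalg.cholesky(P)
    noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
    return mean + noise


def _draw_invwishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    t = scale.shape[0]
    if t == 1:
        return np.array([[scale[0, 0] / rng.chisquare(df)]])
    draw = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.asarray(draw, dtype=float).reshape(t, t)


class AnimalModel(BaseEstimator):
    """Gibbs-sampled multivariate animal model (scikit-learn estimator).

    Parameters
    ----------
    traits : tuple of str
        Trait columns of the phenotype table (1 to 4 metrics).
    fixed_terms : tuple of str
        Subset of {"year", "date", "mass", "sex"}; intercept always fitted.
    random_terms : tuple of str
        Ordered subset of {"additive", "nest", "maternal"}; "additive"
        requires a pedigree.
    prior : PriorSpec or None
        None -> weakly informative default (V = I * V_P/#components,
        nu = t + 0.002).
    n_iter, burn_in, thin, seed :
        Desk-scale chain defaults; see MCMCSettings for the reference
        full-run settings.
    scale_traits : bool
        Z-score traits before fitting (default True), putting V_P near 1.

    Fitted attributes (trailing underscore): ``chain_``, ``summary_``,
    ``ratio_means_``, ``dic_``, ``fixed_report_``, ``correlations_``.
    """

    def __init__(
        self,
        traits: tuple[str, ...] = DEFAULT_TRAITS,
        fixed_terms: tuple[str, ...] = ("year",),
        random_terms: tuple[str, ...] = ("additive", "nest"),
        prior: PriorSpec | None = None,
        n_iter: int = 20_000,
        burn_in: int = 1_000,
        thin: int = 10,
        seed: int = 0,
        scale_traits: bool = True,
    ):
        self.traits = traits
        self.fixed_terms = fixed_terms
        self.random_terms = random_terms
        self.prior = prior
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.scale_traits = scale_traits

    # ------------------------------------------------------------------
    def fit(self, data: pd.DataFrame, pedigree: pd.DataFrame | None = None):
        """Fit to a phenotype table.

        ``data`` needs one row per phenotyped individual with columns
        ``individual``, the trait columns, plus ``nest`` /
        ``social_mother`` / fixed-term covariates as required by the model
        terms. ``pedigree`` is the (id, dam, sire) table and is required
        when the additive term is present.
        """
        traits = tuple(self.traits)
        t = len(traits)
        for term in self.random_terms:
            if term not in ("additive", "nest", "maternal"):
                raise ValueError(f"unknown random term {term!r}")
        data = data.reset_index(drop=True)
        work = standardize(data, traits) if self.scale_traits else data.copy()
        Y = work[list(traits)].to_numpy(dtype=float)
        n = Y.shape[0]
        X, fixed_names = build_design(work, tuple(self.fixed_terms))
        p = X.shape[1]

        rng = np.random.default_rng(self.seed)
        settings = MCMCSettings(self.n_iter, self.burn_in, self.thin, self.seed)
        S = settings.n_stored
        if S < 1:
            raise ValueError("settings store no samples")

        # ---- random-term structures -----------------------------------
        terms: dict[str, dict] = {}
        if "additive" in self.random_terms:
            if pedigree is None:
                raise ValueError("additive term requires a pedigree")
            A, index = additive_relationship(pedigree)
            missing = [i for i in work["individual"].astype(str) if i not in index]
            if missing:
                raise ValueError(f"individuals missing from pedigree: {missing[:5]}")
            rows = np.array([index[str(i)] for i in work["individual"]])
            L = np.linalg.cholesky(A + 1e-10 * np.eye(A.shape[0]))
            W = L[rows, :]
            lam, Q = np.linalg.eigh(W.T @ W)
            lam = np.clip(lam, 0.0, None)
            terms["additive"] = {"kind": "pedigree", "W": W, "Q": Q, "lam": lam,
                                 "q": A.shape[0]}
        if "nest" in self.random_terms:
            codes, levels = pd.factorize(work["nest"], sort=True)
            terms["nest"] = {"kind": "factor", "codes": codes,
                             "q": len(levels),
                             "counts": np.bincount(codes, minlength=len(levels)).astype(float)}
        if "maternal" in self.random_terms:
            codes, levels = pd.factorize(work["social_mother"], sort=True)
            terms["maternal"] = {"kind": "factor", "codes": codes,
                                 "q": len(levels),
                                 "counts": np.bincount(codes, minlength=len(levels)).astype(float)}
            if "nest" in terms:
                nn = work.groupby("social_mother")["nest"].nunique()
                if (nn < 2).all():
                    warnings.warn(
                        "every mother has a single nest: maternal and nest "
                        "variance components are confounded and cannot be "
                        "separated", UserWarning, stacklevel=2,
                    )

        comp_names = tuple(self.random_terms) + ("residual",)
        total_var = float(np.mean(Y.var(axis=0, ddof=1)))
        prior = self.prior or PriorSpec.default(comp_names, t, total_var)
        prior.validate(t)

        # ---- state -----------------------------------------------------
        cov = {term: np.asarray(prior.V[term], dtype=float).copy() for term in comp_names}
        effects = {}
        contrib = {}
        for term, info in terms.items():
            effects[term] = np.zeros((info["q"], t))
            contrib[term] = np.zeros((n, t))
        B = np.zeros((p, t))
        XtX = X.T @ X
        Lx = np.linalg.cholesky(XtX)

        stored_cov = {term: np.empty((S, t, t)) for term in comp_names}
        stored_B = np.empty((S, p, t))
        stored_dev = np.empty(S)
        fitted_sum = np.zeros((n, t))
        R_sum = np.zeros((t, t))

        log2pi = np.log(2.0 * np.pi)
        s_idx = 0
        for it in range(settings.n_iter):
            Rmat = cov["residual"]
            Rinv = np.linalg.inv(Rmat)
            # fixed effects (flat prior): matrix-normal draw
            resid = Y - sum(contrib.values()) if terms else Y.copy()
            Bhat = np.linalg.solve(XtX, X.T @ resid)
            Zb = rng.standard_normal((p, t))
            LR = np.linalg.cholesky(Rmat)
            B = Bhat + np.linalg.solve(Lx.T, Zb) @ LR.T
            XB = X @ B

            for term, info in terms.items():
                partial = Y - XB
                for other in terms:
                    if other != term:
                        partial -= contrib[other]
                Tinv = np.linalg.inv(cov[term])
                if info["kind"] == "pedigree":
                    b = info["Q"].T @ (info["W"].T @ partial) @ Rinv
                    Ut = _sample_blocks(info["lam"], b, Rinv, Tinv, rng)
                    U = info["Q"] @ Ut
                    effects[term] = U
                    contrib[term] = info["W"] @ U
                else:
                    Ssum = np.zeros((info["q"], t))
                    np.add.at(Ssum, info["codes"], partial)
                    b = Ssum @ Rinv
                    E = _sample_blocks(info["counts"], b, Rinv, Tinv, rng)
                    effects[term] = E
                    contrib[term] = E[info["codes"]]

            # covariance draws
            for term, info in terms.items():
                eff = effects[term]
                scale = np.asarray(prior.V[term]) * prior.nu[term] + eff.T @ eff
                cov[term] = _draw_invwishart(prior.nu[term] + info["q"], scale, rng)
            Efull = Y - XB - (sum(contrib.values()) if terms else 0.0)
            scale = np.asarray(prior.V["residual"]) * prior.nu["residual"] + Efull.T @ Efull
            cov["residual"] = _draw_invwishart(prior.nu["residual"] + n, scale, rng)

            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0 and s_idx < S:
                Rs = cov["residual"]
                sign, logdet = np.linalg.slogdet(Rs)
                dev = n * t * log2pi + n * logdet + float(
                    np.trace(np.linalg.solve(Rs, Efull.T @ Efull))
                )
                stored_dev[s_idx] = dev
                for term in comp_names:
                    stored_cov[term][s_idx] = cov[term]
                stored_B[s_idx] = B
                fitted_sum += XB + (sum(contrib.values()) if terms else 0.0)
                R_sum += Rs
                s_idx += 1

        # deviance at posterior-mean location effects and residual covariance
        fitted_mean = fitted_sum / S
        R_mean = R_sum / S
        Em = Y - fitted_mean
        sign, logdet = np.linalg.slogdet(R_mean)
        dev_at_mean = n * t * log2pi + n * logdet + float(
            np.trace(np.linalg.solve(R_mean, Em.T @ Em))
        )

        self.chain_ = PosteriorChain(
            traits=traits,
            random_terms=tuple(self.random_terms),
            fixed_names=fixed_names,
            covariance=stored_cov,
            fixed=stored_B,
            deviance=stored_dev,
            deviance_at_mean=dev_at_mean,
            n_records=n,
            settings=settings,
        )
        self.summary_ = summarize(self.chain_)
        self.ratio_means_ = ratio_mode_means(self.summary_)
        self.dic_ = dic(self.chain_)
        self.fixed_report_ = fixed_effect_report(self.chain_)
        self.correlations_ = (
            genetic_correlations(self.chain_)
            if t > 1 and "additive" in self.random_terms
            else None
        )
        return self


# ---------------------------------------------------------------------------
# chain summaries


def posterior_mode(samples: np.ndarray, n_grid: int = 512) -> float:
    """Mode of a Gaussian KDE (Silverman bandwidth) on an n_grid-point grid."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(samples: np.ndarray, prob: float = 0.95, equal_tailed: bool = False) -> tuple[float, float]:
    """95% credible interval: shortest (HPD) by default, equal-tailed on flag."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if equal_tailed:
        lo, hi = np.quantile(x, [(1 - prob) / 2, 1 - (1 - prob) / 2])
        return float(lo), float(hi)
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def effective_sample_size(samples: np.ndarray) -> float:
    """ESS by Geyer's initial-positive-sequence truncation of the
    autocorrelation sum, capped at the number of stored samples."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(min(n, n / tau))


def variance_ratios(chain: PosteriorChain) -> dict[str, np.ndarray]:
    """Per-sample, per-trait variance ratios h2 / ce2 / me2 (+ resid2).

    V_P is formed per stored sample from the covariance diagonals so the
    posterior uncertainty of every component propagates into each ratio.
    """
    if chain.n_stored == 0:
        raise ValueError("empty chain")
    diags = {term: np.diagonal(arr, axis1=1, axis2=2)
             for term, arr in chain.covariance.items()}  # (S, t)
    VP = sum(diags.values())
    if np.any(VP <= 0):
        raise ValueError("nonpositive total variance in a stored sample")
    out = {"V_P": VP}
    for term in chain.random_terms:
        out[RATIO_LABEL[term]] = diags[term] / VP
    out["resid2"] = diags["residual"] / VP
    return out


def summarize(chain: PosteriorChain) -> pd.DataFrame:
    """Posterior mode (KDE), 95% HPD and ESS for every variance component,
    total variance, and variance ratio, per trait."""
    if chain.n_stored < 100:
        raise ValueError("need at least 100 stored samples to summarize")
    ratios = variance_ratios(chain)
    rows = []

    def add(component: str, trait: str, x: np.ndarray) -> None:
        lo, hi = hpd_interval(x)
        rows.append(
            {
                "component": component,
                "trait": trait,
                "mode": posterior_mode(x),
                "lower": lo,
                "upper": hi,
                "ess": effective_sample_size(x),
            }
        )

    for term, arr in chain.covariance.items():
        for j, trait in enumerate(chain.traits):
            add(COMPONENT_LABEL[term] if term in COMPONENT_LABEL else term, trait, arr[:, j, j])
    for name in list(ratios):
        for j, trait in enumerate(chain.traits):
            add(name, trait, ratios[name][:, j])
    return pd.DataFrame(rows)


def ratio_mode_means(summary: pd.DataFrame) -> dict[str, float]:
    """Cross-trait mean of each ratio's posterior modes (the headline
    percentages)."""
    out = {}
    for name in ("h2", "ce2", "me2"):
        sub = summary[summary["component"] == name]
        if len(sub):
            out[name] = float(sub["mode"].mean())
    return out


def genetic_correlations(chain: PosteriorChain, term: str = "additive") -> pd.DataFrame:
    """Pairwise genetic correlations r_g = G_ij / sqrt(G_ii G_jj), summarized
    as mode + 95% HPD, flagged significant when the interval excludes 0."""
    if term not in chain.covariance:
        raise ValueError(f"term {term!r} not in chain")
    G = chain.covariance[term]
    t = G.shape[1]
    rows = []
    for i in range(t):
        for j in range(i + 1, t):
            d = G[:, i, i] * G[:, j, j]
            if np.any(d <= 0):
                raise ValueError("zero diagonal in a stored sample")
            r = G[:, i, j] / np.sqrt(d)
            lo, hi = hpd_interval(r)
            rows.append(
                {
                    "trait_1": chain.traits[i],
                    "trait_2": chain.traits[j],
                    "mode": posterior_mode(r),
                    "lower": lo,
                    "upper": hi,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)


def fixed_effect_report(chain: PosteriorChain) -> pd.DataFrame:
    """Posterior mode + 95% HPD per fixed term and trait; significant when
    the interval excludes zero."""
    rows = []
    for k, name in enumerate(chain.fixed_names):
        for j, trait in enumerate(chain.traits):
            x = chain.fixed[:, k, j]
            lo, hi = hpd_interval(x)
            rows.append(
                {
                    "term": name,
                    "trait": trait,
                    "mode": posterior_mode(x),
                    "lower": lo,
                    "upper": hi,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)


def interval_excludes_zero(lower: float, upper: float) -> bool:
    """Significance rule for a 95% credible interval."""
    return lower > 0 or upper < 0


def dic(chain: PosteriorChain) -> float:
    """Deviance information criterion: 2 * mean(deviance) - deviance at the
    posterior mean of the location effects and residual covariance."""
    if chain.deviance.size == 0:
        raise ValueError("chain stores no deviances")
    return float(2.0 * chain.deviance.mean() - chain.deviance_at_mean)
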