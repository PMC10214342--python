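"""Bayesian Gaussian hierarchical models for circadian cortisol reaction norms.

Model family
------------
log SG-corrected cortisol is modelled as

    y = X beta + sum_k Z_k u_k + eps,     eps ~ N(0, sigma2 I)

where each random term k groups reaction-norm deviations (intercept and
optionally linear/quadratic time-of-day slopes) by a factor: community
("group"), community-year, research project, individual, individual-year,
mother, and — for the animal models — an additive-genetic term whose
individual-level effects have covariance A (x) Sigma_genetic, with A the
pedigree-derived additive relationship matrix.  The genetic term is
non-centered: independent per-individual deviates are premultiplied by a
Cholesky factor of A, which turns it into an ordinary iid term with a
transformed design matrix.

Inference
---------
Everything is Gaussian, so the posterior is explored with a conjugate
block Gibbs sampler (the same strategy as pedigree mixed-model samplers
in quantitative genetics):

1. the full coefficient vector (beta and every u_k) is drawn jointly
   from its Gaussian full conditional — one sparse-structured normal
   equation solve per sweep, which is what gives the sampler its good
   mixing across heavily confounded terms (individual vs genetic vs
   maternal);
2. each covariance matrix Sigma_k is drawn from an inverse-Wishart full
   conditional under a Huang-Wand hierarchical prior whose marginals
   are half-t(nu, 0, 10) standard deviations and, for 3x3 terms
   (nu = 2), exactly uniform correlations;
3. the residual variance uses the same construction with nu = 3, i.e. a
   half-t(3, 0, 10) marginal on the residual SD.

Fixed effects get independent N(0, 1) priors (covariates are z-scored
upstream).  Pointwise log-likelihoods are stored for PSIS-LOO model
comparison (via arviz).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .pedigree import RelatednessMatrix
from .preprocess import DEMOGRAPHIC_LEVELS, PreparedDataset

#: reaction-norm dimensions a random term may carry
RN_DIMS = ("intercept", "t", "t2")

#: treatment-coded categorical covariates and their level order
#: (first level = reference)
CATEGORICAL_LEVELS = {
    "demographic": DEMOGRAPHIC_LEVELS,          # reference: adult male
    "lcms_method": ["new", "old"],
    "sex": ["male", "female"],
    "reproductive_state": ["cycling", "lactating"],
}

_FULL_COVARIATES = ["demographic", "age_z", "season_sin", "season_cos",
                    "sexratio_z", "groupsize_z", "lcms_method"]

_BASE_FACTORS = ["group", "group_year", "project"]
_INDIV_FACTORS = ["individual", "id_year"]
_ANIMAL_FACTORS = _BASE_FACTORS + _INDIV_FACTORS + ["mother", "genetic"]


class ModelConfigError(ValueError):
    """Model structure inconsistent with the dataset."""


@dataclass
class RandomEffectTerm:
    factor: str
    slope_dims: tuple[str, ...] = ("intercept",)
    genetic: bool = False

    def __post_init__(self) -> None:
        bad = set(self.slope_dims) - set(RN_DIMS)
        if bad:
            raise ModelConfigError(f"unknown slope dimension(s) {bad}")

    @property
    def d(self) -> int:
        return len(self.slope_dims)


@dataclass
class ModelSpec:
    variant: str
    covariates: list[str]
    random_terms: list[RandomEffectTerm]
    response: str = "y"
    subset: tuple[str, tuple] | None = None      # (column, allowed values)
    genetic_A: RelatednessMatrix | None = None
    priors: dict = field(default_factory=lambda: {
        "fixed_sd": 1.0, "re_scale": 10.0, "nu_multivariate": 2,
        "nu_univariate": 3, "nu_residual": 3, "residual_scale": 10.0})

    def describe(self) -> dict:
        return {
            "variant": self.variant,
            "covariates": list(self.covariates),
            "random_terms": [
                {"factor": t.factor, "slope_dims": list(t.slope_dims),
                 "genetic": t.genetic} for t in self.random_terms],
            "response": self.response,
            "subset": list(self.subset) if self.subset else None,
        }


@dataclass
class SamplerSettings:
    """MCMC settings; 4 chains of 4000 iterations with half warmup by
    default, reducible for small-scale runs."""

    chains: int = 4
    iterations: int = 4000
    warmup: int | None = None
    seed: int = 0
    rhat_threshold: float = 1.1
    sandwich: bool = True          # scale-group moves (see _sandwich_moves)

    @property
    def n_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup


def build_model(dataset, variant: str,
                A: RelatednessMatrix | None = None,
                site_groups: list[str] | None = None) -> ModelSpec:
    """Declare one of the named model structures.

    Variants: ``null``, ``intercepts``, ``reaction_norms``,
    ``full_heritability``, ``tai_heritability`` (animal model restricted
    to ``site_groups``), ``dominance_heritability`` (adds the dominance
    covariate), ``trait_heritability`` (animal model without random
    slopes), and per-demographic reaction-norm models
    ``demographic:adult_male`` / ``demographic:adult_female`` /
    ``demographic:immature``.
    """
    df = dataset.data if isinstance(dataset, PreparedDataset) else dataset
    rn = tuple(RN_DIMS)
    icpt = ("intercept",)
    covs = list(_FULL_COVARIATES)
    subset = None

    if variant == "null":
        terms = [RandomEffectTerm(f, icpt) for f in _BASE_FACTORS]
    elif variant == "intercepts":
        terms = [RandomEffectTerm(f, icpt)
                 for f in _BASE_FACTORS + _INDIV_FACTORS]
    elif variant == "reaction_norms":
        terms = ([RandomEffectTerm(f, icpt) for f in _BASE_FACTORS]
                 + [RandomEffectTerm(f, rn) for f in _INDIV_FACTORS])
    elif variant in ("full_heritability", "tai_heritability",
                     "dominance_heritability"):
        terms = [RandomEffectTerm(f, rn, genetic=(f == "genetic"))
                 for f in _ANIMAL_FACTORS]
        if variant == "tai_heritability":
            if not site_groups:
                raise ModelConfigError(
                    "tai_heritability needs site_groups (the communities "
                    "of the single site to retain)")
            subset = ("group", tuple(site_groups))
        if variant == "dominance_heritability":
            covs.append("dominance")
    elif variant == "trait_heritability":
        terms = [RandomEffectTerm(f, icpt, genetic=(f == "genetic"))
                 for f in _ANIMAL_FACTORS]
    elif variant.startswith("demographic:"):
        demo = variant.split(":", 1)[1]
        covs = [c for c in covs if c != "demographic"]
        if demo == "adult_male":
            subset = ("demographic", ("adult male",))
            if "dominance" in df.columns:
                covs.append("dominance")
        elif demo == "adult_female":
            subset = ("demographic", ("cycling female", "lactating female"))
            covs.append("reproductive_state")
        elif demo == "immature":
            subset = ("demographic", ("immature male", "immature female"))
            covs.append("sex")
        else:
            raise ModelConfigError(f"unknown demographic sub-model {demo!r}")
        terms = ([RandomEffectTerm(f, icpt) for f in _BASE_FACTORS]
                 + [RandomEffectTerm(f, rn) for f in _INDIV_FACTORS])
    else:
        raise ModelConfigError(f"unknown model variant {variant!r}")

    needs_A = any(t.genetic for t in terms)
    if needs_A and A is None:
        raise ModelConfigError(
            f"variant {variant!r} is an animal model and requires the "
            "additive relatedness matrix A")
    for c in covs:
        if c not in df.columns:
            raise ModelConfigError(f"dataset lacks covariate column {c!r}")
    return ModelSpec(variant=variant, covariates=covs, random_terms=terms,
                     subset=subset, genetic_A=A if needs_A else None)


# ---------------------------------------------------------------------------
# design matrices

def fixed_design(df: pd.DataFrame, covariates: list[str]
                 ) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept, t, t2, and every covariate
    interacted with each of {1, t, t2} (treatment coding for
    categoricals, reference = first canonical level)."""
    n = len(df)
    t = df["t"].to_numpy(float)
    t2 = df["t2"].to_numpy(float)
    base = [("", np.ones(n))]
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS and not pd.api.types.is_numeric_dtype(
                df[cov]):
            levels = [lv for lv in CATEGORICAL_LEVELS[cov]
                      if lv in set(df[cov])]
            extra = sorted(set(df[cov].astype(str)) - set(levels))
            levels += extra
            for lv in levels[1:]:
                base.append((f"{cov}[{lv}]",
                             (df[cov].astype(str) == lv).to_numpy(float)))
        else:
            base.append((cov, df[cov].to_numpy(float)))
    cols, names = [], []
    for name, x in base:
        for suffix, mult in (("", 1.0), (":t", t), (":t2", t2)):
            label = (name + suffix).lstrip(":") or "intercept"
            if name == "" and suffix:
                label = suffix[1:]
            cols.append(x * mult)
            names.append(label)
    return np.column_stack(cols), names


def _term_design(df: pd.DataFrame, term: RandomEffectTerm,
                 A: RelatednessMatrix | None):
    """Random-term design block (level-major: all dims of level 0, then
    level 1, ...) and its level labels."""
    n = len(df)
    dims = {"intercept": np.ones(n), "t": df["t"].to_numpy(float),
            "t2": df["t2"].to_numpy(float)}
    D = np.column_stack([dims[d] for d in term.slope_dims])
    factor_col = "individual" if term.genetic else term.factor
    if factor_col not in df.columns:
        raise ModelConfigError(f"dataset lacks grouping column {factor_col!r}")
    codes, levels = pd.factorize(df[factor_col].astype(str), sort=True)
    if len(levels) < 2:
        raise ModelConfigError(
            f"grouping factor {term.factor!r} has a single level")
    if term.genetic:
        if A is None:
            raise ModelConfigError("genetic term requires A")
        missing = [i for i in levels if i not in A.index]
        if missing:
            raise ModelConfigError(
                f"individual(s) missing from the relatedness matrix: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
        sub = A.submatrix(list(levels))
        L_A = _safe_cholesky(sub.A)
        M = L_A[codes, :]                      # n x m, mixes individuals
    else:
        M = np.zeros((n, len(levels)))
        M[np.arange(n), codes] = 1.0
    Z = (M[:, :, None] * D[:, None, :]).reshape(n, len(levels) * term.d)
    return Z, list(map(str, levels))


def _safe_cholesky(A: np.ndarray) -> np.ndarray:
    """Lower Cholesky of A, jittering the diagonal when A is numerically
    singular (duplicate founders / clones make A PSD but not PD)."""
    jitter = 0.0
    for _ in range(6):
        try:
            return cholesky(A + jitter * np.eye(len(A)), lower=True)
        except np.linalg.LinAlgError:
            pass
        except Exception:
            pass
        jitter = 1e-8 if jitter == 0.0 else jitter * 100
    raise np.linalg.LinAlgError(
        "could not factorize the relatedness matrix even with diagonal "
        "jitter; check the pedigree for inconsistencies")


# ---------------------------------------------------------------------------
# results container

@dataclass
class FitResult:
    spec: ModelSpec
    settings: SamplerSettings
    fixed_names: list[str]
    beta: np.ndarray                    # (chains, draws, p_fixed)
    Sigma: dict[str, np.ndarray]        # factor -> (chains, draws, d, d)
    sigma2: np.ndarray                  # (chains, draws)
    log_lik: np.ndarray                 # (chains, draws, n)
    term_dims: dict[str, tuple[str, ...]]
    levels: dict[str, list[str]]
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.log_lik.shape[2]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def component_draws(self, factor: str, dim: str) -> np.ndarray:
        """Flattened posterior draws of the variance of ``factor`` in
        reaction-norm dimension ``dim`` ('intercept'/'t'/'t2')."""
        dims = self.term_dims[factor]
        if dim not in dims:
            raise KeyError(
                f"term {factor!r} carries no {dim!r} component "
                f"(has {dims})")
        k = dims.index(dim)
        return self.Sigma[factor][:, :, k, k].reshape(-1)

    def residual_draws(self) -> np.ndarray:
        return self.sigma2.reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        post = {"beta": self.beta, "sigma2": self.sigma2}
        for f, s in self.Sigma.items():
            d = s.shape[-1]
            sds = np.sqrt(s[:, :, np.arange(d), np.arange(d)])
            post[f"sd_{f}"] = sds
        return az.from_dict(posterior=post,
                            log_likelihood={"y": self.log_lik})

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = {"chain": np.repeat(np.arange(self.beta.shape[0]),
                                   self.beta.shape[1]),
                "draw": np.tile(np.arange(self.beta.shape[1]),
                                self.beta.shape[0]),
                "sigma2": self.sigma2.reshape(-1)}
        for j, name in enumerate(self.fixed_names):
            rows[f"beta[{name}]"] = self.beta[:, :, j].reshape(-1)
        for f, s in self.Sigma.items():
            d = s.shape[-1]
            for i in range(d):
                for j in range(i + 1):
                    rows[f"Sigma[{f}][{i},{j}]"] = s[:, :, i, j].reshape(-1)
        pd.DataFrame(rows).to_csv(directory / "draws.csv", index=False)
        meta = {"spec": self.spec.describe(),
                "settings": {"chains": self.settings.chains,
                             "iterations": self.settings.iterations,
                             "warmup": self.settings.n_warmup,
                             "seed": self.settings.seed},
                "term_dims": {k: list(v) for k, v in self.term_dims.items()},
                "diagnostics": self.diagnostics}
        (directory / "diagnostics.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# the Gibbs sampler

def fit_model(spec: ModelSpec, dataset, settings: SamplerSettings
              ) -> FitResult:
    """Draw from the posterior of ``spec`` given the prepared dataset."""
    df = dataset.data if isinstance(dataset, PreparedDataset) else dataset
    if spec.subset is not None:
        col, values = spec.subset
        df = df[df[col].isin(values)]
    df = df.reset_index(drop=True)
    y = df[spec.response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ModelConfigError("non-finite response values")
    n = len(y)

    X, fixed_names = fixed_design(df, spec.covariates)
    p_f = X.shape[1]
    blocks, spans, levels_by_factor = [X], {}, {}
    pos = p_f
    for term in spec.random_terms:
        Z, levels = _term_design(df, term, spec.genetic_A)
        blocks.append(Z)
        spans[term.factor] = (pos, pos + Z.shape[1], term)
        levels_by_factor[term.factor] = levels
        pos += Z.shape[1]
    W = np.concatenate(blocks, axis=1)
    p = W.shape[1]
    WtW = W.T @ W
    Wty = W.T @ y

    pri = spec.priors
    A_sc2 = pri["re_scale"] ** 2
    nu_r = pri["nu_residual"]
    A_r2 = pri["residual_scale"] ** 2
    # flat indices of each term's block-diagonal prior-precision slots
    flat_idx, tiles = {}, {}
    for f, (s, e, term) in spans.items():
        d, L = term.d, (e - s) // term.d
        base = s + np.arange(L)[:, None, None] * d
        r = base + np.arange(d)[None, :, None]
        c = base + np.arange(d)[None, None, :]
        flat_idx[f] = (r * p + c).reshape(-1)
        tiles[f] = L
    fixed_diag = (np.arange(p_f) * p + np.arange(p_f))

    n_keep = settings.iterations - settings.n_warmup
    if n_keep <= 0:
        raise ValueError("iterations must exceed warmup")
    C = settings.chains
    beta_out = np.empty((C, n_keep, p_f))
    sigma2_out = np.empty((C, n_keep))
    loglik_out = np.empty((C, n_keep, n))
    Sigma_out = {f: np.empty((C, n_keep, t.d, t.d))
                 for f, (_, _, t) in spans.items()}

    seeds = np.random.SeedSequence(settings.seed).spawn(C)
    for c_idx in range(C):
        rng = np.random.default_rng(seeds[c_idx])
        _run_chain(rng, y, W, WtW, Wty, p_f, spans, flat_idx, fixed_diag,
                   nu_r, A_r2, A_sc2, pri, settings, n_keep,
                   beta_out[c_idx], sigma2_out[c_idx], loglik_out[c_idx],
                   {f: Sigma_out[f][c_idx] for f in Sigma_out})

    fit = FitResult(
        spec=spec, settings=settings, fixed_names=fixed_names,
        beta=beta_out, Sigma=Sigma_out, sigma2=sigma2_out,
        log_lik=loglik_out,
        term_dims={f: spans[f][2].slope_dims for f in spans},
        levels=levels_by_factor)
    fit.diagnostics = _diagnose(fit, settings)
    return fit


def _run_chain(rng, y, W, WtW, Wty, p_f, spans, flat_idx, fixed_diag,
               nu_r, A_r2, A_sc2, pri, settings, n_keep,
               beta_st, sigma2_st, loglik_st, Sigma_st) -> None:
    n, p = W.shape
    sigma2 = float(np.var(y)) or 1.0
    a_r = 1.0
    state = {}
    for f, (s, e, term) in spans.items():
        d = term.d
        nu = pri["nu_multivariate"] if d > 1 else pri["nu_univariate"]
        state[f] = {"Sigma": 0.1 * np.eye(d), "a": np.ones(d), "nu": nu,
                    "d": d, "L": (e - s) // d, "span": (s, e)}
    theta = np.zeros(p)
    warmup = settings.iterations - n_keep
    for it in range(settings.iterations):
        # --- joint Gaussian draw of (beta, all u) ---
        Q = WtW / sigma2
        Q.flat[fixed_diag] += 1.0 / pri["fixed_sd"] ** 2
        for f, st in state.items():
            Lam = np.linalg.inv(st["Sigma"])
            Q.flat[flat_idx[f]] += np.tile(Lam.reshape(-1), st["L"])
        cfac = cho_factor(Q, lower=True, overwrite_a=True, check_finite=False)
        mu = cho_solve(cfac, Wty / sigma2, check_finite=False)
        z = rng.standard_normal(p)
        theta = mu + solve_triangular(cfac[0], z, lower=True, trans='T',
                                      check_finite=False)
        resid = y - W @ theta

        # --- residual variance (half-t(nu_r, 0, 10) on the SD) ---
        sse = float(resid @ resid)
        sigma2 = float(sps.invgamma.rvs((nu_r + n) / 2,
                                        scale=nu_r / a_r + sse / 2,
                                        random_state=rng))
        a_r = float(sps.invgamma.rvs((nu_r + 1) / 2,
                                     scale=nu_r / sigma2 + 1 / A_r2,
                                     random_state=rng))

        # --- per-term covariance matrices (Huang-Wand hierarchy) ---
        for f, st in state.items():
            s, e = st["span"]
            d, L, nu = st["d"], st["L"], st["nu"]
            U = theta[s:e].reshape(L, d)
            S = U.T @ U
            scale = 2 * nu * np.diag(1.0 / st["a"]) + S
            Sig = sps.invwishart.rvs(df=nu + d - 1 + L, scale=scale,
                                     random_state=rng)
            Sig = np.atleast_2d(Sig)
            Sinv = np.linalg.inv(Sig)
            st["a"] = sps.invgamma.rvs(
                (nu + d) / 2 * np.ones(d),
                scale=nu * np.diag(Sinv) + 1 / A_sc2, random_state=rng)
            st["a"] = np.atleast_1d(st["a"])
            st["Sigma"] = Sig
            # scale-group sandwich move per dimension: rescales the
            # whole term (u and Sigma together), which lets the chain
            # escape the near-zero-variance funnel the centered
            # parameterization suffers from
            if settings.sandwich:
                _sandwich_moves(rng, theta, resid, W, st, sigma2)

        if it >= warmup:
            k = it - warmup
            beta_st[k] = theta[:p_f]
            sigma2_st[k] = sigma2
            loglik_st[k] = (-0.5 * np.log(2 * np.pi * sigma2)
                            - resid ** 2 / (2 * sigma2))
            for f, st in state.items():
                Sigma_st[f][k] = st["Sigma"]


def _slice_sample(logf, x0: float, rng, width: float = 1.0,
                  max_steps: int = 30) -> float:
    """Univariate slice sampler with stepping-out (Neal 2003)."""
    y = logf(x0) - rng.exponential()
    left = x0 - width * rng.random()
    right = left + width
    k = max_steps
    while k and logf(left) > y:
        left -= width
        k -= 1
    k = max_steps
    while k and logf(right) > y:
        right += width
        k -= 1
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _sandwich_moves(rng, theta, resid, W, st, sigma2) -> None:
    """Generalized-Gibbs scale move (Liu & Sabatti 2000) for one term.

    For each reaction-norm dimension j the state is mapped by
    gamma > 0: u[:, j] -> gamma u[:, j], Sigma row/col j -> gamma *
    row/col (so Sigma_jj -> gamma^2 Sigma_jj), with gamma drawn from
    the group-invariant conditional; in x = log gamma coordinates

        log p(x) = -(A e^{2x} - 2 B e^x) / (2 sigma2)
                   - C e^{-2x} + (1 - nu - d) x

    with A = |g_j|^2, B = g_j . (resid + g_j), C = nu (Sigma^-1)_jj / a_j,
    where g_j is the current contribution of dimension j to the linear
    predictor.  The move leaves the posterior invariant and decorrelates
    u from Sigma near the zero-variance boundary.
    """
    s, e = st["span"]
    d, nu = st["d"], st["nu"]
    Sig = st["Sigma"]
    Sinv = np.linalg.inv(Sig)
    for j in range(d):
        idx = np.arange(s + j, e, d)
        gj = W[:, idx] @ theta[idx]
        Aq = float(gj @ gj)
        Bq = float(gj @ resid) + Aq
        Cq = nu * Sinv[j, j] / st["a"][j]
        c0 = 1.0 - nu - d

        def logf(x: float) -> float:
            if abs(x) > 12.0:
                return -np.inf
            ex = np.exp(x)
            return (-(Aq * ex * ex - 2.0 * Bq * ex) / (2.0 * sigma2)
                    - Cq * np.exp(-2.0 * x) + c0 * x)

        gamma = float(np.exp(_slice_sample(logf, 0.0, rng)))
        theta[idx] *= gamma
        resid += (1.0 - gamma) * gj
        Sig[j, :] *= gamma
        Sig[:, j] *= gamma
        Sinv[j, :] /= gamma
        Sinv[:, j] /= gamma


def _diagnose(fit: FitResult, settings: SamplerSettings) -> dict:
    post = {"sigma2": fit.sigma2}
    for f, s in fit.Sigma.items():
        d = s.shape[-1]
        post[f"sd_{f}"] = np.sqrt(s[:, :, np.arange(d), np.arange(d)])
    post["beta"] = fit.beta
    if fit.beta.shape[0] == 1:      # split-half pseudo-chains for Rhat
        half = fit.beta.shape[1] // 2
        post = {k: np.concatenate([v[:, :half], v[:, half:2 * half]])
                for k, v in post.items()}
    idata = az.from_dict(posterior=post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_max = float(max(np.nanmax(np.atleast_1d(v.values))
                         for v in rhat.data_vars.values()))
    ess_min = float(min(np.nanmin(np.atleast_1d(v.values))
                        for v in ess.data_vars.values()))
    converged = rhat_max < settings.rhat_threshold
    if not converged:
        warnings.warn(
            f"sampler convergence warning: max Rhat = {rhat_max:.3f} "
            f">= {settings.rhat_threshold}", stacklevel=3)
    return {"rhat_max": rhat_max, "ess_min": ess_min,
            "converged": bool(converged)}


# ---------------------------------------------------------------------------
# model comparison

def loo(fit: FitResult):
    """PSIS-LOO expected log predictive density of one fit."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return az.loo(fit.to_inference_data(), pointwise=True)


def loo_compare(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Rank fits by PSIS-LOO elpd; columns include ``elpd_diff`` (vs the
    best model) and its standard error ``dse``.

    All fits must share the same response rows.
    """
    sizes = {name: f.n_obs for name, f in fits.items()}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"fits are on different row counts: {sizes}")
    idata = {name: f.to_inference_data() for name, f in fits.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return az.compare(idata, ic="loo")


def reduced_settings(settings: SamplerSettings, factor: float = 0.5,
                     chains: int = 1) -> SamplerSettings:
    """Shorter-chain settings (used for permutation refits)."""
    its = max(100, int(settings.iterations * factor))
    return replace(settings, chains=chains, iterations=its, warmup=its // 2)
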