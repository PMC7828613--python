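"""Bayesian probit structured additive regression (STAR) via Gibbs sampling.

The model for a binary adverse birth outcome Y_i is

    Pr(Y_i = 1) = Phi(eta_i)
    eta_i = gamma' x_i + f(age_i) + b_{mother(i)} + u_{area(i)} + v_{area(i)}

with flat (numerically: very low precision Gaussian) priors on the fixed
effects gamma, a P-spline prior on the age smooth f (random-walk difference
penalty tau_beta * K), iid Gaussian mother random intercepts b, an intrinsic
CAR (Gaussian Markov random field) prior tau_u * Q on the structured area
effect u, iid Gaussian unstructured area effects v, and inverse-Gamma
hyperpriors on all variance components.

Sampling uses the Albert-Chib latent-variable representation: z_i ~
N(eta_i, 1) truncated to (0, inf) when y_i = 1 and to (-inf, 0) otherwise,
which makes every coefficient block conditionally Gaussian. The spline
fitted values and the structured spatial effect are re-centred to sum to
zero each iteration, with the intercept absorbing the shift
(identifiability). Model comparison uses the deviance information
criterion DIC = Dbar + pD, pD = Dbar - D(posterior-mean parameters).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .graphs import AdjacencyGraph
from .splines import PenaltyMatrix, SplineBasis, build_bspline_basis, \
    difference_penalty

logger = logging.getLogger(__name__)

__all__ = [
    "ICARPrecision", "icar_precision", "ModelSpec", "McmcConfig",
    "DesignMatrices", "PosteriorDraws", "FitResult", "assemble_design",
    "gibbs_probit", "compute_dic", "summarize_posterior", "fit_star",
]

OUTCOMES = ("stillbirth", "lbw", "preterm")


@dataclass(frozen=True)
class ICARPrecision:
    """Q = diag(neighbour counts) - adjacency; rank n-1 on a connected graph."""

    matrix: np.ndarray

    @property
    def n_areas(self) -> int:
        return self.matrix.shape[0]


def icar_precision(graph: AdjacencyGraph) -> ICARPrecision:
    comps = graph.components()
    if len(comps) > 1:
        raise ValueError(
            f"graph disconnected; components: {[c[:5] for c in comps]}"
        )
    Q = np.diag(graph.degrees().astype(float)) - graph.adjacency_matrix()
    return ICARPrecision(matrix=Q)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the additive predictor, and their priors.

    ``fixed_terms`` names covariates beyond the intercept: "fuel" (binary
    indicator of unclean cooking fuel) and/or categorical terms
    ("education", "region", "wealth") dummy-coded against the reference
    level in ``references``. Setting ``smooth_age`` replaces a linear age
    term with the P-spline; ``mother_effect`` adds the per-mother random
    intercept; the two spatial switches control the ICAR and iid area
    effects. ``hyperprior_a``/``b`` are the inverse-Gamma shape/scale shared
    by all variance components.
    """

    link: str = "probit"
    fixed_terms: tuple[str, ...] = ("fuel",)
    references: dict = field(default_factory=lambda: {
        "education": "none", "region": "North-Central", "wealth": "middle"})
    smooth_age: bool = False
    spline_degree: int = 3
    spline_knots: int = 20
    spline_penalty_order: int = 2
    mother_effect: bool = False
    spatial_structured: bool = True
    spatial_unstructured: bool = True
    hyperprior_a: float = 0.001
    hyperprior_b: float = 0.001
    fixed_prior_precision: float = 1e-8

    def __post_init__(self) -> None:
        if self.link != "probit":
            raise ValueError("only the probit link is implemented")
        if self.hyperprior_a <= 0 or self.hyperprior_b <= 0:
            raise ValueError("hyperprior parameters must be > 0")

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 25_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class DesignMatrices:
    """Model-ready blocks for one outcome, after complete-case filtering."""

    y: np.ndarray                      # {0,1}, length n
    X: np.ndarray                      # fixed block incl. intercept
    fixed_names: list[str]
    spline: SplineBasis | None
    penalty: PenaltyMatrix | None
    mother_index: np.ndarray | None    # contiguous mother index per row
    n_mothers: int
    area_index: np.ndarray | None      # area id per row
    icar: ICARPrecision | None
    ages: np.ndarray
    audit: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.y.size


def _region_series(df: pd.DataFrame, graph: AdjacencyGraph | None) -> pd.Series:
    s = df["region"]
    if graph is not None and graph.region_labels is not None and \
            pd.api.types.is_integer_dtype(s):
        return s.map(dict(enumerate(graph.region_labels)))
    return s.astype(str)


def assemble_design(
    births: pd.DataFrame,
    spec: ModelSpec,
    graph: AdjacencyGraph | None,
    outcome: str,
) -> DesignMatrices:
    """Build complete-case design blocks for one adverse birth outcome.

    Rows with a missing outcome or a missing required covariate are
    dropped, and the kept/dropped audit is recorded. Categorical terms are
    dummy-coded against the declared reference; a declared level absent
    after filtering is an error. Requesting wealth together with fuel emits
    a collinearity warning (fuel use is strongly graded in wealth), kept in
    the audit, mirroring its exclusion from adjusted models.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    col = f"outcome_{outcome}"
    if col not in births.columns:
        raise ValueError(f"missing outcome column {col}")

    needed = [col]
    if "fuel" in spec.fixed_terms:
        needed.append("fuel_unclean")
    for term in ("education", "region", "wealth"):
        if term in spec.fixed_terms:
            needed.append(term)
    if spec.smooth_age or "age" in spec.fixed_terms:
        needed.append("mother_age")
    if spec.mother_effect:
        needed.append("mother_id")
    if spec.spatial_structured or spec.spatial_unstructured:
        needed.append("area_id")

    n_total = len(births)
    keep = births[needed].notna().all(axis=1)
    df = births.loc[keep].copy()
    audit = {"n_total": n_total, "n_kept": int(keep.sum()),
             "n_dropped": int((~keep).sum()), "warnings": []}
    if df.empty:
        raise ValueError("no complete cases for outcome " + outcome)

    if "wealth" in spec.fixed_terms and "fuel" in spec.fixed_terms:
        msg = ("wealth and cooking fuel are strongly collinear; adjusted "
               "models conventionally exclude wealth")
        audit["warnings"].append(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)

    cols = [np.ones(len(df))]
    names = ["intercept"]
    if "fuel" in spec.fixed_terms:
        cols.append(df["fuel_unclean"].to_numpy(dtype=float))
        names.append("fuel_unclean")
    if "age" in spec.fixed_terms and not spec.smooth_age:
        age = df["mother_age"].to_numpy(dtype=float)
        cols.append(age - age.mean())
        names.append("mother_age_centred")
    for term in ("education", "region", "wealth"):
        if term not in spec.fixed_terms:
            continue
        series = _region_series(df, graph) if term == "region" \
            else df[term].astype(str)
        present = set(series.unique())
        declared = (list(df[term].cat.categories)
                    if isinstance(df[term].dtype, pd.CategoricalDtype)
                    else sorted(present))
        if term == "region" and graph is not None and \
                graph.region_labels is not None:
            declared = list(graph.region_labels)
        missing = [lv for lv in declared if lv not in present]
        if missing:
            raise ValueError(
                f"{term}: levels absent after complete-case filtering: "
                f"{missing}")
        ref = spec.references.get(term, declared[0])
        if ref not in declared:
            ref = declared[0]  # graph uses different region naming
        if ref not in present:
            raise ValueError(f"{term}: reference level {ref!r} not present")
        for lv in declared:
            if lv == ref:
                continue
            cols.append((series == lv).to_numpy(dtype=float))
            names.append(f"{term}[{lv}]")
    X = np.column_stack(cols)

    ages = df["mother_age"].to_numpy(dtype=float) \
        if "mother_age" in df.columns else np.zeros(len(df))
    spline = penalty = None
    if spec.smooth_age:
        spline = build_bspline_basis(
            ages, degree=spec.spline_degree,
            n_interior_knots=spec.spline_knots,
            penalty_order=spec.spline_penalty_order)
        penalty = difference_penalty(spline.n_basis,
                                     spec.spline_penalty_order)

    mother_index = None
    n_mothers = 0
    if spec.mother_effect:
        codes, uniques = pd.factorize(df["mother_id"], sort=True)
        mother_index = codes.astype(np.int64)
        n_mothers = len(uniques)

    area_index = None
    icar = None
    if spec.spatial_structured or spec.spatial_unstructured:
        if graph is None:
            raise ValueError("spatial terms need an adjacency graph")
        area_index = df["area_id"].to_numpy(dtype=np.int64)
        if area_index.min() < 0 or area_index.max() >= graph.n_areas:
            raise ValueError("area_id outside graph range")
        if spec.spatial_structured:
            icar = icar_precision(graph)
        else:
            icar = ICARPrecision(np.zeros((graph.n_areas, graph.n_areas)))

    return DesignMatrices(
        y=df[col].to_numpy(dtype=float),
        X=X, fixed_names=names, spline=spline, penalty=penalty,
        mother_index=mother_index, n_mothers=n_mothers,
        area_index=area_index, icar=icar, ages=ages, audit=audit,
    )


def _sample_truncated_normal(
    mean: np.ndarray, positive: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """z ~ N(mean, 1) truncated to (0, inf) where positive, else (-inf, 0).

    Inverse-CDF in the numerically stable tail: for the positive branch
    z = mean - Phi^{-1}((1-u) * Phi(mean)), which stays accurate when the
    constraint forces z into the far tail of its untruncated law.
    """
    u = rng.uniform(size=mean.size)
    z = np.empty_like(mean)
    pos = positive
    arg_p = np.clip((1.0 - u[pos]) * norm.cdf(mean[pos]), 1e-300, 1.0)
    z[pos] = mean[pos] - norm.ppf(arg_p)
    neg = ~pos
    arg_n = np.clip((1.0 - u[neg]) * norm.cdf(-mean[neg]), 1e-300, 1.0)
    z[neg] = mean[neg] + norm.ppf(arg_n)
    np.maximum(z, 1e-12, where=pos, out=z)
    np.minimum(z, -1e-12, where=neg, out=z)
    return z


def _sample_gaussian(prec: np.ndarray, lin: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec^{-1} lin, prec^{-1}) via Cholesky of the precision."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, lin)
    eps = rng.standard_normal(lin.size)
    return mean + np.linalg.solve(L.T, eps)


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    ll = np.where(y == 1, norm.logcdf(eta), norm.logcdf(-eta))
    return float(-2.0 * ll.sum())


@dataclass
class PosteriorDraws:
    """Stored MCMC draws of every block, plus the per-draw deviance."""

    fixed: np.ndarray                     # S x p
    fixed_names: list[str]
    spline_coef: np.ndarray | None        # S x m
    spline: SplineBasis | None
    mother_mean: np.ndarray | None        # posterior mean of b (n_mothers,)
    mother_draws: np.ndarray | None       # S x n_mothers when small enough
    structured: np.ndarray | None         # S x n_areas
    unstructured: np.ndarray | None       # S x n_areas
    variances: dict[str, np.ndarray]      # component -> S
    deviance: np.ndarray                  # S
    spline_centre_abs: np.ndarray | None  # |mean fitted spline| per draw
    structured_sum_abs: np.ndarray | None
    divergence_flags: list[str]
    mcmc: McmcConfig

    @property
    def n_stored(self) -> int:
        return self.fixed.shape[0]


def gibbs_probit(
    design: DesignMatrices, spec: ModelSpec, mcmc: McmcConfig
) -> PosteriorDraws:
    """Albert-Chib Gibbs sampler for the probit STAR model.

    Block updates per iteration: latent truncated normals z; fixed effects
    (ridge precision ``fixed_prior_precision`` standing in for a flat
    prior); spline coefficients with prior precision tau_beta * K, then
    re-centred; mother and unstructured-area effects (conditionally
    independent given the rest); structured area effects with prior
    precision tau_u * Q, then re-centred; inverse-Gamma variance updates
    with shape a + rank/2 and scale b + quadratic_form/2. Deterministic
    given the seed. Any variance draw above 1e6 is flagged in the draw log.
    """
    if design.n_obs == 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(mcmc.seed)
    y = design.y
    n = y.size
    pos = y == 1

    X = design.X
    p = X.shape[1]
    XtX = X.T @ X
    ridge = spec.fixed_prior_precision * np.eye(p)
    gamma = np.zeros(p)
    gamma[0] = float(np.clip(norm.ppf(np.clip(y.mean(), 1e-4, 1 - 1e-4)),
                             -3, 3))
    eta_fixed = X @ gamma

    use_spline = design.spline is not None
    if use_spline:
        B = design.spline.basis_matrix
        K = design.penalty.matrix
        m = B.shape[1]
        BtB = B.T @ B
        rank_K = design.penalty.rank
        beta = np.zeros(m)
    eta_spline = B @ beta if use_spline else np.zeros(n)

    use_mother = design.mother_index is not None
    if use_mother:
        mi = design.mother_index
        n_mo = design.n_mothers
        mother_counts = np.bincount(mi, minlength=n_mo).astype(float)
        b = np.zeros(n_mo)
    eta_mother = b[mi] if use_mother else np.zeros(n)

    use_str = design.icar is not None and spec.spatial_structured
    use_unstr = design.area_index is not None and spec.spatial_unstructured
    if use_str or use_unstr:
        ai = design.area_index
        n_ar = (design.icar.n_areas if design.icar is not None
                else int(ai.max()) + 1)
        area_counts = np.bincount(ai, minlength=n_ar).astype(float)
    if use_str:
        Q = design.icar.matrix
        u = np.zeros(n_ar)
    eta_str = u[ai] if use_str else np.zeros(n)
    if use_unstr:
        v = np.zeros(n_ar)
    eta_unstr = v[ai] if use_unstr else np.zeros(n)

    a0, b0 = spec.hyperprior_a, spec.hyperprior_b
    sig2 = {"spline": 0.1, "mother": 0.1, "structured": 0.1,
            "unstructured": 0.1}

    S = mcmc.n_stored
    store = {
        "fixed": np.empty((S, p)),
        "deviance": np.empty(S),
    }
    if use_spline:
        store["spline"] = np.empty((S, m))
        store["sig2_spline"] = np.empty(S)
        store["centre"] = np.empty(S)
    if use_mother:
        store["sig2_mother"] = np.empty(S)
        mother_sum = np.zeros(n_mo)
        keep_mother = S * n_mo <= 4_000_000
        if keep_mother:
            store["mother"] = np.empty((S, n_mo))
    if use_str:
        store["structured"] = np.empty((S, n_ar))
        store["sig2_structured"] = np.empty(S)
        store["str_sum"] = np.empty(S)
    if use_unstr:
        store["unstructured"] = np.empty((S, n_ar))
        store["sig2_unstructured"] = np.empty(S)
    flags: list[str] = []

    def ig_draw(rank: float, qf: float) -> float:
        shape = a0 + rank / 2.0
        scale = b0 + qf / 2.0
        return float(scale / rng.gamma(shape))

    s_idx = 0
    for it in range(1, mcmc.n_iter + 1):
        eta = eta_fixed + eta_spline + eta_mother + eta_str + eta_unstr
        z = _sample_truncated_normal(eta, pos, rng)

        # fixed block
        r = z - (eta_spline + eta_mother + eta_str + eta_unstr)
        gamma = _sample_gaussian(XtX + ridge, X.T @ r, rng)

        # spline block, re-centred with the intercept absorbing the shift
        if use_spline:
            eta_fixed = X @ gamma
            r = z - (eta_fixed + eta_mother + eta_str + eta_unstr)
            beta = _sample_gaussian(BtB + (1.0 / sig2["spline"]) * K,
                                    B.T @ r, rng)
            eta_spline = B @ beta
            centre = eta_spline.mean()
            beta = beta - centre  # rows of B sum to 1
            eta_spline -= centre
            gamma[0] += centre
            sig2["spline"] = ig_draw(rank_K, beta @ K @ beta)
        eta_fixed = X @ gamma

        # mother random intercepts: conditionally independent
        if use_mother:
            r = z - (eta_fixed + eta_spline + eta_str + eta_unstr)
            sums = np.bincount(mi, weights=r, minlength=n_mo)
            prec = mother_counts + 1.0 / sig2["mother"]
            b = sums / prec + rng.standard_normal(n_mo) / np.sqrt(prec)
            eta_mother = b[mi]
            sig2["mother"] = ig_draw(n_mo, b @ b)

        # unstructured area effects: conditionally independent
        if use_unstr:
            r = z - (eta_fixed + eta_spline + eta_mother + eta_str)
            sums = np.bincount(ai, weights=r, minlength=n_ar)
            prec = area_counts + 1.0 / sig2["unstructured"]
            v = sums / prec + rng.standard_normal(n_ar) / np.sqrt(prec)
            eta_unstr = v[ai]
            sig2["unstructured"] = ig_draw(n_ar, v @ v)

        # structured (ICAR) area effects, re-centred to sum to zero
        if use_str:
            r = z - (eta_fixed + eta_spline + eta_mother + eta_unstr)
            sums = np.bincount(ai, weights=r, minlength=n_ar)
            prec = np.diag(area_counts) + (1.0 / sig2["structured"]) * Q
            u = _sample_gaussian(prec, sums, rng)
            centre = u.mean()
            u = u - centre
            gamma[0] += centre
            eta_fixed = X @ gamma
            eta_str = u[ai]
            sig2["structured"] = ig_draw(n_ar - 1, u @ Q @ u)

        for comp, val in sig2.items():
            if val > 1e6:
                flags.append(f"iter {it}: sigma2_{comp} = {val:.3g}")

        if it % 100 == 0:
            eta = eta_fixed + eta_spline + eta_mother + eta_str + eta_unstr
            logger.debug("iteration %d deviance %.1f", it, _deviance(y, eta))

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            eta = eta_fixed + eta_spline + eta_mother + eta_str + eta_unstr
            store["fixed"][s_idx] = gamma
            store["deviance"][s_idx] = _deviance(y, eta)
            if use_spline:
                store["spline"][s_idx] = beta
                store["sig2_spline"][s_idx] = sig2["spline"]
                store["centre"][s_idx] = abs(eta_spline.mean())
            if use_mother:
                store["sig2_mother"][s_idx] = sig2["mother"]
                mother_sum += b
                if keep_mother:
                    store["mother"][s_idx] = b
            if use_str:
                store["structured"][s_idx] = u
                store["sig2_structured"][s_idx] = sig2["structured"]
                store["str_sum"][s_idx] = abs(u.sum())
            if use_unstr:
                store["unstructured"][s_idx] = v
                store["sig2_unstructured"][s_idx] = sig2["unstructured"]
            s_idx += 1

    variances = {k[5:]: store[k] for k in store if k.startswith("sig2_")}
    return PosteriorDraws(
        fixed=store["fixed"],
        fixed_names=list(design.fixed_names),
        spline_coef=store.get("spline"),
        spline=design.spline,
        mother_mean=(mother_sum / S) if use_mother else None,
        mother_draws=store.get("mother"),
        structured=store.get("structured"),
        unstructured=store.get("unstructured"),
        variances=variances,
        deviance=store["deviance"],
        spline_centre_abs=store.get("centre"),
        structured_sum_abs=store.get("str_sum"),
        divergence_flags=flags,
        mcmc=mcmc,
    )


def _eta_at_posterior_mean(draws: PosteriorDraws,
                           design: DesignMatrices) -> np.ndarray:
    eta = design.X @ draws.fixed.mean(axis=0)
    if draws.spline_coef is not None:
        eta = eta + design.spline.basis_matrix @ draws.spline_coef.mean(axis=0)
    if draws.mother_mean is not None:
        eta = eta + draws.mother_mean[design.mother_index]
    if draws.structured is not None:
        eta = eta + draws.structured.mean(axis=0)[design.area_index]
    if draws.unstructured is not None:
        eta = eta + draws.unstructured.mean(axis=0)[design.area_index]
    return eta


def compute_dic(draws: PosteriorDraws,
                design: DesignMatrices) -> tuple[float, float, float]:
    """(DIC, pD, Dbar): Dbar = mean stored deviance, pD = Dbar - D(mean)."""
    if draws.n_stored < 2:
        raise ValueError("need >= 2 stored draws")
    dbar = float(draws.deviance.mean())
    dhat = _deviance(design.y, _eta_at_posterior_mean(draws, design))
    p_d = dbar - dhat
    return dbar + p_d, p_d, dbar


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelations."""
    x = x - x.mean()
    n = x.size
    if n < 4 or np.allclose(x, 0):
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (x @ x)
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] < 0.0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction on one chain."""
    n = x.size // 2
    if n < 2:
        return float("nan")
    halves = np.stack([x[:n], x[-n:]])
    w = halves.var(axis=1, ddof=1).mean()
    bvar = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + bvar / (w * n)))


@dataclass
class FitResult:
    """Posterior summaries of one fitted model."""

    params: pd.DataFrame          # name, mean, ci_2.5, ci_97.5, ess, rhat
    smooth: pd.DataFrame | None   # age, mean, lo/hi at 80% and 95%
    spatial: pd.DataFrame | None  # area_id, structured, unstructured, total
    dic: float | None = None
    p_d: float | None = None
    dbar: float | None = None
    audit: dict = field(default_factory=dict)


def summarize_posterior(
    draws: PosteriorDraws,
    age_grid: np.ndarray | Sequence[float] | None = None,
    design: DesignMatrices | None = None,
) -> FitResult:
    """Posterior means, equal-tailed 95% CrIs, smooth bands, spatial means.

    The age smooth is evaluated on ``age_grid`` with 80% and 95% bands; the
    per-area spatial summary reports structured, unstructured and total
    (their sum) posterior means. DIC components are filled when the design
    is supplied.
    """
    rows = []

    def add(name: str, x: np.ndarray) -> None:
        lo, hi = np.quantile(x, [0.025, 0.975])
        rows.append(dict(name=name, mean=float(x.mean()),
                         ci_low=float(lo), ci_high=float(hi),
                         ess=_ess(x), rhat=_split_rhat(x)))

    for k, name in enumerate(draws.fixed_names):
        add(name, draws.fixed[:, k])
    for comp, x in draws.variances.items():
        add(f"sigma2_{comp}", x)
    add("deviance", draws.deviance)
    params = pd.DataFrame(rows)

    smooth = None
    if draws.spline_coef is not None and age_grid is not None \
            and len(age_grid) > 0:
        grid = np.asarray(age_grid, dtype=float)
        F = draws.spline.evaluate(grid) @ draws.spline_coef.T  # grid x S
        qs = np.quantile(F, [0.025, 0.1, 0.9, 0.975], axis=1)
        smooth = pd.DataFrame({
            "age": grid, "mean": F.mean(axis=1),
            "lo95": qs[0], "lo80": qs[1], "hi80": qs[2], "hi95": qs[3],
        })

    spatial = None
    if draws.structured is not None or draws.unstructured is not None:
        some = draws.structured if draws.structured is not None \
            else draws.unstructured
        n_ar = some.shape[1]
        s_mean = (draws.structured.mean(axis=0) if draws.structured is not None
                  else np.zeros(n_ar))
        v_mean = (draws.unstructured.mean(axis=0)
                  if draws.unstructured is not None else np.zeros(n_ar))
        spatial = pd.DataFrame({
            "area_id": np.arange(n_ar), "structured": s_mean,
            "unstructured": v_mean, "total": s_mean + v_mean,
        })

    result = FitResult(params=params, smooth=smooth, spatial=spatial,
                       audit={"divergence_flags": draws.divergence_flags})
    if design is not None:
        result.dic, result.p_d, result.dbar = compute_dic(draws, design)
        result.audit.update(design.audit)
    return result


def fit_star(
    births: pd.DataFrame,
    spec: ModelSpec,
    graph: AdjacencyGraph | None,
    outcome: str,
    mcmc: McmcConfig,
    age_grid: np.ndarray | None = None,
) -> tuple[FitResult, PosteriorDraws, DesignMatrices]:
    """Assemble, sample, and summarize in one call."""
    design = assemble_design(births, spec, graph, outcome)
    draws = gibbs_probit(design, spec, mcmc)
    if age_grid is None and spec.smooth_age:
        age_grid = np.linspace(design.ages.min(), design.ages.max(), 50)
    result = summarize_posterior(draws, age_grid, design)
    return result, draws, design
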