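"""Repeatability GBLUP: REML and Gibbs fitting of the mixed model

    y = X b + Z a + W pe + e

with fixed intercept + year effects, additive genetic effects
``a ~ N(0, G sigma2_a)``, permanent-environment effects
``pe ~ N(0, I sigma2_pe)`` (W = Z, both indexing plants) and residuals
``e ~ N(0, I sigma2_e)``. Narrow-sense heritability and repeatability
derive from the variance components::

    h2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e)
    R  = (sigma2_a + sigma2_pe) / (sigma2_a + sigma2_pe + sigma2_e)

REML maximizes the restricted likelihood with expectation-maximization
updates accelerated by average-information steps (each accepted only when
it improves the restricted log-likelihood, so the EM monotonicity
guarantee is preserved). The Gibbs sampler uses scaled-inverse-chi-square
priors and tolerates designs that are singular for REML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)


class ReMLError(RuntimeError):
    """Base class for REML failures that callers may catch to fall back
    to the MCMC solver."""


class SingularModelError(ReMLError):
    """Coefficient or information matrix singular."""


class NonConvergenceError(ReMLError):
    """Restricted likelihood still moving after ``max_iter`` iterations."""


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_pe: float
    sigma2_e: float

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_pe", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("at least one variance component must be > 0")

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_pe + self.sigma2_e


@dataclass
class GeneticParams:
    """Heritability, repeatability and the 3-way variance partition
    (genetic, permanent-environment, temporary-environment shares)."""

    h2: float
    R: float

    @property
    def partition(self) -> Tuple[float, float, float]:
        return (self.h2, self.R - self.h2, 1.0 - self.R)


def genetic_params(v: VarianceComponents) -> GeneticParams:
    """h2 and R from variance components (h2 <= R always)."""
    total = v.total
    if total <= 0:
        raise ValueError("zero total variance")
    h2 = v.sigma2_a / total
    R = (v.sigma2_a + v.sigma2_pe) / total
    return GeneticParams(h2=h2, R=R)


def gebv_accuracy(pa: float, h2: float) -> float:
    """Breeding-value accuracy ``pa / sqrt(h2)``.

    Values above 1 are possible with noisy heritability estimates and are
    flagged with a warning rather than rejected.
    """
    if h2 <= 0:
        raise ValueError("gebv_accuracy requires h2 > 0")
    acc = pa / np.sqrt(h2)
    if acc > 1:
        warnings.warn(
            f"GEBV accuracy {acc:.3f} > 1 (likely an underestimated h2)",
            stacklevel=2,
        )
    return float(acc)


@dataclass
class MixedModelSpec:
    """Response, designs and kinship of one repeatability-model instance."""

    y: np.ndarray
    X: np.ndarray
    plant_index: np.ndarray      # record -> row of G
    plant_ids: np.ndarray        # all plants in G (columns of Z)
    year_levels: List            # sorted year labels; first = reference
    record_years: np.ndarray
    G: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)


def build_design(
    records: pd.DataFrame,
    kinship: KinshipMatrix,
    trait: Optional[str] = None,
) -> MixedModelSpec:
    """Assemble y, X (intercept + year dummies) and the record->plant map.

    Every record's plant must appear in the kinship matrix; the year
    factor uses the first (sorted) year as reference and is dropped
    entirely when only one year is present.
    """
    df = records
    if trait is not None:
        df = df[df["trait"] == trait]
    if len(df) == 0:
        raise ValueError("no phenotype records to fit")
    plant_pos = {p: i for i, p in enumerate(kinship.ids)}
    unknown = sorted({p for p in df["plant"] if p not in plant_pos})
    if unknown:
        raise ValueError(
            f"{len(unknown)} record plants absent from the kinship matrix: "
            f"{unknown[:10]}"
        )
    y = df["value"].to_numpy(dtype=float)
    plant_index = np.array([plant_pos[p] for p in df["plant"]], dtype=np.intp)
    years = sorted(df["year"].unique())
    n = len(df)
    X = np.ones((n, len(years)))
    record_years = df["year"].to_numpy()
    for k, yr in enumerate(years[1:], start=1):
        X[:, k] = (record_years == yr).astype(float)
    return MixedModelSpec(
        y=y,
        X=X,
        plant_index=plant_index,
        plant_ids=np.asarray(kinship.ids, dtype=object),
        year_levels=list(years),
        record_years=record_years,
        G=np.asarray(kinship.matrix, dtype=float),
    )


@dataclass
class MixedModelFit:
    """Solutions, variance components and diagnostics of one fit."""

    intercept: float
    year_effects: Dict
    a: np.ndarray
    pe: np.ndarray
    plant_ids: np.ndarray
    vc: VarianceComponents
    params: GeneticParams
    solver: str
    diagnostics: Dict = field(default_factory=dict)

    def a_of(self, plant) -> float:
        idx = np.flatnonzero(self.plant_ids == plant)
        if len(idx) == 0:
            raise KeyError(f"plant {plant!r} not in fit")
        return float(self.a[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plant": self.plant_ids,
                "a": self.a,
                "pe": self.pe,
            }
        )


def predict_records(
    fit: MixedModelFit, targets: Sequence[Tuple[object, object]]
) -> np.ndarray:
    """Predicted value per (plant, year): mu + year + a + pe.

    Years unseen in training receive the mean of the estimated year
    effects (reference included as zero), logged once.
    """
    pos = {p: i for i, p in enumerate(fit.plant_ids)}
    effects = fit.year_effects
    mean_effect = float(np.mean(list(effects.values()))) if effects else 0.0
    unseen_logged = False
    out = np.empty(len(targets))
    for t, (plant, year) in enumerate(targets):
        if plant not in pos:
            raise ValueError(f"plant {plant!r} absent from the fitted model")
        if year in effects:
            ye = effects[year]
        else:
            if not unseen_logged:
                logger.info(
                    "year %r unseen in training; using mean year effect", year
                )
                unseen_logged = True
            ye = mean_effect
        i = pos[plant]
        out[t] = fit.intercept + ye + fit.a[i] + fit.pe[i]
    return out


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


class _RemlWork:
    """Woodbury-form workspace: V = M diag(Lam) M' + s_e I with M = Z U,
    where G + jitter I = U diag(d) U'. All per-iteration quantities reduce
    to q x q algebra (q = number of plants)."""

    def __init__(self, spec: MixedModelSpec, jitter: float) -> None:
        q = spec.n_plants
        Gj = spec.G + jitter * np.eye(q)
        self.Gj = Gj
        d, U = np.linalg.eigh((Gj + Gj.T) / 2.0)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.M = U[spec.plant_index, :]          # n x q
        self.A = self.M.T @ self.M               # q x q
        self.X = spec.X
        self.y = spec.y
        self.n, self.p = spec.X.shape
        self.q = q
        self.MtX = self.M.T @ spec.X
        self.spec = spec

    def evaluate(self, theta: np.ndarray, full: bool = True) -> dict:
        s_a, s_pe, s_e = theta
        lam = s_a * self.d + s_pe
        C = self.A + np.diag(s_e / lam)
        try:
            cho = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as exc:
            raise SingularModelError(f"inner matrix singular: {exc}") from exc
        logdet_C = 2.0 * np.log(np.diag(cho[0])).sum()

        def vinv(B):
            return (B - self.M @ cho_solve(cho, self.M.T @ B)) / s_e

        ViX = vinv(self.X)
        Viy = vinv(self.y)
        XtViX = self.X.T @ ViX
        try:
            cho_x = cho_factor((XtViX + XtViX.T) / 2.0, lower=True)
        except np.linalg.LinAlgError as exc:
            raise SingularModelError(
                f"X'V^-1X singular (collinear fixed effects?): {exc}"
            ) from exc
        beta = cho_solve(cho_x, self.X.T @ Viy)
        w = Viy - ViX @ beta                     # P y
        yPy = float(self.y @ w)
        logdet_V = (
            (self.n - self.q) * np.log(s_e)
            + logdet_C
            + np.log(lam).sum()
        )
        logdet_XtViX = 2.0 * np.log(np.diag(cho_x[0])).sum()
        ll = -0.5 * (logdet_V + logdet_XtViX + yPy)
        out = {"ll": ll, "beta": beta, "w": w, "cho": cho, "cho_x": cho_x,
               "ViX": ViX, "vinv": vinv, "lam": lam}
        if not full:
            return out

        T = cho_solve(cho, self.A)               # C^-1 A
        diag_MVM = (np.diag(self.A) - np.einsum("ij,ji->i", self.A, T)) / s_e
        N = (self.MtX - self.A @ cho_solve(cho, self.MtX)) / s_e  # M'ViX
        H = cho_solve(cho_x, N.T)                # p x q
        corr = np.einsum("jp,pj->j", N, H)
        diag_PK = diag_MVM - corr                # per-eigencomponent
        tr_Vi = (self.n - np.trace(T)) / s_e
        XtV2X = ViX.T @ ViX
        tr_P = tr_Vi - float(np.trace(cho_solve(cho_x, XtV2X)))
        Mw = self.M.T @ w
        out.update(
            tr_PKa=float(self.d @ diag_PK),
            tr_PKpe=float(diag_PK.sum()),
            tr_P=tr_P,
            yPKaPy=float(self.d @ (Mw * Mw)),
            yPKpePy=float(Mw @ Mw),
            yPPy=float(w @ w),
            Mw=Mw,
        )
        return out


def reml_fit(
    spec: MixedModelSpec,
    tol: float = 1e-8,
    max_iter: int = 500,
    jitter: float = 1e-6,
    accelerate: bool = True,
    start: Optional[Sequence[float]] = None,
) -> MixedModelFit:
    """Restricted maximum likelihood for the three-component model.

    EM updates (monotone in the restricted log-likelihood) with
    average-information Newton steps accepted only when they improve the
    objective. Components are kept non-negative; boundary estimates are
    reported as zero. Raises :class:`NonConvergenceError` or
    :class:`SingularModelError` so callers can fall back to
    :func:`gibbs_fit`.
    """
    n, p = spec.X.shape
    if n <= p:
        raise SingularModelError(
            f"{n} records cannot identify {p} fixed effects"
        )
    vary = float(np.var(spec.y))
    if vary <= 0:
        raise SingularModelError("response has zero variance")
    floor = 1e-8 * vary
    work = _RemlWork(spec, jitter)
    q = spec.n_plants

    theta = np.asarray(
        start if start is not None else [vary / 3.0] * 3, dtype=float
    )
    theta = np.maximum(theta, floor)
    ev = work.evaluate(theta)
    ll = ev["ll"]
    path = [ll]
    converged = False
    theta_prev = theta.copy()
    for it in range(max_iter):
        scores = 0.5 * np.array(
            [
                ev["yPKaPy"] - ev["tr_PKa"],
                ev["yPKpePy"] - ev["tr_PKpe"],
                ev["yPPy"] - ev["tr_P"],
            ]
        )
        em = np.array(
            [
                theta[0] + theta[0] ** 2 * 2.0 * scores[0] / q,
                theta[1] + theta[1] ** 2 * 2.0 * scores[1] / q,
                theta[2] + theta[2] ** 2 * 2.0 * scores[2] / n,
            ]
        )
        em = np.maximum(em, floor)

        # candidate steps: EM (monotone anchor), boundary jumps for
        # components pushed toward zero, and an AI Newton step
        candidates = [em]
        at_floor = theta <= 2.0 * floor
        pushing_down = (scores < 0) & ~at_floor
        if pushing_down.any():
            for i in np.flatnonzero(pushing_down):
                cand = em.copy()
                cand[i] = floor
                candidates.append(cand)
            if pushing_down.sum() > 1:
                cand = em.copy()
                cand[pushing_down] = floor
                candidates.append(cand)
        if accelerate:
            try:
                Mw, w = ev["Mw"], ev["w"]
                v_list = [
                    work.M @ (work.d * Mw),
                    work.M @ Mw,
                    w,
                ]
                Pv = []
                for v in v_list:
                    Viv = ev["vinv"](v)
                    Pv.append(
                        Viv - ev["ViX"] @ cho_solve(
                            ev["cho_x"], ev["ViX"].T @ v
                        )
                    )
                AI = 0.5 * np.array(
                    [[v_list[i] @ Pv[j] for j in range(3)] for i in range(3)]
                )
                AI = (AI + AI.T) / 2.0
                delta = np.linalg.solve(AI, scores)
                for step in (1.0, 0.5, 0.25):
                    candidates.append(np.maximum(theta + step * delta, floor))
            except np.linalg.LinAlgError:
                pass
        # geometric extrapolation along the recent trajectory defeats the
        # slow crawl on near-flat (sigma2_a, sigma2_pe) ridges
        move = theta - theta_prev
        if np.abs(move).max() > 0:
            for c in (4.0, 16.0, 64.0):
                candidates.append(np.maximum(theta + c * move, floor))
        best_ll, best_theta = None, None
        for cand in candidates:
            try:
                ll_c = work.evaluate(cand, full=False)["ll"]
            except SingularModelError:
                continue
            if best_ll is None or ll_c > best_ll:
                best_ll, best_theta = ll_c, cand
        if best_ll is None:
            raise SingularModelError("all candidate steps singular")
        theta_prev = theta
        theta = best_theta
        ev = work.evaluate(theta)
        new_ll = ev["ll"]
        path.append(new_ll)
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        raise NonConvergenceError(
            f"REML not converged in {max_iter} iterations "
            f"(last change {abs(path[-1] - path[-2]):.3g})"
        )

    return _finalize_reml(spec, work, theta, ev, floor, ll, len(path) - 1, path)


def _finalize_reml(spec, work, theta, ev, floor, ll, n_iter, path):
    s_a, s_pe, s_e = theta
    w = ev["w"]
    Ztw = np.bincount(spec.plant_index, weights=w, minlength=spec.n_plants)
    a_hat = s_a * (work.Gj @ Ztw)
    pe_hat = s_pe * Ztw
    beta = ev["beta"]
    year_effects = {spec.year_levels[0]: 0.0}
    for k, yr in enumerate(spec.year_levels[1:], start=1):
        year_effects[yr] = float(beta[k])

    def report(v):
        return 0.0 if v <= 2.0 * floor else float(v)

    vc = VarianceComponents(report(s_a), report(s_pe), report(s_e))
    _warn_if_unidentifiable(spec.G)
    return MixedModelFit(
        intercept=float(beta[0]),
        year_effects=year_effects,
        a=a_hat,
        pe=pe_hat,
        plant_ids=spec.plant_ids,
        vc=vc,
        params=genetic_params(vc),
        solver="REML",
        diagnostics={
            "iterations": n_iter,
            "loglik": float(ll),
            "loglik_path": [float(x) for x in path],
            "converged": True,
        },
    )


def _warn_if_unidentifiable(G: np.ndarray) -> None:
    q = G.shape[0]
    if q < 2:
        return
    off = G[~np.eye(q, dtype=bool)]
    scale = np.abs(np.diag(G)).mean()
    if scale > 0 and np.abs(off).mean() < 0.02 * scale:
        warnings.warn(
            "G is nearly diagonal: sigma2_a and sigma2_pe are only weakly "
            "identified (Z = W)", stacklevel=3
        )


def blup_solutions(
    spec: MixedModelSpec,
    vc: VarianceComponents,
    jitter: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BLUE/BLUP solutions (b, a, pe) at fixed variance components.

    Same V-inverse route the REML fit uses at convergence; equivalent to
    solving Henderson's mixed-model equations.
    """
    work = _RemlWork(spec, jitter)
    theta = np.array([vc.sigma2_a, vc.sigma2_pe, vc.sigma2_e], dtype=float)
    theta = np.maximum(theta, 1e-12)
    ev = work.evaluate(theta, full=False)
    w = ev["w"]
    Ztw = np.bincount(spec.plant_index, weights=w, minlength=spec.n_plants)
    a_hat = theta[0] * (work.Gj @ Ztw)
    pe_hat = theta[1] * Ztw
    return ev["beta"], a_hat, pe_hat


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------


def gibbs_fit(
    spec: MixedModelSpec,
    n_iter: int = 12000,
    burn_in: int = 2000,
    thin: int = 5,
    seed: int = 0,
    df0: float = 5.0,
    jitter: float = 1e-6,
) -> MixedModelFit:
    """Gibbs sampler with scaled-inverse-chi-square priors (df 5, prior
    scales splitting the phenotypic variance equally across the three
    components). Posterior means are reported; reproducible given
    ``seed``; tolerates designs that are singular under REML."""
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    rng = np.random.default_rng(seed)
    y, X = spec.y, spec.X
    n, p = X.shape
    q = spec.n_plants
    idx = spec.plant_index
    counts = np.bincount(idx, minlength=q).astype(float)

    Gj = spec.G + jitter * np.eye(q)
    Ginv = np.linalg.inv(Gj)
    Ginv = (Ginv + Ginv.T) / 2.0

    vary = float(np.var(y))
    scale0 = max(vary, 1e-12) * (df0 + 2.0) / df0 / 3.0

    XtX = X.T @ X + 1e-8 * np.eye(p)
    XtX_cho = cho_factor(XtX, lower=True)
    Lx = np.linalg.cholesky(np.linalg.inv(XtX))

    b = np.zeros(p)
    a = np.zeros(q)
    pe = np.zeros(q)
    s_a = s_pe = s_e = max(vary, 1e-12) / 3.0

    keep = []
    for it in range(n_iter):
        resid_b = y - a[idx] - pe[idx]
        b_mean = cho_solve(XtX_cho, X.T @ resid_b)
        b = b_mean + np.sqrt(s_e) * (Lx @ rng.standard_normal(p))

        r_a = y - X @ b - pe[idx]
        Ca = np.diag(counts / s_e) + Ginv / s_a
        La = np.linalg.cholesky((Ca + Ca.T) / 2.0)
        rhs = np.bincount(idx, weights=r_a, minlength=q) / s_e
        mean_a = cho_solve((La, True), rhs)
        z = rng.standard_normal(q)
        a = mean_a + np.linalg.solve(La.T, z)

        r_pe = y - X @ b - a[idx]
        prec = counts / s_e + 1.0 / s_pe
        mean_pe = (np.bincount(idx, weights=r_pe, minlength=q) / s_e) / prec
        pe = mean_pe + rng.standard_normal(q) / np.sqrt(prec)

        e = y - X @ b - a[idx] - pe[idx]
        s_a = (df0 * scale0 + a @ (Ginv @ a)) / rng.chisquare(df0 + q)
        s_pe = (df0 * scale0 + pe @ pe) / rng.chisquare(df0 + q)
        s_e = (df0 * scale0 + e @ e) / rng.chisquare(df0 + n)
        s_a, s_pe, s_e = (max(s, 1e-12) for s in (s_a, s_pe, s_e))
        if not np.isfinite([s_a, s_pe, s_e]).all():
            raise RuntimeError(
                f"non-finite variance draw at iteration {it}: "
                f"({s_a}, {s_pe}, {s_e})"
            )
        if it >= burn_in and (it - burn_in) % thin == 0:
            total = s_a + s_pe + s_e
            keep.append(
                (s_a, s_pe, s_e, s_a / total, (s_a + s_pe) / total,
                 b.copy(), a.copy(), pe.copy())
            )

    draws = np.array([k[:5] for k in keep])
    post = draws.mean(axis=0)
    b_post = np.mean([k[5] for k in keep], axis=0)
    a_post = np.mean([k[6] for k in keep], axis=0)
    pe_post = np.mean([k[7] for k in keep], axis=0)
    vc = VarianceComponents(*post[:3])
    params = GeneticParams(h2=float(post[3]), R=float(post[4]))

    year_effects = {spec.year_levels[0]: 0.0}
    for k, yr in enumerate(spec.year_levels[1:], start=1):
        year_effects[yr] = float(b_post[k])
    ess = _effective_sample_size(draws[:, 3])
    return MixedModelFit(
        intercept=float(b_post[0]),
        year_effects=year_effects,
        a=a_post,
        pe=pe_post,
        plant_ids=spec.plant_ids,
        vc=vc,
        params=params,
        solver="MCMC",
        diagnostics={
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
            "n_samples": len(keep),
            "ess_h2": ess,
        },
    )


def _effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence ESS estimate for a scalar chain."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    if m < 10 or np.var(x) == 0:
        return float(m)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[m - 1:] / (np.arange(m, 0, -1))
    acf /= acf[0]
    s = 0.0
    for k in range(1, m):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(m / (1.0 + 2.0 * s))


def fit_repeatability(
    spec: MixedModelSpec,
    solver: str = "auto",
    seed: int = 0,
    reml_kwargs: Optional[dict] = None,
    gibbs_kwargs: Optional[dict] = None,
) -> MixedModelFit:
    """Solver policy: REML first, MCMC fallback on singularity or
    non-convergence (``solver='auto'``); or force either solver."""
    reml_kwargs = reml_kwargs or {}
    gibbs_kwargs = gibbs_kwargs or {}
    if solver == "reml":
        return reml_fit(spec, **reml_kwargs)
    if solver == "mcmc":
        return gibbs_fit(spec, seed=seed, **gibbs_kwargs)
    if solver != "auto":
        raise ValueError(f"unknown solver {solver!r}")
    try:
        return reml_fit(spec, **reml_kwargs)
    except ReMLError as exc:
        logger.info("REML failed (%s); falling back to Gibbs sampling", exc)
        return gibbs_fit(spec, seed=seed, **gibbs_kwargs)
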