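"""Mutation–selection–drift site-frequency-spectrum models and ML fitting.

A nucleotide site carries two alleles, a0 and a1 (here: the minor- and the
major-codon state).  Scaled mutation rates are theta01 = 4*Ne*mu01 (a0->a1)
and theta10 = 4*Ne*mu10 (a1->a0), with mutational bias kappa = theta10 /
theta01; selection on the focal allele a1 is gamma = 4*Ne*s (gamma > 0
favours the focal state).  At stationarity the focal-allele frequency x has
density proportional to x^(theta01-1) (1-x)^(theta10-1) exp(gamma*x), and
the expected sample SFS at size n follows by binomial sampling:

    p_i  ∝  C(n,i) B(i+theta01, n-i+theta10) 1F1(i+theta01; n+theta01+theta10; gamma)

including the monomorphic classes i = 0 and i = n.

The one-step-expansion model starts from this equilibrium, multiplies the
population size by g (so the scaled parameters become g*theta01, g*theta10,
g*gamma), and evolves the allele-frequency distribution for tau time units
(units of 2*Ne_after generations) before sampling.  The solver evolves the
n+1 binomial sampling kernels under the backward diffusion operator
(Crank–Nicolson on a boundary-clustered Gauss–Jacobi grid) and integrates
them against the initial equilibrium density with Gauss–Jacobi quadrature,
whose weight function carries the boundary singularity exactly.

Model family: L1 (full: theta01, theta10, gamma, g, tau), L0 (equilibrium:
g = 1, tau dropped), NS (no selection: gamma = 0 with expansion), NS+L0.
Fitting maximises the multinomial log-likelihood by multi-start Nelder–Mead
on log-transformed positive parameters; nested models are compared with
chi-square likelihood-ratio tests using 2*(lnL_full - lnL_reduced).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_banded
from scipy.special import betaln, gammaln, hyp1f1, roots_jacobi

__all__ = [
    "SelectionParams",
    "ModelFit",
    "expected_sfs_equilibrium",
    "expected_sfs_expansion",
    "sfs_loglik",
    "fit_model",
    "lrt",
    "fit_binned",
]


@dataclass(frozen=True)
class SelectionParams:
    """Scaled parameters of the mutation–selection–drift model."""

    theta01: float
    theta10: float
    gamma: float = 0.0
    g: float = 1.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.theta01 <= 0 or self.theta10 <= 0:
            raise ValueError("theta01 and theta10 must be positive")
        if self.g <= 0:
            raise ValueError("g must be positive")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")

    @property
    def kappa(self) -> float:
        """Mutational bias away from the focal state: theta10 / theta01."""
        return self.theta10 / self.theta01

    def rescaled(self) -> "SelectionParams":
        """Parameters after the population-size change (multiplied by g)."""
        return SelectionParams(
            theta01=self.g * self.theta01,
            theta10=self.g * self.theta10,
            gamma=self.g * self.gamma,
            g=1.0,
            tau=0.0,
        )


def _log_binom(n: int) -> np.ndarray:
    i = np.arange(n + 1)
    return gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)


def expected_sfs_equilibrium(params: SelectionParams, n: int) -> np.ndarray:
    """Expected SFS probabilities p_0..p_n at mutation–selection–drift
    equilibrium (closed form; g and tau are ignored)."""
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    t01, t10, gam = params.theta01, params.theta10, params.gamma
    i = np.arange(n + 1)
    m = hyp1f1(i + t01, n + t01 + t10, gam)
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise FloatingPointError(
            f"hypergeometric evaluation failed for params {params!r}, n={n}"
        )
    ln = _log_binom(n) + betaln(i + t01, n - i + t10) + np.log(m)
    ln -= ln.max()
    p = np.exp(ln)
    return p / p.sum()


@lru_cache(maxsize=512)
def _gauss_jacobi01(K: int, alpha: float, beta: float):
    """Gauss–Jacobi nodes/weights mapped to (0,1) for weight
    x^beta (1-x)^alpha (up to a constant)."""
    t, w = roots_jacobi(K, alpha, beta)
    return (1.0 + t) / 2.0, w


def expected_sfs_expansion(
    params: SelectionParams,
    n: int,
    grid_points: int = 200,
    dt_max: float = 0.02,
) -> np.ndarray:
    """Expected SFS under the one-step-expansion model.

    g = 1 (or tau = 0) reduces analytically to the equilibrium spectrum.  The
    numerical scheme is validated in the test suite against an independent
    Wright–Fisher binomial-transition-matrix computation.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if params.g == 1.0:
        return expected_sfs_equilibrium(params, n)
    if params.tau == 0.0:
        return expected_sfs_equilibrium(params, n)
    t01, t10, gam = params.theta01, params.theta10, params.gamma
    x, w = _gauss_jacobi01(grid_points, t10 - 1.0, t01 - 1.0)
    # quadrature against the initial equilibrium density
    W = w * np.exp(gam * x)
    W /= W.sum()

    # finite-difference grid: quadrature nodes plus the boundary points
    xg = np.concatenate(([0.0], x, [1.0]))
    m = xg.size
    rs = params.rescaled()
    V = 0.5 * xg * (1.0 - xg)
    M = 0.5 * (rs.gamma * xg * (1.0 - xg) + rs.theta01 * (1.0 - xg) - rs.theta10 * xg)
    lo = np.zeros(m)
    di = np.zeros(m)
    up = np.zeros(m)
    hm = xg[1:-1] - xg[:-2]
    hp = xg[2:] - xg[1:-1]
    c2m = 2.0 / (hm * (hm + hp))
    c2p = 2.0 / (hp * (hm + hp))
    c2c = -2.0 / (hm * hp)
    c1m = -hp / (hm * (hm + hp))
    c1p = hm / (hp * (hm + hp))
    c1c = (hp - hm) / (hm * hp)
    Vi, Mi = V[1:-1], M[1:-1]
    # first-order upwinding where advection dominates the cell (keeps the
    # scheme monotone near the boundaries, where V -> 0)
    peclet = np.abs(Mi) * np.maximum(hm, hp) / np.maximum(Vi, 1e-300)
    upwind = peclet > 2.0
    pos = Mi > 0
    lo[1:-1] = np.where(upwind, Vi * c2m + np.where(pos, 0.0, -Mi / hm), Vi * c2m + Mi * c1m)
    di[1:-1] = np.where(
        upwind, Vi * c2c + np.where(pos, -Mi / hp, Mi / hm), Vi * c2c + Mi * c1c
    )
    up[1:-1] = np.where(upwind, Vi * c2p + np.where(pos, Mi / hp, 0.0), Vi * c2p + Mi * c1p)
    # boundary rows: pure (inward) drift, one-sided difference
    di[0] = -M[0] / (xg[1] - xg[0])
    up[0] = M[0] / (xg[1] - xg[0])
    di[-1] = M[-1] / (xg[-1] - xg[-2])
    lo[-1] = -M[-1] / (xg[-1] - xg[-2])

    # initial data: the n+1 binomial sampling kernels
    i = np.arange(n + 1)
    with np.errstate(divide="ignore"):
        lnk = (
            _log_binom(n)[:, None]
            + i[:, None] * np.log(np.maximum(xg, 1e-300))[None, :]
            + (n - i)[:, None] * np.log(np.maximum(1.0 - xg, 1e-300))[None, :]
        )
    U = np.exp(lnk)
    U[:, 0] = 0.0
    U[0, 0] = 1.0
    U[:, -1] = 0.0
    U[n, -1] = 1.0
    U = np.ascontiguousarray(U.T)  # (m, n+1)

    steps = max(16, int(np.ceil(params.tau / dt_max)))
    dt = params.tau / steps
    ab = np.zeros((3, m))
    ab[0, 1:] = -0.5 * dt * up[:-1]
    ab[1, :] = 1.0 - 0.5 * dt * di
    ab[2, :-1] = -0.5 * dt * lo[1:]
    for _ in range(steps):
        rhs = U.copy()
        rhs[1:-1] += 0.5 * dt * (
            lo[1:-1, None] * U[:-2] + di[1:-1, None] * U[1:-1] + up[1:-1, None] * U[2:]
        )
        rhs[0] += 0.5 * dt * (di[0] * U[0] + up[0] * U[1])
        rhs[-1] += 0.5 * dt * (lo[-1] * U[-2] + di[-1] * U[-1])
        U = solve_banded((1, 1), ab, rhs)
    if not np.all(np.isfinite(U)):
        raise FloatingPointError(
            f"non-convergent diffusion solve for params {params!r}"
        )
    p = U[1:-1].T @ W
    p = np.maximum(p, 0.0)
    return p / p.sum()


def expected_sfs(params: SelectionParams, n: int, **kw) -> np.ndarray:
    """Dispatch: equilibrium when g = 1, else the expansion solver."""
    if params.g == 1.0 or params.tau == 0.0:
        return expected_sfs_equilibrium(params, n)
    return expected_sfs_expansion(params, n, **kw)


def sfs_loglik(counts, p, likelihood: str = "multinomial") -> float:
    """Log-likelihood of SFS counts under class probabilities ``p``.

    Multinomial (default): sum_i c_i ln p_i (data-only constant dropped).
    Poisson: independent Poisson classes with means T*p_i, T = total sites.
    Returns -inf when some class with observations has zero probability.
    """
    c = np.asarray(getattr(counts, "counts", counts), dtype=float)
    p = np.asarray(p, dtype=float)
    if c.shape != p.shape:
        raise ValueError("counts and probabilities have different lengths")
    pos = c > 0
    if np.any(p[pos] <= 0):
        return float("-inf")
    ll = float(np.sum(c[pos] * np.log(p[pos])))
    if likelihood == "poisson":
        T = c.sum()
        lam = T * p
        ll = float(np.sum(c[pos] * np.log(lam[pos])) - lam.sum())
    return ll


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

_MODEL_FREE = {
    "L1": ("theta01", "theta10", "gamma", "g", "tau"),
    "L0": ("theta01", "theta10", "gamma"),
    "NS": ("theta01", "theta10", "g", "tau"),
    "NS+L0": ("theta01", "theta10"),
}

DEFAULT_BOUNDS = {
    "theta01": (1e-4, 0.2),
    "theta10": (1e-4, 0.2),
    "gamma": (-10.0, 10.0),
    "g": (0.02, 50.0),
    "tau": (1e-3, 5.0),
}

_START_RANGES = {
    "theta01": (1e-3, 0.05),
    "theta10": (1e-3, 0.05),
    "gamma": (-4.0, 4.0),
    "g": (0.2, 30.0),
    "tau": (0.005, 2.0),
}

_LOG_PARAMS = {"theta01", "theta10", "g", "tau"}


@dataclass
class ModelFit:
    model: str
    loglik: float
    params: SelectionParams
    n_starts: int
    seed: int | None
    starts: list[dict] = field(default_factory=list)
    converged: bool = True

    @property
    def free_parameters(self) -> int:
        return len(_MODEL_FREE[self.model])


def _pack(values: dict, names) -> np.ndarray:
    return np.array(
        [np.log(values[k]) if k in _LOG_PARAMS else values[k] for k in names]
    )


def _unpack(z: np.ndarray, names, fixed: dict) -> dict:
    out = dict(fixed)
    for k, v in zip(names, z):
        out[k] = float(np.exp(v)) if k in _LOG_PARAMS else float(v)
    return out


def _params_from(values: dict, model: str) -> SelectionParams:
    base = dict(values)
    if model in ("L0", "NS+L0"):
        base.setdefault("g", 1.0)
        base.setdefault("tau", 0.0)
        base["g"], base["tau"] = 1.0, 0.0
    if model in ("NS", "NS+L0"):
        base["gamma"] = 0.0
    return SelectionParams(
        theta01=base["theta01"],
        theta10=base["theta10"],
        gamma=base.get("gamma", 0.0),
        g=base.get("g", 1.0),
        tau=base.get("tau", 0.0),
    )


def fit_model(
    sfs,
    model: str = "L1",
    n_starts: int = 50,
    seed: int | None = None,
    bounds: dict | None = None,
    fixed: dict | None = None,
    likelihood: str = "multinomial",
    solver_options: dict | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of an SFS model by multi-start Nelder–Mead.

    Positive parameters are optimised on a log scale; gamma is unconstrained
    within its bounds.  The first start of L1/NS is seeded from a fast
    equilibrium (L0) fit; the remaining starts are drawn log-uniformly from a
    seeded generator.  The runs are ranked and the best is re-polished with a
    tight tolerance.  ``fixed`` pins parameters (e.g. ``{"gamma": 0}``).
    """
    if model not in _MODEL_FREE:
        raise ValueError(f"unknown model {model!r}")
    counts = np.asarray(getattr(sfs, "counts", sfs), dtype=float)
    if counts.sum() <= 0:
        raise ValueError("empty SFS")
    n = counts.size - 1
    fixed = dict(fixed or {})
    names = tuple(k for k in _MODEL_FREE[model] if k not in fixed)
    if not names:
        raise ValueError("no free parameters")
    bnds = dict(DEFAULT_BOUNDS)
    bnds.update(bounds or {})
    lo = _pack({k: bnds[k][0] if k in _LOG_PARAMS else bnds[k][0] for k in names}, names)
    hi = _pack({k: bnds[k][1] if k in _LOG_PARAMS else bnds[k][1] for k in names}, names)
    total = counts.sum()
    so = solver_options or {}

    def objective(z: np.ndarray) -> float:
        zc = np.clip(z, lo, hi)
        penalty = float(np.sum((z - zc) ** 2)) * 1e3
        values = _unpack(zc, names, fixed)
        try:
            p = expected_sfs(_params_from(values, model), n, **so)
            ll = sfs_loglik(counts, p, likelihood=likelihood)
        except FloatingPointError:
            return 1e9
        if not np.isfinite(ll):
            return 1e9
        return -ll / total + penalty  # per-site scale keeps tolerances portable

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    # deterministic cascade start: equilibrium fit first, then expansion grid
    if model in ("L1", "NS") and "theta01" not in fixed:
        try:
            sub = fit_model(
                counts, model="L0" if model == "L1" else "NS+L0",
                n_starts=max(4, n_starts // 4), seed=seed, bounds=bounds,
                fixed={k: v for k, v in fixed.items() if k in ("theta01", "theta10", "gamma")},
                likelihood=likelihood,
            )
            base = dict(
                theta01=sub.params.theta01, theta10=sub.params.theta10,
                gamma=sub.params.gamma, g=1.5, tau=0.1,
            )
            for g0, tau0 in ((1.5, 0.1), (4.0, 0.05), (4.0, 0.5), (15.0, 0.02), (0.5, 0.5)):
                cand = dict(base, g=g0, tau=tau0)
                starts.append(np.clip(_pack({k: cand[k] for k in names}, names), lo, hi))
        except Exception:
            pass
    while len(starts) < n_starts:
        draw = {}
        for k in names:
            a, b = _START_RANGES[k]
            if k in _LOG_PARAMS:
                draw[k] = float(np.exp(rng.uniform(np.log(a), np.log(b))))
            else:
                draw[k] = float(rng.uniform(a, b))
        starts.append(np.clip(_pack(draw, names), lo, hi))
    starts = starts[:n_starts]

    records = []
    best = None
    for z0 in starts:
        res = optimize.minimize(
            objective, z0, method="Nelder-Mead",
            options=dict(maxiter=200 * len(names), xatol=1e-4, fatol=1e-9),
        )
        records.append(
            dict(z0=z0.tolist(), fun=float(res.fun), nit=int(res.nit),
                 success=bool(res.success))
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimisation starts failed")
    # tight polish of the winner
    best = optimize.minimize(
        objective, best.x, method="Nelder-Mead",
        options=dict(maxiter=600 * len(names), xatol=1e-6, fatol=1e-13),
    )
    values = _unpack(np.clip(best.x, lo, hi), names, fixed)
    params = _params_from(values, model)
    ll = sfs_loglik(counts, expected_sfs(params, n, **so), likelihood=likelihood)
    return ModelFit(
        model=model,
        loglik=float(ll),
        params=params,
        n_starts=n_starts,
        seed=seed,
        starts=records,
        converged=any(r["success"] for r in records) or best.success,
    )


def lrt(full: ModelFit | float, reduced: ModelFit | float, df: int) -> tuple[float, float]:
    """Likelihood-ratio test: chi2 = 2*(lnL_full - lnL_reduced), p from chi2(df)."""
    lf = full.loglik if isinstance(full, ModelFit) else float(full)
    lr = reduced.loglik if isinstance(reduced, ModelFit) else float(reduced)
    if lf < lr - 1e-9 * max(1.0, abs(lr)):
        raise ValueError(
            f"full-model lnL ({lf}) below reduced-model lnL ({lr}): "
            "optimizer failure"
        )
    chi2 = 2.0 * (lf - lr)
    return chi2, float(stats.chi2.sf(chi2, df))


def fit_binned(
    spectra,
    covariate,
    k: int = 4,
    model: str = "L1",
    n_boot: int = 200,
    seed: int | None = None,
    **fit_kw,
) -> pd.DataFrame:
    """Fit gamma in k equal-size bins of a per-gene covariate (Fop or rho).

    ``spectra`` is one SFSpectrum (or count vector) per gene, aligned with
    ``covariate``.  Genes are split at type-7 quantile boundaries, the
    spectra pooled within each bin, and the model fitted per bin.  The 95%
    confidence interval comes from a multinomial bootstrap over sites
    (``n_boot`` replicates, refitted from the point estimate).
    """
    cov = np.asarray(covariate, dtype=float)
    if len(spectra) != cov.size:
        raise ValueError("spectra and covariate lengths differ")
    if cov.size < k:
        raise ValueError("fewer genes than bins")
    if np.unique(cov).size == 1:
        raise ValueError("degenerate covariate: all values identical")
    edges = np.quantile(cov, np.linspace(0, 1, k + 1), method="linear")
    # ties at a boundary go to the lower bin
    labels = np.clip(np.searchsorted(edges[1:-1], cov, side="left"), 0, k - 1)
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(k):
        idx = np.where(labels == b)[0]
        pooled = None
        for i in idx:
            c = np.asarray(getattr(spectra[i], "counts", spectra[i]), dtype=float)
            pooled = c.copy() if pooled is None else pooled + c
        if pooled is None or pooled.sum() == 0 or np.count_nonzero(pooled[1:-1]) == 0:
            rows.append(dict(bin=b, n_genes=len(idx), gamma=np.nan,
                             gamma_lo=np.nan, gamma_hi=np.nan, loglik=np.nan))
            continue
        fit = fit_model(pooled, model=model, seed=int(rng.integers(2**31 - 1)), **fit_kw)
        gammas = []
        T = int(pooled.sum())
        p_hat = pooled / pooled.sum()
        for _ in range(n_boot):
            rep = rng.multinomial(T, p_hat).astype(float)
            warm = fit_model(
                rep, model=model, n_starts=1, seed=int(rng.integers(2**31 - 1)),
                fixed=None, **{k_: v for k_, v in fit_kw.items() if k_ != "n_starts"},
            )
            gammas.append(warm.params.gamma)
        lo_ci, hi_ci = (
            (float(np.quantile(gammas, 0.025)), float(np.quantile(gammas, 0.975)))
            if gammas
            else (np.nan, np.nan)
        )
        rows.append(
            dict(bin=b, n_genes=len(idx), gamma=fit.params.gamma,
                 gamma_lo=lo_ci, gamma_hi=hi_ci, loglik=fit.loglik)
        )
    return pd.DataFrame(rows)
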