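"""Posterior sampling, convergence diagnostics and summaries.

The sampler is Metropolis-within-Gibbs: site abundances move by log-scale
random walks (with prior-independence proposals mixed in at sites whose
occupancy is marginalized), detection and occupancy by logit-scale walks,
misidentification by a walk reflected into its prior support, and the
conjugate blocks of the N-mixture baseline by exact Gibbs draws.  Proposal
scales adapt during burn-in only and are frozen afterwards, so the retained
chain targets the exact posterior.

Default chain settings are three chains of 20,000 iterations, a burn-in of
10,000 and thinning by 5, retaining 6,000 draws in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .model import PriorSpec

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "InitializationError",
    "fit_iam",
    "fit_nmixture",
    "gelman_rubin",
    "summarize",
]


class InitializationError(RuntimeError):
    """No finite starting point found; carries the attempted states."""

    def __init__(self, message: str, attempts: list | None = None):
        super().__init__(message)
        self.attempts = attempts or []


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("chain counts, lengths and thinning must be positive")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain."""
        return -((self.n_iter - self.burn_in) // -self.thin)


@dataclass
class PosteriorDraws:
    """Retained draws, per chain: scalars are (chains, draws), site-level
    quantities (chains, draws, sites)."""

    scalars: dict[str, np.ndarray]
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    config: MCMCConfig | None = None

    def pooled(self, name: str) -> np.ndarray:
        return self.scalars[name].reshape(-1)

    def to_long_frame(self, include_sites: bool = False) -> pd.DataFrame:
        """Long (chain, iteration, parameter, value) table for export."""
        rows = []
        for name, arr in self.scalars.items():
            c, d = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "iteration": np.tile(np.arange(d), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        if include_sites:
            for name, arr in self.vectors.items():
                c, d, s = arr.shape
                for i in range(s):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": np.repeat(np.arange(c), d),
                                "iteration": np.tile(np.arange(d), c),
                                "parameter": f"{name}[{i}]",
                                "value": arr[:, :, i].reshape(-1),
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, equal-tailed CrI, width and R-hat."""

    table: pd.DataFrame
    level: float = 0.95

    def mean(self, name: str) -> float:
        return float(self.table.loc[name, "mean"])

    def cri(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["lower"]), float(row["upper"])

    def width(self, name: str) -> float:
        return float(self.table.loc[name, "width"])

    def rhat(self, name: str) -> float:
        return float(self.table.loc[name, "rhat"])

    def contains(self, name: str, value: float) -> bool:
        lo, hi = self.cri(name)
        return lo <= value <= hi


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is (n_chains, n_draws).  Computes
    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance and
    B the between-chain variance of chain means times n.  Returns NaN as a
    flagged sentinel when every chain has zero within-chain variance.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    n = arr.shape[1]
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(arr, axis=1), ddof=1))
    if W == 0.0:
        return float("nan")
    return math.sqrt(((n - 1) / n * W + B / n) / W)


def summarize(
    draws: PosteriorDraws, level: float = 0.95, include_sites: bool = False
) -> PosteriorSummary:
    """Pool chains and compute means, equal-tailed CrIs and R-hat."""
    if not draws.scalars:
        raise ValueError("no draws to summarize")
    alpha = (1.0 - level) / 2.0
    rows = {}

    def _row(name, arr2d):
        pooled = arr2d.reshape(-1)
        lo, hi = np.quantile(pooled, [alpha, 1.0 - alpha])
        rows[name] = {
            "mean": float(pooled.mean()),
            "lower": float(lo),
            "upper": float(hi),
            "width": float(hi - lo),
            "rhat": gelman_rubin(arr2d) if arr2d.shape[0] >= 2 else float("nan"),
        }

    for name, arr in draws.scalars.items():
        _row(name, arr)
    if include_sites:
        for name, arr in draws.vectors.items():
            for i in range(arr.shape[2]):
                _row(f"{name}[{i}]", arr[:, :, i])
    return PosteriorSummary(table=pd.DataFrame.from_dict(rows, orient="index"),
                            level=level)


def _cs_sufficient_stats(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site sum and count of observed replicate counts (NaN = missing)."""
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(y)
    S = np.where(obs, y, 0.0).sum(axis=1)
    R = obs.sum(axis=1).astype(float)
    return S, R


def fit_iam(
    data,
    mcmc: MCMCConfig | None = None,
    prior: PriorSpec | None = None,
    expert_variant: str = "poisson",
    k: float = 1.0,
    update: dict | None = None,
    init: dict | None = None,
) -> PosteriorDraws:
    """Sample the integrated-model posterior.

    ``data`` provides ``y`` (sites x replicates, NaN for missing), ``w`` and
    ``expert_mask``; at least one site must carry expert data.  ``update``
    can freeze parameter blocks (e.g. ``{"m": False}``) and ``init`` can pin
    their starting values — used for oracle cross-checks and conditional
    fits.  Chains start from overdispersed draws, except the site means,
    which start near max(w_i, mean_j y[i,j]/0.5, 1) for numerical stability.
    """
    mcmc = mcmc or MCMCConfig()
    prior = prior or PriorSpec()
    mask = np.asarray(data.expert_mask, dtype=bool)
    if not mask.any():
        raise ValueError("at least one expert site is required")
    y = np.asarray(data.y, dtype=float)
    if y.size == 0:
        raise ValueError("empty citizen-science matrix")
    S, R = _cs_sufficient_stats(y)
    n_sites = S.size
    w = np.where(mask, np.asarray(data.w, dtype=float), 0.0)
    z_exp = ((w > 0) & mask).astype(np.int64)
    variant = {"poisson": 0, "normal": 1}[expert_variant]
    if variant == 0 and np.any(w[mask] != np.floor(w[mask])):
        raise ValueError("Poisson expert layer requires integer expert counts")

    up = {"p": True, "omega": True, "m": True, "lam": True}
    if update:
        up.update(update)
    init = init or {}

    n_ret = mcmc.n_retained
    C = mcmc.n_chains
    out = {
        "p": np.empty((C, n_ret)),
        "omega": np.empty((C, n_ret)),
        "m": np.empty((C, n_ret)),
        "lam": np.empty((C, n_ret, n_sites)),
        "z": np.empty((C, n_ret, n_sites), dtype=np.int64),
    }

    lam_base = np.maximum.reduce(
        [w, np.nan_to_num(np.nanmean(y, axis=1)) / 0.5, np.ones(n_sites)]
    )
    for c in range(C):
        rng = np.random.default_rng((mcmc.seed + 7_919 * c) % 2**31)
        for attempt in range(20):
            p0 = float(init.get("p", rng.uniform(0.05, 0.95)))
            om0 = float(init.get("omega", rng.uniform(0.05, 0.95)))
            m0 = float(init.get("m", rng.uniform(0.1, prior.m_max - 0.1)))
            lam0 = np.asarray(
                init.get("lam", lam_base * np.exp(rng.normal(0.0, 0.2, n_sites))),
                dtype=float,
            ).copy()
            t0 = _kernels._iam_target(
                p0, om0, m0, lam0, S, R, w, mask, z_exp, variant, k,
                prior.variance_floor, prior.lam_shape, prior.lam_rate,
            )
            if t0 > -1.0e290:
                break
        else:
            raise InitializationError(
                "no finite starting point after 20 attempts",
                attempts=[{"p": p0, "omega": om0, "m": m0}],
            )
        _kernels.iam_chain(
            S, R, w, mask, z_exp, variant, k, prior.variance_floor,
            prior.m_max, prior.lam_shape, prior.lam_rate,
            mcmc.n_iter, mcmc.burn_in, mcmc.thin,
            (mcmc.seed + 104_729 * c + 1) % 2**31,
            p0, om0, m0, lam0,
            up["p"], up["omega"], up["m"], up["lam"],
            out["p"][c], out["omega"][c], out["m"][c],
            out["lam"][c], out["z"][c],
        )

    n_site = out["z"] * out["lam"]
    return PosteriorDraws(
        scalars={
            "omega": out["omega"],
            "p": out["p"],
            "m": out["m"],
            "N_total": n_site.sum(axis=2),
        },
        vectors={"lam": out["lam"], "z": out["z"].astype(float),
                 "N_site": n_site},
        config=mcmc,
    )


def fit_nmixture(
    y,
    mcmc: MCMCConfig | None = None,
    prior: PriorSpec | None = None,
) -> PosteriorDraws:
    """Sample the N-mixture baseline posterior from replicated counts."""
    mcmc = mcmc or MCMCConfig()
    prior = prior or PriorSpec()
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty count matrix")
    obs = ~np.isnan(y)
    y_int = np.where(obs, y, 0.0).astype(np.int64)
    n_sites = y.shape[0]

    n_ret = mcmc.n_retained
    C = mcmc.n_chains
    out_p = np.empty((C, n_ret))
    out_lamE = np.empty((C, n_ret))
    out_N = np.empty((C, n_ret, n_sites), dtype=np.int64)

    ymax = np.where(obs.any(axis=1), np.max(np.where(obs, y, 0.0), axis=1), 0.0)
    ymean = np.nan_to_num(np.nanmean(y, axis=1))
    for c in range(C):
        rng = np.random.default_rng((mcmc.seed + 7_919 * c) % 2**31)
        p0 = rng.uniform(0.1, 0.9)
        N0 = np.maximum(ymax, np.round(ymean / p0)).astype(np.int64)
        lamE0 = max(float(N0.mean()), 1.0)
        _kernels.nmix_chain(
            y_int, obs, prior.lam_shape, prior.lam_rate,
            mcmc.n_iter, mcmc.burn_in, mcmc.thin,
            (mcmc.seed + 104_729 * c + 1) % 2**31,
            p0, lamE0, N0,
            out_p[c], out_lamE[c], out_N[c],
        )

    return PosteriorDraws(
        scalars={
            "lambda_E": out_lamE,
            "p": out_p,
            "N_total": out_N.sum(axis=2).astype(float),
        },
        vectors={"N_site": out_N.astype(float)},
        config=mcmc,
    )
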