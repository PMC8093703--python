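"""Log-densities of the integrated abundance model and the N-mixture baseline.

Every density here is a pure function of arrays and scalars, composable into
the joint log-posterior.  The integrated model couples two observation layers
through shared latent site abundances N_i = z_i * lambda_i:

* citizen-science counts  y[i, j] ~ Poisson(N_i * p + m), where p is the
  detection probability (false negatives) and m the expected number of
  misidentified non-target individuals per site per replicate (false
  positives);
* expert counts           w_i ~ Poisson(N_i), or Normal(N_i, k * N_i) when a
  variance scaling k is wanted, available at a (possibly partial) subset of
  sites;
* occupancy               z_i ~ Bernoulli(Omega).

Where expert data exist they are taken to be correct at the level of
presence/absence, so z_i is fixed at 1(w_i > 0) on those sites.

The N-mixture baseline is the classical binomial-Poisson mixture with
integer latent abundances and no false-positive term; it is included to
quantify the inflation false positives induce when ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, xlogy

__all__ = [
    "IAMParams",
    "PriorSpec",
    "NMixtureParams",
    "cs_loglik",
    "expert_loglik_poisson",
    "expert_loglik_normal",
    "occupancy_logdensity",
    "joint_logposterior",
    "nmixture_logposterior",
]

_NEG_INF = -np.inf


@dataclass(frozen=True)
class PriorSpec:
    """Broad priors: U(0,1) on p and Omega, U(0, m_max) on m, Gamma on lambda.

    The Gamma prior uses the shape/rate convention (mean = shape / rate).
    ``variance_floor`` keeps the Normal expert density proper at sites with
    N_i = 0, standing in for the "small variance at unoccupied sites" device.
    """

    m_max: float = 40.0
    lam_shape: float = 1.0
    lam_rate: float = 0.005
    variance_floor: float = 0.01

    def __post_init__(self) -> None:
        if min(self.m_max, self.lam_shape, self.lam_rate, self.variance_floor) <= 0:
            raise ValueError("all prior hyperparameters must be positive")


@dataclass(frozen=True)
class IAMParams:
    """One point in IAM parameter space; k is a fixed model input."""

    omega: float
    p: float
    m: float
    lam: np.ndarray
    z: np.ndarray
    k: float = 1.0

    @property
    def N(self) -> np.ndarray:
        return self.z * self.lam


@dataclass(frozen=True)
class NMixtureParams:
    """N-mixture state: common abundance mean, detection, integer latents."""

    lambda_E: float
    p: float
    N: np.ndarray


def _poisson_logpmf_sum(x: np.ndarray, mu: np.ndarray) -> float:
    """Sum of Poisson log-pmfs, exact at mu = 0 (mass 1 at x = 0)."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((mu == 0) & (x > 0)):
        return _NEG_INF
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(x, mu) - mu - gammaln(x + 1.0)
    return float(np.sum(terms))


def cs_loglik(y: np.ndarray, N: np.ndarray, p: float, m: float) -> float:
    """Log-likelihood of the citizen-science layer.

    ``y`` is sites x replicates; NaN entries are treated as missing and
    contribute nothing.  Returns -inf if any observed count is positive at a
    site whose expected rate N_i*p + m is exactly zero.
    """
    y = np.asarray(y, dtype=float)
    N = np.asarray(N, dtype=float)
    if y.ndim != 2 or y.shape[0] != N.shape[0]:
        raise ValueError(
            f"y has shape {y.shape} but N has {N.shape[0]} sites"
        )
    mu = N * p + m
    if np.any(mu < 0):
        raise ValueError("negative expected count; check p and m")
    obs = ~np.isnan(y)
    mu_full = np.broadcast_to(mu[:, None], y.shape)
    return _poisson_logpmf_sum(y[obs], mu_full[obs])


def expert_loglik_poisson(w: np.ndarray, mask: np.ndarray, N: np.ndarray) -> float:
    """Poisson expert layer, summed over masked-in sites.

    Under this layer an expert zero at an occupied site is impossible
    (-inf), encoding presence/absence accuracy of expert data.
    """
    w = np.asarray(w, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    N = np.asarray(N, dtype=float)
    wi = w[mask]
    if np.any(wi != np.floor(wi)):
        raise ValueError("Poisson expert layer requires integer counts")
    return _poisson_logpmf_sum(wi, N[mask])


def expert_loglik_normal(
    w: np.ndarray,
    mask: np.ndarray,
    N: np.ndarray,
    k: float,
    variance_floor: float = 0.01,
) -> float:
    """Normal expert layer with variance max(k * N_i, variance_floor)."""
    if k <= 0:
        raise ValueError("k must be positive for the Normal expert layer")
    if variance_floor <= 0:
        raise ValueError("variance_floor must be positive")
    w = np.asarray(w, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    N = np.asarray(N, dtype=float)
    var = np.maximum(k * N[mask], variance_floor)
    return float(np.sum(stats.norm.logpdf(w[mask], loc=N[mask], scale=np.sqrt(var))))


def occupancy_logdensity(z: np.ndarray, omega: float) -> float:
    """Bernoulli occupancy log-density with the 0*log(0) convention."""
    z = np.asarray(z, dtype=float)
    if np.any((z != 0) & (z != 1)):
        raise ValueError("z must be binary")
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        val = xlogy(z, omega) + xlogy(1.0 - z, 1.0 - omega)
    return float(np.sum(val))


def _log_prior(params: IAMParams, prior: PriorSpec) -> float:
    if not (0.0 <= params.p <= 1.0 and 0.0 <= params.omega <= 1.0):
        return _NEG_INF
    if not 0.0 <= params.m <= prior.m_max:
        return _NEG_INF
    lam = np.asarray(params.lam, dtype=float)
    if np.any(lam <= 0):
        return _NEG_INF
    # U(0,1) and U(0, m_max) contribute constants; keep only the Gamma terms.
    lp = float(
        np.sum(
            (prior.lam_shape - 1.0) * np.log(lam)
            - prior.lam_rate * lam
        )
    )
    return lp - np.log(prior.m_max)


def joint_logposterior(
    params: IAMParams,
    data,
    prior: PriorSpec | None = None,
    expert_variant: str = "poisson",
) -> float:
    """Joint log-posterior of the integrated model (up to a constant).

    ``data`` needs attributes ``y``, ``w`` and ``expert_mask`` (a simulated
    dataset or any duck-typed equivalent).  The four additive components are
    the citizen-science likelihood, the expert likelihood, the Bernoulli
    occupancy density and the log-priors.  z is fixed by expert consensus
    where expert data exist: a z inconsistent with 1(w_i > 0) is outside the
    model's support and yields -inf.
    """
    if prior is None:
        prior = PriorSpec()
    mask = np.asarray(data.expert_mask, dtype=bool)
    if not mask.any():
        raise ValueError(
            "no expert sites: misidentification is unidentifiable without "
            "overlap between expert and citizen-science data"
        )
    lp = _log_prior(params, prior)
    if not np.isfinite(lp):
        return _NEG_INF
    z = np.asarray(params.z)
    w = np.asarray(data.w, dtype=float)
    if np.any(z[mask] != (w[mask] > 0).astype(z.dtype)):
        return _NEG_INF
    N = params.N
    ll_cs = cs_loglik(data.y, N, params.p, params.m)
    if expert_variant == "poisson":
        ll_w = expert_loglik_poisson(w, mask, N)
    elif expert_variant == "normal":
        ll_w = expert_loglik_normal(w, mask, N, params.k, prior.variance_floor)
    else:
        raise ValueError(f"unknown expert variant {expert_variant!r}")
    ll_z = occupancy_logdensity(z, params.omega)
    return ll_cs + ll_w + ll_z + lp


def nmixture_logposterior(
    params: NMixtureParams,
    y: np.ndarray,
    prior: PriorSpec | None = None,
) -> float:
    """Log-posterior of the binomial-Poisson N-mixture baseline.

    Latent abundances are integer; any N_i below the site's largest observed
    count has zero posterior mass (-inf), not an exception.
    """
    if prior is None:
        prior = PriorSpec()
    y = np.asarray(y, dtype=float)
    N = np.asarray(params.N, dtype=np.int64)
    if params.lambda_E <= 0 or not 0.0 <= params.p <= 1.0 or np.any(N < 0):
        return _NEG_INF
    obs = ~np.isnan(y)
    ymax = np.where(obs.any(axis=1), np.nanmax(np.where(obs, y, 0.0), axis=1), 0.0)
    if np.any(N < ymax):
        return _NEG_INF
    Nf = N.astype(float)
    Nb = np.broadcast_to(Nf[:, None], y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        binom_terms = (
            gammaln(Nb + 1.0)
            - gammaln(y + 1.0)
            - gammaln(Nb - y + 1.0)
            + xlogy(y, params.p)
            + xlogy(Nb - y, 1.0 - params.p)
        )
    ll = float(np.sum(binom_terms[obs]))
    if not np.isfinite(ll):
        return _NEG_INF
    ll += _poisson_logpmf_sum(Nf, np.full_like(Nf, params.lambda_E))
    lp = (
        (prior.lam_shape - 1.0) * np.log(params.lambda_E)
        - prior.lam_rate * params.lambda_E
    )
    return ll + lp
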