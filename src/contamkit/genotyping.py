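"""Contamination-aware genotype and SNP calling from read-count quartets.

The likelihood of a quartet R = (r_A, r_C, r_G, r_T) for a diploid
individual at a position with population allele frequencies f is a
multinomial mixture over the 10 unordered diploid genotypes {y, z} with
Hardy-Weinberg prior weights:

    Pr(R) = sum_{y<=z} w_yz * C(r; r_A..r_T) * prod_x q_x[yz]^{r_x}

where w_yy = f_y^2 and w_yz = 2 f_y f_z (the heterozygote factor 2 can be
switched off), and q_x[yz] is the per-read probability of observing state
x.  With contamination probability gamma, a read originates from the focal
genotype with probability (1 - gamma) and from the pool of the *other*
individuals' reads with probability gamma:

    q_x[yz] = (1 - gamma) * [ (E[y, x] + E[z, x]) / 2 ]
              + gamma * sum_w f'_w E[w, x]

where f'_w is the read frequency of state w at the position excluding the
focal individual, and E is the per-read error matrix: E[a, a] =
1 - (eps_ts + 2 eps_tv), E[a, b] = eps_ts for transitions, eps_tv for
transversions.  With a single error rate this is exactly the classical
model extended by the contaminant term, and gamma = 0 recovers the
uncontaminated model bit-for-bit.

Error rates are estimated by bounded maximum likelihood; gamma is selected
on a small grid by profile likelihood (ties resolved toward the smaller,
more parsimonious value).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .quartets import BASE_INDEX

logger = logging.getLogger(__name__)

#: The 10 unordered diploid genotypes as allele-index pairs, y <= z.
GENOTYPES: tuple[tuple[int, int], ...] = tuple(
    (y, z) for y in range(4) for z in range(y, 4)
)

_TS_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T

DEFAULT_GAMMA_GRID: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2)

try:  # optional JIT for the likelihood kernel
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is present in CI images
    _HAVE_NUMBA = False


def error_rate_matrix(eps_ts: float, eps_tv: float) -> np.ndarray:
    """Per-read 4x4 error matrix E[a, b] = P(read called b | true state a)."""
    if eps_ts < 0 or eps_tv < 0 or eps_ts + 2 * eps_tv >= 1:
        raise ValueError("need eps >= 0 and eps_ts + 2*eps_tv < 1")
    E = np.full((4, 4), eps_tv)
    for a in range(4):
        E[a, a] = 1.0 - (eps_ts + 2 * eps_tv)
        E[a, _TS_PARTNER[a]] = eps_ts
    return E


@dataclass
class GenotypeModel:
    """Parameters of the contamination-aware read-count model at one site.

    ``f`` sums to 1; ``f_prime`` (read frequencies excluding the focal
    individual) sums to 1 when defined, or is None when gamma = 0 or no
    non-focal reads exist (the model then falls back to gamma = 0).
    """

    f: np.ndarray
    eps_ts: float
    eps_tv: float
    gamma: float = 0.0
    f_prime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if not np.isclose(self.f.sum(), 1.0):
            raise ValueError("allele frequencies must sum to 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.f_prime is not None:
            self.f_prime = np.asarray(self.f_prime, dtype=float)
        error_rate_matrix(self.eps_ts, self.eps_tv)  # validates rates


def read_state_probs(
    genotype: tuple[int, int] | str, model: GenotypeModel
) -> np.ndarray:
    """Per-read probability vector over A, C, G, T for a given genotype.

    ``genotype`` is an index pair or a two-letter string like ``"AC"``.
    The vector sums to 1 for any valid model.  With gamma > 0 but no
    defined non-focal read frequencies the contaminant term is dropped
    (gamma = 0 fallback).
    """
    if isinstance(genotype, str):
        genotype = (BASE_INDEX[genotype[0]], BASE_INDEX[genotype[1]])
    y, z = genotype
    E = error_rate_matrix(model.eps_ts, model.eps_tv)
    own = 0.5 * (E[y] + E[z])
    gamma = model.gamma
    if gamma == 0.0:
        return own
    if model.f_prime is None or model.f_prime.sum() <= 0:
        logger.debug("gamma > 0 with no non-focal reads: gamma=0 fallback")
        return own
    fp = model.f_prime / model.f_prime.sum()
    contam = fp @ E
    return (1.0 - gamma) * own + gamma * contam


def quartet_likelihood(
    quartet, model: GenotypeModel, het_factor: bool = True
) -> float:
    """Mixture likelihood of one quartet (sums the 10 diploid genotypes)."""
    r = np.asarray(
        quartet.counts if hasattr(quartet, "counts") else quartet, dtype=np.int64
    )
    total = 0.0
    coeff = np.exp(gammaln(r.sum() + 1) - gammaln(r + 1).sum())
    for y, z in GENOTYPES:
        w = model.f[y] * model.f[z]
        if y != z and het_factor:
            w *= 2.0
        if w == 0.0:
            continue
        q = read_state_probs((y, z), model)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(r > 0, r * np.log(np.where(q > 0, q, 1.0)), 0.0)
        if np.any((r > 0) & (q == 0)):
            continue
        total += w * coeff * np.exp(term.sum())
    return float(total)


# ---------------------------------------------------------------------------
# vectorized site-level machinery


def pooled_frequencies(counts: np.ndarray) -> np.ndarray:
    """Per-position allele frequencies f from pooled read counts (P, N, 4).

    Zero-coverage positions get a uniform vector (they contribute nothing to
    the likelihood anyway).
    """
    tot = counts.sum(axis=1).astype(float)  # (P, 4)
    denom = tot.sum(axis=1, keepdims=True)
    f = np.where(denom > 0, tot / np.where(denom > 0, denom, 1.0), 0.25)
    return f


def nonfocal_frequencies(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Read frequencies excluding the focal individual, per (P, N).

    Returns ``(f_prime, defined)`` where ``defined`` marks quartets with at
    least one non-focal read; undefined rows hold a uniform placeholder and
    are handled by the gamma = 0 fallback.
    """
    other = counts.sum(axis=1, keepdims=True) - counts  # (P, N, 4)
    tot = other.sum(axis=2, keepdims=True).astype(float)
    defined = tot[..., 0] > 0
    fp = np.where(tot > 0, other / np.where(tot > 0, tot, 1.0), 0.25)
    return fp, defined


def genotype_prior(f: np.ndarray, het_factor: bool = True) -> np.ndarray:
    """Hardy-Weinberg prior weights over the 10 genotypes, per position."""
    ys = np.array([g[0] for g in GENOTYPES])
    zs = np.array([g[1] for g in GENOTYPES])
    w = f[:, ys] * f[:, zs]
    if het_factor:
        w[:, ys != zs] *= 2.0
    return w


def _per_read_probs(
    eps_ts: float,
    eps_tv: float,
    gamma: float,
    f_prime: np.ndarray,
    fp_defined: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Own-genotype (10, 4) and contaminant-mixture (P, N, 10, 4) pieces.

    Returns ``(own, q)`` where q is None at gamma = 0 (own applies
    everywhere).
    """
    E = error_rate_matrix(eps_ts, eps_tv)
    ys = np.array([g[0] for g in GENOTYPES])
    zs = np.array([g[1] for g in GENOTYPES])
    own = 0.5 * (E[ys] + E[zs])  # (10, 4)
    if gamma == 0.0:
        return own, None
    contam = f_prime @ E  # (P, N, 4)
    q = (1.0 - gamma) * own[None, None] + gamma * contam[:, :, None, :]
    # quartets with no non-focal reads: fall back to the gamma = 0 model
    q = np.where(fp_defined[:, :, None, None], q, own[None, None])
    return own, q


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _loglik_kernel(counts, log_w, own, contam, use_contam, gamma):  # pragma: no cover
        P, N, _ = counts.shape
        G = own.shape[0]
        total = 0.0
        per_quartet = np.empty((P, N))
        for p in range(P):
            for n in range(N):
                best = -1e308
                terms = np.empty(G)
                for g in range(G):
                    lw = log_w[p, g]
                    if lw == -np.inf:
                        terms[g] = -np.inf
                        continue
                    s = lw
                    for x in range(4):
                        c = counts[p, n, x]
                        if c == 0:
                            continue
                        if use_contam and contam[p, n, 0] >= 0.0:
                            q = (1.0 - gamma) * own[g, x] + gamma * contam[p, n, x]
                        else:
                            q = own[g, x]
                        if q <= 0.0:
                            s = -np.inf
                            break
                        s += c * np.log(q)
                    terms[g] = s
                    if s > best:
                        best = s
                if best == -1e308 or best == -np.inf:
                    per_quartet[p, n] = -np.inf
                    continue
                acc = 0.0
                for g in range(G):
                    if terms[g] > -np.inf:
                        acc += np.exp(terms[g] - best)
                per_quartet[p, n] = best + np.log(acc)
                total += per_quartet[p, n]
        return total, per_quartet


def site_loglikelihood(
    counts: np.ndarray,
    f: np.ndarray,
    eps_ts: float,
    eps_tv: float,
    gamma: float = 0.0,
    f_prime: np.ndarray | None = None,
    fp_defined: np.ndarray | None = None,
    het_factor: bool = True,
    include_coeff: bool = True,
    return_per_quartet: bool = False,
):
    """Total log-likelihood of a (P, N, 4) count array.

    The multinomial coefficient is a parameter-independent constant; it is
    included by default so likelihoods are proper, and can be dropped
    during optimization.
    """
    counts = np.asarray(counts, dtype=np.int64)
    P, N, _ = counts.shape
    w = genotype_prior(f, het_factor=het_factor)
    with np.errstate(divide="ignore"):
        log_w = np.log(w)
    if gamma > 0.0 and f_prime is None:
        f_prime, fp_defined = nonfocal_frequencies(counts)
    if _HAVE_NUMBA:
        if gamma > 0.0:
            E = error_rate_matrix(eps_ts, eps_tv)
            contam = np.ascontiguousarray(f_prime @ E)
            # mark undefined rows with a negative sentinel in slot 0
            contam = np.where(fp_defined[:, :, None], contam, -1.0)
            use_contam = True
        else:
            contam = np.zeros((P, N, 4))
            use_contam = False
        ys = np.array([g[0] for g in GENOTYPES])
        zs = np.array([g[1] for g in GENOTYPES])
        E = error_rate_matrix(eps_ts, eps_tv)
        own = np.ascontiguousarray(0.5 * (E[ys] + E[zs]))
        total, per_quartet = _loglik_kernel(
            counts.astype(np.int64),
            np.ascontiguousarray(log_w),
            own,
            contam,
            use_contam,
            gamma,
        )
    else:
        own, q = _per_read_probs(eps_ts, eps_tv, gamma, f_prime, fp_defined) if gamma > 0 else (
            _per_read_probs(eps_ts, eps_tv, 0.0, None, None)
        )
        if q is None:
            with np.errstate(divide="ignore"):
                log_q = np.log(own)  # (10, 4)
            ll_g = np.einsum("pnx,gx->png", counts, np.nan_to_num(log_q, neginf=-1e30))
            ll_g = np.where(ll_g < -1e20, -np.inf, ll_g)
        else:
            with np.errstate(divide="ignore"):
                log_q = np.log(q)
            ll_g = np.einsum("pnx,pngx->png", counts, np.nan_to_num(log_q, neginf=-1e30))
            ll_g = np.where(ll_g < -1e20, -np.inf, ll_g)
        ll_g = ll_g + log_w[:, None, :]
        per_quartet = logsumexp(ll_g, axis=2)
        total = float(per_quartet.sum())
    if include_coeff:
        coeff = gammaln(counts.sum(axis=2) + 1) - gammaln(counts + 1).sum(axis=2)
        per_quartet = per_quartet + coeff
        total = float(per_quartet.sum())
    if return_per_quartet:
        return total, per_quartet
    return total


@dataclass
class ErrorRateFit:
    eps_ts: float
    eps_tv: float
    loglik: float
    converged: bool
    at_boundary: bool


def estimate_error_rates(
    counts: np.ndarray,
    f: np.ndarray | None = None,
    gamma: float = 0.0,
    het_factor: bool = True,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.2), (0.0, 0.2)),
    starts: tuple[tuple[float, float], ...] = ((1e-3, 1e-3), (5e-3, 2e-3), (2e-2, 1e-2)),
    tol: float = 1e-8,
) -> ErrorRateFit:
    """Maximum-likelihood (eps_ts, eps_tv) with f fixed from pooled reads.

    Bounded L-BFGS-B from three deterministic starting points; returns the
    best fit with its log-likelihood (multinomial coefficient included so
    values are comparable across gamma).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if f is None:
        f = pooled_frequencies(counts)
    f_prime = fp_defined = None
    if gamma > 0.0:
        f_prime, fp_defined = nonfocal_frequencies(counts)
    const_coeff = float(
        (gammaln(counts.sum(axis=2) + 1) - gammaln(counts + 1).sum(axis=2)).sum()
    )

    def neg_loglik(theta: np.ndarray) -> float:
        ll = site_loglikelihood(
            counts,
            f,
            float(theta[0]),
            float(theta[1]),
            gamma=gamma,
            f_prime=f_prime,
            fp_defined=fp_defined,
            het_factor=het_factor,
            include_coeff=False,
        )
        return -ll

    best = None
    for x0 in starts:
        res = minimize(
            neg_loglik,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    eps_ts, eps_tv = (float(v) for v in best.x)
    at_boundary = eps_ts <= bounds[0][0] + 1e-12 or eps_tv <= bounds[1][0] + 1e-12
    if at_boundary:
        logger.info("error-rate estimate at boundary: eps_ts=%g eps_tv=%g", eps_ts, eps_tv)
    return ErrorRateFit(
        eps_ts=eps_ts,
        eps_tv=eps_tv,
        loglik=-float(best.fun) + const_coeff,
        converged=bool(best.success),
        at_boundary=at_boundary,
    )


@dataclass
class GenotypeCallSet:
    """Genotype calls over a (P, N) grid.

    ``calls`` is (P, N, 2) allele indices (sorted), -1 for no-call;
    ``posterior`` the winning genotype's posterior probability;
    ``snp_positions`` the positions with >= 2 distinct alleles among
    called genotypes.
    """

    calls: np.ndarray
    posterior: np.ndarray
    snp_positions: np.ndarray
    individuals: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return int(len(self.snp_positions))


def call_genotypes(
    counts: np.ndarray,
    gamma: float = 0.0,
    eps_ts: float | None = None,
    eps_tv: float | None = None,
    posterior_threshold: float = 0.95,
    het_factor: bool = True,
    individuals: list[str] | None = None,
) -> GenotypeCallSet:
    """Posterior genotype calls for every quartet of a (P, N, 4) array.

    When error rates are not supplied they are first estimated by maximum
    likelihood at the given gamma.  A quartet is called iff its maximum
    genotype posterior reaches ``posterior_threshold``; zero-coverage
    quartets are never called.
    """
    counts = np.asarray(counts, dtype=np.int64)
    P, N, _ = counts.shape
    f = pooled_frequencies(counts)
    if eps_ts is None or eps_tv is None:
        fit = estimate_error_rates(counts, f=f, gamma=gamma, het_factor=het_factor)
        eps_ts, eps_tv = fit.eps_ts, fit.eps_tv
    f_prime = fp_defined = None
    if gamma > 0.0:
        f_prime, fp_defined = nonfocal_frequencies(counts)
    w = genotype_prior(f, het_factor=het_factor)
    with np.errstate(divide="ignore"):
        log_w = np.log(w)
    own, q = _per_read_probs(
        eps_ts, eps_tv, gamma, f_prime, fp_defined
    ) if gamma > 0 else _per_read_probs(eps_ts, eps_tv, 0.0, None, None)
    with np.errstate(divide="ignore"):
        if q is None:
            log_q = np.log(own)
            ll_g = np.einsum("pnx,gx->png", counts, np.nan_to_num(log_q, neginf=-1e30))
        else:
            log_q = np.log(q)
            ll_g = np.einsum("pnx,pngx->png", counts, np.nan_to_num(log_q, neginf=-1e30))
    ll_g = np.where(ll_g < -1e20, -np.inf, ll_g) + log_w[:, None, :]
    norm = logsumexp(ll_g, axis=2, keepdims=True)
    post = np.exp(ll_g - norm)  # (P, N, 10)
    best_g = post.argmax(axis=2)
    best_p = np.take_along_axis(post, best_g[..., None], axis=2)[..., 0]
    geno = np.asarray(GENOTYPES)[best_g]  # (P, N, 2)
    covered = counts.sum(axis=2) > 0
    ok = covered & (best_p >= posterior_threshold)
    calls = np.where(ok[..., None], geno, -1)
    posterior = np.where(ok, best_p, np.nan)
    snp = []
    for p in range(P):
        alleles = set(calls[p][calls[p][:, 0] >= 0].ravel().tolist())
        if len(alleles) >= 2:
            snp.append(p)
    return GenotypeCallSet(
        calls=calls,
        posterior=posterior,
        snp_positions=np.asarray(snp, dtype=np.int64),
        individuals=individuals or [f"ind{i + 1}" for i in range(N)],
    )


@dataclass
class GammaSelection:
    gamma_star: float
    profile: dict[float, float]
    fits: dict[float, ErrorRateFit]
    tie: bool = False


def select_gamma(
    counts: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    het_factor: bool = True,
) -> GammaSelection:
    """Profile-likelihood choice of the contamination rate gamma.

    Error rates are refit for each gamma on the grid; the maximizing gamma
    is returned, ties broken toward the smaller (more parsimonious) value.
    """
    if not grid:
        raise ValueError("gamma grid must be non-empty")
    counts = np.asarray(counts, dtype=np.int64)
    f = pooled_frequencies(counts)
    profile: dict[float, float] = {}
    fits: dict[float, ErrorRateFit] = {}
    for g in grid:
        fit = estimate_error_rates(counts, f=f, gamma=g, het_factor=het_factor)
        profile[g] = fit.loglik
        fits[g] = fit
    best_ll = max(profile.values())
    winners = sorted(g for g, ll in profile.items() if np.isclose(ll, best_ll, atol=1e-9))
    tie = len(winners) > 1
    if tie:
        logger.info("gamma profile tie among %s: choosing smallest", winners)
    return GammaSelection(gamma_star=winners[0], profile=profile, fits=fits, tie=tie)


def enumerate_quartets(r: int):
    """All count vectors (r_A, r_C, r_G, r_T) summing to r (test oracle aid)."""
    for ra, rc, rg in itertools.product(range(r + 1), repeat=3):
        rt = r - ra - rc - rg
        if rt >= 0:
            yield (ra, rc, rg, rt)
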