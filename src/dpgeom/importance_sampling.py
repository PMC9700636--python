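"""Tail probabilities by exponential tilting.

A tail query asks for P(n > nbar) (strict by default; the non-strict
variant >= is used by the large-deviation ratio estimator) along a declared
1-D marginal of a lattice distribution.  Estimation draws i.i.d. samples
from the *tilted* distribution and accumulates the reweighted indicator

    h~ = exp(psi - theta n) 1{n > nbar},

which is unbiased for the tail weight under the base distribution for every
tilt theta.  The Chernoff bound exp(psi - theta nbar) and the matching
variance bound dominate the exact quantities for all theta >= 0; both are
minimised at the Legendre tilt theta(nbar), where the bound equals
exp(-psi*(nbar)) in terms of the large-deviation function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .jump_process import LatticeDistribution, LatticeTruncation
from .info_geometry import cgf_and_mean, legendre_ldf, tilt

__all__ = [
    "TailQuery",
    "TiltedEstimate",
    "exact_tail",
    "tilted_estimate",
    "chernoff_and_variance_bounds",
    "optimal_tilt",
    "eta_difference_estimator",
    "marginal_distribution",
]


@dataclass(frozen=True)
class TailQuery:
    """Exceedance query n > nbar (strict=True) or n >= nbar (strict=False)
    along a declared species (or linear combination ``weights``) of the
    lattice.  Reports always name which convention was used."""

    nbar: float
    species: int = 0
    weights: tuple | None = None
    strict: bool = True

    def values(self, rho: LatticeDistribution) -> np.ndarray:
        return rho.marginal_values(weights=self.weights, species=self.species)

    def indicator(self, values: np.ndarray) -> np.ndarray:
        return (values > self.nbar) if self.strict else (values >= self.nbar)

    @property
    def convention(self) -> str:
        return "strict (n > nbar)" if self.strict else "non-strict (n >= nbar)"


@dataclass
class TiltedEstimate:
    estimate: float
    sample_variance: float
    n_samples: int
    seed: int
    tilt_used: np.ndarray
    chernoff_bound: float
    variance_bound: float
    convention: str

    @property
    def stderr(self) -> float:
        return float(np.sqrt(self.sample_variance / self.n_samples))


def _query_theta(rho: LatticeDistribution, q: TailQuery, theta_1d: float) -> np.ndarray:
    """Lift a scalar tilt along the query direction to a full theta vector."""
    D = rho.truncation.D
    w = np.zeros(D)
    if q.weights is not None:
        w[:] = np.asarray(q.weights, dtype=float)
    else:
        w[q.species] = 1.0
    return theta_1d * w


def exact_tail(rho: LatticeDistribution, q: TailQuery) -> float:
    """Exact tail weight by direct summation over the truncated lattice."""
    vals = q.values(rho)
    if q.nbar >= vals.max() and rho.leaked_mass > 0:
        import warnings

        warnings.warn(
            "tail threshold at/above truncation top with nonzero leaked mass; "
            "result understates the true tail",
            stacklevel=2,
        )
    return float(rho.probs[q.indicator(vals)].sum())


def tilted_estimate(
    rho: LatticeDistribution,
    q: TailQuery,
    theta,
    n_samples: int,
    seed: int,
) -> TiltedEstimate:
    """Monte-Carlo tail estimate from the tilted distribution.

    Sampling is inverse-CDF on the truncated lattice with a seeded
    ``numpy.random.default_rng``; theta may be a scalar (applied along the
    query direction) or a full tilt vector.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    th = (
        _query_theta(rho, q, float(theta))
        if np.ndim(theta) == 0
        else np.asarray(theta, dtype=float)
    )
    tp = cgf_and_mean(rho, th)
    tilted = tilt(rho, th)
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(tilted.probs)
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random(n_samples), side="right")
    vals = q.values(rho)[idx]
    n_full = rho.states[idx]
    log_lr = tp.psi - n_full @ th  # likelihood ratio back to the base measure
    h = np.where(q.indicator(vals), np.exp(log_lr), 0.0)
    cb, vb = chernoff_and_variance_bounds(rho, q, th)
    return TiltedEstimate(
        estimate=float(h.mean()),
        sample_variance=float(h.var(ddof=1)) if n_samples > 1 else 0.0,
        n_samples=n_samples,
        seed=seed,
        tilt_used=th,
        chernoff_bound=cb,
        variance_bound=vb,
        convention=q.convention,
    )


def expected_tilted_estimator(rho: LatticeDistribution, q: TailQuery, theta) -> float:
    """< h~ > under the tilted law by exact summation (unbiasedness identity)."""
    th = (
        _query_theta(rho, q, float(theta))
        if np.ndim(theta) == 0
        else np.asarray(theta, dtype=float)
    )
    tp = cgf_and_mean(rho, th)
    tilted = tilt(rho, th)
    lr = np.exp(tp.psi - rho.states @ th)
    h = np.where(q.indicator(q.values(rho)), lr, 0.0)
    return float(tilted.probs @ h)


def tilted_estimator_variance(rho: LatticeDistribution, q: TailQuery, theta) -> float:
    """Exact variance of the tilted estimator under the tilted law."""
    th = (
        _query_theta(rho, q, float(theta))
        if np.ndim(theta) == 0
        else np.asarray(theta, dtype=float)
    )
    tp = cgf_and_mean(rho, th)
    tilted = tilt(rho, th)
    lr = np.exp(tp.psi - rho.states @ th)
    h = np.where(q.indicator(q.values(rho)), lr, 0.0)
    m = tilted.probs @ h
    return float(tilted.probs @ h**2 - m**2)


def chernoff_and_variance_bounds(
    rho: LatticeDistribution, q: TailQuery, theta
) -> tuple[float, float]:
    """Chernoff bound exp(psi - theta nbar) and the matching variance bound.

    Valid as a tail bound for theta >= 0 along the query direction
    (exceedance queries); the variance bound is
    exp(psi - theta nbar) <h> - <h>^2.
    """
    th = (
        _query_theta(rho, q, float(theta))
        if np.ndim(theta) == 0
        else np.asarray(theta, dtype=float)
    )
    tp = cgf_and_mean(rho, th)
    s = float(th[q.species]) if q.weights is None else _scalar_tilt(th, q)
    chernoff = float(np.exp(tp.psi - s * q.nbar))
    p = exact_tail(rho, q)
    return chernoff, chernoff * p - p**2


def _scalar_tilt(th: np.ndarray, q: TailQuery) -> float:
    """Scalar tilt along the query direction (weights assumed unit-normalised
    in the sense theta = s * w)."""
    w = np.asarray(q.weights, dtype=float)
    nz = w != 0
    return float((th[nz] / w[nz])[0]) if nz.any() else 0.0


def optimal_tilt(rho: LatticeDistribution, q: TailQuery) -> np.ndarray:
    """Variance-optimal tilt theta(nbar): the Legendre maximiser at mean nbar.

    The resulting Chernoff bound equals exp(-psi*(nbar)).
    """
    D = rho.truncation.D
    if D == 1 and q.weights is None and q.species == 0:
        pair = legendre_ldf(rho, [q.nbar])
        return pair.theta_of_n
    # reduce to the 1-D marginal along the query direction
    marg = marginal_distribution(rho, q)
    pair = legendre_ldf(marg, [q.nbar])
    return _query_theta(rho, q, float(pair.theta_of_n[0]))


def marginal_distribution(rho: LatticeDistribution, q: TailQuery) -> LatticeDistribution:
    """1-D lattice distribution of the query projection w . n (integer-valued)."""
    vals = q.values(rho)
    ivals = np.rint(vals).astype(int)
    if np.max(np.abs(vals - ivals)) > 1e-9:
        raise ValueError("query projection must be integer-valued on the lattice")
    if ivals.min() < 0:
        raise ValueError("query projection must be non-negative for lattice marginals")
    top = int(ivals.max())
    trunc = LatticeTruncation([max(top, 1)])
    probs = np.zeros(trunc.n_states)
    np.add.at(probs, ivals, rho.probs)
    return LatticeDistribution(trunc, probs)


def eta_difference_estimator(samples_1, samples_2, nA: float, nB: float) -> float:
    """Difference of exponential-family parameters from large-deviation ratios.

    For two sample sets drawn from exponential-family bases at unknown
    parameters eta_1 and eta_2, the log-ratio of conditional exceedance
    probabilities P(n >= nB | n >= nA) estimates (eta_2 - eta_1)(nB - nA) to
    leading exponential order, so

        [log r_2 - log r_1] / (nB - nA),   r_k = P_k(n >= nB)/P_k(n >= nA)

    estimates eta_2 - eta_1.  Thresholds use the non-strict convention
    (n >= nbar).  Invariant under rescaling counts to frequencies.
    """
    if not nB > nA:
        raise ValueError("need nB > nA")
    out = []
    for s in (samples_1, samples_2):
        s = np.asarray(s, dtype=float)
        kA = np.count_nonzero(s >= nA)
        kB = np.count_nonzero(s >= nB)
        if kA == 0 or kB == 0:
            raise ValueError(
                "zero exceedance count at a threshold; draw more samples or "
                "use tilted sampling to populate the tail"
            )
        out.append(kB / kA)
    return float(np.log(out[1] / out[0]) / (nB - nA))
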