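"""Markov jump processes on truncated non-negative integer lattices.

A model is a set of chemical-reaction-style transitions with mass-action
(proportional-sampling) propensities.  The continuous-time master equation

    dρ/dt = T ρ

is represented by a sparse generator matrix ``T`` over a finite enumeration
of lattice states.  Columns of ``T`` sum to zero, so probability is conserved
exactly; propensity that would carry probability out of the truncation box is
dropped from the generator and reported separately as a boundary-outflow
diagnostic, making truncation error visible rather than silently reflected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import expm
from scipy.sparse.linalg import expm_multiply

__all__ = [
    "Reaction",
    "JumpProcessSpec",
    "LatticeTruncation",
    "LatticeDistribution",
    "GeneratorMatrix",
    "build_generator",
    "evolve_distribution",
    "steady_state",
    "poisson_distribution",
    "binomial_two_species",
]

#: number of lattice states below which dense matrix exponentials are used
DENSE_STATE_LIMIT = 2000

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class Reaction:
    """One mass-action transition ``reactants -> products`` at fixed rate.

    Stoichiometries are non-negative integer vectors of length D.  The
    propensity in state n is ``rate * prod_i n_i! / (n_i - y_i)!`` (falling
    factorial), the proportional-sampling rule underlying mass-action
    kinetics.
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate constant must be > 0, got {self.rate}")
        if any(y < 0 for y in self.reactants) or any(y < 0 for y in self.products):
            raise ValueError("stoichiometries must be non-negative integers")
        if len(self.reactants) != len(self.products):
            raise ValueError("reactant and product vectors must have equal length")


@dataclass(frozen=True)
class JumpProcessSpec:
    """Species list plus mass-action reactions; the model everything derives from."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise ValueError("need at least one species")
        for r in self.reactions:
            if len(r.reactants) != self.D:
                raise ValueError("reaction stoichiometry length must equal species count")

    @property
    def D(self) -> int:
        return len(self.species)

    @classmethod
    def from_json(cls, path_or_str) -> "JumpProcessSpec":
        """Load from the model JSON schema.

        ``{"name": str, "species": [str], "reactions":
        [{"reactants": {species: int}, "products": {species: int}, "rate": float}]}``
        """
        if hasattr(path_or_str, "read"):
            obj = json.load(path_or_str)
        else:
            s = str(path_or_str)
            if s.lstrip().startswith("{"):
                obj = json.loads(s)
            else:
                with open(s) as fh:
                    obj = json.load(fh)
        species = tuple(obj["species"])
        idx = {name: i for i, name in enumerate(species)}
        reactions = []
        for r in obj["reactions"]:
            y = [0] * len(species)
            ybar = [0] * len(species)
            for k, v in r.get("reactants", {}).items():
                y[idx[k]] = int(v)
            for k, v in r.get("products", {}).items():
                ybar[idx[k]] = int(v)
            reactions.append(Reaction(tuple(y), tuple(ybar), float(r["rate"])))
        return cls(species, tuple(reactions), obj.get("name", ""))

    def to_json(self) -> str:
        obj = {
            "name": self.name,
            "species": list(self.species),
            "reactions": [
                {
                    "reactants": {s: y for s, y in zip(self.species, r.reactants) if y},
                    "products": {s: y for s, y in zip(self.species, r.products) if y},
                    "rate": r.rate,
                }
                for r in self.reactions
            ],
        }
        return json.dumps(obj, indent=1)


def two_state_spec(k_plus: float, k_minus: float) -> JumpProcessSpec:
    """The linear two-state hopping model a <-> b."""
    return JumpProcessSpec(
        species=("a", "b"),
        reactions=(
            Reaction((1, 0), (0, 1), k_plus),
            Reaction((0, 1), (1, 0), k_minus),
        ),
        name="two_state",
    )


class LatticeTruncation:
    """Finite box ``0 <= n_i <= max_counts[i]``, optionally cut to a sector.

    Enumeration is row-major over species (the last species index varies
    fastest), matching ``numpy.ravel_multi_index`` with C order; flat indices
    are therefore reproducible across runs.  A *sector* restricts the state
    list to a shell of a linear conserved quantity ``w . n = total`` (states
    keep their relative row-major order), which is how degenerate null spaces
    of generators with conservation laws are avoided.
    """

    def __init__(
        self,
        max_counts,
        sector_weights=None,
        sector_total: int | None = None,
    ) -> None:
        self.max_counts = np.asarray(max_counts, dtype=int)
        if np.any(self.max_counts < 1):
            raise ValueError("every max_count must be >= 1")
        self.D = len(self.max_counts)
        shape = tuple(self.max_counts + 1)
        grid = np.indices(shape).reshape(self.D, -1).T  # row-major states
        if sector_weights is not None:
            if sector_total is None:
                raise ValueError("sector_total required with sector_weights")
            w = np.asarray(sector_weights)
            keep = grid @ w == sector_total
            grid = grid[keep]
            if grid.shape[0] == 0:
                raise ValueError("sector selects no lattice states")
        self.sector_weights = None if sector_weights is None else np.asarray(sector_weights)
        self.sector_total = sector_total
        self.states = np.ascontiguousarray(grid)
        self._index = {tuple(s): i for i, s in enumerate(grid)}

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    def flat_index(self, state) -> int:
        """Flat index of a lattice point; KeyError if outside the truncation."""
        return self._index[tuple(int(x) for x in state)]

    def contains(self, state) -> bool:
        return tuple(int(x) for x in state) in self._index


@dataclass
class LatticeDistribution:
    """Probability vector over the flat enumeration of a truncation.

    ``leaked_mass`` records normalisation deficit accumulated by truncation
    (zero for column-sum-zero generators, but tracked so that callers see
    when a truncation was too small for the probability it was asked to hold).
    """

    truncation: LatticeTruncation
    probs: np.ndarray
    leaked_mass: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.truncation.n_states,):
            raise ValueError("probs length must match truncation state count")
        if np.any(self.probs < -_NORM_TOL):
            raise ValueError("probabilities must be non-negative")
        self.probs = np.clip(self.probs, 0.0, None)
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        # re-normalise representation error below tolerance
        self.probs = self.probs / total

    @property
    def states(self) -> np.ndarray:
        return self.truncation.states

    def mean(self) -> np.ndarray:
        return self.probs @ self.states

    def cov(self) -> np.ndarray:
        m = self.mean()
        dev = self.states - m
        return (dev * self.probs[:, None]).T @ dev

    def marginal_values(self, weights=None, species: int | None = None) -> np.ndarray:
        """Scalar projection ``w . n`` of every state (default species 0)."""
        if weights is not None:
            return self.states @ np.asarray(weights, dtype=float)
        return self.states[:, 0 if species is None else species].astype(float)

    def to_csv(self, path) -> None:
        cols = {f"n_{i+1}": self.states[:, i] for i in range(self.truncation.D)}
        cols["prob"] = self.probs
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LatticeDistribution":
        df = pd.read_csv(path)
        ncols = [c for c in df.columns if c.startswith("n_")]
        states = df[ncols].to_numpy(dtype=int)
        trunc = LatticeTruncation(states.max(axis=0))
        probs = np.zeros(trunc.n_states)
        for s, p in zip(states, df["prob"].to_numpy()):
            probs[trunc.flat_index(s)] = p
        return cls(trunc, probs / probs.sum())


@dataclass
class GeneratorMatrix:
    """Sparse master-equation generator with column sums zero.

    ``boundary_outflow[j]`` is the total propensity from state j whose target
    lies outside the truncation; it was excluded from the matrix, so the
    dynamics reflect at the box wall and the diagnostic quantifies by how much.
    """

    truncation: LatticeTruncation
    matrix: sparse.csc_matrix
    boundary_outflow: np.ndarray = field(repr=False, default=None)

    @property
    def n_states(self) -> int:
        return self.truncation.n_states


def _propensities(spec: JumpProcessSpec, states: np.ndarray, r: Reaction) -> np.ndarray:
    """Mass-action propensity of reaction r in every state (falling factorials)."""
    prop = np.full(states.shape[0], r.rate)
    for i, y in enumerate(r.reactants):
        n = states[:, i].astype(float)
        for k in range(y):
            prop = prop * np.clip(n - k, 0.0, None)
    return prop


def build_generator(spec: JumpProcessSpec, trunc: LatticeTruncation) -> GeneratorMatrix:
    """Assemble the master-equation generator on the truncated lattice.

    For each reaction with reactant vector y, product vector ybar and rate k,
    every state n >= y contributes a jump n -> n - y + ybar with propensity
    k * prod_i n_i!/(n_i-y_i)!.  Jumps leaving the truncation are dropped
    (tracked in ``boundary_outflow``); columns sum to zero.
    """
    if spec.D != trunc.D:
        raise ValueError("species count and truncation dimension differ")
    for r in spec.reactions:
        if np.any(np.asarray(r.reactants) > trunc.max_counts):
            raise ValueError(
                f"truncation too small: reactant vector {r.reactants} exceeds "
                f"max_counts {tuple(trunc.max_counts)}"
            )
    states = trunc.states
    n_states = trunc.n_states
    rows, cols, vals = [], [], []
    diag = np.zeros(n_states)
    outflow = np.zeros(n_states)
    for r in spec.reactions:
        prop = _propensities(spec, states, r)
        shift = np.asarray(r.products) - np.asarray(r.reactants)
        targets = states + shift
        for j in np.nonzero(prop > 0)[0]:
            tgt = tuple(int(x) for x in targets[j])
            if tgt in trunc._index:
                i = trunc._index[tgt]
                rows.append(i)
                cols.append(j)
                vals.append(prop[j])
                diag[j] -= prop[j]
            else:
                outflow[j] += prop[j]
    rows.extend(range(n_states))
    cols.extend(range(n_states))
    vals.extend(diag)
    T = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(n_states, n_states), dtype=float
    )
    return GeneratorMatrix(trunc, T, outflow)


def evolve_distribution(
    gen: GeneratorMatrix, rho0: LatticeDistribution, t: float
) -> LatticeDistribution:
    """Propagate ``rho0`` by ``exp(t T)``; mass is conserved within 1e-9.

    Dense matrix exponential below ``DENSE_STATE_LIMIT`` states, Krylov
    ``expm_multiply`` above.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if rho0.truncation is not gen.truncation and not np.array_equal(
        rho0.truncation.states, gen.truncation.states
    ):
        raise ValueError("distribution and generator use different truncations")
    if t == 0:
        return LatticeDistribution(gen.truncation, rho0.probs.copy(), rho0.leaked_mass)
    if gen.n_states <= DENSE_STATE_LIMIT:
        rho = expm(gen.matrix.toarray() * t) @ rho0.probs
    else:
        rho = expm_multiply(gen.matrix * t, rho0.probs)
    total = rho.sum()
    if abs(total - 1.0) > 1e-9:
        raise RuntimeError(f"mass not conserved during evolution: sum={total}")
    return LatticeDistribution(gen.truncation, np.clip(rho, 0.0, None))


def steady_state(gen: GeneratorMatrix) -> LatticeDistribution:
    """Normalised null vector of the generator; residual ||T rho||_inf < 1e-10.

    Raises if the null space is not one-dimensional, which signals unresolved
    conserved-quantity sectors: restrict the truncation to one sector first.
    """
    T = gen.matrix.toarray()
    w, v = np.linalg.eig(T)
    null_mask = np.abs(w) < 1e-8
    if null_mask.sum() == 0:
        raise RuntimeError("generator has no null vector at tolerance 1e-8")
    if null_mask.sum() > 1:
        raise RuntimeError(
            f"degenerate null space (dimension {int(null_mask.sum())}): the model has "
            "multiple conserved sectors; restrict the lattice to one sector "
            "(LatticeTruncation sector_weights/sector_total) before building the generator"
        )
    vec = np.real(v[:, null_mask][:, 0])
    vec = vec * np.sign(vec.sum())
    vec = np.clip(vec, 0.0, None)
    rho = vec / vec.sum()
    resid = np.max(np.abs(T @ rho))
    if resid > 1e-10:
        raise RuntimeError(f"steady-state residual {resid:.2e} exceeds 1e-10")
    return LatticeDistribution(gen.truncation, rho)


# ---------------------------------------------------------------------------
# parametric base distributions on the lattice

def poisson_distribution(mean, max_counts) -> LatticeDistribution:
    """Product of truncated Poisson marginals with the given mean vector."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    trunc = LatticeTruncation(np.atleast_1d(max_counts))
    if len(mean) != trunc.D:
        raise ValueError("mean vector length must match truncation dimension")
    logp = np.zeros(trunc.n_states)
    from scipy.stats import poisson as _poisson

    for i in range(trunc.D):
        logp += _poisson.logpmf(trunc.states[:, i], mean[i])
    p = np.exp(logp)
    return LatticeDistribution(trunc, p / p.sum())


def binomial_two_species(N: int, nu_b: float) -> LatticeDistribution:
    """Binomial(N, nu_b) on the conserved shell n_a + n_b = N (species a, b)."""
    from scipy.stats import binom as _binom

    trunc = LatticeTruncation((N, N), sector_weights=(1, 1), sector_total=N)
    nb = trunc.states[:, 1]
    p = _binom.pmf(nb, N, nu_b)
    return LatticeDistribution(trunc, p / p.sum())
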