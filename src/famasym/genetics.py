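"""Exact genotype probability algebra at a di-allelic autosomal locus.

Everything here assumes random mating, Mendelian inheritance and
Hardy-Weinberg equilibrium (HWE) at a single autosomal locus with variant
(minor) allele frequency ``q``.  Genotypes are coded as counts 0/1/2 of the
variant allele, and all probability vectors are ordered ``(0, 1, 2)``.

The central object is the 3x3 transmission matrix ``V(q)``: row ``i`` is the
conditional genotype distribution of a first-degree relative (a parent or,
symmetrically, an offspring) of an index person who carries ``i`` copies,
provided that relative's genotype is not itself risk-relevant for the
conditioning event.  Repeated left-multiplication by ``V`` carries an
enrichment in the index person's genotype distribution backwards to
progenitors or forwards to descendants, halving the excess at each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeDistribution",
    "TransmissionMatrix",
    "hwe_distribution",
    "transmission_matrix",
    "propagate",
    "expectation",
    "triad_population_distribution",
]

#: validation tolerance for incoming probability vectors; within this the
#: vector is silently renormalized (guards against drift under repeated
#: propagation), beyond it construction fails.
NORMALIZATION_TOL = 1e-9


def _check_freq(q: float) -> float:
    q = float(q)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {q}")
    return q


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probabilities of carrying 0, 1 or 2 copies of the variant allele."""

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        p = np.array([self.p0, self.p1, self.p2], dtype=float)
        if np.any(p < -NORMALIZATION_TOL) or np.any(p > 1.0 + NORMALIZATION_TOL):
            raise ValueError(f"genotype probabilities out of [0, 1]: {tuple(p)}")
        total = p.sum()
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise ValueError(
                f"genotype probabilities must sum to 1 (got {total!r})"
            )
        p = np.clip(p, 0.0, 1.0)
        p /= p.sum()
        object.__setattr__(self, "p0", float(p[0]))
        object.__setattr__(self, "p1", float(p[1]))
        object.__setattr__(self, "p2", float(p[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2], dtype=float)

    @classmethod
    def from_array(cls, p: np.ndarray) -> "GenotypeDistribution":
        p = np.asarray(p, dtype=float)
        if p.shape != (3,):
            raise ValueError("genotype distribution needs exactly 3 entries")
        return cls(p[0], p[1], p[2])

    def __iter__(self):
        return iter((self.p0, self.p1, self.p2))


@dataclass(frozen=True)
class TransmissionMatrix:
    """Conditional genotype distribution of a first-degree relative.

    Row ``i`` gives the allele-count distribution of a parent (equivalently,
    of an offspring) of an index person carrying ``i`` copies: one allele is
    a uniformly chosen copy of the index person's two, the other is drawn
    from the population at frequency ``q``.
    """

    q: float
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _check_freq(self.q))
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("transmission matrix must be 3x3")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("transmission matrix entries must lie in [0, 1]")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transmission matrix rows must sum to 1")
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "entries", m)

    def __matmul__(self, other):
        return self.entries @ other

    def __rmatmul__(self, other):
        return other @ self.entries


def hwe_distribution(q: float) -> GenotypeDistribution:
    """Hardy-Weinberg genotype distribution ((1-q)^2, 2q(1-q), q^2)."""
    q = _check_freq(q)
    return GenotypeDistribution((1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2)


def transmission_matrix(q: float) -> TransmissionMatrix:
    """Closed-form V(q); rows indexed by the index person's allele count.

    The matrix is its own parent->offspring and offspring->parent operator
    and leaves the HWE distribution invariant (random mating), so repeated
    application converges geometrically (rate 1/2) back to HWE.
    """
    q = _check_freq(q)
    m = np.array(
        [
            [1.0 - q, q, 0.0],
            [(1.0 - q) / 2.0, 0.5, q / 2.0],
            [0.0, 1.0 - q, q],
        ]
    )
    return TransmissionMatrix(q=q, entries=m)


def propagate(
    dist: GenotypeDistribution, q: float, steps: int = 1
) -> GenotypeDistribution:
    """Carry a genotype distribution ``steps`` generations through V(q).

    ``steps=0`` returns the distribution unchanged.  Each step maps the
    distribution of a relative at depth g to depth g+1 (or, forwards, to the
    next descendant generation), provided every intermediate relative is not
    risk-relevant to the conditioning event.
    """
    steps = int(steps)
    if steps < 0:
        raise ValueError("steps must be non-negative")
    if not isinstance(dist, GenotypeDistribution):
        dist = GenotypeDistribution.from_array(np.asarray(dist, dtype=float))
    if steps == 0:
        return dist
    v = transmission_matrix(q).entries
    p = dist.as_array() @ np.linalg.matrix_power(v, steps)
    return GenotypeDistribution.from_array(p)


def expectation(dist: GenotypeDistribution, weights) -> float:
    """Expected value of per-genotype weights under a genotype distribution."""
    if not isinstance(dist, GenotypeDistribution):
        dist = GenotypeDistribution.from_array(np.asarray(dist, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValueError("weights must have exactly 3 entries")
    return float(dist.as_array() @ w)


def mendelian_offspring_probs(m: int, f: int) -> np.ndarray:
    """P(child allele count | mother count m, father count f).

    Each parent transmits one uniformly chosen allele; the child count is
    the sum of two independent Bernoulli transmissions with success
    probabilities m/2 and f/2.
    """
    pm, pf = m / 2.0, f / 2.0
    return np.array(
        [
            (1 - pm) * (1 - pf),
            pm * (1 - pf) + (1 - pm) * pf,
            pm * pf,
        ]
    )


def triad_population_distribution(q: float) -> np.ndarray:
    """Joint (mother, father, child) genotype table in a random-mating population.

    Returns a 3x3x3 array ``T[m, f, c] = HWE(m) * HWE(f) * Mendel(c | m, f)``
    summing to 1; the building block for case-parents triad calculations.
    """
    hwe = hwe_distribution(q).as_array()
    t = np.zeros((3, 3, 3))
    for m in range(3):
        for f in range(3):
            t[m, f, :] = hwe[m] * hwe[f] * mendelian_offspring_probs(m, f)
    return t
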