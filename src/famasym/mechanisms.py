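"""Analytic inter-lineage relative risks for nonstandard genetic mechanisms.

Three mechanisms can skew disease risk toward one parental lineage of an
affected proband without any sex-linked locus being involved:

* a **maternal (prenatal) effect** — the mother's genotype at an autosomal
  locus alters her offspring's risk via the prenatal environment,
  independently of which alleles the offspring inherits;
* a **parent-of-origin (imprinting) effect** — an inherited autosomal
  allele's effect depends on which parent it came from; the worked case
  expresses only the maternally inherited copy, with relative risk ``I``;
* an **inherited mitochondrial variant** — transmitted from mothers only,
  so enrichment does not decay along unbroken female lines.

All relative risks are computed under the rare-disease assumption: risks are
ratios of expected penetrance multipliers, so the baseline lifetime risk
cancels and never appears here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genetics import (
    GenotypeDistribution,
    expectation,
    hwe_distribution,
    mendelian_offspring_probs,
    propagate,
    triad_population_distribution,
    _check_freq,
)

__all__ = [
    "Generation",
    "MaternalEffectModel",
    "ImprintingModel",
    "MitochondrialModel",
    "NullModel",
    "MechanismModel",
    "mother_dist_given_affected",
    "triad_dist_given_affected",
    "interlineage_rr",
    "sibling_rr",
    "invert",
    "asymmetry_curve",
    "matriline_carrier_or",
]


class Generation(enum.IntEnum):
    """Ancestor depth on a parental lineage (mother = 1, grandmother = 2...)."""

    PARENT = 1
    GRANDPARENT = 2
    GREAT_GRANDPARENT = 3


def _depth(generation: Union[Generation, int, str]) -> int:
    if isinstance(generation, str):
        generation = Generation[generation.upper()]
    g = int(generation)
    if g < 1:
        raise ValueError("generation depth must be >= 1")
    return g


@dataclass(frozen=True)
class MaternalEffectModel:
    """Risk to an offspring scales with the *mother's* allele count.

    ``s1`` (``s2``) is the relative risk for the offspring of a mother
    carrying one (two) copies of the variant; by default ``s2 = s1**2``
    (log-additive model).
    """

    q: float
    s1: float
    s2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _check_freq(self.q))
        if self.s1 <= 0:
            raise ValueError("s1 must be positive")
        if self.s2 is None:
            object.__setattr__(self, "s2", self.s1**2)
        elif self.s2 <= 0:
            raise ValueError("s2 must be positive")

    @property
    def penetrance_weights(self) -> np.ndarray:
        """Relative-risk vector S = (1, s1, s2) indexed by maternal count."""
        return np.array([1.0, self.s1, self.s2])


@dataclass(frozen=True)
class ImprintingModel:
    """Risk depends on whether the inherited variant copy came from one parent.

    ``i_rr`` is the relative risk for offspring whose *expressed* parental
    copy (maternal by default) carries the variant.
    """

    q: float
    i_rr: float
    expressed_copy: str = "maternal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", _check_freq(self.q))
        if self.i_rr <= 0:
            raise ValueError("imprinting relative risk must be positive")
        if self.expressed_copy not in ("maternal", "paternal"):
            raise ValueError("expressed_copy must be 'maternal' or 'paternal'")


@dataclass(frozen=True)
class MitochondrialModel:
    """Maternally transmitted variant haplogroup with relative risk ``r_mito``.

    The inter-lineage relative risk quoted for this mechanism is the
    matriline risk ratio in families whose case lineage carries the variant;
    it equals ``r_mito`` exactly in the rare-haplogroup limit and is diluted
    by the population carrier frequency otherwise (see
    :func:`matriline_carrier_or`).
    """

    r_mito: float
    carrier_freq: float = 0.1

    def __post_init__(self) -> None:
        if self.r_mito <= 0:
            raise ValueError("r_mito must be positive")
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise ValueError("carrier_freq must lie in [0, 1]")


@dataclass(frozen=True)
class NullModel:
    """No genetic effect; every inter-lineage relative risk is 1."""


MechanismModel = Union[MaternalEffectModel, ImprintingModel, MitochondrialModel, NullModel]


def _imprinting_child_weights(model: ImprintingModel) -> np.ndarray:
    # expected penetrance multiplier for a child, by the mother's genotype:
    # the child's maternally inherited allele is variant with prob m/2.
    i = model.i_rr
    return np.array([1.0, (1.0 + i) / 2.0, i])


def mother_dist_given_affected(
    model: Union[MaternalEffectModel, ImprintingModel]
) -> GenotypeDistribution:
    """Genotype distribution of an affected proband's mother.

    The mother is the risk-relevant relative under both mechanisms, so her
    HWE prior is reweighted by the expected penetrance multiplier given her
    genotype and renormalized.
    """
    if isinstance(model, MaternalEffectModel):
        w = model.penetrance_weights
    elif isinstance(model, ImprintingModel):
        if model.expressed_copy != "maternal":
            raise ValueError(
                "mother_dist_given_affected applies to maternally expressed "
                "imprinting; the paternal case is its mirror image"
            )
        w = _imprinting_child_weights(model)
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    p = hwe_distribution(model.q).as_array() * w
    return GenotypeDistribution.from_array(p / p.sum())


def triad_dist_given_affected(
    model: Union[MaternalEffectModel, ImprintingModel]
) -> np.ndarray:
    """Case-parents triad table conditional on the child being affected.

    Returns the 3x3x3 joint over (mother, father, child) allele counts.
    Under a maternal effect the reweighting factor depends only on the
    mother's genotype, so the father's marginal stays HWE.  Under maternal
    imprinting the factor is the expected risk over the origin of the
    child's alleles given the parental genotypes.
    """
    q = model.q
    base = triad_population_distribution(q)
    if isinstance(model, MaternalEffectModel):
        w = model.penetrance_weights
        t = base * w[:, None, None]
    elif isinstance(model, ImprintingModel):
        if model.expressed_copy != "maternal":
            raise ValueError("paternal-copy imprinting triads: transpose the "
                             "maternal-case table's parent axes")
        i = model.i_rr
        t = np.zeros_like(base)
        hwe = hwe_distribution(q).as_array()
        for m in range(3):
            pm = m / 2.0  # P(maternal transmitted allele is variant)
            for f in range(3):
                pf = f / 2.0
                # joint over (maternal allele, paternal allele) with risk weight
                for cm, wm in ((0, 1.0 - pm), (1, pm)):
                    risk = i if cm == 1 else 1.0
                    for cp, wp in ((0, 1.0 - pf), (1, pf)):
                        t[m, f, cm + cp] += hwe[m] * hwe[f] * wm * wp * risk
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return t / t.sum()


def interlineage_rr(
    model: MechanismModel, generation: Union[Generation, int, str]
) -> float:
    """Inter-lineage relative risk at a given ancestor depth.

    Compares risk in the proband's maternal-line ancestor at depth ``g``
    (mother g=1, maternal grandmother g=2, ...) with the sex-matched
    paternal-line counterpart; under all three mechanisms the paternal
    lineage sits at the population rate, so the ratio is the maternal-line
    risk normalized to the population.
    """
    g = _depth(generation)
    if isinstance(model, NullModel):
        return 1.0
    if isinstance(model, MitochondrialModel):
        # unbroken female line: every matrilineal ancestor shares the
        # proband's mitochondria, so the excess does not attenuate.
        return float(model.r_mito)
    if isinstance(model, MaternalEffectModel):
        md = mother_dist_given_affected(model)
        w = model.penetrance_weights
        # the depth-g ancestor's own risk is driven by *her* mother's
        # genotype, one propagation beyond the ancestor herself.
        num = expectation(propagate(md, model.q, g), w)
        den = expectation(hwe_distribution(model.q), w)
        return num / den
    if isinstance(model, ImprintingModel):
        if model.expressed_copy == "paternal":
            mirror = ImprintingModel(model.q, model.i_rr, "maternal")
            return 1.0 / interlineage_rr(mirror, g)
        md = mother_dist_given_affected(model)
        anc = propagate(md, model.q, g - 1)  # the ancestor's own genotype
        # her maternally inherited allele is the variant with prob p1/2 + p2
        pi_g = anc.p1 / 2.0 + anc.p2
        i, q = model.i_rr, model.q
        baseline = (1.0 - q) + q * i  # population-average multiplier
        return ((1.0 - pi_g) + pi_g * i) / baseline
    raise TypeError(f"unsupported model type {type(model).__name__}")


def sibling_rr(model: MaternalEffectModel, relationship: str = "full") -> float:
    """Recurrence relative risk for a sibling of a case under a maternal effect.

    Full siblings and maternal half-siblings share the risk-relevant mother,
    giving E[S^2]/E[S]^2 over her HWE genotype; paternal half-siblings have
    independent mothers, so their risk returns to the population rate.
    """
    if not isinstance(model, MaternalEffectModel):
        raise NotImplementedError(
            "sibling recurrence risks are implemented for maternal-effect "
            "models only"
        )
    if relationship not in ("full", "maternal_half", "paternal_half"):
        raise ValueError(f"unknown sibling relationship {relationship!r}")
    if relationship == "paternal_half":
        return 1.0
    hwe = hwe_distribution(model.q)
    w = model.penetrance_weights
    e_s = expectation(hwe, w)
    e_s2 = expectation(hwe, w**2)
    return e_s2 / e_s**2


def matriline_carrier_or(model: MitochondrialModel) -> float:
    """Exact matriline-vs-paternal-line odds for a carrier proband's family.

    Every matrilineal ancestor of a carrier proband carries the variant
    (risk multiplier ``r_mito``); the sex-matched paternal-side ancestor
    sits at the population-average multiplier ``1 + carrier_freq*(r_mito-1)``.
    The ratio tends to ``r_mito`` as the haplogroup becomes rare and is
    constant in generation along the female line.
    """
    r, cf = model.r_mito, model.carrier_freq
    return r / (1.0 + cf * (r - 1.0))


_FAMILIES = ("maternal_log_additive", "imprinting", "mitochondrial")


def _family_rr(family: str, effect: float, q: float, g: int) -> float:
    if family == "maternal_log_additive":
        return interlineage_rr(MaternalEffectModel(q, effect), g)
    if family == "imprinting":
        return interlineage_rr(ImprintingModel(q, effect), g)
    if family == "mitochondrial":
        return interlineage_rr(MitochondrialModel(effect), g)
    raise ValueError(f"unknown mechanism family {family!r}; choose from {_FAMILIES}")


def invert(
    mechanism_family: str,
    target_rr: float,
    q: float | None = None,
    generation: Union[Generation, int, str] = Generation.GRANDPARENT,
) -> float:
    """Effect size at which the inter-lineage RR equals ``target_rr``.

    The map effect -> RR is strictly increasing for effect >= 1 (below 1 it
    folds back, since protective alleles also enrich the maternal lineage),
    so inversion is restricted to targets >= 1 and solved by bracketed
    root-finding on [1, 1e6].
    """
    if target_rr < 1.0:
        raise ValueError("target inter-lineage RR must be >= 1")
    g = _depth(generation)
    if mechanism_family == "mitochondrial":
        return float(target_rr)
    if mechanism_family not in _FAMILIES:
        raise ValueError(f"unknown mechanism family {mechanism_family!r}")
    if q is None or not 0.0 < q < 1.0:
        raise ValueError("nuclear mechanisms need an allele frequency in (0, 1)")
    if target_rr == 1.0:
        return 1.0
    lo, hi = 1.0, 1e6
    f = lambda s: _family_rr(mechanism_family, s, q, g) - target_rr
    if f(hi) < 0:
        raise ValueError(
            f"target RR {target_rr} unreachable for {mechanism_family} at "
            f"q={q}, depth {g}"
        )
    return float(brentq(f, lo, hi, rtol=1e-12, maxiter=200))


def asymmetry_curve(
    mechanism_family: str,
    q: float,
    generation: Union[Generation, int, str],
    grid: Iterable[float],
) -> pd.DataFrame:
    """Tidy table of inter-lineage RR as a function of effect size.

    One row per grid point, suitable for plotting mechanism curves (effect
    sizes below 1 are allowed here: protective maternal alleles still push
    the maternal-lineage RR above 1).
    """
    g = _depth(generation)
    rows = []
    for s in grid:
        s = float(s)
        if s <= 0:
            raise ValueError("effect sizes must be positive")
        rows.append(
            {
                "mechanism": mechanism_family,
                "q": q,
                "generation": Generation(g).name.lower(),
                "effect_size": s,
                "interlineage_rr": _family_rr(mechanism_family, s, q, g),
            }
        )
    return pd.DataFrame(rows)
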