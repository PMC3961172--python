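"""Forward simulation of four-generation pedigrees with ascertainment.

Each simulated family spans eight great-grandparent founders, four
grandparents, two parents and a youngest generation of full sisters.  A
di-allelic autosomal locus segregates Mendelianly from HWE founders, with
parental origin tracked per allele; a mitochondrial variant flag follows the
matriline.  Disease is a lifetime indicator assigned once per individual
with mechanism-specific penetrance, and families are ascertained the way a
sister-matched cohort enrolls: an affected woman whose unaffected full
sister participates and reports both grandmothers' histories.

The simulator is the package's synthetic-data generator: it stands in for
raw cohort records (which are not publicly deposited) and is used to verify
the analytic inter-lineage relative risks empirically.  Internally families
are stored as numpy arrays (one slot per pedigree role), so half a million
families simulate in seconds on one core; individual `Pedigree` objects are
materialized on demand.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .asymmetry import FamilyHistoryRecord
from .genetics import transmission_matrix

__all__ = [
    "SimConfig",
    "Individual",
    "Pedigree",
    "PedigreeCohort",
    "simulate",
    "ascertain",
    "ascertainment_mask",
    "lineage_pair_counts",
    "empirical_rr",
    "EmpiricalRR",
    "halfsib_recurrence_sim",
    "write_outputs",
]

# pedigree roles; ancestors precede descendants so transmission (and the PED
# file) can proceed in order.  Role names read right-to-left from the proband:
# "MMF" is the mother's mother's father.
_FOUNDERS = ("MMM", "MMF", "MFM", "MFF", "FMM", "FMF", "FFM", "FFF")
_PARENT_OF = {
    "MM": ("MMM", "MMF"),
    "MF": ("MFM", "MFF"),
    "FM": ("FMM", "FMF"),
    "FF": ("FFM", "FFF"),
    "M": ("MM", "MF"),
    "F": ("FM", "FF"),
}

_MECHANISMS = (
    "null", "standard_autosomal", "maternal_effect", "imprinting", "mitochondrial",
)


def _role_sex(role: str) -> str:
    if role.startswith("S"):
        return "F"
    return "F" if role.endswith("M") else "M"


def _sister_roles(n_sisters: int) -> tuple[str, ...]:
    return tuple(f"S{k + 1}" for k in range(n_sisters))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run.

    ``f`` is the baseline lifetime risk of the outcome (probability an
    individual with no risk-increasing state is ever affected).  Effect
    parameters follow the analytic models: ``s1``/``s2`` for maternal-effect
    and standard-autosomal penetrance, ``i_rr`` for the imprinted copy,
    ``r_mito`` for the mitochondrial haplogroup.  ``paternity_error_rate``
    is the probability, per child, that the recorded father is not the
    biological one (transmission then uses a random population male).
    """

    mechanism: str = "null"
    q: float = 0.2
    s1: float | None = None
    s2: float | None = None
    i_rr: float | None = None
    expressed_copy: str = "maternal"
    r_mito: float | None = None
    carrier_freq: float = 0.1
    f: float = 0.01
    n_families: int = 1000
    n_sisters: int = 2
    ascertainment: str = "sister_study"
    paternity_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for name in ("q", "carrier_freq", "f", "paternity_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_sisters < 1:
            raise ValueError("n_sisters must be >= 1")
        if self.ascertainment not in ("proband", "sister_study"):
            raise ValueError(f"unknown ascertainment {self.ascertainment!r}")
        if self.expressed_copy not in ("maternal", "paternal"):
            raise ValueError("expressed_copy must be 'maternal' or 'paternal'")
        if self.mechanism in ("maternal_effect", "standard_autosomal"):
            if self.s1 is None or self.s1 <= 0:
                raise ValueError(f"{self.mechanism} requires s1 > 0")
            if self.s2 is None:
                object.__setattr__(self, "s2", self.s1**2)
            elif self.s2 <= 0:
                raise ValueError("s2 must be positive")
        if self.mechanism == "imprinting" and (self.i_rr is None or self.i_rr <= 0):
            raise ValueError("imprinting requires i_rr > 0")
        if self.mechanism == "mitochondrial" and (
            self.r_mito is None or self.r_mito <= 0
        ):
            raise ValueError("mitochondrial requires r_mito > 0")
        if self.f * self._max_multiplier() > 1.0:
            raise ValueError(
                "penetrance overflow: f times the largest relative risk exceeds 1"
            )

    def _max_multiplier(self) -> float:
        if self.mechanism in ("maternal_effect", "standard_autosomal"):
            return max(1.0, self.s1, self.s2)
        if self.mechanism == "imprinting":
            return max(1.0, self.i_rr)
        if self.mechanism == "mitochondrial":
            return max(1.0, self.r_mito)
        return 1.0

    @property
    def roles(self) -> tuple[str, ...]:
        return _FOUNDERS + ("MM", "MF", "FM", "FF", "M", "F") + _sister_roles(
            self.n_sisters
        )


@dataclass(frozen=True)
class Individual:
    """One pedigree member (lifetime snapshot)."""

    id: str
    sex: str  # 'F' or 'M'
    mother_id: str | None
    father_id: str | None
    genotype: int  # variant allele count 0/1/2
    maternal_allele_variant: bool
    mito_variant: bool
    affected: bool
    founder_mother_genotype: int | None = None  # latent, founders only


@dataclass(frozen=True)
class Pedigree:
    """A single four-generation family keyed by role."""

    family_id: str
    members: dict

    def __getitem__(self, role: str) -> Individual:
        return self.members[role]


class PedigreeCohort(Sequence):
    """Array-backed collection of simulated pedigrees.

    Behaves as a sequence of :class:`Pedigree` (materialized lazily) while
    exposing the per-role boolean arrays that the vectorized estimators
    operate on directly.
    """

    def __init__(self, config: SimConfig, mat, pat, mito, affected, founder_latent):
        self.config = config
        self.mat = mat          # role -> bool array: maternally inherited allele
        self.pat = pat          # role -> bool array: paternally inherited allele
        self.mito = mito        # role -> bool array: mitochondrial variant
        self.affected = affected
        self.founder_latent = founder_latent  # founder role -> int array
        self.n_families = config.n_families

    def __len__(self) -> int:
        return self.n_families

    def genotype(self, role: str) -> np.ndarray:
        return self.mat[role].astype(np.int8) + self.pat[role].astype(np.int8)

    def __getitem__(self, i: int) -> Pedigree:
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(self.n_families))]
        if i < 0:
            i += self.n_families
        if not 0 <= i < self.n_families:
            raise IndexError(i)
        fam = f"fam{i}"
        members = {}
        for role in self.config.roles:
            parents = _PARENT_OF.get(role)
            if role.startswith("S"):
                parents = ("M", "F")
            members[role] = Individual(
                id=f"{fam}_{role}",
                sex=_role_sex(role),
                mother_id=f"{fam}_{parents[0]}" if parents else None,
                father_id=f"{fam}_{parents[1]}" if parents else None,
                genotype=int(self.mat[role][i]) + int(self.pat[role][i]),
                maternal_allele_variant=bool(self.mat[role][i]),
                mito_variant=bool(self.mito[role][i]),
                affected=bool(self.affected[role][i]),
                founder_mother_genotype=(
                    int(self.founder_latent[role][i])
                    if role in self.founder_latent
                    else None
                ),
            )
        return Pedigree(family_id=fam, members=members)


def _sample_latent_mother(genotype: np.ndarray, q: float, rng) -> np.ndarray:
    """Draw a latent mother's allele count given her child's, via V(q).

    Used for founders under the maternal-effect mechanism so that founder
    risk is consistent with an unsimulated HWE ancestry.
    """
    v = transmission_matrix(q).entries
    cum = np.cumsum(v, axis=1)
    u = rng.random(genotype.shape[0])
    c0 = cum[genotype, 0]
    c1 = cum[genotype, 1]
    return (u > c0).astype(np.int8) + (u > c1).astype(np.int8)


def simulate(config: SimConfig) -> PedigreeCohort:
    """Forward-simulate a cohort of families under one mechanism.

    Founders draw genotypes from HWE(q) and mitochondrial flags at
    ``carrier_freq``; children receive one uniformly chosen allele per
    parent with origin tracked, and the mother's mitochondrial flag.
    Affection is a single Bernoulli draw per individual with
    mechanism-specific risk.  Deterministic for fixed (seed, config).
    """
    cfg = config
    n = cfg.n_families
    rng = np.random.default_rng(cfg.seed)
    q = cfg.q
    mat, pat, mito = {}, {}, {}
    for role in _FOUNDERS:
        mat[role] = rng.random(n) < q
        pat[role] = rng.random(n) < q
        mito[role] = rng.random(n) < cfg.carrier_freq
    non_founders = [r for r in cfg.roles if r not in _FOUNDERS]
    for role in non_founders:
        mrole, frole = _PARENT_OF.get(role, ("M", "F"))
        pick_m = rng.random(n) < 0.5
        mat[role] = np.where(pick_m, mat[mrole], pat[mrole])
        pick_f = rng.random(n) < 0.5
        transmitted = np.where(pick_f, mat[frole], pat[frole])
        if cfg.paternity_error_rate > 0:
            err = rng.random(n) < cfg.paternity_error_rate
            random_male_allele = rng.random(n) < q
            transmitted = np.where(err, random_male_allele, transmitted)
        pat[role] = transmitted
        mito[role] = mito[mrole].copy()

    founder_latent = {}
    affected = {}
    s = (
        np.array([1.0, cfg.s1, cfg.s2])
        if cfg.mechanism in ("maternal_effect", "standard_autosomal")
        else None
    )
    for role in cfg.roles:
        g_own = mat[role].astype(np.int8) + pat[role].astype(np.int8)
        if cfg.mechanism == "null":
            risk = np.full(n, cfg.f)
        elif cfg.mechanism == "standard_autosomal":
            risk = cfg.f * s[g_own]
        elif cfg.mechanism == "maternal_effect":
            if role in _FOUNDERS:
                latent = _sample_latent_mother(g_own, q, rng)
                founder_latent[role] = latent
                mother_g = latent
            else:
                mrole = _PARENT_OF.get(role, ("M", "F"))[0]
                mother_g = mat[mrole].astype(np.int8) + pat[mrole].astype(np.int8)
            risk = cfg.f * s[mother_g]
        elif cfg.mechanism == "imprinting":
            expressed = mat[role] if cfg.expressed_copy == "maternal" else pat[role]
            risk = cfg.f * np.where(expressed, cfg.i_rr, 1.0)
        elif cfg.mechanism == "mitochondrial":
            risk = cfg.f * np.where(mito[role], cfg.r_mito, 1.0)
        affected[role] = rng.random(n) < risk
    return PedigreeCohort(cfg, mat, pat, mito, affected, founder_latent)


def _as_cohort(pedigrees) -> PedigreeCohort:
    if isinstance(pedigrees, PedigreeCohort):
        return pedigrees
    raise TypeError(
        "vectorized estimators require a PedigreeCohort; materialized "
        "Pedigree lists are for inspection only"
    )


def ascertainment_mask(cohort: PedigreeCohort, scheme: str | None = None) -> np.ndarray:
    """Boolean mask of families satisfying the enrollment scheme.

    ``proband``: at least one affected sister.  ``sister_study``: at least
    one affected and at least one unaffected sister (the participant who
    reports the family history).
    """
    cohort = _as_cohort(cohort)
    scheme = scheme or cohort.config.ascertainment
    sisters = _sister_roles(cohort.config.n_sisters)
    aff = np.stack([cohort.affected[r] for r in sisters])
    any_aff = aff.any(axis=0)
    if scheme == "proband":
        return any_aff
    if scheme == "sister_study":
        if cohort.config.n_sisters < 2:
            raise ValueError(
                "sister_study ascertainment needs at least two sisters per family"
            )
        return any_aff & (~aff).any(axis=0)
    raise ValueError(f"unknown ascertainment scheme {scheme!r}")


def ascertain(pedigrees, scheme: str | None = None) -> list[FamilyHistoryRecord]:
    """Build family-history records for ascertained families.

    Accepts a cohort (fast path) or an iterable of :class:`Pedigree`.  Each
    record carries both grandmothers' and both grandfathers' affection
    flags; the stratum is a single label (no age structure is simulated).
    """
    if isinstance(pedigrees, PedigreeCohort):
        mask = ascertainment_mask(pedigrees, scheme)
        idx = np.flatnonzero(mask)
        mm = pedigrees.affected["MM"]
        fm = pedigrees.affected["FM"]
        mf = pedigrees.affected["MF"]
        ff = pedigrees.affected["FF"]
        return [
            FamilyHistoryRecord(
                family_id=f"fam{i}",
                stratum="all",
                mm_affected=int(mm[i]),
                fm_affected=int(fm[i]),
                mf_affected=int(mf[i]),
                ff_affected=int(ff[i]),
            )
            for i in idx
        ]
    records = []
    scheme = scheme or "sister_study"
    for ped in pedigrees:
        for role in ("MM", "FM", "MF", "FF"):
            if role not in ped.members:
                raise ValueError(f"pedigree {ped.family_id} lacks grandparent {role}")
        sisters = [m for r, m in ped.members.items() if r.startswith("S")]
        if not sisters:
            raise ValueError(f"pedigree {ped.family_id} has no youngest generation")
        any_aff = any(m.affected for m in sisters)
        any_unaff = any(not m.affected for m in sisters)
        keep = any_aff if scheme == "proband" else (any_aff and any_unaff)
        if scheme == "sister_study" and len(sisters) < 2:
            raise ValueError("sister_study ascertainment needs >= 2 sisters")
        if keep:
            records.append(
                FamilyHistoryRecord(
                    family_id=ped.family_id,
                    stratum="all",
                    mm_affected=int(ped["MM"].affected),
                    fm_affected=int(ped["FM"].affected),
                    mf_affected=int(ped["MF"].affected),
                    ff_affected=int(ped["FF"].affected),
                )
            )
    return records


def lineage_pair_counts(
    cohort: PedigreeCohort,
    role_maternal: str = "MM",
    role_paternal: str = "FM",
    scheme: str | None = None,
    carrier_proband_only: bool = False,
) -> tuple[int, int]:
    """Discordant counts (maternal-only, paternal-only) for a sex-matched
    ancestor pair among ascertained families.

    The defaults compare the grandmothers; deeper matriline pairs such as
    ("MMM", "FMM") probe attenuation one generation further back.  With
    ``carrier_proband_only`` the comparison is restricted to families whose
    case matriline carries the mitochondrial variant (the conditioning under
    which the mitochondrial inter-lineage relative risk equals the variant's
    own risk ratio; without it the population-level asymmetry from a
    mitochondrial variant is strongly diluted).
    """
    cohort = _as_cohort(cohort)
    mask = ascertainment_mask(cohort, scheme)
    if carrier_proband_only:
        mask = mask & cohort.mito["S1"]
    am = cohort.affected[role_maternal][mask]
    ap = cohort.affected[role_paternal][mask]
    a = int(np.sum(am & ~ap))
    b = int(np.sum(ap & ~am))
    return a, b


@dataclass(frozen=True)
class EmpiricalRR:
    """Monte Carlo inter-lineage relative-risk estimate."""

    value: float
    se_log: float
    n_conditioning: int
    defined: bool = True

    def __float__(self) -> float:
        return self.value


def _rate(x: np.ndarray) -> tuple[float, int]:
    n = x.shape[0]
    return (float(x.mean()) if n else float("nan")), n


def _ratio_se_log(rates_ns) -> float:
    # delta-method SE of a log ratio of independent binomial rates
    tot = 0.0
    for p, n in rates_ns:
        if n == 0 or p in (0.0, 1.0):
            return float("nan")
        tot += (1.0 - p) / (n * p)
    return float(np.sqrt(tot))


def empirical_rr(
    cohort: PedigreeCohort, relationship: str, direction: str
) -> EmpiricalRR:
    """Empirical inter-lineage relative risk from a simulated cohort.

    Retrospective estimates condition on the designated proband (the
    first-born sister) being affected and compare her maternal- versus
    paternal-side relatives; grandparent comparisons are sex-matched so need
    no population normalizer, while the parent comparison normalizes each
    parent's rate by the unconditional rate in that parent tier.
    Prospective estimates compare risk in the proband given an affected
    maternal- versus paternal-side relative (or affected mother vs father
    for the daughter relationship).
    """
    cohort = _as_cohort(cohort)
    aff = cohort.affected
    c = aff["S1"]  # designated proband: first-born sister
    key = (relationship, direction)
    if key == ("parent", "retrospective"):
        pm, nm = _rate(aff["M"][c])
        pf, nf = _rate(aff["F"][c])
        pop_f, npf = _rate(aff["M"])
        pop_m, npm = _rate(aff["F"])
        parts = [(pm, nm), (pf, nf), (pop_f, npf), (pop_m, npm)]
        if 0.0 in (pf, pop_f, pop_m) or nm == 0:
            return EmpiricalRR(float("nan"), float("nan"), int(c.sum()), False)
        value = (pm / pop_f) / (pf / pop_m)
        return EmpiricalRR(value, _ratio_se_log(parts), int(c.sum()))
    if key == ("grandparent", "retrospective"):
        pm, nm = _rate(aff["MM"][c])
        pf, nf = _rate(aff["FM"][c])
        if pf == 0.0 or nm == 0:
            return EmpiricalRR(float("nan"), float("nan"), int(c.sum()), False)
        return EmpiricalRR(pm / pf, _ratio_se_log([(pm, nm), (pf, nf)]), int(c.sum()))
    if key == ("grandparent", "prospective"):
        p1, n1 = _rate(c[aff["MM"]])
        p2, n2 = _rate(c[aff["FM"]])
        if p2 == 0.0 or n1 == 0 or n2 == 0:
            return EmpiricalRR(float("nan"), float("nan"), n1 + n2, False)
        return EmpiricalRR(p1 / p2, _ratio_se_log([(p1, n1), (p2, n2)]), n1 + n2)
    if key == ("daughter", "prospective"):
        p1, n1 = _rate(c[aff["M"]])
        p2, n2 = _rate(c[aff["F"]])
        if p2 == 0.0 or n1 == 0 or n2 == 0:
            return EmpiricalRR(float("nan"), float("nan"), n1 + n2, False)
        return EmpiricalRR(p1 / p2, _ratio_se_log([(p1, n1), (p2, n2)]), n1 + n2)
    if relationship == "son":
        raise ValueError(
            "the default sibship simulates sisters only; son comparisons "
            "need male youngest-generation members"
        )
    raise ValueError(f"unsupported relationship/direction pair {key!r}")


def halfsib_recurrence_sim(
    q: float,
    s1: float,
    s2: float | None = None,
    f: float = 0.01,
    relationship: str = "maternal_half",
    n_pairs: int = 500_000,
    seed: int = 0,
) -> EmpiricalRR:
    """Monte Carlo sibling recurrence RR under a maternal effect.

    Simulates sibling pairs directly: full siblings and maternal
    half-siblings share a mother (one HWE genotype drives both risks);
    paternal half-siblings have independent mothers.  Returns
    P(sib affected | co-sib affected) / P(affected).
    """
    if relationship not in ("full", "maternal_half", "paternal_half"):
        raise ValueError(f"unknown relationship {relationship!r}")
    s2 = s1**2 if s2 is None else s2
    s = np.array([1.0, s1, s2])
    if f * s.max() > 1.0:
        raise ValueError("penetrance overflow")
    rng = np.random.default_rng(seed)
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    g1 = rng.choice(3, size=n_pairs, p=hwe)
    g2 = g1 if relationship != "paternal_half" else rng.choice(3, size=n_pairs, p=hwe)
    a1 = rng.random(n_pairs) < f * s[g1]
    a2 = rng.random(n_pairs) < f * s[g2]
    p_joint = np.mean(a1 & a2)
    p1, p2 = a1.mean(), a2.mean()
    if p_joint == 0 or p1 == 0 or p2 == 0:
        return EmpiricalRR(float("nan"), float("nan"), n_pairs, False)
    value = float(p_joint / (p1 * p2))
    n11 = float(np.sum(a1 & a2))
    se = float(np.sqrt(1.0 / n11 + 1.0 / np.sum(a1) + 1.0 / np.sum(a2)))
    return EmpiricalRR(value, se, n_pairs)


def write_outputs(cohort: PedigreeCohort, records, directory) -> dict:
    """Write the simulated cohort to plain-text files.

    Produces ``family_history.csv`` (consumable by
    :func:`famasym.asymmetry.read_family_history`), ``pedigrees.ped``
    (PED-like TSV: family, id, father, mother, sex 1=male/2=female,
    phenotype 1=unaffected/2=affected, plus a variant allele count column;
    parents always precede their children), and ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fh_path = directory / "family_history.csv"
    with open(fh_path, "w") as fh:
        fh.write("family_id,stratum,mm_affected,fm_affected,mf_affected,ff_affected\n")
        for r in records:
            def cell(v):
                return "" if v is None else str(int(v))
            fh.write(
                f"{r.family_id},{r.stratum},{cell(r.mm_affected)},"
                f"{cell(r.fm_affected)},{cell(r.mf_affected)},{cell(r.ff_affected)}\n"
            )
    ped_path = directory / "pedigrees.ped"
    cfg = cohort.config
    with open(ped_path, "w") as fh:
        for i in range(len(cohort)):
            fam = f"fam{i}"
            for role in cfg.roles:
                parents = _PARENT_OF.get(role)
                if role.startswith("S"):
                    parents = ("M", "F")
                mother = f"{fam}_{parents[0]}" if parents else "0"
                father = f"{fam}_{parents[1]}" if parents else "0"
                sex = "2" if _role_sex(role) == "F" else "1"
                pheno = "2" if cohort.affected[role][i] else "1"
                geno = int(cohort.mat[role][i]) + int(cohort.pat[role][i])
                fh.write(
                    f"{fam}\t{fam}_{role}\t{father}\t{mother}\t{sex}\t{pheno}\t{geno}\n"
                )
    manifest_path = directory / "manifest.json"
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "n_families": len(cohort),
        "n_records": len(records),
        "famasym_version": __version__,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"family_history": fh_path, "pedigrees": ped_path, "manifest": manifest_path}
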