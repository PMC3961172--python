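"""Inter-lineage asymmetry estimation from family-history tables.

A family where exactly one of the two sex-matched grandparents (say, the
maternal grandmother MM versus the paternal grandmother FM) is affected is a
*discordant pair*; only such families inform the maternal-vs-paternal
asymmetry.  The estimator is the matched-pair odds ratio a/b, where a
families are maternal-only and b paternal-only, with a Wald confidence
interval on the log scale and an exact two-sided binomial test of
a successes in a+b trials at probability 1/2.

The packaged fixture ships the NIEHS Sister Study grandmother counts
(published aggregate data; the individual-level records are not deposited),
stratified by the youngest age at breast-cancer diagnosis among the
granddaughters, so the study's headline analysis reproduces in one call.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FamilyHistoryRecord",
    "DiscordantPairTable",
    "AsymmetryEstimate",
    "read_family_history",
    "tabulate",
    "discordant_or",
    "analyze_table",
    "at_least_one_rate",
    "lineage_totals",
    "within_cluster_or",
    "load_sister_study_table",
    "SISTER_STUDY_STRATA",
]

SISTER_STUDY_STRATA = (
    "<30", "30-34", "35-39", "40-44", "45-49", "50-54", "55-59", "60-89",
)

_COUNT_COLS = ["n_neither", "n_maternal_only", "n_paternal_only", "n_both"]


@dataclass(frozen=True)
class FamilyHistoryRecord:
    """One family's reported grandparent affection history."""

    family_id: str
    stratum: str = "all"
    mm_affected: int | None = None  # maternal grandmother
    fm_affected: int | None = None  # paternal grandmother
    mf_affected: int | None = None  # maternal grandfather
    ff_affected: int | None = None  # paternal grandfather

    @property
    def grandmothers_reported(self) -> bool:
        return self.mm_affected is not None and self.fm_affected is not None

    @property
    def grandmother_discordant(self) -> bool:
        return self.grandmothers_reported and self.mm_affected != self.fm_affected

    @property
    def grandfather_discordant(self) -> bool:
        return (
            self.mf_affected is not None
            and self.ff_affected is not None
            and self.mf_affected != self.ff_affected
        )


@dataclass
class DiscordantPairTable:
    """Per-stratum family counts in the four grandmother-history cells."""

    counts: pd.DataFrame  # index: strata; columns: _COUNT_COLS
    n_missing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _COUNT_COLS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        counts = self.counts[_COUNT_COLS].astype(int)
        if (counts < 0).any().any():
            raise ValueError("family counts must be non-negative")
        self.counts = counts

    @property
    def strata(self) -> list:
        return list(self.counts.index)

    def totals(self) -> pd.Series:
        """Column sums across strata (the TOTAL row)."""
        return self.counts.sum(axis=0)

    def stratum_counts(self, stratum: str) -> pd.Series:
        return self.counts.loc[stratum]

    def to_records(self) -> list[FamilyHistoryRecord]:
        """Expand counts into per-family rows (synthetic family ids)."""
        records, k = [], 0
        cell_flags = {
            "n_neither": (0, 0),
            "n_maternal_only": (1, 0),
            "n_paternal_only": (0, 1),
            "n_both": (1, 1),
        }
        for stratum, row in self.counts.iterrows():
            for col, (mm, fm) in cell_flags.items():
                for _ in range(int(row[col])):
                    records.append(
                        FamilyHistoryRecord(
                            family_id=f"F{k:06d}", stratum=str(stratum),
                            mm_affected=mm, fm_affected=fm,
                        )
                    )
                    k += 1
        return records


@dataclass(frozen=True)
class AsymmetryEstimate:
    """Discordant-pair odds ratio with Wald CI and exact binomial p."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    n_maternal_only: int
    n_paternal_only: int
    level: float = 0.95
    zero_cell: bool = False

    @property
    def defined(self) -> bool:
        return math.isfinite(self.odds_ratio) and self.odds_ratio > 0


_DEFAULT_COLUMNS = {
    "family_id": "family_id",
    "stratum": "stratum",
    "mm_affected": "mm_affected",
    "fm_affected": "fm_affected",
    "mf_affected": "mf_affected",
    "ff_affected": "ff_affected",
}


def _parse_indicator(value, column: str, family_id: str) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan"):
        return None
    if s in ("0", "1"):
        return int(s)
    try:
        f = float(s)
    except ValueError:
        f = None
    if f in (0.0, 1.0):
        return int(f)
    raise ValueError(
        f"unparseable affection indicator {value!r} in column {column} "
        f"(family {family_id})"
    )


def read_family_history(
    path, columns: Mapping[str, str] | None = None
) -> list[FamilyHistoryRecord]:
    """Read a per-family history CSV into records.

    ``columns`` maps the canonical field names (family_id, stratum,
    mm_affected, fm_affected, mf_affected, ff_affected) to the CSV's header
    names.  Grandfather columns and the stratum column are optional; missing
    indicators (empty cells) are kept as None and excluded downstream from
    pair analyses.  Duplicate family ids are an error.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for required in ("family_id", "mm_affected", "fm_affected"):
        if colmap[required] not in df.columns:
            raise ValueError(f"input CSV lacks required column {colmap[required]!r}")
    ids = df[colmap["family_id"]]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate family_id values: {sorted(set(dup))[:5]}")
    has_stratum = colmap["stratum"] in df.columns
    records = []
    for _, row in df.iterrows():
        fid = str(row[colmap["family_id"]])
        kwargs = {}
        for fld in ("mm_affected", "fm_affected", "mf_affected", "ff_affected"):
            col = colmap[fld]
            if col in df.columns:
                kwargs[fld] = _parse_indicator(row[col], col, fid)
        records.append(
            FamilyHistoryRecord(
                family_id=fid,
                stratum=str(row[colmap["stratum"]]) if has_stratum else "all",
                **kwargs,
            )
        )
    return records


def tabulate(
    records: Iterable[FamilyHistoryRecord],
    strata_order: Sequence[str] | None = None,
) -> DiscordantPairTable:
    """Cross-tabulate families by stratum and grandmother history.

    Families with either grandmother's status missing are excluded from the
    four cells and counted separately in ``n_missing``.
    """
    records = list(records)
    if strata_order is None:
        strata_order = sorted({r.stratum for r in records}) or ["all"]
    strata_order = list(strata_order)
    counts = pd.DataFrame(
        0, index=pd.Index(strata_order, name="stratum"), columns=_COUNT_COLS
    )
    n_missing: dict = {}
    for r in records:
        if r.stratum not in counts.index:
            raise ValueError(f"record stratum {r.stratum!r} not in strata_order")
        if not r.grandmothers_reported:
            n_missing[r.stratum] = n_missing.get(r.stratum, 0) + 1
            continue
        col = {
            (0, 0): "n_neither",
            (1, 0): "n_maternal_only",
            (0, 1): "n_paternal_only",
            (1, 1): "n_both",
        }[(r.mm_affected, r.fm_affected)]
        counts.loc[r.stratum, col] += 1
    return DiscordantPairTable(counts=counts, n_missing=n_missing)


def discordant_or(
    a: int,
    b: int,
    level: float = 0.95,
    zero_correction: bool = False,
) -> AsymmetryEstimate:
    """Matched-pair odds ratio from discordant counts.

    ``a`` counts maternal-only, ``b`` paternal-only families.  The CI is
    Wald on the log OR with standard error sqrt(1/a + 1/b); the p-value is
    the exact two-sided binomial test (doubled smaller tail, capped at 1) of
    a out of a+b at probability 1/2.  With a zero cell, the OR is 0 or
    infinite and the CI undefined unless the Haldane-Anscombe +1/2
    correction is requested.
    """
    a, b = int(a), int(b)
    if a < 0 or b < 0:
        raise ValueError("discordant counts must be non-negative")
    n = a + b
    if n == 0:
        raise ValueError("no discordant pairs")
    p = min(1.0, 2.0 * min(stats.binom.cdf(a, n, 0.5), stats.binom.sf(a - 1, n, 0.5)))
    zero = a == 0 or b == 0
    if zero and not zero_correction:
        return AsymmetryEstimate(
            odds_ratio=0.0 if a == 0 else math.inf,
            ci_low=math.nan, ci_high=math.nan, p_two_sided=p,
            n_maternal_only=a, n_paternal_only=b, level=level, zero_cell=True,
        )
    aa, bb = (a + 0.5, b + 0.5) if zero else (float(a), float(b))
    log_or = math.log(aa / bb)
    se = math.sqrt(1.0 / aa + 1.0 / bb)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return AsymmetryEstimate(
        odds_ratio=aa / bb,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_two_sided=float(p),
        n_maternal_only=a,
        n_paternal_only=b,
        level=level,
        zero_cell=zero,
    )


def analyze_table(table: DiscordantPairTable, level: float = 0.95) -> pd.DataFrame:
    """Per-stratum and pooled asymmetry estimates.

    Returns one row per stratum plus a TOTAL row with columns
    (stratum, a, b, odds_ratio, ci_low, ci_high, p, defined); a stratum with
    no discordant pairs is flagged undefined rather than dropped.
    """
    rows = []
    items = [(s, table.stratum_counts(s)) for s in table.strata]
    items.append(("TOTAL", table.totals()))
    for label, c in items:
        a, b = int(c["n_maternal_only"]), int(c["n_paternal_only"])
        if a + b == 0:
            rows.append(
                dict(stratum=label, a=a, b=b, odds_ratio=math.nan,
                     ci_low=math.nan, ci_high=math.nan, p=math.nan, defined=False)
            )
            continue
        est = discordant_or(a, b, level=level)
        rows.append(
            dict(stratum=label, a=a, b=b, odds_ratio=est.odds_ratio,
                 ci_low=est.ci_low, ci_high=est.ci_high, p=est.p_two_sided,
                 defined=est.defined)
        )
    return pd.DataFrame(rows)


def at_least_one_rate(table: DiscordantPairTable) -> pd.Series:
    """Per-stratum proportion of families with >= 1 affected grandmother."""
    c = table.counts
    totals = c.sum(axis=1)
    affected = c["n_maternal_only"] + c["n_paternal_only"] + c["n_both"]
    with np.errstate(invalid="ignore"):
        rate = affected / totals.replace(0, np.nan)
    return rate.rename("at_least_one_rate")


def lineage_totals(table: DiscordantPairTable) -> tuple[int, int]:
    """(affected maternal grandmothers, affected paternal grandmothers)."""
    t = table.totals()
    maternal = int(t["n_maternal_only"] + t["n_both"])
    paternal = int(t["n_paternal_only"] + t["n_both"])
    return maternal, paternal


def within_cluster_or(
    records: Iterable[FamilyHistoryRecord],
    b_resamples: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> AsymmetryEstimate:
    """Within-cluster resampling OR for families with up to two discordant pairs.

    When the disease affects both sexes a family can contribute both a
    grandmother and a grandfather discordant pair; pooling them naively
    ignores the within-family dependence.  Each resample picks one
    discordant pair uniformly at random per contributing family and computes
    the matched-pair OR; the estimate is the exponentiated mean log-OR, with
    variance = mean within-resample Wald variance minus the between-resample
    variance of the log-ORs, and a normal-approximation two-sided p.
    """
    if b_resamples < 1:
        raise ValueError("b_resamples must be >= 1")
    pairs = []  # per family: list of 'm'/'p' directions available
    for r in records:
        fam = []
        if r.grandmother_discordant:
            fam.append("m" if r.mm_affected else "p")
        if r.grandfather_discordant:
            fam.append("m" if r.mf_affected else "p")
        if fam:
            pairs.append(fam)
    if not pairs:
        raise ValueError("no family contributes a discordant grandparent pair")
    rng = np.random.default_rng(seed)
    n_two = sum(len(f) == 2 for f in pairs)
    singles_m = sum(1 for f in pairs if len(f) == 1 and f[0] == "m")
    singles_p = sum(1 for f in pairs if len(f) == 1 and f[0] == "p")
    doubles = [f for f in pairs if len(f) == 2]
    log_ors, wvars, a_all_zero_b = [], [], True
    for _ in range(b_resamples):
        a, b = singles_m, singles_p
        if n_two:
            picks = rng.integers(0, 2, size=n_two)
            for fam, k in zip(doubles, picks):
                if fam[k] == "m":
                    a += 1
                else:
                    b += 1
        if b > 0:
            a_all_zero_b = False
        if a == 0 or b == 0:
            a, b = a + 0.5, b + 0.5  # rare under resampling; keep draws usable
        log_ors.append(math.log(a / b))
        wvars.append(1.0 / a + 1.0 / b)
    if a_all_zero_b:
        return AsymmetryEstimate(
            odds_ratio=math.inf, ci_low=math.nan, ci_high=math.nan,
            p_two_sided=math.nan, n_maternal_only=singles_m + n_two,
            n_paternal_only=0, level=level, zero_cell=True,
        )
    mean_log = float(np.mean(log_ors))
    var = float(np.mean(wvars) - np.var(log_ors, ddof=0))
    var = max(var, 1e-12)
    se = math.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * stats.norm.sf(abs(mean_log) / se)
    # expected discordant split under the resampling scheme, for reporting
    a_mean = singles_m + n_two * np.mean(
        [sum(x == "m" for x in f) / 2.0 for f in doubles]
    ) if doubles else singles_m
    return AsymmetryEstimate(
        odds_ratio=math.exp(mean_log),
        ci_low=math.exp(mean_log - z * se),
        ci_high=math.exp(mean_log + z * se),
        p_two_sided=float(min(1.0, p)),
        n_maternal_only=int(round(a_mean)),
        n_paternal_only=int(round(singles_m + singles_p + n_two - a_mean)),
        level=level,
    )


def load_sister_study_table() -> DiscordantPairTable:
    """Packaged Sister Study grandmother-history counts by diagnosis-age stratum."""
    ref = importlib.resources.files("famasym.data") / "sister_study_grandmothers.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df = df.set_index("stratum")
    return DiscordantPairTable(counts=df)
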