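"""Species- and family-level neoplasia prevalence and chi-square comparisons.

Prevalence is affected individuals over the total housed population of a
unit (species or taxonomic family). Units whose census is smaller than
``min_n`` (default 10 individuals) are still computed for display but
flagged as excluded; family aggregates sum only over included species, so
a handful of single-animal exhibits cannot dominate a family estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .registry import RegistryBundle, ValidationError

DEFAULT_MIN_N = 10


@dataclass(frozen=True)
class PrevalenceResult:
    unit: str  # species or family name
    cases: int
    total: int
    included: bool  # census total >= min_n

    @property
    def prevalence(self) -> float:
        return self.cases / self.total

    @property
    def prevalence_pct(self) -> float:
        """Percentage at the display precision (one decimal)."""
        return round(100.0 * self.prevalence, 1)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    units: tuple[str, str] | None = None


def species_prevalence(
    bundle: RegistryBundle, min_n: int = DEFAULT_MIN_N
) -> list[PrevalenceResult]:
    """One result per census species, in census order."""
    counts: dict[str, int] = {}
    for c in bundle.cases:
        counts[c.species] = counts.get(c.species, 0) + 1
    out = []
    for sc in bundle.census:
        n_cases = counts.get(sc.species, 0)
        if sc.total_individuals == 0:
            if n_cases:
                raise ValidationError(
                    f"{sc.species}: {n_cases} cases but zero census total"
                )
            continue
        out.append(
            PrevalenceResult(
                unit=sc.species,
                cases=n_cases,
                total=sc.total_individuals,
                included=sc.total_individuals >= min_n,
            )
        )
    return out


def family_prevalence(
    bundle: RegistryBundle, min_n: int = DEFAULT_MIN_N
) -> list[PrevalenceResult]:
    """Family aggregates summed only over species with census >= min_n.

    Families whose species all fall below the threshold yield no row.
    """
    per_species = species_prevalence(bundle, min_n=min_n)
    family_of = {sc.species: sc.family for sc in bundle.census}
    agg: dict[str, list[int]] = {}
    for r in per_species:
        if not r.included:
            continue
        fam = family_of[r.unit]
        cases, total = agg.setdefault(fam, [0, 0])
        agg[fam][0] = cases + r.cases
        agg[fam][1] = total + r.total
    return [
        PrevalenceResult(unit=fam, cases=c, total=t, included=True)
        for fam, (c, t) in sorted(agg.items())
    ]


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df=1, no
    continuity correction, upper-tail p."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(stat), df=int(df), p_value=float(p),
        table=((a, b), (c, d)),
    )


def compare_extreme_prevalences(results: list[PrevalenceResult]) -> ChiSquareResult:
    """2x2 chi-square between the lowest- and highest-prevalence included
    units; ties broken by larger census, then by name."""
    included = [r for r in results if r.included]
    if len(included) < 2:
        raise ValueError("need at least two included units to compare")

    def pick(extreme):
        p = extreme(r.prevalence for r in included)
        tied = [r for r in included if r.prevalence == p]
        return sorted(tied, key=lambda r: (-r.total, r.unit))[0]

    lo, hi = pick(min), pick(max)
    res = pearson_chi2_2x2(
        hi.cases, hi.total - hi.cases, lo.cases, lo.total - lo.cases
    )
    return ChiSquareResult(
        statistic=res.statistic, df=res.df, p_value=res.p_value,
        table=res.table, units=(hi.unit, lo.unit),
    )


__all__ = [
    "PrevalenceResult", "ChiSquareResult", "DEFAULT_MIN_N",
    "species_prevalence", "family_prevalence",
    "pearson_chi2_2x2", "compare_extreme_prevalences",
]
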