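"""Sex-linkage, heterozygosity, shared-polymorphism and census statistics.

The central statistic is the *extent of Y linkage* of an inversion: the
fraction of Y-bearing larvae that carry it (st/i or i/i).  An inversion in
absolute linkage disequilibrium with maleness scores 1.0; an autosomal
inversion occurs at similar carrier rates in both sexes.  Triploid X0X0Y
individuals with an inverted constituent count as Y-bearing carriers.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .nomenclature import InversionID, format_inversion_name
from .records import LarvaRecord, Rank, Sex, TaxonCatalog


class LinkageClass(str, Enum):
    SEX_LINKED = "sex_linked"
    AUTOSOMAL = "autosomal"
    AMBIGUOUS = "ambiguous"


class UndefinedResultError(ValueError):
    """A statistic's denominator is zero (no scored larvae)."""


@dataclass(frozen=True)
class LinkageResult:
    """Carrier rates of one inversion split by Y-bearing status.

    ``y_linkage`` is the carrier fraction among Y-bearing larvae;
    ``male_fraction_of_carriers`` (the share of all carriers that are
    Y-bearing) is carried as a secondary view of the same contrast.
    """

    inversion: InversionID
    n_y_bearing: int
    n_female: int
    y_linkage: float
    female_carrier_rate: float
    male_fraction_of_carriers: Optional[float] = None

    def classification(
        self, sex_threshold: float = 0.95, autosomal_tolerance: float = 0.10
    ) -> LinkageClass:
        return classify_inversion_linkage(self, sex_threshold, autosomal_tolerance)


def extent_of_y_linkage(
    records: Sequence[LarvaRecord], inversion: InversionID
) -> LinkageResult:
    """Carrier fraction of ``inversion`` among Y-bearing larvae.

    Counts every Y-bearing larva scored for the inversion in the
    denominator; carriers are st/i or i/i (triploids with an inverted
    constituent included).  The analogous rate over females is returned
    alongside.

    Raises
    ------
    UndefinedResultError
        If no Y-bearing larva was scored for the inversion.
    """
    n_y = n_y_car = n_f = n_f_car = 0
    for r in records:
        g = r.genotype_for(inversion)
        if g is None:
            continue
        if r.y_bearing:
            n_y += 1
            n_y_car += g.state.is_carrier
        else:
            n_f += 1
            n_f_car += g.state.is_carrier
    if n_y == 0:
        raise UndefinedResultError(
            f"no Y-bearing larvae scored for {format_inversion_name(inversion)}"
        )
    n_car = n_y_car + n_f_car
    return LinkageResult(
        inversion=inversion,
        n_y_bearing=n_y,
        n_female=n_f,
        y_linkage=n_y_car / n_y,
        female_carrier_rate=(n_f_car / n_f) if n_f else 0.0,
        male_fraction_of_carriers=(n_y_car / n_car) if n_car else None,
    )


def classify_inversion_linkage(
    result: LinkageResult,
    sex_threshold: float = 0.95,
    autosomal_tolerance: float = 0.10,
) -> LinkageClass:
    """Classify an inversion as sex-linked, autosomal, or ambiguous.

    Sex-linked: found (very nearly) exclusively in Y-bearing larvae --
    carrier rate at least ``sex_threshold`` among Y-bearers and at most
    ``1 - sex_threshold`` among females.  Autosomal: carrier rates in the
    two sexes within ``autosomal_tolerance`` of each other.  Anything else
    is ambiguous.
    """
    for name, v in (("sex_threshold", sex_threshold),
                    ("autosomal_tolerance", autosomal_tolerance)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if (
        result.y_linkage >= sex_threshold
        and result.female_carrier_rate <= 1.0 - sex_threshold
    ):
        return LinkageClass.SEX_LINKED
    if abs(result.y_linkage - result.female_carrier_rate) <= autosomal_tolerance:
        return LinkageClass.AUTOSOMAL
    return LinkageClass.AMBIGUOUS


def heterozygote_proportion(
    records: Sequence[LarvaRecord],
    taxon: str,
    inversion: InversionID,
) -> tuple[float, int]:
    """Proportion of a taxon's scored larvae heterozygous (st/i) for an inversion.

    Returns ``(proportion, n_scored)``.
    """
    n = n_het = 0
    for r in records:
        if r.taxon_assignment != taxon:
            continue
        g = r.genotype_for(inversion)
        if g is None:
            continue
        n += 1
        n_het += g.state.is_heterozygote
    if n == 0:
        raise UndefinedResultError(
            f"no larvae of taxon {taxon!r} scored for "
            f"{format_inversion_name(inversion)}"
        )
    return n_het / n, n


@dataclass
class SharedPolymorphismIncidence:
    per_inversion: dict[str, tuple[int, int]]  # inversion -> (sharing, total)
    taxa_sharing_all: list[str]


def shared_polymorphism_incidence(
    table: pd.DataFrame,
) -> SharedPolymorphismIncidence:
    """Count, per autosomal inversion, how many taxa share it.

    ``table`` is a taxon-indexed DataFrame of heterozygote proportions.  A
    taxon shares an inversion iff its proportion is strictly positive (a
    printed zero means absence).  Also reports which taxa are positive for
    every listed inversion.
    """
    if table.empty:
        raise ValueError("polymorphism table is empty")
    if ((table < 0) | (table > 1)).any().any():
        raise ValueError("heterozygote proportions must lie in [0, 1]")
    n_taxa = len(table.index)
    per_inv = {
        str(col): (int((table[col] > 0).sum()), n_taxa) for col in table.columns
    }
    all_mask = (table > 0).all(axis=1)
    return SharedPolymorphismIncidence(
        per_inversion=per_inv,
        taxa_sharing_all=list(table.index[all_mask]),
    )


def taxon_census(catalog: TaxonCatalog) -> dict[str, int]:
    """Counts of taxa by rank: total, siblings, cytotypes."""
    n_sib = sum(1 for e in catalog if e.rank is Rank.SIBLING)
    n_cyt = sum(1 for e in catalog if e.rank is Rank.CYTOTYPE)
    return {"n_total": n_sib + n_cyt, "n_sibling": n_sib, "n_cytotype": n_cyt}


def linkage_table(
    records: Sequence[LarvaRecord],
    inversions: Sequence[InversionID],
) -> pd.DataFrame:
    """Survey-style table: one row per inversion with counts and Y linkage."""
    rows = []
    for inv in inversions:
        res = extent_of_y_linkage(records, inv)
        rows.append(
            {
                "inversion": format_inversion_name(inv),
                "n_y_bearing": res.n_y_bearing,
                "n_female": res.n_female,
                "y_linkage": res.y_linkage,
                "female_carrier_rate": res.female_carrier_rate,
                "classification": res.classification().value,
            }
        )
    return pd.DataFrame(rows)
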