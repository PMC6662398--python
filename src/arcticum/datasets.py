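"""Published survey data for the *Simulium arcticum* complex, built in code.

These are the printed summary tables of the cytotaxonomic survey of the
complex -- the taxon catalog (nine sibling species plus 22 cytotypes), the
per-taxon Y-linkage survey, the shared autosomal-polymorphism heterozygote
proportions, the geographic range areas with pairwise contact counts, the
two-site census of the IIL-6 cytotype, and the distal-breakpoint sharing
matrix for eleven IIL sex-linked inversions.  They serve as worked inputs
for the analysis modules and as regression fixtures.
"""

from __future__ import annotations

import datetime as _dt

import pandas as pd

from .nomenclature import parse_inversion_name
from .records import (
    Accuracy,
    GenotypeState,
    Genotype,
    LarvaRecord,
    Rank,
    Sex,
    Site,
    TaxonCatalog,
    TaxonEntry,
)

# --------------------------------------------------------------------------
# Taxon catalog: 9 sibling species and 22 cytotypes, each diagnosed by its
# sex-chromosome constitution.

_SIBLINGS = [
    ("S. brevicercum", "IIL-st"),
    ("S. arcticum IIL-1", "IIL-1"),
    ("S. saxosum", "IIL-2"),
    ("S. arcticum s.s.", "IIL-3"),
    ("S. apricarium", "IIL-7"),
    ("S. vampirum", "IIL-8,IIS-10·11"),
    ("S. chromatinum", "IIL-11"),
    ("S. arcticum IIS-4", "IIS-4"),
    ("S. negativum", "IL-3·4"),
]

_CYTOTYPES = [
    "IIL-9", "IIL-13", "IIL-15", "IIL-10", "IIL-79", "IIL-19", "IIL-18",
    "IIL-22", "IIL-6", "IIL-80", "IIL-12", "IIS-15", "IIL-73·74", "IIL-17",
    "IIL-21", "IIS-12", "IIL-dup", "IIS-49·52", "IIL-57·58", "IIL-14",
    "IIL-16", "IIL-68",
]


def taxon_catalog() -> TaxonCatalog:
    """The 31-taxon catalog of the complex (9 siblings, 22 cytotypes)."""
    entries = [
        TaxonEntry(
            name=name,
            rank=Rank.SIBLING,
            sex_chromosome=tuple(parse_inversion_name(p) for p in sc.split(",")),
        )
        for name, sc in _SIBLINGS
    ]
    entries += [
        TaxonEntry(
            name=f"S. arcticum {inv}",
            rank=Rank.CYTOTYPE,
            sex_chromosome=(parse_inversion_name(inv),),
        )
        for inv in _CYTOTYPES
    ]
    return TaxonCatalog(entries)


# --------------------------------------------------------------------------
# Y-linkage survey: per-taxon number of sites, male larvae analysed, and
# extent of Y linkage for the 27 taxa with an inverted sex chromosome.
# Male counts unavailable in the published survey are stored as missing.

_LINKAGE_ROWS = [
    ("S. arcticum IIL-1", 5, 278, 1.000),
    ("S. arcticum s.s. IIL-3", 36, 2753, 0.998),
    ("S. arcticum IIL-6", 2, 113, 1.000),
    ("S. arcticum IIL-9", 17, 479, 0.981),
    ("S. arcticum IIL-10", 9, 296, 1.000),
    ("S. arcticum IIL-13", 4, 25, 1.000),
    ("S. arcticum IIL-15", 12, 80, 1.000),
    ("S. arcticum IIL-17", 2, 82, 0.975),
    ("S. arcticum IIL-18", 12, 183, 0.967),
    ("S. arcticum IIL-19", 5, 500, 0.994),
    ("S. arcticum IIL-21", 1, 86, 1.000),
    ("S. arcticum IIL-22", 3, 261, 0.996),
    ("S. arcticum IIL-38", 1, 27, 1.000),
    ("S. arcticum IIL-51", 1, 16, 1.000),
    ("S. arcticum IIL-68", 3, 106, 1.000),
    ("S. arcticum IIL-73·74", 2, 159, 1.000),
    ("S. arcticum IIL-79", 8, 221, 0.996),
    ("S. arcticum IIL-80", 3, 21, 1.000),
    ("S. arcticum IIL-duplication", 1, 21, 1.000),
    ("S. arcticum IIS-12", 1, 17, 1.000),
    ("S. arcticum IIS-15", 1, 24, 1.000),
    ("S. negativum IL-3·4", 7, 216, 1.000),
    ("S. arcticum IIS-49·52", 1, None, 1.000),
    ("S. arcticum IIL-57·58", 1, None, 1.000),
    ("S. arcticum IIL-14", 1, None, 1.000),
    ("S. arcticum IIL-16", 1, None, 1.000),
    ("S. arcticum IIL-12", 1, None, 1.000),
]


def y_linkage_survey() -> pd.DataFrame:
    """Published per-taxon extent-of-Y-linkage survey."""
    df = pd.DataFrame(
        _LINKAGE_ROWS,
        columns=["taxon", "sites_observed", "male_larvae", "y_linkage"],
    )
    df["male_larvae"] = df["male_larvae"].astype("Int64")
    return df


# --------------------------------------------------------------------------
# Shared autosomal polymorphisms: heterozygote proportions for the three
# commonest autosomal inversions across 15 taxa of the complex.

_POLY_ROWS = [
    ("S. brevicercum", 0.039, 0.055, 0.190),
    ("S. saxosum", 0.022, 0.174, 0.060),
    ("S. arcticum s.s.", 0.497, 0.028, 0.595),
    ("S. apricarium", 0.004, 0.147, 0.0),
    ("S. negativum", 0.079, 0.0, 0.0),
    ("S. arcticum IIL-9", 0.088, 0.055, 0.071),
    ("S. arcticum IIL-13", 0.004, 0.028, 0.0),
    ("S. arcticum IIL-15", 0.0, 0.0, 0.012),
    ("S. arcticum IIL-18", 0.002, 0.0, 0.0),
    ("S. arcticum IIL-19", 0.041, 0.294, 0.0),
    ("S. arcticum IIL-21", 0.0, 0.174, 0.0),
    ("S. arcticum IIL-22", 0.142, 0.0, 0.0),
    ("S. arcticum IIL-73·74", 0.015, 0.046, 0.0),
    ("S. arcticum IIL-79", 0.041, 0.009, 0.060),
    ("S. arcticum IIL-6", 0.457, 0.005, 0.0),
]


def autosomal_polymorphism_table() -> pd.DataFrame:
    """Taxon x inversion matrix of heterozygote proportions (15 taxa)."""
    df = pd.DataFrame(_POLY_ROWS, columns=["taxon", "IS-1", "IL-1", "IIL-20"])
    return df.set_index("taxon")


# --------------------------------------------------------------------------
# Range areas and pairwise contact counts for all 31 taxa, as published.
# Areas are in square kilometres in the survey's (unpublished) projection;
# the 79 km2 single-location entries are 5-km buffer discs.

_RANGE_ROWS = [
    ("S. saxosum", "sibling", 2829500, 8, 16),
    ("S. negativum", "sibling", 2819090, 8, 18),
    ("S. arcticum IIL-1", "sibling", 2770444, 7, 7),
    ("S. brevicercum", "sibling", 2312022, 8, 18),
    ("S. apricarium", "sibling", 1950914, 6, 15),
    ("S. arcticum s.s.", "sibling", 1683894, 8, 14),
    ("S. chromatinum", "sibling", 812216, 5, 3),
    ("S. vampirum", "sibling", 605393, 6, 0),
    ("S. arcticum IIS-4", "sibling", 15736, 6, 0),
    ("S. arcticum IIL-9", "cytotype", 80355, 7, 11),
    ("S. arcticum IIL-13", "cytotype", 39902, 6, 5),
    ("S. arcticum IIL-15", "cytotype", 30369, 5, 6),
    ("S. arcticum IIL-10", "cytotype", 25729, 5, 4),
    ("S. arcticum IIL-79", "cytotype", 20384, 6, 3),
    ("S. arcticum IIL-19", "cytotype", 14432, 6, 5),
    ("S. arcticum IIL-18", "cytotype", 8193, 5, 5),
    ("S. arcticum IIL-22", "cytotype", 2776, 6, 3),
    ("S. arcticum IIL-6", "cytotype", 1197, 3, 0),
    ("S. arcticum IIL-80", "cytotype", 1095, 6, 2),
    ("S. arcticum IIL-12", "cytotype", 729, 1, 0),
    ("S. arcticum IIS-15", "cytotype", 441, 5, 3),
    ("S. arcticum IIL-73·74", "cytotype", 81, 4, 2),
    ("S. arcticum IIL-17", "cytotype", 79, 5, 2),
    ("S. arcticum IIL-21", "cytotype", 79, 4, 1),
    ("S. arcticum IIS-12", "cytotype", 79, 3, 1),
    ("S. arcticum IIL-duplication", "cytotype", 79, 3, 1),
    ("S. arcticum IIS-49·52", "cytotype", 79, 3, 0),
    ("S. arcticum IIL-57·58", "cytotype", 79, 3, 0),
    ("S. arcticum IIL-14", "cytotype", 79, 0, 0),
    ("S. arcticum IIL-16", "cytotype", 79, 1, 0),
    ("S. arcticum IIL-68", "cytotype", 8, 4, 2),
]


def range_contact_summary() -> pd.DataFrame:
    """Published range areas (km2) and contact counts, split by partner rank."""
    return pd.DataFrame(
        _RANGE_ROWS,
        columns=["taxon", "rank", "area_km2", "contacts_siblings", "contacts_cytotypes"],
    )


def range_catalog() -> TaxonCatalog:
    """Taxon catalog implied by the range summary (31 taxa; ranks only)."""
    entries = []
    for name, rank, *_ in _RANGE_ROWS:
        if name == "S. brevicercum":
            sc = (parse_inversion_name("IIL-st"),)
        elif name == "S. vampirum":
            sc = (parse_inversion_name("IIL-8"), parse_inversion_name("IIS-10·11"))
        elif name == "S. negativum":
            sc = (parse_inversion_name("IL-3·4"),)
        elif name == "S. saxosum":
            sc = (parse_inversion_name("IIL-2"),)
        elif name == "S. apricarium":
            sc = (parse_inversion_name("IIL-7"),)
        elif name == "S. chromatinum":
            sc = (parse_inversion_name("IIL-11"),)
        elif name == "S. arcticum s.s.":
            sc = (parse_inversion_name("IIL-3"),)
        else:
            sc = (parse_inversion_name(name.replace("S. arcticum ", "")),)
        entries.append(TaxonEntry(name=name, rank=Rank(rank), sex_chromosome=sc))
    return TaxonCatalog(entries)


# --------------------------------------------------------------------------
# The IIL-6 cytotype: two Alaskan sites, per-site counts of standard females,
# heterozygous males, and one X0X0Y triploid whose single inverted constituent
# makes it a Y-bearing carrier.

IIL6_SITES = [
    Site("delta_clearwater", "Delta Clearwater River, Alaska",
         63.959281, -145.647495, Accuracy.GPS, elevation_m=411.8),
    Site("monument_creek", "Monument Creek, Alaska",
         65.051123, -146.030510, Accuracy.GPS, elevation_m=388.0),
]

# (site_id, n_females_standard, n_males_het, n_polyploid_carriers)
_IIL6_COUNTS = [
    ("delta_clearwater", 83, 102, 1),
    ("monument_creek", 10, 10, 0),
]


def iil6_site_counts() -> pd.DataFrame:
    return pd.DataFrame(
        _IIL6_COUNTS, columns=["site_id", "females_standard", "males_het", "polyploid"]
    )


def iil6_records() -> list[LarvaRecord]:
    """Expand the two-site IIL-6 census into individual larval records.

    Females are standard homozygotes, males are st/i heterozygotes, and the
    single X0X0Y triploid is stored as a Y-bearing male-determining carrier
    with an explicit ploidy note.
    """
    inv = parse_inversion_name("IIL-6")
    date = _dt.date(2016, 5, 15)
    records: list[LarvaRecord] = []
    for site_id, n_f, n_m, n_poly in _IIL6_COUNTS:
        for i in range(n_f):
            records.append(
                LarvaRecord(
                    f"{site_id}_F{i:03d}", site_id, date, Sex.F, False,
                    [Genotype(inv, GenotypeState.ST_ST)], "S. arcticum IIL-6",
                )
            )
        for i in range(n_m):
            records.append(
                LarvaRecord(
                    f"{site_id}_M{i:03d}", site_id, date, Sex.M, True,
                    [Genotype(inv, GenotypeState.ST_I)], "S. arcticum IIL-6",
                )
            )
        for i in range(n_poly):
            records.append(
                LarvaRecord(
                    f"{site_id}_P{i:03d}", site_id, date, Sex.M, True,
                    [Genotype(inv, GenotypeState.ST_I, ploidy_note="st/st/i")],
                    "S. arcticum IIL-6",
                )
            )
    return records


# --------------------------------------------------------------------------
# Rock Creek (Missoula County, Montana) worked collection: all 447 females
# standard; the 261 males split between IIL-9 st/i (106) and IIL-19 st/i (155).

ROCK_CREEK_SITE = Site(
    "rock_creek", "Rock Creek, Missoula County, Montana",
    46.70, -113.67, Accuracy.LEGACY,
)


def rock_creek_records() -> list[LarvaRecord]:
    iil9 = parse_inversion_name("IIL-9")
    iil19 = parse_inversion_name("IIL-19")
    date = _dt.date(2006, 3, 14)
    records: list[LarvaRecord] = []
    for i in range(447):
        records.append(
            LarvaRecord(
                f"rc_F{i:03d}", "rock_creek", date, Sex.F, False,
                [Genotype(iil9, GenotypeState.ST_ST),
                 Genotype(iil19, GenotypeState.ST_ST)],
            )
        )
    for i in range(106):
        records.append(
            LarvaRecord(
                f"rc_M9_{i:03d}", "rock_creek", date, Sex.M, True,
                [Genotype(iil9, GenotypeState.ST_I),
                 Genotype(iil19, GenotypeState.ST_ST)],
                "S. arcticum IIL-9",
            )
        )
    for i in range(155):
        records.append(
            LarvaRecord(
                f"rc_M19_{i:03d}", "rock_creek", date, Sex.M, True,
                [Genotype(iil9, GenotypeState.ST_ST),
                 Genotype(iil19, GenotypeState.ST_I)],
                "S. arcticum IIL-19",
            )
        )
    return records


# --------------------------------------------------------------------------
# Distal-distal breakpoint sharing among 11 IIL sex-linked inversions, as
# published (+ = the two inversions' distal breakpoints coincide).

_DISTAL_ORDER = [
    "IIL-1", "IIL-15", "IIL-3", "IIL-22", "IIL-6", "IIL-10",
    "IIL-68", "IIL-13", "IIL-16", "IIL-17", "IIL-19",
]

_DISTAL_SHARED_PAIRS = [
    ("IIL-1", "IIL-15"),
    ("IIL-3", "IIL-22"),
    ("IIL-3", "IIL-6"),
    ("IIL-22", "IIL-6"),
    ("IIL-10", "IIL-68"),
    ("IIL-13", "IIL-16"),
    ("IIL-13", "IIL-17"),
    ("IIL-13", "IIL-19"),
    ("IIL-16", "IIL-17"),
    ("IIL-16", "IIL-19"),
    ("IIL-17", "IIL-19"),
]


def distal_sharing_matrix() -> pd.DataFrame:
    """Published +/- matrix of distal-distal breakpoint sharing (11 inversions)."""
    df = pd.DataFrame("-", index=_DISTAL_ORDER, columns=_DISTAL_ORDER)
    for a, b in _DISTAL_SHARED_PAIRS:
        df.loc[a, b] = "+"
        df.loc[b, a] = "+"
    for name in _DISTAL_ORDER:
        df.loc[name, name] = ""
    return df


# --------------------------------------------------------------------------
# Autosomal heterozygote proportions within the IIL-6 cytotype (n = 206).

IIL6_AUTOSOMAL_HET = {
    "IS-1": 0.457,
    "IL-1": 0.005,
    "IL-2": 0.005,
    "IIS-3": 0.005,
    "IIS-4": 0.047,
}
IIL6_N = 206
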