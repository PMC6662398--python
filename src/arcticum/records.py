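"""Domain types and CSV readers/writers for larval chromosome-scoring data.

A *larval record* is one chromosomally scored black-fly larva: its site,
collection date, sex, whether it carries a Y chromosome, and a genotype
(``st/st``, ``st/i`` or ``i/i``) for every inversion scored on its polytene
chromosomes.  Sites carry WGS84 coordinates with an explicit positional
accuracy class (GPS, legacy description, or county centroid).  A taxon
catalog lists the named members of the complex -- full sibling species and
cytotypes -- each diagnosed by its sex-chromosome inversion.

CSV schemas (UTF-8, header mandatory):

* records: ``larva_id, site_id, date, sex, y_bearing`` then one column per
  scored inversion holding ``st/st|st/i|i/i`` (blank = not scored; a
  triploid cell such as ``st/st/i`` is accepted and recorded in the
  genotype's ploidy note).
* sites: ``site_id, name, lat, lon, elevation_m, accuracy``.
* taxa: ``name, rank, sex_chromosome``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .nomenclature import (
    InversionID,
    Special,
    canonical_name,
    format_inversion_name,
    parse_inversion_name,
)

PathLike = Union[str, Path]


class GenotypeState(str, Enum):
    ST_ST = "st/st"
    ST_I = "st/i"
    I_I = "i/i"

    @property
    def is_carrier(self) -> bool:
        return self is not GenotypeState.ST_ST

    @property
    def is_heterozygote(self) -> bool:
        return self is GenotypeState.ST_I


class Sex(str, Enum):
    F = "F"
    M = "M"


class Accuracy(str, Enum):
    """Positional accuracy of a collection site.

    ``gps`` is ±5 m, ``legacy`` a described location within ~1 km, and
    ``county_centroid`` the centroid of a county (~100 km).
    """

    GPS = "gps"
    LEGACY = "legacy"
    COUNTY_CENTROID = "county_centroid"


class Rank(str, Enum):
    SIBLING = "sibling"
    CYTOTYPE = "cytotype"


@dataclass(frozen=True)
class Genotype:
    inversion: InversionID
    state: GenotypeState
    ploidy_note: Optional[str] = None


@dataclass
class LarvaRecord:
    larva_id: str
    site_id: str
    collection_date: Optional[_dt.date]
    sex: Sex
    y_bearing: bool
    genotypes: list[Genotype] = field(default_factory=list)
    taxon_assignment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex is Sex.M and not self.y_bearing:
            raise ValueError(f"larva {self.larva_id}: sex=M requires y_bearing=True")

    def genotype_for(self, inversion: InversionID) -> Optional[Genotype]:
        for g in self.genotypes:
            if g.inversion == inversion:
                return g
        return None


@dataclass(frozen=True)
class Site:
    site_id: str
    name: str
    lat: float
    lon: float
    accuracy: Accuracy
    elevation_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"site {self.site_id}: latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"site {self.site_id}: longitude {self.lon} out of range")


@dataclass(frozen=True)
class TaxonEntry:
    name: str
    rank: Rank
    # The diagnostic sex-chromosome inversion(s); taxa with non-inverted sex
    # chromosomes (e.g. S. brevicercum) carry a single standard entry.
    sex_chromosome: tuple[InversionID, ...]


@dataclass
class TaxonCatalog:
    entries: list[TaxonEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate taxon names in catalog: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def rank_of(self, name: str) -> Rank:
        for e in self.entries:
            if e.name == name:
                return e.rank
        raise KeyError(name)


# ---------------------------------------------------------------------------
# date handling


def parse_collection_date(text: str) -> _dt.date:
    """Accept ISO-8601 (2006-03-14) and US month/day/year (3/14/2006) dates."""
    text = text.strip()
    try:
        return _dt.date.fromisoformat(text)
    except ValueError:
        pass
    for fmt in ("%m/%d/%Y", "%m/%d/%y"):
        try:
            return _dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable collection date {text!r}")


# ---------------------------------------------------------------------------
# genotype cells

_TRIPLOID_STATES = {
    "st/st/st": (GenotypeState.ST_ST, False),
    "st/st/i": (GenotypeState.ST_I, True),
    "st/i/i": (GenotypeState.ST_I, True),
    "i/i/i": (GenotypeState.I_I, True),
}


def parse_genotype_cell(inversion: InversionID, cell: str) -> Genotype:
    """Parse one genotype cell; triploid spellings keep a ploidy note."""
    value = cell.strip().lower()
    try:
        return Genotype(inversion, GenotypeState(value))
    except ValueError:
        pass
    if value in _TRIPLOID_STATES:
        state, _carrier = _TRIPLOID_STATES[value]
        return Genotype(inversion, state, ploidy_note=cell.strip())
    raise ValueError(
        f"unknown genotype state {cell!r} for {format_inversion_name(inversion)}"
    )


_META_COLUMNS = ("larva_id", "site_id", "date", "sex", "y_bearing")
_TRUE_TOKENS = {"true", "t", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n"}


def _parse_bool(cell: str, default: Optional[bool] = None) -> bool:
    v = str(cell).strip().lower()
    if v in _TRUE_TOKENS:
        return True
    if v in _FALSE_TOKENS:
        return False
    if v in ("", "nan") and default is not None:
        return default
    raise ValueError(f"unparseable boolean {cell!r}")


def load_larval_records(path: PathLike) -> list[LarvaRecord]:
    """Load larval records from CSV; one record per data row.

    Columns beyond the five metadata columns are inversion names; their
    cells are genotype states (blank = inversion not scored on that larva).
    Errors name the offending row and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing mandatory column(s): {missing}")
    inversion_cols = [c for c in df.columns if c not in _META_COLUMNS and c != "taxon"]
    inversions = {c: parse_inversion_name(c) for c in inversion_cols}
    records: list[LarvaRecord] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after header
        sex = Sex(row["sex"].strip().upper())
        y_bearing = _parse_bool(row["y_bearing"], default=(sex is Sex.M))
        genotypes = []
        for col in inversion_cols:
            cell = row[col]
            if not str(cell).strip():
                continue
            try:
                genotypes.append(parse_genotype_cell(inversions[col], cell))
            except ValueError as exc:
                raise ValueError(f"row {rownum}, column {col!r}: {exc}") from exc
        date = parse_collection_date(row["date"]) if row["date"].strip() else None
        taxon = row["taxon"].strip() if "taxon" in df.columns else ""
        try:
            records.append(
                LarvaRecord(
                    larva_id=row["larva_id"],
                    site_id=row["site_id"],
                    collection_date=date,
                    sex=sex,
                    y_bearing=y_bearing,
                    genotypes=genotypes,
                    taxon_assignment=taxon or None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
    return records


def write_larval_records(records: Sequence[LarvaRecord], path: PathLike) -> None:
    """Write records to the CSV schema read by :func:`load_larval_records`."""
    inv_names: list[str] = []
    for r in records:
        for g in r.genotypes:
            name = format_inversion_name(g.inversion)
            if name not in inv_names:
                inv_names.append(name)
    rows = []
    for r in records:
        row = {
            "larva_id": r.larva_id,
            "site_id": r.site_id,
            "date": r.collection_date.isoformat() if r.collection_date else "",
            "sex": r.sex.value,
            "y_bearing": str(r.y_bearing).lower(),
            "taxon": r.taxon_assignment or "",
        }
        for g in r.genotypes:
            cell = g.ploidy_note if g.ploidy_note else g.state.value
            row[format_inversion_name(g.inversion)] = cell
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_META_COLUMNS) + ["taxon"] + inv_names)
    df.to_csv(path, index=False)


def load_sites(path: PathLike) -> list[Site]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("site_id", "name", "lat", "lon", "accuracy")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sites CSV missing mandatory column(s): {missing}")
    sites = []
    for idx, row in df.iterrows():
        elev = row.get("elevation_m", "")
        sites.append(
            Site(
                site_id=row["site_id"],
                name=row["name"],
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                accuracy=Accuracy(row["accuracy"].strip().lower()),
                elevation_m=float(elev) if str(elev).strip() else None,
            )
        )
    return sites


def write_sites(sites: Sequence[Site], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "name": s.name,
                "lat": s.lat,
                "lon": s.lon,
                "elevation_m": "" if s.elevation_m is None else s.elevation_m,
                "accuracy": s.accuracy.value,
            }
            for s in sites
        ]
    )
    df.to_csv(path, index=False)


def _parse_sex_chromosome(cell: str) -> tuple[InversionID, ...]:
    parts = [p for p in str(cell).replace(";", ",").split(",") if p.strip()]
    if not parts:
        raise ValueError("empty sex_chromosome cell")
    return tuple(parse_inversion_name(p) for p in parts)


def load_taxon_catalog(path: PathLike) -> TaxonCatalog:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("name", "rank", "sex_chromosome")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"taxon CSV missing mandatory column(s): {missing}")
    entries = [
        TaxonEntry(
            name=row["name"],
            rank=Rank(row["rank"].strip().lower()),
            sex_chromosome=_parse_sex_chromosome(row["sex_chromosome"]),
        )
        for _, row in df.iterrows()
    ]
    return TaxonCatalog(entries)


def write_taxon_catalog(catalog: TaxonCatalog, path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "name": e.name,
                "rank": e.rank.value,
                "sex_chromosome": ",".join(
                    format_inversion_name(i) for i in e.sex_chromosome
                ),
            }
            for e in catalog
        ]
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    orphan_site_ids: list[str]
    unknown_taxa: list[str]
    sex_contradictions: list[str]
    counts: pd.DataFrame  # columns: site_id, date, taxon, n

    @property
    def n_problems(self) -> int:
        return (
            len(self.orphan_site_ids)
            + len(self.unknown_taxa)
            + len(self.sex_contradictions)
        )

    def __bool__(self) -> bool:
        return self.n_problems == 0


def validate_collection(
    records: Sequence[LarvaRecord],
    sites: Sequence[Site],
    catalog: Optional[TaxonCatalog] = None,
) -> ValidationReport:
    """Cross-check records against the site table and taxon catalog.

    Flags site ids absent from the site table, taxon assignments absent from
    the catalog, and sex/Y-bearing contradictions; also tabulates record
    counts per (site, date, taxon).
    """
    site_ids = {s.site_id for s in sites}
    catalog_names = set(catalog.names()) if catalog is not None else None
    orphans, unknown, contradictions = [], [], []
    tally: dict[tuple, int] = {}
    for r in records:
        if r.site_id not in site_ids:
            orphans.append(r.larva_id)
        if (
            catalog_names is not None
            and r.taxon_assignment is not None
            and r.taxon_assignment not in catalog_names
        ):
            unknown.append(r.larva_id)
        if r.sex is Sex.M and not r.y_bearing:
            contradictions.append(r.larva_id)
        key = (
            r.site_id,
            r.collection_date.isoformat() if r.collection_date else "",
            r.taxon_assignment or "",
        )
        tally[key] = tally.get(key, 0) + 1
    counts = pd.DataFrame(
        [(s, d, t, n) for (s, d, t), n in sorted(tally.items())],
        columns=["site_id", "date", "taxon", "n"],
    )
    return ValidationReport(orphans, unknown, contradictions, counts)
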