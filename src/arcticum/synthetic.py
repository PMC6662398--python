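"""Synthetic data with the statistical structure of the real survey.

The generator emulates the study design of a continental cytotaxonomic
survey: a handful of sibling species with large (order 10^6 km2) ranges;
cytotypes whose few collection sites nest inside a sibling's range (the
generative form of the sympatric-origin prediction), with an optional count
of "orphan" cytotypes placed outside every sibling range to model the
exception; larval collections per site with a configurable sex ratio,
near-complete Y linkage of each taxon's diagnostic inversion, and autosomal
inversions segregating at specified heterozygote proportions; and a
breakpoint catalog with an exact number of planted sharing events.

Everything is deterministic under the config's seed, and the true generating
parameters are exported alongside so each analysis stage can be checked for
parameter recovery.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point

from .breakpoints import BreakpointCatalog, BreakpointEntry
from .georange import AlbersEqualArea, RangePolygon, build_range_polygon
from .nomenclature import InversionID, format_inversion_name, parse_inversion_name
from .records import (
    Accuracy,
    Genotype,
    GenotypeState,
    LarvaRecord,
    Rank,
    Sex,
    Site,
    TaxonCatalog,
    TaxonEntry,
)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic survey.

    Defaults mirror the real study's shape: 9 siblings and 22 cytotypes, one
    of which falls outside all sibling ranges; Y linkage 0.99 (the survey's
    values run 0.967-1.000); autosomal heterozygosities at the scale of the
    published shared-polymorphism table; ~200 larvae per collection at an
    even sex ratio; and a site-accuracy mixture matching the survey's
    96 GPS / 119 legacy / 92 county-centroid split.
    """

    seed: int
    n_siblings: int = 9
    n_cytotypes: int = 22
    n_orphan_cytotypes: int = 1
    sites_per_sibling: int = 25
    max_sites_per_cytotype: int = 8
    sibling_spread_km: float = 450.0
    cytotype_spread_km: float = 60.0
    y_linkage: float = 0.99
    y_linkage_by_taxon: dict[str, float] = field(default_factory=dict)
    autosomal_het: dict[str, float] = field(
        default_factory=lambda: {"IS-1": 0.457, "IL-1": 0.055, "IIL-20": 0.060}
    )
    larvae_per_site: int = 200
    sex_ratio: float = 0.5
    multi_taxon_fraction: float = 0.5
    accuracy_mixture: tuple[float, float, float] = (96 / 307, 119 / 307, 92 / 307)
    include_standard_sibling: bool = True
    n_breakpoint_inversions: int = 30
    planted_shared_breakpoints: int = 46

    def __post_init__(self) -> None:
        probs = [self.y_linkage, self.sex_ratio, self.multi_taxon_fraction,
                 *self.accuracy_mixture, *self.autosomal_het.values(),
                 *self.y_linkage_by_taxon.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.accuracy_mixture) - 1.0) > 1e-9:
            raise ValueError("accuracy_mixture must sum to 1")

    def lam(self, taxon: str) -> float:
        return self.y_linkage_by_taxon.get(taxon, self.y_linkage)


@dataclass
class SyntheticGeography:
    sites: list[Site]
    catalog: TaxonCatalog
    true_ranges: list[RangePolygon]
    site_frequencies: dict[str, dict[str, float]]  # site_id -> taxon -> p
    diagnostic: dict[str, Optional[InversionID]]  # taxon -> diagnostic inversion


def _taxon_names_and_diagnostics(
    config: SimulationConfig,
) -> tuple[list[TaxonEntry], dict[str, Optional[InversionID]]]:
    entries: list[TaxonEntry] = []
    diagnostic: dict[str, Optional[InversionID]] = {}
    for i in range(config.n_siblings):
        name = f"sibling-{i + 1:02d}"
        if i == 0 and config.include_standard_sibling:
            inv = None
            sc = (parse_inversion_name("IIL-st"),)
        else:
            inv = parse_inversion_name(f"IIL-{i + 1}")
            sc = (inv,)
        entries.append(TaxonEntry(name=name, rank=Rank.SIBLING, sex_chromosome=sc))
        diagnostic[name] = inv
    for j in range(config.n_cytotypes):
        name = f"cytotype-{j + 1:02d}"
        inv = parse_inversion_name(f"IIL-{100 + j}")
        entries.append(
            TaxonEntry(name=name, rank=Rank.CYTOTYPE, sex_chromosome=(inv,))
        )
        diagnostic[name] = inv
    return entries, diagnostic


def _sample_inside(polygon, rng: np.random.Generator, n: int) -> np.ndarray:
    """Rejection-sample n points strictly inside a shapely polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    out = []
    while len(out) < n:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if polygon.contains(Point(x, y)):
            out.append((x, y))
    return np.array(out)


def simulate_geography(config: SimulationConfig) -> SyntheticGeography:
    """Generate sites, a taxon catalog, and the true range polygons.

    Sibling site clouds are Gaussian in the projected plane around centres
    spread across western North America; each nested cytotype's sites are
    drawn inside its host sibling's convex hull, while orphan cytotypes are
    placed far outside every sibling range.
    """
    rng = np.random.default_rng(config.seed)
    proj = AlbersEqualArea()
    entries, diagnostic = _taxon_names_and_diagnostics(config)
    catalog = TaxonCatalog(entries)
    siblings = [e.name for e in entries if e.rank is Rank.SIBLING]
    cytotypes = [e.name for e in entries if e.rank is Rank.CYTOTYPE]
    if config.n_orphan_cytotypes > len(cytotypes):
        raise ValueError("more orphan cytotypes than cytotypes")

    sites: list[Site] = []
    site_frequencies: dict[str, dict[str, float]] = {}
    taxon_points: dict[str, list[tuple[float, float]]] = {t: [] for t in
                                                          siblings + cytotypes}
    accuracy_classes = [Accuracy.GPS, Accuracy.LEGACY, Accuracy.COUNTY_CENTROID]

    def add_site(taxon: str, x: float, y: float) -> Site:
        sid = f"s{len(sites) + 1:04d}"
        lon, lat = proj.inverse(x, y)
        acc = accuracy_classes[
            rng.choice(3, p=np.asarray(config.accuracy_mixture))
        ]
        site = Site(sid, f"synthetic site {sid}", float(lat), float(lon), acc)
        sites.append(site)
        taxon_points[taxon].append((x, y))
        return site

    # sibling clouds
    spread_m = config.sibling_spread_km * 1e3
    centre_lons = rng.uniform(-140.0, -105.0, size=config.n_siblings)
    centre_lats = rng.uniform(45.0, 62.0, size=config.n_siblings)
    cx, cy = proj.forward(centre_lons, centre_lats)
    sibling_sites: dict[str, list[Site]] = {}
    for name, x0, y0 in zip(siblings, cx, cy):
        pts = rng.normal([x0, y0], spread_m, size=(config.sites_per_sibling, 2))
        sibling_sites[name] = [add_site(name, x, y) for x, y in pts]

    sibling_ranges = {
        name: build_range_polygon(
            name, np.array(taxon_points[name]), rank=Rank.SIBLING
        )
        for name in siblings
    }

    # nested cytotypes inside a host sibling's hull; orphans far to the east
    n_orphan = config.n_orphan_cytotypes
    orphan_set = set(cytotypes[-n_orphan:]) if n_orphan else set()
    cyto_sites: dict[str, list[Site]] = {}
    for j, name in enumerate(cytotypes):
        n_sites = int(rng.integers(1, config.max_sites_per_cytotype + 1))
        if name in orphan_set:
            # well east of the sibling window (lon >= -75): no contact possible
            lon0 = -70.0 + (j % 5)
            lat0 = 45.0 + (j % 10)
            x0, y0 = proj.forward(lon0, lat0)
            pts = rng.normal(
                [float(x0), float(y0)], config.cytotype_spread_km * 1e3,
                size=(n_sites, 2),
            )
        else:
            host = siblings[int(rng.integers(0, len(siblings)))]
            pts = _sample_inside(sibling_ranges[host].polygon, rng, n_sites)
        cyto_sites[name] = [add_site(name, x, y) for x, y in pts]

    true_ranges = list(sibling_ranges.values()) + [
        build_range_polygon(name, np.array(taxon_points[name]), rank=Rank.CYTOTYPE)
        for name in cytotypes
    ]

    # per-site taxon frequency vectors: each site hosts its owner taxon and,
    # for a fraction of sibling sites, one or two of that sibling's nested
    # cytotypes as minority taxa
    for name in siblings:
        nested = [
            c for c in cytotypes
            if c not in orphan_set
            and any(
                sibling_ranges[name].polygon.contains(Point(p))
                for p in taxon_points[c]
            )
        ]
        for site in sibling_sites[name]:
            freqs = {name: 1.0}
            if nested and rng.uniform() < config.multi_taxon_fraction:
                k = int(rng.integers(1, min(2, len(nested)) + 1))
                chosen = list(rng.choice(nested, size=k, replace=False))
                w = rng.dirichlet(np.ones(k + 1) * 2.0)
                freqs = {name: float(w[0])}
                for c, wc in zip(chosen, w[1:]):
                    freqs[c] = float(wc)
            site_frequencies[site.site_id] = freqs
    for name in cytotypes:
        for site in cyto_sites[name]:
            site_frequencies[site.site_id] = {name: 1.0}

    return SyntheticGeography(
        sites=sites,
        catalog=catalog,
        true_ranges=true_ranges,
        site_frequencies=site_frequencies,
        diagnostic=diagnostic,
    )


def _hw_genotype(q: float, rng: np.random.Generator) -> GenotypeState:
    """Draw a genotype with heterozygote probability q.

    Homozygote mass is split by Hardy-Weinberg from the allele frequency
    implied by q (for q > 0.5, where no HW solution exists, it is split
    evenly).
    """
    u = rng.uniform()
    if u < q:
        return GenotypeState.ST_I
    if q > 0.5:
        w_ii = 0.5
    else:
        p = 0.5 * (1.0 - math.sqrt(1.0 - 2.0 * q))  # inverted-allele frequency
        denom = p * p + (1.0 - p) * (1.0 - p)
        w_ii = p * p / denom
    return GenotypeState.I_I if (u - q) / (1.0 - q) < w_ii else GenotypeState.ST_ST


def simulate_larvae(
    config: SimulationConfig,
    geography: SyntheticGeography,
) -> list[LarvaRecord]:
    """Draw larval records site by site.

    Each larva's taxon comes from its site's frequency vector; sex from the
    configured sex ratio.  Y-bearing larvae carry their taxon's diagnostic
    inversion st/i with probability lambda (the taxon's Y linkage); females
    and non-carriers are standard.  Autosomal inversions are drawn
    independently at the configured heterozygote proportions.
    """
    rng = np.random.default_rng(config.seed + 1)
    autosomal = {
        parse_inversion_name(k): q for k, q in config.autosomal_het.items()
    }
    records: list[LarvaRecord] = []
    date = _dt.date(2018, 5, 1)
    for site in geography.sites:
        freqs = geography.site_frequencies[site.site_id]
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"site {site.site_id}: taxon frequencies sum to "
                f"{sum(freqs.values())}, not 1"
            )
        taxa = list(freqs)
        p = np.array([freqs[t] for t in taxa])
        site_diags = {
            geography.diagnostic[t] for t in taxa if geography.diagnostic[t]
        }
        for i in range(config.larvae_per_site):
            taxon = taxa[int(rng.choice(len(taxa), p=p))]
            male = rng.uniform() < config.sex_ratio
            genotypes: list[Genotype] = []
            diag = geography.diagnostic[taxon]
            for inv in sorted(site_diags, key=format_inversion_name):
                if male and inv == diag and rng.uniform() < config.lam(taxon):
                    state = GenotypeState.ST_I
                else:
                    state = GenotypeState.ST_ST
                genotypes.append(Genotype(inv, state))
            for inv, q in autosomal.items():
                genotypes.append(Genotype(inv, _hw_genotype(q, rng)))
            records.append(
                LarvaRecord(
                    larva_id=f"{site.site_id}_L{i:04d}",
                    site_id=site.site_id,
                    collection_date=date,
                    sex=Sex.M if male else Sex.F,
                    y_bearing=male,
                    genotypes=genotypes,
                    taxon_assignment=taxon,
                )
            )
    return records


def simulate_breakpoint_catalog(config: SimulationConfig) -> BreakpointCatalog:
    """A breakpoint catalog with exactly the configured number of shared events.

    Proximal labels are drawn from an even-number pool and distal labels from
    an odd pool, so no sharing arises by accident; the planted events are
    groups of inversions assigned a common distal label (a group of g
    inversions contributes g(g-1)/2 distal-distal share events).  The section
    domain is sized to the catalog rather than to any real band map so that
    the planted count is exact.
    """
    n = config.n_breakpoint_inversions
    k = config.planted_shared_breakpoints
    if n < 2:
        raise ValueError("need at least two inversions")
    rng = np.random.default_rng(config.seed + 2)
    # disjoint label pools: proximal even, distal odd
    prox_pool = list(range(2, 4 * n + 2, 2))
    dist_pool = list(range(1, 4 * n + 1, 2))
    rng.shuffle(prox_pool)
    rng.shuffle(dist_pool)

    # partition k into triangular numbers C(g,2) over disjoint groups
    groups: list[int] = []
    remaining, available = k, n
    while remaining > 0:
        g = int((1 + math.sqrt(1 + 8 * remaining)) / 2)  # largest g: C(g,2)<=k
        while g * (g - 1) // 2 > remaining:
            g -= 1
        if g < 2 or g > available:
            raise ValueError(
                f"cannot plant exactly {k} share events among {n} inversions"
            )
        groups.append(g)
        remaining -= g * (g - 1) // 2
        available -= g

    dist_labels = [dist_pool[i] for i in range(n)]
    idx = 0
    for g in groups:
        shared = dist_labels[idx]
        for j in range(idx, idx + g):
            dist_labels[j] = shared
        idx += g

    entries = [
        BreakpointEntry(
            inversion=parse_inversion_name(f"IIL-{200 + i}"),
            proximal=prox_pool[i],
            distal=dist_labels[i],
        )
        for i in range(n)
    ]
    return BreakpointCatalog(entries, section_domain=range(1, 4 * n + 2))


@dataclass
class SyntheticDataset:
    """One complete synthetic survey plus its generating truth."""

    config: SimulationConfig
    geography: SyntheticGeography
    records: list[LarvaRecord]
    breakpoint_catalog: BreakpointCatalog

    def truth(self) -> dict:
        cfg = self.config
        return {
            "seed": cfg.seed,
            "y_linkage": {
                t: cfg.lam(t) for t in self.geography.catalog.names()
            },
            "autosomal_het": dict(cfg.autosomal_het),
            "site_frequencies": self.geography.site_frequencies,
            "n_orphan_cytotypes": cfg.n_orphan_cytotypes,
            "planted_shared_breakpoints": cfg.planted_shared_breakpoints,
            "diagnostic": {
                t: (format_inversion_name(i) if i else None)
                for t, i in self.geography.diagnostic.items()
            },
        }

    def write_truth(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.truth(), fh, indent=1, sort_keys=True)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate geography, larvae, and breakpoint catalog in one call."""
    geography = simulate_geography(config)
    records = simulate_larvae(config, geography)
    bp = simulate_breakpoint_catalog(config)
    return SyntheticDataset(config, geography, records, bp)
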