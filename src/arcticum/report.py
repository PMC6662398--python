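"""Pipeline orchestration and the Rothfels-criteria scorecard.

The sympatric-speciation model for black flies makes testable predictions
about a species complex: (1) many taxa differing in their sex-chromosome
systems, (2) strong linkage disequilibrium between sex-linked inversions and
maleness, (3) extensive sharing of ancestral autosomal polymorphisms, and
(4) sympatric (nested or widely overlapping) distributions of the most
closely related taxa.  A fifth prediction -- that taxa differ in their
biology -- needs ecological data outside this package's scope and is always
reported as not evaluated.

:func:`run_pipeline` evaluates the four computable criteria from raw larval
records, sites, and catalogs; :func:`scorecard_from_survey` evaluates them
from published summary tables instead.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import georange, linkage, saturation
from .breakpoints import BreakpointCatalog, shared_breakpoint_matrix
from .georange import SympatryCensus
from .nomenclature import InversionID, format_inversion_name
from .records import LarvaRecord, Rank, Site, TaxonCatalog

logger = logging.getLogger("arcticum")


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Thresholds for the scorecard verdicts plus saturation settings."""

    min_linkage: float = 0.95          # criterion 2: weakest acceptable Y linkage
    majority: float = 0.5              # criterion 3: sharing fraction counted as "most taxa"
    sympatry_threshold: float = 0.9    # criterion 4: fraction of nested cytotypes
    saturation_grid_step: int = 100
    saturation_replicates: int = 100
    seed: int = 0


@dataclass
class RothfelsScorecard:
    n_sex_chromosome_systems: int
    min_y_linkage: float
    polymorphism_incidence: dict[str, tuple[int, int]]
    best_shared_polymorphism: tuple[str, int, int]  # (inversion, sharing, total)
    sympatry: SympatryCensus
    verdicts: dict[str, Optional[bool]]

    def to_dict(self) -> dict:
        inv, n_share, n_taxa = self.best_shared_polymorphism
        return {
            "n_sex_chromosome_systems": self.n_sex_chromosome_systems,
            "min_y_linkage": self.min_y_linkage,
            "polymorphism_incidence": {
                k: list(v) for k, v in sorted(self.polymorphism_incidence.items())
            },
            "best_shared_polymorphism": [inv, n_share, n_taxa],
            "n_cytotypes_with_sibling_contact":
                self.sympatry.n_cytotypes_with_sibling_contact,
            "n_cytotypes_total": self.sympatry.n_cytotypes_total,
            "verdicts": dict(sorted(self.verdicts.items())),
        }


def _verdicts(
    n_systems: int,
    min_linkage: float,
    best_share: tuple[str, int, int],
    census: SympatryCensus,
    config: PipelineConfig,
) -> dict[str, Optional[bool]]:
    _, n_share, n_taxa = best_share
    return {
        "c1_sex_chromosome_changes": n_systems >= 2,
        "c2_linkage_disequilibrium": min_linkage >= config.min_linkage,
        "c3_shared_autosomal_polymorphisms":
            n_taxa > 0 and n_share / n_taxa > config.majority,
        "c4_sympatric_distributions":
            census.sympatry_fraction >= config.sympatry_threshold,
        "c5_biological_differences": None,  # not evaluated here
    }


def scorecard_from_survey(
    linkage_survey: pd.DataFrame,
    polymorphism_table: pd.DataFrame,
    range_summary: pd.DataFrame,
    catalog: TaxonCatalog,
    config: Optional[PipelineConfig] = None,
) -> RothfelsScorecard:
    """Scorecard straight from published summary tables.

    ``linkage_survey`` needs a ``y_linkage`` column; ``polymorphism_table``
    is a taxon-indexed heterozygote-proportion matrix; ``range_summary``
    holds per-taxon contact counts split by partner rank.
    """
    config = config or PipelineConfig()
    census = linkage.taxon_census(catalog)
    min_link = float(linkage_survey["y_linkage"].min())
    incidence = linkage.shared_polymorphism_incidence(polymorphism_table)
    best_inv, (best_n, total) = max(
        incidence.per_inversion.items(), key=lambda kv: kv[1][0]
    )
    sym = georange.sympatry_census_from_counts(range_summary)
    best = (best_inv, best_n, total)
    return RothfelsScorecard(
        n_sex_chromosome_systems=census["n_total"],
        min_y_linkage=min_link,
        polymorphism_incidence=incidence.per_inversion,
        best_shared_polymorphism=best,
        sympatry=sym,
        verdicts=_verdicts(census["n_total"], min_link, best, sym, config),
    )


def _diagnostic_inversions(catalog: TaxonCatalog) -> dict[str, list[InversionID]]:
    out: dict[str, list[InversionID]] = {}
    for e in catalog:
        out[e.name] = [i for i in e.sex_chromosome if i.special is None]
    return out


def run_pipeline(
    records: Sequence[LarvaRecord],
    sites: Sequence[Site],
    catalog: TaxonCatalog,
    breakpoint_catalog: Optional[BreakpointCatalog] = None,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[Path] = None,
) -> RothfelsScorecard:
    """Run linkage, range, saturation, and breakpoint stages in order.

    Writes TSV/GeoJSON/JSON artifacts to ``outdir`` when given; reruns on
    identical inputs and seed reproduce them byte for byte.  Stage failures
    are re-raised as :class:`PipelineStageError` naming the stage.
    """
    config = config or PipelineConfig()
    records = list(records)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    diag = _diagnostic_inversions(catalog)

    # ---- stage 1: linkage -------------------------------------------------
    t0 = time.perf_counter()
    try:
        if not records:
            raise ValueError("no larval records")
        scored = {g.inversion for r in records for g in r.genotypes}
        if not any(i in scored for invs in diag.values() for i in invs):
            raise ValueError("no diagnostic inversion scored in the records")
        # Y linkage is a within-taxon statistic: each taxon's diagnostic
        # inversion is assessed over that taxon's own larvae (at multi-taxon
        # sites other taxa's males are standard for it by definition)
        link_rows = []
        for e in catalog:
            for inv in diag[e.name]:
                if inv not in scored:
                    continue
                own = [r for r in records if r.taxon_assignment == e.name]
                pool = own if own else list(records)
                if not any(r.y_bearing and r.genotype_for(inv) for r in pool):
                    continue  # scored only in females; linkage undefined
                res = linkage.extent_of_y_linkage(pool, inv)
                link_rows.append(
                    {
                        "taxon": e.name,
                        "inversion": format_inversion_name(inv),
                        "n_y_bearing": res.n_y_bearing,
                        "n_female": res.n_female,
                        "y_linkage": res.y_linkage,
                        "female_carrier_rate": res.female_carrier_rate,
                        "classification": res.classification().value,
                    }
                )
        link_tbl = pd.DataFrame(link_rows)
        if link_tbl.empty:
            raise ValueError("no diagnostic inversion assessable for Y linkage")
        min_link = float(link_tbl["y_linkage"].min())
        # autosomal = scored but diagnostic of no taxon
        diag_set = {i for invs in diag.values() for i in invs}
        autosomal = sorted(
            (i for i in scored if i not in diag_set), key=format_inversion_name
        )
        taxa_seen = sorted(
            {r.taxon_assignment for r in records if r.taxon_assignment}
        )
        poly_rows = {}
        for taxon in taxa_seen:
            row = {}
            for inv in autosomal:
                try:
                    prop, _n = linkage.heterozygote_proportion(records, taxon, inv)
                except linkage.UndefinedResultError:
                    prop = 0.0
                row[format_inversion_name(inv)] = prop
            poly_rows[taxon] = row
        poly_table = pd.DataFrame.from_dict(poly_rows, orient="index")
        if autosomal and not poly_table.empty:
            incidence = linkage.shared_polymorphism_incidence(poly_table)
            best_inv, (best_n, total) = max(
                incidence.per_inversion.items(), key=lambda kv: kv[1][0]
            )
            best = (best_inv, best_n, total)
            per_inversion = incidence.per_inversion
        else:
            best = ("", 0, len(taxa_seen))
            per_inversion = {}
        census = linkage.taxon_census(catalog)
    except Exception as exc:
        raise PipelineStageError("linkage_stats", exc) from exc
    logger.info("linkage_stats done in %.2fs", time.perf_counter() - t0)

    # ---- stage 2: geographic ranges ---------------------------------------
    t0 = time.perf_counter()
    try:
        site_by_id = {s.site_id: s for s in sites}
        taxon_sites: dict[str, list[Site]] = {}
        for r in records:
            if r.taxon_assignment and r.site_id in site_by_id:
                taxon_sites.setdefault(r.taxon_assignment, [])
                s = site_by_id[r.site_id]
                if s not in taxon_sites[r.taxon_assignment]:
                    taxon_sites[r.taxon_assignment].append(s)
        ranges = []
        for taxon, tsites in sorted(taxon_sites.items()):
            pts = georange.project_points(tsites)
            ranges.append(
                georange.build_range_polygon(taxon, pts, rank=catalog.rank_of(taxon))
            )
        if len(ranges) >= 2:
            matrix = georange.pairwise_contact_matrix(ranges)
            sym = georange.sympatry_census(matrix)
        else:
            sym = SympatryCensus(0, 0, georange._group_stats(
                pd.DataFrame(columns=["taxon", "rank", "contacts_siblings",
                                      "contacts_cytotypes"])))
    except Exception as exc:
        raise PipelineStageError("georange", exc) from exc
    logger.info("georange done in %.2fs", time.perf_counter() - t0)

    # ---- stage 3: saturation ----------------------------------------------
    t0 = time.perf_counter()
    try:
        curves = []
        by_site: dict[str, list[LarvaRecord]] = {}
        for r in records:
            by_site.setdefault(r.site_id, []).append(r)
        for site_id in sorted(by_site):
            coll = by_site[site_id]
            if len(coll) < config.saturation_grid_step:
                continue
            curves.append(
                saturation.saturation_curve(
                    coll,
                    grid=saturation.default_grid(
                        len(coll), config.saturation_grid_step
                    ),
                    n_replicates=config.saturation_replicates,
                    seed=config.seed,
                    site_id=site_id,
                )
            )
    except Exception as exc:
        raise PipelineStageError("saturation", exc) from exc
    logger.info("saturation done in %.2fs", time.perf_counter() - t0)

    # ---- stage 4: breakpoints ----------------------------------------------
    t0 = time.perf_counter()
    bp_result = None
    try:
        if breakpoint_catalog is not None and len(breakpoint_catalog) >= 2:
            bp_result = shared_breakpoint_matrix(breakpoint_catalog)
    except Exception as exc:
        raise PipelineStageError("breakpoints", exc) from exc
    logger.info("breakpoints done in %.2fs", time.perf_counter() - t0)

    scorecard = RothfelsScorecard(
        n_sex_chromosome_systems=census["n_total"],
        min_y_linkage=min_link,
        polymorphism_incidence=per_inversion,
        best_shared_polymorphism=best,
        sympatry=sym,
        verdicts=_verdicts(census["n_total"], min_link, best, sym, config),
    )

    if outdir is not None:
        link_tbl.to_csv(outdir / "linkage.tsv", sep="\t", index=False)
        poly_table.to_csv(outdir / "polymorphisms.tsv", sep="\t")
        if len(ranges) >= 2:
            matrix.contact_counts().to_csv(
                outdir / "contacts.tsv", sep="\t", index=False
            )
            georange.write_geojson(
                georange.ranges_to_geojson(ranges), outdir / "ranges.geojson"
            )
        if curves:
            pd.concat([c.to_frame() for c in curves]).to_csv(
                outdir / "saturation.tsv", sep="\t", index=False
            )
        if bp_result is not None:
            summary = {
                "n_comparisons": bp_result.n_comparisons,
                "n_shared": bp_result.n_shared,
                "percent": bp_result.percent_shared,
            }
            with open(outdir / "breakpoints.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            for cat in ("distal_distal", "proximal_proximal", "proximal_distal"):
                bp_result.sign_matrix(cat).to_csv(
                    outdir / f"breakpoints_{cat}.tsv", sep="\t"
                )
        with open(outdir / "scorecard.json", "w", encoding="utf-8") as fh:
            json.dump(scorecard.to_dict(), fh, indent=1, sort_keys=True)

    return scorecard
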