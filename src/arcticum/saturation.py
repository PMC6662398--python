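"""Sampling-saturation (rarefaction) analysis of sex-chromosome diversity.

How many larvae must be scored at one site before its sex-chromosome
diversity is fully detected?  Real collections of a few hundred to a few
thousand larvae are repeatedly subsampled without replacement at increasing
sizes; the number of distinct Y-chromosome types detected per subsample,
averaged over replicates, traces a species-accumulation curve whose plateau
marks saturation.

Diversity is counted over Y types only: at a multi-taxon site females are
chromosomally uninformative for taxon identity, whereas each Y-bearing larva
carries its taxon's diagnostic inversion (the non-inverted standard sequence
counts as one further type when present).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import InversionID, format_inversion_name
from .records import LarvaRecord


def y_type_of(
    record: LarvaRecord, diagnostic: Optional[Sequence[InversionID]] = None
) -> Optional[str]:
    """The Y-chromosome type of a larva, or None for non-Y-bearing larvae.

    The type is the set of diagnostic inversions the larva carries, as a
    canonical joined name; a Y-bearing larva carrying none of them is the
    ``standard`` type.  ``diagnostic`` restricts which inversions are
    informative (default: all scored).
    """
    if not record.y_bearing:
        return None
    allowed = None if diagnostic is None else set(diagnostic)
    carried = sorted(
        format_inversion_name(g.inversion)
        for g in record.genotypes
        if g.state.is_carrier and (allowed is None or g.inversion in allowed)
    )
    return "+".join(carried) if carried else "standard"


def distinct_y_types(
    records: Sequence[LarvaRecord],
    diagnostic: Optional[Sequence[InversionID]] = None,
) -> int:
    """Number of distinct Y types among the Y-bearing larvae."""
    return len({t for r in records if (t := y_type_of(r, diagnostic)) is not None})


@dataclass
class SaturationCurve:
    site_id: str
    grid: list[int]
    mean_distinct: list[float]
    sd_distinct: list[float]
    mean_fraction: list[float]
    total_distinct: int
    n_replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "n": self.grid,
                "mean_distinct": self.mean_distinct,
                "sd": self.sd_distinct,
                "fraction": self.mean_fraction,
            }
        )


def default_grid(collection_size: int, step: int = 100) -> list[int]:
    """Subsample sizes 100, 200, ... up to and including the collection size."""
    grid = list(range(step, collection_size + 1, step))
    if not grid or grid[-1] != collection_size:
        grid.append(collection_size)
    return grid


def saturation_curve(
    records: Sequence[LarvaRecord],
    grid: Optional[Sequence[int]] = None,
    n_replicates: int = 500,
    seed: int = 0,
    site_id: Optional[str] = None,
    diagnostic: Optional[Sequence[InversionID]] = None,
) -> SaturationCurve:
    """Rarefaction of detected Y-type diversity over subsample size.

    For each size on the grid, draws ``n_replicates`` subsamples without
    replacement from the collection and counts the distinct Y types each
    detects.  Deterministic for a fixed seed.
    """
    records = list(records)
    total = len(records)
    if grid is None:
        grid = default_grid(total)
    grid = sorted(set(int(n) for n in grid))
    if grid and grid[-1] > total:
        raise ValueError(
            f"grid size {grid[-1]} exceeds collection size {total}"
        )
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    y_types = np.array(
        [y_type_of(r, diagnostic) or "" for r in records], dtype=object
    )
    total_distinct = distinct_y_types(records, diagnostic)
    rng = np.random.default_rng(seed)
    means, sds, fracs = [], [], []
    for n in grid:
        counts = np.empty(n_replicates)
        for k in range(n_replicates):
            idx = rng.choice(total, size=n, replace=False)
            counts[k] = len({t for t in y_types[idx] if t})
        means.append(float(counts.mean()))
        sds.append(float(counts.std(ddof=1)) if n_replicates > 1 else 0.0)
        fracs.append(
            float(counts.mean() / total_distinct) if total_distinct else 0.0
        )
    sid = site_id or (records[0].site_id if records else "")
    return SaturationCurve(
        site_id=sid,
        grid=list(grid),
        mean_distinct=means,
        sd_distinct=sds,
        mean_fraction=fracs,
        total_distinct=total_distinct,
        n_replicates=n_replicates,
        seed=seed,
    )


def saturation_size(curve: SaturationCurve, threshold: float = 0.9) -> Optional[int]:
    """Smallest grid size whose mean detected fraction reaches ``threshold``.

    Returns None when the curve never reaches it.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    for n, frac in zip(curve.grid, curve.mean_fraction):
        if frac >= threshold:
            return n
    return None


def expected_distinct(frequencies: Sequence[float], n: int) -> float:
    """Analytic species-accumulation expectation sum_i 1 - (1 - p_i)^n.

    Binomial approximation to sampling without replacement; accurate when
    the subsample is small relative to the collection.
    """
    p = np.asarray(frequencies, dtype=float)
    return float(np.sum(1.0 - (1.0 - p) ** n))
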