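"""Breakpoint-sharing enumeration among sex-linked inversions.

Each paracentric inversion has two breakpoints on its arm's band map: a
*proximal* one (nearer the centromere) and a *distal* one.  If new sex-linked
inversions were seeded by existing ones, their breakpoints should coincide
more often than chance; the analysis enumerates, for every pair of
sex-linked inversions, whether they share a breakpoint in each of three
categories -- distal-distal, proximal-proximal, and proximal-distal /
distal-proximal -- and profiles per-section breakpoint counts to spot
positional hot spots.

Two denominator conventions are supported for the percent shared.  The
survey convention counts each inversion's two breakpoints against every
inversion's breakpoint set including itself (n x n x 2; for the complex's 30
sex-linked inversions, 1,800); the ``unordered_pairs`` convention counts the
four breakpoint comparisons of each distinct pair (4 * n(n-1)/2).  Shared
flags are only ever raised for distinct pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import InversionID, format_inversion_name

#: Band-map section domain of the long arm of chromosome II.
IIL_SECTIONS = range(55, 72)


@dataclass(frozen=True)
class BreakpointEntry:
    inversion: InversionID
    proximal: int
    distal: int

    def __post_init__(self) -> None:
        if self.proximal == self.distal:
            raise ValueError(
                f"{format_inversion_name(self.inversion)}: proximal and distal "
                "breakpoints must differ"
            )


@dataclass
class BreakpointCatalog:
    entries: list[BreakpointEntry]
    section_domain: Optional[range] = None

    def __post_init__(self) -> None:
        if self.section_domain is not None:
            for e in self.entries:
                for label in (e.proximal, e.distal):
                    if label not in self.section_domain:
                        raise ValueError(
                            f"{format_inversion_name(e.inversion)}: section "
                            f"{label} outside domain "
                            f"[{self.section_domain.start}, {self.section_domain.stop - 1}]"
                        )

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [format_inversion_name(e.inversion) for e in self.entries]


def load_breakpoint_catalog(path) -> BreakpointCatalog:
    """Read a breakpoint CSV: inversion, arm, proximal_section, distal_section."""
    from .nomenclature import parse_inversion_name

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("inversion", "proximal_section", "distal_section")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"breakpoint CSV missing mandatory column(s): {missing}")
    entries = [
        BreakpointEntry(
            inversion=parse_inversion_name(row["inversion"]),
            proximal=int(row["proximal_section"]),
            distal=int(row["distal_section"]),
        )
        for _, row in df.iterrows()
    ]
    return BreakpointCatalog(entries)


def write_breakpoint_catalog(catalog: BreakpointCatalog, path) -> None:
    df = pd.DataFrame(
        [
            {
                "inversion": format_inversion_name(e.inversion),
                "arm": e.inversion.arm.value,
                "proximal_section": e.proximal,
                "distal_section": e.distal,
            }
            for e in catalog.entries
        ]
    )
    df.to_csv(path, index=False)


def comparison_count(n_inversions: int, convention: str = "paper") -> int:
    """Total breakpoint comparisons for ``n_inversions`` sex-linked inversions.

    ``"paper"``: each inversion's two breakpoints against every inversion's
    breakpoint set, self included (n * n * 2).  ``"unordered_pairs"``: the
    four comparisons of each distinct unordered pair (4 * n(n-1)/2).
    """
    if n_inversions < 1:
        raise ValueError("n_inversions must be >= 1")
    if convention == "paper":
        return n_inversions * n_inversions * 2
    if convention == "unordered_pairs":
        return 4 * n_inversions * (n_inversions - 1) // 2
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class SharedBreakpointResult:
    names: list[str]
    distal_distal: pd.DataFrame      # symmetric bool
    proximal_proximal: pd.DataFrame  # symmetric bool
    proximal_distal: pd.DataFrame    # cell (i, j): proximal of i vs distal of j
    n_comparisons: int
    n_shared: int

    @property
    def percent_shared(self) -> float:
        return 100.0 * self.n_shared / self.n_comparisons

    def percent_rounded(self, decimals: int = 1) -> float:
        return round(self.percent_shared, decimals)

    def percent_truncated(self, decimals: int = 2) -> float:
        factor = 10 ** decimals
        return math.floor(self.percent_shared * factor) / factor

    def sign_matrix(self, category: str) -> pd.DataFrame:
        """A +/- matrix for one category (diagonal blank)."""
        mat = {
            "distal_distal": self.distal_distal,
            "proximal_proximal": self.proximal_proximal,
            "proximal_distal": self.proximal_distal,
        }[category]
        out = mat.map(lambda v: "+" if v else "-").astype(str)
        for name in out.index:
            out.loc[name, name] = ""
        return out


def shared_breakpoint_matrix(
    catalog: BreakpointCatalog,
    convention: str = "paper",
    tolerance: int = 0,
) -> SharedBreakpointResult:
    """Flag breakpoint sharing for every distinct inversion pair.

    Two section labels are shared when they differ by at most ``tolerance``
    (0 = exact equality; a positive value absorbs scoring ambiguity in
    weakly banded "puffing" regions).  Self-pairs are never flagged.
    ``n_shared`` counts share events: one per flagged symmetric pair in the
    distal-distal and proximal-proximal categories, and one per flagged
    ordered cell in the mixed category.
    """
    names = catalog.names()
    n = len(names)
    if n < 2:
        raise ValueError("need at least two catalog entries")
    prox = np.array([e.proximal for e in catalog.entries])
    dist = np.array([e.distal for e in catalog.entries])

    def share(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        m = np.abs(a[:, None] - b[None, :]) <= tolerance
        np.fill_diagonal(m, False)
        return m

    dd = share(dist, dist)
    pp = share(prox, prox)
    pd_ = share(prox, dist)  # not symmetric in general
    n_shared = int(np.triu(dd, 1).sum() + np.triu(pp, 1).sum() + pd_.sum())
    return SharedBreakpointResult(
        names=names,
        distal_distal=pd.DataFrame(dd, index=names, columns=names),
        proximal_proximal=pd.DataFrame(pp, index=names, columns=names),
        proximal_distal=pd.DataFrame(pd_, index=names, columns=names),
        n_comparisons=comparison_count(n, convention),
        n_shared=n_shared,
    )


@dataclass
class HotspotProfile:
    counts: pd.Series  # index: section label; value: breakpoint count
    max_sections: list[int]

    @property
    def max_count(self) -> int:
        return int(self.counts.max()) if len(self.counts) else 0


def hotspot_profile(catalog: BreakpointCatalog) -> HotspotProfile:
    """Histogram of breakpoint landmarks per arm section.

    Every inversion contributes its two flanking labels; sections hosting
    the most breakpoints are candidate structural hot spots.
    """
    labels: list[int] = []
    for e in catalog.entries:
        labels.extend((e.proximal, e.distal))
    if catalog.section_domain is not None:
        index = list(catalog.section_domain)
    else:
        index = sorted(set(labels))
    counts = pd.Series(0, index=index, dtype=int)
    for lab in labels:
        counts[lab] += 1
    max_count = counts.max() if len(counts) else 0
    max_sections = [int(s) for s in counts.index[counts == max_count]] if labels else []
    return HotspotProfile(counts=counts, max_sections=max_sections)
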