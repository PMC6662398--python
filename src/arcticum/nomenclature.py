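"""Parsing and formatting of black-fly paracentric inversion names.

Inversions in the *Simulium arcticum* complex are named by chromosome arm
(IS, IL, IIS, IIL) followed by one or more component numbers, e.g. ``IIL-6``
for a simple inversion or ``IL-3·4`` for a compound one.  Published tables
are typographically inconsistent: the component separator appears as a
middle dot (``·``), an ASCII period (``IIL-73.74``) or a second hyphen
(``IIS-49-52``), hyphens may be Unicode non-breaking hyphens, and stray
spaces occur.  :func:`parse_inversion_name` normalises all of these to one
canonical form whose separator is the middle dot.

Two special non-numeric designations occur: a tandem *duplication* used as a
sex chromosome (``IIL-dup``), and the *standard* (non-inverted) sequence for
taxa whose sex chromosomes carry no inversion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class Arm(str, Enum):
    """Polytene chromosome arm: chromosome I or II, short or long arm."""

    IS = "IS"
    IL = "IL"
    IIS = "IIS"
    IIL = "IIL"


class Special(str, Enum):
    DUPLICATION = "duplication"
    STANDARD = "standard"


class InversionParseError(ValueError):
    """Raised when an inversion name cannot be interpreted."""


# Unicode hyphen/dash variants that occur in published tables.
_DASHES = "‐‑‒–—−"
_DUP_TOKENS = {"dup", "dup.", "duplication"}
_STANDARD_TOKENS = {"st", "st/st", "standard"}


@dataclass(frozen=True)
class InversionID:
    """A parsed inversion name: arm plus ordered component numbers.

    ``components`` is empty exactly when ``special`` is set (a duplication
    or the standard sequence carries no inversion numbers).
    """

    arm: Arm
    components: tuple[int, ...] = field(default_factory=tuple)
    special: Optional[Special] = None

    def __post_init__(self) -> None:
        if self.special is None:
            if not self.components:
                raise ValueError("components must be non-empty unless special is set")
            if any(c < 1 for c in self.components):
                raise ValueError("components must be positive integers")
        elif self.components:
            raise ValueError("special inversions carry no components")

    def __str__(self) -> str:
        return format_inversion_name(self)

    @property
    def is_compound(self) -> bool:
        return len(self.components) > 1


def _normalise(text: str) -> str:
    for d in _DASHES:
        text = text.replace(d, "-")
    return text.replace(" ", "").strip()


def parse_inversion_name(text: str) -> InversionID:
    """Parse an inversion name such as ``"IIL-6"`` or ``"IL-3·4"``.

    Accepts ``·``, ``.`` and ``-`` as component separators, Unicode hyphen
    variants, embedded spaces, and the special tokens ``dup``/``duplication``
    and ``st``/``standard``.

    Raises
    ------
    InversionParseError
        If the arm token is not one of IS/IL/IIS/IIL or a component is not
        a positive integer.
    """
    if not text or not text.strip():
        raise InversionParseError("empty inversion name")
    cleaned = _normalise(text)
    m = re.match(r"^(IIS|IIL|IS|IL)[-]?(.*)$", cleaned, flags=re.IGNORECASE)
    if not m:
        token = cleaned.split("-")[0] if "-" in cleaned else cleaned
        raise InversionParseError(f"unknown chromosome arm token {token!r} in {text!r}")
    arm = Arm(m.group(1).upper())
    rest = m.group(2)
    if not rest:
        raise InversionParseError(f"missing component numbers in {text!r}")
    low = rest.lower()
    if low in _DUP_TOKENS:
        return InversionID(arm=arm, special=Special.DUPLICATION)
    if low in _STANDARD_TOKENS:
        return InversionID(arm=arm, special=Special.STANDARD)
    parts = re.split(r"[·.\-]", rest)
    components = []
    for part in parts:
        if not part.isdigit():
            raise InversionParseError(
                f"non-numeric inversion component {part!r} in {text!r}"
            )
        components.append(int(part))
    return InversionID(arm=arm, components=tuple(components))


def format_inversion_name(inv: InversionID) -> str:
    """Canonical spelling: ``ARM-n[·m...]``, ``ARM-duplication`` or ``ARM-st``."""
    if inv.special is Special.DUPLICATION:
        return f"{inv.arm.value}-duplication"
    if inv.special is Special.STANDARD:
        return f"{inv.arm.value}-st"
    return f"{inv.arm.value}-" + "·".join(str(c) for c in inv.components)


def canonical_name(text: str) -> str:
    """Normalise any accepted spelling to the canonical one."""
    return format_inversion_name(parse_inversion_name(text))


def sort_key(inv: InversionID) -> tuple:
    order = {Arm.IS: 0, Arm.IL: 1, Arm.IIS: 2, Arm.IIL: 3}
    return (order[inv.arm], inv.special is not None, inv.components)
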