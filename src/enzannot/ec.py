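"""Enzyme Commission (EC) number handling.

An EC number is a four-level code ``class.subclass.sub-subclass.serial``
(e.g. ``2.6.1.57``, tyrosine aminotransferase).  Annotations are often
incomplete: trailing levels may be unspecified and written as ``-``
(e.g. ``1.14.-.-`` is specified only to depth 2).  Incomplete codes are
first-class labels here, distinct from any of their depth-4 refinements:
a model trained with ``1.14.-.-`` in its vocabulary treats it as a
different class from ``1.14.11.38``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering

__all__ = ["ECNumber", "ECParseError", "parse_ec", "format_ec"]

WILDCARD = "-"


class ECParseError(ValueError):
    """Raised when an EC string cannot be parsed."""


@total_ordering
@dataclass(frozen=True)
class ECNumber:
    """A four-level EC code; ``None`` marks an unspecified level.

    Invariant: no specified level may follow an unspecified one, so the
    specified levels form a prefix and ``specified_depth`` is its length.
    """

    levels: tuple[int | None, int | None, int | None, int | None]

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise ECParseError(f"EC number needs 4 levels, got {len(self.levels)}")
        seen_wildcard = False
        for lev in self.levels:
            if lev is None:
                seen_wildcard = True
            else:
                if seen_wildcard:
                    raise ECParseError(
                        f"specified level after wildcard in {self.levels!r}"
                    )
                if not isinstance(lev, int) or lev <= 0:
                    raise ECParseError(f"EC level must be a positive integer: {lev!r}")
        if self.levels[0] is None:
            raise ECParseError("EC number must specify at least the first level")

    @property
    def specified_depth(self) -> int:
        """Number of leading specified (non-wildcard) levels, 1..4."""
        return sum(1 for lev in self.levels if lev is not None)

    def truncate(self, depth: int) -> "ECNumber":
        """Blank out all levels beyond ``depth`` (e.g. depth 3 maps
        1.14.11.38 to 1.14.11.-); used for level-wise evaluation."""
        if not 1 <= depth <= 4:
            raise ValueError(f"depth must be 1..4, got {depth}")
        return ECNumber(
            tuple(lev if i < depth else None for i, lev in enumerate(self.levels))
        )

    def __str__(self) -> str:
        return format_ec(self)

    def _sort_key(self) -> tuple:
        # wildcards sort before any integer so 1.14.-.- < 1.14.11.38
        return tuple((-1 if lev is None else lev) for lev in self.levels)

    def __lt__(self, other: "ECNumber") -> bool:
        return self._sort_key() < other._sort_key()


def parse_ec(text: str) -> ECNumber:
    """Parse a dot-separated EC string such as ``2.6.1.57`` or ``1.14.-.-``.

    One to four components are accepted; missing trailing components are
    treated as unspecified, so ``1.14`` parses the same as ``1.14.-.-``.

    Raises
    ------
    ECParseError
        On empty input, more than 4 components, a component that is
        neither a positive integer nor ``-``, or a specified component
        following a wildcard.
    """
    parts = [p.strip() for p in text.strip().split(".")]
    if parts == [""]:
        raise ECParseError("empty EC string")
    if len(parts) > 4:
        raise ECParseError(f"EC string {text!r} has {len(parts)} components (max 4)")
    levels: list[int | None] = []
    for part in parts:
        if part == WILDCARD:
            levels.append(None)
        else:
            try:
                value = int(part)
            except ValueError:
                raise ECParseError(
                    f"malformed EC component {part!r} in {text!r}"
                ) from None
            if value <= 0:
                raise ECParseError(f"non-positive EC component {part!r} in {text!r}")
            levels.append(value)
    while len(levels) < 4:
        levels.append(None)
    return ECNumber(tuple(levels))


def format_ec(ec: ECNumber) -> str:
    """Canonical dot-joined form; inverse of :func:`parse_ec`."""
    return ".".join(WILDCARD if lev is None else str(lev) for lev in ec.levels)
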