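"""Half-open interval algebra on a discretized tonotopic axis.

The axis is a row of ``n_cells`` unit-width cells indexed ``0 .. n_cells-1``.
A *synaptic interval* is a half-open span ``[start, start + length)`` of
contiguous cells; sets of such intervals support two operations:

* ``add``       -- set union ("addition"); overlapping or abutting spans fuse.
* ``multiply``  -- set difference ("multiplication" by an inhibitor): cells of
  the excitatory operand that the inhibitory operand covers are removed.

Both operations return the canonical form: parts sorted by start, pairwise
disjoint, with no two parts touching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence


class AxisError(ValueError):
    """Two interval sets live on different axes."""


class BoundsError(ValueError):
    """An interval does not fit on its axis."""


@dataclass(frozen=True)
class TonotopicAxis:
    """A partition of the tonotopic axis into ``n_cells`` unit cells.

    Parameters
    ----------
    n_cells:
        Number of cell-width partitions.
    max_len:
        Largest admissible codeword length, in cells.  Constrains which
        intervals are valid *codewords* (see :mod:`placecode.acoustic`), not
        which sets the algebra can produce.  Defaults to ``n_cells``.
    dx:
        Physical width of one cell, in abstract units.  Kept purely for
        conversion at the edges; the algebra itself is integer-valued.
    """

    n_cells: int
    max_len: int = 0  # 0 sentinel -> n_cells
    dx: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.max_len == 0:
            object.__setattr__(self, "max_len", self.n_cells)
        if not (1 <= self.max_len <= self.n_cells):
            raise ValueError(
                f"max_len must be in [1, {self.n_cells}], got {self.max_len}"
            )
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def n_starts(self) -> int:
        """Size of the admissible start-point set for codewords."""
        return self.n_cells - self.max_len + 1

    def start_points(self) -> range:
        """Admissible start cells for maximal-length codewords."""
        return range(self.n_starts)

    def lengths(self) -> range:
        """Achievable codeword lengths, in cells."""
        return range(1, self.max_len + 1)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open span ``[start, start + length)`` of cells.

    ``start`` is the cell index at the closed end and identifies the
    interval's location on the axis; ``length`` is a cell count >= 1.
    """

    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")

    @property
    def stop(self) -> int:
        return self.start + self.length

    def cells(self) -> range:
        return range(self.start, self.stop)

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.stop and other.start < self.stop


class IntervalSet:
    """Canonical finite union of intervals on a shared axis.

    Instances are immutable; construct them with :func:`canonicalize` (or the
    :meth:`empty` / :meth:`from_text` helpers).  ``parts`` is always sorted by
    start, pairwise disjoint, and gap-separated (abutting spans are merged,
    since ``[a,b) u [b,c) = [a,c)``).
    """

    __slots__ = ("axis", "parts")

    def __init__(self, axis: TonotopicAxis, parts: Sequence[Interval], *, _trusted: bool = False):
        if not _trusted:
            merged = canonicalize(parts, axis)
            parts = merged.parts
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "parts", tuple(parts))

    def __setattr__(self, *args) -> None:  # pragma: no cover
        raise AttributeError("IntervalSet is immutable")

    @classmethod
    def empty(cls, axis: TonotopicAxis) -> "IntervalSet":
        return cls(axis, (), _trusted=True)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.parts)

    def __len__(self) -> int:
        return len(self.parts)

    def __bool__(self) -> bool:
        return bool(self.parts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.axis == other.axis and self.parts == other.parts

    def __hash__(self) -> int:
        return hash((self.axis, self.parts))

    def __repr__(self) -> str:
        body = ", ".join(f"[{p.start},{p.stop})" for p in self.parts)
        return f"IntervalSet({{{body}}})"

    @property
    def total_length(self) -> int:
        return sum(p.length for p in self.parts)

    def cells(self) -> list[int]:
        """All covered cell indices, ascending."""
        out: list[int] = []
        for p in self.parts:
            out.extend(p.cells())
        return out

    def covers(self, cell: int) -> bool:
        return any(p.start <= cell < p.stop for p in self.parts)

    def issubset(self, other: "IntervalSet") -> bool:
        _check_axes(self, other)
        return multiply(other, self).total_length == 0

    # -- plain-text round trip ------------------------------------------------

    def to_text(self) -> str:
        """Serialize as comma-separated ``start:length`` pairs ('' if empty)."""
        return ",".join(f"{p.start}:{p.length}" for p in self.parts)

    @classmethod
    def from_text(cls, text: str, axis: TonotopicAxis) -> "IntervalSet":
        text = text.strip()
        if not text:
            return cls.empty(axis)
        raw = []
        for token in text.split(","):
            s, _, l = token.partition(":")
            raw.append(Interval(int(s), int(l)))
        return canonicalize(raw, axis)


def _check_fits(iv: Interval, axis: TonotopicAxis) -> None:
    if iv.stop > axis.n_cells:
        raise BoundsError(
            f"interval [{iv.start},{iv.stop}) exceeds axis of {axis.n_cells} cells"
        )


def _check_axes(a: IntervalSet, b: IntervalSet) -> None:
    if a.axis != b.axis:
        raise AxisError(f"operands live on different axes: {a.axis} vs {b.axis}")


def canonicalize(raw: Iterable[Interval], axis: TonotopicAxis) -> IntervalSet:
    """Return the unique sorted, merged, disjoint representation of a union.

    Raises :class:`BoundsError` if any raw interval does not fit the axis.
    """
    items = sorted(raw, key=lambda iv: iv.start)
    for iv in items:
        _check_fits(iv, axis)
    merged: list[Interval] = []
    for iv in items:
        if merged and iv.start <= merged[-1].stop:
            last = merged[-1]
            if iv.stop > last.stop:
                merged[-1] = Interval(last.start, iv.stop - last.start)
        else:
            merged.append(iv)
    return IntervalSet(axis, merged, _trusted=True)


def add(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Addition of interval sets: their union, in canonical form.

    Summation is sublinear: ``total_length(add(a, b)) <=
    total_length(a) + total_length(b)``, with equality iff the covered cell
    sets are disjoint.
    """
    _check_axes(a, b)
    return canonicalize(list(a.parts) + list(b.parts), a.axis)


def multiply(inh: IntervalSet, exc: IntervalSet) -> IntervalSet:
    """Multiplication: remove the inhibitor's cells from the multiplicand.

    Returns ``exc \\ inh`` in canonical form.  The result is a subset of
    ``exc``; a single part may be split in two when the inhibitor carves out
    its middle.  The inhibitor comes first, mirroring ``h^I . h^E``.
    """
    _check_axes(inh, exc)
    out: list[Interval] = []
    for part in exc.parts:
        lo, hi = part.start, part.stop
        for cut in inh.parts:
            if cut.stop <= lo:
                continue
            if cut.start >= hi:
                break
            if cut.start > lo:
                out.append(Interval(lo, cut.start - lo))
            lo = max(lo, cut.stop)
            if lo >= hi:
                break
        if lo < hi:
            out.append(Interval(lo, hi - lo))
    return canonicalize(out, exc.axis)


def total_length(s: IntervalSet) -> int:
    """Number of distinct cells covered by the set."""
    return s.total_length
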