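"""Predicted interval-length curves for canonical E/I configurations.

Each generator places intervals on a large scratch axis, evaluates the
algebraic expression exactly, and records (parameter, total length) pairs.
Curves are deterministic and integer-valued; any placement that would clip at
an axis boundary raises rather than silently truncating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .algebra import (
    BoundsError,
    Interval,
    IntervalSet,
    TonotopicAxis,
    add,
    multiply,
)


@dataclass(frozen=True)
class PredictionCurve:
    """One predicted (parameter, length) series."""

    panel: str
    param_name: str
    points: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        params = [p for p, _ in self.points]
        if any(b <= a for a, b in zip(params, params[1:])):
            raise ValueError("curve parameters must be strictly increasing")
        if any(l < 0 for _, l in self.points):
            raise ValueError("lengths must be non-negative")

    @property
    def params(self) -> list[int]:
        return [p for p, _ in self.points]

    @property
    def lengths(self) -> list[int]:
        return [l for _, l in self.points]


def _axis_for(extent: int) -> TonotopicAxis:
    """Scratch axis comfortably larger than the widest placement."""
    return TonotopicAxis(n_cells=max(4 * extent + 16, 32))


def _single(axis: TonotopicAxis, start: int, length: int) -> IntervalSet:
    if length == 0:
        return IntervalSet.empty(axis)
    if start < 0 or start + length > axis.n_cells:
        raise BoundsError(
            f"placement [{start},{start + length}) clips the {axis.n_cells}-cell axis"
        )
    return IntervalSet(axis, [Interval(start, length)])


def addition_same_start(len_fixed: int, len_range: Iterable[int]) -> PredictionCurve:
    """Two co-located intervals; one length swept.  Length = max of the two."""
    sweep = list(len_range)
    axis = _axis_for(max([len_fixed, *sweep]))
    base = axis.n_cells // 4
    fixed = _single(axis, base, len_fixed)
    pts = []
    for lam in sweep:
        total = add(fixed, _single(axis, base, lam)).total_length
        pts.append((lam, total))
    return PredictionCurve("addition_same_start", "length_cells", tuple(pts))


def addition_shifted(length: int, sep_range: Iterable[int]) -> PredictionCurve:
    """Two equal intervals, one shifted right.  Length = len + min(d, len)."""
    sweep = list(sep_range)
    axis = _axis_for(length + max(sweep, default=0))
    base = axis.n_cells // 4
    fixed = _single(axis, base, length)
    pts = []
    for d in sweep:
        if d < 0:
            raise ValueError("separation must be >= 0")
        total = add(fixed, _single(axis, base + d, length)).total_length
        pts.append((d, total))
    return PredictionCurve("addition_shifted", "separation_cells", tuple(pts))


def multiplication_same_start(len_exc: int, len_inh_range: Iterable[int]) -> PredictionCurve:
    """Co-located E and I; I length swept.  Length = max(0, lenE - lenI)."""
    sweep = list(len_inh_range)
    axis = _axis_for(max([len_exc, *sweep]))
    base = axis.n_cells // 4
    exc = _single(axis, base, len_exc)
    pts = []
    for lam in sweep:
        total = multiply(_single(axis, base, lam), exc).total_length
        pts.append((lam, total))
    return PredictionCurve("multiplication_same_start", "inh_length_cells", tuple(pts))


def multiplication_shifted(len_exc: int, len_inh: int,
                           sep_range: Iterable[int]) -> PredictionCurve:
    """I interval shifted right of E.  For equal lengths: min(d, lenE)."""
    sweep = list(sep_range)
    axis = _axis_for(len_exc + len_inh + max(sweep, default=0))
    base = axis.n_cells // 4
    exc = _single(axis, base, len_exc)
    pts = []
    for d in sweep:
        if d < 0:
            raise ValueError("separation must be >= 0")
        total = multiply(_single(axis, base + d, len_inh), exc).total_length
        pts.append((d, total))
    return PredictionCurve("multiplication_shifted", "separation_cells", tuple(pts))


def two_exc_one_inh(len_exc: int, len_inh: int,
                    shift_range: Iterable[int]) -> PredictionCurve:
    """Two E intervals shifted symmetrically out of a fixed I interval.

    At shift 0 all three share a start; E1 moves left by s and E2 right by s.
    Length = |(E1 + E2) \\ I|: zero while both E sit inside I, rising to
    2*len_exc at full disjointness (for equal lengths, exactly 2*min(s, len)).
    """
    sweep = list(shift_range)
    smax = max(sweep, default=0)
    axis = _axis_for(len_exc + len_inh + 2 * smax)
    base = axis.n_cells // 2
    inh = _single(axis, base, len_inh)
    pts = []
    for s in sweep:
        if s < 0:
            raise ValueError("shift must be >= 0")
        e1 = _single(axis, base - s, len_exc)
        e2 = _single(axis, base + s, len_exc)
        total = multiply(inh, add(e1, e2)).total_length
        pts.append((s, total))
    return PredictionCurve("two_exc_one_inh", "shift_cells", tuple(pts))


def _composite(axis: TonotopicAxis, start: int, len_exc: int, len_flank: int
               ) -> tuple[IntervalSet, IntervalSet]:
    """I-E-I triplet with flanks abutting the E part; returns (E, I) sets."""
    exc = _single(axis, start, len_exc)
    left = _single(axis, start - len_flank, len_flank)
    right = _single(axis, start + len_exc, len_flank)
    return exc, add(left, right)


def center_surround(len_exc: int, len_flank: int, sep_range: Iterable[int],
                    mode: Literal["simultaneous", "sequential"] = "simultaneous",
                    ) -> PredictionCurve:
    """Two I-E-I composites, one shifted right of the other.

    simultaneous:
        evaluates ``(I1 + I2) . (E1 + E2)`` as one expression; the curve is
        non-monotone, dipping where one composite's flank cancels part of the
        other's E interval, then rising to 2*len_exc at full disjointness.
    sequential:
        evaluates each triplet alone and combines the two products
        (``I1.E1 + I2.E2``, a union).  Because each flank never touches the
        *other* composite's E interval, the result behaves like the plain
        addition of two excitatory intervals: monotone non-decreasing from
        len_exc to 2*len_exc, with no dip (right distributivity fails, so it
        differs from the simultaneous curve).
    """
    sweep = list(sep_range)
    smax = max(sweep, default=0)
    axis = _axis_for(2 * (len_exc + 2 * len_flank) + smax)
    base = axis.n_cells // 2 - (len_exc + smax) // 2
    pts = []
    for d in sweep:
        if d < 0:
            raise ValueError("separation must be >= 0")
        e1, i1 = _composite(axis, base, len_exc, len_flank)
        e2, i2 = _composite(axis, base + d, len_exc, len_flank)
        if mode == "simultaneous":
            total = multiply(add(i1, i2), add(e1, e2)).total_length
        elif mode == "sequential":
            total = add(multiply(i1, e1), multiply(i2, e2)).total_length
        else:
            raise ValueError(f"unknown mode {mode!r}")
        pts.append((d, total))
    return PredictionCurve(f"center_surround_{mode}", "separation_cells", tuple(pts))


#: Panel name -> generator with its default sweep, for the CLI.
def default_panels() -> dict[str, PredictionCurve]:
    """The six default curves (lengths in cells, sweeps sized as in a 40-cell
    working range)."""
    return {
        "addition_same_start": addition_same_start(20, range(1, 41)),
        "addition_shifted": addition_shifted(10, range(0, 31)),
        "multiplication_same_start": multiplication_same_start(10, range(0, 21)),
        "multiplication_shifted": multiplication_shifted(10, 10, range(0, 21)),
        "two_exc_one_inh": two_exc_one_inh(10, 10, range(0, 21)),
        "center_surround_simultaneous": center_surround(10, 5, range(0, 41), "simultaneous"),
        "center_surround_sequential": center_surround(10, 5, range(0, 41), "sequential"),
    }
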