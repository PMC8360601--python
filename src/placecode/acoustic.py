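"""Mapping between a discretized acoustic space and the tonotopic axis.

Pure tones are points of a two-dimensional acoustic space with frequency on
one axis and sound pressure on the other, both discretized into half-open
bins on linear scales.  A tone maps to a single interval on the tonotopic
axis: the frequency bin sets the interval's start cell, the pressure bin sets
its length (lowest audible pressure -> one cell).  With matched dimensions
(``n_freq == axis.n_starts`` and ``n_press == axis.max_len``) the mapping is
bijective and decoding is exact per part, although a fused part can always
also arise from several overlapping tones -- that ambiguity is inherent to
the code and is reported with every decode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

from .algebra import Interval, IntervalSet, TonotopicAxis, add


class AudibilityError(ValueError):
    """Frequency or pressure outside the audible (representable) range."""


class MappingError(ValueError):
    """Tone indices exceed what the axis can represent."""


class NotACodewordError(ValueError):
    """An interval part is not the image of any single tone."""


class ConfigurationError(ValueError):
    """Invalid capacity configuration."""


@dataclass(frozen=True)
class AcousticSpace:
    """Discretized frequency/pressure grid of audible pure tones."""

    f0: float
    df: float
    n_freq: int
    p0: float
    dp: float
    n_press: int

    def __post_init__(self) -> None:
        if self.n_freq < 1 or self.n_press < 1:
            raise ValueError("n_freq and n_press must be >= 1")
        if self.df <= 0 or self.dp <= 0:
            raise ValueError("df and dp must be positive")

    @property
    def f_max(self) -> float:
        return self.f0 + self.n_freq * self.df

    @property
    def p_max(self) -> float:
        return self.p0 + self.n_press * self.dp

    def matches(self, axis: TonotopicAxis) -> bool:
        """True iff tone -> interval is bijective on this axis."""
        return self.n_freq == axis.n_starts and self.n_press == axis.max_len


@dataclass(frozen=True)
class Tone:
    """A pure tone by (frequency bin, pressure bin) index."""

    f_index: int
    p_index: int

    def __post_init__(self) -> None:
        if self.f_index < 0 or self.p_index < 0:
            raise ValueError("tone indices must be >= 0")


def default_space(axis: TonotopicAxis, f0: float = 1000.0, df: float = 100.0,
                  p0: float = 0.0, dp: float = 1.0) -> AcousticSpace:
    """An acoustic space dimensioned bijectively for ``axis``."""
    return AcousticSpace(f0=f0, df=df, n_freq=axis.n_starts,
                         p0=p0, dp=dp, n_press=axis.max_len)


def quantize(f: float, p: float, space: AcousticSpace) -> Tone:
    """Assign physical (frequency, pressure) to its half-open bin indices."""
    if not (space.f0 <= f < space.f_max):
        raise AudibilityError(
            f"frequency {f} outside audible range [{space.f0}, {space.f_max})"
        )
    if not (space.p0 <= p < space.p_max):
        raise AudibilityError(
            f"pressure {p} outside audible range [{space.p0}, {space.p_max})"
        )
    return Tone(int((f - space.f0) // space.df), int((p - space.p0) // space.dp))


def map_tone(tone: Tone, axis: TonotopicAxis) -> Interval:
    """Map a tone to its synaptic interval.

    Frequency -> location: start cell equals the frequency bin index.
    Pressure -> size: length is ``p_index + 1`` cells, so the lowest audible
    pressure occupies a single cell and louder tones lengthen rightward from
    the fixed closed end.
    """
    length = tone.p_index + 1
    if length > axis.max_len:
        raise MappingError(
            f"pressure index {tone.p_index} needs length {length} > max_len {axis.max_len}"
        )
    if tone.f_index >= axis.n_starts:
        raise MappingError(
            f"frequency index {tone.f_index} outside start-point set of size {axis.n_starts}"
        )
    return Interval(start=tone.f_index, length=length)


class DecodeResult(NamedTuple):
    tones: list[Tone]
    ambiguous: bool


def decode_interval(s: IntervalSet, axis: TonotopicAxis) -> DecodeResult:
    """Invert the tone mapping part-by-part.

    Each canonical part is decoded as the single tone that would produce it.
    ``ambiguous`` is set whenever the set is non-empty: a part of length L can
    equally be the fusion of several overlapping lower-pressure tones, so the
    single-tone reading is only one consistent explanation.
    """
    tones: list[Tone] = []
    for part in s.parts:
        if part.length > axis.max_len:
            raise NotACodewordError(
                f"part length {part.length} exceeds max codeword length {axis.max_len}"
            )
        if part.start >= axis.n_starts:
            raise NotACodewordError(
                f"part start {part.start} outside admissible start set (size {axis.n_starts})"
            )
        tones.append(Tone(f_index=part.start, p_index=part.length - 1))
    return DecodeResult(tones=tones, ambiguous=bool(tones))


def encode_stimulus(tones: list[Tone], axis: TonotopicAxis) -> IntervalSet:
    """Union of the intervals of all component tones (overlaps fuse)."""
    out = IntervalSet.empty(axis)
    for t in tones:
        out = add(out, IntervalSet(axis, [map_tone(t, axis)]))
    return out


def coding_capacity(scheme: Literal["flexible", "columnar"], n_cells: int,
                    fixed_levels: int) -> int:
    """Achievable level count of the complementary acoustic dimension.

    flexible:
        ``fixed_levels`` is the pressure-level count |P| (= max codeword
        length); returns |F| = n_cells - |P| + 1.  A population of
        |F| + |P| - 1 cells suffices for |F| frequencies x |P| pressures.
    columnar:
        ``fixed_levels`` is the frequency-level count |F| (= column count);
        returns |P| = n_cells / |F| (neurons per column, a population count
        code within the active column).  Requires exact divisibility.
    """
    if n_cells < 1 or fixed_levels < 1:
        raise ConfigurationError("n_cells and fixed_levels must be >= 1")
    if scheme == "flexible":
        if fixed_levels > n_cells:
            raise ConfigurationError(
                f"|P|={fixed_levels} cannot exceed n_cells={n_cells}"
            )
        return n_cells - fixed_levels + 1
    if scheme == "columnar":
        if n_cells % fixed_levels != 0:
            raise ConfigurationError(
                f"n_cells={n_cells} not divisible into {fixed_levels} equal columns"
            )
        return n_cells // fixed_levels
    raise ConfigurationError(f"unknown scheme {scheme!r}")
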