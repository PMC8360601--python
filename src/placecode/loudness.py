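"""Loudness summation and the critical band as interval algebra.

A multi-tone stimulus is the union ``H_m`` of equal-length intervals, one per
component.  A dominant tone carries two inhibitory flanks that abut its
excitatory interval with no overlap; the union of the three is the *critical
interval* ``H_CI``.  The loudness proxy is the length that survives the
flanks:

    |h_l| = |(h_L + h_R) . H_m|

which stays pinned at the dominant interval's length as long as the stimulus
stays inside the critical interval, and grows cell-for-cell once it escapes.
The component count at which the curve first leaves the flat regime (n*)
gives the critical bandwidth: (n* - 1) spacings, or (n* - 1) * delta * df in
frequency units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

from .algebra import Interval, IntervalSet, TonotopicAxis, add, multiply
from .predictions import PredictionCurve


class ConfigurationError(ValueError):
    """Geometry violates the lateral-inhibitory layout."""


@dataclass(frozen=True)
class MultiToneStimulus:
    """Equally spaced multi-tone stimulus on the tonotopic axis.

    ``n_tones`` components, each an interval of ``lam`` cells, adjacent
    starts ``delta`` cells apart, widening around the dominant tone whose
    interval starts at ``center_start``.  In frequency units the bandwidth is
    ``(n_tones - 1) * delta * df``.
    """

    n_tones: int
    lam: int
    delta: int
    center_start: int
    placement: Literal["alternate", "rightward"] = "alternate"

    def __post_init__(self) -> None:
        if self.n_tones < 1:
            raise ValueError("n_tones must be >= 1")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")

    def starts(self) -> list[int]:
        """Component start cells in placement order (dominant first)."""
        if self.placement == "rightward":
            offsets = [k * self.delta for k in range(self.n_tones)]
        else:  # alternate right, then left, widening the band symmetrically
            offsets = [0]
            k = 1
            while len(offsets) < self.n_tones:
                offsets.append(k * self.delta)
                if len(offsets) < self.n_tones:
                    offsets.append(-k * self.delta)
                k += 1
        return [self.center_start + o for o in offsets]

    def bandwidth_cells(self) -> int:
        return (self.n_tones - 1) * self.delta


@dataclass(frozen=True)
class CriticalBandConfig:
    """Dominant excitatory interval with abutting inhibitory flanks.

    The left flank occupies ``[dominant.start - flank_left_len,
    dominant.start)`` and the right flank ``[dominant.stop, dominant.stop +
    flank_right_len)``; neither overlaps the dominant interval.  Flank
    lengths of zero give the all-excitatory control.
    """

    dominant: Interval
    flank_left_len: int
    flank_right_len: int

    def __post_init__(self) -> None:
        if self.flank_left_len < 0 or self.flank_right_len < 0:
            raise ValueError("flank lengths must be >= 0")

    def flanks(self, axis: TonotopicAxis) -> IntervalSet:
        """The union h_L + h_R (may be empty)."""
        parts = []
        if self.flank_left_len > 0:
            if self.dominant.start - self.flank_left_len < 0:
                raise ConfigurationError("left flank overflows the axis")
            parts.append(Interval(self.dominant.start - self.flank_left_len,
                                  self.flank_left_len))
        if self.flank_right_len > 0:
            parts.append(Interval(self.dominant.stop, self.flank_right_len))
        return IntervalSet(axis, parts)


def build_multitone(stim: MultiToneStimulus, axis: TonotopicAxis) -> IntervalSet:
    """Canonical union H_m of the stimulus's component intervals."""
    out = IntervalSet.empty(axis)
    for s in stim.starts():
        if s < 0:
            raise ConfigurationError("component interval falls off the axis")
        out = add(out, IntervalSet(axis, [Interval(s, stim.lam)]))
    return out


def critical_interval(cfg: CriticalBandConfig, axis: TonotopicAxis) -> IntervalSet:
    """H_CI = dominant u left flank u right flank (one fused part)."""
    dom = IntervalSet(axis, [cfg.dominant])
    flanks = cfg.flanks(axis)
    if multiply(dom, flanks).total_length != flanks.total_length:
        raise ConfigurationError("flanks overlap the dominant interval")
    return add(dom, flanks)


def loudness_length(h_m: IntervalSet, cfg: CriticalBandConfig) -> int:
    """Loudness proxy |h_l| = |(h_L + h_R) . H_m|.

    Equals ``cfg.dominant.length`` whenever H_m lies inside the critical
    interval and contains the dominant interval; with zero-length flanks it
    degenerates to |H_m| (no flat region -- the all-excitatory control).
    """
    flanks = cfg.flanks(h_m.axis)
    return multiply(flanks, h_m).total_length


@dataclass(frozen=True)
class CriticalBandCurve:
    """|h_l| as a function of component count, with the deviation point."""

    points: tuple[tuple[int, int], ...]  # (n_components, loudness_length)
    baseline: int                        # dominant interval length
    n_star: int | None                   # first n with |h_l| > baseline

    def bandwidth_cells(self, delta: int) -> int | None:
        """Critical band as a span of cells: (n* - 1) spacings."""
        return None if self.n_star is None else (self.n_star - 1) * delta

    def bandwidth_hz(self, delta: int, df: float) -> float | None:
        cells = self.bandwidth_cells(delta)
        return None if cells is None else cells * df


def critical_band_curve(stim_template: MultiToneStimulus, cfg: CriticalBandConfig,
                        n_max: int, axis: TonotopicAxis) -> CriticalBandCurve:
    """Sweep the component count from 1 to ``n_max``.

    The curve is flat at the dominant length while the stimulus stays inside
    the critical interval and increases once it escapes; ``n_star`` is the
    smallest component count past the flat regime (None if the flanks are
    long enough that the stimulus never escapes within ``n_max``).
    """
    pts = []
    n_star: int | None = None
    for n in range(1, n_max + 1):
        h_m = build_multitone(replace(stim_template, n_tones=n), axis)
        val = loudness_length(h_m, cfg)
        pts.append((n, val))
        if n_star is None and val > cfg.dominant.length:
            n_star = n
    return CriticalBandCurve(points=tuple(pts), baseline=cfg.dominant.length,
                             n_star=n_star)


def four_tone_curve(lam: int, flank_left_len: int, flank_right_len: int,
                    sep_range, axis: TonotopicAxis, base_start: int,
                    dominant_index: int = 0) -> PredictionCurve:
    """|h_l| for a four-tone stimulus as the common separation grows.

    Four intervals of ``lam`` cells start at ``base_start + i*sep``; the
    dominant tone (default: lowest frequency) carries the abutting flanks.
    At sep 0 all components coincide and |h_l| is the dominant length; once
    all components clear the flanks it equals |H_m|.
    """
    if not 0 <= dominant_index < 4:
        raise ValueError("dominant_index must be 0..3")
    pts = []
    for sep in sep_range:
        if sep < 0:
            raise ValueError("separation must be >= 0")
        starts = [base_start + i * sep for i in range(4)]
        h_m = IntervalSet.empty(axis)
        for s in starts:
            h_m = add(h_m, IntervalSet(axis, [Interval(s, lam)]))
        cfg = CriticalBandConfig(dominant=Interval(starts[dominant_index], lam),
                                 flank_left_len=flank_left_len,
                                 flank_right_len=flank_right_len)
        pts.append((sep, loudness_length(h_m, cfg)))
    return PredictionCurve("four_tone", "separation_cells", tuple(pts))
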