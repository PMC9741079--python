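"""Frustum-sum channel measurements.

Each pair of consecutive centerline spheres bounds one *section*, modelled
as a truncated cone (frustum) — a cylinder when the two radii agree — whose
height h is the straight-line distance between the two centers.  Per
section:

    V = (1/3) * pi * h * (r1**2 + r1*r2 + r2**2)
    S = pi * (r1 + r2) * sqrt((r1 - r2)**2 + h**2)

with S the lateral (side) surface only; end caps are never counted.  A
channel's length, lateral surface and volume are the sums over its
sections, and a protein's totals are the sums over all of its channels.
Both formulas are additive under subdivision of a section at any point with
linearly interpolated radius, so totals do not depend on how finely a
straight, linearly tapered stretch is sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .channel_model import ChannelProfile, ProteinChannelSet
from .errors import ValidationError


@dataclass(frozen=True)
class ChannelMeasurement:
    """Totals for one channel or one protein: length (Å), lateral surface (Å²), volume (Å³)."""

    length: float
    surface: float
    volume: float

    def __post_init__(self) -> None:
        if self.length < 0 or self.surface < 0 or self.volume < 0:
            raise ValidationError("measurements must be non-negative")
        if self.length == 0 and (self.surface != 0 or self.volume != 0):
            raise ValidationError("zero length requires zero surface and volume")

    def __add__(self, other: "ChannelMeasurement") -> "ChannelMeasurement":
        return ChannelMeasurement(
            self.length + other.length,
            self.surface + other.surface,
            self.volume + other.volume,
        )


def _check_section_args(r1: float, r2: float, h: float) -> None:
    if r1 <= 0 or r2 <= 0:
        raise ValidationError(f"section radii must be > 0, got r1={r1}, r2={r2}")
    if h < 0:
        raise ValidationError(f"section height must be >= 0, got h={h}")


def section_volume(r1: float, r2: float, h: float) -> float:
    """Volume (Å³) of one frustum section; pi*r**2*h when r1 == r2."""
    _check_section_args(r1, r2, h)
    return math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


def section_surface(r1: float, r2: float, h: float) -> float:
    """Lateral surface (Å²) of one frustum section, without end caps.

    The slant height is sqrt((r1 - r2)**2 + h**2); for a cylinder this
    reduces to 2*pi*r*h.
    """
    _check_section_args(r1, r2, h)
    return math.pi * (r1 + r2) * math.hypot(r1 - r2, h)


def measure_channel(profile: ChannelProfile) -> ChannelMeasurement:
    """Sum length, lateral surface and volume over a profile's sections.

    Raises :class:`~tunnelmetrics.errors.ValidationError` on coincident
    consecutive centers (zero-height sections are only meaningful with a
    direction, and the profile invariant forbids them anyway).
    """
    centers = np.array([n.center for n in profile.nodes])
    radii = np.array([n.r for n in profile.nodes])
    heights = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    if np.any(heights == 0):
        raise ValidationError(
            f"channel {profile.channel_id!r}: coincident consecutive centers"
        )
    length = float(heights.sum())
    surface = float(
        sum(
            section_surface(r1, r2, h)
            for r1, r2, h in zip(radii[:-1], radii[1:], heights)
        )
    )
    volume = float(
        sum(
            section_volume(r1, r2, h)
            for r1, r2, h in zip(radii[:-1], radii[1:], heights)
        )
    )
    return ChannelMeasurement(length, surface, volume)


def measure_protein(
    channel_set: ProteinChannelSet, longest_only: bool = False
) -> ChannelMeasurement:
    """Component-wise sum of :func:`measure_channel` over a protein's channels.

    With ``longest_only`` the totals cover just the single longest channel;
    the default sums every channel reported for the protein.
    """
    if not channel_set.channels:
        raise ValidationError(
            f"protein {channel_set.protein_id!r}: empty channel list"
        )
    measurements = [measure_channel(c) for c in channel_set.channels]
    if longest_only:
        return max(measurements, key=lambda m: m.length)
    total = ChannelMeasurement(0.0, 0.0, 0.0)
    for m in measurements:
        total = total + m
    return total
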