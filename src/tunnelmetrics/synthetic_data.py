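"""Seeded generators for benchmark inputs with known ground truth.

Two generators cover the two halves of the pipeline:

* :func:`generate_dimension_dataset` — a species × dimension table with the
  variance-contraction structure of interest: optimum growth temperatures
  spread over 18–110 °C, class means that do not drift with temperature
  (unless a slope is requested), and a within-class spread that shrinks
  log-linearly with T_opt so the coolest class is several-fold more
  variable than the hottest.

* :func:`generate_tube_structure` — a toy channel-bearing "protein": a
  tube of wall pseudo-atoms around the z axis with a prescribed (piecewise
  linear) inner radius profile R(z), plus the exact ground-truth centerline
  profile, for end-to-end tracer and geometry validation.

Both are pure functions of their spec, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channel_model import AtomSet, ChannelProfile, MeasurementDataset, SphereNode
from .errors import ValidationError

#: default per-dimension means (Å, Å², Å³) and coolest-class SDs — order-of-
#: magnitude realistic for summed enzyme tunnel systems, with a 15% relative
#: spread in the coolest class
DEFAULT_MEANS: Mapping[str, float] = {"length": 400.0, "surface": 4000.0, "volume": 3000.0}
DEFAULT_SIGMA0: Mapping[str, float] = {"length": 60.0, "surface": 600.0, "volume": 450.0}

CLASS_BANDS = {"<50": (18.0, 50.0), "50-80": (50.0, 80.0), ">80": (80.0, 110.0)}

ENZYME_SUBUNITS: Mapping[str, tuple[str, ...]] = {
    "Mmr": ("alpha", "beta", "gamma"),
    "Hdr": ("A", "B", "C"),
}

WALL_VDW = 1.70  # carbon wall pseudo-atoms


@dataclass(frozen=True)
class DimensionGenSpec:
    """Parameters of the dimension-table generator.

    ``kappa`` is the SD contraction factor sigma(">80") / sigma("<50");
    the SD varies log-linearly with T_opt between the band centers of the
    two extreme classes.  ``slope`` adds a linear drift of the mean with
    T_opt (units per °C); the default 0 models temperature-independent
    means.  Values are truncated at zero by redraw, negligible because the
    spec requires mean > 6 * sigma0.
    """

    n_per_class: int = 30
    t_range: tuple[float, float] = (18.0, 110.0)
    means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sigma0: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA0))
    kappa: float = 0.25
    slope: Mapping[str, float] = field(
        default_factory=lambda: {d: 0.0 for d in DEFAULT_MEANS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if not (0 < self.kappa <= 1):
            raise ValidationError(f"kappa must lie in (0, 1], got {self.kappa}")
        lo, hi = self.t_range
        if not (0 < lo < 50 and 80 < hi < 130):
            raise ValidationError(
                "t_range must start below 50 and end above 80 (within (0, 130))"
            )
        for dim, mu in self.means.items():
            s0 = self.sigma0[dim]
            if s0 <= 0:
                raise ValidationError(f"sigma0[{dim}] must be > 0")
            if mu <= 6 * s0:
                raise ValidationError(
                    f"means[{dim}]={mu} must exceed 6*sigma0={6 * s0} so that "
                    f"truncation at 0 is negligible"
                )


def _sd_at(t_opt: float, spec: DimensionGenSpec, dim: str) -> float:
    """SD log-linear in T_opt, anchored at the extreme-class band centers."""
    lo_c = (spec.t_range[0] + 50.0) / 2.0
    hi_c = (80.0 + spec.t_range[1]) / 2.0
    frac = (t_opt - lo_c) / (hi_c - lo_c)
    return spec.sigma0[dim] * spec.kappa**frac


def generate_dimension_dataset(spec: DimensionGenSpec) -> MeasurementDataset:
    """Draw a full measurement table under the spec's variance structure.

    Per enzyme, subunit and temperature class, ``n_per_class`` species are
    drawn: T_opt uniform within the class band (clipped to ``t_range``),
    each dimension normal with mean ``means[dim] + slope[dim] * t_opt`` and
    SD from the log-linear contraction curve, redrawn while non-positive.
    """
    rng = np.random.default_rng(spec.seed)
    bands = {
        "<50": (spec.t_range[0], 50.0),
        "50-80": (50.0, 80.0),
        ">80": (80.0, spec.t_range[1]),
    }
    rows = []
    for enzyme, subunits in ENZYME_SUBUNITS.items():
        for subunit in subunits:
            counter = 0
            for t_class, (lo, hi) in bands.items():
                for _ in range(spec.n_per_class):
                    counter += 1
                    t_opt = float(rng.uniform(lo, hi))
                    row = {
                        "species": f"Methanosynthetica sp. {enzyme}-{subunit}-{counter:03d}",
                        "enzyme": enzyme,
                        "subunit": subunit,
                        "t_opt": t_opt,
                    }
                    for dim, mu in spec.means.items():
                        loc = mu + spec.slope[dim] * t_opt
                        sd = _sd_at(t_opt, spec, dim)
                        value = float(rng.normal(loc, sd))
                        while value <= 0:  # truncation by redraw; essentially never
                            value = float(rng.normal(loc, sd))
                        row[dim] = value
                    rows.append(row)
    return MeasurementDataset(pd.DataFrame(rows))


@dataclass(frozen=True)
class TubeSpec:
    """Parameters of the toy tube-structure generator.

    ``radius_profile`` is a piecewise-linear inner radius R(z) given as
    breakpoints (z, R) spanning [0, length]; a constant tube is two
    breakpoints.  ``atom_spacing`` is the wall sampling step both along z
    and around each ring; it must stay <= 2 Å or the wall leaks probes of
    the tracer's default size.  ``capped`` closes the (z=0, z=length) ends.
    """

    length: float = 20.0
    radius_profile: tuple[tuple[float, float], ...] = ((0.0, 2.0), (20.0, 2.0))
    atom_spacing: float = 1.2
    capped: tuple[bool, bool] = (False, False)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "radius_profile", tuple((float(z), float(r)) for z, r in self.radius_profile)
        )
        if self.length <= 0:
            raise ValidationError("tube length must be > 0")
        if self.atom_spacing <= 0:
            raise ValidationError("atom_spacing must be > 0")
        if self.atom_spacing > 2.0:
            raise ValidationError(
                f"atom_spacing {self.atom_spacing} A > 2 A: wall would leak"
            )
        zs = [z for z, _ in self.radius_profile]
        if len(zs) < 2 or zs != sorted(zs) or zs[0] != 0.0 or zs[-1] != self.length:
            raise ValidationError(
                "radius_profile breakpoints must be sorted and span [0, length]"
            )
        if min(r for _, r in self.radius_profile) <= 1.0:
            raise ValidationError("min inner radius must exceed 1 A")

    def radius_at(self, z: float) -> float:
        return float(np.interp(z, [p[0] for p in self.radius_profile],
                               [p[1] for p in self.radius_profile]))


def generate_tube_structure(spec: TubeSpec) -> tuple[AtomSet, ChannelProfile]:
    """Build the wall atoms and the exact ground-truth centerline profile.

    Wall atoms sit on rings of radius R(z) + vdW around the z axis (so the
    clearance on the axis at a ring equals R(z) exactly), at z steps of
    ``atom_spacing``; ring phases are drawn from the seed.  Capped ends get
    a disk of atoms.  The ground-truth profile samples the axis at every
    ring z plus every breakpoint, with r = R(z).
    """
    rng = np.random.default_rng(spec.seed)
    n_rings = int(math.ceil(spec.length / spec.atom_spacing)) + 1
    ring_z = np.linspace(0.0, spec.length, n_rings)
    coords: list[tuple[float, float, float]] = []

    def add_ring(z: float, rho: float, phase: float) -> None:
        n = max(int(math.ceil(2 * math.pi * rho / spec.atom_spacing)), 6)
        theta = phase + 2 * math.pi * np.arange(n) / n
        for t in theta:
            coords.append((rho * math.cos(t), rho * math.sin(t), z))

    for z in ring_z:
        rho = spec.radius_at(float(z)) + WALL_VDW
        add_ring(float(z), rho, float(rng.uniform(0, 2 * math.pi)))

    for capped, z_end in zip(spec.capped, (0.0, spec.length)):
        if capped:
            rho_max = spec.radius_at(z_end) + WALL_VDW
            coords.append((0.0, 0.0, z_end))
            for rho in np.arange(spec.atom_spacing, rho_max, spec.atom_spacing):
                add_ring(z_end, float(rho), float(rng.uniform(0, 2 * math.pi)))

    arr = np.array(coords)
    atoms = AtomSet(arr, np.full(len(arr), WALL_VDW), tuple("W" for _ in coords))

    sample_z = np.unique(np.concatenate([ring_z, [z for z, _ in spec.radius_profile]]))
    nodes = tuple(
        SphereNode(0.0, 0.0, float(z), spec.radius_at(float(z))) for z in sample_z
    )
    truth = ChannelProfile("ground_truth", nodes)
    return atoms, truth
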