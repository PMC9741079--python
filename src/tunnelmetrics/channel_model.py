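"""Domain types and file I/O for channel profiles, structures and species tables.

A molecular channel (tunnel) is represented as an ordered chain of spheres:
each sample carries a 3D centerline point (Å) and the local channel radius
(Å), which is what tunnel-detection tools such as MOLE or CAVER export.
This module defines the in-memory types and three interchange formats:

* profile JSON — the canonical dialect: a top-level list of protein objects,
  each with ``protein_id, species, enzyme, subunit, source`` and a list of
  channels ``{channel_id, nodes: [{x, y, z, r}]}``;
* profile CSV — a flat compatibility format for tool exports, with header
  ``channel_id,x,y,z,r``, rows of one channel contiguous and in path order;
* dataset TSV — per-protein measurements joined with species metadata,
  columns ``species, enzyme, subunit, t_opt, length, surface, volume``.

All coordinates and radii are in Å; there is no unit autodetection.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

ENZYMES = ("Mmr", "Hdr")
SOURCES = ("predicted", "resolved")

#: van der Waals radii (Å) used when reading structures, keyed by element.
VDW_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}
DEFAULT_VDW = 1.70

DIMENSIONS = ("length", "surface", "volume")


@dataclass(frozen=True)
class SphereNode:
    """One centerline sample: center (x, y, z) in Å and local radius r in Å."""

    x: float
    y: float
    z: float
    r: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "r"):
            object.__setattr__(self, name, float(getattr(self, name)))
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"SphereNode.{name} must be finite, got {v!r}")
        if self.r <= 0:
            raise ValidationError(f"SphereNode.r must be > 0, got {self.r}")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class ChannelProfile:
    """An ordered chain of spheres describing one channel."""

    channel_id: str
    nodes: tuple[SphereNode, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if len(self.nodes) < 2:
            raise ValidationError(
                f"channel {self.channel_id!r}: a profile needs >= 2 nodes, "
                f"got {len(self.nodes)}"
            )
        for i, (a, b) in enumerate(zip(self.nodes, self.nodes[1:])):
            if (a.x, a.y, a.z) == (b.x, b.y, b.z):
                raise ValidationError(
                    f"channel {self.channel_id!r}: nodes {i} and {i + 1} share "
                    f"the same center"
                )

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class ProteinChannelSet:
    """All channels detected in one protein, with species metadata."""

    protein_id: str
    species: str
    enzyme: str
    subunit: str
    source: str
    channels: tuple[ChannelProfile, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.enzyme not in ENZYMES:
            raise ValidationError(
                f"protein {self.protein_id!r}: enzyme must be one of {ENZYMES}, "
                f"got {self.enzyme!r}"
            )
        if self.source not in SOURCES:
            raise ValidationError(
                f"protein {self.protein_id!r}: source must be one of {SOURCES}, "
                f"got {self.source!r}"
            )
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"protein {self.protein_id!r}: duplicate channel_id in {ids}"
            )


@dataclass(frozen=True)
class AtomSet:
    """A bag of atoms: coordinates (Å), van der Waals radii (Å) and names.

    This is the tracer's input; chain/model structure is deliberately
    discarded — the clearance field only needs positions and radii.
    """

    coords: np.ndarray  # (n, 3) float
    radii: np.ndarray  # (n,) float
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "names", tuple(self.names))
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
            raise ValidationError("AtomSet.coords must be a non-empty (n, 3) array")
        if radii.shape != (coords.shape[0],):
            raise ValidationError("AtomSet.radii must be (n,) matching coords")
        if len(self.names) != coords.shape[0]:
            raise ValidationError("AtomSet.names must match the atom count")
        if not np.all(np.isfinite(coords)) or not np.all(np.isfinite(radii)):
            raise ValidationError("AtomSet coordinates/radii must be finite")
        if np.any(radii <= 0):
            raise ValidationError("AtomSet radii must all be > 0")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SpeciesRecord:
    """One species/enzyme/subunit row with its optimum growth temperature."""

    species: str
    enzyme: str
    subunit: str
    t_opt: float
    t_class: str = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.t_opt < 130):
            raise ValidationError(
                f"{self.species!r}: t_opt must lie in (0, 130) degC, got {self.t_opt}"
            )
        from .stats import assign_class  # local import: stats depends on this module

        object.__setattr__(self, "t_class", assign_class(self.t_opt))


class MeasurementDataset:
    """Per-protein channel measurements joined with species metadata.

    Thin wrapper over a :class:`pandas.DataFrame` with validated columns
    ``species, enzyme, subunit, t_opt, t_class, length, surface, volume``
    (``length`` in Å, ``surface`` in Å², ``volume`` in Å³).
    """

    REQUIRED = ("species", "enzyme", "subunit", "t_opt") + DIMENSIONS

    def __init__(self, frame: pd.DataFrame):
        from .stats import assign_class

        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"dataset missing required columns: {missing}")
        frame = frame.reset_index(drop=True).copy()
        for i, t in enumerate(frame["t_opt"]):
            try:
                float(t)
            except (TypeError, ValueError):
                raise ParseError(f"row {i}: non-numeric t_opt {t!r}") from None
        frame["t_opt"] = frame["t_opt"].astype(float)
        for dim in DIMENSIONS:
            vals = frame[dim].astype(float)
            bad = vals < 0
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(f"row {i}: negative {dim} {vals.iloc[i]}")
            frame[dim] = vals
        frame["t_class"] = [assign_class(t) for t in frame["t_opt"]]
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementDataset):
            return NotImplemented
        return self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# profile JSON
# ---------------------------------------------------------------------------


def _as_stream(source: str | Path | IO[str], mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_profile_json(source: str | Path | IO[str]) -> list[ProteinChannelSet]:
    """Read the canonical profile JSON dialect.

    Returns one :class:`ProteinChannelSet` per top-level object, node order
    preserved. Malformed records raise :class:`ParseError` naming the path
    of the offending element; invariant violations (e.g. ``r <= 0``) raise
    :class:`ValidationError`.
    """
    stream, owned = _as_stream(source)
    try:
        try:
            data = json.load(stream)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON: {exc}") from exc
    finally:
        if owned:
            stream.close()
    if not isinstance(data, list):
        raise ParseError("profile JSON must be a top-level list of proteins")
    sets = []
    for pi, prot in enumerate(data):
        where = f"protein[{pi}]"
        if not isinstance(prot, dict):
            raise ParseError(f"{where}: expected an object")
        try:
            channels = []
            for ci, chan in enumerate(prot["channels"]):
                nodes = tuple(
                    SphereNode(float(n["x"]), float(n["y"]), float(n["z"]), float(n["r"]))
                    for n in chan["nodes"]
                )
                channels.append(ChannelProfile(str(chan["channel_id"]), nodes))
            return_set = ProteinChannelSet(
                protein_id=str(prot["protein_id"]),
                species=str(prot["species"]),
                enzyme=str(prot["enzyme"]),
                subunit=str(prot["subunit"]),
                source=str(prot["source"]),
                channels=tuple(channels),
            )
        except KeyError as exc:
            raise ParseError(f"{where}: missing field {exc.args[0]!r}") from exc
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ParseError(f"{where}: {exc}") from exc
        sets.append(return_set)
    return sets


def write_profile_json(sets: Iterable[ProteinChannelSet], dest: str | Path | IO[str]) -> None:
    """Write protein channel sets in the canonical JSON dialect."""
    payload = [
        {
            "protein_id": s.protein_id,
            "species": s.species,
            "enzyme": s.enzyme,
            "subunit": s.subunit,
            "source": s.source,
            "channels": [
                {
                    "channel_id": c.channel_id,
                    "nodes": [{"x": n.x, "y": n.y, "z": n.z, "r": n.r} for n in c.nodes],
                }
                for c in s.channels
            ],
        }
        for s in sets
    ]
    stream, owned = _as_stream(dest, "w")
    try:
        json.dump(payload, stream, indent=1)
    finally:
        if owned:
            stream.close()


# ---------------------------------------------------------------------------
# profile CSV (tunnel-tool export compatibility)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("channel_id", "x", "y", "z", "r")


def read_profile_csv(source: str | Path | IO[str]) -> list[ChannelProfile]:
    """Read the flat CSV dialect: header ``channel_id,x,y,z,r``.

    Rows of one channel must be contiguous and in path order; interleaved
    channel ids are a dialect violation and raise :class:`ParseError`.
    """
    stream, owned = _as_stream(source)
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise ParseError("empty CSV: expected header channel_id,x,y,z,r")
        missing = [c for c in _CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ParseError(
                f"CSV missing required column(s) {missing}; "
                f"required header: {','.join(_CSV_COLUMNS)}"
            )
        profiles: list[ChannelProfile] = []
        seen: set[str] = set()
        current_id: str | None = None
        nodes: list[SphereNode] = []

        def flush() -> None:
            if current_id is not None:
                profiles.append(ChannelProfile(current_id, tuple(nodes)))

        for ln, row in enumerate(reader, start=2):
            cid = row["channel_id"]
            try:
                node = SphereNode(
                    float(row["x"]), float(row["y"]), float(row["z"]), float(row["r"])
                )
            except (TypeError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"line {ln}: {exc}") from exc
            if cid != current_id:
                if cid in seen:
                    raise ParseError(
                        f"line {ln}: channel_id {cid!r} reappears after another "
                        f"channel; rows of a channel must be contiguous"
                    )
                flush()
                seen.add(cid)
                current_id, nodes = cid, []
            nodes.append(node)
        flush()
        return profiles
    finally:
        if owned:
            stream.close()


def write_profile_csv(profiles: Iterable[ChannelProfile], dest: str | Path | IO[str]) -> None:
    stream, owned = _as_stream(dest, "w")
    try:
        writer = csv.writer(stream)
        writer.writerow(_CSV_COLUMNS)
        for p in profiles:
            for n in p.nodes:
                writer.writerow([p.channel_id, repr(n.x), repr(n.y), repr(n.z), repr(n.r)])
    finally:
        if owned:
            stream.close()


# ---------------------------------------------------------------------------
# structures (PDB)
# ---------------------------------------------------------------------------


def read_structure_pdb(path: str | Path) -> AtomSet:
    """Read ATOM/HETATM records from a PDB file into an :class:`AtomSet`.

    Van der Waals radii come from the built-in per-element table
    (:data:`VDW_RADII`); unknown elements get the default 1.70 Å with a
    logged warning. All models/chains are used.
    """
    structure = gemmi.read_pdb(str(path))
    coords: list[list[float]] = []
    radii: list[float] = []
    names: list[str] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    element = atom.element.name.upper()
                    if element not in VDW_RADII:
                        logger.warning(
                            "unknown element %r for atom %s: using default "
                            "vdW radius %.2f A",
                            element,
                            atom.name,
                            DEFAULT_VDW,
                        )
                    radii.append(VDW_RADII.get(element, DEFAULT_VDW))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    names.append(atom.name)
    if not coords:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return AtomSet(np.array(coords), np.array(radii), tuple(names))


def write_structure_pdb(atoms: AtomSet, path: str | Path, element: str = "C") -> None:
    """Write an :class:`AtomSet` as a minimal single-chain PDB file."""
    structure = gemmi.Structure()
    structure.name = "tunnelmetrics"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i in range(len(atoms)):
        residue = gemmi.Residue()
        residue.name = "UNK"
        residue.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = atoms.names[i][:4]
        atom.element = gemmi.Element(element)
        x, y, z = atoms.coords[i]
        atom.pos = gemmi.Position(x, y, z)
        atom.occ = 1.0
        residue.add_atom(atom)
        chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


# ---------------------------------------------------------------------------
# dataset tables
# ---------------------------------------------------------------------------


def read_dataset_table(
    source: str | Path | IO[str],
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> MeasurementDataset:
    """Read a measurement table (TSV by default) into a dataset.

    Required columns: ``species, enzyme, subunit, t_opt, length, surface,
    volume``. ``column_map`` renames external headers onto those names,
    which is the entry point for reanalysing third-party measurement tables
    whose headers differ (pass e.g. ``{"Topt (degC)": "t_opt"}``).
    Temperature classes are assigned from ``t_opt``.
    """
    stream, owned = _as_stream(source)
    try:
        frame = pd.read_csv(stream, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=list(MeasurementDataset.REQUIRED))
    finally:
        if owned:
            stream.close()
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    if frame.empty:
        # headerless/empty input: an empty dataset, not an error
        frame = frame.reindex(
            columns=list(dict.fromkeys(list(frame.columns) + list(MeasurementDataset.REQUIRED)))
        )
    return MeasurementDataset(frame)


def write_dataset_table(dataset: MeasurementDataset, dest: str | Path | IO[str]) -> None:
    stream, owned = _as_stream(dest, "w")
    try:
        dataset.frame.to_csv(stream, sep="\t", index=False)
    finally:
        if owned:
            stream.close()
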