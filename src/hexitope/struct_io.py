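"""Structure and trajectory I/O with semantic entity annotation.

Coordinates are Å throughout.  Residues keep the author numbering of the
coordinate file (1-based); no renumbering is ever performed silently.
Multi-model PDB is the canonical trajectory dialect; plain XYZ frame series
are also accepted.  Hydrogens are retained when present, because a 2 Å
inter-residue contact distance is only physically attainable as an atom-atom
distance when hydrogens participate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bpdb

from hexitope.errors import (
    ConfigurationError,
    LookupFailure,
    StructureError,
    StructureParseError,
)

#: residue key: (chain_id, seq_number, insertion_code)
ResKey = tuple[str, int, str]


@dataclass
class Atom:
    """A single atom: label, element symbol and Cartesian coordinates (Å)."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: empty element symbol")


@dataclass
class Residue:
    """A residue identified by (chain, author seq number, insertion code)."""

    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom]
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.key}: no atoms")

    @property
    def key(self) -> ResKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.name}{self.seq_number}{self.insertion_code}"


@dataclass
class Topology:
    """Ordered residues plus the chain→entity and entity→region annotation.

    ``entity_map`` assigns each chain a semantic label such as ``P1``…``P6``
    for the six protomers of a connexon, or ``AB1-HC`` / ``AB1-LC`` for the
    heavy and light chains of the first bound antibody.  ``region_map`` names
    residue sets within an entity (``EC1``, ``EC2``, ``CDR1``…``CDR3``,
    ``CONST``) by author residue number.
    """

    residues: list[Residue]
    entity_map: dict[str, str] = field(default_factory=dict)
    region_map: dict[str, dict[str, list[int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise StructureError("duplicate residue keys in topology")
        self._index: dict[ResKey, Residue] = {r.key: r for r in self.residues}
        # global atom index range of each residue, in file order
        self._slices: dict[ResKey, tuple[int, int]] = {}
        start = 0
        for r in self.residues:
            self._slices[r.key] = (start, start + len(r.atoms))
            start += len(r.atoms)
        self._n_atoms = start

    @property
    def n_atoms(self) -> int:
        return self._n_atoms

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    @property
    def protomers(self) -> list[str]:
        """Protomer entity labels in cyclic order (P1, P2, ...)."""
        labels = {e for e in self.entity_map.values() if _is_protomer(e)}
        return sorted(labels, key=lambda p: int(p[1:]))

    @property
    def antibody_entities(self) -> list[str]:
        return sorted({e for e in self.entity_map.values() if e.startswith("AB")})

    def antibodies(self) -> list[str]:
        """Antibody labels (``AB1``, ``AB2``) irrespective of chain role."""
        return sorted({e.split("-")[0] for e in self.antibody_entities})

    def residue(self, key: ResKey) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise LookupFailure(f"no residue {key} in topology") from None

    def atom_slice(self, key: ResKey) -> tuple[int, int]:
        """[start, stop) indices of a residue's atoms in the flat atom order."""
        try:
            return self._slices[key]
        except KeyError:
            raise LookupFailure(f"no residue {key} in topology") from None

    def chains_of_entity(self, entity: str) -> list[str]:
        chains = [c for c, e in self.entity_map.items() if e == entity or e.split("-")[0] == entity]
        if not chains:
            raise LookupFailure(f"no chain mapped to entity {entity!r}")
        return chains

    def residues_of_entity(self, entity: str) -> list[Residue]:
        chains = set(self.chains_of_entity(entity))
        return [r for r in self.residues if r.chain_id in chains]

    def residues_in_region(self, entity: str, region: str) -> list[Residue]:
        try:
            numbers = set(self.region_map[entity][region])
        except KeyError:
            raise LookupFailure(f"no region {region!r} for entity {entity!r}") from None
        return [r for r in self.residues_of_entity(entity) if r.seq_number in numbers]

    def entity_of(self, chain_id: str) -> str:
        try:
            return self.entity_map[chain_id]
        except KeyError:
            raise LookupFailure(f"chain {chain_id!r} has no entity label") from None

    def find(self, entity: str, seq_number: int, insertion_code: str = "") -> Residue:
        """Look a residue up by entity label and author number."""
        for r in self.residues_of_entity(entity):
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        raise LookupFailure(f"no residue {seq_number}{insertion_code} in entity {entity!r}")

    def coords(self) -> np.ndarray:
        """Flat (n_atoms, 3) coordinate array in topology atom order."""
        return np.concatenate([[a.coords for a in r.atoms] for r in self.residues])


@dataclass
class Trajectory:
    """Frame series sharing one Topology's atom order; times in ns."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray   # (n_frames,)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.frames):
            raise StructureError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def window(self, t_start: float, t_stop: float) -> "Trajectory":
        """Retain frames with time in the closed interval [t_start, t_stop] ns."""
        if t_stop < t_start:
            raise StructureError("empty time window")
        mask = (self.times >= t_start) & (self.times <= t_stop)
        if not mask.any():
            raise StructureError(
                f"window [{t_start}, {t_stop}] ns contains no frames "
                f"(trajectory spans {self.times[0]}-{self.times[-1]} ns)"
            )
        return Trajectory(self.frames[mask], self.times[mask])


def _is_protomer(label: str) -> bool:
    return len(label) >= 2 and label[0] == "P" and label[1:].isdigit()


# ---------------------------------------------------------------------------
# readers / writers


def _residues_from_atom_array(arr: bst.AtomArray) -> list[Residue]:
    residues: list[Residue] = []
    starts = bst.get_residue_starts(arr, add_exclusive_stop=True)
    for i, j in zip(starts[:-1], starts[1:]):
        sub = arr[i:j]
        atoms = [
            Atom(name=str(sub.atom_name[k]), element=str(sub.element[k]) or "X",
                 coords=sub.coord[k])
            for k in range(len(sub))
        ]
        residues.append(
            Residue(
                chain_id=str(sub.chain_id[0]),
                seq_number=int(sub.res_id[0]),
                insertion_code=str(sub.ins_code[0]).strip(),
                name=str(sub.res_name[0]),
                atoms=atoms,
            )
        )
    return residues


def _locate_bad_pdb_line(path: str) -> int | None:
    # fallback used only to name the offending line in a parse error
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return lineno
    return None


def read_structure(path: str, format: str = "pdb") -> tuple[Topology, np.ndarray]:
    """Read a coordinate file into a :class:`Topology` plus its first frame.

    Parameters
    ----------
    path:
        PDB or XYZ file.
    format:
        ``"pdb"`` (default) or ``"xyz"``.  XYZ carries no chain/residue
        metadata, so its atoms are grouped into a single residue of chain
        ``A``; XYZ is primarily useful as a frame series via
        :func:`read_trajectory`.

    Returns
    -------
    (topology, frame):
        The topology (with coordinates of the first model stored on its
        atoms) and the same coordinates as a flat ``(n_atoms, 3)`` array.
    """
    if format == "pdb":
        try:
            pdb_file = bpdb.PDBFile.read(path)
            arr = pdb_file.get_structure(model=1, altloc="first")
        except FileNotFoundError:
            raise
        except OSError as exc:
            raise StructureParseError(f"{path}: {exc}") from exc
        except Exception as exc:
            lineno = _locate_bad_pdb_line(path)
            where = f" (line {lineno})" if lineno else ""
            raise StructureParseError(f"{path}: malformed PDB record{where}: {exc}") from exc
        residues = _residues_from_atom_array(arr)
    elif format == "xyz":
        frames, _ = _read_xyz_frames(path)
        atoms = [
            Atom(name=f"X{i + 1}", element="X", coords=c) for i, c in enumerate(frames[0])
        ]
        residues = [Residue(chain_id="A", seq_number=1, name="UNK", atoms=atoms)]
    else:
        raise ValueError(f"unknown structure format {format!r}")
    if not residues:
        raise StructureParseError(f"{path}: no atoms found")
    topo = Topology(residues=residues)
    return topo, topo.coords()


def _read_xyz_frames(path: str) -> tuple[list[np.ndarray], list[str]]:
    frames: list[np.ndarray] = []
    comments: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise StructureParseError(f"{path}: expected atom count at line {i + 1}")
        if i + 1 + n >= len(lines) + 1:
            raise StructureParseError(f"{path}: truncated frame at line {i + 1}")
        comments.append(lines[i + 1].rstrip("\n"))
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise StructureParseError(f"{path}: malformed XYZ record (line {i + 3 + k})")
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise StructureParseError(f"{path}: malformed XYZ record (line {i + 3 + k})")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise StructureParseError(f"{path}: no frames")
    return frames, comments


def read_trajectory(
    paths: str | list[str],
    topology: Topology,
    window: tuple[float, float] | None = None,
    stride_ns: float = 1.0,
    format: str = "pdb",
) -> Trajectory:
    """Read a frame series and (optionally) retain a closed time window.

    Frame times default to ``model index × stride_ns`` (the first model is
    t = 0) because neither multi-model PDB nor XYZ carries time metadata.
    ``window=(t0, t1)`` retains frames with ``t0 <= t <= t1`` — e.g. the
    last 10 ns of a 150 ns run is ``window=(140.0, 150.0)``.
    """
    if isinstance(paths, str):
        paths = [paths]
    all_frames: list[np.ndarray] = []
    for path in paths:
        if format == "pdb":
            try:
                pdb_file = bpdb.PDBFile.read(path)
                stack = pdb_file.get_structure(altloc="first")
            except Exception as exc:
                raise StructureParseError(f"{path}: {exc}") from exc
            coords = stack.coord if stack.coord.ndim == 3 else stack.coord[None]
            all_frames.extend(coords)
        elif format == "xyz":
            frames, _ = _read_xyz_frames(path)
            all_frames.extend(frames)
        else:
            raise ValueError(f"unknown trajectory format {format!r}")
    for i, f in enumerate(all_frames):
        if len(f) != topology.n_atoms:
            raise StructureError(
                f"frame {i}: {len(f)} atoms, topology has {topology.n_atoms}"
            )
    times = np.arange(len(all_frames)) * float(stride_ns)
    traj = Trajectory(np.asarray(all_frames), times)
    if window is not None:
        traj = traj.window(*window)
    return traj


def write_structure(
    path: str,
    topology: Topology,
    frames: np.ndarray | None = None,
) -> None:
    """Write a PDB (multi-model when several frames are given)."""
    if frames is None:
        frames = topology.coords()[None]
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = topology.n_atoms
    arr = bst.AtomArray(n)
    i = 0
    for r in topology.residues:
        for a in r.atoms:
            arr.chain_id[i] = r.chain_id
            arr.res_id[i] = r.seq_number
            arr.ins_code[i] = r.insertion_code
            arr.res_name[i] = r.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.hetero[i] = False
            i += 1
    if len(frames) == 1:
        arr.coord = frames[0]
        out: bst.AtomArray | bst.AtomArrayStack = arr
    else:
        out = bst.stack([arr] * len(frames))
        out.coord = frames
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(out)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# entity assignment


def assign_entities(topology: Topology, mapping: dict) -> Topology:
    """Attach entity labels and named regions from a configuration table.

    ``mapping`` has two blocks::

        chains:            # chain id -> entity label
          A: P1
          ...
          H: AB1-HC
        regions:           # entity label -> region name -> residue numbers
          P1: {EC1: [54, 55, 56, 57, 58], EC2: [175, 176, 177]}
          AB1-HC: {CDR1: [30], ...}

    Residue numbers are explicit lists.  A ``regions`` entry keyed
    ``"protomer"`` is expanded to every protomer entity, which is the
    common case for a homomeric channel.
    """
    chain_map = dict(mapping.get("chains", {}))
    missing = [c for c in topology.chains if c not in chain_map]
    if missing:
        raise ConfigurationError(f"chains without entity label: {missing}")
    # config entries for chains absent from this structure are ignored, so
    # one config can serve the full complex and its sub-structures (poses)
    present = set(topology.chains)
    chain_map = {c: e for c, e in chain_map.items() if c in present}
    protomer_labels = [e for e in chain_map.values() if _is_protomer(e)]
    if len(protomer_labels) != len(set(protomer_labels)):
        raise ConfigurationError("duplicate protomer labels in entity map")

    regions_cfg = {k: {rn: list(v) for rn, v in d.items()} for k, d in mapping.get("regions", {}).items()}
    region_map: dict[str, dict[str, list[int]]] = {}
    protomer_default = regions_cfg.pop("protomer", None)
    for entity in set(chain_map.values()):
        if _is_protomer(entity) and protomer_default is not None:
            region_map[entity] = {rn: list(v) for rn, v in protomer_default.items()}
    known_entities = set(chain_map.values())
    for entity, regions in regions_cfg.items():
        if entity in known_entities:
            region_map.setdefault(entity, {}).update(regions)

    topo = Topology(residues=topology.residues, entity_map=chain_map, region_map=region_map)
    # region residue numbers must exist
    for entity, regions in topo.region_map.items():
        present = {r.seq_number for r in topo.residues_of_entity(entity)}
        for rn, numbers in regions.items():
            absent = sorted(set(numbers) - present)
            if absent:
                raise ConfigurationError(
                    f"region {entity}/{rn}: residues {absent} not in topology"
                )
    return topo
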