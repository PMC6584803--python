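"""Docking-pose orientation filtering.

Docking servers emit tens of rigid-body poses; only poses in which the three
heavy-chain complementarity-determining regions (CDR1-3) face the EC1 loops
of the channel are paratope-consistent.  "Facing" is operationalized as the
conjunction of (a) a proximity test — some CDR residue within a cutoff
distance of some EC1 residue — and (b) an orientation test — the CDR
centroid lies nearer the EC1 centroid than the antibody centroid does, i.e.
the loop points toward the channel rather than away from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hexitope.contact_analysis import min_residue_distance
from hexitope.errors import ConfigurationError, HexitopeError
from hexitope.struct_io import Residue, Topology

_CDRS = ("CDR1", "CDR2", "CDR3")


@dataclass
class Pose:
    """A single rigid placement of the antibody relative to the channel."""

    pose_id: str
    topology: Topology
    coords: np.ndarray  # (n_atoms, 3)
    score: float | None = None  # opaque docking score, never recomputed

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise HexitopeError(
                f"pose {self.pose_id}: coords shape {self.coords.shape} does not "
                f"match topology ({self.topology.n_atoms} atoms)"
            )


def _region_coords(pose: Pose, residues: list[Residue]) -> np.ndarray:
    if not residues:
        raise HexitopeError("empty region")
    idx = np.concatenate(
        [np.arange(*pose.topology.atom_slice(r.key)) for r in residues]
    )
    return pose.coords[idx]


def cdr_faces_ec1(
    pose: Pose,
    cdr_residues: list[Residue],
    ec1_residues: list[Residue],
    antibody_entity: str,
    contact_cutoff: float = 8.0,
) -> bool:
    """True iff one CDR loop faces the EC1 loops in this pose.

    Proximity: at least one CDR×EC1 residue pair has minimum atom distance
    strictly below ``contact_cutoff``.  Orientation: the CDR centroid is
    nearer the EC1 centroid than the whole antibody entity's centroid is.
    """
    cdr_xyz = _region_coords(pose, cdr_residues)
    ec1_xyz = _region_coords(pose, ec1_residues)
    if contact_cutoff <= 0:
        return False
    near = False
    for r in cdr_residues:
        a0, a1 = pose.topology.atom_slice(r.key)
        for s in ec1_residues:
            b0, b1 = pose.topology.atom_slice(s.key)
            if min_residue_distance(pose.coords[a0:a1], pose.coords[b0:b1]) < contact_cutoff:
                near = True
                break
        if near:
            break
    if not near:
        return False
    ab_residues = pose.topology.residues_of_entity(antibody_entity)
    ab_centroid = _region_coords(pose, ab_residues).mean(axis=0)
    ec1_centroid = ec1_xyz.mean(axis=0)
    cdr_centroid = cdr_xyz.mean(axis=0)
    return float(np.linalg.norm(cdr_centroid - ec1_centroid)) < float(
        np.linalg.norm(ab_centroid - ec1_centroid)
    )


def _collect_ec1(topo: Topology) -> list[Residue]:
    residues: list[Residue] = []
    for protomer in topo.protomers:
        if "EC1" in topo.region_map.get(protomer, {}):
            residues.extend(topo.residues_in_region(protomer, "EC1"))
    if not residues:
        raise ConfigurationError("no EC1 region defined on any protomer")
    return residues


def evaluate_pose(
    pose: Pose,
    heavy_entity: str = "AB1-HC",
    contact_cutoff: float = 8.0,
) -> dict[str, bool]:
    """Per-CDR facing verdicts for one pose (keys ``CDR1``…``CDR3``)."""
    topo = pose.topology
    ec1 = _collect_ec1(topo)
    regions = topo.region_map.get(heavy_entity, {})
    missing = [c for c in _CDRS if c not in regions]
    if missing:
        raise ConfigurationError(f"entity {heavy_entity!r} lacks regions {missing}")
    antibody = heavy_entity.split("-")[0]
    return {
        cdr: cdr_faces_ec1(
            pose,
            topo.residues_in_region(heavy_entity, cdr),
            ec1,
            antibody_entity=antibody,
            contact_cutoff=contact_cutoff,
        )
        for cdr in _CDRS
    }


def filter_poses(
    poses: list[Pose],
    heavy_entity: str = "AB1-HC",
    contact_cutoff: float = 8.0,
    require_all_cdrs: bool = True,
) -> tuple[list[Pose], pd.DataFrame]:
    """Keep poses whose heavy-chain CDRs face EC1.

    With ``require_all_cdrs`` (default) all three CDRs must face; otherwise
    one suffices.  Returns the retained poses and a verdict table with one
    row per input pose.  An empty retained list is a legitimate outcome
    (callers distinguish "no pose passed" from errors).
    """
    if not poses:
        raise HexitopeError("no poses to filter")
    rows = []
    retained: list[Pose] = []
    for pose in poses:
        verdicts = evaluate_pose(pose, heavy_entity, contact_cutoff)
        keep = all(verdicts.values()) if require_all_cdrs else any(verdicts.values())
        rows.append({"pose_id": pose.pose_id, **verdicts, "retained": keep})
        if keep:
            retained.append(pose)
    return retained, pd.DataFrame(rows)
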