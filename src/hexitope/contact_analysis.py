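"""Inter-residue distances and interaction probabilities.

The central statistic is the *interaction probability* of a residue pair:
the fraction of trajectory frames in which the minimum atom-atom distance
between the two residues is strictly below a fixed threshold (2 Å by
default), expressed as a percentage.  Residue-level probabilities against a
partner entity are the frame-wise union over all pairs involving that
residue — a residue counts as interacting in a frame if *any* of its pairs
is in contact, so the residue value is never below any of its pair values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from hexitope.errors import HexitopeError, LookupFailure
from hexitope.struct_io import Residue, Topology, Trajectory

#: a residue reference: (entity label, author residue number)
ResRef = tuple[str, int]
#: an inter-entity residue pair
PairRef = tuple[ResRef, ResRef]

_HYDROGEN = {"H", "D"}


def _mode_mask(residue: Residue, atom_mode: str) -> np.ndarray:
    if atom_mode == "all":
        mask = np.ones(len(residue.atoms), dtype=bool)
    elif atom_mode == "heavy":
        mask = np.array([a.element.upper() not in _HYDROGEN for a in residue.atoms])
    elif atom_mode == "calpha":
        mask = np.array([a.name.strip() == "CA" for a in residue.atoms])
    else:
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    if not mask.any():
        raise HexitopeError(
            f"residue {residue.key} has no atoms under atom_mode={atom_mode!r}"
        )
    return mask


def min_residue_distance(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    method: str = "auto",
) -> float:
    """Minimum pairwise atom distance (Å) between two atom coordinate sets.

    ``method="brute"`` computes the full distance matrix; ``"kdtree"`` uses a
    KD-tree nearest-neighbor query (the accelerated path for large
    selections); ``"auto"`` picks by size.  All methods return identical
    values — the brute-force path doubles as the oracle in the test suite.
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise HexitopeError("empty atom selection")
    if method == "auto":
        method = "kdtree" if len(a) * len(b) > 4096 else "brute"
    if method == "brute":
        return float(cdist(a, b).min())
    if method == "kdtree":
        tree = cKDTree(b)
        d, _ = tree.query(a, k=1)
        return float(np.min(d))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ContactSeries:
    """Per-pair, per-frame contact indicators at a fixed distance threshold."""

    pairs: list[PairRef]
    indicator: np.ndarray  # bool, (n_pairs, n_frames)
    threshold: float
    names: dict[ResRef, str] = field(default_factory=dict)
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.shape[0] != len(self.pairs):
            raise HexitopeError("indicator rows must match pair count")
        if self.threshold <= 0:
            raise HexitopeError("threshold must be positive")

    @property
    def n_frames(self) -> int:
        return self.indicator.shape[1]

    def entities(self) -> set[str]:
        return {ref[0] for pair in self.pairs for ref in pair}


@dataclass
class ContactTable:
    """Pair- and residue-level interaction probabilities, in percent.

    ``residue_probability`` is keyed by ``(residue_ref, partner_entity)``
    where the partner entity is the antibody label (``AB1``) for channel
    residues and the channel (``channel``) for antibody residues, so the
    same residue can carry one value per binding partner.
    """

    pair_probability: dict[PairRef, float]
    residue_probability: dict[tuple[ResRef, str], float]
    threshold: float
    names: dict[ResRef, str] = field(default_factory=dict)
    window: tuple[float, float] | None = None

    @classmethod
    def from_residue_frame(
        cls,
        df: pd.DataFrame,
        partner: str,
        threshold: float = 2.0,
        entity_col: str = "protomer",
    ) -> "ContactTable":
        """Build a residue-level-only table from a published-style frame.

        Expects columns ``entity_col``, ``residue``, ``number`` and
        ``probability_pct``; pair-level probabilities are unavailable in
        that layout and are left empty.
        """
        residue_probability = {}
        names = {}
        for row in df.itertuples():
            ref = (getattr(row, entity_col), int(row.number))
            residue_probability[(ref, partner)] = float(row.probability_pct)
            names[ref] = str(row.residue)
        return cls(
            pair_probability={},
            residue_probability=residue_probability,
            threshold=threshold,
            names=names,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (ref, partner), prob in sorted(self.residue_probability.items()):
            entity, resnum = ref
            rows.append(
                {
                    "entity": entity,
                    "residue": self.names.get(ref, ""),
                    "number": resnum,
                    "partner": partner,
                    "probability_pct": round(prob, 1),
                }
            )
        return pd.DataFrame(rows)


def _partner_group(entity: str) -> str:
    """Collapse an entity label to its binding-partner group.

    Antibody chains ``AB1-HC``/``AB1-LC`` collapse to ``AB1``; protomers and
    anything else collapse to ``channel``.
    """
    if entity.startswith("AB"):
        return entity.split("-")[0]
    return "channel"


def pair_contact_series(
    traj: Trajectory,
    topo: Topology,
    pairs: list[PairRef],
    threshold: float = 2.0,
    atom_mode: str = "all",
) -> ContactSeries:
    """Evaluate the contact indicator for each residue pair in each frame.

    A pair is in contact in a frame iff its minimum atom-atom distance is
    *strictly* below ``threshold`` (a distance exactly equal to the
    threshold is not a contact).
    """
    if traj.n_frames < 1:
        raise HexitopeError("trajectory has no frames")
    if not pairs:
        raise HexitopeError("no residue pairs given")
    slices = []
    masks = []
    names: dict[ResRef, str] = {}
    for ref_a, ref_b in pairs:
        row = []
        for entity, resnum in (ref_a, ref_b):
            res = topo.find(entity, resnum)
            row.append((topo.atom_slice(res.key), _mode_mask(res, atom_mode)))
            names[(entity, resnum)] = res.name
        slices.append((row[0][0], row[1][0]))
        masks.append((row[0][1], row[1][1]))
    indicator = np.zeros((len(pairs), traj.n_frames), dtype=bool)
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        for p, (((a0, a1), (b0, b1)), (ma, mb)) in enumerate(zip(slices, masks)):
            d = min_residue_distance(frame[a0:a1][ma], frame[b0:b1][mb])
            indicator[p, f] = d < threshold
    t0, t1 = float(traj.times[0]), float(traj.times[-1])
    return ContactSeries(
        pairs=list(pairs), indicator=indicator, threshold=threshold,
        names=names, window=(t0, t1),
    )


def enumerate_candidate_pairs(
    traj: Trajectory,
    topo: Topology,
    entity_a: str,
    entity_b: str,
    threshold: float = 2.0,
    buffer: float = 10.0,
) -> list[PairRef]:
    """All inter-entity residue pairs ever within ``threshold + buffer`` Å.

    A KD-tree prefilter per frame keeps the candidate set (and therefore the
    exact per-pair evaluation) desk-scale; pairs that never approach the
    contact threshold are excluded up front.
    """
    res_a = topo.residues_of_entity(entity_a)
    res_b = topo.residues_of_entity(entity_b)
    if not res_a or not res_b:
        raise LookupFailure(f"entity {entity_a!r} or {entity_b!r} has no residues")
    cutoff = threshold + buffer
    idx_a = np.concatenate([np.arange(*topo.atom_slice(r.key)) for r in res_a])
    idx_b = np.concatenate([np.arange(*topo.atom_slice(r.key)) for r in res_b])
    res_of_a = np.concatenate(
        [np.full(len(r.atoms), i) for i, r in enumerate(res_a)]
    )
    res_of_b = np.concatenate(
        [np.full(len(r.atoms), i) for i, r in enumerate(res_b)]
    )
    found: set[tuple[int, int]] = set()
    for frame in traj.frames:
        tree_b = cKDTree(frame[idx_b])
        neighbor_lists = cKDTree(frame[idx_a]).query_ball_tree(tree_b, r=cutoff)
        for ia, nbrs in enumerate(neighbor_lists):
            for ib in nbrs:
                found.add((int(res_of_a[ia]), int(res_of_b[ib])))
    return [
        ((entity_a, res_a[i].seq_number), (entity_b, res_b[j].seq_number))
        for i, j in sorted(found)
    ]


def interaction_probability(series: ContactSeries) -> ContactTable:
    """Turn contact indicators into pair- and residue-level percentages.

    Pair probability is ``100 × (frames in contact) / n_frames``.  Residue
    probability against a partner group is the percentage of frames in which
    any pair joining the residue to that partner is in contact.
    """
    if series.n_frames < 1:
        raise HexitopeError("contact series has no frames")
    n = series.n_frames
    pair_probability = {
        pair: 100.0 * series.indicator[i].sum() / n
        for i, pair in enumerate(series.pairs)
    }
    residue_probability: dict[tuple[ResRef, str], float] = {}
    union: dict[tuple[ResRef, str], np.ndarray] = {}
    for i, (ref_a, ref_b) in enumerate(series.pairs):
        row = series.indicator[i]
        for ref, other in ((ref_a, ref_b), (ref_b, ref_a)):
            key = (ref, _partner_group(other[0]))
            if key in union:
                union[key] = union[key] | row
            else:
                union[key] = row.copy()
    for key, rows in union.items():
        residue_probability[key] = 100.0 * rows.sum() / n
    return ContactTable(
        pair_probability=pair_probability,
        residue_probability=residue_probability,
        threshold=series.threshold,
        names=dict(series.names),
        window=series.window,
    )


def aggregate_residue_level(series: ContactSeries, entity: str) -> dict[ResRef, float]:
    """Residue-level probabilities for one entity (or entity group).

    The per-residue indicator is the frame-wise OR over every pair that
    involves a residue of ``entity``; the result maps each such residue to
    the percentage of frames in which it touches the partner entity.
    """
    group = entity.split("-")[0]
    union: dict[ResRef, np.ndarray] = {}
    for i, pair in enumerate(series.pairs):
        for ref in pair:
            if ref[0] == entity or ref[0].split("-")[0] == group:
                if ref in union:
                    union[ref] = union[ref] | series.indicator[i]
                else:
                    union[ref] = series.indicator[i].copy()
    if not union:
        raise LookupFailure(f"entity {entity!r} appears in no pair of the series")
    n = series.n_frames
    return {ref: 100.0 * rows.sum() / n for ref, rows in union.items()}


def render_table(table: ContactTable, topo: Topology | None = None) -> pd.DataFrame:
    """Residue-level table in the published layout (probabilities as integers)."""
    df = table.to_frame()
    if df.empty:
        return df
    df["probability_pct"] = df["probability_pct"].round().astype(int)
    if topo is not None:
        regions = []
        for _, row in df.iterrows():
            entity, num = row["entity"], row["number"]
            name = ""
            for rn, nums in topo.region_map.get(entity, {}).items():
                if num in nums:
                    name = rn
                    break
            regions.append(name)
        df.insert(1, "region", regions)
    return df
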