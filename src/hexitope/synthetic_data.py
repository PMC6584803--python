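"""Synthetic inputs with controlled ground truth.

Real inputs for this analysis — the equilibrated antibody-hemichannel MD
trajectory, the docking-pose ensemble and the raw patch-clamp recordings —
are not publicly deposited.  This module generates controllable stand-ins:

* a toy hexamer-plus-antibodies complex whose antibody→protomer contact sets
  are exact by construction,
* frame series in which each scheduled residue pair is in or out of contact
  per a Bernoulli or two-state Markov draw with a prescribed stationary
  contact fraction,
* labeled docking-pose sets with a known number of correctly oriented poses,
* Ohmic pre/post-antibody current traces with a prescribed residual
  conductance fraction,
* synthetic full-length family sequences carrying the bundled epitope motifs
  at alignment-mappable positions.

Toy residues are minimal (3 pseudo-atoms) so that brute-force geometric
oracles stay fast; controllability, not physical realism, is the goal.  All
generators are seed-deterministic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from hexitope.contact_analysis import PairRef
from hexitope.ephys_validation import ConductanceRecord, CurrentRecording
from hexitope.errors import ConfigurationError, HexitopeError
from hexitope.motif_scan import MotifRecord
from hexitope.pose_filter import Pose
from hexitope.struct_io import Atom, Residue, Topology, Trajectory

# channel geometry (Å)
_RING_RADIUS = 20.0
_EC1_NUMBERS = (54, 55, 56, 57, 58)
_EC2_NUMBERS = (172, 173, 174, 175, 176, 177, 178, 179)
_RESNAMES = {
    53: "CYS", 54: "ASN", 55: "THR", 56: "LEU", 57: "GLN", 58: "PRO",
    172: "TRP", 173: "PRO", 174: "CYS", 175: "PRO", 176: "ASN", 177: "THR",
    178: "VAL", 179: "ASP",
}
# antibody chain layout: residue numbers per region
_HC_REGIONS = {"CDR1": [30], "CDR2": [55], "CDR3": [104], "CONST": [10, 11]}
_LC_REGIONS = {"CDR1": [160], "CDR2": [181], "CONST": [183, 185]}
#: antibody concentration used in the validation experiments (nM); recorded
#: for provenance only, plays no computational role.
ANTIBODY_CONCENTRATION_NM = 952.0


def _pseudo_residue(chain: str, number: int, name: str, anchor: np.ndarray) -> Residue:
    """3-atom residue; the first atom (N) sits exactly at ``anchor``."""
    offsets = np.array([[0.0, 0.0, 0.0], [0.4, 0.0, 0.3], [0.0, 0.4, 0.6]])
    atoms = [
        Atom("N", "N", anchor + offsets[0]),
        Atom("CA", "C", anchor + offsets[1]),
        Atom("C", "C", anchor + offsets[2]),
    ]
    return Residue(chain_id=chain, seq_number=number, name=name, atoms=atoms)


@dataclass
class ToyComplex:
    """A generated complex plus its ground-truth contact bookkeeping."""

    topology: Topology
    contact_map: dict[str, list[str]]
    #: exact-by-construction contact pairs ((protomer, 54), (antibody chain entity, resnum))
    contact_pairs: list[PairRef]
    contact_distance: float

    @property
    def coords(self) -> np.ndarray:
        return self.topology.coords()


def build_toy_complex(
    n_protomers: int = 6,
    n_antibodies: int = 2,
    contact_map: dict[str, list[str]] | None = None,
    contact_distance: float = 1.5,
) -> ToyComplex:
    """Hexameric (or smaller) channel with antibodies placed per contact_map.

    The default map reproduces the reference binding configuration: the
    first antibody touches P1-P4, the second P4, P5, P6 and P1, so the two
    diametrically opposed protomers P1 and P4 engage both antibodies and the
    overall stoichiometry is 6 protomers : 2 antibodies.  Each designated
    contact is realized as a CDR (or light-chain) residue whose nearest atom
    sits exactly ``contact_distance`` Å above the EC1 apex (residue 54) of
    the mapped protomer; every other antibody residue is kept far (>10 Å)
    from the channel.
    """
    protomer_labels = [f"P{k + 1}" for k in range(n_protomers)]
    if contact_map is None:
        if n_antibodies == 2 and n_protomers == 6:
            contact_map = {"AB1": ["P1", "P2", "P3", "P4"], "AB2": ["P4", "P5", "P6", "P1"]}
        else:
            contact_map = {
                f"AB{a + 1}": [protomer_labels[a % n_protomers]] for a in range(n_antibodies)
            }
    for ab, protomers in contact_map.items():
        bad = [p for p in protomers if p not in protomer_labels]
        if bad:
            raise ConfigurationError(f"{ab}: contact_map references absent protomers {bad}")

    residues: list[Residue] = []
    entity_map: dict[str, str] = {}
    anchors: dict[str, np.ndarray] = {}
    chain_ids = [chr(ord("A") + k) for k in range(n_protomers)]
    for k, (chain, label) in enumerate(zip(chain_ids, protomer_labels)):
        theta = 2.0 * np.pi * k / n_protomers
        base = np.array([_RING_RADIUS * np.cos(theta), _RING_RADIUS * np.sin(theta), 0.0])
        entity_map[chain] = label
        # EC1 stacked on top (residue 54 is the apex), EC2 below
        for i, num in enumerate(_EC1_NUMBERS):
            z = 20.0 - i
            residues.append(_pseudo_residue(chain, num, _RESNAMES[num], base + [0, 0, z]))
        for i, num in enumerate(_EC2_NUMBERS):
            z = 14.0 - i
            residues.append(_pseudo_residue(chain, num, _RESNAMES[num], base + [0, 0, z]))
        anchors[label] = base + [0.0, 0.0, 20.0]  # N atom of residue 54

    region_map: dict[str, dict[str, list[int]]] = {
        label: {"EC1": list(_EC1_NUMBERS), "EC2": list(_EC2_NUMBERS)}
        for label in protomer_labels
    }

    hc_chains = ["H", "I", "J", "K"]
    lc_chains = ["L", "M", "N", "O"]
    contact_pairs: list[PairRef] = []
    for a in range(n_antibodies):
        ab = f"AB{a + 1}"
        hc, lc = hc_chains[a], lc_chains[a]
        entity_map[hc] = f"{ab}-HC"
        entity_map[lc] = f"{ab}-LC"
        region_map[f"{ab}-HC"] = {r: list(v) for r, v in _HC_REGIONS.items()}
        region_map[f"{ab}-LC"] = {r: list(v) for r, v in _LC_REGIONS.items()}
        mapped = contact_map.get(ab, [])
        centroid = (
            np.mean([anchors[p] for p in mapped], axis=0) if mapped
            else np.array([0.0, 0.0, 20.0])
        )
        # residues available to realize contacts, in preference order
        contact_residues = [(hc, "CDR1", 30), (hc, "CDR2", 55), (hc, "CDR3", 104), (lc, "CONST", 183)]
        if len(mapped) > len(contact_residues):
            raise ConfigurationError(
                f"{ab}: at most {len(contact_residues)} contacted protomers supported"
            )
        used: set[tuple[str, int]] = set()
        hc_names = {30: "THR", 55: "HIS", 104: "TRP", 10: "GLY", 11: "SER"}
        lc_names = {160: "SER", 181: "SER", 183: "ARG", 185: "THR"}
        for j, protomer in enumerate(mapped):
            chain, _, num = contact_residues[j]
            name = hc_names.get(num) if chain == hc else lc_names.get(num)
            # the apex residue's topmost atom is its C, at anchor + (0, 0.4, 0.6);
            # stacking the contact residue straight above it makes the minimum
            # inter-residue distance exactly contact_distance
            pos = anchors[protomer] + [0.0, 0.4, 0.6 + contact_distance]
            residues.append(_pseudo_residue(chain, num, name or "GLY", pos))
            used.add((chain, num))
            entity = entity_map[chain]
            contact_pairs.append(((protomer, 54), (entity, num)))
        # remaining antibody residues sit high above the ring, far from everything
        far = centroid + [4.0 * a, 0.0, 25.0]
        shift = 0
        for chain, names, regions in ((hc, hc_names, _HC_REGIONS), (lc, lc_names, _LC_REGIONS)):
            for nums in regions.values():
                for num in nums:
                    if (chain, num) in used:
                        continue
                    residues.append(
                        _pseudo_residue(chain, num, names.get(num, "GLY"),
                                        far + [2.0 * shift, 0.0, 0.0])
                    )
                    shift += 1

    topo = Topology(residues=residues, entity_map=entity_map, region_map=region_map)
    # correct the contact distance for the lateral stagger of later antibodies
    return ToyComplex(
        topology=topo,
        contact_map={ab: list(v) for ab, v in contact_map.items()},
        contact_pairs=contact_pairs,
        contact_distance=contact_distance,
    )


@dataclass
class ContactSchedule:
    """Target contact fraction per residue pair plus a temporal model."""

    fractions: dict[PairRef, float]
    model: str = "bernoulli"  # "bernoulli" | "two_state_markov"
    mean_dwell_frames: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, frac in self.fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise HexitopeError(f"{pair}: contact fraction {frac} outside [0, 1]")
        if self.model not in ("bernoulli", "two_state_markov"):
            raise HexitopeError(f"unknown temporal model {self.model!r}")
        if self.mean_dwell_frames < 1:
            raise HexitopeError("mean dwell must be >= 1 frame")


def _draw_indicator(frac: float, n: int, model: str, dwell: float,
                    rng: np.random.Generator) -> np.ndarray:
    if model == "bernoulli" or frac in (0.0, 1.0):
        return rng.random(n) < frac
    # two-state Markov chain with stationary P(contact) = frac and mean
    # contact dwell = dwell frames: leave rate a = 1/dwell, enter rate
    # b = a * frac / (1 - frac)
    a = 1.0 / dwell
    b = a * frac / (1.0 - frac)
    out = np.empty(n, dtype=bool)
    state = rng.random() < frac  # start from the stationary law
    for i in range(n):
        out[i] = state
        if state:
            state = rng.random() >= a
        else:
            state = rng.random() < b
    return out


def simulate_contact_trajectory(
    complex_: ToyComplex,
    schedule: ContactSchedule,
    n_frames: int,
    contact_distance: float = 1.5,
    apart_distance: float = 6.0,
    dt_ns: float = 0.02,
) -> tuple[Trajectory, dict[PairRef, np.ndarray]]:
    """Frame series realizing the scheduled contact fractions geometrically.

    In each frame, the second residue of each scheduled pair (the mobile,
    antibody-side residue) is placed with its nearest atom exactly
    ``contact_distance`` Å (in contact) or ``apart_distance`` Å (apart) from
    the first atom of its partner.  Returns the trajectory and the
    ground-truth indicator per pair; the same seed reproduces frames
    bit-exactly.
    """
    if n_frames < 1:
        raise HexitopeError("n_frames must be >= 1")
    topo = complex_.topology
    mobiles = [pair[1] for pair in schedule.fractions]
    if len(mobiles) != len(set(mobiles)):
        raise HexitopeError("each mobile residue may appear in only one scheduled pair")
    rng = np.random.default_rng(schedule.seed)
    base = topo.coords()
    placements = []
    for (ent_a, num_a), (ent_b, num_b) in schedule.fractions:
        res_a = topo.find(ent_a, num_a)
        res_b = topo.find(ent_b, num_b)
        # anchor on the partner's topmost atom so that placing the mobile
        # residue straight above it realizes the minimum distance exactly
        coords_a = np.array([a.coords for a in res_a.atoms])
        anchor = coords_a[np.argmax(coords_a[:, 2])]
        b0, b1 = topo.atom_slice(res_b.key)
        placements.append((anchor, b0, b1))
    truth: dict[PairRef, np.ndarray] = {}
    frames = np.repeat(base[None], n_frames, axis=0)
    local = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.4], [0.0, 0.0, 0.8]])
    for pair, (anchor, b0, b1) in zip(schedule.fractions, placements):
        ind = _draw_indicator(
            schedule.fractions[pair], n_frames, schedule.model,
            schedule.mean_dwell_frames, rng,
        )
        truth[pair] = ind
        d = np.where(ind, contact_distance, apart_distance)
        frames[:, b0:b1, :] = anchor + local[None] + np.stack(
            [np.zeros(n_frames), np.zeros(n_frames), d], axis=1
        )[:, None, :]
    times = np.arange(n_frames) * dt_ns
    return Trajectory(frames, times), truth


# ---------------------------------------------------------------------------
# docking poses


def build_pose(kind: str, pose_id: str, rng: np.random.Generator | None = None) -> Pose:
    """One antibody pose against a fixed channel.

    Kinds: ``correct`` (all CDRs near EC1 and pointing inward), ``flipped``
    (CDRs away from the channel), ``displaced`` (antibody far off axis),
    ``inverted`` (CDRs near EC1 but the antibody body sits between them and
    the channel, failing the orientation test), ``cdr3_only`` (only CDR3
    faces EC1).
    """
    complex_ = build_toy_complex(n_protomers=6, n_antibodies=1, contact_map={"AB1": []})
    topo = complex_.topology
    apex = np.array([0.0, 0.0, 20.0])  # mean EC1 apex height on the ring axis

    def place(entity: str, num: int, pos: np.ndarray) -> None:
        res = topo.find(entity, num)
        b0, b1 = topo.atom_slice(res.key)
        local = np.array([[0, 0, 0], [0.4, 0, 0.3], [0, 0.4, 0.6]])
        coords[b0:b1] = pos + local

    coords = topo.coords().copy()
    ring = [topo.find(p, 54).atoms[0].coords for p in topo.protomers]
    cdr_nums = {"CDR1": 30, "CDR2": 55, "CDR3": 104}
    if kind == "correct":
        for (region, num), anchor in zip(cdr_nums.items(), ring[:3]):
            place("AB1-HC", num, anchor + [0, 0, 5.0])
        body = apex + [0, 0, 35.0]
    elif kind == "flipped":
        for region, num in cdr_nums.items():
            place("AB1-HC", num, apex + [0, 0, 45.0])
        body = apex + [0, 0, 25.0]
    elif kind == "displaced":
        for (region, num), anchor in zip(cdr_nums.items(), ring[:3]):
            place("AB1-HC", num, anchor + [60.0, 0, 5.0])
        body = apex + [60.0, 0, 25.0]
    elif kind == "inverted":
        # CDRs within the proximity cutoff, but the rest of the antibody mass
        # sits below them, pulling the entity centroid closer to EC1
        for (region, num), anchor in zip(cdr_nums.items(), ring[:3]):
            place("AB1-HC", num, anchor + [0, 0, 7.5])
        body = apex + [0, 0, 2.0]
    elif kind == "cdr3_only":
        place("AB1-HC", cdr_nums["CDR3"], ring[0] + [0, 0, 5.0])
        for num in (cdr_nums["CDR1"], cdr_nums["CDR2"]):
            place("AB1-HC", num, apex + [0, 0, 45.0])
        body = apex + [0, 0, 35.0]
    else:
        raise ValueError(f"unknown pose kind {kind!r}")
    # non-CDR antibody residues form the body
    shift = 0
    for entity, regions in (("AB1-HC", _HC_REGIONS), ("AB1-LC", _LC_REGIONS)):
        for region, nums in regions.items():
            for num in nums:
                if entity == "AB1-HC" and num in cdr_nums.values():
                    continue
                place(entity, num, body + [2.0 * shift, 0, 0])
                shift += 1
    score = float(rng.uniform(-30, -5)) if rng is not None else None
    return Pose(pose_id=pose_id, topology=topo, coords=coords, score=score)


def generate_pose_set(
    n: int = 50,
    n_correct: int = 1,
    seed: int = 0,
) -> tuple[list[Pose], list[bool]]:
    """``n`` poses, exactly ``n_correct`` of them correctly oriented.

    Which positions in the list are correct is randomized by ``seed``;
    returns the poses and the ground-truth labels.
    """
    if not 0 <= n_correct <= n or n < 1:
        raise HexitopeError(f"invalid counts n={n}, n_correct={n_correct}")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=n_correct, replace=False)] = True
    bad_kinds = ["flipped", "displaced", "inverted"]
    poses = []
    for i in range(n):
        kind = "correct" if labels[i] else bad_kinds[int(rng.integers(len(bad_kinds)))]
        poses.append(build_pose(kind, pose_id=f"pose{i:03d}", rng=rng))
    return poses, labels.tolist()


# ---------------------------------------------------------------------------
# current traces


def simulate_current_traces(
    g_control_ns: float = 10.0,
    residual_fraction: float = 0.168,
    step_mv: float = 40.0,
    noise_sd_pa: float = 5.0,
    leak_g_ns: float = 0.0,
    seed: int = 0,
    rate_hz: float = 1000.0,
    t_pre_s: float = 0.1,
    t_step_s: float = 0.4,
) -> tuple[CurrentRecording, CurrentRecording]:
    """Ohmic pre/post-antibody traces for a depolarizing step protocol.

    The command sits at 0 mV, then steps to ``step_mv`` (+40 mV by default).
    Post-antibody channel conductance is ``residual_fraction ×`` the control
    conductance; ``leak_g_ns`` adds an antibody-insensitive leak to both
    recordings.  Gaussian current noise has SD ``noise_sd_pa``.
    """
    if g_control_ns < 0 or residual_fraction < 0:
        raise HexitopeError("conductances must be non-negative")
    rng = np.random.default_rng(seed)
    n_pre = int(round(t_pre_s * rate_hz))
    n_step = int(round(t_step_s * rate_hz))
    n = n_pre + n_step
    time = np.arange(n) / rate_hz
    voltage = np.concatenate([np.zeros(n_pre), np.full(n_step, step_mv)])

    def trace(g_channel: float, condition: str) -> CurrentRecording:
        current = (g_channel + leak_g_ns) * voltage + rng.normal(0.0, noise_sd_pa, n)
        return CurrentRecording(time=time, voltage=voltage, current=current,
                                condition=condition)

    pre = trace(g_control_ns, "control")
    post = trace(g_control_ns * residual_fraction, "antibody")
    return pre, post


def simulate_blocked_trace(
    leak_g_ns: float,
    step_mv: float = 40.0,
    noise_sd_pa: float = 5.0,
    seed: int = 0,
    **kwargs,
) -> CurrentRecording:
    """Channels fully blocked (divalent cation block): leak current only."""
    pre, _ = simulate_current_traces(
        g_control_ns=0.0, residual_fraction=0.0, step_mv=step_mv,
        noise_sd_pa=noise_sd_pa, leak_g_ns=leak_g_ns, seed=seed, **kwargs,
    )
    pre.condition = "blocked"
    return pre


# ---------------------------------------------------------------------------
# bundled reference tables and synthetic family sequences

_CHECKSUMS = {
    "family_motifs.tsv": "65ad5ce7a55aabbd262a410ae37ba0f96d8c629804b528adc1e411bd8fccc9aa",
    "channel_contacts.tsv": "f207b47bd3357173e14a89e4b8cdd3b6f58dc8636903834aed0cec0de1a55bbb",
    "antibody_contacts.tsv": "0a0032e0ad516e90d019d3c448515ff5469b557b6c7cee84ee342a86efd40736",
    "residual_conductance.tsv": "8058ae9f1ffa76ade8712cf2c84498a30fbaf72ad7e35d39101bb7fc82b53c19",
}


def _data_bytes(name: str) -> bytes:
    return resources.files("hexitope.data").joinpath(name).read_bytes()


def bundled_tables(verify: bool = True) -> dict[str, pd.DataFrame]:
    """Load the bundled reference tables, verifying their checksums.

    Keys: ``family_motifs`` (20 isoform epitope motifs),
    ``channel_contacts`` (hemichannel-residue interaction probabilities),
    ``antibody_contacts`` (antibody-residue interaction probabilities),
    ``residual_conductance`` (10 isoform residual conductances, % of
    control).
    """
    import io

    out = {}
    for name, sha in _CHECKSUMS.items():
        raw = _data_bytes(name)
        if verify and sha is not None:
            actual = hashlib.sha256(raw).hexdigest()
            if actual != sha:
                raise HexitopeError(f"bundled table {name} is corrupted (checksum mismatch)")
        out[name.removesuffix(".tsv")] = pd.read_csv(
            io.BytesIO(raw), sep="\t", comment="#"
        )
    return out


def reference_motif() -> MotifRecord:
    """The hCx26 epitope motif (EC1 NTLQP, EC2 PN)."""
    return MotifRecord(gene="GJB2", protein="hCx26", ec1_motif="NTLQP", ec2_motif="PN")


def bundled_conductance_records() -> list[ConductanceRecord]:
    df = bundled_tables()["residual_conductance"]
    return [
        ConductanceRecord(isoform=row.isoform, residual_pct=float(row.residual_pct),
                          source="bundled_reference_table")
        for row in df.itertuples()
    ]


_FAMILY_SEED = 2019  # fixture identity, not a tunable
_SCAFFOLD_LEN = 220
_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_family_sequences(seed: int = _FAMILY_SEED) -> tuple[str, dict[str, tuple[str, str]]]:
    """Synthetic full-length family sequences carrying the bundled motifs.

    Returns ``(reference_sequence, {protein: (gene, sequence)})``.  Each
    isoform shares a common scaffold (so pairwise alignment transfers the
    epitope positions reliably) with its own motif residues at EC1 54-58 and
    EC2 175-176, a sprinkling of isoform-specific substitutions away from
    the epitope, and, for a few isoforms, N-terminal extensions or an
    internal deletion to exercise the alignment-based position mapping.
    These are synthetic scaffolds, not the true connexin sequences.
    """
    rng = np.random.default_rng(seed)
    scaffold = list(rng.choice(list(_AA), size=_SCAFFOLD_LEN))
    ec1_idx = [53, 54, 55, 56, 57]   # 0-based positions 54-58
    ec2_idx = [174, 175]             # 0-based positions 175-176
    protected = set(ec1_idx) | set(ec2_idx)
    protected |= {i + d for i in (*ec1_idx, *ec2_idx) for d in (-3, -2, -1, 1, 2, 3)}
    table = bundled_tables()["family_motifs"]
    ref_seq = None
    out: dict[str, tuple[str, str]] = {}
    for row in table.itertuples():
        seq = list(scaffold)
        for i, aa in zip(ec1_idx, row.ec1_motif):
            seq[i] = aa
        for i, aa in zip(ec2_idx, row.ec2_motif):
            seq[i] = aa
        if row.protein != "hCx26":
            # isoform-specific drift away from the epitope
            n_sub = int(rng.integers(6, 12))
            sites = [i for i in rng.permutation(_SCAFFOLD_LEN) if i not in protected][:n_sub]
            for i in sites:
                seq[i] = str(rng.choice(list(_AA.replace(seq[i], ""))))
        sequence = "".join(seq)
        if row.protein == "hCx43":
            sequence = "MGD" + sequence           # N-terminal extension
        elif row.protein == "hCx45":
            sequence = sequence[:100] + sequence[102:]  # internal deletion
        elif row.protein == "hCx40":
            sequence = "MA" + sequence
        if row.protein == "hCx26":
            ref_seq = sequence
        out[row.protein] = (row.gene, sequence)
    assert ref_seq is not None
    return ref_seq, out


def write_family_fasta(path: str, seed: int = _FAMILY_SEED) -> str:
    """Write the synthetic family FASTA (headers ``>GENE|PROTEIN``).

    Returns the reference (hCx26) sequence.
    """
    ref_seq, family = make_family_sequences(seed)
    with open(path, "w") as fh:
        for protein, (gene, seq) in family.items():
            fh.write(f">{gene}|{protein} synthetic scaffold carrying the epitope motif\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return ref_seq


def default_entity_config(n_protomers: int = 6, n_antibodies: int = 2) -> dict:
    """Entity/region mapping matching :func:`build_toy_complex` output."""
    chains = {chr(ord("A") + k): f"P{k + 1}" for k in range(n_protomers)}
    hc = ["H", "I", "J", "K"]
    lc = ["L", "M", "N", "O"]
    for a in range(n_antibodies):
        chains[hc[a]] = f"AB{a + 1}-HC"
        chains[lc[a]] = f"AB{a + 1}-LC"
    regions: dict = {"protomer": {"EC1": list(_EC1_NUMBERS), "EC2": list(_EC2_NUMBERS)}}
    for a in range(n_antibodies):
        regions[f"AB{a + 1}-HC"] = {r: list(v) for r, v in _HC_REGIONS.items()}
        regions[f"AB{a + 1}-LC"] = {r: list(v) for r, v in _LC_REGIONS.items()}
    return {"chains": chains, "regions": regions}
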