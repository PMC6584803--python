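import numpy as np
import pytest

from hexitope import (
    Topology,
    assign_entities,
    read_structure,
    read_trajectory,
    write_structure,
)
from hexitope.errors import ConfigurationError, StructureError, StructureParseError
from hexitope.struct_io import Atom, Residue
from hexitope import synthetic_data as synth

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.675   6.719  -4.163  1.00  0.00           C
END
"""

INSERTION_PDB = """\
ATOM      1  CA  GLY A  10       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A  10A      1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A  10B      2.000   0.000   0.000  1.00  0.00           C
END
"""


def test_minimal_pdb_parses_to_one_residue(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    topo, frame = read_structure(str(p))
    assert len(topo.residues) == 1
    assert len(topo.residues[0].atoms) == 3
    assert frame.shape == (3, 3)
    np.testing.assert_allclose(frame[0], [11.104, 6.134, -6.504])


def test_insertion_codes_yield_distinct_residues(tmp_path):
    p = tmp_path / "icode.pdb"
    p.write_text(INSERTION_PDB)
    topo, _ = read_structure(str(p))
    keys = [r.key for r in topo.residues]
    assert keys == [("A", 10, ""), ("A", 10, "A"), ("A", 10, "B")]


def test_malformed_pdb_names_line(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text(MINIMAL_PDB.replace("11.104", "xx.xxx"))
    with pytest.raises(StructureParseError, match="line 1"):
        read_structure(str(p))


def test_round_trip_preserves_keys_counts_coords(tmp_path, toy_complex):
    topo = toy_complex.topology
    p = tmp_path / "complex.pdb"
    write_structure(str(p), topo)
    topo2, frame2 = read_structure(str(p))
    assert [r.key for r in topo2.residues] == [r.key for r in topo.residues]
    assert [len(r.atoms) for r in topo2.residues] == [len(r.atoms) for r in topo.residues]
    np.testing.assert_allclose(frame2, topo.coords(), atol=5e-4)


def test_toy_complex_has_ten_chains(toy_complex):
    assert len(toy_complex.topology.chains) == 10  # 6 protomers + 2x(HC+LC)


def test_trajectory_windowing(tmp_path, toy_complex):
    topo = toy_complex.topology
    frames = np.repeat(topo.coords()[None], 15, axis=0)
    p = tmp_path / "traj.pdb"
    write_structure(str(p), topo, frames=frames)
    # 15 frames at 0, 10, ..., 140 ns; retain the last 10 ns of a 150 ns run
    traj = read_trajectory(str(p), topo, stride_ns=10.0, window=(140.0, 150.0))
    assert traj.n_frames == 1 and traj.times[0] == 140.0
    full = read_trajectory(str(p), topo, stride_ns=10.0)
    assert full.n_frames == 15
    # idempotence: re-applying the same window changes nothing
    once = full.window(40.0, 90.0)
    twice = once.window(40.0, 90.0)
    np.testing.assert_array_equal(once.frames, twice.frames)
    with pytest.raises(StructureError):
        full.window(500.0, 600.0)


def test_trajectory_atom_count_mismatch(tmp_path, toy_complex):
    topo = toy_complex.topology
    p = tmp_path / "small.pdb"
    small = Topology(residues=topo.residues[:3])
    write_structure(str(p), small)
    with pytest.raises(StructureError, match="atoms"):
        read_trajectory(str(p), topo)


def test_xyz_frame_series(tmp_path):
    p = tmp_path / "frames.xyz"
    p.write_text(
        "2\nframe 0\nC 0.0 0.0 0.0\nC 1.0 0.0 0.0\n"
        "2\nframe 1\nC 0.0 0.0 1.0\nC 1.0 0.0 1.0\n"
    )
    topo, frame = read_structure(str(p), format="xyz")
    assert topo.n_atoms == 2
    traj = read_trajectory(str(p), topo, format="xyz", stride_ns=0.5)
    assert traj.n_frames == 2
    np.testing.assert_allclose(traj.times, [0.0, 0.5])


def test_assign_entities_config_echo(toy_complex):
    topo = toy_complex.topology
    cfg = synth.default_entity_config()
    annotated = assign_entities(Topology(residues=topo.residues), cfg)
    assert annotated.protomers == ["P1", "P2", "P3", "P4", "P5", "P6"]
    assert sorted(annotated.antibodies()) == ["AB1", "AB2"]
    ec1 = annotated.residues_in_region("P3", "EC1")
    assert [r.seq_number for r in ec1] == [54, 55, 56, 57, 58]


def test_assign_entities_missing_chain_errors(toy_complex):
    cfg = synth.default_entity_config()
    del cfg["chains"]["A"]
    with pytest.raises(ConfigurationError, match="without entity label"):
        assign_entities(Topology(residues=toy_complex.topology.residues), cfg)


def test_assign_entities_duplicate_protomer_errors(toy_complex):
    cfg = synth.default_entity_config()
    cfg["chains"]["B"] = "P1"
    with pytest.raises(ConfigurationError, match="duplicate"):
        assign_entities(Topology(residues=toy_complex.topology.residues), cfg)


def test_assign_entities_region_outside_topology_errors(toy_complex):
    cfg = synth.default_entity_config()
    cfg["regions"]["protomer"]["EC1"] = [54, 55, 999]
    with pytest.raises(ConfigurationError, match="999"):
        assign_entities(Topology(residues=toy_complex.topology.residues), cfg)


def test_atom_and_residue_invariants():
    with pytest.raises(StructureError):
        Atom("CA", "C", [0.0, np.nan, 0.0])
    with pytest.raises(StructureError):
        Atom("CA", "", [0.0, 0.0, 0.0])
    with pytest.raises(StructureError):
        Residue(chain_id="A", seq_number=1, name="GLY", atoms=[])
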