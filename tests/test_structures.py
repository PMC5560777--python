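"""Structure model, I/O round trips, selection, pockets, superposition."""

import numpy as np
import pytest
from conftest import grid_refine_min_rmsd, random_rigid_transform

from pipgate.errors import (
    GeometryError,
    MissingResidueError,
    PocketAssignmentError,
    SelectionQueryError,
    StructureParseError,
    TrajectoryError,
)
from pipgate.structures import (
    AtomRecord,
    ResidueRoleMap,
    StructureModel,
    Trajectory,
    assign_pockets,
    pocket_ca_rmsd,
    read_structure,
    read_trajectory,
    select_atoms,
    superpose_kabsch,
    write_structure,
    write_trajectory,
)
from pipgate.synthetic import TrajectoryScript, generate_channel_trajectory


ONE_ATOM_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)


def test_read_one_atom_pdb(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(ONE_ATOM_PDB)
    model = read_structure(p)
    assert model.n_atoms == 1
    atom = model.atoms[0]
    assert atom.atom_name == "CA"
    assert atom.residue_name == "ALA"
    assert atom.residue_number == 1
    assert atom.chain_id == "A"
    np.testing.assert_allclose(atom.position, [1.0, 2.0, 3.0])


@pytest.mark.parametrize(
    "content,match",
    [
        ("ATOM      1  CA  ALA A   1       1.0\n", "line 1"),
        ("REMARK ok\nATOM      1  CA  ALA A   1       a.b     2.000   3.000\n", "line 2"),
        ("REMARK nothing else\n", "no ATOM"),
        ("", "empty"),
    ],
)
def test_malformed_pdb_errors(tmp_path, content, match):
    p = tmp_path / "bad.pdb"
    p.write_text(content)
    with pytest.raises(StructureParseError, match=match):
        read_structure(p)


def test_pdb_round_trip_identity(all_bonded_toy, tmp_path):
    model, _, _ = all_bonded_toy
    path = tmp_path / "toy.pdb"
    write_structure(model, path)
    back = read_structure(path)
    assert back.n_atoms == model.n_atoms
    for a, b in zip(model.atoms, back.atoms):
        assert (a.chain_id, a.residue_number, a.atom_name) == (
            b.chain_id, b.residue_number, b.atom_name
        )
    # PDB stores Å with 3 decimals
    assert np.abs(back.positions - model.positions).max() <= 1e-3


def test_pdb_gro_cross_format(all_bonded_toy, tmp_path):
    model, _, _ = all_bonded_toy
    write_structure(model, tmp_path / "toy.pdb")
    write_structure(model, tmp_path / "toy.gro")
    from_pdb = read_structure(tmp_path / "toy.pdb")
    from_gro = read_structure(tmp_path / "toy.gro")
    # combined format precision: PDB 5e-4 Å + GRO 5e-3 Å (3-decimal nm)
    assert np.abs(from_pdb.positions - from_gro.positions).max() <= 6e-3


def test_multimodel_pdb_three_identical_models(all_bonded_toy, tmp_path):
    model, _, _ = all_bonded_toy
    frames = np.repeat(model.positions[None, :, :], 3, axis=0)
    traj = Trajectory(topology=model, frames=frames, times=np.arange(3.0))
    path = tmp_path / "frames.pdb"
    write_trajectory(traj, path, format="PDB")
    back = read_trajectory(model, path)
    assert back.n_frames == 3
    assert np.abs(back.frames - model.positions[None]).max() <= 1e-3
    np.testing.assert_array_equal(back.times, [0.0, 1.0, 2.0])


def test_dcd_round_trip_matches_generator(all_bonded_toy, tmp_path):
    model, traj, _ = all_bonded_toy
    path = tmp_path / "traj.dcd"
    write_trajectory(traj, path)
    back = read_trajectory(model, path)
    assert back.n_frames == traj.n_frames
    assert np.abs(back.frames - traj.frames).max() <= 1e-4
    np.testing.assert_allclose(back.times, traj.times, atol=1e-5)


def test_empty_trajectory_file_errors(all_bonded_toy, tmp_path):
    model, _, _ = all_bonded_toy
    path = tmp_path / "empty.dcd"
    path.write_bytes(b"")
    with pytest.raises(TrajectoryError, match="empty"):
        read_trajectory(model, path)


def test_atom_count_mismatch_errors(all_bonded_toy, tmp_path):
    model, traj, _ = all_bonded_toy
    path = tmp_path / "traj.dcd"
    write_trajectory(traj, path)
    small = StructureModel(model.atoms[:10], title="subset")
    with pytest.raises(TrajectoryError):
        read_trajectory(small, path)


def test_trajectory_invariants(all_bonded_toy):
    model, _, _ = all_bonded_toy
    frames = np.repeat(model.positions[None], 2, axis=0)
    with pytest.raises(TrajectoryError, match="strictly increasing"):
        Trajectory(topology=model, frames=frames, times=np.array([1.0, 1.0]))
    with pytest.raises(TrajectoryError, match="atom count"):
        Trajectory(topology=model, frames=frames[:, :5], times=np.arange(2.0))


# ---------------------------------------------------------------------------
# Selection


def test_select_single_ca(all_bonded_toy):
    model, _, _ = all_bonded_toy
    idx = select_atoms(model, "chain A and resid 192 and name CA")
    assert len(idx) == 1
    assert model.names[idx[0]] == "CA"
    assert model.resids[idx[0]] == 192


def test_select_residue_range_counts_by_construction(all_bonded_toy):
    model, _, _ = all_bonded_toy
    idx = select_atoms(model, "resid 88-92")
    expected = int(np.sum((model.resids >= 88) & (model.resids <= 92)))
    assert len(idx) == expected
    assert expected >= 4 * 5  # at least one atom per residue per chain
    # deterministic file order
    assert idx == sorted(idx)


def test_select_empty_and_invalid(all_bonded_toy):
    model, _, _ = all_bonded_toy
    assert select_atoms(model, "chain Z") == []
    with pytest.raises(SelectionQueryError):
        select_atoms(model, "resid and and name")


# ---------------------------------------------------------------------------
# Pocket assignment


def test_assign_pockets_bijection(all_bonded_toy, roles):
    _, traj, _ = all_bonded_toy
    pockets = assign_pockets(traj, roles)
    assert sorted(pockets.lipids) == [("P", 1), ("P", 2), ("P", 3), ("P", 4)]
    assert pockets.chains == (("A",), ("B",), ("C",), ("D",))


def test_assign_pockets_stable_under_jitter(roles):
    base = TrajectoryScript(n_frames=1, seed=21)
    jittered = TrajectoryScript(n_frames=1, seed=21, jitter_sigma=0.5)
    _, traj0, _ = generate_channel_trajectory(base)
    _, trajj, _ = generate_channel_trajectory(jittered)
    assert assign_pockets(traj0, roles).lipids == assign_pockets(trajj, roles).lipids


def test_assign_pockets_lipid_order_invariance(all_bonded_toy, roles):
    model, traj, _ = all_bonded_toy
    pockets = assign_pockets(traj, roles)
    # permute all lipid atoms to the front of the atom list
    lipid = np.flatnonzero(model.resnames == "PIP")
    rest = np.flatnonzero(model.resnames != "PIP")
    perm = np.concatenate([lipid[::-1], rest])
    atoms = [
        AtomRecord(i, a.atom_name, a.residue_name, a.residue_number, a.chain_id,
                   a.element, a.position)
        for i, a in enumerate(model.atoms[j] for j in perm)
    ]
    permuted = StructureModel(atoms, title="permuted")
    ptraj = Trajectory(
        topology=permuted, frames=traj.frames[:, perm, :], times=traj.times
    )
    assert assign_pockets(ptraj, roles).lipids == pockets.lipids


def test_assign_pockets_three_lipids_errors(all_bonded_toy, roles):
    model, traj, _ = all_bonded_toy
    keep = ~((model.resnames == "PIP") & (model.resids == 4))
    atoms = [
        AtomRecord(i, a.atom_name, a.residue_name, a.residue_number, a.chain_id,
                   a.element, a.position)
        for i, a in enumerate(model.atoms[j] for j in np.flatnonzero(keep))
    ]
    reduced = StructureModel(atoms)
    rtraj = Trajectory(
        topology=reduced, frames=traj.frames[:, keep, :], times=traj.times
    )
    with pytest.raises(PocketAssignmentError, match="exactly 4"):
        assign_pockets(rtraj, roles)


# ---------------------------------------------------------------------------
# Kabsch superposition


def test_kabsch_rigid_copy_zero_rmsd():
    rng = np.random.default_rng(31)
    pts = rng.normal(size=(12, 3)) * 5
    rot, trans = random_rigid_transform(rng)
    moved = pts @ rot.T + trans
    r, t, rmsd = superpose_kabsch(pts, moved)
    assert rmsd <= 1e-6
    assert np.isclose(np.linalg.det(r), 1.0, atol=1e-9)
    np.testing.assert_allclose(pts @ r.T + t, moved, atol=1e-9)


def test_kabsch_identity_on_self():
    pts = np.random.default_rng(32).normal(size=(8, 3))
    r, t, rmsd = superpose_kabsch(pts, pts)
    np.testing.assert_allclose(r, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(t, 0.0, atol=1e-9)
    assert rmsd <= 1e-9


def test_kabsch_degenerate_inputs():
    with pytest.raises(GeometryError):
        superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
    with pytest.raises(GeometryError, match="collinear"):
        superpose_kabsch(line, line)


def test_kabsch_agrees_with_rotation_grid_oracle():
    rng = np.random.default_rng(33)
    for _ in range(20):
        mob = rng.normal(size=(4, 3)) * 4
        ref = rng.normal(size=(4, 3)) * 4
        _, _, rmsd = superpose_kabsch(mob, ref)
        oracle = grid_refine_min_rmsd(mob, ref)
        assert abs(rmsd - oracle) <= 1e-4


def test_kabsch_rmsd_invariant_under_joint_rigid_transform():
    rng = np.random.default_rng(34)
    mob = rng.normal(size=(10, 3)) * 3
    ref = rng.normal(size=(10, 3)) * 3
    _, _, rmsd0 = superpose_kabsch(mob, ref)
    rot, trans = random_rigid_transform(rng)
    _, _, rmsd1 = superpose_kabsch(mob @ rot.T + trans, ref @ rot.T + trans)
    assert abs(rmsd0 - rmsd1) <= 1e-6


# ---------------------------------------------------------------------------
# Pocket Cα RMSD


def test_pocket_ca_rmsd_self_is_zero(all_bonded_toy, roles):
    model, _, _ = all_bonded_toy
    assert pocket_ca_rmsd(model, model, roles) <= 1e-9


def test_pocket_ca_rmsd_single_displacement_matches_oracle(all_bonded_toy, roles):
    model, _, _ = all_bonded_toy
    d = 2.0
    # displace one pocket Cα by d
    idx = model.index_of("A", 192, "CA")
    moved = [
        AtomRecord(i, a.atom_name, a.residue_name, a.residue_number, a.chain_id,
                   a.element,
                   a.position + (np.array([d, 0, 0]) if i == idx else 0.0))
        for i, a in enumerate(model.atoms)
    ]
    model_b = StructureModel(moved)
    rmsd = pocket_ca_rmsd(model, model_b, roles)
    n = len(roles.pocket_residues) * 4
    # superposition can only reduce the naive d/sqrt(n) figure
    assert rmsd <= d / np.sqrt(n) + 1e-9
    assert rmsd >= 0.5 * d / np.sqrt(n)
    # cross-check against the independent rotation-grid minimizer
    ca_a, ca_b = [], []
    for chain in "ABCD":
        for resid in roles.pocket_residues:
            ca_a.append(model.positions[model.index_of(chain, resid, "CA")])
            ca_b.append(model_b.positions[model_b.index_of(chain, resid, "CA")])
    oracle = grid_refine_min_rmsd(np.asarray(ca_a), np.asarray(ca_b))
    assert abs(rmsd - oracle) <= 1e-4


def test_pocket_ca_rmsd_missing_residues_listed(all_bonded_toy, roles):
    model, _, _ = all_bonded_toy
    keep = ~((model.chains == "B") & (model.resids == 195) & (model.names == "CA"))
    atoms = [
        AtomRecord(i, a.atom_name, a.residue_name, a.residue_number, a.chain_id,
                   a.element, a.position)
        for i, a in enumerate(model.atoms[j] for j in np.flatnonzero(keep))
    ]
    reduced = StructureModel(atoms)
    with pytest.raises(MissingResidueError, match="B:195"):
        pocket_ca_rmsd(model, reduced, roles)
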