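"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (all-pairs loops, rotation-grid
searches) so that they stay independent of the implementation paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pipgate.hbonds import HBondCriteria
from pipgate.structures import ResidueRoleMap
from pipgate.synthetic import (
    BondInterval,
    TrajectoryScript,
    WaterScript,
    all_bonded_schedule,
    generate_channel_trajectory,
)


# ---------------------------------------------------------------------------
# Oracles


def brute_force_hbonds(coords, donors, acceptors, criteria, donor_hydrogens=None):
    """O(N^2) all-pairs hydrogen-bond reference detector."""
    triples = []
    cut = criteria.distance_cutoff if criteria.use_hydrogens else criteria.heavy_atom_cutoff
    for d in donors:
        for a in acceptors:
            dist = np.linalg.norm(coords[d] - coords[a])
            if dist > cut:
                continue
            if not criteria.use_hydrogens:
                triples.append((d, -1, a))
                continue
            for h in donor_hydrogens[d]:
                hd = coords[d] - coords[h]
                ha = coords[a] - coords[h]
                cos = float(hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                angle = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                if angle >= criteria.angle_cutoff:
                    triples.append((d, int(h), a))
    return triples


def random_hbond_instance(rng, n_donors=50, n_acceptors=50, box=20.0):
    """Random donors (each with one hydrogen) and acceptors in a cubic box."""
    donor_pos = rng.uniform(0, box, size=(n_donors, 3))
    h_pos = donor_pos + rng.normal(0, 0.6, size=(n_donors, 3))
    acc_pos = rng.uniform(0, box, size=(n_acceptors, 3))
    coords = np.vstack([donor_pos, h_pos, acc_pos])
    donors = list(range(n_donors))
    hydrogens = {d: [n_donors + d] for d in donors}
    acceptors = list(range(2 * n_donors, 2 * n_donors + n_acceptors))
    return coords, donors, acceptors, hydrogens


def grid_refine_min_rmsd(mobile, reference, grid_deg=30.0):
    """Minimum RMSD over proper rotations by grid search plus local refinement.

    Centres both point sets, scans Euler angles on a grid, then polishes the
    best cell with Nelder-Mead.  Independent of the Kabsch closed form.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(euler):
        rot = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
        return float(np.sqrt(np.mean(np.sum((mob @ rot.T - ref) ** 2, axis=1))))

    angles = np.arange(0.0, 360.0, grid_deg)
    betas = np.arange(0.0, 180.1, grid_deg)
    best, best_val = None, np.inf
    for a in angles:
        for b in betas:
            for c in angles:
                val = rmsd_of((a, b, c))
                if val < best_val:
                    best, best_val = (a, b, c), val
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 4000})
    return min(best_val, float(res.fun))


def random_rigid_transform(rng):
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-30, 30, size=3)
    return rot, trans


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def roles():
    return ResidueRoleMap()


@pytest.fixture(scope="session")
def criteria():
    return HBondCriteria()


@pytest.fixture(scope="session")
def all_bonded_toy():
    """20-frame toy with every 5'-PO4 pair bonded in every pocket."""
    script = TrajectoryScript(
        n_frames=20,
        bond_schedule=all_bonded_schedule(20),
        gate_schedule=((0, 10.0),),
        seed=11,
    )
    return generate_channel_trajectory(script)


@pytest.fixture(scope="session")
def switching_toy():
    """200-frame toy: 0'K-5'PO4 bonded in [0, 100), broken in [100, 200)."""
    schedule = tuple(
        BondInterval("0'K-5'PO4", p, 0, 100, True) for p in range(4)
    )
    script = TrajectoryScript(n_frames=200, bond_schedule=schedule, seed=12)
    return generate_channel_trajectory(script)


@pytest.fixture(scope="session")
def watery_toy():
    """60-frame toy with 500 uniformly placed pore waters."""
    script = TrajectoryScript(
        n_frames=60,
        bond_schedule=all_bonded_schedule(60),
        water=WaterScript(mode="uniform", n_waters=500),
        seed=13,
    )
    return generate_channel_trajectory(script)
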