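"""HBC gate geometry, pore-axis hydration profiles, and dewetting detection.

The helix-bundle-crossing (HBC) gate diameter is the mean of the two
diagonal distances between the side-chain centres of mass of the four -2'F
residues.  Pore hydration is measured as water-oxygen counts in 1 Å axial
bins inside a cylinder around the conduction axis, with the selectivity
filter at z = 0 and z decreasing toward the cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import GeometryError, MissingResidueError
from .structures import ResidueRoleMap, StructureModel, Trajectory

#: Phenylalanine side-chain heavy atoms used for the gate centre of mass.
F_SIDECHAIN_ATOMS = ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")

#: Backbone atoms defining the selectivity-filter reference point.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

DEFAULT_WATER_RESNAMES = ("TIP3", "HOH", "SOL", "WAT")


@dataclass
class GateDiameterSeries:
    """Per-frame diagonal distances across the HBC gate (Å)."""

    times: np.ndarray
    d_ac: np.ndarray
    d_bd: np.ndarray
    diagonal_chains: tuple[tuple[str, str], tuple[str, str]]

    @property
    def diameter(self) -> np.ndarray:
        return 0.5 * (self.d_ac + self.d_bd)


@dataclass
class HydrationProfile:
    """Mean water-oxygen counts per axial bin per time window."""

    z_edges: np.ndarray  # (n_bins + 1,), Å, descending toward cytoplasm stored ascending
    window_edges: np.ndarray  # (n_windows + 1,), ns
    counts: np.ndarray  # (n_windows, n_bins), mean count per frame
    dewetted: np.ndarray | None = None  # bool, same shape as counts

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


def _sidechain_coms(
    model: StructureModel, frame: np.ndarray, roles: ResidueRoleMap
) -> tuple[list[str], np.ndarray]:
    """Mass-weighted -2'F side-chain centres of mass, one per chain."""
    resid = roles.minus2_f
    chains = sorted({c for c in model.chains[model.resids == resid]})
    if len(chains) != 4:
        raise MissingResidueError(
            f"expected -2'F residue {resid} in 4 subunits, found {len(chains)}"
        )
    coms = []
    for chain in chains:
        mask = (
            (model.chains == chain)
            & (model.resids == resid)
            & np.isin(model.names, list(F_SIDECHAIN_ATOMS))
        )
        idx = np.flatnonzero(mask)
        present = set(model.names[idx])
        missing = set(F_SIDECHAIN_ATOMS) - present
        if missing:
            raise MissingResidueError(
                f"-2'F {chain}:{resid} missing side-chain atoms {sorted(missing)}"
            )
        m = model.masses[idx]
        coms.append((frame[idx] * m[:, None]).sum(axis=0) / m.sum())
    return chains, np.asarray(coms)


def hbc_diameter(traj: Trajectory, roles: ResidueRoleMap) -> GateDiameterSeries:
    """Gate diameter series from the four -2'F side-chain centres of mass.

    The two diagonal pairings are fixed at frame 0 as the two largest
    COM-COM distances (which partition the four subunits); keeping them
    fixed prevents pair swapping when the gate distorts.
    """
    model = traj.topology
    chains, coms0 = _sidechain_coms(model, traj.frames[0], roles)
    pairs = sorted(
        combinations(range(4), 2),
        key=lambda p: -np.linalg.norm(coms0[p[0]] - coms0[p[1]]),
    )
    i, j = pairs[0]
    k, l = sorted(set(range(4)) - {i, j})
    d_ac = np.empty(traj.n_frames)
    d_bd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, coms = _sidechain_coms(model, traj.frames[f], roles)
        d_ac[f] = np.linalg.norm(coms[i] - coms[j])
        d_bd[f] = np.linalg.norm(coms[k] - coms[l])
    return GateDiameterSeries(
        times=traj.times,
        d_ac=d_ac,
        d_bd=d_bd,
        diagonal_chains=((chains[i], chains[j]), (chains[k], chains[l])),
    )


def pore_axis_frame(
    frame: np.ndarray, model: StructureModel, roles: ResidueRoleMap
) -> tuple[np.ndarray, np.ndarray]:
    """Conduction-axis reference for one frame.

    Returns ``(origin, axis)``: the origin is the mass-weighted centre of
    the selectivity-filter backbone atoms over all four chains; the unit
    axis points from the origin toward the -2'F gate centre, i.e.
    cytoplasmic.  Axial coordinates are measured as
    ``z = -(r - origin) . axis`` so that the filter sits at 0 Å and the
    pore interior is at negative z.
    """
    filt_mask = np.isin(model.resids, list(roles.selectivity_filter_residues)) & np.isin(
        model.names, list(BACKBONE_ATOMS)
    )
    # restrict to protein chains that actually carry the filter residues
    idx = np.flatnonzero(filt_mask)
    if idx.size == 0:
        raise MissingResidueError(
            f"no selectivity-filter residues {roles.selectivity_filter_residues} found"
        )
    chains_with = {model.chains[i] for i in idx}
    if len(chains_with) != 4:
        raise MissingResidueError(
            f"selectivity filter present in {len(chains_with)} chains, expected 4"
        )
    m = model.masses[idx]
    origin = (frame[idx] * m[:, None]).sum(axis=0) / m.sum()
    _, coms = _sidechain_coms(model, frame, roles)
    gate_center = coms.mean(axis=0)
    vec = gate_center - origin
    norm = np.linalg.norm(vec)
    if norm < 1e-6:
        raise GeometryError("degenerate pore axis: filter and gate centres coincide")
    return origin, vec / norm


def axial_coordinates(
    frame: np.ndarray, positions_idx: np.ndarray, origin: np.ndarray, axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(z, radial) coordinates of selected atoms in the pore frame."""
    rel = frame[positions_idx] - origin
    proj = rel @ axis
    z = -proj
    radial = np.linalg.norm(rel - proj[:, None] * axis[None, :], axis=1)
    return z, radial


def water_oxygen_indices(
    model: StructureModel, water_resnames: Sequence[str] = DEFAULT_WATER_RESNAMES
) -> np.ndarray:
    mask = np.isin(model.resnames, list(water_resnames)) & (
        (model.elements == "O") | np.isin(model.names, ["O", "OW", "OH2"])
    )
    return np.flatnonzero(mask)


def water_density_profile(
    traj: Trajectory,
    roles: ResidueRoleMap,
    cylinder_radius: float = 8.0,
    bin_width: float = 1.0,
    window_ns: float = 10.0,
    z_range: tuple[float, float] = (-25.0, 0.0),
    water_resnames: Sequence[str] = DEFAULT_WATER_RESNAMES,
) -> HydrationProfile:
    """Water-oxygen counts binned along the pore axis, averaged per window."""
    import warnings as _warnings

    model = traj.topology
    widx = water_oxygen_indices(model, water_resnames)
    z_lo, z_hi = z_range
    n_bins = int(round((z_hi - z_lo) / bin_width))
    z_edges = z_lo + bin_width * np.arange(n_bins + 1)
    t0, t1 = traj.times[0], traj.times[-1]
    n_windows = max(int(np.ceil((t1 - t0) / window_ns)), 1)
    window_edges = t0 + window_ns * np.arange(n_windows + 1)
    sums = np.zeros((n_windows, n_bins))
    nframes_in = np.zeros(n_windows)
    if widx.size == 0:
        _warnings.warn("no water residues found; hydration profile is all zero")
        return HydrationProfile(z_edges=z_edges, window_edges=window_edges, counts=sums)
    for f in range(traj.n_frames):
        origin, axis = pore_axis_frame(traj.frames[f], model, roles)
        z, radial = axial_coordinates(traj.frames[f], widx, origin, axis)
        inside = (radial <= cylinder_radius) & (z >= z_lo) & (z <= z_hi)
        hist, _ = np.histogram(z[inside], bins=z_edges)
        w = min(int((traj.times[f] - t0) // window_ns), n_windows - 1)
        sums[w] += hist
        nframes_in[w] += 1
    counts = np.where(nframes_in[:, None] > 0, sums / np.maximum(nframes_in, 1)[:, None], 0.0)
    return HydrationProfile(z_edges=z_edges, window_edges=window_edges, counts=counts)


def detect_dewetting(
    profile: HydrationProfile, threshold_fraction: float = 0.2
) -> np.ndarray:
    """Flag (window, bin) cells whose mean count falls below a fraction of bulk.

    The bulk reference is the median of the nonzero bins of the first time
    window.  The 0.2 default is a package choice for marking qualitatively
    dry segments; a threshold of 0 flags nothing.
    """
    if profile.counts.size == 0:
        raise GeometryError("empty hydration profile")
    first = profile.counts[0]
    nonzero = first[first > 0]
    if nonzero.size == 0:
        raise GeometryError(
            "all-zero first window: no bulk reference for dewetting detection"
        )
    bulk = float(np.median(nonzero))
    flags = profile.counts < threshold_fraction * bulk
    profile.dewetted = flags
    return flags
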