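"""Geometric hydrogen-bond detection and per-pair time series.

A hydrogen bond is declared when the donor-acceptor heavy-atom distance is
within the cutoff (default 3.5 Å) and the D-H···A angle at the hydrogen is
at least the angle cutoff (default 150°).  Topologies without explicit
hydrogens can use a stricter heavy-atom-only distance rule (default 3.2 Å).
These are widely used geometric defaults and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import MissingResidueError, PipgateError, TraceError
from .structures import (
    PIP2_PHOSPHATE_GROUPS,
    PhosphateGroupSpec,
    PocketAssignment,
    ResidueRoleMap,
    StructureModel,
    Trajectory,
)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria for hydrogen-bond detection."""

    distance_cutoff: float = 3.5  # Å, donor-acceptor
    angle_cutoff: float = 150.0  # degrees, D-H···A at the hydrogen
    heavy_atom_cutoff: float = 3.2  # Å, used when use_hydrogens is False
    use_hydrogens: bool = True

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.heavy_atom_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if not (0.0 < self.angle_cutoff <= 180.0):
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class PairSpec:
    """A donor/acceptor pair to monitor, e.g. 0'K side chain to the 5'-PO4.

    ``acceptor`` is either the label of a lipid phosphate group ("P1'",
    "P4'", "P5'") or a ``(role, atom_names)`` tuple naming protein acceptor
    atoms (e.g. ("9'E", ("OE1", "OE2"))).  ``pocket_scope`` is "all" or a
    single pocket index.
    """

    label: str
    donor_role: str
    donor_atom_names: tuple[str, ...]
    acceptor: str | tuple[str, tuple[str, ...]]
    include_backbone_amide: bool = False
    pocket_scope: int | str = "all"

    def __post_init__(self):
        if not self.donor_atom_names:
            raise ValueError(f"pair {self.label}: donor atom names empty")
        if isinstance(self.acceptor, tuple) and not self.acceptor[1]:
            raise ValueError(f"pair {self.label}: acceptor atom names empty")


#: The pairs the analyses monitor by default.  The 6' donor atom covers both
#: the WT lysine (NZ) and the 6'Y tyrosine (OH).
DEFAULT_PAIRS: dict[str, PairSpec] = {
    "0'K-5'PO4": PairSpec("0'K-5'PO4", "0'K", ("NZ",), "P5'"),
    "5'K-5'PO4": PairSpec("5'K-5'PO4", "5'K", ("NZ",), "P5'"),
    "6'-5'PO4": PairSpec("6'-5'PO4", "6'", ("NZ", "OH"), "P5'"),
    "6'-9'E": PairSpec("6'-9'E", "6'", ("NZ", "OH"), ("9'E", ("OE1", "OE2"))),
    "K64-5'PO4": PairSpec("K64-5'PO4", "K64", ("NZ",), "P5'"),
    "K90-5'PO4": PairSpec("K90-5'PO4", "K90", ("NZ",), "P5'"),
    "R92-1'PO4": PairSpec(
        "R92-1'PO4", "R92", ("NH1", "NH2", "NE"), "P1'", include_backbone_amide=True
    ),
}


@dataclass
class HBondTimeSeries:
    """Per-frame hydrogen-bond counts for one pair in one pocket."""

    pair_label: str
    pocket: int
    times: np.ndarray  # ns
    counts: np.ndarray  # int, >= 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != self.times.shape:
            raise ValueError("counts and times must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def find_donor_hydrogens(
    model: StructureModel,
    donors: Sequence[int],
    coords: np.ndarray | None = None,
    max_dh: float = 1.25,
) -> dict[int, list[int]]:
    """Map donor heavy atoms to their covalently attached hydrogens.

    A hydrogen belongs to a donor when it is in the same residue and within
    ``max_dh`` Å of it (default 1.25 Å, comfortably above covalent D-H
    lengths and below any nonbonded contact).
    """
    if coords is None:
        coords = model.positions
    h_mask = (model.elements == "H") | np.char.startswith(
        model.names.astype(str), "H"
    )
    out: dict[int, list[int]] = {}
    for d in donors:
        same_res = (
            (model.chains == model.chains[d])
            & (model.resids == model.resids[d])
            & h_mask
        )
        cand = np.flatnonzero(same_res)
        if cand.size:
            dist = np.linalg.norm(coords[cand] - coords[d], axis=1)
            out[int(d)] = [int(i) for i in cand[dist <= max_dh]]
        else:
            out[int(d)] = []
    return out


def detect_hbonds_frame(
    coords: np.ndarray,
    donors: Sequence[int],
    acceptors: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
    donor_hydrogens: Mapping[int, Sequence[int]] | None = None,
) -> list[tuple[int, int, int]]:
    """Detect hydrogen bonds in one frame.

    Returns (donor, hydrogen, acceptor) index triples; the hydrogen index is
    -1 under the heavy-atom-only rule.  Each donor-acceptor pair is reported
    at most once per hydrogen.
    """
    coords = np.asarray(coords, dtype=float)
    donors = [int(d) for d in donors]
    acceptors = [int(a) for a in acceptors]
    if set(donors) & set(acceptors):
        raise PipgateError("donor and acceptor lists must be disjoint")
    if not donors or not acceptors:
        return []
    if criteria.use_hydrogens:
        if donor_hydrogens is None:
            raise PipgateError("donor_hydrogens required when use_hydrogens is on")
        for d in donors:
            if not donor_hydrogens.get(d):
                raise MissingResidueError(
                    f"donor atom {d} has no attached hydrogen "
                    "(required when use_hydrogens is on)"
                )
        cutoff = criteria.distance_cutoff
    else:
        cutoff = criteria.heavy_atom_cutoff

    acc_pos = coords[acceptors]
    tree = cKDTree(acc_pos)
    triples: list[tuple[int, int, int]] = []
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff))
    for d in donors:
        near = tree.query_ball_point(coords[d], cutoff)
        for j in sorted(near):
            a = acceptors[j]
            if not criteria.use_hydrogens:
                triples.append((d, -1, a))
                continue
            for h in donor_hydrogens[d]:
                hd = coords[d] - coords[h]
                ha = coords[a] - coords[h]
                nh = np.linalg.norm(hd) * np.linalg.norm(ha)
                if nh == 0:
                    continue
                # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
                if float(hd @ ha) / nh <= cos_cut:
                    triples.append((d, int(h), a))
    return triples


def _resolve_pair_atoms(
    model: StructureModel,
    pair: PairSpec,
    roles: ResidueRoleMap,
    pockets: PocketAssignment,
    pocket: int,
    phosphate_groups: Mapping[str, PhosphateGroupSpec] = PIP2_PHOSPHATE_GROUPS,
) -> tuple[list[int], list[int]]:
    """Resolve donor and acceptor atom indices for one pocket."""
    chains = pockets.chains[pocket]
    donor_resid = roles.residue_for(pair.donor_role)
    donor_names = list(pair.donor_atom_names)
    if pair.include_backbone_amide:
        donor_names.append("N")
    donor_idx = [
        int(i)
        for i in np.flatnonzero(
            np.isin(model.chains, chains)
            & (model.resids == donor_resid)
            & np.isin(model.names, donor_names)
        )
    ]
    if not donor_idx:
        raise MissingResidueError(
            f"pair {pair.label}: no donor atoms {donor_names} in residue "
            f"{donor_resid} of chains {chains}"
        )
    if isinstance(pair.acceptor, str):
        group = phosphate_groups[pair.acceptor]
        lip_chain, lip_resid = pockets.lipids[pocket]
        acc_idx = [
            int(i)
            for i in np.flatnonzero(
                (model.chains == lip_chain)
                & (model.resids == lip_resid)
                & np.isin(model.names, list(group.acceptor_oxygens))
            )
        ]
        if not acc_idx:
            raise MissingResidueError(
                f"pair {pair.label}: lipid {lip_chain}:{lip_resid} has no "
                f"{group.label} acceptor oxygens"
            )
    else:
        acc_role, acc_names = pair.acceptor
        acc_resid = roles.residue_for(acc_role)
        acc_idx = [
            int(i)
            for i in np.flatnonzero(
                np.isin(model.chains, chains)
                & (model.resids == acc_resid)
                & np.isin(model.names, list(acc_names))
            )
        ]
        if not acc_idx:
            raise MissingResidueError(
                f"pair {pair.label}: no acceptor atoms {acc_names} in residue "
                f"{acc_resid} of chains {chains}"
            )
    return donor_idx, acc_idx


def pair_timeseries(
    traj: Trajectory,
    pair: PairSpec,
    roles: ResidueRoleMap,
    pockets: PocketAssignment,
    criteria: HBondCriteria = HBondCriteria(),
    phosphate_groups: Mapping[str, PhosphateGroupSpec] = PIP2_PHOSPHATE_GROUPS,
) -> list[HBondTimeSeries]:
    """Per-frame hydrogen-bond counts for one pair, one series per pocket.

    Raw counts are stored unsmoothed; any running-mean smoothing belongs to
    the presentation layer.
    """
    model = traj.topology
    scope = range(4) if pair.pocket_scope == "all" else [int(pair.pocket_scope)]
    resolved = {
        p: _resolve_pair_atoms(model, pair, roles, pockets, p, phosphate_groups)
        for p in scope
    }
    hyd = None
    if criteria.use_hydrogens:
        all_donors = sorted({d for don, _ in resolved.values() for d in don})
        hyd = find_donor_hydrogens(model, all_donors, traj.frames[0])
    out = []
    for p in scope:
        donors, acceptors = resolved[p]
        counts = np.empty(traj.n_frames, dtype=int)
        for f in range(traj.n_frames):
            triples = detect_hbonds_frame(
                traj.frames[f], donors, acceptors, criteria, donor_hydrogens=hyd
            )
            counts[f] = len(triples)
        out.append(
            HBondTimeSeries(
                pair_label=pair.label, pocket=p, times=traj.times, counts=counts
            )
        )
    return out


def hbond_probability(series: HBondTimeSeries, max_bonds: int = 2) -> float:
    """Occupancy probability: mean over frames of min(count, cap)/cap."""
    if max_bonds < 1:
        raise ValueError("max_bonds must be >= 1")
    if series.counts.size == 0:
        raise TraceError("empty hydrogen-bond series")
    return float(np.mean(np.minimum(series.counts, max_bonds)) / max_bonds)


def hbond_probability_summary(
    series_list: Sequence[HBondTimeSeries], max_bonds: int = 2
) -> tuple[float, float, int]:
    """Mean ± SEM of the occupancy probability over (pocket × simulation) units."""
    probs = np.array([hbond_probability(s, max_bonds) for s in series_list])
    n = probs.size
    if n == 0:
        raise TraceError("no series to summarise")
    sem = float(probs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(probs.mean()), sem, n
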