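"""Seeded generators with known ground truth for every downstream metric.

``generate_channel_trajectory`` builds a C4-symmetric toy tetramer (chains
A-D) with pseudo-residues for every functional role, four PIP2 pseudo-lipids
with P1'/P4'/P5' phosphate groups, a scripted HBC gate, and scripted pore
waters.  Hydrogen-bond schedules place donor and acceptor at 2.8 Å with a
collinear hydrogen (bonded) or at 6.0 Å (broken), so the geometric detector
sees exactly the scripted counts.  Nothing here is a physical simulation:
no forces, no thermodynamics, no membrane.

``generate_ephys_trace`` and ``generate_flux_trace`` emit piecewise
exponential current and fluorescence traces with protocol events and
Gaussian noise.  All randomness comes from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .assays import CurrentTrace, FluxTrace, ProtocolEvent
from .errors import PipgateError, TraceError
from .structures import AtomRecord, ResidueRoleMap, StructureModel, Trajectory

KNOWN_PAIRS = (
    "0'K-5'PO4",
    "5'K-5'PO4",
    "6'-5'PO4",
    "6'-9'E",
    "K64-5'PO4",
    "K90-5'PO4",
    "R92-1'PO4",
)


@dataclass(frozen=True)
class BondInterval:
    """One scripted on/off segment for a pair in a pocket (frame interval)."""

    pair: str
    pocket: int
    start: int
    stop: int  # exclusive
    bonded: bool


@dataclass(frozen=True)
class WaterScript:
    """Scripted pore waters.

    mode "uniform": ``n_waters`` oxygens resampled each frame, z uniform
    over [-25, 0] minus any active dry bands, radius uniform in a disk
    inside the analysis cylinder.  mode "per_bin": exactly
    ``counts_per_bin[i]`` oxygens in each 1 Å bin every frame (dry bands are
    not allowed, since the water count must stay constant).
    """

    mode: str = "uniform"
    n_waters: int = 0
    counts_per_bin: tuple[int, ...] | None = None
    z_range: tuple[float, float] = (-25.0, 0.0)
    bin_width: float = 1.0
    radius: float = 7.5
    dry_bands: tuple[tuple[float, float, int, int], ...] = ()  # (z0, z1, f0, f1)

    def __post_init__(self):
        if self.mode not in ("uniform", "per_bin"):
            raise PipgateError(f"unknown water mode {self.mode!r}")
        if self.mode == "per_bin" and self.dry_bands:
            raise PipgateError("dry bands require the uniform water mode")
        if self.mode == "per_bin" and self.counts_per_bin is None:
            raise PipgateError("per_bin mode needs counts_per_bin")

    @property
    def n_bins(self) -> int:
        return int(round((self.z_range[1] - self.z_range[0]) / self.bin_width))

    @property
    def total_waters(self) -> int:
        if self.mode == "uniform":
            return self.n_waters
        return int(sum(self.counts_per_bin))


@dataclass(frozen=True)
class TrajectoryScript:
    """Full script for a toy trajectory."""

    n_frames: int = 100
    frame_dt_ns: float = 1.0
    bond_schedule: tuple[BondInterval, ...] = ()
    gate_schedule: tuple[tuple[int, float], ...] = ((0, 10.0),)  # (frame, Å)
    water: WaterScript | None = None
    jitter_sigma: float = 0.0
    six_prime: str = "K"  # "K" (WT lysine) or "Y" (tyrosine mutant)
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise PipgateError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise PipgateError("jitter sigma must be >= 0")
        if self.six_prime not in ("K", "Y"):
            raise PipgateError("six_prime must be 'K' or 'Y'")
        for iv in self.bond_schedule:
            if iv.pair not in KNOWN_PAIRS:
                raise PipgateError(f"schedule references unknown pair {iv.pair!r}")
            if not 0 <= iv.pocket <= 3:
                raise PipgateError(f"schedule references unknown pocket {iv.pocket}")
            if not (0 <= iv.start < iv.stop <= self.n_frames):
                raise PipgateError(
                    f"interval [{iv.start}, {iv.stop}) outside [0, {self.n_frames})"
                )

    def bond_state(self, pair: str, pocket: int, frame: int) -> bool:
        state = False
        for iv in self.bond_schedule:
            if iv.pair == pair and iv.pocket == pocket and iv.start <= frame < iv.stop:
                state = iv.bonded
        return state

    def gate_diameter(self, frame: int) -> float:
        frames = np.array([f for f, _ in self.gate_schedule], dtype=float)
        diams = np.array([d for _, d in self.gate_schedule], dtype=float)
        return float(np.interp(frame, frames, diams))


def all_bonded_schedule(
    n_frames: int,
    pairs: Sequence[str] = ("0'K-5'PO4", "5'K-5'PO4", "6'-5'PO4"),
    pockets: Sequence[int] = (0, 1, 2, 3),
) -> tuple[BondInterval, ...]:
    """Convenience: the given pairs bonded in every pocket for all frames."""
    return tuple(
        BondInterval(pair, pocket, 0, n_frames, True)
        for pair in pairs
        for pocket in pockets
    )


# ---------------------------------------------------------------------------
# Toy tetramer geometry

_CHAINS = ("A", "B", "C", "D")
_POCKET_RADIUS = 18.0
_POCKET_Z = -10.0
_GATE_Z = -20.0
_FILTER_BASE_RADIUS = 3.0
_O_FROM_P = 2.5
_BONDED_DA = 2.8
_BROKEN_DA = 6.0
_DH = 1.0

_F_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def _chain_frame(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.deg2rad(90.0 * k)
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    v = np.array([-np.sin(theta), np.cos(theta), 0.0])
    w = np.array([0.0, 0.0, 1.0])
    return u, v, w


class _ToyBuilder:
    """Accumulates atoms and remembers the index handles of dynamic ones."""

    def __init__(self, roles: ResidueRoleMap, six_prime: str):
        self.roles = roles
        self.six_prime = six_prime
        self.records: list[AtomRecord] = []
        # (pair, pocket) -> dict with donor idx, hydrogen idxs, bonded/broken pos
        self.donors: dict[tuple[str, int], dict] = {}
        # pocket -> dict for the 9'E acceptor that follows the 6' donor
        self.nine_e: dict[int, dict] = {}
        self.gate_ring: dict[int, list[int]] = {}
        self.water_idx: list[int] = []
        self.protein_idx: list[int] = []

    def add(self, name, resname, resid, chain, element, pos, is_water=False) -> int:
        idx = len(self.records)
        self.records.append(
            AtomRecord(idx, name, resname, int(resid), chain, element, np.asarray(pos, float))
        )
        if is_water:
            self.water_idx.append(idx)
        else:
            self.protein_idx.append(idx)
        return idx


def _tripod(v: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a1 = v
    a2 = -0.5 * v + (np.sqrt(3) / 2) * w
    a3 = -0.5 * v - (np.sqrt(3) / 2) * w
    return a1, a2, a3


def _norm(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x)


def _build_static(roles: ResidueRoleMap, six_prime: str) -> _ToyBuilder:
    b = _ToyBuilder(roles, six_prime)
    for k, chain in enumerate(_CHAINS):
        u, v, w = _chain_frame(k)
        pocket_center = _POCKET_RADIUS * u + np.array([0, 0, _POCKET_Z])
        a1, a2, a3 = _tripod(v, w)

        # selectivity filter: backbone atoms exactly at z = 0 so that the
        # mass-weighted origin is the lab origin by C4 symmetry
        for j, resid in enumerate(roles.selectivity_filter_residues):
            base = (_FILTER_BASE_RADIUS + 0.6 * j) * u
            for m, name in enumerate(("N", "CA", "C", "O")):
                elem = "N" if name == "N" else ("O" if name == "O" else "C")
                b.add(name, "GLY", resid, chain, elem, base + 0.5 * m * v)

        # generic pocket-residue Cα scaffold (all pocket residues)
        for resid in roles.pocket_residues:
            off = resid - min(roles.pocket_residues)
            pos = pocket_center + 5.0 * u + 0.9 * (off % 12) * w + 2.2 * (off // 12) * v
            b.add("CA", "ALA", resid, chain, "C", pos)

        # -2'F gate ring (positions overwritten per frame; placeholders here)
        ring = []
        ring.append(b.add("CB", "PHE", roles.minus2_f, chain, "C", pocket_center + 30 * w))
        for m, name in enumerate(_F_RING_ATOMS):
            ang = np.deg2rad(60.0 * m)
            pos = pocket_center + 30 * w + 1.4 * (np.cos(ang) * v + np.sin(ang) * w)
            ring.append(b.add(name, "PHE", roles.minus2_f, chain, "C", pos))
        b.gate_ring[k] = ring

        # PIP2 pseudo-lipid for pocket k, chains P with resid k+1
        p5 = pocket_center
        p4 = pocket_center + 6.0 * w
        p1 = pocket_center - 6.0 * w
        b.add("C1", "PIP", k + 1, "P", "C", pocket_center + 1.5 * u)
        for p_name, p_pos, o_names in (
            ("P5", p5, ("O5A", "O5B", "O5C")),
            ("P4", p4, ("O4A", "O4B", "O4C")),
            ("P1", p1, ("O1A", "O1B", "O1C")),
        ):
            b.add(p_name, "PIP", k + 1, "P", "P", p_pos)
            for o_name, a in zip(o_names, (a1, a2, a3)):
                b.add(o_name, "PIP", k + 1, "P", "O", p_pos + _O_FROM_P * a)

        o5a = p5 + _O_FROM_P * a1
        o5b = p5 + _O_FROM_P * a2
        o5c = p5 + _O_FROM_P * a3
        o1a = p1 + _O_FROM_P * a1

        def add_donor(pair, resid, resname, donor_name, h_names, acceptor, direction,
                      extra_h_dir=None):
            bonded = acceptor + _BONDED_DA * direction
            broken = acceptor + _BROKEN_DA * direction
            didx = b.add(donor_name, resname, resid, chain,
                         "O" if donor_name == "OH" else "N", bonded)
            h_idx = []
            # first hydrogen points back toward the acceptor (collinear)
            h_idx.append(b.add(h_names[0], resname, resid, chain, "H",
                               bonded - _DH * direction))
            h_offsets = [-_DH * direction]
            if extra_h_dir is not None and len(h_names) > 1:
                h_idx.append(b.add(h_names[1], resname, resid, chain, "H",
                                   bonded + _DH * extra_h_dir))
                h_offsets.append(_DH * extra_h_dir)
            b.donors[(pair, k)] = {
                "donor": didx,
                "hydrogens": h_idx,
                "h_offsets": h_offsets,
                "bonded": bonded,
                "broken": broken,
            }

        n1 = _norm(a1 + u)
        n2 = _norm(a2 + u)
        add_donor("0'K-5'PO4", roles.zero_k, "LYS", "NZ", ("HZ1",), o5a, a1)
        add_donor("5'K-5'PO4", roles.five_k, "LYS", "NZ", ("HZ1",), o5b, a2)
        if six_prime == "K":
            add_donor("6'-5'PO4", roles.six, "LYS", "NZ", ("HZ1", "HZ2"), o5c, a3,
                      extra_h_dir=u)
        else:
            add_donor("6'-5'PO4", roles.six, "TYR", "OH", ("HH",), o5c, a3)
        add_donor("K64-5'PO4", roles.k64, "LYS", "NZ", ("HZ1",), o5a, n1)
        add_donor("K90-5'PO4", roles.k90, "LYS", "NZ", ("HZ1",), o5b, n2)
        add_donor("R92-1'PO4", roles.r92, "ARG", "NH1", ("HH11",), o1a, a1)
        # R92 backbone amide, far from any acceptor in the toy
        nb = b.add("N", "ARG", roles.r92, chain, "N", pocket_center + 10.0 * u)
        b.add("H", "ARG", roles.r92, chain, "H",
              pocket_center + 10.0 * u + _DH * w)

        # 9'E side-chain oxygens follow the 6' donor: OE1 sits along +u from
        # the donor at H-bond (2.8 Å) or broken (6.0 Å) distance
        oe1 = b.add("OE1", "GLU", roles.nine_e, chain, "O",
                    pocket_center + 12.0 * u)
        oe2 = b.add("OE2", "GLU", roles.nine_e, chain, "O",
                    pocket_center + 12.0 * u + 4.5 * w)
        b.nine_e[k] = {"oe1": oe1, "oe2": oe2, "dir": u}
    return b


def generate_channel_trajectory(
    script: TrajectoryScript, roles: ResidueRoleMap | None = None
) -> tuple[StructureModel, Trajectory, dict]:
    """Build the toy tetramer and its scripted trajectory plus ground truth.

    Returns ``(topology, trajectory, truth)`` where ``truth`` holds, per
    frame, the scripted bond counts per (pair, pocket), the association
    score, the gate diameter, and the expected water count per axial bin.
    """
    roles = roles or ResidueRoleMap()
    rng = np.random.default_rng(script.seed)
    b = _build_static(roles, script.six_prime)

    n_waters = script.water.total_waters if script.water else 0
    water_first = len(b.records)
    for i in range(n_waters):
        b.add("O", "HOH", 1000 + i, "W", "O", np.zeros(3), is_water=True)

    base = np.array([r.position for r in b.records])
    n_frames = script.n_frames
    frames = np.empty((n_frames, base.shape[0], 3))
    times = script.frame_dt_ns * np.arange(n_frames)

    bond_truth = {
        (pair, pocket): np.zeros(n_frames, dtype=int)
        for pair in KNOWN_PAIRS
        for pocket in range(4)
    }
    gate_truth = np.empty(n_frames)
    ws = script.water
    water_expected = (
        np.zeros((n_frames, ws.n_bins)) if ws is not None else None
    )

    for f in range(n_frames):
        pos = base.copy()
        # donors and 6'-9'E acceptors
        for k in range(4):
            for pair in KNOWN_PAIRS:
                if pair == "6'-9'E":
                    continue
                info = b.donors[(pair, k)]
                bonded = script.bond_state(pair, k, f)
                target = info["bonded"] if bonded else info["broken"]
                pos[info["donor"]] = target
                for h, off in zip(info["hydrogens"], info["h_offsets"]):
                    pos[h] = target + off
                bond_truth[(pair, k)][f] = int(bonded)
            # 9'E follows the 6' donor
            six_info = b.donors[("6'-5'PO4", k)]
            donor_pos = pos[six_info["donor"]]
            e_info = b.nine_e[k]
            e_bonded = script.bond_state("6'-9'E", k, f)
            dist = _BONDED_DA if e_bonded else _BROKEN_DA
            pos[e_info["oe1"]] = donor_pos + dist * e_info["dir"]
            pos[e_info["oe2"]] = pos[e_info["oe1"]] + 4.5 * np.array([0, 0, 1.0])
            # a tyrosine 6' has a single hydrogen aimed at the phosphate, so
            # the 6'-9'E geometry can never satisfy the angular criterion
            bond_truth[("6'-9'E", k)][f] = int(e_bonded and script.six_prime == "K")

        # gate ring: centres of mass on the scripted diagonals
        diameter = script.gate_diameter(f)
        gate_truth[f] = diameter
        for k in range(4):
            u, v, w = _chain_frame(k)
            com = 0.5 * diameter * u + np.array([0, 0, _GATE_Z])
            ring = b.gate_ring[k]
            pos[ring[0]] = com  # CB at the centre
            for m, idx in enumerate(ring[1:]):
                ang = np.deg2rad(60.0 * m)
                pos[idx] = com + 1.4 * (np.cos(ang) * v + np.sin(ang) * w)

        if script.jitter_sigma > 0:
            jitter = rng.normal(0.0, script.jitter_sigma, size=(len(b.protein_idx), 3))
            pos[b.protein_idx] += jitter

        # waters
        if ws is not None and n_waters > 0:
            z_lo, z_hi = ws.z_range
            edges = z_lo + ws.bin_width * np.arange(ws.n_bins + 1)
            if ws.mode == "per_bin":
                zs = []
                for bin_i, count in enumerate(ws.counts_per_bin):
                    zs.append(edges[bin_i] + ws.bin_width * rng.random(count))
                    water_expected[f, bin_i] = count
                z = np.concatenate(zs) if zs else np.empty(0)
            else:
                active = [
                    (z0, z1)
                    for z0, z1, f0, f1 in ws.dry_bands
                    if f0 <= f < f1
                ]
                allowed = _complement_intervals((z_lo, z_hi), active)
                lengths = np.array([hi - lo for lo, hi in allowed])
                total_len = lengths.sum()
                seg = rng.choice(len(allowed), size=n_waters, p=lengths / total_len)
                zlo_arr = np.array([allowed[s][0] for s in seg])
                zlen = np.array([allowed[s][1] - allowed[s][0] for s in seg])
                z = zlo_arr + zlen * rng.random(n_waters)
                density = ws.n_waters / total_len
                for bin_i in range(ws.n_bins):
                    blo, bhi = edges[bin_i], edges[bin_i + 1]
                    overlap = sum(
                        max(0.0, min(bhi, hi) - max(blo, lo)) for lo, hi in allowed
                    )
                    water_expected[f, bin_i] = density * overlap
            r = ws.radius * np.sqrt(rng.random(z.size))
            phi = 2 * np.pi * rng.random(z.size)
            pos[water_first:water_first + z.size, 0] = r * np.cos(phi)
            pos[water_first:water_first + z.size, 1] = r * np.sin(phi)
            pos[water_first:water_first + z.size, 2] = z

        frames[f] = pos

    # topology carries frame 0 coordinates
    records0 = [replace(r, position=frames[0, i]) for i, r in enumerate(b.records)]
    model = StructureModel(records0, title=f"toy GIRK2 tetramer (6'{script.six_prime})")
    traj = Trajectory(topology=model, frames=frames, times=times)

    assoc = np.zeros(n_frames, dtype=int)
    for pocket in range(4):
        assoc += (
            bond_truth[("0'K-5'PO4", pocket)]
            + bond_truth[("5'K-5'PO4", pocket)]
            + bond_truth[("6'-5'PO4", pocket)]
            - bond_truth[("6'-9'E", pocket)]
        )
    truth = {
        "bond_counts": bond_truth,
        "association_score": assoc,
        "gate_diameter": gate_truth,
        "water_expected_per_bin": water_expected,
        "times_ns": times,
    }
    return model, traj, truth


def _complement_intervals(
    domain: tuple[float, float], cut: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    lo, hi = domain
    points = [lo]
    for c0, c1 in sorted(cut):
        points += [max(c0, lo), min(c1, hi)]
    points.append(hi)
    out = []
    for i in range(0, len(points), 2):
        if points[i + 1] > points[i]:
            out.append((points[i], points[i + 1]))
    return out


# ---------------------------------------------------------------------------
# Electrophysiology traces


@dataclass(frozen=True)
class EphysSimConfig:
    """Whole-cell current simulation settings.

    Defaults follow the study conditions: a large inward Ba2+-sensitive
    basal current, depletion/recovery time constants on the tens-of-seconds
    scale, and graded fractional inhibition saturating near 0.7 for long
    Vsp activation times.
    """

    protocol: str = "inhibition"  # "inhibition", "recovery" or "drug"
    sample_rate_hz: float = 10.0
    ba_sensitive_pA: float = -500.0
    leak_pA: float = -20.0
    tau_depletion_s: float = 24.9
    tau_recovery_s: float = 35.8
    fractional_inhibition: Mapping[float, float] = field(
        default_factory=lambda: {50.0: 0.15, 100.0: 0.4, 300.0: 0.7, 500.0: 0.7}
    )
    drug_percent_change: Mapping[str, float] = field(
        default_factory=lambda: {"MPD": -89.5}
    )
    noise_sigma_pA: float = 5.0
    capacitance_pF: float = 10.0
    holding_mV: float = -120.0
    basal_s: float = 100.0
    post_pulse_s: float = 250.0
    depletion_window_s: float = 100.0
    recovery_window_s: float = 180.0
    drug_s: float = 80.0
    ba_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.tau_depletion_s <= 0 or self.tau_recovery_s <= 0:
            raise TraceError("time constants must be positive")
        if self.sample_rate_hz <= 0:
            raise TraceError("sample rate must be positive")
        for name in ("basal_s", "post_pulse_s", "depletion_window_s",
                     "recovery_window_s", "drug_s", "ba_s"):
            if getattr(self, name) <= 0:
                raise TraceError(f"epoch length {name} must be positive "
                                 "(epochs may not overlap or vanish)")


def generate_ephys_trace(
    config: EphysSimConfig,
    pulse_duration_ms: float | None = None,
    drug: str | None = None,
) -> tuple[CurrentTrace, dict]:
    """Simulate one whole-cell trace for the configured protocol.

    Returns ``(trace, truth)``; truth carries the programmed Ba2+-sensitive
    current, taus, fractional inhibition, and fit-segment boundaries.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sample_rate_hz
    i_basal = config.leak_pA + config.ba_sensitive_pA
    i_ba = config.leak_pA
    events: list[ProtocolEvent] = []
    truth: dict = {
        "ba_sensitive_pA": config.ba_sensitive_pA,
        "capacitance_pF": config.capacitance_pF,
    }

    if config.protocol == "inhibition":
        if pulse_duration_ms is None:
            pulse_duration_ms = 300.0
        frac = config.fractional_inhibition[pulse_duration_ms]
        t_pulse = config.basal_s
        t_ba = t_pulse + config.post_pulse_s
        t_end = t_ba + config.ba_s
        times = np.arange(0.0, t_end, dt)
        current = np.full_like(times, i_basal)
        i_inhib = config.leak_pA + (1.0 - frac) * config.ba_sensitive_pA
        seg = times >= t_pulse
        current[seg] = i_inhib + (i_basal - i_inhib) * np.exp(
            -(times[seg] - t_pulse) / config.tau_depletion_s
        )
        current[times >= t_ba] = i_ba
        events = [
            ProtocolEvent(t_pulse, "vsp_pulse", duration_ms=pulse_duration_ms),
            ProtocolEvent(t_ba, "Ba_on"),
        ]
        truth.update(
            fractional_inhibition=frac,
            pulse_duration_ms=pulse_duration_ms,
            tau_depletion_s=config.tau_depletion_s,
        )
    elif config.protocol == "recovery":
        if pulse_duration_ms is None:
            pulse_duration_ms = 100.0
        frac = config.fractional_inhibition[pulse_duration_ms]
        t_pulse = config.basal_s
        t_rec = t_pulse + config.depletion_window_s
        t_end = t_rec + config.recovery_window_s
        times = np.arange(0.0, t_end, dt)
        current = np.full_like(times, i_basal)
        i_inhib = config.leak_pA + (1.0 - frac) * config.ba_sensitive_pA
        dep = times >= t_pulse
        current[dep] = i_inhib + (i_basal - i_inhib) * np.exp(
            -(times[dep] - t_pulse) / config.tau_depletion_s
        )
        i_at_rec = i_inhib + (i_basal - i_inhib) * np.exp(
            -config.depletion_window_s / config.tau_depletion_s
        )
        rec = times >= t_rec
        current[rec] = i_basal + (i_at_rec - i_basal) * np.exp(
            -(times[rec] - t_rec) / config.tau_recovery_s
        )
        events = [ProtocolEvent(t_pulse, "vsp_pulse", duration_ms=pulse_duration_ms)]
        truth.update(
            tau_depletion_s=config.tau_depletion_s,
            tau_recovery_s=config.tau_recovery_s,
            depletion_segment=(t_pulse, t_rec),
            recovery_segment=(t_rec, t_end),
            fractional_inhibition=frac,
        )
    elif config.protocol == "drug":
        if drug is None:
            drug = next(iter(config.drug_percent_change))
        pct = config.drug_percent_change[drug]
        t_drug = config.basal_s
        t_off = t_drug + config.drug_s
        t_ba = t_off + 40.0
        t_end = t_ba + config.ba_s
        times = np.arange(0.0, t_end, dt)
        current = np.full_like(times, i_basal)
        i_drug = i_basal + (pct / 100.0) * config.ba_sensitive_pA
        current[(times >= t_drug) & (times < t_off)] = i_drug
        current[times >= t_ba] = i_ba
        events = [
            ProtocolEvent(t_drug, "drug_on", name=drug),
            ProtocolEvent(t_off, "drug_off", name=drug),
            ProtocolEvent(t_ba, "Ba_on"),
        ]
        truth.update(drug=drug, percent_change=pct)
    else:
        raise TraceError(f"unknown protocol {config.protocol!r}")

    current = current + rng.normal(0.0, config.noise_sigma_pA, size=times.size)
    trace = CurrentTrace(
        times=times,
        current=current,
        holding_mV=config.holding_mV,
        capacitance_pF=config.capacitance_pF,
        events=events,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Flux traces


@dataclass(frozen=True)
class FluxSimConfig:
    """ACMA quench simulation settings.

    The quench amplitude is solved so that the noiseless trace has exactly
    the configured true relative flux under the 900-s normalisation.
    """

    true_relative_flux: float = 0.5
    condition: str = "lipid"  # "lipid" or "vehicle"
    lipid_name: str = "PI(4,5)P2"
    t_cccp_s: float = 60.0
    t_lipid_s: float = 120.0
    val_delay_s: float = 920.0  # valinomycin this long after lipid addition
    post_val_s: float = 300.0
    dt_s: float = 2.0
    f0: float = 100.0
    cccp_level: float = 0.97  # plateau after the CCCP dip, relative to basal
    floor: float = 0.2  # valinomycin floor, relative to basal
    quench_tau_s: float = 180.0
    cccp_tau_s: float = 5.0
    val_tau_s: float = 20.0
    noise_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.true_relative_flux <= 1.0:
            raise TraceError("true relative flux must be in [0, 1]")
        if not self.t_cccp_s < self.t_lipid_s:
            raise TraceError("events out of order: CCCP must precede lipid")
        if self.val_delay_s < 900.0:
            raise TraceError("valinomycin must come >= 900 s after lipid")


def generate_flux_trace(config: FluxSimConfig) -> tuple[FluxTrace, dict]:
    """Simulate one ACMA fluorescence trace; truth holds the programmed flux."""
    rng = np.random.default_rng(config.seed)
    t_lip = config.t_lipid_s
    t_val = t_lip + config.val_delay_s
    t_end = t_val + config.post_val_s
    times = np.arange(0.0, t_end, config.dt_s)
    b = config.cccp_level
    g1 = 1.0 - np.exp(-900.0 / config.quench_tau_s)
    g2 = 1.0 - np.exp(-config.val_delay_s / config.quench_tau_s)
    rf = config.true_relative_flux
    amp = rf * (b - config.floor) / (g1 + rf * g2)

    fhat = np.ones_like(times)
    cccp = times >= config.t_cccp_s
    fhat[cccp] = b + (1.0 - b) * np.exp(
        -(times[cccp] - config.t_cccp_s) / config.cccp_tau_s
    )
    quench = times >= t_lip
    fhat[quench] = b - amp * (1.0 - np.exp(-(times[quench] - t_lip) / config.quench_tau_s))
    pre_val_level = b - amp * (1.0 - np.exp(-config.val_delay_s / config.quench_tau_s))
    post = times > t_val
    fhat[post] = config.floor + (pre_val_level - config.floor) * np.exp(
        -(times[post] - t_val) / config.val_tau_s
    )
    f = config.f0 * fhat
    f = f * (1.0 + rng.normal(0.0, config.noise_fraction, size=times.size))
    events = [
        ProtocolEvent(config.t_cccp_s, "CCCP"),
        ProtocolEvent(
            t_lip,
            "lipid" if config.condition == "lipid" else "vehicle",
            name=config.lipid_name if config.condition == "lipid" else None,
        ),
        ProtocolEvent(t_val, "valinomycin"),
    ]
    trace = FluxTrace(times=times, fluorescence=f, events=events)
    truth = {"relative_flux": rf, "condition": config.condition}
    return trace, truth
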