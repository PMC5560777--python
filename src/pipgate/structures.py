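"""Structure/trajectory data model, I/O, selection, pockets, superposition.

Coordinates are Å throughout; trajectory times are ns.  Residue numbers are
the 1-based author numbers found in the files; atom indices are 0-based
positions in file order.  File reading and writing and the selection
language are delegated to MDAnalysis behind this module's interface.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    GeometryError,
    MissingResidueError,
    PocketAssignmentError,
    SelectionQueryError,
    StructureParseError,
    TrajectoryError,
)

_ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098, "NA": 22.990, "CL": 35.45, "MG": 24.305,
    "F": 18.998, "ZN": 65.38, "FE": 55.845, "CA": 40.078,
}

_TWO_LETTER = {"CL", "NA", "MG", "ZN", "FE", "BR"}


def guess_element(atom_name: str) -> str:
    """Guess an element symbol from a PDB-style atom name.

    Digits and primes are stripped; two-letter ion names are recognised
    only when the whole stripped name matches (so "CA" in a protein residue
    stays carbon at the caller's discretion — here "CA"/"CB"/... map to C).
    """
    stripped = re.sub(r"[0-9']", "", atom_name).strip().upper()
    if not stripped:
        return "X"
    if stripped in _TWO_LETTER:
        return stripped.capitalize()
    return stripped[0]


def _mass_of(element: str) -> float:
    return _ATOMIC_MASSES.get(element.upper(), 12.011)


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position (Å)."""

    atom_id: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class StructureModel:
    """An ordered collection of atoms with array views and a cached Universe.

    The triple (chain_id, residue_number, atom_name) is unique; atom order
    is file order and stable across reads.
    """

    def __init__(self, atoms: Sequence[AtomRecord], title: str = ""):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("StructureModel must contain at least one atom")
        keys = {(a.chain_id, a.residue_number, a.atom_name) for a in atoms}
        if len(keys) != len(atoms):
            raise ValueError("(chain_id, residue_number, atom_name) must be unique")
        self.atoms = tuple(atoms)
        self.title = title
        self.names = np.array([a.atom_name for a in atoms])
        self.resnames = np.array([a.residue_name for a in atoms])
        self.resids = np.array([a.residue_number for a in atoms], dtype=int)
        self.chains = np.array([a.chain_id for a in atoms])
        self.elements = np.array([a.element for a in atoms])
        self.positions = np.array([a.position for a in atoms], dtype=float)
        self.masses = np.array([_mass_of(e) for e in self.elements])
        self._universe = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        mask = (
            (self.chains == chain_id)
            & (self.resids == residue_number)
            & (self.names == atom_name)
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise MissingResidueError(
                f"no atom {atom_name} in residue {chain_id}:{residue_number}"
            )
        return int(idx[0])

    def to_universe(self):
        """Build (and cache) an MDAnalysis Universe mirroring this model."""
        if self._universe is not None:
            return self._universe
        import MDAnalysis as mda

        resindex = np.zeros(self.n_atoms, dtype=int)
        res_keys: list[tuple[str, int, str]] = []
        for i in range(self.n_atoms):
            key = (self.chains[i], int(self.resids[i]), self.resnames[i])
            if not res_keys or res_keys[-1] != key:
                res_keys.append(key)
            resindex[i] = len(res_keys) - 1
        seg_ids = sorted({k[0] for k in res_keys})
        seg_index = {s: j for j, s in enumerate(seg_ids)}
        res_segindex = np.array([seg_index[k[0]] for k in res_keys], dtype=int)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(
                self.n_atoms,
                n_residues=len(res_keys),
                n_segments=len(seg_ids),
                atom_resindex=resindex,
                residue_segindex=res_segindex,
                trajectory=True,
            )
            u.add_TopologyAttr("names", self.names.tolist())
            u.add_TopologyAttr("elements", self.elements.tolist())
            u.add_TopologyAttr("masses", self.masses)
            u.add_TopologyAttr("chainIDs", self.chains.tolist())
            u.add_TopologyAttr("resids", [k[1] for k in res_keys])
            u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
            u.add_TopologyAttr("segids", seg_ids)
            u.add_TopologyAttr("occupancies", np.ones(self.n_atoms))
            u.add_TopologyAttr("tempfactors", np.zeros(self.n_atoms))
            u.add_TopologyAttr("record_types", ["ATOM"] * self.n_atoms)
        u.atoms.positions = self.positions
        self._universe = u
        return u


@dataclass
class Trajectory:
    """Time-ordered coordinate frames over a fixed topology (Å, ns)."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,), ns
    box: np.ndarray | None = None  # (n_frames, 6) lengths+angles, optional

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise TrajectoryError("times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# Residue roles and pockets


_SINGLE_ROLES = ("0'K", "5'K", "6'", "9'E", "-2'F", "K64", "K90", "R92")


@dataclass(frozen=True)
class ResidueRoleMap:
    """Chain-agnostic mapping from functional roles to residue numbers.

    Defaults follow mouse GIRK2 author numbering: K194 is the 0' position,
    K199 the 5', K200 the 6' (lysine in WT, tyrosine in the 6'Y mutant),
    E203 the 9', and F192 (-2'F) forms the HBC gate.  The PIP2 pocket is
    residues 62-64, 88-92 and 192-203.
    """

    zero_k: int = 194
    five_k: int = 199
    six: int = 200
    nine_e: int = 203
    minus2_f: int = 192
    k64: int = 64
    k90: int = 90
    r92: int = 92
    selectivity_filter_residues: tuple[int, ...] = (155, 156, 157)
    pocket_residues: tuple[int, ...] = tuple(
        list(range(62, 65)) + list(range(88, 93)) + list(range(192, 204))
    )

    def residue_for(self, role: str) -> int:
        table = {
            "0'K": self.zero_k,
            "5'K": self.five_k,
            "6'": self.six,
            "6'K": self.six,
            "6'Y": self.six,
            "9'E": self.nine_e,
            "-2'F": self.minus2_f,
            "K64": self.k64,
            "K90": self.k90,
            "R92": self.r92,
        }
        if role not in table:
            raise KeyError(f"unknown residue role {role!r}")
        return table[role]


@dataclass(frozen=True)
class PhosphateGroupSpec:
    """One inositol phosphate group of the lipid: label, P atom, O acceptors."""

    label: str  # "P1'", "P4'" or "P5'"
    phosphorus: str
    acceptor_oxygens: tuple[str, ...]
    lipid_resname: str = "PIP"

    def __post_init__(self):
        if len(self.acceptor_oxygens) < 1:
            raise ValueError(f"group {self.label}: need >=1 acceptor oxygen")


PIP2_PHOSPHATE_GROUPS: dict[str, PhosphateGroupSpec] = {
    "P1'": PhosphateGroupSpec("P1'", "P1", ("O1A", "O1B", "O1C")),
    "P4'": PhosphateGroupSpec("P4'", "P4", ("O4A", "O4B", "O4C")),
    "P5'": PhosphateGroupSpec("P5'", "P5", ("O5A", "O5B", "O5C")),
}


@dataclass(frozen=True)
class PocketAssignment:
    """Fixed bijection between the four lipids and the four pockets.

    ``lipids[i]`` is the (chain_id, residue_number) key of the lipid in
    pocket i; ``chains[i]`` the protein chain(s) forming that pocket.
    """

    lipids: tuple[tuple[str, int], ...]
    chains: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        if len(self.lipids) != 4 or len(self.chains) != 4:
            raise PocketAssignmentError("exactly four pockets required")
        if len(set(self.lipids)) != 4:
            raise PocketAssignmentError("lipid-to-pocket map must be a bijection")

    def pocket_of_lipid(self, lipid_key: tuple[str, int]) -> int:
        return self.lipids.index(lipid_key)


def assign_pockets(
    traj: Trajectory,
    roles: ResidueRoleMap,
    lipid_residue_name: str = "PIP",
) -> PocketAssignment:
    """Assign each lipid to the pocket whose 0'K NZ atom is nearest at frame 0.

    Pockets are indexed by the sorted order of the protein chains carrying
    the 0'K residue; the assignment is locked for the whole trajectory.
    """
    model = traj.topology
    lipid_mask = model.resnames == lipid_residue_name
    lipid_keys = sorted(
        {(str(model.chains[i]), int(model.resids[i])) for i in np.flatnonzero(lipid_mask)}
    )
    if len(lipid_keys) != 4:
        raise PocketAssignmentError(
            f"expected exactly 4 lipid residues named {lipid_residue_name!r}, "
            f"found {len(lipid_keys)}"
        )
    nz_mask = (model.resids == roles.zero_k) & (model.names == "NZ")
    pocket_chains = sorted({str(model.chains[i]) for i in np.flatnonzero(nz_mask)})
    if len(pocket_chains) != 4:
        raise PocketAssignmentError(
            f"expected 0'K NZ in 4 chains, found chains {pocket_chains}"
        )
    frame0 = traj.frames[0]
    nz_pos = np.array(
        [
            frame0[model.index_of(c, roles.zero_k, "NZ")]
            for c in pocket_chains
        ]
    )
    assignment: dict[int, tuple[str, int]] = {}
    for key in lipid_keys:
        sel = (model.chains == key[0]) & (model.resids == key[1]) & lipid_mask
        center = frame0[np.flatnonzero(sel)].mean(axis=0)
        pocket = int(np.argmin(np.linalg.norm(nz_pos - center, axis=1)))
        if pocket in assignment:
            raise PocketAssignmentError(
                f"lipids {assignment[pocket]} and {key} both nearest pocket {pocket}"
            )
        assignment[pocket] = key
    lipids = tuple(assignment[i] for i in range(4))
    chains = tuple((c,) for c in pocket_chains)
    return PocketAssignment(lipids=lipids, chains=chains)


# ---------------------------------------------------------------------------
# File I/O


def _validate_pdb_file(path: Path) -> None:
    n_atom_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_atom_lines += 1
                if len(line.rstrip("\n")) < 54:
                    raise StructureParseError(
                        f"{path}: malformed record at line {lineno}: too short"
                    )
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise StructureParseError(
                        f"{path}: malformed coordinates at line {lineno}"
                    ) from None
    if n_atom_lines == 0:
        raise StructureParseError(f"{path}: no ATOM/HETATM records")


def _validate_gro_file(path: Path) -> None:
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise StructureParseError(f"{path}: truncated GRO file")
    try:
        n = int(lines[1].split()[0])
    except (ValueError, IndexError):
        raise StructureParseError(f"{path}: bad atom count at line 2") from None
    if len(lines) < n + 3:
        raise StructureParseError(
            f"{path}: expected {n} atom lines, file has {len(lines) - 3}"
        )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.upper()
    return path.suffix.lstrip(".").upper() or "PDB"


def _model_from_universe(u, title: str) -> StructureModel:
    ag = u.atoms
    n = len(ag)
    chains = (
        ag.chainIDs if hasattr(ag, "chainIDs") else np.array([""] * n)
    )
    try:
        elements = np.asarray(ag.elements)
        if np.all(elements == ""):
            raise AttributeError
    except Exception:
        elements = np.array([guess_element(name) for name in ag.names])
    chain_ids = [str(c).strip() for c in chains]
    keys = {
        (chain_ids[i], int(ag.resids[i]), str(ag.names[i])) for i in range(n)
    }
    if len(keys) != n:
        # chain-less formats (GRO): disambiguate repeated residue numbers by
        # occurrence order, so the k-th copy of a residue gets the k-th letter
        import string

        seen: dict[tuple[int, str], int] = {}
        res_chain: dict[int, str] = {}
        for i in range(n):
            ri = int(ag.resindices[i])
            if ri not in res_chain:
                rkey = (int(ag.resids[i]), str(ag.resnames[i]))
                occ = seen.get(rkey, 0)
                seen[rkey] = occ + 1
                res_chain[ri] = string.ascii_uppercase[occ % 26]
            chain_ids[i] = res_chain[ri]
    atoms = [
        AtomRecord(
            atom_id=i,
            atom_name=str(ag.names[i]),
            residue_name=str(ag.resnames[i]),
            residue_number=int(ag.resids[i]),
            chain_id=chain_ids[i],
            element=str(elements[i]) or guess_element(str(ag.names[i])),
            position=ag.positions[i].astype(float),
        )
        for i in range(n)
    ]
    return StructureModel(atoms, title=title)


def read_structure(path, format: str | None = None) -> StructureModel:
    """Read a PDB or GRO structure into a StructureModel (coordinates in Å)."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise StructureParseError(f"{path}: empty file")
    fmt = _infer_format(path, format)
    if fmt == "PDB":
        _validate_pdb_file(path)
    elif fmt == "GRO":
        _validate_gro_file(path)
    else:
        raise StructureParseError(f"unsupported structure format {fmt!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt, to_guess=())
    except Exception as exc:  # pragma: no cover - MDAnalysis internals
        raise StructureParseError(f"{path}: {exc}") from exc
    return _model_from_universe(u, title=path.stem)


def write_structure(model: StructureModel, path, format: str | None = None) -> None:
    """Write a StructureModel as PDB or GRO."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = _infer_format(path, format)
    u = model.to_universe()
    u.atoms.positions = model.positions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=model.n_atoms, format=fmt) as w:
            w.write(u.atoms)


def read_trajectory(
    topology: StructureModel, path, format: str | None = None
) -> Trajectory:
    """Read XTC/DCD/multi-model-PDB frames onto a topology.

    Times are normalised to ns.  Formats without time metadata (multi-model
    PDB) get the frame index as the time.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"no such trajectory file: {path}")
    if path.stat().st_size == 0:
        raise TrajectoryError(f"{path}: empty trajectory file")
    fmt = _infer_format(path, format)
    u = topology.to_universe()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path), format=fmt)
    except Exception as exc:
        raise TrajectoryError(f"{path}: {exc}") from exc
    frames, times_ps, boxes = [], [], []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                frames.append(ts.positions.copy().astype(float))
                times_ps.append(float(ts.time) if ts.time is not None else np.nan)
                boxes.append(None if ts.dimensions is None else ts.dimensions.copy())
    except Exception as exc:
        raise TrajectoryError(
            f"{path}: truncated frame after {len(frames)} good frame(s): {exc}"
        ) from exc
    finally:
        # detach the file-backed reader so the cached Universe stays reusable
        u.load_new(topology.positions[None, :, :], order="fac")
    if not frames:
        raise TrajectoryError(f"{path}: contains no frames")
    times_ps = np.asarray(times_ps)
    n = len(frames)
    if fmt == "PDB" or np.any(~np.isfinite(times_ps)) or (
        n > 1 and not np.all(np.diff(times_ps) > 0)
    ):
        times_ns = np.arange(n, dtype=float)
    else:
        times_ns = times_ps / 1000.0
    box = None
    if all(b is not None for b in boxes):
        box = np.asarray(boxes, dtype=float)
    return Trajectory(topology=topology, frames=np.asarray(frames), times=times_ns, box=box)


def write_trajectory(
    traj: Trajectory, path, format: str | None = None
) -> None:
    """Write frames as multi-model PDB or DCD."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = _infer_format(path, format)
    u = traj.topology.to_universe()
    kwargs = {}
    if traj.n_frames > 1 and fmt in ("DCD", "XTC"):
        steps = np.diff(traj.times)
        if np.allclose(steps, steps[0]):
            kwargs["dt"] = float(steps[0]) * 1000.0  # ns -> ps
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, format=fmt, multiframe=True,
                        **kwargs) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i]
                w.write(u.atoms)
    u.atoms.positions = traj.topology.positions


# ---------------------------------------------------------------------------
# Selection


_RANGE_RE = re.compile(r"(?<=[\s])(\d+)\s*-\s*(\d+)")


def _translate_query(query: str) -> str:
    q = re.sub(r"\bchain\b(?!ID)", "chainID", query)
    q = _RANGE_RE.sub(r"\1:\2", " " + q)[1:]
    return q


def select_atoms(model: StructureModel, query: str) -> list[int]:
    """Select atom indices (file order) with a chain/resid/resname/name query.

    The grammar is the MDAnalysis selection language with two conveniences:
    ``chain X`` is an alias for ``chainID X`` and residue ranges may be
    written ``88-92`` as well as ``88:92``.  An empty selection is not an
    error; a syntactically invalid query is.
    """
    u = model.to_universe()
    u.atoms.positions = model.positions
    try:
        ag = u.select_atoms(_translate_query(query))
    except Exception as exc:
        raise SelectionQueryError(f"invalid selection {query!r}: {exc}") from exc
    return sorted(int(i) for i in ag.ix)


# ---------------------------------------------------------------------------
# Superposition and RMSD


def superpose_kabsch(mobile, reference):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with ``x' = R @ x + t``
    mapping mobile onto reference; the rotation is proper (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must both be (N, 3) with equal N")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points for superposition")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean
    for pts, name in ((mob_c, "mobile"), (ref_c, "reference")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[0] == 0 or s[1] / s[0] < 1e-9:
            raise GeometryError(f"{name} point set is collinear or degenerate")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_mean - rot @ mob_mean
    moved = mob_c @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1))))
    return rot, trans, rmsd


def pocket_ca_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    roles: ResidueRoleMap,
    chains: Sequence[str] | None = None,
) -> float:
    """Cα RMSD over the PIP2-pocket residues after pocket-selection superposition.

    Both models must contain a Cα for every pocket residue in every matched
    chain (chains present in both models, or an explicit ``chains`` subset —
    useful when an entry also contains non-channel chains)."""
    if chains is None:
        chains = sorted(set(model_a.chains) & set(model_b.chains))
    else:
        chains = sorted(chains)
    missing = []
    coords_a, coords_b = [], []
    for chain in chains:
        has_any = False
        for resid in roles.pocket_residues:
            try:
                ia = model_a.index_of(chain, resid, "CA")
                ib = model_b.index_of(chain, resid, "CA")
            except MissingResidueError:
                missing.append((chain, resid))
                continue
            has_any = True
            coords_a.append(model_a.positions[ia])
            coords_b.append(model_b.positions[ib])
        if not has_any:
            # chain carries none of the pocket residues (e.g. lipid chain)
            missing = [m for m in missing if m[0] != chain]
    if missing:
        raise MissingResidueError(
            "missing pocket Cα atoms: " + ", ".join(f"{c}:{r}" for c, r in missing)
        )
    if not coords_a:
        raise MissingResidueError("no pocket Cα atoms in matched chains")
    _, _, rmsd = superpose_kabsch(np.asarray(coords_a), np.asarray(coords_b))
    return rmsd
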