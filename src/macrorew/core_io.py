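"""Domain types and file readers for macrocycle trajectory analysis.

All coordinates are in Å, energies in kcal/mol, time in ns. Atom indexing
is 0-based internally; PDB serial numbers are converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "BoostSeries",
    "TorsionSet",
    "read_topology",
    "read_trajectory",
    "write_trajectory_xyz",
    "read_boost_log",
    "read_torsions",
    "compute_dihedrals",
]

# Single-bond covalent radii (Å), Cordero et al. values for common elements.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_DEFAULT_RADIUS = 0.77
# Tolerance added to the sum of covalent radii when inferring bonds.
BOND_TOLERANCE = 0.45


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_id: int
    residue_name: str


@dataclass
class Topology:
    """Molecular topology: atoms plus an undirected bond list.

    ``formal_charge`` is the net molecular charge in elementary charges.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    formal_charge: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise ValueError(
                    f"atom indices must be contiguous from 0; atom {i} has index {atom.index}"
                )
        seen = set()
        canon = []
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a}, {b}) references a nonexistent atom")
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                canon.append(key)
        self.bonds = canon

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    def heavy_atom_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.element != "H"], dtype=int)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def bond_separation_matrix(self) -> np.ndarray:
        """All-pairs shortest path length over the bond graph (np.inf if disconnected)."""
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import shortest_path

        n = self.n_atoms
        if self.bonds:
            rows, cols = zip(*self.bonds)
        else:
            rows, cols = (), ()
        mat = csr_matrix(
            (np.ones(len(rows)), (np.array(rows, dtype=int), np.array(cols, dtype=int))),
            shape=(n, n),
        )
        return shortest_path(mat, method="D", directed=False, unweighted=True)

    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms], dtype=int)


@dataclass
class Trajectory:
    """Cartesian coordinates (frames × atoms × 3, Å) with topology and time stride."""

    coords: np.ndarray
    topology: Topology
    frame_interval: float = 1.0  # ns per saved frame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3); got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class BoostSeries:
    """Per-frame aMD boost energies (kcal/mol): dihedral and total-potential terms."""

    dv_dihedral: np.ndarray
    dv_total: np.ndarray

    def __post_init__(self) -> None:
        self.dv_dihedral = np.asarray(self.dv_dihedral, dtype=float)
        self.dv_total = np.asarray(self.dv_total, dtype=float)
        if self.dv_dihedral.shape != self.dv_total.shape or self.dv_dihedral.ndim != 1:
            raise ValueError("dv_dihedral and dv_total must be equal-length 1D arrays")
        if not (np.isfinite(self.dv_dihedral).all() and np.isfinite(self.dv_total).all()):
            raise ValueError("boost energies must be finite")
        if (self.dv_dihedral < 0).any() or (self.dv_total < 0).any():
            raise ValueError("boost energies must be >= 0")

    def __len__(self) -> int:
        return len(self.dv_total)


@dataclass
class TorsionSet:
    """Atom-index quadruples defining the analysed torsions (e.g. T1..T11)."""

    quadruples: list[tuple[int, int, int, int]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.quadruples = [tuple(int(i) for i in q) for q in self.quadruples]
        for q in self.quadruples:
            if len(q) != 4:
                raise ValueError(f"torsion {q} is not a quadruple")
            if len(set(q)) != 4:
                raise ValueError(f"torsion {q} repeats an atom")
        if not self.labels:
            self.labels = [f"T{i + 1}" for i in range(len(self.quadruples))]
        if len(self.labels) != len(self.quadruples):
            raise ValueError("labels and quadruples must have equal length")

    def validate_against(self, topology: Topology) -> None:
        n = topology.n_atoms
        for q in self.quadruples:
            if any(i < 0 or i >= n for i in q):
                raise ValueError(f"torsion {q} references an atom outside 0..{n - 1}")

    def __len__(self) -> int:
        return len(self.quadruples)


# ---------------------------------------------------------------------------
# Readers


def _infer_bonds(elements: np.ndarray, coords: np.ndarray) -> list[tuple[int, int]]:
    """Infer bonds from interatomic distances using a covalent-radius cutoff."""
    radii = np.array([COVALENT_RADII.get(e, _DEFAULT_RADIUS) for e in elements])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cutoff = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    bonded = (dist <= cutoff) & (dist > 1e-6)
    bonds = []
    n = len(elements)
    for i in range(n):
        for j in range(i + 1, n):
            if bonded[i, j]:
                bonds.append((i, j))
    return bonds


def _element_from_pdb(record: str, name: str) -> str:
    el = record[76:78].strip() if len(record) >= 78 else ""
    if not el:
        el = name.strip()[:1]
    return el.capitalize()


def read_topology(path: str, formal_charge: int = 0) -> tuple[Topology, np.ndarray]:
    """Read a PDB file into a Topology plus the first-model coordinates.

    Bonds come from CONECT records when present, otherwise from
    covalent-radius distance inference. Returns ``(topology, coords)``
    with coords shaped (n_atoms, 3) in Å.
    """
    atoms: list[Atom] = []
    coords: list[list[float]] = []
    serial_to_index: dict[int, int] = {}
    conect_pairs: set[tuple[int, int]] = set()
    in_first_model = True

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.rstrip("\n")
            tag = rec[:6].strip()
            if tag == "ENDMDL":
                in_first_model = False
            if tag in ("ATOM", "HETATM") and in_first_model:
                try:
                    serial = int(rec[6:11])
                    name = rec[12:16].strip()
                    resname = rec[17:20].strip() or "UNK"
                    resid = int(rec[22:26]) if rec[22:26].strip() else 0
                    x = float(rec[30:38])
                    y = float(rec[38:46])
                    z = float(rec[46:54])
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}: malformed {tag} record at line {lineno}") from exc
                idx = len(atoms)
                serial_to_index[serial] = idx
                atoms.append(Atom(idx, name, _element_from_pdb(rec, name), resid, resname))
                coords.append([x, y, z])
            elif tag == "CONECT":
                try:
                    serials = [int(rec[i : i + 5]) for i in range(6, min(len(rec), 31), 5)
                               if rec[i : i + 5].strip()]
                except ValueError as exc:
                    raise ValueError(f"{path}: malformed CONECT record at line {lineno}") from exc
                if serials:
                    base = serials[0]
                    for other in serials[1:]:
                        conect_pairs.add((min(base, other), max(base, other)))

    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found (empty input)")

    xyz = np.asarray(coords, dtype=float)
    if conect_pairs:
        bonds = [
            (serial_to_index[a], serial_to_index[b])
            for a, b in sorted(conect_pairs)
            if a in serial_to_index and b in serial_to_index
        ]
    else:
        bonds = _infer_bonds(np.array([a.element for a in atoms]), xyz)
    return Topology(atoms=atoms, bonds=bonds, formal_charge=formal_charge), xyz


def _read_frames_mdanalysis(path: str, fmt: str | None) -> np.ndarray:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path, format=fmt)
        frames = []
        try:
            for ts in u.trajectory:
                frames.append(ts.positions.copy())
        except (EOFError, OSError, ValueError):
            warnings.warn(f"{path}: truncated final frame dropped", stacklevel=3)
    return np.asarray(frames, dtype=float)


def _read_xyz_frames(path: str) -> np.ndarray:
    """Multi-frame XYZ reader tolerant of a truncated final frame."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {pos + 1}") from exc
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            warnings.warn(f"{path}: truncated final frame dropped", stacklevel=2)
            break
        frame = []
        for row in block:
            parts = row.split()
            frame.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(frame)
        pos += 2 + n
    return np.asarray(frames, dtype=float)


def read_trajectory(path: str, topology: Topology, frame_interval: float = 1.0) -> Trajectory:
    """Read a DCD, multi-frame XYZ, or multi-model PDB trajectory.

    The frame atom count must match the topology; coordinates are returned
    in Å in file order.
    """
    lower = path.lower()
    if lower.endswith(".xyz"):
        coords = _read_xyz_frames(path)
    elif lower.endswith(".dcd"):
        coords = _read_frames_mdanalysis(path, "DCD")
    elif lower.endswith(".pdb"):
        coords = _read_frames_mdanalysis(path, "PDB")
    else:
        raise ValueError(f"unsupported trajectory format: {path}")
    if coords.size == 0:
        raise ValueError(f"{path}: no complete frames read (empty input)")
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"{path}: frames have {coords.shape[1]} atoms but topology has "
            f"{topology.n_atoms} (structural mismatch)"
        )
    return Trajectory(coords=coords, topology=topology, frame_interval=frame_interval)


def write_trajectory_xyz(traj: Trajectory, path: str) -> None:
    """Write a trajectory as multi-frame XYZ (full float precision)."""
    elements = traj.topology.elements()
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.topology.n_atoms}\nframe {f}\n")
            for el, (x, y, z) in zip(elements, traj.coords[f]):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


# Column layout of an AMBER amd.log row (0-based), overridable because the
# log schema varies between engine versions.
AMD_LOG_COLUMNS = {"dv_total": 6, "dv_dihedral": 7}


def read_boost_log(path: str, columns: dict[str, int] | None = None) -> BoostSeries:
    """Read per-frame boost energies from an AMBER amd.log-style text file.

    Lines starting with ``#`` (or any non-numeric payload) are skipped with
    a warning; ``columns`` maps field names to 0-based column indices.
    """
    cols = dict(AMD_LOG_COLUMNS)
    if columns:
        cols.update(columns)
    need = max(cols.values()) + 1
    dih, tot = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "|")):
                continue
            parts = stripped.split()
            try:
                if len(parts) < need:
                    raise ValueError
                d = float(parts[cols["dv_dihedral"]])
                t = float(parts[cols["dv_total"]])
            except ValueError:
                warnings.warn(f"{path}: skipping non-numeric row at line {lineno}", stacklevel=2)
                continue
            dih.append(d)
            tot.append(t)
    if not dih:
        raise ValueError(f"{path}: no numeric rows found (empty input)")
    return BoostSeries(dv_dihedral=np.array(dih), dv_total=np.array(tot))


def write_boost_log(boost: BoostSeries, path: str) -> None:
    """Write a boost series in the amd.log column dialect read_boost_log expects."""
    ncol = max(AMD_LOG_COLUMNS.values()) + 1
    with open(path, "w") as fh:
        fh.write("# step ntwx atoms temp Etot dihed dV-total dV-dihedral\n")
        for i, (d, t) in enumerate(zip(boost.dv_dihedral, boost.dv_total)):
            row = ["0.0"] * ncol
            row[0] = str(i + 1)
            row[AMD_LOG_COLUMNS["dv_total"]] = f"{t:.10f}"
            row[AMD_LOG_COLUMNS["dv_dihedral"]] = f"{d:.10f}"
            fh.write(" ".join(row) + "\n")


def read_torsions(path: str) -> TorsionSet:
    """Read torsion definitions: four whitespace-separated 0-based atom
    indices per line, with an optional trailing label column."""
    quadruples, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: need 4 atom indices")
            try:
                quad = tuple(int(p) for p in parts[:4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer atom index") from exc
            quadruples.append(quad)
            labels.append(parts[4] if len(parts) > 4 else f"T{len(quadruples)}")
    if not quadruples:
        raise ValueError(f"{path}: no torsion definitions found (empty input)")
    return TorsionSet(quadruples=quadruples, labels=labels)


# ---------------------------------------------------------------------------
# Dihedrals


def compute_dihedrals(traj: Trajectory, torsions: TorsionSet) -> np.ndarray:
    """Signed dihedral angles for every frame × torsion, degrees in (−180, 180].

    Uses the atan2 formulation; a collinear atom triple makes the dihedral
    undefined and raises, naming the offending frame and torsion.
    """
    torsions.validate_against(traj.topology)
    quads = np.array(torsions.quadruples, dtype=int)
    p0 = traj.coords[:, quads[:, 0]]
    p1 = traj.coords[:, quads[:, 1]]
    p2 = traj.coords[:, quads[:, 2]]
    p3 = traj.coords[:, quads[:, 3]]

    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1_norm = np.linalg.norm(n1, axis=-1)
    n2_norm = np.linalg.norm(n2, axis=-1)
    bad = (n1_norm < 1e-10) | (n2_norm < 1e-10)
    if bad.any():
        f, t = np.argwhere(bad)[0]
        raise ValueError(
            f"undefined dihedral: collinear atoms in frame {f}, torsion "
            f"{torsions.labels[t]}"
        )
    b1_unit = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = (n1 * n2).sum(axis=-1)
    y = (np.cross(n1, n2) * b1_unit).sum(axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # canonical wrap (−180, 180]: map exact −180 to +180
    ang[ang <= -180.0] += 360.0
    return ang
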