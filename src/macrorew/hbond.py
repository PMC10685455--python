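"""Intramolecular hydrogen-bond (IMHB) detection and reweighted occupancy.

A donor is an N/O heavy atom with a bound hydrogen (one donor entry per
N–H / O–H pair); acceptors are oxygens plus nitrogens that retain an
available lone pair (carbonyl O always qualifies; amide N never does).
A contact requires donor-heavy to acceptor-heavy distance ≤ d_max AND
donor–H···acceptor angle ≥ angle_min (both inclusive) AND a minimum
bond-graph separation so covalently adjacent polar atoms are not
self-counted. Occupancies are accumulated with per-frame statistical
weights, giving reweighted contact maps; per-donor shares of the total
occupancy quantify which NH drives the IMHB network, and polar/apolar
difference maps split contacts into short-range (adjacent residues on
the macrocycle ring) and long-range (transannular) classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "Donor",
    "ContactMap",
    "find_donors_acceptors",
    "detect_frame",
    "contact_occupancy",
    "donor_contributions",
    "compare_phases",
    "PhaseComparison",
]


@dataclass
class HBondCriteria:
    """Geometric IMHB criteria.

    d_max          : donor-heavy to acceptor-heavy distance cutoff, Å
    angle_min      : minimum donor–H···acceptor angle, degrees (90° is
                     deliberately permissive, to catch unconventional
                     short-range IMHBs)
    min_separation : minimum bond-graph separation (bonds) between the
                     heavy atoms for the pair to count as intramolecular
    """

    d_max: float = 3.5
    angle_min: float = 90.0
    min_separation: int = 3

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if not (0 <= self.angle_min <= 180):
            raise ValueError("angle_min must be in [0, 180]")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class Donor:
    heavy: int
    hydrogen: int
    label: str


@dataclass
class ContactMap:
    """Donor × acceptor matrix of reweighted occupancies in [0, 1]."""

    donor_labels: list[str]
    acceptor_labels: list[str]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.shape != (len(self.donor_labels), len(self.acceptor_labels)):
            raise ValueError("occupancy shape must be (donors, acceptors)")
        if (self.occupancy < -1e-12).any() or (self.occupancy > 1 + 1e-12).any():
            raise ValueError("occupancies must lie in [0, 1]")


def _neighbors(topology: Topology) -> list[list[int]]:
    return topology.adjacency()


def _is_carbonyl_carbon(topology: Topology, adj: list[list[int]], c: int) -> bool:
    atoms = topology.atoms
    if atoms[c].element != "C":
        return False
    for nb in adj[c]:
        # terminal oxygen on a carbon: carbonyl-like
        if atoms[nb].element == "O" and len(adj[nb]) == 1:
            return True
    return False


def find_donors_acceptors(topology: Topology) -> tuple[list[Donor], list[int]]:
    """Enumerate H-bond donors and acceptors from the bond graph.

    Donors: one (heavy, H) entry per N–H or O–H bond, labeled D1, D2, ...
    in topology order. Acceptors: all oxygens, plus nitrogens that are
    neither amide nitrogens (bonded to a carbonyl carbon) nor H-bearing —
    i.e. nitrogens with a freely available lone pair.
    """
    atoms = topology.atoms
    adj = _neighbors(topology)
    if not any(a.element == "H" for a in atoms):
        raise ValueError(
            "topology has no hydrogens: explicit H atoms are required for "
            "donor detection"
        )
    donors: list[Donor] = []
    for a in atoms:
        if a.element not in ("N", "O"):
            continue
        for nb in adj[a.index]:
            if atoms[nb].element == "H":
                donors.append(Donor(a.index, nb, f"D{len(donors) + 1}"))
    acceptors: list[int] = []
    for a in atoms:
        if a.element == "O":
            acceptors.append(a.index)
        elif a.element == "N":
            has_h = any(atoms[nb].element == "H" for nb in adj[a.index])
            amide = any(_is_carbonyl_carbon(topology, adj, nb) for nb in adj[a.index])
            if not has_h and not amide:
                acceptors.append(a.index)
    return donors, acceptors


def _angles_deg(h: np.ndarray, d: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Donor–H···acceptor angle (vertex at H), degrees."""
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = (v1 * v2).sum(axis=-1) / np.maximum(n1 * n2, 1e-300)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_frame(
    coords: np.ndarray,
    donors: list[Donor],
    acceptors: list[int],
    criteria: HBondCriteria,
    topology: Topology,
    separation: np.ndarray | None = None,
) -> set[tuple[int, int]]:
    """Contacts in one frame as a set of (donor heavy, acceptor) index pairs.

    Both geometric cutoffs are inclusive; identical donor/acceptor heavy
    atoms are skipped. ``separation`` may carry a precomputed bond-graph
    separation matrix to avoid recomputing it per frame.
    """
    if separation is None:
        separation = topology.bond_separation_matrix()
    coords = np.asarray(coords, dtype=float)
    contacts: set[tuple[int, int]] = set()
    for donor in donors:
        for acc in acceptors:
            if acc == donor.heavy:
                continue
            if separation[donor.heavy, acc] < criteria.min_separation:
                continue
            dist = np.linalg.norm(coords[donor.heavy] - coords[acc])
            if dist > criteria.d_max:
                continue
            ang = _angles_deg(coords[donor.hydrogen], coords[donor.heavy], coords[acc])
            if ang >= criteria.angle_min:
                contacts.add((donor.heavy, acc))
    return contacts


def contact_occupancy(
    traj: Trajectory,
    weights: np.ndarray,
    criteria: HBondCriteria,
    donors: list[Donor],
    acceptors: list[int],
    acceptor_labels: list[str] | None = None,
) -> ContactMap:
    """Reweighted occupancy per (donor, acceptor): Σ_frames w · 1[contact]."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != traj.n_frames:
        raise ValueError("weights length must equal frame count")
    sep = traj.topology.bond_separation_matrix()
    d_heavy = np.array([d.heavy for d in donors], dtype=int)
    d_hyd = np.array([d.hydrogen for d in donors], dtype=int)
    acc = np.asarray(acceptors, dtype=int)
    occ = np.zeros((len(donors), len(acc)))
    if len(donors) and len(acc):
        # pair eligibility mask (identity + graph separation), frame-independent
        eligible = sep[np.ix_(d_heavy, acc)] >= criteria.min_separation
        eligible &= d_heavy[:, None] != acc[None, :]
        X = traj.coords
        dist = np.linalg.norm(
            X[:, d_heavy, None, :] - X[:, None, acc, :], axis=-1
        )  # frames × donors × acceptors
        v1 = X[:, d_heavy, None, :] - X[:, d_hyd, None, :]
        v2 = X[:, None, acc, :] - X[:, d_hyd, None, :]
        cosang = (v1 * v2).sum(-1) / np.maximum(
            np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1), 1e-300
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        contact = (dist <= criteria.d_max) & (ang >= criteria.angle_min) & eligible
        occ = np.einsum("f,fda->da", weights, contact.astype(float))
    donor_labels = [d.label for d in donors]
    if acceptor_labels is None:
        acceptor_labels = [f"A{i + 1}" for i in range(len(acc))]
    return ContactMap(donor_labels, acceptor_labels, np.clip(occ, 0.0, 1.0))


def donor_contributions(cmap: ContactMap) -> np.ndarray:
    """Per-donor percentage share of the total IMHB occupancy.

    Shares sum to 100% whenever any contact exists; an all-zero map yields
    NaN shares (undefined).
    """
    row = cmap.occupancy.sum(axis=1)
    total = row.sum()
    if total <= 0:
        return np.full(len(row), np.nan)
    return row / total * 100.0


@dataclass
class PhaseComparison:
    """Apolar − polar occupancy differences with a per-pair range class."""

    difference: np.ndarray  # apolar − polar
    per_donor_difference: np.ndarray
    pair_class: np.ndarray  # "short-range" | "long-range" strings
    short_range_total: float  # Σ difference over short-range pairs
    long_range_total: float


def ring_distance(res_a: int, res_b: int, n_ring_residues: int) -> int:
    """Sequence separation around the macrocycle ring (minimum of the two
    directions)."""
    d = abs(res_a - res_b) % n_ring_residues
    return min(d, n_ring_residues - d)


def compare_phases(
    map_polar: ContactMap,
    map_apolar: ContactMap,
    topology: Topology,
    donors: list[Donor],
    acceptors: list[int],
) -> PhaseComparison:
    """Contrast IMHB networks between a polar and an apolar solvent phase.

    Pairs between adjacent ring residues (ring separation ≤ 1) are
    short-range; all others (transannular) are long-range. Chameleonic
    macrocycles typically gain long-range contacts in the apolar phase.
    """
    if (
        map_polar.donor_labels != map_apolar.donor_labels
        or map_polar.acceptor_labels != map_apolar.acceptor_labels
    ):
        raise ValueError("contact maps have mismatched donor/acceptor orderings")
    diff = map_apolar.occupancy - map_polar.occupancy
    resids = topology.residue_ids()
    n_ring = len(np.unique(resids))
    pair_class = np.empty(diff.shape, dtype=object)
    for i, donor in enumerate(donors):
        for j, acc in enumerate(acceptors):
            sep = ring_distance(resids[donor.heavy], resids[acc], n_ring)
            pair_class[i, j] = "short-range" if sep <= 1 else "long-range"
    short = pair_class == "short-range"
    return PhaseComparison(
        difference=diff,
        per_donor_difference=diff.sum(axis=1),
        pair_class=pair_class,
        short_range_total=float(diff[short].sum()),
        long_range_total=float(diff[~short].sum()),
    )
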