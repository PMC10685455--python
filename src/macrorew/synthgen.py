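"""Synthetic inputs with planted ground truth.

Every generator is a pure, seeded function producing artifacts in the
package's own domain types, with the statistical structure the consuming
analysis is supposed to recover:

* ``toy_macrocycle`` — an idealized semipeptidic macrocycle (simplified
  amide residues closed by an alkyl linker through a secondary amine),
  giving a topology whose donors/acceptors are known by construction;
* ``sample_boosted_potential`` — Metropolis sampling on an aMD-boosted
  1D potential with exactly known per-step boost energies, the oracle
  substrate for reweighting tests (boosted Metropolis has an exact
  stationary distribution, unlike MD);
* ``plant_torus_clusters`` — von-Mises torsion clusters on the n-torus
  with known populations, ground truth for dPCA + K-means;
* ``plant_hbond_trajectory`` — frames alternating between a
  contact-formed and a broken template, scheduled so the weighted
  occupancy of each planned pair equals its target.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .core_io import Atom, BoostSeries, Topology, Trajectory
from .hbond import Donor, find_donors_acceptors
from .reweight import KB, AMDParams, boost_energy

__all__ = [
    "toy_macrocycle",
    "sample_boosted_potential",
    "plant_torus_clusters",
    "plant_hbond_trajectory",
]

# idealized geometry constants (Å)
_RING_BOND = 1.5
_CO_BOND = 1.23
_NH_BOND = 1.0
_CH_BOND = 1.09


def toy_macrocycle(n_residues: int = 3, linker_len: int = 2) -> tuple[Topology, np.ndarray]:
    """Idealized macrocycle: ``n_residues`` simplified amide units
    (N, H, Cα, C, O) closed by a CH₂ linker entered through a secondary
    amine N–H.

    The ring backbone (N, Cα, C per residue; amine N; linker carbons) is
    laid out on a circle with 1.5 Å spacing; carbonyl O and polar H point
    radially outward, CH₂ hydrogens out of plane. By construction the
    molecule has ``n_residues`` amide N–H donors (each residue N that
    follows a carbonyl, plus the linker N–H that closes the ring onto the
    last carbonyl), one secondary-amine donor (the first residue N, which
    bonds only alkyl carbons), and ``n_residues`` carbonyl acceptors.

    Returns ``(topology, coords)`` with one 3D conformation.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if linker_len < 2:
        raise ValueError("linker_len must be >= 2")

    # ring backbone sequence: [N CA C] * n_residues, amine N, CH2 * linker_len
    ring_atoms: list[tuple[str, str, int, str]] = []  # (name, element, resid, resname)
    for r in range(n_residues):
        ring_atoms += [("N", "N", r, "AMD"), ("CA", "C", r, "AMD"), ("C", "C", r, "AMD")]
    ring_atoms.append(("NL", "N", n_residues, "LNK"))
    for c in range(linker_len):
        ring_atoms.append((f"CL{c + 1}", "C", n_residues, "LNK"))

    m = len(ring_atoms)
    radius = _RING_BOND / (2.0 * math.sin(math.pi / m))

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    ring_index: list[int] = []

    def add_atom(name: str, element: str, resid: int, resname: str, xyz: np.ndarray) -> int:
        idx = len(atoms)
        atoms.append(Atom(idx, name, element, resid, resname))
        coords.append(np.asarray(xyz, dtype=float))
        return idx

    for i, (name, element, resid, resname) in enumerate(ring_atoms):
        theta = 2.0 * math.pi * i / m
        pos = np.array([radius * math.cos(theta), radius * math.sin(theta), 0.0])
        ring_index.append(add_atom(name, element, resid, resname, pos))

    for i in range(m):
        bonds.append((ring_index[i], ring_index[(i + 1) % m]))

    def outward(i: int) -> np.ndarray:
        p = coords[ring_index[i]]
        return p / np.linalg.norm(p)

    # decorate the ring: H on each N, O on each C (carbonyl), 2 H per CH2
    for i, (name, element, resid, resname) in enumerate(ring_atoms):
        base = coords[ring_index[i]]
        if element == "N":
            h = add_atom("H", "H", resid, resname, base + _NH_BOND * outward(i))
            bonds.append((ring_index[i], h))
        elif name == "C":  # backbone carbonyl carbon
            o = add_atom("O", "O", resid, resname, base + _CO_BOND * outward(i))
            bonds.append((ring_index[i], o))
        elif name.startswith("CL"):
            for sign in (1.0, -1.0):
                off = np.array([0.0, 0.0, sign * _CH_BOND])
                h = add_atom("H", "H", resid, resname, base + off)
                bonds.append((ring_index[i], h))

    topo = Topology(atoms=atoms, bonds=bonds, formal_charge=0)
    return topo, np.array(coords)


def _potential_fn(potential: str, **kw):
    if potential == "harmonic":
        k = kw.get("k", 1.0)
        return lambda x: 0.5 * k * x * x
    if potential == "double_well":
        barrier = kw.get("barrier", 5.0)
        x0 = kw.get("x0", 1.0)
        return lambda x: barrier * ((x / x0) ** 2 - 1.0) ** 2
    raise ValueError(f"unknown potential {potential!r}")


def sample_boosted_potential(
    potential: str,
    amd: AMDParams,
    temperature: float = 300.0,
    n_steps: int = 100_000,
    seed: int = 0,
    step_size: float = 0.5,
    x_init: float = 0.0,
    **potential_kwargs,
) -> tuple[np.ndarray, BoostSeries, float]:
    """Metropolis sampling of the aMD-boosted surface V*(x) = V(x) + ΔV(V(x)).

    The boost uses the total-potential channel of ``amd`` (e_tot,
    alpha_tot); ΔV per retained step is computed exactly from V(x), so
    reweighting with exp(β ΔV) must recover Boltzmann statistics of V.
    Returns ``(samples, BoostSeries, acceptance_rate)``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    vfun = _potential_fn(potential, **potential_kwargs)
    beta = 1.0 / (KB * temperature)

    def v_star(x: float) -> float:
        v = vfun(x)
        return v + boost_energy(v, amd.e_tot, amd.alpha_tot)

    rng = np.random.default_rng(seed)
    proposals = rng.normal(0.0, step_size, size=n_steps)
    uniforms = rng.random(n_steps)

    xs = np.empty(n_steps)
    x = float(x_init)
    vs = v_star(x)
    accepted = 0
    for i in range(n_steps):
        xn = x + proposals[i]
        vn = v_star(xn)
        if vn <= vs or uniforms[i] < math.exp(-beta * (vn - vs)):
            x, vs = xn, vn
            accepted += 1
        xs[i] = x
    rate = accepted / n_steps
    if rate < 0.01:
        warnings.warn(f"Metropolis acceptance rate {rate:.3%} is below 1%", stacklevel=2)
    v_vals = np.array([vfun(x) for x in xs])
    dv = boost_energy(v_vals, amd.e_tot, amd.alpha_tot)
    boost = BoostSeries(dv_dihedral=np.zeros(n_steps), dv_total=np.asarray(dv))
    return xs, boost, rate


def plant_torus_clusters(
    n_torsions: int,
    k: int,
    populations: np.ndarray,
    concentration: float,
    n_frames: int,
    seed: int = 0,
    center_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Torsion series from k von-Mises clusters on the n-torus.

    Cluster centers are drawn uniformly; each frame picks a cluster with
    probability ``populations`` and adds von-Mises noise of the given
    concentration (κ) per torsion. ``concentration=np.inf`` puts frames
    exactly at the centers. ``center_seed`` pins the cluster layout
    independently of the frame noise, so different seeds can sample the
    SAME planted distribution (repeat-run scenarios); by default the
    layout follows ``seed``. Returns ``(angles_deg, labels, centers_deg)``
    with angles wrapped to (−180, 180].
    """
    populations = np.asarray(populations, dtype=float)
    if abs(populations.sum() - 1.0) > 1e-9:
        raise ValueError("populations must sum to 1")
    if k != len(populations):
        raise ValueError("populations length must equal k")
    if k > n_frames:
        raise ValueError("k must not exceed n_frames")
    rng = np.random.default_rng(seed)
    center_rng = np.random.default_rng(seed if center_seed is None else center_seed)
    centers = center_rng.uniform(-180.0, 180.0, size=(k, n_torsions))
    labels = rng.choice(k, size=n_frames, p=populations)
    if np.isinf(concentration):
        noise = np.zeros((n_frames, n_torsions))
    else:
        noise = np.degrees(rng.vonmises(0.0, concentration, size=(n_frames, n_torsions)))
    angles = centers[labels] + noise
    angles = np.mod(angles + 180.0, 360.0) - 180.0  # (−180, 180]
    angles[angles == -180.0] = 180.0
    return angles, labels, centers


def _formed_acceptor_position(
    d_pos: np.ndarray, h_pos: np.ndarray, distance: float, angle_deg: float
) -> np.ndarray:
    """Acceptor position at the given donor-heavy distance and D–H···A angle."""
    u = h_pos - d_pos
    d_dh = np.linalg.norm(u)
    u = u / d_dh
    # any unit vector perpendicular to u
    trial = np.array([1.0, 0.0, 0.0])
    if abs(u @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    w = trial - (trial @ u) * u
    w = w / np.linalg.norm(w)
    cos_a = math.cos(math.radians(angle_deg))
    # |HA| from the D-H-A triangle: t² − 2 d cosθ t + d² − distance² = 0
    t = d_dh * cos_a + math.sqrt((d_dh * cos_a) ** 2 - d_dh**2 + distance**2)
    direction = cos_a * (-u) + math.sin(math.radians(angle_deg)) * w
    return h_pos + t * direction


def plant_hbond_trajectory(
    topology: Topology,
    base_coords: np.ndarray,
    contact_plan: dict[tuple[int, int], float],
    n_frames: int,
    weights: np.ndarray | None = None,
    seed: int = 0,
    formed_distance: float = 2.9,
    formed_angle: float = 165.0,
    broken_distance: float = 5.5,
    frame_interval: float = 1.0,
    min_separation: int = 3,
) -> tuple[Trajectory, dict[tuple[int, int], float]]:
    """Trajectory whose weighted occupancy of each planned (donor-heavy,
    acceptor) pair equals its target as closely as the weights allow.

    Frames copy the base conformation; each planned acceptor is moved to a
    contact-formed template (heavy-atom distance ``formed_distance``,
    D–H···A angle ``formed_angle``) in a scheduled frame subset and to a
    broken template (``broken_distance``) elsewhere. The subset is chosen
    greedily over descending weights so its weight sum approaches the
    target; the achieved occupancies are returned as the ground truth.
    An acceptor may appear in at most one planned pair.
    """
    if weights is None:
        weights = np.full(n_frames, 1.0 / n_frames)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    if len(weights) != n_frames:
        raise ValueError("weights length must equal n_frames")
    donors, acceptors = find_donors_acceptors(topology)
    donor_by_heavy = {d.heavy: d for d in donors}
    separation = topology.bond_separation_matrix()
    seen_acc: set[int] = set()
    for (dh, acc), target in contact_plan.items():
        if dh not in donor_by_heavy:
            raise ValueError(f"atom {dh} is not a donor heavy atom")
        if acc not in acceptors:
            raise ValueError(f"atom {acc} is not an acceptor")
        if separation[dh, acc] < min_separation:
            raise ValueError(
                f"pair ({dh}, {acc}) is only {separation[dh, acc]:.0f} bonds apart; "
                f"it can never count as intramolecular (min_separation={min_separation})"
            )
        if acc in seen_acc:
            raise ValueError(f"acceptor {acc} appears in more than one planned pair")
        seen_acc.add(acc)
        if not (0.0 <= target <= 1.0):
            raise ValueError("occupancy targets must lie in [0, 1]")

    coords = np.repeat(base_coords[None, :, :], n_frames, axis=0)
    achieved: dict[tuple[int, int], float] = {}
    # greedy over descending weight; seeded random tie-break so equal-weight
    # (e.g. uniform) schedules spread formed frames across the trajectory
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.permutation(n_frames), -weights))
    for (dh, acc), target in contact_plan.items():
        donor: Donor = donor_by_heavy[dh]
        d_pos = base_coords[donor.heavy]
        h_pos = base_coords[donor.hydrogen]
        u = d_pos - h_pos
        u = -u / np.linalg.norm(u)  # from D through H, outward
        broken_pos = d_pos + broken_distance * u
        formed_pos = _formed_acceptor_position(d_pos, h_pos, formed_distance, formed_angle)
        total = 0.0
        formed_mask = np.zeros(n_frames, dtype=bool)
        for f in order:
            if total + weights[f] <= target + 1e-12:
                total += weights[f]
                formed_mask[f] = True
        if abs(total - target) > 0.01:
            warnings.warn(
                f"pair ({dh}, {acc}): target {target} infeasible under the given "
                f"weights; nearest achievable occupancy is {total:.6f}",
                stacklevel=2,
            )
        coords[:, acc, :] = np.where(formed_mask[:, None], formed_pos, broken_pos)
        # frame-order weighted count: the exact value contact_occupancy measures
        achieved[(dh, acc)] = float(np.dot(weights, formed_mask.astype(float)))
    traj = Trajectory(coords=coords, topology=topology, frame_interval=frame_interval)
    return traj, achieved
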