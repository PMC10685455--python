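"""Statistical reweighting of dual-boost accelerated-MD ensembles.

Accelerated MD adds a boost potential ΔV(x) to the true potential wherever
it lies below a threshold, flattening barriers. Canonical averages are
recovered by weighting each saved frame with exp(β ΔV). Because the
exponential estimator has high variance, the exponential is commonly
replaced by its Maclaurin series truncated at a finite order (default 20),
which trades a small bias for much lower weight variance.

Units: energies kcal/mol, temperature K. k_B = 0.0019872 kcal/(mol·K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import BoostSeries

KB = 0.0019872  # kcal/(mol·K)

__all__ = [
    "KB",
    "WeightParams",
    "AMDParams",
    "FES2D",
    "compute_weights",
    "reweighted_histogram",
    "free_energy_surface",
    "dual_boost_params",
    "boost_energy",
]


@dataclass
class WeightParams:
    """Reweighting configuration.

    temperature : simulation temperature in K (sets β = 1/(k_B T))
    order       : Maclaurin truncation order (ignored in exponential mode)
    mode        : "exponential" or "maclaurin"
    use_boost   : which boost component enters β·ΔV — "sum" (dihedral +
                  total, the dual-boost default), "total", or "dihedral"
    """

    temperature: float = 300.0
    order: int = 20
    mode: str = "maclaurin"
    use_boost: str = "sum"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.mode not in ("exponential", "maclaurin"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.use_boost not in ("sum", "total", "dihedral"):
            raise ValueError(f"unknown use_boost {self.use_boost!r}")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


@dataclass
class AMDParams:
    """Dual-boost thresholds (E) and smoothing constants (α), kcal/mol."""

    e_dih: float
    alpha_dih: float
    e_tot: float
    alpha_tot: float

    def __post_init__(self) -> None:
        if self.alpha_dih <= 0 or self.alpha_tot <= 0:
            raise ValueError("alpha parameters must be > 0")


@dataclass
class FES2D:
    """Reweighted free-energy surface on a 2D grid.

    ``occupied`` marks bins with any sampled weight; ``free_energy`` is NaN
    on unoccupied bins (explicitly "not sampled", not zero energy) and has
    its minimum at exactly 0 over occupied bins.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray
    occupied: np.ndarray
    temperature: float


def _select_dv(dv: BoostSeries, use_boost: str) -> np.ndarray:
    if use_boost == "sum":
        return dv.dv_dihedral + dv.dv_total
    if use_boost == "total":
        return dv.dv_total.copy()
    return dv.dv_dihedral.copy()


def maclaurin_factor(bdv: np.ndarray, order: int) -> np.ndarray:
    """Σ_{n=0..order} (βΔV)^n / n!, evaluated stably by running products."""
    bdv = np.asarray(bdv, dtype=float)
    acc = np.ones_like(bdv)
    term = np.ones_like(bdv)
    for n in range(1, order + 1):
        term = term * bdv / n
        acc = acc + term
    return acc


def compute_weights(dv: BoostSeries, params: WeightParams | None = None) -> np.ndarray:
    """Per-frame statistical weights, normalized to sum to 1.

    Raw weights are exp(β ΔV) in exponential mode or the order-truncated
    Maclaurin series of the exponential otherwise; ΔV per frame is chosen
    by ``params.use_boost`` (dual-boost default: dihedral + total).
    """
    params = params or WeightParams()
    total = _select_dv(dv, params.use_boost)
    if not np.isfinite(total).all():
        raise ValueError("boost energies must be finite")
    bdv = params.beta * total
    if params.mode == "exponential":
        # shift by max before exponentiating; cancels on normalization
        raw = np.exp(bdv - bdv.max())
    else:
        if params.order == 0:
            warnings.warn("Maclaurin order 0: all raw weights are 1", stacklevel=2)
        raw = maclaurin_factor(bdv, params.order)
    s = raw.sum()
    if s <= 0 or not np.isfinite(s):
        raise ValueError("degenerate weights: non-finite or zero normalization")
    return raw / s


def reweighted_histogram(
    values: np.ndarray, weights: np.ndarray, edges: np.ndarray
) -> tuple[np.ndarray, float]:
    """Weighted histogram probabilities over half-open bins [lo, hi)
    (last bin closed). Returns ``(probabilities, overflow)`` where
    ``overflow`` is the total weight of values outside the edge range."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    inside = (values >= edges[0]) & (values <= edges[-1])
    hist, _ = np.histogram(values[inside], bins=edges, weights=weights[inside])
    overflow = float(weights[~inside].sum())
    return hist, overflow


def free_energy_surface(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    temperature: float = 300.0,
) -> FES2D:
    """Reweighted 2D free-energy surface F = −k_B T ln(p / p_max).

    The most probable bin sits at F = 0; bins with zero sampled weight are
    flagged unoccupied and carry NaN free energy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (len(x) == len(y) == len(weights)):
        raise ValueError("x, y and weights must have equal length")
    prob, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges], weights=weights)
    total = prob.sum()
    if total > 0:
        prob = prob / total
    occupied = prob > 0
    if occupied.sum() <= 1:
        warnings.warn("degenerate free-energy surface: all frames in one bin", stacklevel=2)
    fes = np.full_like(prob, np.nan)
    if occupied.any():
        pmax = prob.max()
        fes[occupied] = -KB * temperature * np.log(prob[occupied] / pmax)
    return FES2D(
        x_edges=np.asarray(x_edges, dtype=float),
        y_edges=np.asarray(y_edges, dtype=float),
        probability=prob,
        free_energy=fes,
        occupied=occupied,
        temperature=temperature,
    )


# Per-movable-dihedral boost coefficients following the Pierce protocol:
# threshold offset 3.5 kcal/mol and α = 3.5/5 kcal/mol per dihedral.
DIH_THRESHOLD_PER_DIHEDRAL = 3.5
DIH_ALPHA_PER_DIHEDRAL = 3.5 / 5.0
# Per-atom total-potential coefficients: 0.2 kcal/mol/atom in aqueous-like
# solvents; raised to 0.56 for DMSO (more internal degrees of freedom).
TOT_OFFSET_PER_ATOM = {"aqueous_like": 0.2, "dmso": 0.56}
TOT_ALPHA_PER_ATOM = 0.2
# α floor keeping AMDParams valid when no dihedral is movable (e_dih then
# equals the average dihedral energy, i.e. a zero boost window anyway).
_ALPHA_FLOOR = 1e-6


def dual_boost_params(
    avg_dihedral_energy: float,
    avg_total_potential: float,
    n_free_backbone_dihedrals: int,
    n_atoms: int,
    solvent_class: str = "aqueous_like",
    dih_threshold_coeff: float = DIH_THRESHOLD_PER_DIHEDRAL,
    dih_alpha_coeff: float = DIH_ALPHA_PER_DIHEDRAL,
    tot_offset_per_atom: float | None = None,
    tot_alpha_per_atom: float = TOT_ALPHA_PER_ATOM,
) -> AMDParams:
    """Dual-boost parameters from system size.

    The dihedral threshold scales with the number of freely movable
    backbone dihedrals; the total-potential threshold sits a per-atom
    offset above the average unbiased potential (0.56 kcal/mol·atom in
    DMSO, 0.2 otherwise).
    """
    if n_atoms <= 0:
        raise ValueError("n_atoms must be > 0")
    if n_free_backbone_dihedrals < 0:
        raise ValueError("n_free_backbone_dihedrals must be >= 0")
    if solvent_class not in TOT_OFFSET_PER_ATOM:
        raise ValueError(f"unknown solvent_class {solvent_class!r}")
    if tot_offset_per_atom is None:
        tot_offset_per_atom = TOT_OFFSET_PER_ATOM[solvent_class]
    e_dih = avg_dihedral_energy + dih_threshold_coeff * n_free_backbone_dihedrals
    alpha_dih = max(dih_alpha_coeff * n_free_backbone_dihedrals, _ALPHA_FLOOR)
    e_tot = avg_total_potential + tot_offset_per_atom * n_atoms
    alpha_tot = max(tot_alpha_per_atom * n_atoms, _ALPHA_FLOOR)
    return AMDParams(e_dih=e_dih, alpha_dih=alpha_dih, e_tot=e_tot, alpha_tot=alpha_tot)


def boost_energy(v: np.ndarray | float, e: float, alpha: float) -> np.ndarray | float:
    """aMD boost ΔV(v) = (E − v)² / (α + E − v) for v < E, else 0."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    v_arr = np.asarray(v, dtype=float)
    gap = np.maximum(e - v_arr, 0.0)
    dv = gap**2 / (alpha + gap)  # alpha > 0 keeps the denominator positive
    if np.isscalar(v) or v_arr.ndim == 0:
        return float(dv)
    return dv
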