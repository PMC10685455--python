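"""Conformer-averaged partial charges.

Partial charges fitted to a single conformer inherit that conformer's
conformational bias (a charge set derived from a high-free-energy state
misrepresents the ensemble). Plain per-atom averaging over several
independently generated conformers (default 10) neutralizes single-
conformer inaccuracies. Charges are in elementary-charge units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChargeSet",
    "read_charge_table",
    "write_charge_table",
    "average_charges",
    "validate_charges",
    "charge_spread",
    "DEFAULT_CONFORMER_COUNT",
]

DEFAULT_CONFORMER_COUNT = 10


@dataclass
class ChargeSet:
    charges: np.ndarray
    conformer_id: str = ""

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.ndim != 1:
            raise ValueError("charges must be a 1D per-atom array")

    @property
    def total(self) -> float:
        return float(self.charges.sum())

    def __len__(self) -> int:
        return len(self.charges)


def read_charge_table(path: str, conformer_id: str | None = None) -> ChargeSet:
    """Read a plain-text charge table: one float per line, '#' comments."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values.append(float(stripped.split()[0]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: not a number") from exc
    if not values:
        raise ValueError(f"{path}: no charges found (empty input)")
    return ChargeSet(np.array(values), conformer_id or path)


def write_charge_table(cs: ChargeSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# conformer: {cs.conformer_id}\n")
        for q in cs.charges:
            fh.write(f"{q:.10f}\n")


def average_charges(sets: list[ChargeSet]) -> ChargeSet:
    """Element-wise arithmetic mean over conformers (identical atom order
    assumed)."""
    if not sets:
        raise ValueError("need at least one charge set")
    n = len(sets[0])
    for cs in sets:
        if len(cs) != n:
            raise ValueError(
                f"charge-set length mismatch: {len(cs)} vs {n} (atom orders differ?)"
            )
    if len(sets) < DEFAULT_CONFORMER_COUNT:
        warnings.warn(
            f"averaging over {len(sets)} conformers "
            f"(fewer than the recommended {DEFAULT_CONFORMER_COUNT})",
            stacklevel=2,
        )
    mean = np.mean([cs.charges for cs in sets], axis=0)
    return ChargeSet(mean, conformer_id=f"averaged({len(sets)})")


@dataclass
class ChargeValidation:
    passed: bool
    deviation: float  # |Σq − formal charge|, e
    outliers: list[tuple[int, float]]  # (atom index, charge) beyond magnitude cutoff


def validate_charges(
    cs: ChargeSet, formal_charge: int, tol: float = 1e-4, outlier_magnitude: float = 1.5
) -> ChargeValidation:
    """Check the total charge against the formal charge and flag per-atom
    outliers beyond ``outlier_magnitude``."""
    deviation = abs(cs.total - formal_charge)
    outliers = [
        (int(i), float(q)) for i, q in enumerate(cs.charges) if abs(q) > outlier_magnitude
    ]
    return ChargeValidation(passed=deviation <= tol, deviation=deviation, outliers=outliers)


def charge_spread(sets: list[ChargeSet]) -> np.ndarray:
    """Per-atom sample standard deviation (ddof=1) across conformers."""
    if len(sets) < 2:
        raise ValueError("charge_spread needs at least 2 conformer sets")
    n = len(sets[0])
    for cs in sets:
        if len(cs) != n:
            raise ValueError("charge-set length mismatch")
    return np.std([cs.charges for cs in sets], axis=0, ddof=1)
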