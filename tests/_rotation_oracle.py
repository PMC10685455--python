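"""Brute-force superposition oracle, independent of the Kabsch/SVD route."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD over rotations via a coarse Euler-angle grid followed
    by Nelder-Mead refinement (no SVD involved)."""
    ac = a - a.mean(0)
    bc = b - b.mean(0)

    def rmsd_of(euler):
        rot = Rotation.from_euler("zyx", euler).as_matrix()
        return np.sqrt(((ac @ rot.T - bc) ** 2).sum() / len(a))

    best, best_e = np.inf, None
    grid = np.linspace(-np.pi, np.pi, 13)
    for e1 in grid:
        for e2 in np.linspace(-np.pi / 2, np.pi / 2, 7):
            for e3 in grid:
                r = rmsd_of([e1, e2, e3])
                if r < best:
                    best, best_e = r, [e1, e2, e3]
    res = minimize(rmsd_of, best_e, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 10_000})
    return float(min(best, res.fun))
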