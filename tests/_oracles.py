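"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they verify: the motif oracle is a
direct window enumeration with its own complement table, and the
superposition oracle searches rotation space (random quaternions + local
simplex refinement) instead of solving the Kabsch problem in closed form.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_hits(seq: str, consensus: str, max_mismatch: int) -> set[tuple[int, str]]:
    """All (start, strand) motif windows within max_mismatch, by enumeration."""
    s = seq.upper()
    cons = consensus.upper()
    L = len(cons)
    found: set[tuple[int, str]] = set()
    for start in range(len(s) - L + 1):
        window = s[start : start + L]
        mm_plus = sum(
            1 for a, b in zip(window, cons) if a not in _COMP or a != b
        )
        if mm_plus <= max_mismatch:
            found.add((start, "+"))
        site = "".join(_COMP.get(c, "N") for c in reversed(window))
        mm_minus = sum(1 for a, b in zip(site, cons) if a not in _COMP or a != b)
        if mm_minus <= max_mismatch:
            found.add((start, "-"))
    return found


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_search_rmsd(
    reference: np.ndarray, mobile: np.ndarray, n_candidates: int = 600, seed: int = 0
) -> float:
    """Minimum RMSD over proper rotations by quaternion search.

    Centers both point sets, evaluates the RMSD at ``n_candidates`` random
    unit quaternions, then refines the best few by Nelder-Mead on the
    quaternion components.  Independent of the closed-form solution.
    """
    a = reference - reference.mean(axis=0)
    b = mobile - mobile.mean(axis=0)
    n = a.shape[0]

    def rmsd_of(q: np.ndarray) -> float:
        r = _quat_to_matrix(q)
        return float(np.sqrt(np.sum((b @ r.T - a) ** 2) / n))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_candidates, 4))
    scores = np.array([rmsd_of(q) for q in quats])
    best = np.inf
    for idx in np.argsort(scores)[:5]:
        res = minimize(
            rmsd_of,
            quats[idx] / np.linalg.norm(quats[idx]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        best = min(best, float(res.fun))
    return best
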