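"""Independent reference implementations used only by the tests.

These deliberately avoid the code paths of the package: the RMSD oracle uses
the quaternion characteristic-polynomial route (4x4 eigenproblem) instead of
the package's SVD Kabsch; the component oracle uses breadth-first search on an
explicit cell set instead of ``scipy.ndimage`` labelling.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def quaternion_rmsd_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form minimum RMSD between two paired point sets."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    p = x - x.mean(axis=0)
    q = y - y.mean(axis=0)
    g = float((p**2).sum() + (q**2).sum())
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, sxz + szx],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, sxz + szx, syz + szy, -sxx - syy + szz],
        ]
    )
    lam_max = float(np.linalg.eigvalsh(k)[-1])
    return float(np.sqrt(max(0.0, (g - 2.0 * lam_max) / n)))


def connected_components_oracle(cells: set[tuple[int, int, int]]) -> list[set]:
    """6-connected components of a voxel set by breadth-first search."""
    remaining = set(cells)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            cx, cy, cz = queue.popleft()
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nb = (cx + dx, cy + dy, cz + dz)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation (QR-based) and a random translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return q, t
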