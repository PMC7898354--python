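"""Independent brute-force oracles shared by the test modules."""

import numpy as np
from scipy.spatial.transform import Rotation


def quaternion_grid_rmsd(mobile, target):
    """Brute-force orientation search: dense random rotations + refinement.

    Deliberately independent of the closed-form superposition it checks.
    """
    rng = np.random.default_rng(0)
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)
    best = np.inf
    best_q = None
    for q in Rotation.random(4000, random_state=rng):
        r = np.sqrt(np.mean(np.sum((a @ q.as_matrix().T - b) ** 2, axis=1)))
        if r < best:
            best, best_q = r, q
    for scale in (0.1, 0.03, 0.01, 0.003, 0.001, 3e-4, 1e-4, 3e-5, 1e-5):
        for _ in range(200):
            q = best_q * Rotation.from_rotvec(scale * rng.standard_normal(3))
            r = np.sqrt(np.mean(np.sum((a @ q.as_matrix().T - b) ** 2, axis=1)))
            if r < best:
                best, best_q = r, q
    return best
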