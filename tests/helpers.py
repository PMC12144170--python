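"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the triangle
intersection oracle uses the separating-axis theorem rather than the
interval test, and the healing-zone oracle is a scalar if/else transcription
of the published rules.
"""

from __future__ import annotations

import numpy as np


def sat_tri_tri(T1: np.ndarray, T2: np.ndarray) -> np.ndarray:
    """Separating-axis intersection test for paired triangles (n,3,3)."""
    e1 = [T1[:, 1] - T1[:, 0], T1[:, 2] - T1[:, 1], T1[:, 0] - T1[:, 2]]
    e2 = [T2[:, 1] - T2[:, 0], T2[:, 2] - T2[:, 1], T2[:, 0] - T2[:, 2]]
    axes = [np.cross(e1[0], e1[1]), np.cross(e2[0], e2[1])]
    for a in e1:
        for b in e2:
            axes.append(np.cross(a, b))
    separated = np.zeros(T1.shape[0], dtype=bool)
    for ax in axes:
        valid = np.linalg.norm(ax, axis=1) > 1e-12
        p1 = np.einsum("nij,nj->ni", T1, ax)
        p2 = np.einsum("nij,nj->ni", T2, ax)
        gap = (p1.min(1) > p2.max(1) + 1e-12) | (p2.min(1) > p1.max(1) + 1e-12)
        separated |= gap & valid
    return ~separated


def dense_first_contact(scene, coarse_step=0.05, fine_step=0.005,
                        max_angle=40.0) -> float | None:
    """Brute-force first-contact angle on the scene's meshes (positive sweep)."""
    from fracturetwin.kinematics import rotate_vertices

    statics = [scene.radius_mesh, scene.ulna_mesh]
    tbs = [m.vertices[m.faces] for m in statics]
    bounds = [(tb.min(1), tb.max(1)) for tb in tbs]
    carp = scene.carpal_mesh

    def contact(angle: float) -> bool:
        v = rotate_vertices(carp.vertices, scene.rotation_center,
                            scene.rotation_axis, angle)
        ta = v[carp.faces]
        lo_a, hi_a = ta.min(1), ta.max(1)
        for tb, (lo_b, hi_b) in zip(tbs, bounds):
            ov = np.ones((len(ta), len(tb)), dtype=bool)
            for ax in range(3):
                ov &= (lo_a[:, None, ax] <= hi_b[None, :, ax])
                ov &= (hi_a[:, None, ax] >= lo_b[None, :, ax])
            ii, jj = np.nonzero(ov)
            if ii.size and sat_tri_tri(ta[ii], tb[jj]).any():
                return True
        return False

    coarse = np.arange(0.0, max_angle + 1e-9, coarse_step)
    hit = next((a for a in coarse if contact(a)), None)
    if hit is None:
        return None
    fine = np.arange(max(0.0, hit - coarse_step), hit + 1e-9, fine_step)
    return float(next((a for a in fine if contact(a)), hit))


def zone_oracle(gamma: float, eps_vol: float, cfg) -> str:
    """Scalar transcription of the healing-zone rules."""
    if gamma < cfg.gamma_low and abs(eps_vol) < cfg.eps_low:
        return "understimulated"
    if gamma <= cfg.gamma_im and abs(eps_vol) <= cfg.eps_im:
        return "intramembranous"
    if (gamma <= cfg.gamma_ec and cfg.eps_ec_compressive <= eps_vol
            <= cfg.eps_ec_tensile):
        return "endochondral"
    return "excessive"


def random_rotations(n: int, seed: int = 0) -> np.ndarray:
    """(n, 3, 3) uniformly distributed rotation matrices (QR of Gaussians)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, 3, 3))
    Q, R = np.linalg.qr(A)
    sign = np.sign(np.einsum("nii->ni", R))
    Q = Q * sign[:, None, :]
    det = np.linalg.det(Q)
    Q[det < 0, :, 0] *= -1.0
    return Q
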