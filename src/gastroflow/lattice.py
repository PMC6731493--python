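"""D3Q19 stencil and multiple-relaxation-time (MRT) collision matrices.

The moment basis is the standard orthogonal D3Q19 set (density, energy,
energy square, momentum, energy flux, second-order stress and third-order
moments).  Equilibrium moments are taken as the moments of the second-order
Maxwellian equilibrium, so setting every relaxation rate equal to ``1/tau``
reduces the MRT collision exactly to BGK.  Only the shear-stress rate is
physics-bound (``s_nu = 1/tau``); the remaining rates default to common
stabilizing values and are configurable.
"""

from __future__ import annotations

import numpy as np

# velocity set: rest, 6 axis, 12 edge-diagonal
C = np.array(
    [
        (0, 0, 0),
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 0), (-1, -1, 0), (1, -1, 0), (-1, 1, 0),
        (1, 0, 1), (-1, 0, -1), (1, 0, -1), (-1, 0, 1),
        (0, 1, 1), (0, -1, -1), (0, 1, -1), (0, -1, 1),
    ],
    dtype=np.int64,
)

W = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)

OPP = np.array(
    [np.where((C == -c).all(axis=1))[0][0] for c in C], dtype=np.int64
)

CS2 = 1.0 / 3.0


def moment_matrix() -> np.ndarray:
    """Orthogonal D3Q19 moment-transform matrix (rows = moments)."""
    cx, cy, cz = C[:, 0].astype(float), C[:, 1].astype(float), C[:, 2].astype(float)
    c2 = cx**2 + cy**2 + cz**2
    rows = [
        np.ones(19),
        19 * c2 - 30,                         # energy
        (21 * c2**2 - 53 * c2 + 24) / 2,      # energy^2
        cx, (5 * c2 - 9) * cx,                # j_x, q_x
        cy, (5 * c2 - 9) * cy,
        cz, (5 * c2 - 9) * cz,
        3 * cx**2 - c2, (3 * c2 - 5) * (3 * cx**2 - c2),
        cy**2 - cz**2, (3 * c2 - 5) * (cy**2 - cz**2),
        cx * cy, cy * cz, cx * cz,
        (cy**2 - cz**2) * cx, (cz**2 - cx**2) * cy, (cx**2 - cy**2) * cz,
    ]
    return np.array(rows)


M = moment_matrix()
M_INV = M.T / np.einsum("ij,ij->i", M, M)  # rows are mutually orthogonal

# moment indices
_SHEAR = [9, 11, 13, 14, 15]
_CONSERVED = [0, 3, 5, 7]


def magic_odd_rate(tau: float, magic: float = 3.0 / 16.0) -> float:
    """Odd-moment rate from the TRT 'magic' relation.

    (1/s_nu - 1/2)(1/s_odd - 1/2) = magic; 3/16 places half-way bounce-back
    walls exactly on the link midpoint independent of viscosity.
    """
    return 1.0 / (0.5 + magic / (tau - 0.5))


def relaxation_rates(
    tau: float,
    s_e: float = 1.19,
    s_eps: float = 1.4,
    s_q: float | None = None,
    s_pi: float = 1.4,
    s_m: float | None = None,
    bgk: bool = False,
) -> np.ndarray:
    """Diagonal of the moment-space relaxation matrix S for viscosity tau.

    ``s_q``/``s_m`` (odd moments) default to the magic-relation value, which
    removes the viscosity-dependent wall slip of bounce-back.
    """
    omega = 1.0 / tau
    if bgk:
        return np.full(19, omega)
    if s_q is None:
        s_q = magic_odd_rate(tau)
    if s_m is None:
        s_m = magic_odd_rate(tau)
    s = np.empty(19)
    s[:] = s_e
    s[0] = s[3] = s[5] = s[7] = 0.0  # conserved: rate irrelevant
    s[1] = s_e
    s[2] = s_eps
    s[4] = s[6] = s[8] = s_q
    s[10] = s[12] = s_pi
    for k in _SHEAR:
        s[k] = omega
    s[16] = s[17] = s[18] = s_m
    return s


def collision_matrix(rates: np.ndarray) -> np.ndarray:
    """A = M^-1 S M: velocity-space collision operator, f' = f - A (f - feq)."""
    return (M_INV * rates[None, :]) @ M


def feq(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order equilibrium; u shape (..., 3), returns (..., 19)."""
    cu = np.tensordot(u, C.astype(float), axes=([-1], [1]))  # (..., 19)
    usq = np.sum(u**2, axis=-1)[..., None]
    return W * np.asarray(rho)[..., None] * (1 + 3 * cu + 4.5 * cu**2 - 1.5 * usq)
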