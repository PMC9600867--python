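"""Isoparametric 6-node triangle kernels shared by the solver and analysis.

Reference element: area coordinates (L1, L2, L3) with L1 = 1 - xi - eta,
nodes 0..2 at the corners, 3..5 at edge midpoints of (0,1), (1,2), (2,0).
Quadrature rules on the reference triangle: the classic 3-point degree-2
rule (default for assembly; mildly reduced integration also eases volumetric
locking under the penalty) and a 6-point degree-4 rule.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "tri6_shape",
    "tri6_reference_data",
    "edge3_reference_data",
    "element_gradients",
    "deformation_gradients",
]

_rule_cache: dict = {}


def _quad_rule(n_quad: int):
    if n_quad == 3:
        pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
        w = np.full(3, 1 / 6)
    elif n_quad == 6:
        # Dunavant degree-4 rule
        a, b = 0.445948490915965, 0.091576213509771
        wa, wb = 0.223381589678011 / 2, 0.109951743655322 / 2
        pts = np.array(
            [
                [a, a], [1 - 2 * a, a], [a, 1 - 2 * a],
                [b, b], [1 - 2 * b, b], [b, 1 - 2 * b],
            ]
        )
        w = np.array([wa, wa, wa, wb, wb, wb])
    else:
        raise ValueError("supported triangle rules: 3 or 6 points")
    return pts, w


def tri6_shape(xi, eta):
    """Shape functions and reference derivatives at one point.

    Returns (N (6,), dN (6, 2)).
    """
    L1, L2, L3 = 1.0 - xi - eta, xi, eta
    N = np.array(
        [
            L1 * (2 * L1 - 1),
            L2 * (2 * L2 - 1),
            L3 * (2 * L3 - 1),
            4 * L1 * L2,
            4 * L2 * L3,
            4 * L3 * L1,
        ]
    )
    dL = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # dL_a/d(xi,eta)
    dN = np.array(
        [
            (4 * L1 - 1) * dL[0],
            (4 * L2 - 1) * dL[1],
            (4 * L3 - 1) * dL[2],
            4 * (L1 * dL[1] + L2 * dL[0]),
            4 * (L2 * dL[2] + L3 * dL[1]),
            4 * (L3 * dL[0] + L1 * dL[2]),
        ]
    )
    return N, dN


def tri6_reference_data(n_quad: int = 3):
    """(N (nq,6), dN (nq,6,2), w (nq,)) tabulated at the quadrature points."""
    key = ("tri6", n_quad)
    if key not in _rule_cache:
        pts, w = _quad_rule(n_quad)
        N = np.empty((len(pts), 6))
        dN = np.empty((len(pts), 6, 2))
        for q, (xi, eta) in enumerate(pts):
            N[q], dN[q] = tri6_shape(xi, eta)
        _rule_cache[key] = (N, dN, w)
    return _rule_cache[key]


def edge3_reference_data(n_quad: int = 3):
    """Quadratic 1D edge [n0, n1, mid] on xi in [-1, 1]: (N, dN, w)."""
    key = ("edge3", n_quad)
    if key not in _rule_cache:
        xi, w = np.polynomial.legendre.leggauss(n_quad)
        N = np.stack([xi * (xi - 1) / 2, xi * (xi + 1) / 2, 1 - xi * xi], axis=1)
        dN = np.stack([xi - 0.5, xi + 0.5, -2 * xi], axis=1)
        _rule_cache[key] = (N, dN, w)
    return _rule_cache[key]


def element_gradients(nodes, elements, n_quad: int = 3):
    """Precompute physical shape-function gradients and weighted Jacobians.

    Returns (gradN (nel, nq, 6, 2), wdetJ (nel, nq)) in the reference
    configuration.  Raises on non-positive isoparametric Jacobians.
    """
    _N, dN, w = tri6_reference_data(n_quad)
    X = nodes[elements]                                # (nel, 6, 2)
    Jac = np.einsum("eai,qaj->eqij", X, dN)            # dx/dxi
    detJ = np.linalg.det(Jac)
    if np.any(detJ <= 0):
        bad = np.argwhere(detJ <= 0)[0]
        raise ValueError(
            f"non-positive isoparametric Jacobian in element {int(bad[0])}"
        )
    invJ = np.linalg.inv(Jac)
    gradN = np.einsum("qaj,eqji->eqai", dN, invJ)       # dN_a/dx_i
    return gradN, w[None, :] * detJ


def deformation_gradients(u_elems, gradN):
    """In-plane deformation gradients F (nel, nq, 2, 2) from element dofs.

    ``u_elems`` is (nel, 6, 2) nodal displacements; F = I + du/dX.
    """
    F = np.einsum("eai,eqaj->eqij", u_elems, gradN)
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    return F
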