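"""Three-parameter Yeoh hyperelasticity for plaque tissue.

The strain energy is evaluated on the isochoric first invariant
``I1_bar = J^(-2/3) tr(C)`` with a quadratic volumetric penalty enforcing
quasi-incompressibility:

    W(F) = c1 (I1_bar - 3) + c2 (I1_bar - 3)^2 + c3 (I1_bar - 3)^3
           + kappa/2 (J - 1)^2

All stress-like constants are in Pa.  The initial shear modulus of the model
is ``mu0 = 2 c1``; the default penalty modulus is ``kappa = 1000 mu0``, which
keeps ``|J - 1|`` at convergence around 1e-4..1e-3 for arterial loads.

Kinematics are plane strain: a 2x2 in-plane deformation gradient is embedded
into a 3x3 gradient with unit out-of-plane stretch.  All tensor functions
below accept batched arrays of 3x3 gradients (leading dimensions arbitrary)
so the finite-element assembly can evaluate whole element blocks at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import TissueLabel

__all__ = [
    "YeohMaterial",
    "MaterialTable",
    "KinematicState",
    "table2_presets",
    "strain_energy",
    "cauchy_stress",
    "first_piola_stress",
    "material_tangent",
]

#: default ratio kappa / mu0 for quasi-incompressibility
DEFAULT_KAPPA_RATIO = 1000.0


@dataclass(frozen=True)
class YeohMaterial:
    """Yeoh constants ``c1, c2, c3`` (Pa) plus volumetric penalty ``kappa``.

    ``kappa`` defaults to ``1000 * 2 c1`` (near-incompressible regime); a
    larger value may be supplied, a smaller one is rejected.
    """

    c1: float
    c2: float
    c3: float
    kappa: float | None = None
    name: str = ""

    def __post_init__(self):
        if not self.c1 > 0:
            raise ValueError(f"c1 must be positive, got {self.c1}")
        kappa = self.kappa
        if kappa is None:
            kappa = DEFAULT_KAPPA_RATIO * self.mu0
            object.__setattr__(self, "kappa", kappa)
        if kappa < DEFAULT_KAPPA_RATIO * self.mu0 * (1 - 1e-12):
            raise ValueError(
                f"kappa={kappa:g} below the near-incompressible floor "
                f"{DEFAULT_KAPPA_RATIO * self.mu0:g} (= 1000 * 2 c1)"
            )

    @property
    def mu0(self) -> float:
        """Initial (small-strain) shear modulus, 2 c1."""
        return 2.0 * self.c1

    def with_kappa_ratio(self, ratio: float) -> "YeohMaterial":
        """Copy of this material with ``kappa = ratio * mu0``."""
        return YeohMaterial(self.c1, self.c2, self.c3, ratio * self.mu0, self.name)

    def dW_dI1(self, x):
        """Derivative of the Yeoh polynomial w.r.t. I1_bar at x = I1_bar - 3."""
        return self.c1 + 2.0 * self.c2 * x + 3.0 * self.c3 * x * x


@dataclass(frozen=True)
class MaterialTable:
    """Mapping of every tissue label to a Yeoh material."""

    materials: dict

    def __post_init__(self):
        mats = {TissueLabel.from_any(k): v for k, v in self.materials.items()}
        missing = [lab.name for lab in TissueLabel if lab not in mats]
        if missing:
            raise ValueError(f"material table missing tissue labels: {missing}")
        object.__setattr__(self, "materials", mats)

    def __getitem__(self, label) -> YeohMaterial:
        return self.materials[TissueLabel.from_any(label)]

    def with_kappa_ratio(self, ratio: float) -> "MaterialTable":
        return MaterialTable(
            {k: v.with_kappa_ratio(ratio) for k, v in self.materials.items()}
        )

    def substitute(self, label, material: YeohMaterial) -> "MaterialTable":
        """Table with one tissue's material replaced (e.g. CALC -> MATX props)."""
        mats = dict(self.materials)
        mats[TissueLabel.from_any(label)] = material
        return MaterialTable(mats)


def table2_presets(kappa_ratio: float = DEFAULT_KAPPA_RATIO) -> MaterialTable:
    """Literature material presets for the three plaque tissue classes (Pa).

    MATX is the fibrous/cellular matrix, CALC macro-calcification, LRNC the
    lipid-rich necrotic core.  CALC is an order of magnitude stiffer than the
    soft tissues (mu0 = 6.04e5 Pa vs 4.70e4 / 5.92e4 Pa), which is what makes
    it load-bearing.
    """
    mk = lambda c1, c2, c3, name: YeohMaterial(
        c1, c2, c3, kappa_ratio * 2.0 * c1, name
    )
    return MaterialTable(
        {
            TissueLabel.MATX: mk(2.35e4, 1.26e5, 1.12e5, "MATX"),
            TissueLabel.CALC: mk(3.02e5, -2.28e5, 2.61e5, "CALC"),
            TissueLabel.LRNC: mk(2.96e4, -3.32e4, 1.29e5, "LRNC"),
        }
    )


@dataclass
class KinematicState:
    """Deformation gradient container with derived invariants.

    ``F`` is 3x3 (or batched ...x3x3).  A 2x2 in-plane gradient is embedded
    with unit out-of-plane stretch via :meth:`from_plane_strain`.
    """

    F: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape[-2:] != (3, 3):
            raise ValueError("F must be (...,3,3); use from_plane_strain for 2x2")
        self.F = F
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise ValueError("non-positive J: inverted deformation state")

    @classmethod
    def from_plane_strain(cls, F2: np.ndarray) -> "KinematicState":
        F2 = np.asarray(F2, dtype=float)
        return cls(embed_plane_strain(F2))

    @property
    def J(self):
        return np.linalg.det(self.F)

    @property
    def C(self):
        return np.swapaxes(self.F, -1, -2) @ self.F

    @property
    def I1_bar(self):
        J = self.J
        I1 = np.einsum("...ij,...ij->...", self.F, self.F)
        return J ** (-2.0 / 3.0) * I1


def embed_plane_strain(F2: np.ndarray) -> np.ndarray:
    """Embed a (...,2,2) in-plane gradient into (...,3,3) with F33 = 1."""
    F2 = np.asarray(F2, dtype=float)
    out = np.zeros(F2.shape[:-2] + (3, 3), dtype=float)
    out[..., :2, :2] = F2
    out[..., 2, 2] = 1.0
    return out


def _invariants(F):
    """Return (J, H=F^{-T}, I1, I1_bar) for batched 3x3 gradients."""
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("non-positive J: inverted deformation state")
    H = np.swapaxes(np.linalg.inv(F), -1, -2)
    I1 = np.einsum("...ij,...ij->...", F, F)
    I1b = J ** (-2.0 / 3.0) * I1
    return J, H, I1, I1b


def strain_energy(material: YeohMaterial, state: KinematicState | np.ndarray):
    """Yeoh strain-energy density W(F) in Pa; zero at the reference state."""
    F = state.F if isinstance(state, KinematicState) else np.asarray(state, float)
    J, _, _, I1b = _invariants(F)
    x = I1b - 3.0
    W = material.c1 * x + material.c2 * x**2 + material.c3 * x**3
    W = W + 0.5 * material.kappa * (J - 1.0) ** 2
    return W


def first_piola_stress(material: YeohMaterial, F: np.ndarray) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF for batched 3x3 gradients."""
    F = np.asarray(F, dtype=float)
    J, H, _, I1b = _invariants(F)
    x = I1b - 3.0
    Wp = material.dW_dI1(x)
    Jm23 = J ** (-2.0 / 3.0)
    # dI1_bar/dF = 2 J^{-2/3} F - (2/3) I1_bar F^{-T}
    G = 2.0 * Jm23[..., None, None] * F - (2.0 / 3.0) * I1b[..., None, None] * H
    P = Wp[..., None, None] * G
    P = P + (material.kappa * (J - 1.0) * J)[..., None, None] * H
    return P


def cauchy_stress(material: YeohMaterial, state: KinematicState | np.ndarray):
    """Cauchy stress sigma = P F^T / J; symmetric, zero at F = I."""
    F = state.F if isinstance(state, KinematicState) else np.asarray(state, float)
    P = first_piola_stress(material, F)
    J = np.linalg.det(F)
    return P @ np.swapaxes(F, -1, -2) / J[..., None, None]


def material_tangent(material: YeohMaterial, state: KinematicState | np.ndarray):
    """First-elasticity tensor A_iJkL = d2W / dF_iJ dF_kL (batched ...x3x3x3x3).

    As a second derivative of the energy it carries major symmetry
    A_iJkL = A_kLiJ; it is the consistent linearization used by Newton's
    method (the Cauchy-stress linearization follows by push-forward).
    """
    F = state.F if isinstance(state, KinematicState) else np.asarray(state, float)
    F = np.asarray(F, dtype=float)
    J, H, _, I1b = _invariants(F)
    x = I1b - 3.0
    Wp = material.dW_dI1(x)
    Wpp = 2.0 * material.c2 + 6.0 * material.c3 * x
    Jm23 = J ** (-2.0 / 3.0)
    G = 2.0 * Jm23[..., None, None] * F - (2.0 / 3.0) * I1b[..., None, None] * H

    eye = np.eye(3)
    # dH_iJ/dF_kL = -H_iL H_kJ
    dH = -np.einsum("...il,...kj->...ijkl", H, H)
    # dG_iJ/dF_kL
    dG = (
        -(4.0 / 3.0) * Jm23[..., None, None, None, None]
        * np.einsum("...ij,...kl->...ijkl", F, H)
        + 2.0 * Jm23[..., None, None, None, None]
        * np.einsum("ik,jl->ijkl", eye, eye)
        - (2.0 / 3.0) * np.einsum("...kl,...ij->...ijkl", G, H)
        - (2.0 / 3.0) * I1b[..., None, None, None, None] * dH
    )
    A = (
        Wpp[..., None, None, None, None] * np.einsum("...ij,...kl->...ijkl", G, G)
        + Wp[..., None, None, None, None] * dG
        + (material.kappa * (2.0 * J - 1.0) * J)[..., None, None, None, None]
        * np.einsum("...ij,...kl->...ijkl", H, H)
        + (material.kappa * (J - 1.0) * J)[..., None, None, None, None] * dH
    )
    return A
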