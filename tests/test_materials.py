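"""Constitutive layer: Yeoh energy, stress, tangent, tissue presets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaquestretch.labels import TissueLabel
from plaquestretch.materials import (
    KinematicState,
    YeohMaterial,
    cauchy_stress,
    first_piola_stress,
    material_tangent,
    strain_energy,
    table2_presets,
)

PRESET_CONSTANTS = {
    TissueLabel.MATX: (2.35e4, 1.26e5, 1.12e5),
    TissueLabel.CALC: (3.02e5, -2.28e5, 2.61e5),
    TissueLabel.LRNC: (2.96e4, -3.32e4, 1.29e5),
}


def _random_states(n, scale=0.05, seed=0):
    """Random 3x3 gradients with J near 1 (volumetric part mild)."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.5:
            out.append(F)
    return out


@pytest.mark.parametrize("label", list(TissueLabel))
def test_preset_constants_and_kappa(label, presets):
    mat = presets[label]
    c1, c2, c3 = PRESET_CONSTANTS[label]
    assert (mat.c1, mat.c2, mat.c3) == (c1, c2, c3)
    assert mat.kappa == pytest.approx(1000.0 * 2.0 * c1)


def test_stiffness_ordering(presets):
    """CALC is the stiffest tissue, MATX the softest (initial shear moduli)."""
    mu = {lab: presets[lab].mu0 for lab in TissueLabel}
    assert mu[TissueLabel.CALC] == pytest.approx(6.04e5)
    assert mu[TissueLabel.LRNC] == pytest.approx(5.92e4)
    assert mu[TissueLabel.MATX] == pytest.approx(4.70e4)
    assert mu[TissueLabel.CALC] > mu[TissueLabel.LRNC] > mu[TissueLabel.MATX]


def test_material_validation():
    with pytest.raises(ValueError, match="c1"):
        YeohMaterial(-1.0, 0.0, 0.0)
    with pytest.raises(ValueError, match="kappa"):
        YeohMaterial(1e4, 0.0, 0.0, kappa=1e4)  # below 1000 * mu0


@pytest.mark.parametrize("label", list(TissueLabel))
def test_reference_state_is_stress_free(label, presets):
    mat = presets[label]
    state = KinematicState(np.eye(3))
    assert strain_energy(mat, state) == 0.0
    assert np.allclose(cauchy_stress(mat, state), 0.0)


def test_uniaxial_energy_matches_hand_evaluation(presets):
    """Incompressible uniaxial stretch 1.2: cubic polynomial in (I1-3)."""
    lam = 1.2
    F = np.diag([lam, lam**-0.5, lam**-0.5])
    mat = presets[TissueLabel.MATX]
    x = lam**2 + 2.0 / lam - 3.0
    expected = mat.c1 * x + mat.c2 * x**2 + mat.c3 * x**3  # J=1: no penalty
    W = strain_energy(mat, KinematicState(F))
    assert W == pytest.approx(expected, rel=1e-12)
    assert W == pytest.approx(4.08e3, rel=2e-3)


@pytest.mark.parametrize("label", list(TissueLabel))
def test_frame_indifference(label, presets):
    """W(QF) = W(F) for random rotations Q."""
    mat = presets[label]
    rng = np.random.default_rng(7)
    F = _random_states(1, seed=3)[0]
    W0 = strain_energy(mat, KinematicState(F))
    for _ in range(10):
        A = rng.standard_normal((3, 3))
        Q, _r = np.linalg.qr(A)
        Q *= np.sign(np.linalg.det(Q))
        W = strain_energy(mat, KinematicState(Q @ F))
        assert W == pytest.approx(W0, rel=1e-12)


@pytest.mark.parametrize("label", list(TissueLabel))
def test_small_strain_shear_modulus(label, presets):
    mat = presets[label]
    gamma = 1e-4
    F = np.eye(3)
    F[0, 1] = gamma
    sig = cauchy_stress(mat, KinematicState(F))
    assert sig[0, 1] / gamma == pytest.approx(mat.mu0, rel=1e-3)


def test_stress_matches_energy_finite_differences(presets):
    """Cauchy stress vs a central-difference oracle on the energy."""
    mat = presets[TissueLabel.MATX]
    eps = 1e-6
    for F in _random_states(5, seed=11):
        Pfd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += eps
                Fm[i, j] -= eps
                Pfd[i, j] = (
                    strain_energy(mat, Fp) - strain_energy(mat, Fm)
                ) / (2 * eps)
        sig_fd = Pfd @ F.T / np.linalg.det(F)
        sig = cauchy_stress(mat, KinematicState(F))
        assert np.allclose(sig, sig_fd, rtol=1e-4, atol=1e-4 * np.abs(sig).max())
        assert np.allclose(sig, sig.T, rtol=1e-9, atol=1e-9 * np.abs(sig).max())


@pytest.mark.parametrize("label", list(TissueLabel))
def test_tangent_matches_stress_finite_differences(label, presets):
    mat = presets[label]
    eps = 1e-6
    for F in _random_states(10, seed=int(label)):
        A = material_tangent(mat, F)
        scale = np.abs(A).max()
        # major symmetry to machine tolerance
        assert np.allclose(A, np.einsum("ijkl->klij", A), atol=1e-12 * scale)
        Afd = np.zeros((3, 3, 3, 3))
        for k in range(3):
            for l in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[k, l] += eps
                Fm[k, l] -= eps
                Afd[:, :, k, l] = (
                    first_piola_stress(mat, Fp) - first_piola_stress(mat, Fm)
                ) / (2 * eps)
        assert np.abs(A - Afd).max() < 1e-3 * scale


def test_tangent_small_strain_limit(presets):
    """At F=I the tangent is isotropic elasticity: shear 2c1, bulk kappa."""
    mat = presets[TissueLabel.MATX]
    A = material_tangent(mat, np.eye(3))
    eye = np.eye(3)
    mu, k = mat.mu0, mat.kappa
    iso = (
        mu * (np.einsum("ik,jl->ijkl", eye, eye) + np.einsum("il,jk->ijkl", eye, eye))
        - (2 * mu / 3) * np.einsum("ij,kl->ijkl", eye, eye)
        + k * np.einsum("ij,kl->ijkl", eye, eye)
    )
    assert np.abs(A - iso).max() < 1e-3 * np.abs(iso).max()


@pytest.mark.parametrize("label", list(TissueLabel))
@pytest.mark.parametrize("mode", ["uniaxial", "equibiaxial"])
def test_energy_nonnegative_in_working_range(label, mode, presets):
    """Negative c2 (CALC/LRNC) must not produce softening for lam in [0.8, 1.5]."""
    mat = presets[label]
    for lam in np.linspace(0.8, 1.5, 141):
        if mode == "uniaxial":
            F = np.diag([lam, lam**-0.5, lam**-0.5])
        else:
            F = np.diag([lam, lam, lam**-2.0])
        assert strain_energy(mat, KinematicState(F)) >= -1e-10


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    lam=st.floats(0.8, 1.5),
    angle=st.floats(0.0, 2 * np.pi),
    label=st.sampled_from(list(TissueLabel)),
)
def test_energy_rotation_invariant_and_nonnegative_property(lam, angle, label):
    """For any incompressible uniaxial stretch in the working range and any
    in-plane rotation, the energy is rotation-invariant and non-negative."""
    mat = table2_presets()[label]
    F = np.diag([lam, lam**-0.5, lam**-0.5])
    c, s = np.cos(angle), np.sin(angle)
    Q = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    W = strain_energy(mat, KinematicState(F))
    WQ = strain_energy(mat, KinematicState(Q @ F))
    assert W >= -1e-10
    assert WQ == pytest.approx(W, rel=1e-10, abs=1e-10)


def test_inverted_state_rejected(presets):
    with pytest.raises(ValueError, match="[Jj]"):
        KinematicState(np.diag([-1.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        strain_energy(presets[TissueLabel.MATX], np.diag([0.0, 1.0, 1.0]))


def test_plane_strain_embedding():
    F2 = np.array([[1.1, 0.02], [-0.01, 0.95]])
    st = KinematicState.from_plane_strain(F2)
    assert st.F.shape == (3, 3)
    assert st.F[2, 2] == 1.0
    assert st.J == pytest.approx(np.linalg.det(F2))
    assert st.I1_bar == pytest.approx(
        np.linalg.det(F2) ** (-2 / 3) * (np.sum(F2 * F2) + 1.0)
    )
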