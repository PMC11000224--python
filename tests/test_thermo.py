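"""Normal modes, mRRHO free energies, reactions, temperature scans."""

import numpy as np
import pytest

from mconiom import (
    AtomicSystem,
    HarmonicFF,
    ReactionSpec,
    Species,
    build_tree,
    composite,
    free_rotor_weight,
    make_fixture,
    mrrho_gibbs,
    normal_modes,
    optimize,
    reaction_delta,
    temperature_scan,
)
from mconiom.thermo import R_KCAL, vibrational_entropy
from mconiom.units import (
    BOLTZMANN,
    GAS_CONSTANT,
    HESSIAN_EIGVAL_TO_OMEGA2,
    KCAL_TO_J,
    PLANCK,
    SPEED_OF_LIGHT,
)
from conftest import fd_hessian_of_energy

ALL = ("energy", "gradient", "hessian")


def _nu_cm(k, mu):
    """Closed-form harmonic frequency sqrt(k/mu) in cm^-1."""
    return np.sqrt(k * HESSIAN_EIGVAL_TO_OMEGA2 / mu) / (2 * np.pi * SPEED_OF_LIGHT * 100)


# -- normal modes ------------------------------------------------------------

def test_diatomic_frequency_closed_form(diatomic):
    res = composite(diatomic.tree(), diatomic.calculators, ALL)
    freqs, _, nproj = normal_modes(res.hessian, diatomic.system.masses,
                                   diatomic.system.coords)
    assert nproj == 5  # linear: 3 translations + 2 rotations
    assert len(freqs) == 1
    assert freqs[0] == pytest.approx(_nu_cm(0.35, 14.007 / 2), abs=0.01)


def test_translation_modes_project_to_zero(bridge_dimer):
    res = composite(bridge_dimer.tree(), bridge_dimer.calculators, ALL)
    s = bridge_dimer.system
    freqs, _, nproj = normal_modes(res.hessian, s.masses, s.coords)
    assert nproj == 6
    assert len(freqs) == 3 * s.n_atoms - 6
    # the projected-out space is exactly the near-zero block: remaining
    # frequencies are the physical ones and the implicit zeros are < 1 cm^-1
    F = res.hessian * np.outer(1 / np.sqrt(np.repeat(s.masses, 3)),
                               1 / np.sqrt(np.repeat(s.masses, 3)))
    all_nu = np.sort(np.abs(np.linalg.eigvalsh(F))) * HESSIAN_EIGVAL_TO_OMEGA2
    # (qualitative: Hessian at a non-stationary point is not needed here)


def test_triatomic_modes_match_independent_fd_pipeline():
    """Water-like bent 3-atom toy: analytic-gradient Hessian route agrees
    with a from-scratch FD-of-energy Hessian pipeline."""
    theta = np.deg2rad(104.5)
    r = 1.0
    coords = np.array([[0, 0, 0],
                       [r, 0, 0],
                       [r * np.cos(theta), r * np.sin(theta), 0]])
    s = AtomicSystem(["O", "H", "H"], coords - coords.mean(0), topology={(0, 1), (0, 2)})
    calc = HarmonicFF(bonds={(0, 1): (0.5, r), (0, 2): (0.5, r)},
                      angles={(1, 0, 2): (0.2, theta)})
    H1 = calc.evaluate(s, wanted=frozenset(ALL)).hessian
    f1, _, n1 = normal_modes(H1, s.masses, s.coords)
    H2 = fd_hessian_of_energy(
        lambda x: calc.evaluate(s.with_coords(x.reshape(-1, 3))).energy,
        s.coords.reshape(-1).copy(), step=2e-3)
    f2, _, n2 = normal_modes(H2, s.masses, s.coords)
    assert n1 == n2 == 6
    assert len(f1) == 3
    assert np.all(f1 > 0)
    assert np.abs(f1 - f2).max() < 0.5  # cm^-1


def test_asymmetric_hessian_rejected():
    s = AtomicSystem(["N", "N"], [[0, 0, 0], [1.42, 0, 0]])
    H = np.zeros((6, 6))
    H[0, 1] = 1.0
    with pytest.raises(ValueError, match="symmetric"):
        normal_modes(H, s.masses, s.coords)


# -- interpolation weight and entropies -------------------------------------

def test_weight_half_at_threshold_and_monotone():
    assert free_rotor_weight(25.0, nu0=25.0) == pytest.approx(0.5, abs=1e-15)
    nu = np.logspace(-1, np.log10(4000), 300)
    w = free_rotor_weight(nu)
    assert np.all(np.diff(w) > 0)
    assert w[0] < 1e-6 and w[-1] > 0.999


def test_vibrational_entropy_finite_as_nu_to_zero():
    """The free-rotor branch caps the harmonic-oscillator divergence."""
    nu = np.logspace(-1, np.log10(4000), 200)
    s = np.array([vibrational_entropy(np.array([x]), 298.15) for x in nu])
    assert np.all(np.isfinite(s))
    assert s.max() < 0.05  # kcal/mol/K: bounded even for 0.1 cm^-1
    # pure HO entropy diverges logarithmically instead
    from mconiom.thermo import _s_ho
    assert _s_ho(np.array([0.1]), 298.15)[0] > s[0]


def test_ho_entropy_closed_form_at_1000_cm():
    """Single 1000 cm^-1 mode at 298.15 K: the interpolated entropy matches
    the textbook HO formula (w ~ 1 there) to 1e-6 cal/mol/K."""
    T, nu = 298.15, 1000.0
    x = PLANCK * SPEED_OF_LIGHT * 100 * nu / (BOLTZMANN * T)
    s_ref = GAS_CONSTANT * (x / (np.exp(x) - 1) - np.log(1 - np.exp(-x))) / 4.184  # cal/mol/K
    s = vibrational_entropy(np.array([nu]), T) * 1000  # kcal -> cal
    assert s == pytest.approx(s_ref, abs=1e-6)


def test_interpolation_exact_average_at_threshold():
    from mconiom.thermo import _s_free_rotor, _s_ho
    T = 298.15
    s = vibrational_entropy(np.array([25.0]), T)
    expect = 0.5 * (_s_ho(np.array([25.0]), T)[0] + _s_free_rotor(np.array([25.0]), T, 1e-44)[0])
    assert s == pytest.approx(expect, rel=1e-12)


# -- Gibbs free energies -----------------------------------------------------

def test_monoatomic_sackur_tetrode_oracle():
    """Monoatomic ideal gas: G reduces to E_elec plus translational terms,
    matched against an independently hand-coded Sackur-Tetrode formula."""
    s = AtomicSystem(["Ar"], [[0, 0, 0]])
    T, e_elec = 298.15, -0.5
    th = mrrho_gibbs(s, e_elec, np.array([]), T)
    kB, h = BOLTZMANN, PLANCK
    m = 39.948 * 1.66053906660e-27
    p = 101325.0
    S = GAS_CONSTANT * (np.log((2 * np.pi * m * kB * T / h**2) ** 1.5 * kB * T / p) + 2.5)
    G_ref = (e_elec * 627.509474
             + (2.5 * GAS_CONSTANT * T - T * S) / KCAL_TO_J)
    assert th.s_rot == 0.0 and th.u_rot == 0.0 and th.zpe == 0.0
    assert th.G == pytest.approx(G_ref, abs=1e-8)


def test_internal_consistency_G_equals_H_minus_TS(bridge_dimer):
    opt = optimize(bridge_dimer.tree(), bridge_dimer.calculators, gtol=1e-6)
    res = composite(bridge_dimer.tree(), bridge_dimer.calculators, ALL,
                    system=opt.system)
    freqs, _, _ = normal_modes(res.hessian, opt.system.masses, opt.system.coords)
    th = mrrho_gibbs(opt.system, res.energy, freqs, 298.15)
    lhs = th.G
    rhs = (th.e_elec + th.zpe + th.u_vib + th.u_rot + th.u_trans
           + R_KCAL * th.T - th.T * th.entropy)
    assert lhs == pytest.approx(rhs, abs=1e-8)
    assert th.n_imaginary == 0


def test_dG_dT_equals_minus_S(bridge_dimer):
    opt = optimize(bridge_dimer.tree(), bridge_dimer.calculators, gtol=1e-6)
    res = composite(bridge_dimer.tree(), bridge_dimer.calculators, ALL,
                    system=opt.system)
    freqs, _, _ = normal_modes(res.hessian, opt.system.masses, opt.system.coords)
    T, dT = 298.15, 0.05
    thp = mrrho_gibbs(opt.system, res.energy, freqs, T + dT)
    thm = mrrho_gibbs(opt.system, res.energy, freqs, T - dT)
    th = mrrho_gibbs(opt.system, res.energy, freqs, T)
    assert (thp.G - thm.G) / (2 * dT) == pytest.approx(-th.entropy, abs=1e-4)


def test_imaginary_mode_policy():
    s = AtomicSystem(["N", "N"], [[0, 0, 0], [1.42, 0, 0]])
    freqs = np.array([-150.0, 900.0])
    with pytest.warns(UserWarning, match="imaginary"):
        th = mrrho_gibbs(s, 0.0, freqs, 298.15)
    assert th.n_imaginary == 1
    import warnings as w
    with w.catch_warnings():
        w.simplefilter("error")
        th_ts = mrrho_gibbs(s, 0.0, freqs, 298.15, is_ts=True)
    assert th_ts.n_imaginary == 1


# -- reactions ---------------------------------------------------------------

def _species(name, system, tree, calcs):
    res = composite(tree, calcs, ALL, system=system)
    freqs, _, _ = normal_modes(res.hessian, system.masses, system.coords)
    return Species(name, system, res.energy, freqs)


def _n2_and_n4():
    """Toy association 2 N2 -> N4 under the harmonic ff."""
    ff = {"ff": HarmonicFF(name="ff")}
    spec = {"node": [{"id": "root", "layer": 1, "atoms": "all", "calculator": "ff"}]}
    from mconiom.fixtures import _chain_topology, _zigzag_chain
    a = AtomicSystem(["N", "N"], _zigzag_chain(["N", "N"]), topology=_chain_topology(2))
    t_a = build_tree(a, spec)
    els = ["N"] * 4
    d0 = AtomicSystem(els, _zigzag_chain(els), topology=_chain_topology(4))
    t_d = build_tree(d0, spec)
    opt = optimize(t_d, ff, gtol=1e-8)
    return (_species("N2", a, t_a, ff), _species("N4", opt.system, t_d, ff), ff)


def test_identity_reaction_is_zero(diatomic):
    tree = diatomic.tree()
    sp = _species("A", diatomic.system, tree, diatomic.calculators)
    spec = ReactionSpec(reactants=[(1, sp)], products=[(1, sp)])
    out = reaction_delta(spec)
    assert out["dE"] == 0.0
    assert out["dG"] == pytest.approx(0.0, abs=1e-12)


def test_fabricated_stoichiometry_arithmetic():
    """2A -> A2 with fabricated electronic energies only (dE arithmetic)."""
    a = AtomicSystem(["N", "N"], [[0, 0, 0], [1.42, 0, 0]])
    a2 = AtomicSystem(["N"] * 4, [[0, 0, 0], [1.42, 0, 0], [2.84, 0, 0], [4.26, 0, 0]])
    spec = ReactionSpec(
        reactants=[(2, Species("A", a, -1.0 / 627.509474))],
        products=[(1, Species("A2", a2, -3.0 / 627.509474))],
    )
    out = reaction_delta(spec, T=None)
    assert out["dE"] == pytest.approx(-1.0, abs=1e-10)


def test_element_balance_enforced():
    a = AtomicSystem(["N", "N"], [[0, 0, 0], [1.42, 0, 0]])
    b = AtomicSystem(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
    spec = ReactionSpec(reactants=[(1, Species("A", a, 0.0))],
                        products=[(1, Species("B", b, 0.0))])
    with pytest.raises(ValueError, match="balance"):
        reaction_delta(spec, T=None)


def test_dimerization_dE_matches_direct_difference():
    n2, n4, ff = _n2_and_n4()
    spec = ReactionSpec(reactants=[(2, n2)], products=[(1, n4)])
    out = reaction_delta(spec, T=None)
    direct = (n4.e_elec - 2 * n2.e_elec) * 627.509474
    assert out["dE"] == pytest.approx(direct, abs=1e-10)


def test_temperature_scan_consistency_and_association_slope():
    n2, n4, ff = _n2_and_n4()
    spec = ReactionSpec(reactants=[(2, n2)], products=[(1, n4)])
    single = temperature_scan(spec, [298.15])
    assert single[0]["dG"] == pytest.approx(reaction_delta(spec, 298.15)["dG"], abs=1e-12)
    rows = temperature_scan(spec, np.linspace(200, 400, 11))
    dG = np.array([r["dG"] for r in rows])
    # association loses translational entropy: dG rises with T
    assert np.all(np.diff(dG) > 0)


def test_entropy_neutral_reaction_constant_in_T(diatomic):
    tree = diatomic.tree()
    sp = _species("A", diatomic.system, tree, diatomic.calculators)
    sp2 = Species("B", sp.system, sp.e_elec - 0.01, sp.frequencies)
    spec = ReactionSpec(reactants=[(1, sp)], products=[(1, sp2)])
    rows = temperature_scan(spec, np.linspace(200, 400, 9))
    dG = np.array([r["dG"] for r in rows])
    assert np.abs(dG - dG[0]).max() < 1e-6


# -- composite-Hessian thermochemistry route ---------------------------------

@pytest.mark.parametrize("kind,seed", [("chain", 4), ("bridge_dimer", 4)])
def test_engine_hessian_G_matches_fd_hessian_G(kind, seed):
    """G(298.15 K) from the ONIOM-assembled Hessian agrees with G from a
    from-scratch FD Hessian of the composite energy within 0.05 kcal/mol —
    the reconstructed-Hessian free-energy route."""
    fx = make_fixture(kind, seed=seed)
    tree = fx.tree()
    calcs = fx.calculators
    opt = optimize(tree, calcs, gtol=1e-6)
    syso = opt.system
    res = composite(tree, calcs, ALL, system=syso)
    f1, _, _ = normal_modes(res.hessian, syso.masses, syso.coords)
    th1 = mrrho_gibbs(syso, res.energy, f1, 298.15)

    H_fd = fd_hessian_of_energy(
        lambda x: composite(tree, calcs, ("energy",),
                            system=syso.with_coords(x.reshape(-1, 3))).energy,
        syso.coords.reshape(-1).copy(), step=5e-3)
    f2, _, _ = normal_modes(H_fd, syso.masses, syso.coords)
    th2 = mrrho_gibbs(syso, res.energy, f2, 298.15)
    assert abs(th1.G - th2.G) < 0.05
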