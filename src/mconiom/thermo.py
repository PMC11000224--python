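"""Normal-mode analysis and mRRHO thermochemistry.

Free energies follow the modified rigid-rotor-harmonic-oscillator
(mRRHO) model: ideal-gas translational (Sackur-Tetrode) and rigid-rotor
rotational contributions, harmonic vibrational energies, and a
vibrational entropy in which every mode is a smooth interpolation
between the harmonic-oscillator entropy and the entropy of a free rotor
with an effective moment of inertia,

    S_vib(nu) = w(nu) S_HO(nu) + (1 - w(nu)) S_FR(nu),
    w(nu) = 1 / (1 + (nu0 / nu)^alpha),

with threshold nu0 = 25 cm^-1 and exponent alpha = 4 by default.  The
free-rotor branch keeps the entropy finite as nu -> 0, which is what
makes free energies of large floppy systems numerically stable; the
effective moment is damped toward an average molecular moment
B_av = 1e-44 kg m^2.

Hessians can come from any source — in particular from the ONIOM
engine's composite assembly, which is the route used for multiscale
reaction free energies.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import AtomicSystem
from .units import (
    AMU_TO_KG,
    ANGSTROM_TO_M,
    ATM_PA,
    AVOGADRO,
    BOLTZMANN,
    GAS_CONSTANT,
    HARTREE_TO_KCALMOL,
    HESSIAN_EIGVAL_TO_OMEGA2,
    KCAL_TO_J,
    PLANCK,
    SPEED_OF_LIGHT,
)

__all__ = [
    "normal_modes",
    "mrrho_gibbs",
    "ThermoResult",
    "Species",
    "ReactionSpec",
    "reaction_delta",
    "temperature_scan",
    "free_rotor_weight",
    "vibrational_entropy",
]

#: near-zero frequency magnitude (cm^-1) below which a mode counts as
#: a projected-out translation/rotation remnant
_ZERO_MODE_CUTOFF = 1.0

R_KCAL = GAS_CONSTANT / KCAL_TO_J  # kcal/mol/K


def _inertia_tensor(coords_m: np.ndarray, masses_kg: np.ndarray) -> np.ndarray:
    com = masses_kg @ coords_m / masses_kg.sum()
    x = coords_m - com
    r2 = (x**2).sum(axis=1)
    I = np.zeros((3, 3))
    for m, xi, rr in zip(masses_kg, x, r2):
        I += m * (rr * np.eye(3) - np.outer(xi, xi))
    return I


def is_linear(system: AtomicSystem, tol: float = 1e-6) -> bool:
    """Linear iff the smallest principal moment is negligible vs the largest."""
    if system.n_atoms <= 2:
        return True
    I = _inertia_tensor(system.coords * ANGSTROM_TO_M, system.masses * AMU_TO_KG)
    ev = np.linalg.eigvalsh(I)
    return bool(ev[0] / max(ev[2], 1e-300) < tol)


def normal_modes(hessian: np.ndarray, masses: np.ndarray, coords: np.ndarray,
                 symmetry_tol: float = 1e-7):
    """Harmonic frequencies (cm^-1) and mass-weighted modes from a Hessian.

    Mass-weights H (Hartree/A^2, masses in amu), projects out rigid
    translations and rotations about the center of mass (Eckart frame),
    and diagonalizes.  Imaginary frequencies are returned as negative
    numbers.  Returns ``(frequencies, modes, n_projected)`` where modes
    are columns in mass-weighted coordinates.
    """
    H = np.asarray(hessian, dtype=float)
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float)
    n = len(masses)
    if H.shape != (3 * n, 3 * n):
        raise ValueError(f"Hessian shape {H.shape} does not match {n} atoms")
    asym = np.abs(H - H.T).max()
    if asym > max(symmetry_tol, 1e-7 * max(np.abs(H).max(), 1.0)):
        raise ValueError(f"Hessian is not symmetric (max |H - H^T| = {asym:.3e})")
    H = 0.5 * (H + H.T)

    invsqrt = 1.0 / np.sqrt(np.repeat(masses, 3))
    F = H * np.outer(invsqrt, invsqrt)

    # translation / rotation vectors in mass-weighted coordinates
    sq = np.sqrt(np.repeat(masses, 3))
    vecs = []
    for ax in range(3):
        t = np.zeros(3 * n)
        t[ax::3] = 1.0
        vecs.append(t * sq)
    com = masses @ coords / masses.sum()
    x = coords - com
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        rot = np.cross(np.tile(e, (n, 1)), x).reshape(-1)
        vecs.append(rot * sq)
    # orthonormal basis of the translation/rotation span via SVD (the
    # rotation vectors are rank-deficient for linear molecules)
    U, sv, _ = np.linalg.svd(np.array(vecs).T, full_matrices=False)
    keep = sv > 1e-8 * max(sv[0], 1.0)
    B = U[:, keep]
    n_projected = int(keep.sum())
    P = np.eye(3 * n) - B @ B.T
    Fp = P @ F @ P
    Fp = 0.5 * (Fp + Fp.T)

    w2, modes = np.linalg.eigh(Fp)
    omega2 = w2 * HESSIAN_EIGVAL_TO_OMEGA2
    nu = np.sign(omega2) * np.sqrt(np.abs(omega2)) / (2.0 * np.pi * SPEED_OF_LIGHT * 100.0)

    # drop the n_projected eigenpairs closest to zero (the projected space)
    order = np.argsort(np.abs(nu))
    drop = set(order[:n_projected].tolist())
    sel = [i for i in range(len(nu)) if i not in drop]
    return nu[sel], modes[:, sel], n_projected


def free_rotor_weight(nu_cm: np.ndarray | float, nu0: float = 25.0,
                      alpha: float = 4.0) -> np.ndarray | float:
    """Head-Gordon-type interpolation weight w = 1/(1 + (nu0/nu)^alpha).

    w -> 1 for nu >> nu0 (harmonic oscillator), w -> 0 for nu -> 0
    (free rotor); w(nu0) = 1/2 exactly.
    """
    nu = np.asarray(nu_cm, dtype=float)
    w = 1.0 / (1.0 + (nu0 / np.maximum(nu, 1e-300)) ** alpha)
    return w if w.ndim else float(w)


def _s_ho(nu_cm: np.ndarray, T: float) -> np.ndarray:
    """Harmonic-oscillator entropy per mode, kcal/mol/K."""
    x = PLANCK * SPEED_OF_LIGHT * 100.0 * nu_cm / (BOLTZMANN * T)
    ex = np.exp(-x)
    return R_KCAL * (x * ex / (1.0 - ex) - np.log(1.0 - ex))


def _s_free_rotor(nu_cm: np.ndarray, T: float, b_av: float) -> np.ndarray:
    """Free-rotor entropy per mode with damped effective moment, kcal/mol/K."""
    nu_hz = SPEED_OF_LIGHT * 100.0 * nu_cm
    mu = PLANCK / (8.0 * np.pi**2 * nu_hz)
    mu_eff = mu * b_av / (mu + b_av)
    arg = 8.0 * np.pi**3 * mu_eff * BOLTZMANN * T / PLANCK**2
    return R_KCAL * (0.5 + 0.5 * np.log(arg))


def vibrational_entropy(nu_cm: np.ndarray, T: float, nu0: float = 25.0,
                        alpha: float = 4.0, b_av: float = 1e-44,
                        interpolate: bool = True) -> float:
    """mRRHO vibrational entropy (kcal/mol/K) over real modes.

    With ``interpolate=False`` a hard variant is used instead: plain HO
    entropy above ``nu0`` and pure free-rotor entropy below it.
    """
    nu = np.asarray(nu_cm, dtype=float)
    nu = nu[nu > 0]
    if nu.size == 0:
        return 0.0
    s_ho = _s_ho(nu, T)
    s_fr = _s_free_rotor(nu, T, b_av)
    if interpolate:
        w = free_rotor_weight(nu, nu0, alpha)
        return float(np.sum(w * s_ho + (1.0 - w) * s_fr))
    return float(np.sum(np.where(nu >= nu0, s_ho, s_fr)))


@dataclass
class ThermoResult:
    """mRRHO thermochemistry of one structure at one temperature.

    All energies in kcal/mol, entropies in kcal/mol/K, T in K.  ``G``
    satisfies G = E_elec + ZPE + U_vib + U_rot + U_trans + RT - T * S.
    """

    T: float
    e_elec: float
    zpe: float
    frequencies: np.ndarray
    n_imaginary: int
    u_trans: float
    u_rot: float
    u_vib: float
    s_trans: float
    s_rot: float
    s_vib: float
    linear: bool
    components: dict = field(default_factory=dict)

    @property
    def enthalpy(self) -> float:
        return self.e_elec + self.zpe + self.u_vib + self.u_rot + self.u_trans + R_KCAL * self.T

    @property
    def entropy(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib

    @property
    def G(self) -> float:
        return self.enthalpy - self.T * self.entropy

    @property
    def g_mrrho_correction(self) -> float:
        """Thermostatistical correction delta-G added to the electronic energy."""
        return self.G - self.e_elec

    def summary(self) -> str:
        lines = [
            f"T                 {self.T:12.2f} K",
            f"E(elec)           {self.e_elec:12.4f} kcal/mol",
            f"ZPE               {self.zpe:12.4f} kcal/mol",
            f"U(vib)            {self.u_vib:12.4f} kcal/mol",
            f"U(rot)            {self.u_rot:12.4f} kcal/mol",
            f"U(trans)          {self.u_trans:12.4f} kcal/mol",
            f"S(vib)            {1000 * self.s_vib:12.4f} cal/mol/K",
            f"S(rot)            {1000 * self.s_rot:12.4f} cal/mol/K",
            f"S(trans)          {1000 * self.s_trans:12.4f} cal/mol/K",
            f"H                 {self.enthalpy:12.4f} kcal/mol",
            f"G                 {self.G:12.4f} kcal/mol",
            f"imaginary modes   {self.n_imaginary:12d}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "T_K": self.T, "E_elec": self.e_elec, "ZPE": self.zpe,
            "U_vib": self.u_vib, "U_rot": self.u_rot, "U_trans": self.u_trans,
            "S_vib": self.s_vib, "S_rot": self.s_rot, "S_trans": self.s_trans,
            "H": self.enthalpy, "S": self.entropy, "G": self.G,
            "n_imaginary": self.n_imaginary,
            "frequencies_cm1": [float(f) for f in self.frequencies],
        }


def mrrho_gibbs(system: AtomicSystem, e_elec_hartree: float,
                frequencies: np.ndarray, T: float, *,
                nu0: float = 25.0, alpha: float = 4.0, b_av: float = 1e-44,
                pressure: float = ATM_PA, sigma: int = 1,
                is_ts: bool = False, interpolate: bool = True) -> ThermoResult:
    """mRRHO Gibbs free energy of one structure at temperature T.

    ``frequencies`` are in cm^-1 with imaginary modes negative (as
    produced by :func:`normal_modes`).  Imaginary modes are excluded from
    the vibrational sums — with a warning for a declared minimum, silently
    for exactly one when ``is_ts`` is set.  ``sigma`` is the rotational
    symmetry number (no point-group perception is attempted; default 1).
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    nu = np.asarray(frequencies, dtype=float)
    nu = nu[np.abs(nu) > _ZERO_MODE_CUTOFF]
    imag = nu[nu < 0]
    n_imag = int(imag.size)
    if n_imag:
        if is_ts and n_imag == 1:
            pass
        else:
            warnings.warn(
                f"{n_imag} imaginary mode(s) excluded from thermochemistry "
                f"(most negative {imag.min():.1f} cm^-1)", stacklevel=2)
    real = nu[nu > 0]
    if real.size == 0 and system.n_atoms > 1:
        raise ValueError("no real vibrational modes; cannot compute thermochemistry")

    hc100 = PLANCK * SPEED_OF_LIGHT * 100.0
    zpe = float(np.sum(0.5 * hc100 * real)) * AVOGADRO / KCAL_TO_J
    x = hc100 * real / (BOLTZMANN * T)
    u_ho = hc100 * real / (np.exp(x) - 1.0) * AVOGADRO / KCAL_TO_J
    # the internal energy is interpolated with the same weights as the
    # entropy (free rotor: RT/2 per mode); this keeps dG/dT = -S exact
    if interpolate:
        w = free_rotor_weight(real, nu0, alpha)
    else:
        w = (real >= nu0).astype(float)
    u_vib = float(np.sum(w * u_ho + (1.0 - w) * 0.5 * R_KCAL * T))
    s_vib = vibrational_entropy(real, T, nu0, alpha, b_av, interpolate)

    m_kg = float(system.masses.sum()) * AMU_TO_KG
    q_t = (2.0 * np.pi * m_kg * BOLTZMANN * T / PLANCK**2) ** 1.5 * BOLTZMANN * T / pressure
    s_trans = R_KCAL * (np.log(q_t) + 2.5)
    u_trans = 1.5 * R_KCAL * T

    if system.n_atoms == 1:
        s_rot, u_rot, linear = 0.0, 0.0, False
    else:
        I = _inertia_tensor(system.coords * ANGSTROM_TO_M, system.masses * AMU_TO_KG)
        ev = np.sort(np.linalg.eigvalsh(I))
        linear = bool(ev[0] / max(ev[2], 1e-300) < 1e-6)
        if linear:
            theta = PLANCK**2 / (8.0 * np.pi**2 * ev[2] * BOLTZMANN)
            s_rot = R_KCAL * (1.0 + np.log(T / (sigma * theta)))
            u_rot = R_KCAL * T
        else:
            theta = PLANCK**2 / (8.0 * np.pi**2 * ev * BOLTZMANN)
            s_rot = R_KCAL * (1.5 + np.log(np.sqrt(np.pi) / sigma
                                           * np.sqrt(T**3 / np.prod(theta))))
            u_rot = 1.5 * R_KCAL * T

    return ThermoResult(
        T=T, e_elec=e_elec_hartree * HARTREE_TO_KCALMOL, zpe=zpe,
        frequencies=nu, n_imaginary=n_imag,
        u_trans=float(u_trans), u_rot=float(u_rot), u_vib=u_vib,
        s_trans=float(s_trans), s_rot=float(s_rot), s_vib=s_vib,
        linear=linear,
        components={"nu0_cm1": nu0, "alpha": alpha, "b_av_kgm2": b_av,
                    "pressure_Pa": pressure, "sigma": sigma},
    )


# ---------------------------------------------------------------------------
# reactions


@dataclass
class Species:
    """One reaction participant: geometry, electronic energy (Hartree) and,
    when free energies are requested, its harmonic frequencies (cm^-1)."""

    name: str
    system: AtomicSystem
    e_elec: float
    frequencies: np.ndarray | None = None
    sigma: int = 1
    is_ts: bool = False


@dataclass
class ReactionSpec:
    """reactants/products as (stoichiometry, Species) lists."""

    reactants: list[tuple[int, Species]]
    products: list[tuple[int, Species]]

    def element_balance(self) -> dict[str, int]:
        """products-minus-reactants element counts; all-zero means balanced."""
        counts: dict[str, int] = {}
        for side, sign in ((self.reactants, -1), (self.products, +1)):
            for stoich, sp in side:
                for el in sp.system.elements:
                    counts[el] = counts.get(el, 0) + sign * stoich
        return {el: c for el, c in counts.items() if c != 0}


def reaction_delta(spec: ReactionSpec, T: float | None = 298.15,
                   check_balance: bool = True, **mrrho_kw) -> dict:
    """Reaction Delta-E and (if T given and frequencies available) Delta-G.

    Returns {"dE": kcal/mol, "dG": kcal/mol or None, "T": K, ...} computed
    as sum(products) - sum(reactants) with stoichiometry.
    """
    if check_balance:
        imbalance = spec.element_balance()
        if imbalance:
            raise ValueError(
                f"reaction does not balance: products-minus-reactants {imbalance} "
                "(declare small molecules such as H2 explicitly)"
            )
    dE = 0.0
    have_freqs = True
    for side, sign in ((spec.reactants, -1.0), (spec.products, +1.0)):
        for stoich, sp in side:
            dE += sign * stoich * sp.e_elec * HARTREE_TO_KCALMOL
            have_freqs &= sp.frequencies is not None
    out = {"dE": dE, "dG": None, "T": T}
    if T is not None and have_freqs:
        dG = 0.0
        for side, sign in ((spec.reactants, -1.0), (spec.products, +1.0)):
            for stoich, sp in side:
                th = mrrho_gibbs(sp.system, sp.e_elec, sp.frequencies, T,
                                 sigma=sp.sigma, is_ts=sp.is_ts, **mrrho_kw)
                dG += sign * stoich * th.G
        out["dG"] = dG
    return out


def temperature_scan(spec: ReactionSpec, T_grid, write_csv: str | Path | None = None,
                     **mrrho_kw) -> list[dict]:
    """Delta-G(T) over a temperature grid; frequencies are computed once per
    species (they enter via the spec) and only the thermostatistics are
    re-evaluated at each T.  Optionally writes a CSV with columns T_K, dE, dG.
    """
    T_grid = list(T_grid)
    if not T_grid:
        raise ValueError("temperature grid is empty")
    rows = [
        {"T_K": float(T), **{k: v for k, v in reaction_delta(spec, T, **mrrho_kw).items()
                             if k in ("dE", "dG")}}
        for T in T_grid
    ]
    if write_csv is not None:
        with open(write_csv, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["T_K", "dE", "dG"])
            w.writeheader()
            w.writerows(rows)
    return rows
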