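"""Flory-Huggins theory of DNA solutions with single-chain collapse.

The model treats a DNA solution on a lattice: the mixing ("external") free
energy is the standard Flory-Huggins expression for a polymer of ``N``
lattice segments at volume fraction ``phi`` in a solvent of quality ``chi``,
and each DNA molecule additionally carries an "internal" free energy, after
Post and Zimm, describing the conformation of the single chain through the
expansion factor ``alpha`` (radius of gyration relative to the unperturbed
theta-solvent coil).  Per lattice site, in units of kT::

    f(phi, alpha) = (1 - phi) ln(1 - phi) + (phi / N) ln phi
                    + chi phi (1 - phi) + (phi / N) g(alpha)

    g(alpha) = N [ (chi - 1) + B2 w / (2^{3/2} alpha^3)
                   + B3 w^2 / (2 * 3^{5/2} alpha^6) ]
               + (3/2)(alpha^2 - 1) - 3 ln alpha

where ``B2 = 1/2 - chi`` and ``B3`` are the second and third virial
coefficients of the osmotic pressure of segments inside the coil, and ``w``
(omega) measures chain flexibility through the segment density of the
unperturbed coil.  In a poor solvent (``chi > 1/2``) the attractive ``B2``
term competes with the repulsive ``B3`` term and the chain entropy, and the
global minimum of ``g`` over ``0 < alpha <= 1.5`` jumps from the expanded
coil to a compact globule -- the coil-globule collapse transition.  Longer
chains (larger ``N``) collapse at smaller ``chi``.

Two-phase coexistence is found by equating the chemical potentials of DNA
and solvent between a dilute and a dense phase.  The dilute phase uses the
collapse value of ``alpha`` at the working ``chi``; in the dense phase
intermolecular contacts substitute for the intramolecular ones, so the
unperturbed (theta-solvent, ``chi = 0.5``) ``alpha`` is used.  Coexisting
volume fractions are converted to mass concentrations by multiplying with
the DNA density ``rho``.

Parameter interpretation
------------------------
The chain descriptors are computed from the molecular weight ``M`` (g/mol,
at 650 g/mol per base pair) as::

    <h0^2> = 4e-15 * M^{8/7}   [cm^2]   unperturbed mean-square end-to-end length
    omega  = 9 pi * M / (N_A * rho * <h0^2>^{3/2})
    N      = M / 4000

i.e. one lattice segment corresponds to 4000 g/mol of DNA (about 6 bp).
``B3 = 1 + chi^2/(2q) - chi^3/(6q^2)`` with lattice coordination number
``q = 10``; this grouping keeps ``B3 > 0`` over the working range of
``chi`` (a ``chi^2 q`` grouping turns negative near ``chi = 0.55`` and
makes the free energy unbounded below).  With these choices the model
predicts dilute-branch coexistence at ``chi = 0.7`` of ~157 mg/mL for a
200 bp chain and ~0.15 ug/mL for a 2.5 kb chain.  See ``docs/methods.md``
for the calibration of these typeset-ambiguous carriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AVOGADRO",
    "MASS_PER_BP",
    "DomainError",
    "ConvergenceError",
    "DNAChain",
    "SolventCondition",
    "MixtureState",
    "BinodalPoint",
    "PhaseDiagram",
    "b3_default",
    "b3_lattice_weighted",
    "make_chain",
    "internal_free_energy",
    "free_energy_intensive",
    "free_energy_extensive",
    "alpha_stationarity_residual",
    "expansion_alpha",
    "chemical_potentials",
    "critical_chi",
    "binodal_point",
    "phase_diagram",
    "phi_to_concentration",
    "concentration_to_phi",
]

AVOGADRO = 6.02214076e23
#: average mass of one base pair of double-stranded DNA, g/mol
MASS_PER_BP = 650.0
#: mass of DNA occupying one lattice site, g/mol (defines segment number N)
SITE_MASS = 4000.0
#: prefactor and exponent of the unperturbed mean-square end-to-end length,
#: <h0^2> = H0SQ_PREFACTOR * M^H0SQ_EXPONENT in cm^2 with M in g/mol
H0SQ_PREFACTOR = 4e-15
H0SQ_EXPONENT = 8.0 / 7.0
#: upper end of the expansion-factor search interval
ALPHA_MAX = 1.5


class DomainError(ValueError):
    """Raised when an argument lies outside the model's domain."""


class ConvergenceError(RuntimeError):
    """Raised when a solver fails to converge; carries diagnostics."""


def b3_default(chi: float, q: float) -> float:
    """Third virial coefficient, ``1 + chi^2/(2q) - chi^3/(6q^2)``.

    Positive over the physically used range of ``chi`` (up to ``chi ~ q``),
    which keeps the globule branch of the internal free energy bounded.
    """
    return 1.0 + chi**2 / (2.0 * q) - chi**3 / (6.0 * q**2)


def b3_lattice_weighted(chi: float, q: float) -> float:
    """Alternative grouping ``1 + chi^2 q/2 - chi^3 q^2/6``.

    Turns negative near ``chi = 0.55`` for ``q = 10``, which makes the
    free energy unbounded below as ``alpha -> 0``; kept only so the two
    readings can be compared against the calibration anchors.
    """
    return 1.0 + 0.5 * chi**2 * q - chi**3 * q**2 / 6.0


@dataclass(frozen=True)
class DNAChain:
    """One DNA species in the lattice model.

    Attributes
    ----------
    length_bp : int
        Contour length in base pairs.
    molecular_weight : float
        g/mol, ``length_bp * 650``.
    segment_number_N : float
        Number of lattice segments (ratio of DNA to solvent molecular
        volume); proportional to molecular weight.
    omega : float
        Dimensionless flexibility measure (segment density of the
        unperturbed coil).
    h0_squared : float
        Unperturbed mean-square end-to-end length, cm^2.
    """

    length_bp: int
    molecular_weight: float
    segment_number_N: float
    omega: float
    h0_squared: float


def make_chain(length_bp: int) -> DNAChain:
    """Build a :class:`DNAChain` from its length in base pairs.

    Raises
    ------
    DomainError
        If ``length_bp`` is not a positive integer.
    """
    if length_bp < 1 or int(length_bp) != length_bp:
        raise DomainError(f"length_bp must be a positive integer, got {length_bp!r}")
    m = MASS_PER_BP * float(length_bp)
    h0sq = H0SQ_PREFACTOR * m**H0SQ_EXPONENT
    omega = 9.0 * math.pi * m / (AVOGADRO * SolventCondition.DEFAULT_RHO * h0sq**1.5)
    n_seg = m / SITE_MASS
    return DNAChain(
        length_bp=int(length_bp),
        molecular_weight=m,
        segment_number_N=n_seg,
        omega=omega,
        h0_squared=h0sq,
    )


@dataclass(frozen=True)
class SolventCondition:
    """Solvent quality and lattice parameters.

    ``B2 = 1/2 - chi`` always; ``B3`` is recomputed from ``chi`` and ``q``
    through ``b3_expression`` (replaceable, see module docstring).  The
    ``b2_override``/``b3_override`` fields exist only for limiting-case
    diagnostics (e.g. switching the virial terms off entirely) and should
    be left at ``None`` in normal use.
    """

    chi: float
    q: float = 10.0
    rho_dna: float = 1.8  # g/cm^3
    b3_expression: Callable[[float, float], float] = b3_default
    b2_override: Optional[float] = None
    b3_override: Optional[float] = None

    DEFAULT_RHO = 1.8

    @property
    def B2(self) -> float:
        if self.b2_override is not None:
            return self.b2_override
        return 0.5 - self.chi

    @property
    def B3(self) -> float:
        if self.b3_override is not None:
            return self.b3_override
        return self.b3_expression(self.chi, self.q)

    def at_chi(self, chi: float) -> "SolventCondition":
        """Same lattice/density parameters at a different ``chi``."""
        return replace(self, chi=chi)


@dataclass(frozen=True)
class MixtureState:
    """A point in composition-conformation space.

    ``phi_dna`` is the DNA volume fraction (solvent fraction is
    ``1 - phi_dna``); ``alpha`` the single-chain expansion factor.
    """

    phi_dna: float
    alpha: float = 1.0

    @property
    def phi_solvent(self) -> float:
        return 1.0 - self.phi_dna


def internal_free_energy(alpha: float, chain: DNAChain, solvent: SolventCondition) -> float:
    """Internal (single-chain) free energy ``g(alpha)`` per molecule, in kT.

    This is the square-bracketed part of the total free energy: virial
    contributions of intramolecular segment contacts plus the elastic and
    entropic cost of deviating from the unperturbed coil.
    """
    if alpha <= 0:
        raise DomainError(f"alpha must be positive, got {alpha}")
    n, w = chain.segment_number_N, chain.omega
    b2, b3 = solvent.B2, solvent.B3
    return (
        n
        * (
            (solvent.chi - 1.0)
            + b2 * w / (2.0**1.5 * alpha**3)
            + b3 * w**2 / (2.0 * 3.0**2.5 * alpha**6)
        )
        + 1.5 * (alpha**2 - 1.0)
        - 3.0 * math.log(alpha)
    )


def free_energy_intensive(
    state: MixtureState, chain: DNAChain, solvent: SolventCondition
) -> float:
    """Free energy per lattice site, ``Delta G * V_s / (V kT)``.

    Mixing terms plus ``phi/N`` times the internal single-chain free
    energy.  Vanishes for pure solvent (``phi_dna = 0``).

    Raises
    ------
    DomainError
        If ``phi_dna`` is outside ``[0, 1)`` or ``alpha <= 0``.
    """
    phi = state.phi_dna
    if not 0.0 <= phi < 1.0:
        raise DomainError(f"phi_dna must lie in [0, 1), got {phi}")
    if phi == 0.0:
        return 0.0
    n = chain.segment_number_N
    g = internal_free_energy(state.alpha, chain, solvent)
    return (
        (1.0 - phi) * math.log1p(-phi)
        + phi / n * math.log(phi)
        + solvent.chi * phi * (1.0 - phi)
        + phi / n * g
    )


def free_energy_extensive(
    n_solvent: float,
    n_dna: float,
    alpha: float,
    chain: DNAChain,
    solvent: SolventCondition,
) -> float:
    """Total free energy ``Delta G / kT`` for given molecule numbers.

    The extensive form (total volume ``V = V_s (n_solvent + n_dna N)``)
    used as the differentiation target when validating the analytic
    chemical potentials.
    """
    n = chain.segment_number_N
    total = n_solvent + n_dna * n
    phi = n_dna * n / total
    g = internal_free_energy(alpha, chain, solvent)
    out = 0.0
    if n_solvent > 0:
        out += n_solvent * math.log1p(-phi)
    if n_dna > 0:
        out += n_dna * math.log(phi)
    return out + solvent.chi * n_solvent * phi + n_dna * g


def alpha_stationarity_residual(
    alpha: float, chain: DNAChain, solvent: SolventCondition
) -> float:
    """Residual of the stationarity condition ``d g / d alpha = 0``.

    Multiplying the derivative of the internal free energy by
    ``alpha^7 / 3`` gives the polynomial form::

        3 a^8 - 3 a^6 - N (3 B2 w a^3 / 2^{3/2} + B3 w^2 / 3^{3/2})

    whose positive roots are the stationary points of ``g(alpha)``.
    """
    if alpha <= 0:
        raise DomainError(f"alpha must be positive, got {alpha}")
    n, w = chain.segment_number_N, chain.omega
    return (
        3.0 * alpha**8
        - 3.0 * alpha**6
        - n * (3.0 * solvent.B2 * w * alpha**3 / 2.0**1.5 + solvent.B3 * w**2 / 3.0**1.5)
    )


def expansion_alpha(
    chain: DNAChain, solvent: SolventCondition, alpha_max: float = ALPHA_MAX
) -> float:
    """Expansion factor at the global minimum of the internal free energy.

    Stationary points are the real positive roots of the degree-8
    stationarity polynomial; the global minimum is selected among them and
    the interval boundary ``alpha_max`` (the ``alpha -> 0`` boundary
    carries ``g -> +inf`` for ``B3 > 0`` and never wins).

    Returns
    -------
    float
        ``alpha`` in ``(0, alpha_max]``.

    Raises
    ------
    ConvergenceError
        If no candidate yields a finite free energy (requires ``B3 > 0``).
    """
    n, w = chain.segment_number_N, chain.omega
    b2, b3 = solvent.B2, solvent.B3
    c1 = 3.0 * n * b2 * w / 2.0**1.5
    c0 = n * b3 * w**2 / 3.0**1.5
    roots = np.roots([3.0, 0.0, -3.0, 0.0, 0.0, -c1, 0.0, 0.0, -c0])
    candidates = [alpha_max]
    for r in roots:
        if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and 0.0 < r.real <= alpha_max:
            candidates.append(float(r.real))
    values = [internal_free_energy(a, chain, solvent) for a in candidates]
    if not all(math.isfinite(v) for v in values):
        raise ConvergenceError(
            f"non-finite internal free energy among candidates {candidates} "
            f"(B2={b2}, B3={b3}, N={n}, omega={w})"
        )
    return candidates[int(np.argmin(values))]


def chemical_potentials(
    state: MixtureState, chain: DNAChain, solvent: SolventCondition
) -> tuple[float, float]:
    """Exchange chemical potentials ``(mu_DNA, mu_solvent)`` in kT.

    Obtained by differentiating the extensive free energy with respect to
    the molecule numbers::

        mu_DNA     = ln phi - (N-1)(1-phi) + chi N (1-phi)^2 + g(alpha)
        mu_solvent = ln(1-phi) + (1 - 1/N) phi + chi phi^2

    The solvent potential does not involve ``alpha``.

    Raises
    ------
    DomainError
        For boundary volume fractions (``phi_dna <= 0`` or ``>= 1``).
    """
    phi = state.phi_dna
    if not 0.0 < phi < 1.0:
        raise DomainError(f"phi_dna must lie in (0, 1), got {phi}")
    n = chain.segment_number_N
    g = internal_free_energy(state.alpha, chain, solvent)
    mu_dna = (
        math.log(phi)
        - (n - 1.0) * (1.0 - phi)
        + solvent.chi * n * (1.0 - phi) ** 2
        + g
    )
    mu_solvent = _mu_solvent(phi, n, solvent.chi)
    return mu_dna, mu_solvent


def _mu_solvent(phi: float, n: float, chi: float) -> float:
    # (log1p(-phi) + phi) groups the cancelling pair so that phi ~ 1e-30
    # still yields the correct -phi/N + chi phi^2 leading behaviour.
    return (math.log1p(-phi) + phi) - phi / n + chi * phi**2


def _mu_dna_log(t: float, n: float, chi: float, g: float) -> float:
    # mu_DNA as a function of t = ln(phi); phi may underflow to 0.0 for
    # very long chains while t stays finite.
    phi = math.exp(t) if t > -745.0 else 0.0
    return t - (n - 1.0) * (1.0 - phi) + chi * n * (1.0 - phi) ** 2 + g


def critical_chi(chain: DNAChain) -> float:
    """Flory-Huggins critical interaction parameter, ``(1 + 1/sqrt(N))^2 / 2``.

    Below this ``chi`` the solvent chemical potential is monotonic in
    ``phi`` and no two-phase coexistence exists.
    """
    return 0.5 * (1.0 + 1.0 / math.sqrt(chain.segment_number_N)) ** 2


def phi_to_concentration(phi: float, rho_dna: float = SolventCondition.DEFAULT_RHO) -> float:
    """Volume fraction to mass concentration in g/mL (rho in g/cm^3)."""
    return phi * rho_dna


def concentration_to_phi(c: float, rho_dna: float = SolventCondition.DEFAULT_RHO) -> float:
    """Mass concentration in g/mL to volume fraction."""
    return c / rho_dna


@dataclass(frozen=True)
class BinodalPoint:
    """Coexisting compositions at one solvent quality.

    ``phi_dilute`` may underflow to ``0.0`` for very long chains;
    ``log10_phi_dilute`` is always finite and is the authoritative value
    on the dilute branch.  Concentrations are in g/mL.
    """

    chi: float
    phi_dilute: float
    phi_dense: float
    log10_phi_dilute: float
    c_dilute: float
    c_dense: float
    alpha_dilute: float
    alpha_dense: float
    residual_mu_dna: float
    residual_mu_solvent: float


def binodal_point(
    chain: DNAChain,
    chi: float,
    solvent: Optional[SolventCondition] = None,
    dense_alpha_unity: bool = False,
    tol: float = 1e-10,
) -> Optional[BinodalPoint]:
    """Coexisting dilute/dense volume fractions at solvent quality ``chi``.

    Solves the simultaneous equality of DNA and solvent chemical
    potentials between the two phases.  The dilute phase uses the collapse
    ``alpha`` at ``chi``; the dense phase uses the unperturbed ``alpha``
    of a theta-solvent (``chi = 0.5``), or exactly 1 when
    ``dense_alpha_unity`` is set.

    The system reduces to two nested scalar root-finds: for a trial
    dilute fraction, solvent-potential equality fixes the dense fraction
    uniquely on the decreasing branch beyond the second spinodal; the
    remaining DNA-potential mismatch is a scalar function of
    ``ln(phi_dilute)`` that is bracketed and solved with Brent's method.
    Working in ``ln(phi)`` keeps chromosome-scale chains (dilute branch
    far below double-precision underflow) solvable.

    Returns
    -------
    BinodalPoint or None
        ``None`` signals "no coexistence" (``chi`` at or below the
        critical point, or no root of the coexistence system).

    Raises
    ------
    DomainError
        If ``chi <= 0``.
    """
    if chi <= 0:
        raise DomainError(f"chi must be positive, got {chi}")
    if solvent is None:
        solvent = SolventCondition(chi=chi)
    else:
        solvent = solvent.at_chi(chi)
    n = chain.segment_number_N
    if chi <= critical_chi(chain) * (1.0 + 1e-12):
        return None

    alpha_dil = expansion_alpha(chain, solvent)
    if dense_alpha_unity:
        alpha_den = 1.0
    else:
        alpha_den = expansion_alpha(chain, solvent.at_chi(0.5))
    g_dil = internal_free_energy(alpha_dil, chain, solvent)
    g_den = internal_free_energy(alpha_den, chain, solvent)

    # spinodal roots of d mu_solvent / d phi = 0:
    # 2 chi phi^2 - (2 chi - 1 + 1/N) phi + 1/N = 0
    a_, b_, c_ = 2.0 * chi, -(2.0 * chi - 1.0 + 1.0 / n), 1.0 / n
    disc = b_ * b_ - 4.0 * a_ * c_
    if disc <= 0:
        return None
    sq = math.sqrt(disc)
    ps1 = (-b_ - sq) / (2.0 * a_)  # local min of mu_solvent
    ps2 = (-b_ + sq) / (2.0 * a_)  # local max of mu_solvent

    def mus(phi: float) -> float:
        return _mu_solvent(phi, n, chi)

    # Dilute fractions whose solvent potential cannot be matched on the
    # dense branch (below the local max at ps2) are excluded from the
    # outer bracket.
    t_lo = math.log(1e-300)
    if mus(ps2) < 0.0:
        f = lambda t: mus(math.exp(t)) - mus(ps2)
        t_hi0 = math.log(ps1) - 1e-9
        if f(t_lo) * f(t_hi0) < 0:
            t_lo = brentq(f, t_lo, t_hi0, xtol=1e-12) + 1e-9

    def phi_dense_for(t1: float) -> float:
        phi1 = math.exp(t1) if t1 > -745.0 else 0.0
        target = mus(phi1)
        f = lambda p: mus(p) - target
        lo, hi = ps2 * (1.0 + 1e-12) + 1e-300, 1.0 - 1e-14
        if f(lo) < 0.0 or f(hi) > 0.0:
            raise ConvergenceError(
                f"dense-branch bracket failed at chi={chi}, N={n}, t1={t1}"
            )
        return brentq(f, lo, hi, xtol=1e-16, rtol=8.9e-16)

    def mismatch(t1: float) -> float:
        phi2 = phi_dense_for(t1)
        return _mu_dna_log(t1, n, chi, g_dil) - _mu_dna_log(
            math.log(phi2), n, chi, g_den
        )

    t_hi = math.log(ps1) - 1e-7
    ts = np.linspace(t_lo, t_hi, 256)
    vals = np.array([mismatch(t) for t in ts])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) > 0:
        i = sign_change[0]
        lo_b, hi_b = ts[i], ts[i + 1]
    elif vals[0] > 0:
        # Root lies below the double-precision underflow of phi: there the
        # dilute mu_DNA is exactly linear in t = ln(phi) and the dense side
        # is constant, so step straight to the root and bracket it.
        t_guess = t_lo - vals[0]
        lo_b, hi_b = t_guess - 1.0, t_lo
        if mismatch(lo_b) > 0:
            return None
    else:
        return None
    t1 = brentq(mismatch, lo_b, hi_b, xtol=1e-13, rtol=8.9e-16)
    phi1 = math.exp(t1) if t1 > -745.0 else 0.0
    phi2 = phi_dense_for(t1)

    res_d = mismatch(t1)
    res_s = mus(phi1) - mus(phi2)
    if abs(res_s) > tol or abs(res_d) > max(tol, 1e-9 * abs(g_dil)):
        raise ConvergenceError(
            f"binodal residuals above tolerance at chi={chi}, N={n}: "
            f"d_mu_solvent={res_s:.3e}, d_mu_dna={res_d:.3e}"
        )
    rho = solvent.rho_dna
    return BinodalPoint(
        chi=chi,
        phi_dilute=phi1,
        phi_dense=phi2,
        log10_phi_dilute=t1 / math.log(10.0),
        c_dilute=phi_to_concentration(phi1, rho),
        c_dense=phi_to_concentration(phi2, rho),
        alpha_dilute=alpha_dil,
        alpha_dense=alpha_den,
        residual_mu_dna=res_d,
        residual_mu_solvent=res_s,
    )


@dataclass(frozen=True)
class PhaseDiagram:
    """Binodal branch and collapse boundary of one chain over a chi grid."""

    chain: DNAChain
    chi_grid: tuple[float, ...]
    binodal_points: tuple[Optional[BinodalPoint], ...]
    alphas: tuple[float, ...]
    collapse_chi: Optional[float]

    def to_dataframe(self):
        """Tidy table: one row per chi with coexistence and collapse data."""
        import pandas as pd

        rows = []
        for chi, bp, alpha in zip(self.chi_grid, self.binodal_points, self.alphas):
            rows.append(
                {
                    "length_bp": self.chain.length_bp,
                    "chi": chi,
                    "alpha_dilute": alpha,
                    "coexists": bp is not None,
                    "phi_dilute": bp.phi_dilute if bp else np.nan,
                    "phi_dense": bp.phi_dense if bp else np.nan,
                    "log10_phi_dilute": bp.log10_phi_dilute if bp else np.nan,
                    "c_dilute_g_per_mL": bp.c_dilute if bp else np.nan,
                    "c_dense_g_per_mL": bp.c_dense if bp else np.nan,
                }
            )
        return pd.DataFrame(rows)


def phase_diagram(
    chain: DNAChain,
    chi_grid: Sequence[float],
    solvent: Optional[SolventCondition] = None,
    collapse_threshold: float = 0.5,
    collapse_jump: float = 0.2,
    dense_alpha_unity: bool = False,
) -> PhaseDiagram:
    """Binodal branch plus dilute-solution collapse boundary over a chi grid.

    ``collapse_chi`` is the smallest grid ``chi`` at which the expansion
    factor either drops below ``collapse_threshold`` or jumps down by more
    than ``collapse_jump`` between adjacent grid points (the collapse
    transition is strongly first-order here, so the two criteria normally
    coincide).

    Raises
    ------
    DomainError
        For an empty or unsorted ``chi_grid``.
    """
    chis = [float(c) for c in chi_grid]
    if len(chis) == 0:
        raise DomainError("chi_grid must not be empty")
    if any(b <= a for a, b in zip(chis, chis[1:])):
        raise DomainError("chi_grid must be sorted strictly ascending")
    base = solvent if solvent is not None else SolventCondition(chi=chis[0])

    alphas = [expansion_alpha(chain, base.at_chi(c)) for c in chis]
    collapse_chi = None
    prev = None
    for c, a in zip(chis, alphas):
        if a < collapse_threshold or (prev is not None and prev - a > collapse_jump):
            collapse_chi = c
            break
        prev = a

    points = [
        binodal_point(chain, c, solvent=base, dense_alpha_unity=dense_alpha_unity)
        for c in chis
    ]
    return PhaseDiagram(
        chain=chain,
        chi_grid=tuple(chis),
        binodal_points=tuple(points),
        alphas=tuple(alphas),
        collapse_chi=collapse_chi,
    )
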