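"""Forward model of steady-state polarized fluorescence from probes on oriented filaments.

The "helix plus isotropic" model describes a fluorescent probe population in a
muscle fiber as a mixture of two components:

* an *ordered* fraction whose absorption and emission dipoles lie on cones of
  half-angles ``phi_a`` and ``phi_e`` about the local actin-filament axis, the
  filament itself wobbling about the fiber axis by at most ``theta_half``;
* a *disordered* fraction ``n_disordered`` of isotropically oriented probes.

Measured are four intensity components I_xy where the first subscript is the
excitation polarization and the second the emission polarization, each either
parallel (``p``, along the fiber axis OZ) or transverse (``t``, along OX; the
light propagates along OY).  Each component is the photoselection average
``<(a.e_exc)^2 (e.e_em)^2>`` over the orientation distribution.

For the ordered branch the probes are distributed along the actin helix, so the
dipole azimuths about the filament axis are averaged uniformly and
independently for absorption and emission.  With that averaging the mean
projection of a cone dipole onto a lab axis has the closed form

    f_phi(c^2) = cos^2(phi) * c^2 + sin^2(phi) * (1 - c^2) / 2,

where ``c = w . e_axis`` is the projection of the filament axis onto the lab
axis, and each intensity factorizes into f_A * f_E averaged over the filament
wobble.  This construction reproduces the textbook magic angle: for collinear
dipoles on a rigid cone the two polarization ratios cross zero together at
arccos(1/sqrt(3)) = 54.7356 deg.

The disordered branch is a rigid, randomly oriented dipole pair with fixed
inter-dipole angle gamma, whose photoselection averages are the classical
closed forms (1 + 2 cos^2 g)/15 for parallel-polarizer components and
(2 - cos^2 g)/15 for crossed ones, i.e. fundamental anisotropy
r0 = (3 cos^2 g - 1)/5.

All interface angles are degrees; radians are used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

__all__ = [
    "ProbeGeometry",
    "OrientationState",
    "IntensityQuadruple",
    "PolarizationRatios",
    "Quadrature",
    "InfeasibleGeometryError",
    "AEDANS_S1",
    "FITC_ACTIN",
    "AF_TPM",
    "BUILTIN_PROBES",
    "isotropic_quadruple",
    "ordered_quadruple",
    "model_quadruple",
    "polarization_ratios",
    "magic_angle_solve",
    "tied_phi_a",
    "dipole_azimuth_offset",
]

MAGIC_ANGLE_DEG = math.degrees(math.acos(1.0 / math.sqrt(3.0)))


class InfeasibleGeometryError(ValueError):
    """Raised when a (phi_a, phi_e, gamma) combination is geometrically impossible."""


@dataclass(frozen=True)
class ProbeGeometry:
    """A fluorescent dye characterized by its inter-dipole angle.

    Parameters
    ----------
    name : str
        Probe identifier.
    gamma : float
        Angle between the absorption and emission transition dipoles, degrees.
        Fixed per dye and never fitted.
    """

    name: str
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 90.0:
            raise ValueError(f"gamma must be in [0, 90] deg, got {self.gamma}")


#: 1,5-IAEDANS on Cys707 of myosin subfragment-1 (SH1 helix)
AEDANS_S1 = ProbeGeometry("AEDANS-S1", 20.0)
#: FITC-phalloidin bound in the F-actin groove
FITC_ACTIN = ProbeGeometry("FITC-actin", 14.0)
#: 5-IAF on Cys190 of tropomyosin
AF_TPM = ProbeGeometry("AF-Tpm", 17.0)

BUILTIN_PROBES = {p.name: p for p in (AEDANS_S1, FITC_ACTIN, AF_TPM)}


def tied_phi_a(phi_e: float, gamma: float) -> float:
    """Absorption-cone half-angle tied to the emission cone (coplanar dipoles).

    The inverse problem fits only ``phi_e``; the absorption cone is tied as
    ``phi_a = phi_e - gamma`` (or ``phi_e + gamma`` when ``phi_e < gamma``),
    which keeps the inter-dipole angle at gamma with zero azimuthal offset.
    """
    return phi_e - gamma if phi_e >= gamma else phi_e + gamma


def dipole_azimuth_offset(phi_a: float, phi_e: float, gamma: float) -> float:
    """Azimuthal offset delta (deg) between the two dipoles on their cones.

    Solves ``cos g = cos(phi_a) cos(phi_e) + sin(phi_a) sin(phi_e) cos(delta)``.
    Raises :class:`InfeasibleGeometryError` when gamma is outside
    ``[|phi_a - phi_e|, phi_a + phi_e]`` so no delta exists.
    """
    a, e, g = (math.radians(x) for x in (phi_a, phi_e, gamma))
    denom = math.sin(a) * math.sin(e)
    num = math.cos(g) - math.cos(a) * math.cos(e)
    if denom == 0.0:
        if abs(num) < 1e-12:
            return 0.0
        raise InfeasibleGeometryError(
            f"no dipole azimuth offset exists: |phi_a - phi_e| = "
            f"{abs(phi_a - phi_e):.3f} deg must not exceed gamma = {gamma} deg"
        )
    x = num / denom
    if x > 1.0 + 1e-9 or x < -1.0 - 1e-9:
        raise InfeasibleGeometryError(
            f"gamma = {gamma} deg outside feasible range "
            f"[{abs(phi_a - phi_e):.3f}, {phi_a + phi_e:.3f}] deg "
            f"for phi_a = {phi_a}, phi_e = {phi_e}"
        )
    return math.degrees(math.acos(min(1.0, max(-1.0, x))))


@dataclass(frozen=True)
class OrientationState:
    """Orientation-model parameters for one probe population.

    Parameters
    ----------
    phi_e : float
        Emission-cone half-angle about the filament axis, degrees.
    n_disordered : float
        Fraction of isotropically (disorderly) oriented probes in [0, 1].
        This is the quantity reported as N in fit results; the ordered
        fraction is ``1 - n_disordered``.
    theta_half : float
        Maximal deviation of the filament axis from the fiber axis, degrees.
    phi_a : float, optional
        Absorption-cone half-angle, degrees.  When None it is tied to
        ``phi_e`` through the probe's gamma (see :func:`tied_phi_a`).
    """

    phi_e: float
    n_disordered: float
    theta_half: float
    phi_a: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_e <= 90.0:
            raise ValueError(f"phi_e must be in [0, 90] deg, got {self.phi_e}")
        if self.phi_a is not None and not 0.0 <= self.phi_a <= 90.0:
            raise ValueError(f"phi_a must be in [0, 90] deg, got {self.phi_a}")
        if not 0.0 <= self.n_disordered <= 1.0:
            raise ValueError(
                f"n_disordered must be in [0, 1], got {self.n_disordered}"
            )
        if not 0.0 <= self.theta_half < 90.0:
            raise ValueError(
                f"theta_half must be in [0, 90) deg, got {self.theta_half}"
            )

    def resolve_phi_a(self, probe: ProbeGeometry) -> float:
        """Explicit phi_a, applying the gamma tie when phi_a is unset."""
        if self.phi_a is None:
            return tied_phi_a(self.phi_e, probe.gamma)
        if abs(self.phi_a - self.phi_e) > probe.gamma + 1e-9:
            raise InfeasibleGeometryError(
                f"|phi_a - phi_e| = {abs(self.phi_a - self.phi_e):.3f} deg "
                f"exceeds gamma = {probe.gamma} deg for probe {probe.name}"
            )
        return self.phi_a


@dataclass(frozen=True)
class IntensityQuadruple:
    """The four polarized fluorescence components for one fiber/condition.

    Ordered as (pIp, pIt, tIt, tIp): first subscript excitation polarization,
    second emission polarization; arbitrary common units.
    """

    i_pp: float
    i_pt: float
    i_tt: float
    i_tp: float

    def __post_init__(self) -> None:
        comps = self.as_array()
        if np.any(comps < 0):
            raise ValueError(f"intensities must be nonnegative, got {tuple(comps)}")
        if not np.any(comps > 0):
            raise ValueError("at least one intensity component must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.i_pp, self.i_pt, self.i_tt, self.i_tp], dtype=float)

    def total(self) -> float:
        return float(self.as_array().sum())

    def normalized(self) -> "IntensityQuadruple":
        """Sum-normalized copy (components summing to 1)."""
        return IntensityQuadruple(*(self.as_array() / self.total()))

    def scaled(self, c: float) -> "IntensityQuadruple":
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return IntensityQuadruple(*(self.as_array() * c))


@dataclass(frozen=True)
class PolarizationRatios:
    """P_par = (pIp - pIt)/(pIp + pIt), P_perp = (tIt - tIp)/(tIt + tIp)."""

    p_par: float
    p_perp: float


@dataclass(frozen=True)
class Quadrature:
    """Integration settings for the ordered-branch orientation average.

    ``n_beta`` points on the periodic filament azimuth (the integrand is a
    degree-4 trigonometric polynomial, so any grid with >= 5 points is exact;
    64 is kept as a generous default), ``n_theta`` Gauss-Legendre nodes on the
    wobble polar angle.  ``wobble`` selects the filament-deviation density:
    ``"polar"`` is uniform in the polar angle on [0, theta_half] (the default,
    honoring theta_half as a plain maximal deviation), ``"solid_angle"`` is
    uniform over the spherical cap.  ``check`` re-evaluates at doubled
    resolution and errors if agreement is worse than ``rtol``.
    """

    n_beta: int = 64
    n_theta: int = 32
    wobble: str = "polar"
    check: bool = False
    rtol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_beta < 5 or self.n_theta < 2:
            raise ValueError("quadrature resolution too low (n_beta >= 5, n_theta >= 2)")
        if self.wobble not in ("polar", "solid_angle"):
            raise ValueError(f"unknown wobble distribution {self.wobble!r}")


DEFAULT_QUADRATURE = Quadrature()


def isotropic_quadruple(probe: ProbeGeometry) -> IntensityQuadruple:
    """Photoselection averages for a static isotropic population (closed form).

    Parallel-polarizer components (pIp, tIt) are (1 + 2 cos^2 g)/15; crossed
    components (pIt, tIp) are (2 - cos^2 g)/15, with g the probe's
    inter-dipole angle.  Scale is arbitrary but fixed so that the four
    components sum to the same value as any other population (the two
    populations share absorption cross-section and quantum yield).
    """
    c2 = math.cos(math.radians(probe.gamma)) ** 2
    par = (1.0 + 2.0 * c2) / 15.0
    crossed = (2.0 - c2) / 15.0
    return IntensityQuadruple(par, crossed, par, crossed)


def _cone_projection(phi_rad: float, c2: np.ndarray) -> np.ndarray:
    # azimuth-averaged <(d . e_axis)^2> for a dipole on a cone of half-angle
    # phi about an axis whose squared projection on the lab axis is c2
    return math.cos(phi_rad) ** 2 * c2 + math.sin(phi_rad) ** 2 * (1.0 - c2) / 2.0


def _ordered_components(
    phi_a: float, phi_e: float, theta_half: float, quad: Quadrature
) -> np.ndarray:
    a = math.radians(phi_a)
    e = math.radians(phi_e)
    th = math.radians(theta_half)

    if th == 0.0:
        theta = np.array([0.0])
        w = np.array([1.0])
    else:
        x, gw = leggauss(quad.n_theta)
        theta = 0.5 * th * (x + 1.0)
        if quad.wobble == "polar":
            w = gw * 0.5  # uniform density 1/theta_half, absorbed in weights
        else:
            s = np.sin(theta)
            w = gw * s
            w = w / w.sum()
    beta = (np.arange(quad.n_beta) + 0.5) * (2.0 * math.pi / quad.n_beta)

    cz2 = np.cos(theta) ** 2  # (w . z)^2, shape (ntheta,)
    cx2 = np.sin(theta)[:, None] ** 2 * np.cos(beta)[None, :] ** 2  # (w . x)^2

    fa_z = _cone_projection(a, cz2)
    fe_z = _cone_projection(e, cz2)
    fa_x = _cone_projection(a, cx2)
    fe_x = _cone_projection(e, cx2)

    wb = np.full(quad.n_beta, 1.0 / quad.n_beta)
    i_pp = np.sum(w * fa_z * fe_z) * np.sum(wb)
    i_pt = np.sum(w * fa_z * (fe_x @ wb))
    i_tp = np.sum(w * (fa_x @ wb) * fe_z)
    i_tt = np.sum(w * ((fa_x * fe_x) @ wb))
    if th != 0.0 and quad.wobble == "polar":
        norm = w.sum()  # equals 1/2 * 2 = 1; kept explicit for safety
        return np.array([i_pp, i_pt, i_tt, i_tp]) / norm
    return np.array([i_pp, i_pt, i_tt, i_tp])


def ordered_quadruple(
    state: OrientationState,
    probe: ProbeGeometry,
    quadrature: Quadrature = DEFAULT_QUADRATURE,
) -> IntensityQuadruple:
    """Photoselection averages for the fully ordered (helical) population.

    Averages ``(a.e_exc)^2 (e.e_em)^2`` over (i) the dipole azimuths, uniform
    and independent on their cones (the probes are distributed along the actin
    helix), (ii) the filament azimuth, uniform, and (iii) the filament polar
    deviation on [0, theta_half] per the configured wobble distribution.
    ``state.n_disordered`` is ignored here; see :func:`model_quadruple` for
    the mixture.

    Raises
    ------
    InfeasibleGeometryError
        If the explicit (phi_a, phi_e) pair is incompatible with the probe's
        inter-dipole angle.
    RuntimeError
        If ``quadrature.check`` is set and doubling the resolution moves the
        result by more than ``quadrature.rtol`` (reported in the message).
    """
    phi_a = state.resolve_phi_a(probe)
    comps = _ordered_components(phi_a, state.phi_e, state.theta_half, quadrature)
    if quadrature.check:
        fine = replace(quadrature, n_beta=2 * quadrature.n_beta,
                       n_theta=2 * quadrature.n_theta, check=False)
        comps_fine = _ordered_components(phi_a, state.phi_e, state.theta_half, fine)
        achieved = float(np.max(np.abs(comps - comps_fine) / np.maximum(comps_fine, 1e-300)))
        if achieved > quadrature.rtol:
            raise RuntimeError(
                f"quadrature not converged: relative tolerance achieved "
                f"{achieved:.3e} > requested {quadrature.rtol:.3e}"
            )
    return IntensityQuadruple(*comps)


def model_quadruple(
    state: OrientationState,
    probe: ProbeGeometry,
    quadrature: Quadrature = DEFAULT_QUADRATURE,
) -> IntensityQuadruple:
    """Mixture forward model: (1 - N) * ordered + N * isotropic.

    N = ``state.n_disordered``.  The mixture is component-wise with no
    per-population renormalization — both populations share absorption
    cross-section and quantum yield — and the result is defined up to one
    common positive scale.
    """
    n = state.n_disordered
    iso = isotropic_quadruple(probe).as_array()
    if n >= 1.0:
        return IntensityQuadruple(*iso)
    ordered = ordered_quadruple(state, probe, quadrature).as_array()
    return IntensityQuadruple(*((1.0 - n) * ordered + n * iso))


def polarization_ratios(q: IntensityQuadruple) -> PolarizationRatios:
    """Exact polarization-ratio arithmetic; scale invariant by construction."""
    den_par = q.i_pp + q.i_pt
    den_perp = q.i_tt + q.i_tp
    if den_par <= 0 or den_perp <= 0:
        raise ZeroDivisionError(
            f"polarization ratios undefined: pIp + pIt = {den_par}, "
            f"tIt + tIp = {den_perp}; both must be positive"
        )
    return PolarizationRatios(
        p_par=(q.i_pp - q.i_pt) / den_par,
        p_perp=(q.i_tt - q.i_tp) / den_perp,
    )


def magic_angle_solve(
    probe: ProbeGeometry,
    theta_half: float = 0.0,
    quadrature: Quadrature = DEFAULT_QUADRATURE,
    xtol: float = 1e-4,
) -> float:
    """Cone half-angle (deg) at which P_par equals P_perp for ordered probes.

    Solves on (0, 90) deg for the fully ordered state with phi_a = phi_e
    (untied; N = 0 disordered).  For collinear dipoles and no filament wobble
    the root is the magic angle 54.74 deg.
    """

    def gap(phi: float) -> float:
        state = OrientationState(
            phi_e=phi, n_disordered=0.0, theta_half=theta_half, phi_a=phi
        )
        r = polarization_ratios(ordered_quadruple(state, probe, quadrature))
        return r.p_par - r.p_perp

    lo, hi = 1e-3, 90.0 - 1e-3
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"no sign change of P_par - P_perp in ({lo}, {hi}) deg: "
            f"endpoints {g_lo:.4f}, {g_hi:.4f}"
        )
    return float(brentq(gap, lo, hi, xtol=xtol))
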