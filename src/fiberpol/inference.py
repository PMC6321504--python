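"""Inverse orientation fitting, ensemble aggregation, stiffness and frame correction.

The inverse problem recovers (phi_e, N, theta_half) per fiber by least squares
between the sum-normalized observed intensity quadruple and the forward model,
with the absorption cone tied to the emission cone through the probe's fixed
inter-dipole angle.  Fiber ensembles (typically 8-10 ghost fibers per
condition) are summarized as mean +/- SEM per parameter.

The filament wobble half-angle converts to a bending stiffness through the
semiflexible-filament relation for a filament of length L clamped at one end,

    sin^2(theta) = 0.87 * (k T / epsilon) * L,

so epsilon = 0.87 k T L / sin^2(theta_half).  Tropomyosin cone angles can be
re-expressed in the rotating F-actin frame ("corrected" phi_e) by subtracting
the actin-probe angular shift relative to a reference condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann
from scipy.optimize import least_squares

from .photophysics import (
    DEFAULT_QUADRATURE,
    IntensityQuadruple,
    OrientationState,
    ProbeGeometry,
    Quadrature,
    model_quadruple,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "OrientationModel",
    "OrientationEnsembleResults",
    "StiffnessContext",
    "fit_orientation",
    "fit_ensemble",
    "stiffness_from_theta",
    "theta_from_stiffness",
    "corrected_phi_e",
    "SEMIFLEXIBLE_COEFF",
]

#: numerical coefficient of the semiflexible-filament relation
SEMIFLEXIBLE_COEFF = 0.87

#: default filament length (m) and temperature (K) for stiffness conversion
DEFAULT_L = 1e-6
DEFAULT_T = 293.15


@dataclass(frozen=True)
class FitOptions:
    """Settings of the per-fiber bounded least-squares fit.

    A deterministic multi-start grid (5 phi_e x 3 N x 3 theta_half = 45
    starts) is scored by SSR; the ``n_polish`` best starts are refined with
    bounded least squares and the global best refined minimum is returned.
    Bounds: phi_e in [0, 90] deg, N in [0, 1], theta_half in [0, 60] deg.
    """

    phi_e_starts: tuple = (15.0, 30.0, 45.0, 60.0, 75.0)
    n_starts_grid: tuple = (0.1, 0.5, 0.9)
    theta_starts: tuple = (5.0, 25.0, 45.0)
    n_polish: int = 8
    bounds_lo: tuple = (0.0, 0.0, 0.0)
    bounds_hi: tuple = (90.0, 1.0, 60.0)
    ftol: float = 1e-14
    xtol: float = 1e-12
    gtol: float = 1e-14
    ssr_tie: float = 1e-6
    tie_phi_e: float = 2.0
    tie_n: float = 0.05
    disordered_cut: float = 0.99
    quadrature: Quadrature = DEFAULT_QUADRATURE

    @property
    def n_starts(self) -> int:
        return len(self.phi_e_starts) * len(self.n_starts_grid) * len(self.theta_starts)


DEFAULT_FIT_OPTIONS = FitOptions()


@dataclass
class FitResult:
    """Single-fiber inverse-model fit.

    ``estimate.n_disordered`` is the reported N (disordered-probe fraction).
    ``degenerate`` flags distinct tied minima; ``disordered_only`` flags fits
    where N ~ 1 so the ordered-population parameters are unidentifiable.
    """

    estimate: OrientationState
    ssr: float
    n_starts: int
    degenerate: bool = False
    disordered_only: bool = False

    @property
    def phi_e(self) -> float:
        return self.estimate.phi_e

    @property
    def n_disordered(self) -> float:
        return self.estimate.n_disordered

    @property
    def theta_half(self) -> float:
        return self.estimate.theta_half


def _residuals_factory(q: IntensityQuadruple, probe: ProbeGeometry, quad: Quadrature):
    obs = q.as_array()
    obs = obs / obs.sum()

    def residuals(p: np.ndarray) -> np.ndarray:
        phi_e, n_dis, theta = p
        state = OrientationState(
            phi_e=float(np.clip(phi_e, 0.0, 90.0)),
            n_disordered=float(np.clip(n_dis, 0.0, 1.0)),
            theta_half=float(np.clip(theta, 0.0, 89.999)),
        )
        model = model_quadruple(state, probe, quad).as_array()
        return model / model.sum() - obs

    return residuals


def fit_orientation(
    q: IntensityQuadruple,
    probe: ProbeGeometry,
    options: FitOptions = DEFAULT_FIT_OPTIONS,
) -> FitResult:
    """Fit the helix-plus-isotropic model to one intensity quadruple.

    Minimizes the SSR between sum-normalized observed and model quadruples
    over (phi_e, N, theta_half); the probe's gamma is fixed and phi_a is tied
    to phi_e.  Returns the global best over the multi-start grid.

    Raises
    ------
    RuntimeError
        If every polished start fails to converge (with per-start diagnostics).
    """
    residuals = _residuals_factory(q, probe, options.quadrature)

    starts = [
        np.array([pe, nd, th])
        for pe in options.phi_e_starts
        for nd in options.n_starts_grid
        for th in options.theta_starts
    ]
    coarse = np.array([float(np.sum(residuals(p) ** 2)) for p in starts])
    order = np.argsort(coarse)[: max(1, options.n_polish)]

    minima: list[tuple[float, np.ndarray]] = []
    failures: list[str] = []
    for idx in order:
        try:
            sol = least_squares(
                residuals,
                starts[idx],
                bounds=(options.bounds_lo, options.bounds_hi),
                ftol=options.ftol,
                xtol=options.xtol,
                gtol=options.gtol,
                max_nfev=400,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"start {starts[idx]}: {exc}")
            continue
        if not sol.success and not np.isfinite(sol.cost):
            failures.append(f"start {starts[idx]}: {sol.message}")
            continue
        minima.append((2.0 * sol.cost, sol.x))
    if not minima:
        raise RuntimeError(
            "orientation fit failed from every start:\n" + "\n".join(failures)
        )

    minima.sort(key=lambda t: t[0])
    best_ssr, best_p = minima[0]
    degenerate = any(
        (ssr - best_ssr) <= options.ssr_tie
        and (
            abs(p[0] - best_p[0]) > options.tie_phi_e
            or abs(p[1] - best_p[1]) > options.tie_n
        )
        for ssr, p in minima[1:]
    )
    disordered_only = best_p[1] >= options.disordered_cut

    phi_e, n_dis, theta = (float(x) for x in best_p)
    state = OrientationState(phi_e=phi_e, n_disordered=n_dis, theta_half=theta)
    # store the tied phi_a explicitly on the returned estimate
    state = OrientationState(
        phi_e=phi_e,
        n_disordered=n_dis,
        theta_half=theta,
        phi_a=state.resolve_phi_a(probe),
    )
    return FitResult(
        estimate=state,
        ssr=float(best_ssr),
        n_starts=options.n_starts,
        degenerate=bool(degenerate),
        disordered_only=bool(disordered_only),
    )


@dataclass
class OrientationEnsembleResults:
    """Fit results for an ensemble of fibers measured under one condition.

    Carries per-fiber :class:`FitResult` objects plus mean and SEM of each
    parameter.  SEM is NaN (and ``sem_defined`` False) for a single fiber.
    """

    per_fiber: list[FitResult]
    n_failed: int
    probe: ProbeGeometry

    @property
    def n_fibers(self) -> int:
        return len(self.per_fiber)

    @property
    def sem_defined(self) -> bool:
        return self.n_fibers >= 2

    def values(self, param: str) -> np.ndarray:
        return np.array([getattr(f, param) for f in self.per_fiber])

    def mean(self, param: str) -> float:
        return float(self.values(param).mean())

    def sem(self, param: str) -> float:
        if not self.sem_defined:
            return float("nan")
        v = self.values(param)
        return float(v.std(ddof=1) / math.sqrt(len(v)))

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {p: self.mean(p) for p in ("phi_e", "n_disordered", "theta_half")}
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            {p: self.sem(p) for p in ("phi_e", "n_disordered", "theta_half")}
        )

    def sin2_theta(self) -> np.ndarray:
        """Per-fiber sin^2 of the fitted wobble angle (propto 1/epsilon).

        This is the directly fitted, well-behaved quantity; per-fiber epsilon
        is its reciprocal and has no finite moments when the wobble is near
        zero, so ensemble stiffness is derived from the MEAN sin^2(theta)
        (see :meth:`ensemble_stiffness`).
        """
        return np.sin(np.radians(self.values("theta_half"))) ** 2

    def stiffness(self, L: float = DEFAULT_L, T: float = DEFAULT_T) -> np.ndarray:
        """Per-fiber bending stiffness (N m^2); inf where the fitted wobble is 0."""
        s2 = self.sin2_theta()
        with np.errstate(divide="ignore"):
            return SEMIFLEXIBLE_COEFF * Boltzmann * T * L / s2

    def ensemble_stiffness(
        self, L: float = DEFAULT_L, T: float = DEFAULT_T
    ) -> float:
        """Condition-level bending stiffness from the ensemble-mean sin^2(theta).

        Returns NaN when every fiber fitted zero wobble.
        """
        m = float(self.sin2_theta().mean())
        if m <= 0.0:
            return float("nan")
        return SEMIFLEXIBLE_COEFF * Boltzmann * T * L / m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phi_e": self.values("phi_e"),
                "phi_a": [f.estimate.phi_a for f in self.per_fiber],
                "n_disordered": self.values("n_disordered"),
                "theta_half": self.values("theta_half"),
                "ssr": [f.ssr for f in self.per_fiber],
                "degenerate": [f.degenerate for f in self.per_fiber],
                "disordered_only": [f.disordered_only for f in self.per_fiber],
            }
        )

    def summary(self) -> str:
        lines = [
            "Orientation ensemble fit",
            f"  probe: {self.probe.name} (gamma = {self.probe.gamma} deg)",
            f"  fibers: {self.n_fibers} fitted, {self.n_failed} failed",
            f"  {'param':<14}{'mean':>10}{'SEM':>10}",
        ]
        for p, label in (
            ("phi_e", "Phi_E (deg)"),
            ("n_disordered", "N"),
            ("theta_half", "theta½ (deg)"),
        ):
            lines.append(f"  {label:<14}{self.mean(p):>10.3f}{self.sem(p):>10.3f}")
        return "\n".join(lines)


class OrientationModel:
    """Helix-plus-isotropic orientation model for a fiber ensemble.

    Parameters
    ----------
    quadruples : sequence of IntensityQuadruple
        One measured quadruple per fiber (all same probe and condition).
    probe : ProbeGeometry
        The dye; its inter-dipole angle gamma is fixed, never fitted.
    options : FitOptions, optional

    Examples
    --------
    >>> model = OrientationModel(quads, AEDANS_S1)
    >>> res = model.fit()
    >>> res.params["n_disordered"], res.bse["n_disordered"]
    """

    def __init__(
        self,
        quadruples,
        probe: ProbeGeometry,
        options: FitOptions = DEFAULT_FIT_OPTIONS,
    ):
        quadruples = list(quadruples)
        if not quadruples:
            raise ValueError("at least one fiber quadruple is required")
        self.quadruples = quadruples
        self.probe = probe
        self.options = options

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        probe: ProbeGeometry,
        options: FitOptions = DEFAULT_FIT_OPTIONS,
    ) -> "OrientationModel":
        """Build from a frame with I_pp, I_pt, I_tt, I_tp columns (one row per fiber)."""
        quads = [
            IntensityQuadruple(r.I_pp, r.I_pt, r.I_tt, r.I_tp)
            for r in df.itertuples()
        ]
        return cls(quads, probe, options)

    def fit(self) -> OrientationEnsembleResults:
        fits: list[FitResult] = []
        errors: list[str] = []
        for i, q in enumerate(self.quadruples):
            try:
                fits.append(fit_orientation(q, self.probe, self.options))
            except RuntimeError as exc:
                errors.append(f"fiber {i}: {exc}")
        if not fits:
            raise RuntimeError(
                "all fibers failed to fit:\n" + "\n".join(errors)
            )
        return OrientationEnsembleResults(
            per_fiber=fits, n_failed=len(errors), probe=self.probe
        )


def fit_ensemble(
    qs,
    probe: ProbeGeometry,
    options: FitOptions = DEFAULT_FIT_OPTIONS,
) -> OrientationEnsembleResults:
    """Functional wrapper: fit every fiber and aggregate (mean +/- SEM)."""
    return OrientationModel(qs, probe, options).fit()


@dataclass(frozen=True)
class StiffnessContext:
    """Bending stiffness with the length/temperature used to derive it.

    ``epsilon`` in N m^2 (the field reports it in units of 1e-26 N m^2;
    see :attr:`epsilon_1e26`); ``at_boundary`` marks sin^2(theta) = 1.
    """

    epsilon: float
    L: float
    T: float
    k: float = Boltzmann
    at_boundary: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.L <= 0 or self.T <= 0:
            raise ValueError("epsilon, L and T must all be positive")

    @property
    def epsilon_1e26(self) -> float:
        """Stiffness in the conventional reporting units of 1e-26 N m^2."""
        return self.epsilon * 1e26

    @property
    def sin2_theta(self) -> float:
        return SEMIFLEXIBLE_COEFF * self.k * self.T * self.L / self.epsilon


def stiffness_from_theta(
    theta_half: float, L: float = DEFAULT_L, T: float = DEFAULT_T
) -> StiffnessContext:
    """Bending stiffness from the wobble half-angle: eps = 0.87 k T L / sin^2(theta)."""
    if not 0.0 < theta_half < 90.0:
        raise ValueError(
            f"theta_half must be in (0, 90) deg for stiffness conversion, "
            f"got {theta_half}"
        )
    s2 = math.sin(math.radians(theta_half)) ** 2
    eps = SEMIFLEXIBLE_COEFF * Boltzmann * T * L / s2
    return StiffnessContext(
        epsilon=eps, L=L, T=T, at_boundary=abs(s2 - 1.0) < 1e-12
    )


def theta_from_stiffness(ctx: StiffnessContext) -> float:
    """Wobble half-angle (deg) implied by a stiffness: exact inverse of
    :func:`stiffness_from_theta` on the shared domain.

    Raises
    ------
    ValueError
        If 0.87 k T L / epsilon exceeds 1 (filament too soft for the
        small-angle regime of the relation).
    """
    s2 = ctx.sin2_theta
    if s2 > 1.0:
        raise ValueError(
            f"sin^2(theta) = {s2:.4f} > 1: filament too soft for the "
            f"semiflexible relation at L = {ctx.L} m, T = {ctx.T} K"
        )
    if s2 == 1.0:
        warnings.warn("sin^2(theta) = 1: theta at the 90 deg boundary")
    return math.degrees(math.asin(math.sqrt(s2)))


def corrected_phi_e(
    tpm_obs: float, actin_obs: float, actin_ref: float
) -> float:
    """Tropomyosin phi_e re-expressed in the rotating F-actin frame.

    corrected = tpm_obs - (actin_obs - actin_ref): the tropomyosin cone angle
    minus the rotation of the actin helix relative to the reference condition
    (by default the S1-free, low-Ca blocked state).  Invariant under adding a
    common constant to actin_obs and actin_ref.
    """
    for name, v in (("tpm_obs", tpm_obs), ("actin_obs", actin_obs),
                    ("actin_ref", actin_ref)):
        if not 0.0 <= v <= 90.0:
            raise ValueError(f"{name} must be in [0, 90] deg, got {v}")
    corrected = tpm_obs - (actin_obs - actin_ref)
    if not 0.0 <= corrected <= 90.0:
        warnings.warn(
            f"corrected phi_e = {corrected:.2f} deg outside [0, 90]; clamped"
        )
        corrected = min(90.0, max(0.0, corrected))
    return corrected
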