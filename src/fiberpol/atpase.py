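"""Ca2+-activated ATPase curves: baseline/maximum normalization and Hill fitting.

Actin-activated S1 ATPase is assayed over a pCa ladder (pCa 8 -> 4).  Raw
activities are corrected by subtracting the S1-alone baseline and normalized
to the post-subtraction maximum, then fitted to the Hill equation

    a(pCa) = floor + amplitude / (1 + 10^(nH * (pCa - pCa50)))

which decreases in pCa (saturates at high Ca2+, i.e. low pCa).  pCa50 is the
calcium sensitivity readout; replicates are fitted jointly in one SSR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ATPaseCurve",
    "HillFit",
    "HillModel",
    "normalize_activity",
    "hill_model",
    "fit_hill",
]


@dataclass(frozen=True)
class ATPaseCurve:
    """An ATPase activity vs pCa data set (replicates as repeated pCa values).

    ``baseline`` is the S1-alone activity in the same (arbitrary) units;
    zero for already-corrected data.
    """

    pCa: np.ndarray
    activity: np.ndarray
    baseline: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pCa", np.asarray(self.pCa, dtype=float))
        object.__setattr__(self, "activity", np.asarray(self.activity, dtype=float))
        if self.pCa.shape != self.activity.shape:
            raise ValueError("pCa and activity must have matching shapes")
        if not np.all(np.isfinite(self.activity)) or not np.all(np.isfinite(self.pCa)):
            raise ValueError("pCa and activity values must be finite")
        if np.any(self.pCa < 4.0) or np.any(self.pCa > 9.0):
            raise ValueError("pCa values must lie within [4, 9]")

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.pCa))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, baseline: float = 0.0) -> "ATPaseCurve":
        """From a long-format frame with ``pCa`` and ``activity`` columns."""
        return cls(df["pCa"].to_numpy(), df["activity"].to_numpy(), baseline)


def normalize_activity(curve: ATPaseCurve) -> ATPaseCurve:
    """Subtract the baseline, divide by the shared post-subtraction maximum.

    Output activities lie in [~0, 1] with maximum exactly 1 and baseline 0;
    idempotent on already-normalized data.
    """
    shifted = curve.activity - curve.baseline
    peak = shifted.max()
    if peak <= 0:
        raise ValueError(
            f"non-positive dynamic range after baseline subtraction "
            f"(max activity - baseline = {peak:.4g})"
        )
    return ATPaseCurve(curve.pCa.copy(), shifted / peak, baseline=0.0)


def hill_model(
    pCa,
    pCa50: float,
    n_h: float,
    floor: float = 0.0,
    amplitude: float = 1.0,
):
    """Hill equation in pCa: floor + amplitude / (1 + 10^(nH (pCa - pCa50)))."""
    if n_h <= 0:
        raise ValueError(f"Hill coefficient must be positive, got {n_h}")
    pCa = np.asarray(pCa, dtype=float)
    out = floor + amplitude / (1.0 + 10.0 ** (n_h * (pCa - pCa50)))
    return float(out) if out.ndim == 0 else out


_PARAM_NAMES = ("pCa50", "n_h", "floor", "amplitude")
_BOUNDS_LO = np.array([4.0, 1e-6, -0.2, 1e-6])
_BOUNDS_HI = np.array([8.0, 6.0, 0.5, 1.5])
_PCA50_STARTS = (5.0, 6.0, 6.5, 7.0, 7.5)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with Jacobian-based standard errors."""

    pCa50: float
    n_h: float
    floor: float
    amplitude: float
    se_pCa50: float
    se_n_h: float
    ssr: float
    n_obs: int
    at_bound: bool = False

    def predict(self, pCa):
        return hill_model(pCa, self.pCa50, self.n_h, self.floor, self.amplitude)


class HillModel:
    """Hill-equation model of a normalized ATPase-pCa curve.

    Parameters
    ----------
    curve : ATPaseCurve
        Normalized curve (run :func:`normalize_activity` first if it still
        carries a baseline); needs >= 4 distinct pCa points.

    ``fit()`` runs bounded nonlinear least squares over
    (pCa50 in [4, 8], nH in (0, 6], floor in [-0.2, 0.5], amplitude in
    (0, 1.5]) from a deterministic pCa50 start grid and returns a
    :class:`HillResults`.
    """

    def __init__(self, curve: ATPaseCurve):
        if curve.n_distinct < 4:
            raise ValueError(
                f"need >= 4 distinct pCa points to fit, got {curve.n_distinct}"
            )
        if curve.baseline != 0.0:
            curve = normalize_activity(curve)
        self.curve = curve

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, baseline: float = 0.0) -> "HillModel":
        curve = ATPaseCurve.from_dataframe(df, baseline)
        if baseline != 0.0:
            curve = normalize_activity(curve)
        return cls(curve)

    def fit(self) -> "HillResults":
        y = self.curve.activity
        if float(y.max() - y.min()) < 1e-9:
            raise ValueError(
                "activity curve is flat: Hill parameters are unidentifiable"
            )
        x = self.curve.pCa

        def residuals(p):
            return hill_model(x, *p) - y

        best = None
        for p50 in _PCA50_STARTS:
            p0 = np.clip(
                np.array([p50, 1.5, 0.0, 1.0]), _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9
            )
            sol = least_squares(
                residuals, p0, bounds=(_BOUNDS_LO, _BOUNDS_HI),
                ftol=1e-14, xtol=1e-12, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        p = best.x
        ssr = 2.0 * best.cost
        dof = max(1, len(y) - len(p))
        try:
            cov = np.linalg.inv(best.jac.T @ best.jac) * ssr / dof
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(len(p), np.nan)
        at_bound = bool(
            np.any(np.abs(p - _BOUNDS_LO) < 1e-8) or np.any(np.abs(p - _BOUNDS_HI) < 1e-8)
        )
        fitres = HillFit(
            pCa50=float(p[0]), n_h=float(p[1]), floor=float(p[2]),
            amplitude=float(p[3]), se_pCa50=float(se[0]), se_n_h=float(se[1]),
            ssr=float(ssr), n_obs=len(y), at_bound=at_bound,
        )
        return HillResults(self, fitres)


class HillResults:
    """Results wrapper for a fitted Hill curve (statsmodels-flavoured)."""

    def __init__(self, model: HillModel, fit: HillFit):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> pd.Series:
        f = self.fit
        return pd.Series(
            {"pCa50": f.pCa50, "n_h": f.n_h, "floor": f.floor,
             "amplitude": f.amplitude}
        )

    @property
    def bse(self) -> pd.Series:
        f = self.fit
        return pd.Series(
            {"pCa50": f.se_pCa50, "n_h": f.se_n_h, "floor": float("nan"),
             "amplitude": float("nan")}
        )

    @property
    def pCa50(self) -> float:
        return self.fit.pCa50

    def predict(self, pCa):
        return self.fit.predict(pCa)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Hill fit of normalized ATPase-pCa curve",
            f"  n obs: {f.n_obs}  SSR: {f.ssr:.4g}"
            + ("  [parameter at bound]" if f.at_bound else ""),
            f"  pCa50     = {f.pCa50:.3f} +/- {f.se_pCa50:.3f}",
            f"  nH        = {f.n_h:.3f} +/- {f.se_n_h:.3f}",
            f"  floor     = {f.floor:.3f}",
            f"  amplitude = {f.amplitude:.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: data points and the fitted curve vs pCa."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.curve.pCa
        ax.plot(x, self.model.curve.activity, "o", label="data")
        grid = np.linspace(x.min(), x.max(), 200)
        ax.plot(grid, self.predict(grid), "-", label="Hill fit")
        ax.invert_xaxis()  # high Ca2+ (low pCa) on the right
        ax.set_xlabel("pCa")
        ax.set_ylabel("normalized activity")
        ax.legend()
        return ax


def fit_hill(curve: ATPaseCurve) -> HillFit:
    """Functional wrapper: normalize if needed, fit, return the HillFit."""
    return HillModel(curve).fit().fit
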