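"""Seeded synthetic experiments: fiber ensembles and ATPase assays.

The generator emulates the full study design so every pipeline stage is
testable without measured data: per condition it draws ``n_fibers`` intensity
quadruples from the forward model of a true orientation state, perturbed by
per-component multiplicative lognormal noise (default CV 2%), and per variant
a triplicate ATPase activity table over the pCa 8 -> 4 ladder from a Hill
curve with additive Gaussian noise.

Wild-type truth values are anchored to the characterized ghost-fiber numbers
for the slow-muscle gamma-tropomyosin system (cone angles, disordered
fractions and bending stiffnesses per state of the actomyosin ATPase cycle;
pCa50 per variant); entries with no published value are fixed once at
field-realistic levels and documented in the methods note.  Mutant scenarios
are derived from the wild type by applying the trinary feature row of the
reference signature matrix with fixed effect magnitudes (2 deg on cone
angles, 0.08 on disordered fractions, x/1.7 on stiffness), so the
generator's truth table IS the expected classification outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atpase import ATPaseCurve, hill_model
from .comparison import (
    CA_LEVELS,
    MISSING,
    NORM,
    UP,
    DOWN,
    ConditionKey,
    ReferenceSignature,
    load_reference_signatures,
)
from .inference import (
    DEFAULT_L,
    DEFAULT_T,
    StiffnessContext,
    stiffness_from_theta,
    theta_from_stiffness,
)
from .photophysics import (
    AEDANS_S1,
    AF_TPM,
    BUILTIN_PROBES,
    FITC_ACTIN,
    IntensityQuadruple,
    OrientationState,
    ProbeGeometry,
    model_quadruple,
)

__all__ = [
    "ConditionTruth",
    "ScenarioTable",
    "default_scenario",
    "wildtype_conditions",
    "scenario_from_signature",
    "generate_fiber_dataset",
    "generate_atpase_assay",
    "PROBE_BY_TARGET",
    "WT_PCA50",
    "MUTANT_PCA50",
    "EFFECT_PHI_E",
    "EFFECT_N",
    "EFFECT_EPS_FACTOR",
]

PROBE_BY_TARGET = {"Tpm": AF_TPM, "actin": FITC_ACTIN, "S1": AEDANS_S1}

#: default wild-type calcium sensitivity (midpoint of the reported WT range)
WT_PCA50 = 6.5
#: reported pCa50 per mutant variant
MUTANT_PCA50 = {"E173A": 6.84, "R90P": 6.92, "E150A": 7.33, "A155T": 6.69}

#: effect magnitudes used to encode mutant scenarios (see module docstring)
EFFECT_PHI_E = 2.0  # degrees
EFFECT_N = 0.08  # disordered-fraction units
EFFECT_EPS_FACTOR = 1.7  # stiffness ratio
#: pCa50 shift applied for variants without a reported value
EFFECT_PCA50 = 0.34


@dataclass(frozen=True)
class ConditionTruth:
    """True (phi_e, N, epsilon) for one condition; theta_half is derived
    from epsilon via the semiflexible-filament relation at the scenario's
    L and T."""

    phi_e: float
    n_disordered: float
    epsilon: float  # N m^2

    def state(self, L: float = DEFAULT_L, T: float = DEFAULT_T) -> OrientationState:
        theta = theta_from_stiffness(StiffnessContext(self.epsilon, L, T))
        return OrientationState(
            phi_e=self.phi_e, n_disordered=self.n_disordered, theta_half=theta
        )


def _eps_from_theta(theta_half: float, L: float = DEFAULT_L, T: float = DEFAULT_T) -> float:
    return stiffness_from_theta(theta_half, L, T).epsilon


def wildtype_conditions(L: float = DEFAULT_L, T: float = DEFAULT_T) -> dict:
    """WT truth table over the 12 conditions the signature features read.

    Published anchors: tropomyosin corrected cone angles 56.7/58.6 deg
    (-S1, high/low Ca) and 54.2/54.7 deg (AM state), 54.8 deg under ATP;
    tropomyosin stiffness 13.9e-26 (-S1, high Ca) and 16.1 -> 7.5 e-26 N m^2
    (AM -> ATP); actin angles 48.4 -> 47.5 deg (AM -> ATP, high Ca) with the
    high-Ca value 1.5 deg above low Ca in the -S1 state; actin stiffness
    5.2e-26 (-S1, high Ca) and 4.2 -> 5.5 e-26 (AM -> ATP); S1-probe
    44.7 -> 51.2 deg and N 0.393/0.432 -> 0.576 (AM -> ATP).  S1-probe
    wobble is fixed at 25 deg.
    """
    eps_s1 = _eps_from_theta(25.0, L, T)
    tpm = "Tpm"
    act = "actin"
    s1 = "S1"
    k = ConditionKey
    return {
        # tropomyosin probe (5-IAF), -S1 and AM states
        k(tpm, "high", "none", False): ConditionTruth(56.7, 0.20, 13.9e-26),
        k(tpm, "low", "none", False): ConditionTruth(58.6, 0.20, 10.0e-26),
        k(tpm, "high", "none", True): ConditionTruth(54.2, 0.20, 16.1e-26),
        k(tpm, "low", "none", True): ConditionTruth(54.7, 0.20, 14.0e-26),
        # actin probe (FITC-phalloidin)
        k(act, "high", "none", False): ConditionTruth(46.5, 0.25, 5.2e-26),
        k(act, "low", "none", False): ConditionTruth(45.0, 0.25, 6.0e-26),
        k(act, "high", "none", True): ConditionTruth(48.4, 0.25, 4.2e-26),
        k(act, "low", "none", True): ConditionTruth(47.2, 0.25, 4.6e-26),
        # myosin-head probe (1,5-IAEDANS), AM and AM*.ATP states
        k(s1, "high", "none", True): ConditionTruth(44.7, 0.393, eps_s1),
        k(s1, "low", "none", True): ConditionTruth(45.5, 0.432, eps_s1),
        k(s1, "high", "ATP", True): ConditionTruth(51.2, 0.576, eps_s1),
        k(s1, "low", "ATP", True): ConditionTruth(51.2, 0.576, eps_s1),
    }


def scenario_from_signature(
    wt: dict,
    row: ReferenceSignature,
    variant: str,
    d_phi: float = EFFECT_PHI_E,
    d_n: float = EFFECT_N,
    eps_factor: float = EFFECT_EPS_FACTOR,
) -> dict:
    """Mutant truth table implied by a trinary reference row.

    Inverts the feature map of :mod:`fiberpol.comparison`: e.g. a ``up``
    troponin-shift feature lowers the tropomyosin cone angle by ``d_phi``;
    ``up`` strong binding lowers both Phi_E and N of the S1 probe.  Missing
    and norm features leave the WT truth unchanged.
    """
    feats = row.feature_dict
    out: dict[ConditionKey, ConditionTruth] = {}

    def sgn(feature: str) -> int:
        v = feats.get(feature, MISSING)
        return {UP: 1, DOWN: -1}.get(v, 0)

    for key, truth in wt.items():
        ca = key.ca
        phi, n, eps = truth.phi_e, truth.n_disordered, truth.epsilon
        if key.probe_target == "Tpm" and key.nucleotide == "none":
            shift = f"tn_shift_{ca}" if not key.s1_present else f"s1_shift_{ca}"
            phi -= sgn(shift) * d_phi  # inner-domain shift = lower angle
            if not key.s1_present:
                eps *= eps_factor ** sgn(f"tpm_stiffness_{ca}")
        elif key.probe_target == "actin" and key.nucleotide == "none":
            feat = (
                f"actin_on_tpm_{ca}" if not key.s1_present else f"actin_on_s1_{ca}"
            )
            phi += sgn(feat) * d_phi
        elif key.probe_target == "S1":
            feat = (
                f"strong_binding_{ca}"
                if key.nucleotide == "none"
                else f"strong_binding_atp_{ca}"
            )
            phi -= sgn(feat) * d_phi
            n -= sgn(feat) * d_n
        out[replace(key, variant=variant)] = ConditionTruth(phi, n, eps)
    return out


@dataclass
class ScenarioTable:
    """Complete specification of a synthetic experiment.

    ``conditions`` maps variant-carrying :class:`ConditionKey`s to truth
    parameters; ``pca50``/``n_h`` drive the ATPase branch; ``cv`` is the
    per-component multiplicative noise CV and ``n_fibers`` the ensemble size
    per condition.
    """

    conditions: dict
    pca50: dict
    n_h: float = 1.5
    cv: float = 0.02
    n_fibers: int = 10
    L: float = DEFAULT_L
    T: float = DEFAULT_T
    atpase_noise_sd: float = 0.03
    atpase_baseline: float = 0.1

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        for key in self.conditions:
            if key.probe_target not in PROBE_BY_TARGET:
                raise ValueError(f"unresolvable condition {key}")
            if key.variant is None:
                raise ValueError(f"scenario condition {key} lacks a variant")

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.conditions):
            t = self.conditions[key]
            state = t.state(self.L, self.T)
            rows.append(
                {
                    "variant": key.variant,
                    "probe_target": key.probe_target,
                    "ca": key.ca,
                    "nucleotide": key.nucleotide,
                    "s1_present": key.s1_present,
                    "phi_e": t.phi_e,
                    "n_disordered": t.n_disordered,
                    "theta_half": state.theta_half,
                    "epsilon_1e26": t.epsilon * 1e26,
                }
            )
        return pd.DataFrame(rows)


def default_scenario(
    variants=("WT", "E173A", "R90P", "E150A", "A155T"),
    n_fibers: int = 10,
    cv: float = 0.02,
    references: list | None = None,
) -> ScenarioTable:
    """The default study design: WT plus the four gamma-tropomyosin mutants.

    Mutant truths are generated from the corresponding rows of the packaged
    reference signature matrix (gene TPM3); unknown variant names raise.
    """
    wt = wildtype_conditions()
    if references is None:
        references = load_reference_signatures()
    by_name = {(r.name, r.gene): r for r in references}
    conditions: dict[ConditionKey, ConditionTruth] = {}
    pca50: dict[str, float] = {}
    for variant in variants:
        if variant == "WT":
            conditions.update(
                {replace(k, variant="WT"): v for k, v in wt.items()}
            )
            pca50["WT"] = WT_PCA50
            continue
        row = by_name.get((variant, "TPM3"))
        if row is None:
            raise ValueError(f"no reference row for variant {variant!r} (TPM3)")
        conditions.update(scenario_from_signature(wt, row, variant))
        if variant in MUTANT_PCA50:
            pca50[variant] = MUTANT_PCA50[variant]
        else:
            shift = {UP: EFFECT_PCA50, DOWN: -EFFECT_PCA50}.get(
                row.feature_dict["ca_sensitivity"], 0.0
            )
            pca50[variant] = WT_PCA50 + shift
    return ScenarioTable(
        conditions=conditions, pca50=pca50, n_fibers=n_fibers, cv=cv
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested coefficient of variation."""
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size) - 0.5 * sigma * sigma)


def generate_fiber_dataset(scenario: ScenarioTable, seed: int):
    """Simulate the fiber table: returns (DataFrame, truth DataFrame).

    The frame follows the fiber-CSV schema (fiber_id, variant, probe_target,
    ca, nucleotide, s1_present, I_pp, I_pt, I_tt, I_tp).  Deterministic under
    (scenario, seed); conditions are generated in sorted key order.

    Raises
    ------
    ValueError
        If a truth state is infeasible, naming the offending condition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for key in sorted(scenario.conditions):
        truth = scenario.conditions[key]
        probe = PROBE_BY_TARGET[key.probe_target]
        try:
            state = truth.state(scenario.L, scenario.T)
            base = model_quadruple(state, probe).as_array()
        except (ValueError, RuntimeError) as exc:
            raise ValueError(
                f"infeasible truth state for condition {key.label()}: {exc}"
            ) from exc
        factors = _lognormal_factors(rng, scenario.cv, (scenario.n_fibers, 4))
        for i in range(scenario.n_fibers):
            vals = base * factors[i]
            rows.append(
                {
                    "fiber_id": f"{key.variant}-{key.probe_target}-{key.ca}"
                    f"-{key.nucleotide}-{'S1' if key.s1_present else 'noS1'}"
                    f"-{i:02d}",
                    "variant": key.variant,
                    "probe_target": key.probe_target,
                    "ca": key.ca,
                    "nucleotide": key.nucleotide,
                    "s1_present": key.s1_present,
                    "I_pp": vals[0],
                    "I_pt": vals[1],
                    "I_tt": vals[2],
                    "I_tp": vals[3],
                }
            )
    return pd.DataFrame(rows), scenario.truth_frame()


def generate_atpase_assay(
    pCa50: float,
    n_h: float = 1.5,
    noise_sd: float = 0.03,
    n_replicates: int = 3,
    seed: int = 0,
    baseline: float = 0.1,
) -> ATPaseCurve:
    """Simulate one ATPase assay on the pCa 8 -> 4 ladder (0.25 steps).

    Activity = baseline + Hill(pCa; floor 0, amplitude 1) + N(0, noise_sd),
    replicated ``n_replicates`` times per pCa; deterministic under ``seed``.
    """
    if not 4.0 <= pCa50 <= 8.0:
        raise ValueError(f"pCa50 must be in [4, 8], got {pCa50}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    grid = np.arange(8.0, 4.0 - 1e-9, -0.25)
    pCa = np.repeat(grid, n_replicates)
    clean = hill_model(pCa, pCa50, n_h, 0.0, 1.0)
    noise = rng.normal(0.0, noise_sd, pCa.shape) if noise_sd > 0 else 0.0
    return ATPaseCurve(pCa=pCa, activity=baseline + clean + noise, baseline=baseline)
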