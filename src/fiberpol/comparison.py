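"""Mutant-vs-WT deltas, trinary sign calls and myopathy-signature classification.

For each experimental condition (probe target x Ca level x nucleotide x S1
presence) the mutant and wild-type fiber ensembles are compared per parameter
(Phi_E, epsilon, N) with a two-sample Student's t-test; significant
differences become trinary calls (up / down / norm).  The calls map onto a
15-feature interpretation vector — calcium sensitivity, tropomyosin stiffness,
azimuthal tropomyosin shifts driven by troponin or by myosin heads, actin
monomer switching, and strong binding of myosin heads (with and without ATP),
each at high and low Ca2+ — and the vector is classified against a packaged
reference matrix of previously characterized mutations plus per-myopathy
consensus patterns by nearest-neighbor Hamming distance.

Interpretation conventions (probe geometry -> physiology):

* a DECREASE of Phi_E for the tropomyosin probe means a shift of tropomyosin
  toward the inner actin domain (feature "shift" goes UP);
* an increase of Phi_E for the actin probe means more switched-on monomers;
* strong binding of myosin heads requires CONCORDANT decreases of both Phi_E
  and N of the S1 probe; discordant evidence yields a missing feature.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "UP",
    "DOWN",
    "NORM",
    "MISSING",
    "FEATURE_NAMES",
    "ConditionKey",
    "ConditionSamples",
    "SignCall",
    "ParamDelta",
    "DeltaRecord",
    "DeltaTable",
    "MyopathySignature",
    "ReferenceSignature",
    "ClassificationResult",
    "sign_call",
    "delta_table",
    "signature_from_deltas",
    "classify_signature",
    "load_reference_signatures",
]

UP = "up"
DOWN = "down"
NORM = "norm"
MISSING = "missing"

PROBE_TARGETS = ("Tpm", "actin", "S1")
CA_LEVELS = ("high", "low")
NUCLEOTIDES = ("none", "ADP", "ATP")

#: the 15 interpretation features, ordered as in the reference matrix
FEATURE_NAMES = (
    "ca_sensitivity",
    "tpm_stiffness_high",
    "tpm_stiffness_low",
    "tn_shift_high",
    "tn_shift_low",
    "s1_shift_high",
    "s1_shift_low",
    "actin_on_tpm_high",
    "actin_on_tpm_low",
    "actin_on_s1_high",
    "actin_on_s1_low",
    "strong_binding_high",
    "strong_binding_low",
    "strong_binding_atp_high",
    "strong_binding_atp_low",
)


@dataclass(frozen=True, order=True)
class ConditionKey:
    """One experimental condition of the ghost-fiber assay.

    Nucleotide states are defined via the myosin head (AM without nucleotide,
    AM.ADP with MgADP, AM*.ATP with MgATP), so a nucleotide other than
    ``none`` — and the S1 probe itself — require S1 to be present.
    """

    probe_target: str
    ca: str
    nucleotide: str = "none"
    s1_present: bool = True
    variant: str | None = None

    def __post_init__(self) -> None:
        if self.probe_target not in PROBE_TARGETS:
            raise ValueError(f"unknown probe_target {self.probe_target!r}")
        if self.ca not in CA_LEVELS:
            raise ValueError(f"ca must be 'high' or 'low', got {self.ca!r}")
        if self.nucleotide not in NUCLEOTIDES:
            raise ValueError(f"unknown nucleotide {self.nucleotide!r}")
        if self.probe_target == "S1" and not self.s1_present:
            raise ValueError("probe_target 'S1' requires s1_present")
        if self.nucleotide != "none" and not self.s1_present:
            raise ValueError(
                "nucleotide states are defined via the myosin head; "
                f"nucleotide={self.nucleotide!r} requires s1_present"
            )

    def condition(self) -> tuple:
        """Variant-independent identity used to match mutant against WT."""
        return (self.probe_target, self.ca, self.nucleotide, self.s1_present)

    def label(self) -> str:
        s1 = "+S1" if self.s1_present else "-S1"
        v = f"{self.variant}:" if self.variant else ""
        return f"{v}{self.probe_target}/{self.ca}Ca/{self.nucleotide}/{s1}"


@dataclass
class ConditionSamples:
    """Per-fiber parameter samples for one condition (inputs to the t-tests).

    Stiffness is carried as per-fiber sin^2(theta_half) — the directly fitted
    quantity, proportional to 1/epsilon — because per-fiber epsilon is a
    reciprocal with no finite moments when the wobble is small.  The epsilon
    delta is computed from ensemble means and its significance tested on the
    sin^2 values with the sign flipped.
    """

    phi_e: np.ndarray
    sin2_theta: np.ndarray
    n_disordered: np.ndarray
    L: float = 1e-6
    T: float = 293.15

    @classmethod
    def from_results(cls, results, L: float = 1e-6, T: float = 293.15):
        """Adapter from an :class:`~fiberpol.inference.OrientationEnsembleResults`."""
        return cls(
            phi_e=results.values("phi_e"),
            sin2_theta=results.sin2_theta(),
            n_disordered=results.values("n_disordered"),
            L=L,
            T=T,
        )

    def ensemble_epsilon(self) -> float:
        from scipy.constants import Boltzmann

        m = float(np.asarray(self.sin2_theta, float).mean())
        if m <= 0.0:
            return float("nan")
        return 0.87 * Boltzmann * self.T * self.L / m


class SignCall(NamedTuple):
    sign: str
    p_value: float
    t_stat: float


def sign_call(
    mutant_values,
    wt_values,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> SignCall:
    """Trinary call from a two-sample two-sided t-test (Student by default).

    Returns ``up``/``down`` by the sign of (mutant mean - WT mean) when
    p < alpha, otherwise ``norm``.  Two zero-variance samples with equal
    means give ``norm``; with unequal means the difference is certain and
    p is reported as 0.
    """
    m = np.asarray(mutant_values, dtype=float)
    w = np.asarray(wt_values, dtype=float)
    if len(m) < 2 or len(w) < 2:
        raise ValueError("each sample needs at least 2 values for a t-test")
    diff = m.mean() - w.mean()
    if m.std() == 0.0 and w.std() == 0.0:
        if diff == 0.0:
            return SignCall(NORM, 1.0, 0.0)
        return SignCall(UP if diff > 0 else DOWN, 0.0, float("inf"))
    t, p = stats.ttest_ind(m, w, equal_var=equal_var)
    if p < alpha:
        return SignCall(UP if diff > 0 else DOWN, float(p), float(t))
    return SignCall(NORM, float(p), float(t))


@dataclass
class ParamDelta:
    """Mutant-minus-WT difference for one parameter under one condition."""

    delta: float
    sem: float
    p_value: float
    sign: str


@dataclass
class DeltaRecord:
    key: ConditionKey
    phi_e: ParamDelta
    epsilon: ParamDelta
    n_disordered: ParamDelta


@dataclass
class DeltaTable:
    """Delta records over the shared conditions; unmatched keys are reported."""

    records: list
    unmatched_mutant: list
    unmatched_wt: list

    def by_condition(self) -> dict:
        return {r.key.condition(): r for r in self.records}


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def _param_delta(mv, wv, alpha, equal_var) -> ParamDelta:
    call = sign_call(mv, wv, alpha=alpha, equal_var=equal_var)
    mv = np.asarray(mv, float)
    wv = np.asarray(wv, float)
    sem = float(np.sqrt(_sem(mv) ** 2 + _sem(wv) ** 2))
    return ParamDelta(
        delta=float(mv.mean() - wv.mean()),
        sem=sem,
        p_value=call.p_value,
        sign=call.sign,
    )


def _epsilon_delta(ms: ConditionSamples, ws: ConditionSamples, alpha, equal_var) -> ParamDelta:
    # significance is tested on the directly fitted sin^2(theta) ~ 1/epsilon
    # and the sign flipped; the delta itself compares ensemble epsilons
    call = sign_call(ms.sin2_theta, ws.sin2_theta, alpha=alpha, equal_var=equal_var)
    em, ew = ms.ensemble_epsilon(), ws.ensemble_epsilon()
    delta = em - ew

    def _eps_sem(s: ConditionSamples, e: float) -> float:
        m = float(np.asarray(s.sin2_theta, float).mean())
        if not np.isfinite(e) or m <= 0.0:
            return float("nan")
        return e * _sem(np.asarray(s.sin2_theta, float)) / m

    sem = float(np.sqrt(_eps_sem(ms, em) ** 2 + _eps_sem(ws, ew) ** 2))
    return ParamDelta(
        delta=float(delta), sem=sem, p_value=call.p_value, sign=_flip(call.sign)
    )


def delta_table(
    mutant: Mapping[ConditionKey, ConditionSamples],
    wt: Mapping[ConditionKey, ConditionSamples],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> DeltaTable:
    """Mutant-vs-WT differences (Phi_E, epsilon, N) per shared condition.

    Conditions are matched ignoring the variant field; keys present on only
    one side are returned in the ``unmatched_*`` lists, never dropped
    silently.  Raises if no condition is shared.
    """
    wt_by_cond = {k.condition(): v for k, v in wt.items()}
    records: list[DeltaRecord] = []
    unmatched_mutant = []
    for key in sorted(mutant.keys()):
        if key.condition() not in wt_by_cond:
            unmatched_mutant.append(key)
            continue
        ms = mutant[key]
        ws = wt_by_cond[key.condition()]
        records.append(
            DeltaRecord(
                key=key,
                phi_e=_param_delta(ms.phi_e, ws.phi_e, alpha, equal_var),
                epsilon=_epsilon_delta(ms, ws, alpha, equal_var),
                n_disordered=_param_delta(
                    ms.n_disordered, ws.n_disordered, alpha, equal_var
                ),
            )
        )
    matched = {r.key.condition() for r in records}
    unmatched_wt = [k for k in sorted(wt.keys()) if k.condition() not in matched]
    if not records:
        raise ValueError("mutant and WT share no condition keys")
    for k in unmatched_mutant:
        logger.warning("condition %s present only in mutant data", k.label())
    for k in unmatched_wt:
        logger.warning("condition %s present only in WT data", k.label())
    return DeltaTable(records, unmatched_mutant, unmatched_wt)


@dataclass
class MyopathySignature:
    """Trinary feature vector over the 15 interpretation features."""

    features: dict
    label: str | None = None
    conflicts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        full = {f: self.features.get(f, MISSING) for f in FEATURE_NAMES}
        bad = {f: v for f, v in full.items() if v not in (UP, DOWN, NORM, MISSING)}
        if bad:
            raise ValueError(f"invalid feature values: {bad}")
        self.features = full

    @property
    def vector(self) -> tuple:
        return tuple(self.features[f] for f in FEATURE_NAMES)

    @property
    def n_missing(self) -> int:
        return sum(v == MISSING for v in self.vector)


def _flip(sign: str) -> str:
    return {UP: DOWN, DOWN: UP}.get(sign, sign)


def _concordant(a: str, b: str, context: str, conflicts: list) -> str:
    if a == b:
        return a
    conflicts.append(
        f"{context}: discordant Phi_E ({a}) vs N ({b}) evidence; feature set to missing"
    )
    logger.warning("%s", conflicts[-1])
    return MISSING


def signature_from_deltas(
    records: Iterable[DeltaRecord],
    pCa50_mut: float | None = None,
    pCa50_wt: float | None = None,
    se_mut: float | None = None,
    se_wt: float | None = None,
    ca_threshold: float = 0.1,
) -> MyopathySignature:
    """Deterministic mapping from delta records to the 15-feature signature.

    * tropomyosin shift features invert the Phi_E sign (a lower tropomyosin
      cone angle = a larger shift toward the inner actin domain);
    * actin switching-on follows the actin-probe Phi_E sign directly;
    * strong binding requires concordant (inverted) Phi_E and N calls of the
      S1 probe, else the feature is missing and a conflict is logged;
    * calcium sensitivity is up/down when |pCa50_mut - pCa50_wt| exceeds
      ``ca_threshold`` (and, when standard errors are supplied, the SEs do
      not overlap), else norm; missing when either pCa50 is absent.

    Conditions not covered by ``records`` yield missing features.
    """
    by_cond = {r.key.condition(): r for r in records}
    conflicts: list[str] = []
    feats: dict[str, str] = {}

    def rec(probe, ca, nuc, s1):
        return by_cond.get((probe, ca, nuc, s1))

    for ca in CA_LEVELS:
        r = rec("Tpm", ca, "none", False)
        feats[f"tn_shift_{ca}"] = _flip(r.phi_e.sign) if r else MISSING
        feats[f"tpm_stiffness_{ca}"] = r.epsilon.sign if r else MISSING
        r = rec("Tpm", ca, "none", True)
        feats[f"s1_shift_{ca}"] = _flip(r.phi_e.sign) if r else MISSING
        r = rec("actin", ca, "none", False)
        feats[f"actin_on_tpm_{ca}"] = r.phi_e.sign if r else MISSING
        r = rec("actin", ca, "none", True)
        feats[f"actin_on_s1_{ca}"] = r.phi_e.sign if r else MISSING
        r = rec("S1", ca, "none", True)
        feats[f"strong_binding_{ca}"] = (
            _concordant(
                _flip(r.phi_e.sign),
                _flip(r.n_disordered.sign),
                f"strong_binding_{ca}",
                conflicts,
            )
            if r
            else MISSING
        )
        r = rec("S1", ca, "ATP", True)
        feats[f"strong_binding_atp_{ca}"] = (
            _concordant(
                _flip(r.phi_e.sign),
                _flip(r.n_disordered.sign),
                f"strong_binding_atp_{ca}",
                conflicts,
            )
            if r
            else MISSING
        )

    if pCa50_mut is None or pCa50_wt is None:
        feats["ca_sensitivity"] = MISSING
    else:
        diff = pCa50_mut - pCa50_wt
        significant = abs(diff) > ca_threshold
        if significant and se_mut is not None and se_wt is not None:
            significant = abs(diff) > (se_mut + se_wt)
        if not significant:
            feats["ca_sensitivity"] = NORM
        else:
            feats["ca_sensitivity"] = UP if diff > 0 else DOWN

    return MyopathySignature(features=feats, conflicts=conflicts)


@dataclass(frozen=True)
class ReferenceSignature:
    """One row of the reference matrix (a characterized mutation or a
    per-myopathy consensus pattern)."""

    name: str
    gene: str
    diagnosis: str
    group: str
    kind: str
    features: tuple
    aliases: tuple = ()

    @property
    def feature_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.features))


def load_reference_signatures(path=None) -> list:
    """Load the packaged (or a user-supplied) reference signature matrix."""
    if path is None:
        ref = importlib.resources.files("fiberpol.data") / "signature_matrix.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str).fillna("")
    else:
        df = pd.read_csv(path, dtype=str).fillna("")
    missing_cols = set(FEATURE_NAMES) - set(df.columns)
    if missing_cols:
        raise ValueError(f"reference matrix lacks columns: {sorted(missing_cols)}")
    out = []
    for row in df.itertuples(index=False):
        feats = tuple(
            (getattr(row, f) or MISSING) for f in FEATURE_NAMES
        )
        out.append(
            ReferenceSignature(
                name=row.name if isinstance(row.name, str) else row[0],
                gene=row.gene,
                diagnosis=row.diagnosis,
                group=row.group or "unassigned",
                kind=row.kind,
                features=feats,
                aliases=tuple(a for a in row.aliases.split(";") if a),
            )
        )
    return out


@dataclass
class ClassificationResult:
    label: str
    distances: pd.DataFrame
    tie: bool

    @property
    def best(self) -> pd.Series:
        return self.distances.iloc[0]


def classify_signature(
    sig: MyopathySignature,
    references: list | None = None,
    tie_margin: float = 1.0 / len(FEATURE_NAMES),
) -> ClassificationResult:
    """Nearest-reference classification by normalized Hamming distance.

    Distance to each reference is the fraction of mismatching features among
    those non-missing in BOTH vectors; references sharing no feature with the
    query are excluded.  Ties at equal distance prefer the reference with
    more compared features (a full experimental row beats a sparse consensus
    pattern).  ``tie`` flags a second myopathy group within ``tie_margin``
    (one feature in 15) of the best.
    """
    if all(v == MISSING for v in sig.vector):
        raise ValueError("cannot classify: every feature of the signature is missing")
    if references is None:
        references = load_reference_signatures()
    if not references:
        raise ValueError("reference set is empty")

    rows = []
    for ref in references:
        pairs = [
            (a, b)
            for a, b in zip(sig.vector, ref.features)
            if a != MISSING and b != MISSING
        ]
        if not pairs:
            continue
        mism = sum(a != b for a, b in pairs)
        rows.append(
            {
                "name": ref.name,
                "gene": ref.gene,
                "group": ref.group,
                "kind": ref.kind,
                "distance": mism / len(pairs),
                "n_compared": len(pairs),
                "n_mismatched": mism,
            }
        )
    if not rows:
        raise ValueError("no reference shares any feature with the signature")
    df = pd.DataFrame(rows).sort_values(
        by=["distance", "n_compared", "name"], ascending=[True, False, True]
    ).reset_index(drop=True)
    best = df.iloc[0]
    others = df[df["group"] != best["group"]]
    tie = bool(
        len(others) > 0
        and (others["distance"].min() - best["distance"]) <= tie_margin + 1e-12
    )
    return ClassificationResult(label=str(best["group"]), distances=df, tie=tie)
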