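"""File schemas, run configuration and the pipeline driver.

Tabular data are RFC-4180 CSV, reports JSON, configuration YAML or JSON.
There is no domain-standard container for polarized-fluorescence fiber data,
so the schemas are defined (and versioned) here:

fiber CSV (one row per fiber per condition), header exactly::

    fiber_id,variant,probe_target,ca,nucleotide,s1_present,I_pp,I_pt,I_tt,I_tp

ATPase CSV (long format, replicates as rows)::

    variant,replicate,pCa,activity,baseline

Angles are serialized in degrees (printed at 0.1 deg precision), bending
stiffness in units of 1e-26 N m^2.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atpase import ATPaseCurve, HillModel
from .comparison import (
    ConditionKey,
    ConditionSamples,
    classify_signature,
    delta_table,
    load_reference_signatures,
    signature_from_deltas,
)
from .inference import (
    DEFAULT_L,
    DEFAULT_T,
    FitOptions,
    OrientationModel,
    corrected_phi_e,
)
from .photophysics import BUILTIN_PROBES, IntensityQuadruple, ProbeGeometry, Quadrature

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_VERSION",
    "FIBER_COLUMNS",
    "ATPASE_COLUMNS",
    "FiberRecord",
    "FiberCSVError",
    "RunConfig",
    "load_config",
    "read_fiber_csv",
    "write_fiber_csv",
    "read_atpase_csv",
    "run_pipeline",
]

SCHEMA_VERSION = "1.0"

FIBER_COLUMNS = [
    "fiber_id",
    "variant",
    "probe_target",
    "ca",
    "nucleotide",
    "s1_present",
    "I_pp",
    "I_pt",
    "I_tt",
    "I_tp",
]

ATPASE_COLUMNS = ["variant", "replicate", "pCa", "activity", "baseline"]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


class FiberCSVError(ValueError):
    """Malformed fiber CSV; the message lists every offending line."""


@dataclass(frozen=True)
class FiberRecord:
    fiber_id: str
    key: ConditionKey
    quadruple: IntensityQuadruple


def read_fiber_csv(path) -> list:
    """Parse and validate a fiber CSV; rejects malformed rows with line numbers."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FiberCSVError(f"{path}: empty file") from None
        if header != FIBER_COLUMNS:
            raise FiberCSVError(
                f"{path}: header must be exactly {','.join(FIBER_COLUMNS)}, "
                f"got {','.join(header)}"
            )
        records = []
        errors = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(FIBER_COLUMNS):
                errors.append(f"line {lineno}: expected {len(FIBER_COLUMNS)} fields")
                continue
            d = dict(zip(FIBER_COLUMNS, row))
            problems = []
            s1 = _BOOL.get(d["s1_present"].strip().lower())
            if s1 is None:
                problems.append(f"s1_present {d['s1_present']!r} not boolean")
            vals = []
            for col in ("I_pp", "I_pt", "I_tt", "I_tp"):
                try:
                    v = float(d[col])
                except ValueError:
                    problems.append(f"{col} {d[col]!r} not numeric")
                    continue
                if v < 0:
                    problems.append(f"{col} = {v} is negative")
                vals.append(v)
            key = None
            if not problems:
                try:
                    key = ConditionKey(
                        probe_target=d["probe_target"],
                        ca=d["ca"],
                        nucleotide=d["nucleotide"],
                        s1_present=s1,
                        variant=d["variant"],
                    )
                    quad = IntensityQuadruple(*vals)
                except ValueError as exc:
                    problems.append(str(exc))
            if problems:
                errors.append(f"line {lineno}: " + "; ".join(problems))
                continue
            records.append(FiberRecord(d["fiber_id"], key, quad))
    if errors:
        raise FiberCSVError(f"{path}: invalid rows:\n  " + "\n  ".join(errors))
    return records


def write_fiber_csv(records, path) -> None:
    """Inverse of :func:`read_fiber_csv` (read o write = identity on valid data)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(FIBER_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.fiber_id,
                    r.key.variant,
                    r.key.probe_target,
                    r.key.ca,
                    r.key.nucleotide,
                    r.key.s1_present,
                    repr(r.quadruple.i_pp),
                    repr(r.quadruple.i_pt),
                    repr(r.quadruple.i_tt),
                    repr(r.quadruple.i_tp),
                ]
            )


def frame_to_records(df: pd.DataFrame) -> list:
    """Fiber records from a schema-conform DataFrame (as from the generator)."""
    records = []
    for r in df.itertuples(index=False):
        key = ConditionKey(
            probe_target=r.probe_target,
            ca=r.ca,
            nucleotide=r.nucleotide,
            s1_present=bool(r.s1_present),
            variant=r.variant,
        )
        records.append(
            FiberRecord(r.fiber_id, key, IntensityQuadruple(r.I_pp, r.I_pt, r.I_tt, r.I_tp))
        )
    return records


def read_atpase_csv(path) -> dict:
    """ATPase curves per variant from the long-format CSV."""
    df = pd.read_csv(path)
    missing = set(ATPASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ATPase CSV lacks columns {sorted(missing)}")
    out = {}
    for variant, sub in df.groupby("variant", sort=True):
        baselines = sub["baseline"].unique()
        if len(baselines) != 1:
            raise ValueError(
                f"{path}: variant {variant!r} has non-constant baseline column"
            )
        out[str(variant)] = ATPaseCurve(
            pCa=sub["pCa"].to_numpy(),
            activity=sub["activity"].to_numpy(),
            baseline=float(baselines[0]),
        )
    return out


def write_atpase_csv(curves: dict, path) -> None:
    rows = []
    for variant in sorted(curves):
        c = curves[variant]
        grid = {}
        for p, a in zip(c.pCa, c.activity):
            grid.setdefault(p, []).append(a)
        for p in sorted(grid, reverse=True):
            for rep, a in enumerate(grid[p], start=1):
                rows.append(
                    {
                        "variant": variant,
                        "replicate": rep,
                        "pCa": p,
                        "activity": a,
                        "baseline": c.baseline,
                    }
                )
    pd.DataFrame(rows, columns=ATPASE_COLUMNS).to_csv(path, index=False)


_CONFIG_FIELDS = {
    "gamma",
    "L",
    "T",
    "alpha",
    "ca_sens_threshold",
    "equal_var",
    "n_polish",
    "n_beta",
    "n_theta",
    "wobble",
    "cv",
    "n_fibers",
    "signature_matrix",
    "seed",
    "reference_condition",
}


@dataclass
class RunConfig:
    """Run configuration; unknown keys in a config file are rejected.

    ``gamma`` may override the inter-dipole angle per probe target;
    ``reference_condition`` names the actin condition whose mean Phi_E
    anchors the rotating-actin-frame correction (default: the S1-free,
    low-Ca blocked state).
    """

    gamma: dict = field(default_factory=dict)
    L: float = DEFAULT_L
    T: float = DEFAULT_T
    alpha: float = 0.05
    ca_sens_threshold: float = 0.1
    equal_var: bool = True
    n_polish: int = 8
    n_beta: int = 64
    n_theta: int = 32
    wobble: str = "polar"
    cv: float = 0.02
    n_fibers: int = 10
    signature_matrix: str | None = None
    seed: int = 0
    reference_condition: dict = field(
        default_factory=lambda: {"ca": "low", "nucleotide": "none", "s1_present": False}
    )

    def probe_for(self, target: str) -> ProbeGeometry:
        base = {"Tpm": "AF-Tpm", "actin": "FITC-actin", "S1": "AEDANS-S1"}[target]
        probe = BUILTIN_PROBES[base]
        if target in self.gamma:
            probe = ProbeGeometry(probe.name, float(self.gamma[target]))
        return probe

    def fit_options(self) -> FitOptions:
        return FitOptions(
            n_polish=self.n_polish,
            quadrature=Quadrature(
                n_beta=self.n_beta, n_theta=self.n_theta, wobble=self.wobble
            ),
        )


def load_config(path) -> RunConfig:
    """Load a YAML-or-JSON run config, rejecting unknown keys and
    checking that referenced files exist."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    # YAML 1.1 reads bare scientific notation like 2e-6 as a string
    for key in ("L", "T", "alpha", "ca_sens_threshold", "cv"):
        if key in raw:
            raw[key] = float(raw[key])
    for key in ("n_polish", "n_beta", "n_theta", "n_fibers", "seed"):
        if key in raw:
            raw[key] = int(raw[key])
    cfg = RunConfig(**raw)
    if cfg.signature_matrix is not None and not Path(cfg.signature_matrix).exists():
        raise ValueError(
            f"{path}: signature_matrix file {cfg.signature_matrix!r} does not exist"
        )
    return cfg


def _group_records(records) -> dict:
    groups: dict[ConditionKey, list] = {}
    for r in records:
        groups.setdefault(r.key, []).append(r.quadruple)
    return groups


def _fit_groups(groups: dict, config: RunConfig, log: list) -> dict:
    options = config.fit_options()
    fits = {}
    for key in sorted(groups):
        probe = config.probe_for(key.probe_target)
        model = OrientationModel(groups[key], probe, options)
        res = model.fit()
        if res.n_failed:
            log.append(f"{key.label()}: {res.n_failed} fiber fit(s) failed, excluded")
        flagged = sum(f.degenerate for f in res.per_fiber)
        if flagged:
            log.append(f"{key.label()}: {flagged} fiber fit(s) flagged degenerate")
        diso = sum(f.disordered_only for f in res.per_fiber)
        if diso:
            log.append(f"{key.label()}: {diso} fiber fit(s) disordered-only")
        fits[key] = res
    return fits


def _corrected_tpm_angles(fits: dict, config: RunConfig, variant: str, log: list) -> dict:
    ref_spec = config.reference_condition
    ref_key = ConditionKey(
        "actin",
        ref_spec.get("ca", "low"),
        ref_spec.get("nucleotide", "none"),
        ref_spec.get("s1_present", False),
        variant,
    )
    if ref_key not in fits:
        log.append(
            f"{variant}: actin reference condition {ref_key.label()} missing; "
            "corrected Phi_E skipped"
        )
        return {}
    actin_ref = fits[ref_key].mean("phi_e")
    out = {}
    for key, res in fits.items():
        if key.probe_target != "Tpm" or key.variant != variant:
            continue
        actin_key = replace(key, probe_target="actin")
        if actin_key not in fits:
            log.append(
                f"{key.label()}: no matching actin condition; corrected Phi_E skipped"
            )
            continue
        out[key.label()] = corrected_phi_e(
            res.mean("phi_e"), fits[actin_key].mean("phi_e"), actin_ref
        )
    return out


def _round_floats(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if not np.isfinite(f) else round(f, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig, fiber_csv, atpase_csv=None) -> dict:
    """End-to-end analysis: fit -> stiffness -> frame correction -> Hill ->
    deltas -> signature -> classification.

    Returns a JSON-serializable report; every skipped step and flagged fit is
    recorded under ``"log"``.  With WT-only input the delta table is empty
    and classification is skipped with a logged reason.
    """
    log: list[str] = []
    records = (
        read_fiber_csv(fiber_csv)
        if isinstance(fiber_csv, (str, Path))
        else list(fiber_csv)
    )
    groups = _group_records(records)
    fits = _fit_groups(groups, config, log)

    ensembles = {
        key.label(): {
            "n_fibers": res.n_fibers,
            "phi_e": res.mean("phi_e"),
            "phi_e_sem": res.sem("phi_e"),
            "n_disordered": res.mean("n_disordered"),
            "n_disordered_sem": res.sem("n_disordered"),
            "theta_half": res.mean("theta_half"),
            "epsilon_1e26": res.ensemble_stiffness(config.L, config.T) * 1e26,
        }
        for key, res in fits.items()
    }

    variants = sorted({k.variant for k in fits})
    corrected = {}
    for variant in variants:
        corrected.update(_corrected_tpm_angles(fits, config, variant, log))

    hill = {}
    if atpase_csv is not None:
        curves = (
            read_atpase_csv(atpase_csv)
            if isinstance(atpase_csv, (str, Path))
            else atpase_csv
        )
        for variant in sorted(curves):
            res = HillModel(curves[variant]).fit()
            hill[variant] = {
                "pCa50": res.fit.pCa50,
                "se_pCa50": res.fit.se_pCa50,
                "n_h": res.fit.n_h,
                "at_bound": res.fit.at_bound,
            }
            if res.fit.at_bound:
                log.append(f"{variant}: Hill fit parameter at a bound")

    references = load_reference_signatures(config.signature_matrix)
    mutants = [v for v in variants if v != "WT"]
    deltas_out = {}
    signatures = {}
    classification = {}
    if "WT" not in variants:
        log.append("classification skipped: no WT variant in the data")
    elif not mutants:
        log.append("classification skipped: no mutant variants in the data")
    else:
        wt_samples = {
            k: ConditionSamples.from_results(v, config.L, config.T)
            for k, v in fits.items()
            if k.variant == "WT"
        }
        for variant in mutants:
            mut_samples = {
                k: ConditionSamples.from_results(v, config.L, config.T)
                for k, v in fits.items()
                if k.variant == variant
            }
            table = delta_table(
                mut_samples, wt_samples, alpha=config.alpha, equal_var=config.equal_var
            )
            for k in table.unmatched_mutant + table.unmatched_wt:
                log.append(f"{variant}: unmatched condition {k.label()}")
            deltas_out[variant] = [
                {
                    "condition": r.key.label(),
                    "d_phi_e": r.phi_e.delta,
                    "p_phi_e": r.phi_e.p_value,
                    "sign_phi_e": r.phi_e.sign,
                    "d_epsilon_1e26": r.epsilon.delta * 1e26,
                    "p_epsilon": r.epsilon.p_value,
                    "sign_epsilon": r.epsilon.sign,
                    "d_n": r.n_disordered.delta,
                    "p_n": r.n_disordered.p_value,
                    "sign_n": r.n_disordered.sign,
                }
                for r in table.records
            ]
            sig = signature_from_deltas(
                table.records,
                pCa50_mut=hill.get(variant, {}).get("pCa50"),
                pCa50_wt=hill.get("WT", {}).get("pCa50"),
                se_mut=hill.get(variant, {}).get("se_pCa50"),
                se_wt=hill.get("WT", {}).get("se_pCa50"),
                ca_threshold=config.ca_sens_threshold,
            )
            for c in sig.conflicts:
                log.append(f"{variant}: {c}")
            signatures[variant] = dict(sig.features)
            result = classify_signature(sig, references)
            classification[variant] = {
                "label": result.label,
                "tie": result.tie,
                "nearest": result.distances.head(3).to_dict(orient="records"),
            }

    report = {
        "schema_version": SCHEMA_VERSION,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": {
            "L": config.L,
            "T": config.T,
            "alpha": config.alpha,
            "seed": config.seed,
        },
        "ensembles": ensembles,
        "corrected_tpm_phi_e": corrected,
        "hill": hill,
        "deltas": deltas_out,
        "signatures": signatures,
        "classification": classification,
        "log": log,
    }
    return _round_floats(report)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
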