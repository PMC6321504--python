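"""Sign calls, delta tables, signature construction and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fiberpol.comparison import (
    DOWN,
    FEATURE_NAMES,
    MISSING,
    NORM,
    UP,
    ClassificationResult,
    ConditionKey,
    ConditionSamples,
    MyopathySignature,
    classify_signature,
    delta_table,
    load_reference_signatures,
    sign_call,
    signature_from_deltas,
)


def _samples(phi, s2, n, jitter=0.0, rng=None, n_fibers=5):
    """Constant-parameter fiber samples with optional jitter."""
    def arr(v):
        base = np.full(n_fibers, float(v))
        if jitter and rng is not None:
            base = base + rng.normal(0, jitter, n_fibers)
        return base

    return ConditionSamples(phi_e=arr(phi), sin2_theta=np.abs(arr(s2)), n_disordered=arr(n))


def default_keys():
    keys = []
    for ca in ("high", "low"):
        keys += [
            ConditionKey("Tpm", ca, "none", False, "X"),
            ConditionKey("Tpm", ca, "none", True, "X"),
            ConditionKey("actin", ca, "none", False, "X"),
            ConditionKey("actin", ca, "none", True, "X"),
            ConditionKey("S1", ca, "none", True, "X"),
            ConditionKey("S1", ca, "ATP", True, "X"),
        ]
    return keys


class TestSignCall:
    def test_identical_samples_norm(self):
        call = sign_call([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert call.sign == NORM

    def test_separated_samples(self):
        rng = np.random.default_rng(0)
        mut = 54.2 + rng.normal(0, 0.1, 10)
        wt = 51.2 + rng.normal(0, 0.1, 10)
        call = sign_call(wt, mut)  # mutant lower
        assert call.sign == DOWN and call.p_value < 1e-6

    def test_textbook_t_oracle(self):
        """Borderline case checked against the hand-computed pooled t-test."""
        m = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([2.0, 3.0, 4.0, 6.0])
        diff = m.mean() - w.mean()
        sp2 = ((len(m) - 1) * m.var(ddof=1) + (len(w) - 1) * w.var(ddof=1)) / (
            len(m) + len(w) - 2
        )
        t_hand = diff / np.sqrt(sp2 * (1 / len(m) + 1 / len(w)))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=len(m) + len(w) - 2)
        call = sign_call(m, w, alpha=0.5)
        assert call.t_stat == pytest.approx(t_hand, rel=1e-9)
        assert call.p_value == pytest.approx(p_hand, rel=1e-9)

    def test_zero_variance_unequal_means(self):
        call = sign_call([2.0, 2.0], [1.0, 1.0])
        assert call.sign == UP and call.p_value == 0.0

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError):
            sign_call([1.0], [1.0, 2.0])

    def test_alpha_monotonicity(self):
        """alpha -> 0 makes every call norm; alpha -> 1 none (unequal means)."""
        rng = np.random.default_rng(3)
        m = rng.normal(0.0, 1.0, 6)
        w = rng.normal(0.5, 1.0, 6)
        assert sign_call(m, w, alpha=1e-12).sign == NORM
        assert sign_call(m, w, alpha=1.0 - 1e-12).sign != NORM


class TestDeltaTable:
    def test_identical_data_all_norm(self):
        data = {k: _samples(50.0, 0.05, 0.3) for k in default_keys()}
        wt = {k: _samples(50.0, 0.05, 0.3) for k in default_keys()}
        table = delta_table(data, wt)
        for rec in table.records:
            for fam in (rec.phi_e, rec.epsilon, rec.n_disordered):
                assert fam.sign == NORM
                assert fam.delta == pytest.approx(0.0, abs=1e-12)

    def test_planted_offset_detected(self):
        keys = default_keys()
        wt = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        mut = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        target = keys[4]  # S1 probe, high Ca, AM state
        mut[target] = _samples(52.0, 0.05, 0.3)
        table = delta_table(mut, wt)
        for rec in table.records:
            expect = UP if rec.key == target else NORM
            assert rec.phi_e.sign == expect
            if rec.key == target:
                assert rec.phi_e.delta == pytest.approx(2.0)

    def test_antisymmetry(self, rng):
        keys = default_keys()
        a = {
            k: _samples(50 + rng.normal(), 0.05, 0.3, jitter=0.2, rng=rng)
            for k in keys
        }
        b = {
            k: _samples(50 + rng.normal(), 0.06, 0.35, jitter=0.2, rng=rng)
            for k in keys
        }
        fwd = {r.key.condition(): r for r in delta_table(a, b).records}
        rev = {r.key.condition(): r for r in delta_table(b, a).records}
        flip = {UP: DOWN, DOWN: UP, NORM: NORM}
        for cond, r in fwd.items():
            s = rev[cond]
            for fam in ("phi_e", "epsilon", "n_disordered"):
                rf, sf = getattr(r, fam), getattr(s, fam)
                assert sf.sign == flip[rf.sign]
                assert sf.delta == pytest.approx(-rf.delta, rel=1e-9, abs=1e-15)

    def test_unmatched_keys_reported(self):
        keys = default_keys()
        wt = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        mut = {k: _samples(50.0, 0.05, 0.3) for k in keys[:-1]}
        extra = ConditionKey("S1", "high", "ADP", True, "X")
        mut[extra] = _samples(50.0, 0.05, 0.3)
        table = delta_table(mut, wt)
        assert [k.condition() for k in table.unmatched_mutant] == [extra.condition()]
        assert [k.condition() for k in table.unmatched_wt] == [keys[-1].condition()]

    def test_no_shared_keys_raises(self):
        wt = {ConditionKey("S1", "high", "none", True, "WT"): _samples(50, 0.05, 0.3)}
        mut = {ConditionKey("S1", "low", "none", True, "M"): _samples(50, 0.05, 0.3)}
        with pytest.raises(ValueError, match="share no condition"):
            delta_table(mut, wt)


def build_signature_inputs(row_features, d_phi=2.0, d_n=0.08, eps_factor=1.7):
    """Noise-free mutant/WT sample pairs realizing a trinary feature row."""
    feats = dict(zip(FEATURE_NAMES, row_features))
    sgn = lambda f: {UP: 1, DOWN: -1}.get(feats.get(f, MISSING), 0)
    keys = default_keys()
    wt = {k: _samples(50.0, 0.05, 0.3) for k in keys}
    mut = {}
    for k in keys:
        phi, s2, n = 50.0, 0.05, 0.3
        ca = k.ca
        if k.probe_target == "Tpm":
            f = f"tn_shift_{ca}" if not k.s1_present else f"s1_shift_{ca}"
            phi -= sgn(f) * d_phi
            if not k.s1_present:
                # stiffness up = sin^2 down
                s2 /= eps_factor ** sgn(f"tpm_stiffness_{ca}")
        elif k.probe_target == "actin":
            f = f"actin_on_tpm_{ca}" if not k.s1_present else f"actin_on_s1_{ca}"
            phi += sgn(f) * d_phi
        else:
            f = (
                f"strong_binding_{ca}"
                if k.nucleotide == "none"
                else f"strong_binding_atp_{ca}"
            )
            phi -= sgn(f) * d_phi
            n -= sgn(f) * d_n
        mut[k] = _samples(phi, s2, n)
    return mut, wt


class TestSignature:
    def test_e173a_row_semantics_roundtrip(self):
        """Noise-free deltas realizing the E173A reference row reproduce all
        15 features of that row."""
        refs = load_reference_signatures()
        row = next(r for r in refs if r.name == "E173A" and r.gene == "TPM3")
        mut, wt = build_signature_inputs(row.features)
        table = delta_table(mut, wt)
        sig = signature_from_deltas(
            table.records, pCa50_mut=6.84, pCa50_wt=6.5, se_mut=0.04, se_wt=0.04
        )
        assert sig.vector == row.features

    def test_all_norm_signature(self):
        keys = default_keys()
        data = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        wt = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        sig = signature_from_deltas(
            delta_table(data, wt).records, pCa50_mut=6.5, pCa50_wt=6.5
        )
        assert all(v == NORM for v in sig.vector)

    def test_discordant_strong_binding_evidence(self):
        keys = default_keys()
        wt = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        mut = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        am_high = ConditionKey("S1", "high", "none", True, "X")
        mut[am_high] = _samples(48.0, 0.05, 0.38)  # phi down but N up
        sig = signature_from_deltas(
            delta_table(mut, wt).records, pCa50_mut=6.5, pCa50_wt=6.5
        )
        assert sig.features["strong_binding_high"] == MISSING
        assert any("strong_binding_high" in c for c in sig.conflicts)

    def test_missing_conditions_yield_missing_features(self):
        keys = [k for k in default_keys() if k.probe_target == "S1"]
        wt = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        sig = signature_from_deltas(delta_table(wt, wt).records)
        assert sig.features["tn_shift_high"] == MISSING
        assert sig.features["ca_sensitivity"] == MISSING
        assert sig.features["strong_binding_high"] == NORM

    @pytest.mark.parametrize(
        "d, se, expect",
        [
            (0.34, 0.04, UP),
            (-0.34, 0.04, DOWN),
            (0.05, 0.04, NORM),  # below the 0.1 threshold
            (0.3, 0.2, NORM),  # overlapping standard errors
        ],
    )
    def test_calcium_sensitivity_rule(self, d, se, expect):
        keys = default_keys()
        wt = {k: _samples(50.0, 0.05, 0.3) for k in keys}
        sig = signature_from_deltas(
            delta_table(wt, wt).records,
            pCa50_mut=6.5 + d,
            pCa50_wt=6.5,
            se_mut=se,
            se_wt=se,
        )
        assert sig.features["ca_sensitivity"] == expect

    def test_invariant_under_common_phi_shift(self):
        refs = load_reference_signatures()
        row = next(r for r in refs if r.name == "R90P")
        mut, wt = build_signature_inputs(row.features)
        sig1 = signature_from_deltas(delta_table(mut, wt).records)
        shifted_mut = {
            k: ConditionSamples(v.phi_e + 3.0, v.sin2_theta, v.n_disordered)
            for k, v in mut.items()
        }
        shifted_wt = {
            k: ConditionSamples(v.phi_e + 3.0, v.sin2_theta, v.n_disordered)
            for k, v in wt.items()
        }
        sig2 = signature_from_deltas(delta_table(shifted_mut, shifted_wt).records)
        assert sig1.vector == sig2.vector


@pytest.fixture(scope="module")
def refs():
    return load_reference_signatures()


class TestClassify:
    def test_reference_rows_self_classify_at_distance_zero(self, refs):
        for ref in (r for r in refs if r.kind == "row"):
            sig = MyopathySignature(features=ref.feature_dict)
            res = classify_signature(sig, refs)
            assert res.label == ref.group
            assert res.best["distance"] == 0.0

    def test_a155t_nearest_nonself_is_cap_cluster(self, refs):
        """Excluding its own row, the A155T (TPM3) pattern lands in the
        Cap-like cluster (the truncation-mutant pattern)."""
        row = next(r for r in refs if r.name == "A155T" and r.gene == "TPM3")
        others = [r for r in refs if not (r.name == "A155T" and r.gene == "TPM3")]
        res = classify_signature(MyopathySignature(features=row.feature_dict), others)
        assert res.label == "Cap"
        cap_rows = res.distances[
            (res.distances["kind"] == "row") & (res.distances["group"] == "Cap")
        ]
        assert cap_rows.iloc[0]["name"] == "E139X"

    def test_brute_force_nearest_neighbor_oracle(self, refs, rng):
        """Random trinary vectors classify identically to an independent
        brute-force scan of the reference matrix."""
        values = (UP, DOWN, NORM)
        for _ in range(40):
            vec = tuple(rng.choice(values) for _ in FEATURE_NAMES)
            sig = MyopathySignature(features=dict(zip(FEATURE_NAMES, vec)))
            res = classify_signature(sig, refs)
            # independent brute force (same tie-break: distance, then coverage)
            best = None
            for ref in refs:
                pairs = [
                    (a, b)
                    for a, b in zip(vec, ref.features)
                    if a != MISSING and b != MISSING
                ]
                if not pairs:
                    continue
                d = sum(a != b for a, b in pairs) / len(pairs)
                key = (d, -len(pairs), ref.name)
                if best is None or key < best[0]:
                    best = (key, ref.group)
            assert res.label == best[1]

    def test_all_missing_raises(self, refs):
        sig = MyopathySignature(features={})
        with pytest.raises(ValueError, match="missing"):
            classify_signature(sig, refs)

    def test_empty_reference_set_raises(self):
        sig = MyopathySignature(features={"ca_sensitivity": UP})
        with pytest.raises(ValueError, match="empty"):
            classify_signature(sig, [])

    def test_alias_stored_for_truncation_row(self, refs):
        row = next(r for r in refs if r.name == "E139X")
        assert "E139del" in row.aliases


class TestConditionKey:
    def test_invariants(self):
        with pytest.raises(ValueError):
            ConditionKey("S1", "high", "none", False)
        with pytest.raises(ValueError):
            ConditionKey("Tpm", "high", "ATP", False)
        with pytest.raises(ValueError):
            ConditionKey("myosin", "high", "none", True)

    def test_variant_excluded_from_matching(self):
        a = ConditionKey("Tpm", "high", "none", True, "WT")
        b = ConditionKey("Tpm", "high", "none", True, "E173A")
        assert a.condition() == b.condition()
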