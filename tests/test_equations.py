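"""Reference-equation fixtures: transcription exactness, worked examples,
decomposition, importance and value-flow tracing."""

import math

import numpy as np
import pandas as pd
import pytest

from uhsr.equations import (
    FG_PROBE_WEIGHTS, PSI_COEFS, RF_EQUATION, XI_INTERCEPT,
    alpha_reference, beta_reference, decompose, feature_importance,
    fg_probe_linear, gamma_references, psi_reference, reference_chain,
    rf_governing, value_flow, xi_reference,
)
from uhsr.errors import UnsupportedFormError
from uhsr.features import FEATURE_NAMES, FG_NAMES


def onehot_fg(name):
    v = np.zeros(16)
    v[FG_NAMES.index(name)] = 1.0
    return v


class TestRfGoverning:
    def test_worked_example_at_origin(self):
        assert rf_governing(0.0, 0.0) == pytest.approx(
            1 / (1 + math.exp(-1.55)), abs=1e-12)
        assert rf_governing(0.0, 0.0) == pytest.approx(0.8249, abs=1e-4)

    def test_half_point(self):
        # psi + xi = -1.55/5.15 puts the linear predictor at zero
        psi = -1.55 / 5.15
        assert rf_governing(psi, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_limits_and_monotonicity(self):
        assert rf_governing(-50.0, 0.0) == pytest.approx(0.0, abs=1e-9)
        assert rf_governing(50.0, 0.0) == pytest.approx(1.0, abs=1e-9)
        grid = np.linspace(-3, 3, 41)
        vals = rf_governing(grid, 0.0)
        assert np.all(np.diff(vals) > 0)
        vals = rf_governing(0.0, grid)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))


class TestPsiReference:
    def test_transcription_exact(self):
        for i, name in enumerate(("Hex", "EA", "DCM", "MeOH", "Et2O")):
            pure = np.eye(5)[i]
            assert psi_reference(pure) == PSI_COEFS[name]

    def test_zero_composition(self):
        assert psi_reference(np.zeros(5)) == 0.0

    def test_renormalize(self):
        assert psi_reference([2, 0, 0, 0, 0], renormalize=True) == \
            pytest.approx(-1.37)


class TestXiReference:
    def test_transcription_exact(self):
        assert xi_reference(0.0, 0.0) == XI_INTERCEPT == 0.69
        assert xi_reference(1.0, 0.0) - 0.69 == pytest.approx(0.37)
        assert xi_reference(0.0, 1.0) - 0.69 == pytest.approx(-0.35)

    def test_worked_example(self):
        assert xi_reference(1.0, 1.0) == pytest.approx(-0.29, abs=1e-12)

    def test_affine_in_beta_at_alpha_zero(self):
        b = np.linspace(-2, 2, 9)
        vals = xi_reference(0.0, b)
        slopes = np.diff(vals) / np.diff(b)
        np.testing.assert_allclose(slopes, -0.35, atol=1e-12)


class TestFgProbe:
    def test_printed_values(self):
        assert fg_probe_linear(onehot_fg("CtAm")) == pytest.approx(1.43)
        assert fg_probe_linear(onehot_fg("CtI")) == pytest.approx(-2.97)
        assert fg_probe_linear(np.zeros(16)) == 0.0

    def test_polarity_ordering_preserved(self):
        order = ["CtAm", "CtCO2H", "CtNH2", "CtOH", "CtPh", "CtAl", "CtR2CO",
                 "CtRCO2R", "CtNO2", "CtCN", "CtF", "CtCl", "CtROR", "CtMe",
                 "CtBr", "CtI"]
        weights = [FG_PROBE_WEIGHTS[n] for n in order]
        assert all(a >= b for a, b in zip(weights, weights[1:]))

    def test_additive_in_counts(self):
        v = onehot_fg("CtAm") + 2 * onehot_fg("CtI")
        assert fg_probe_linear(v) == pytest.approx(1.43 - 2 * 2.97)


class TestInterpretiveTranscriptions:
    def test_gamma1_baseline(self):
        g = gamma_references(np.zeros(16))
        assert g[0] == pytest.approx(5.16 * math.log(0.86), abs=1e-12)

    def test_gamma1_monotone_in_amide(self):
        lo = gamma_references(np.zeros(16))[0]
        hi = gamma_references(onehot_fg("CtAm"))[0]
        assert hi > lo
        assert hi - lo == pytest.approx(5.16)

    def test_beta_zero_count_baseline_deterministic(self):
        g1, b1 = beta_reference(np.zeros(16))
        g2, b2 = beta_reference(np.zeros(16))
        np.testing.assert_array_equal(g1, g2)
        assert b1 == b2 and math.isfinite(b1)

    def test_alpha_reference_finite(self):
        assert math.isfinite(alpha_reference(1.34, 1))


class TestDecompose:
    def test_constants(self):
        _, c1 = decompose(RF_EQUATION, "xi", 0.0)
        assert c1 == pytest.approx(1.55)
        _, c1 = decompose(RF_EQUATION, "xi", 1.0)
        assert c1 == pytest.approx(6.70)

    def test_partial_curves_strictly_increasing(self):
        curve, _ = decompose(RF_EQUATION, "xi", 0.3)
        grid = np.linspace(-2, 2, 21)
        assert np.all(np.diff(curve(grid)) > 0)

    def test_rejects_non_sigmoid_affine(self):
        with pytest.raises(UnsupportedFormError):
            decompose(lambda p, x: p + x, "xi", 0.0)


class TestValueFlow:
    def test_terminal_matches_direct_evaluation(self, small_noiseless_dataset):
        from uhsr.features import assemble_features
        chain = reference_chain()
        for rec in small_noiseless_dataset.records[:10]:
            trace = value_flow(chain, rec)
            direct = float(chain.predict(assemble_features(rec)[None, :])[0])
            assert trace.terminal == pytest.approx(direct, abs=1e-9)
            # the trace also reproduces the fixture composition by hand
            by_hand = rf_governing(
                psi_reference(assemble_features(rec)[:5]),
                xi_reference(trace.value("alpha"), trace.value("beta")))
            assert trace.terminal == pytest.approx(by_hand, abs=1e-9)

    def test_iodine_touches_only_solute_branch(self):
        chain = reference_chain()
        x0 = np.zeros(23)
        x0[0] = 1.0  # pure hexane
        x1 = x0.copy()
        x1[FEATURE_NAMES.index("CtI")] = 1.0
        t0, t1 = chain.trace(x0), chain.trace(x1)
        changed = {n for (n, v0, _), (_, v1, _)
                   in zip(t0.entries, t1.entries) if v0 != v1}
        assert "gamma5" in changed and "beta" in changed
        assert "xi" in changed and "rf" in changed
        assert "psi" not in changed
        assert not changed & {"gamma1", "gamma2", "gamma3", "gamma4", "alpha"}

    def test_json_export_shape(self):
        chain = reference_chain(beta_mode="probe")
        x = np.zeros(23)
        x[0] = 1.0
        entries = chain.trace(x).to_json()
        assert all(set(e) == {"node", "value", "parent"} for e in entries)
        assert entries[-1]["node"] == "rf" and entries[-1]["parent"] is None


class TestFeatureImportance:
    def test_single_variable_equation(self):
        table = pd.DataFrame({"x1": np.linspace(0, 1, 50),
                              "x2": np.linspace(1, 2, 50)})
        imp = feature_importance(lambda df: 3.0 * df["x1"].to_numpy(), table)
        by = dict(zip(imp.feature, imp.importance))
        assert by["x1"] == pytest.approx(1.0)
        assert by["x2"] == pytest.approx(0.0)

    def test_symmetric_equation_equal_importance(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"x1": rng.normal(0, 1, 200),
                              "x2": rng.normal(0, 1, 200)})
        imp = feature_importance(
            lambda df: df["x1"].to_numpy() + df["x2"].to_numpy(),
            table, stds={"x1": 1.0, "x2": 1.0})
        by = dict(zip(imp.feature, imp.importance))
        assert by["x1"] == pytest.approx(by["x2"], abs=1e-9)

    def test_zero_variance_flagged(self):
        table = pd.DataFrame({"x1": np.linspace(0, 1, 20),
                              "x2": np.ones(20)})
        imp = feature_importance(lambda df: df["x1"].to_numpy() + df["x2"], table)
        row = imp[imp.feature == "x2"].iloc[0]
        assert row.zero_variance and row.importance == 0.0

    def test_meoh_ranks_first_for_equal_composition_steps(
            self, small_noiseless_dataset):
        # per-unit-composition sensitivity: methanol has by far the largest
        # solvent coefficient, so an equal volume-fraction step moves Rf most
        from uhsr.features import features_matrix
        chain = reference_chain(beta_mode="probe")
        X = features_matrix(small_noiseless_dataset.records)
        table = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        steps = {c: float(table[c].std(ddof=0)) for c in table.columns}
        for n in ("Hex", "EA", "DCM", "MeOH", "Et2O"):
            steps[n] = 0.05
        imp = feature_importance(chain, table, stds=steps)
        by = dict(zip(imp.feature, imp.importance))
        solvents = {n: by[n] for n in ("Hex", "EA", "DCM", "MeOH", "Et2O")}
        assert max(solvents, key=solvents.get) == "MeOH"
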