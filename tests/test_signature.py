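import numpy as np
import pandas as pd
import pytest

from ifacemut.errors import InsufficientControlsError, NormalizationError
from ifacemut.signature import (
    CtTable,
    ExpressionMatrix,
    delta_delta_ct,
    ifn_score,
    normalize_counts,
    read_ct_table,
    read_expression_matrix,
    write_ct_table,
    write_expression_matrix,
)
from ifacemut.synthetic import (
    ISG_PANEL_PROBES,
    QPCR_PANEL_GENES,
    QPCR_REFERENCE_GENES,
    REFERENCE_PROBES,
    make_ct_table,
    make_expression_matrix,
)


def _matrix(rows, roles, probes=None, refs=("R1", "R2")):
    probes = probes or [f"G{i}" for i in range(len(rows[0]) - len(refs))] + list(refs)
    counts = pd.DataFrame(rows, index=list(roles), columns=probes)
    return ExpressionMatrix(
        counts=counts,
        roles=pd.Series([roles[s] for s in counts.index], index=counts.index),
        reference_probes=list(refs),
    )


def test_identical_samples_give_unit_fold_changes():
    rows = [[10, 20, 30, 5, 8]] * 4
    roles = {"c1": "control", "c2": "control", "c3": "control", "p1": "case"}
    m = _matrix(rows, roles)
    norm = normalize_counts(m)
    assert np.allclose(norm.counts.values, 1.0)


def test_doubling_panel_counts_doubles_fold_changes():
    base = [10.0, 20.0, 30.0, 5.0, 8.0]
    doubled = [20.0, 40.0, 60.0, 5.0, 8.0]  # references unchanged
    roles = {"c1": "control", "c2": "control", "p1": "case"}
    m = _matrix([base, base, doubled], roles)
    norm = normalize_counts(m)
    assert np.allclose(norm.counts.loc["p1"].values, 2.0)
    assert np.allclose(norm.counts.loc["c1"].values, 1.0)


def test_scaling_a_whole_sample_is_invariant():
    """Multiplying a sample's panel AND reference counts by a constant does
    not change its fold changes (reference scaling removes it)."""
    rng = np.random.default_rng(2)
    base = rng.uniform(10, 100, 5)
    rows = [base, base * rng.uniform(0.5, 2), base * 7.3]
    roles = {"c1": "control", "c2": "control", "p1": "case"}
    m = _matrix([list(r) for r in rows], roles)
    norm = normalize_counts(m)
    m2 = _matrix([list(rows[0]), list(rows[1]), list(rows[2] * 100.0)], roles)
    norm2 = normalize_counts(m2)
    assert np.allclose(norm.counts.values, norm2.counts.values)


def test_planted_fold_changes_recovered():
    probes = ["G0", "G1", "G2", "R1", "R2"]
    control = np.array([50.0, 80.0, 20.0, 100.0, 400.0])
    planted = np.array([3.0, 0.25, 10.0])
    case = control.copy()
    case[:3] *= planted
    roles = {"c1": "control", "c2": "control", "p1": "case"}
    m = _matrix([list(control), list(control), list(case)], roles, probes=probes)
    norm = normalize_counts(m)
    assert np.allclose(norm.counts.loc["p1"].values, planted, rtol=1e-9)


def test_zero_reference_count_names_sample():
    rows = [[10, 20, 30, 5, 8], [10, 20, 30, 0, 8]]
    roles = {"c1": "control", "bad": "control"}
    with pytest.raises(NormalizationError, match="bad"):
        normalize_counts(_matrix(rows, roles))


def test_degenerate_controls_threshold_is_one():
    rows = [[10, 20, 30, 5, 8]] * 3 + [[30, 60, 90, 5, 8]]
    roles = {"c1": "control", "c2": "control", "c3": "control", "p1": "case"}
    result = ifn_score(normalize_counts(_matrix(rows, roles)))
    assert result.threshold == pytest.approx(1.0)
    assert result.calls["p1"] == "positive"
    assert result.n_controls == 3


def test_uniform_tenfold_case_scores_ten():
    m = make_expression_matrix(n_controls=29, case_elevation=10.0, seed=4)
    result = ifn_score(normalize_counts(m))
    assert result.per_sample_score["case_1"] == pytest.approx(10.0, rel=1e-9)
    assert result.calls["case_1"] == "positive"


def test_threshold_equals_mean_plus_two_sd_recomputed(study_case):
    m = make_expression_matrix(n_controls=29, case_elevation=10.0, seed=9)
    norm = normalize_counts(m)
    result = ifn_score(norm)
    # independent recomputation from the normalized matrix
    panel = norm.counts[norm.panel_probes]
    ctrl_scores = panel.loc[norm.control_samples].median(axis=1)
    expected = ctrl_scores.mean() + 2.0 * ctrl_scores.std(ddof=1)
    assert result.threshold == pytest.approx(float(expected), rel=1e-12)
    assert result.n_controls == 29
    # calls are consistent and monotone in score
    for sample in result.per_sample_score.index:
        assert (result.calls[sample] == "positive") == (
            result.per_sample_score[sample] > result.threshold
        )


def test_null_case_called_negative():
    m = make_expression_matrix(n_controls=29, case_elevation=1.0, seed=12)
    result = ifn_score(normalize_counts(m))
    assert result.calls["case_1"] == "negative"


def test_threshold_depends_only_on_controls():
    m1 = make_expression_matrix(n_controls=20, n_cases=1, case_elevation=10.0, seed=3)
    m2 = make_expression_matrix(n_controls=20, n_cases=3, case_elevation=4.0, seed=3)
    t1 = ifn_score(normalize_counts(m1)).threshold
    t2 = ifn_score(normalize_counts(m2)).threshold
    assert t1 == pytest.approx(t2, rel=1e-12)


def test_insufficient_controls_raise():
    rows = [[10, 20, 30, 5, 8], [30, 60, 90, 5, 8]]
    roles = {"c1": "control", "p1": "case"}
    with pytest.raises(InsufficientControlsError):
        ifn_score(normalize_counts(_matrix(rows, roles)))


def test_sem_mode_is_tighter():
    m = make_expression_matrix(n_controls=29, seed=6)
    norm = normalize_counts(m)
    assert ifn_score(norm, sd_mode="sem").threshold < ifn_score(norm, sd_mode="sd").threshold


def test_panel_composition():
    m = make_expression_matrix(seed=0)
    assert m.panel_probes == ISG_PANEL_PROBES
    assert len(m.panel_probes) == 24
    assert m.reference_probes == REFERENCE_PROBES
    assert len(m.reference_probes) == 3
    assert len(m.control_samples) == 29


def test_expression_matrix_round_trip(tmp_path):
    m = make_expression_matrix(seed=8)
    path = tmp_path / "counts.tsv"
    write_expression_matrix(m, path)
    back = read_expression_matrix(path)
    assert back.reference_probes == m.reference_probes
    assert list(back.roles) == list(m.roles)
    assert np.allclose(back.counts.values, m.counts.values, rtol=1e-9)


class TestDeltaDeltaCt:
    def _table(self, values, refs=("BACT", "GAPDH"), calibrators=("d1", "d2")):
        genes = ["MX1"] + list(refs)
        df = pd.DataFrame(values, index=list(values.keys()), columns=genes) \
            if isinstance(values, dict) else values
        return CtTable(values=df, reference_genes=list(refs), calibrators=list(calibrators))

    def test_calibrator_itself_has_rq_one(self):
        df = pd.DataFrame(
            {"MX1": [25.0, 25.0], "BACT": [20.0, 20.0], "GAPDH": [21.0, 21.0]},
            index=["d1", "d2"],
        )
        rq = delta_delta_ct(self._table(df), "MX1")
        assert np.allclose(rq.values, 1.0)

    def test_one_cycle_lower_doubles_expression(self):
        df = pd.DataFrame(
            {"MX1": [25.0, 25.0, 24.0], "BACT": [20.0] * 3, "GAPDH": [21.0] * 3},
            index=["d1", "d2", "case"],
        )
        rq = delta_delta_ct(self._table(df), "MX1")
        assert rq["case"] == pytest.approx(2.0)
        assert rq["d1"] == pytest.approx(1.0)

    def test_random_table_matches_stepwise_recomputation(self):
        rng = np.random.default_rng(21)
        samples = [f"s{i}" for i in range(6)]
        df = pd.DataFrame(
            rng.uniform(18, 30, size=(6, 3)), index=samples, columns=["MX1", "BACT", "GAPDH"]
        )
        table = self._table(df, calibrators=samples[:3])
        rq = delta_delta_ct(table, "MX1")
        dct = df["MX1"] - df[["BACT", "GAPDH"]].mean(axis=1)
        ddct = dct - dct.loc[samples[:3]].mean()
        assert np.allclose(rq.values, np.power(2.0, -ddct.values))

    def test_missing_gene_raises(self):
        df = pd.DataFrame(
            {"MX1": [25.0, 25.0], "BACT": [20.0, 20.0], "GAPDH": [21.0, 21.0]},
            index=["d1", "d2"],
        )
        with pytest.raises(KeyError):
            delta_delta_ct(self._table(df), "ISG15")

    def test_synthetic_case_elevated_about_fold(self):
        table = make_ct_table(case_fold=8.0, seed=5)
        for gene in QPCR_PANEL_GENES:
            rq = delta_delta_ct(table, gene)
            assert rq["case_1"] > 3.0  # strongly elevated vs donors near 1
            assert 0.5 < rq[table.calibrators].mean() < 2.0

    def test_ct_table_round_trip(self, tmp_path):
        table = make_ct_table(seed=13)
        path = tmp_path / "ct.tsv"
        write_ct_table(table, path)
        back = read_ct_table(path)
        assert back.reference_genes == QPCR_REFERENCE_GENES
        assert back.calibrators == table.calibrators
        assert np.allclose(back.values.values, table.values.values, rtol=1e-9)
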