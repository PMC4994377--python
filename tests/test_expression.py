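"""FPKM transforms, specificity/stress calling, clustering and qPCR."""

import numpy as np
import pandas as pd
import pytest

from genefam.expression import (
    call_stress_response,
    call_tissue_specific,
    ddct,
    hierarchical_cluster,
    log_transform,
)

TISSUES = ["grain", "root", "stem", "leaf", "spike"]


def _matrix(rows: dict):
    return pd.DataFrame.from_dict(rows, orient="index", columns=TISSUES)


class TestLogTransform:
    def test_reference_points(self):
        m = _matrix({"g": [0, 9, 99, 0, 0]})
        t = log_transform(m)
        assert t.loc["g", "grain"] == 0.0
        assert t.loc["g", "root"] == pytest.approx(1.0)
        assert t.loc["g", "stem"] == pytest.approx(2.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            log_transform(_matrix({"g": [-1, 0, 0, 0, 0]}))

    def test_monotone(self):
        m = _matrix({"a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1]})
        t = log_transform(m)
        assert (t.loc["a"].diff().dropna() > 0).all()


class TestTissueSpecific:
    def test_single_tissue_expression_is_specific(self):
        calls = call_tissue_specific(_matrix({"g": [5, 0, 0, 0, 0]}), 1.0)
        assert calls[0].tissue_specific == "grain"

    def test_silent_gene_not_specific(self):
        calls = call_tissue_specific(_matrix({"g": [0, 0, 0, 0, 0]}), 1.0)
        assert calls[0].expressed_in == () and calls[0].tissue_specific is None

    def test_two_tissue_expression_not_specific(self):
        calls = call_tissue_specific(_matrix({"g": [5, 5, 0, 0, 0]}), 1.0)
        assert calls[0].tissue_specific is None
        assert calls[0].expressed_in == ("grain", "root")


def _stress_design(ctrl, treat, reps=3):
    cols, data, sheet = [], [], []
    rng = np.random.default_rng(0)
    for cond, mean in (("control", ctrl), ("treatment", treat)):
        for r in range(1, reps + 1):
            name = f"{cond}_r{r}"
            cols.append(name)
            data.append(mean * rng.normal(1.0, 0.02, size=len(mean)))
            sheet.append({"sample": name, "condition": cond, "timepoint": 6.0, "replicate": r})
    m = pd.DataFrame(
        np.column_stack(data), index=[f"g{i}" for i in range(len(ctrl))], columns=cols
    )
    return m, pd.DataFrame(sheet)


class TestStressResponse:
    def test_fourfold_induction_called_up(self):
        m, sheet = _stress_design(np.array([2.0]), np.array([8.0]))
        call = call_stress_response(m, sheet)[0]
        assert call.verdict == "up"
        assert call.log2_fc == pytest.approx(2.0, abs=0.1)

    def test_flat_gene_unchanged(self):
        m, sheet = _stress_design(np.array([8.0]), np.array([8.0]))
        assert call_stress_response(m, sheet)[0].verdict == "unchanged"

    def test_silent_control_expressed_treatment_is_specific(self):
        m, sheet = _stress_design(np.array([0.1]), np.array([12.0]))
        assert call_stress_response(m, sheet)[0].verdict == "specific"

    def test_fourfold_repression_called_down(self):
        m, sheet = _stress_design(np.array([8.0]), np.array([2.0]))
        assert call_stress_response(m, sheet)[0].verdict == "down"

    def test_missing_control_rejected(self):
        m, sheet = _stress_design(np.array([2.0]), np.array([8.0]))
        treat_only = sheet[sheet.condition == "treatment"]
        with pytest.raises(ValueError, match="control"):
            call_stress_response(m[list(treat_only["sample"])], treat_only)

    def test_unreplicated_design_is_fold_change_only(self):
        m, sheet = _stress_design(np.array([2.0]), np.array([8.0]), reps=1)
        call = call_stress_response(m, sheet)[0]
        assert call.verdict == "up" and call.p is None and call.q is None

    def test_bh_q_values_monotone_in_p_and_not_smaller(self):
        rng = np.random.default_rng(4)
        ctrl = rng.uniform(2, 50, size=30)
        treat = ctrl * rng.choice([1.0, 4.0], size=30)
        m, sheet = _stress_design(ctrl, treat)
        calls = call_stress_response(m, sheet)
        ps = np.array([c.p for c in calls])
        qs = np.array([c.q for c in calls])
        assert (qs >= ps - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-12).all()


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_height_zero(self):
        m = _matrix({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]})
        z, order = hierarchical_cluster(m)
        assert z[0, 2] == pytest.approx(0.0)

    def test_planted_two_block_structure_forms_top_split(self):
        rng = np.random.default_rng(2)
        rows = {}
        for i in range(5):
            rows[f"lo{i}"] = np.abs(rng.normal(1, 0.2, 5))
        for i in range(5):
            rows[f"hi{i}"] = np.abs(rng.normal(500, 30, 5))
        m = pd.DataFrame.from_dict(rows, orient="index", columns=TISSUES)
        z, order = hierarchical_cluster(m)
        top_blocks = {g[:2] for g in order[:5]}, {g[:2] for g in order[5:]}
        assert top_blocks == ({"lo"}, {"hi"}) or top_blocks == ({"hi"}, {"lo"})

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(_matrix({"a": [1, 2, 3, 4, 5]}))


def _ct_rows(gene, ct_t_salt, ct_r_salt, ct_t_ctrl, ct_r_ctrl, tp=6.0):
    return [
        dict(gene=gene, condition="treatment", timepoint=tp, replicate=1,
             ct_target=ct_t_salt, ct_reference=ct_r_salt),
        dict(gene=gene, condition="control", timepoint=tp, replicate=1,
             ct_target=ct_t_ctrl, ct_reference=ct_r_ctrl),
    ]


class TestDdct:
    def test_printed_formula_example(self):
        res = ddct(pd.DataFrame(_ct_rows("g", 24, 20, 26, 20)))[0]
        assert res.ddct == pytest.approx(-2.0)
        assert res.fold == pytest.approx(4.0)

    def test_identical_conditions_give_unity(self):
        res = ddct(pd.DataFrame(_ct_rows("g", 26, 20, 26, 20)))[0]
        assert res.fold == pytest.approx(1.0)

    def test_late_target_gives_quarter(self):
        res = ddct(pd.DataFrame(_ct_rows("g", 28, 20, 26, 20)))[0]
        assert res.fold == pytest.approx(0.25)

    def test_missing_condition_raises_with_gene_name(self):
        rows = _ct_rows("g", 24, 20, 26, 20)[:1]
        with pytest.raises(ValueError, match="g @"):
            ddct(pd.DataFrame(rows))

    def test_ct_out_of_cycle_range_rejected(self):
        rows = _ct_rows("g", 50, 20, 26, 20)
        with pytest.raises(ValueError, match="0-45"):
            ddct(pd.DataFrame(rows))

    def test_condition_swap_inverts_fold(self):
        rows = pd.DataFrame(_ct_rows("g", 23.1, 19.7, 26.4, 20.2))
        fwd = ddct(rows)[0].fold
        swapped = rows.replace({"condition": {"treatment": "control", "control": "treatment"}})
        rev = ddct(swapped)[0].fold
        assert fwd * rev == pytest.approx(1.0)
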