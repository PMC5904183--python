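"""Stepwise probe-level regulation calling, dependence and overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stiffscape import synthetic
from stiffscape.transcriptome import (GeneCallResults, apply_flat_filter,
                                      assess_gata2_dependence, call_genes,
                                      count_regulated_tfs,
                                      cross_stimulus_overlap, filter_expressed,
                                      probe_log2fc, StiffnessResponseModel)

from conftest import make_matrix


class TestFilterExpressed:
    def test_all_above_floor_unchanged(self, two_cond_design):
        m = make_matrix({("p1", "g1"): [6, 6, 6, 6],
                         ("p2", "g1"): [5, 5, 5, 5]}, two_cond_design)
        out = filter_expressed(m, floor=5)
        assert out.values.shape == m.values.shape

    def test_strict_inequality_at_floor(self):
        # mean 4.9 removed, mean exactly 5.0 retained
        design = {"a": "x", "b": "y"}
        m = make_matrix({("p1", "g1"): [4.8, 5.0],
                         ("p2", "g1"): [5.0, 5.0]}, design)
        out = filter_expressed(m, floor=5)
        kept = out.values.index.get_level_values("probe_set_id").tolist()
        assert kept == ["p2"]

    def test_floor_scope_is_contrast_samples(self):
        # mean over the contrast arms only decides survival
        design = {"a": "x", "b": "y", "c": "z"}
        m = make_matrix({("p1", "g1"): [4.0, 4.0, 20.0]}, design)
        assert filter_expressed(m, 5, conditions=["x", "y"]).values.empty
        assert not filter_expressed(m, 5, conditions=["y", "z"]).values.empty

    def test_empty_matrix_rejected(self, two_cond_design):
        m = make_matrix({("p1", "g1"): [6, 6, 6, 6]}, two_cond_design)
        empty = filter_expressed(m, floor=99)
        with pytest.raises(ValueError):
            filter_expressed(empty, floor=5)


class TestProbeLog2FC:
    def test_identity_contrast_is_zero(self, two_cond_design):
        m = make_matrix({("p1", "g1"): [7, 8, 6, 9]}, two_cond_design)
        fcs = probe_log2fc(m, "stiff", "stiff")
        assert np.allclose(fcs.log2fc, 0.0)

    def test_exact_arithmetic(self, two_cond_design):
        m = make_matrix({("p1", "g1"): [7, 7, 8, 8]}, two_cond_design)
        fcs = probe_log2fc(m, "stiff", "soft")
        assert fcs.log2fc.tolist() == [1.0]

    def test_missing_condition_is_design_error(self, two_cond_design):
        m = make_matrix({("p1", "g1"): [7, 7, 8, 8]}, two_cond_design)
        with pytest.raises(KeyError):
            probe_log2fc(m, "stiff", "OSS")

    def test_matches_bruteforce_on_synthetic(self):
        matrix, _ = synthetic.gen_probe_matrix(
            synthetic.ArraySimConfig(n_genes=30, seed=7))
        fcs = probe_log2fc(matrix, "ctrl-stiff", "ctrl-soft")
        # independent recomputation: per-sample averaging with plain loops
        stiff = [s for s, c in matrix.design.items() if c == "ctrl-stiff"]
        soft = [s for s, c in matrix.design.items() if c == "ctrl-soft"]
        for _, row in fcs.sample(50, random_state=0).iterrows():
            vals = matrix.values.loc[(row.probe_set_id, row.gene_id)]
            expect = sum(vals[s] for s in soft) / len(soft) \
                - sum(vals[s] for s in stiff) / len(stiff)
            assert row.log2fc == pytest.approx(expect, abs=1e-12)


def oracle_call_genes(probe_fcs: pd.DataFrame, threshold: float,
                      min_probes: int) -> dict:
    """Brute-force re-implementation of the gene-calling rule with plain
    Python loops; independent of the production code path."""
    verdicts = {}
    for gene in sorted(set(probe_fcs.gene_id)):
        ups, downs = [], []
        for _, r in probe_fcs[probe_fcs.gene_id == gene].iterrows():
            if r.log2fc > threshold:
                ups.append(r.log2fc)
            elif r.log2fc < -threshold:
                downs.append(r.log2fc)
        if len(ups) >= min_probes and len(downs) >= min_probes:
            verdicts[gene] = ("bidirectional", None)
        elif len(ups) >= min_probes:
            verdicts[gene] = ("up", sum(ups) / len(ups))
        elif len(downs) >= min_probes:
            verdicts[gene] = ("down", sum(downs) / len(downs))
        else:
            verdicts[gene] = ("unregulated", None)
    return verdicts


def fcs_frame(gene_fcs: dict) -> pd.DataFrame:
    rows = []
    i = 0
    for gene, fcs in gene_fcs.items():
        for fc in fcs:
            rows.append({"probe_set_id": f"p{i}", "gene_id": gene,
                         "log2fc": float(fc)})
            i += 1
    return pd.DataFrame(rows)


class TestCallGenes:
    def test_below_min_probes_unregulated(self):
        res = call_genes(fcs_frame({"g1": [1.0, 1.0]}), 0.5, 3)
        assert res.calls.status.tolist() == ["unregulated"]

    def test_hand_example_up_with_average(self):
        res = call_genes(fcs_frame({"g1": [0.8, 0.6, 0.7, 0.1]}), 0.5, 3)
        rec = res.calls.iloc[0]
        assert rec.status == "up"
        assert rec.avg_log2fc_regulated == pytest.approx(0.7)
        assert rec.n_probes_up == 3 and rec.n_probes_total == 4

    def test_threshold_is_strict(self):
        res = call_genes(fcs_frame({"g1": [0.5, 0.5, 0.5]}), 0.5, 3)
        assert res.calls.status.tolist() == ["unregulated"]

    def test_bidirectional_flagged_and_excluded(self):
        res = call_genes(fcs_frame({"g1": [1, 1, 1, -1, -1, -1]}), 0.5, 3)
        assert res.calls.status.tolist() == ["bidirectional"]
        assert res.up_genes == set() and res.down_genes == set()
        assert res.bidirectional_fraction == 1.0

    def test_min_probes_validation(self):
        with pytest.raises(ValueError):
            call_genes(fcs_frame({"g1": [1.0]}), 0.5, 0)

    @pytest.mark.parametrize("threshold,min_probes",
                             list(itertools.product([0.3, 0.5, 1.0], [1, 2, 3])))
    def test_matches_bruteforce_oracle(self, threshold, min_probes):
        rng = np.random.default_rng(42)
        gene_fcs = {f"g{i}": rng.normal(0, 0.8, rng.integers(1, 8))
                    for i in range(20)}
        frame = fcs_frame(gene_fcs)
        res = call_genes(frame, threshold, min_probes)
        oracle = oracle_call_genes(frame, threshold, min_probes)
        for _, rec in res.calls.iterrows():
            status, avg = oracle[rec.gene_id]
            assert rec.status == status
            if avg is not None:
                assert rec.avg_log2fc_regulated == pytest.approx(avg)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=12),
           st.sampled_from([0.3, 0.5, 0.8]))
    def test_regulated_count_monotone_in_threshold(self, fcs, threshold):
        frame = fcs_frame({"g1": fcs})
        lo = call_genes(frame, threshold, 2)
        hi = call_genes(frame, threshold + 0.25, 2)
        assert hi.n_regulated <= lo.n_regulated
        stricter = call_genes(frame, threshold, 3)
        assert stricter.n_regulated <= lo.n_regulated


class TestDependence:
    def test_zero_kd_contrast_nothing_dependent(self):
        res = call_genes(fcs_frame({"g1": [1, 1, 1]}), 0.5, 3)
        kd = pd.DataFrame({"probe_set_id": [f"p{i}" for i in range(3)],
                           "gene_id": "g1", "log2fc": [0.0, 0.0, 0.0]})
        dep = assess_gata2_dependence(res, kd)
        assert not dep.dependent.any()

    def test_reversal_hand_example(self):
        res = call_genes(fcs_frame({"g1": [0.9, 0.9, 0.9]}), 0.5, 3)
        kd = pd.DataFrame({"probe_set_id": ["p0", "p1", "p2"],
                           "gene_id": "g1", "log2fc": [-0.6, -0.6, -0.6]})
        dep = assess_gata2_dependence(res, kd)
        rec = dep.iloc[0]
        assert rec.dependent and rec.concordant_reversal
        assert rec.avg_log2fc_kd == pytest.approx(-0.6)

    def test_uses_only_previously_regulated_probes(self):
        # the sub-threshold probe p3 must not enter the knockdown average
        res = call_genes(fcs_frame({"g1": [0.9, 0.9, 0.9, 0.1]}), 0.5, 3)
        kd = pd.DataFrame({"probe_set_id": ["p0", "p1", "p2", "p3"],
                           "gene_id": "g1", "log2fc": [0.6, 0.6, 0.6, -99.0]})
        dep = assess_gata2_dependence(res, kd)
        assert dep.iloc[0].avg_log2fc_kd == pytest.approx(0.6)
        assert not dep.iloc[0].concordant_reversal

    def test_missing_probes_marked_unassessable(self):
        res = call_genes(fcs_frame({"g1": [1, 1, 1]}), 0.5, 3)
        kd = pd.DataFrame({"probe_set_id": ["q1"], "gene_id": ["g9"],
                           "log2fc": [2.0]})
        dep = assess_gata2_dependence(res, kd)
        assert len(dep) == 1 and not dep.iloc[0].assessable


class TestFlatFilter:
    def test_no_calls_inside_band(self):
        design = {"a": "static", "b": "static", "c": "OSS", "d": "OSS"}
        m = make_matrix({("g1", "g1"): [7, 7, 7.4, 7.4],
                         ("g2", "g2"): [7, 7, 6.6, 6.6]}, design)
        up, down = apply_flat_filter(m, "static", "OSS")
        assert up == set() and down == set()

    def test_toy_counts_with_strict_inequalities(self):
        design = {"a": "static", "b": "OSS"}
        fcs = {"g1": 0.6, "g2": 0.5, "g3": -0.4, "g4": -0.8, "g5": 0.51}
        m = make_matrix({(g, g): [7.0, 7.0 + fc] for g, fc in fcs.items()},
                        design)
        up, down = apply_flat_filter(m, "static", "OSS")
        assert up == {"g1", "g5"} and down == {"g4"}

    def test_floor_applies_before_fold_change(self):
        design = {"a": "static", "b": "OSS"}
        m = make_matrix({("g1", "g1"): [3.0, 5.0]}, design)  # mean 4 < 5
        up, down = apply_flat_filter(m, "static", "OSS")
        assert up == set()


class TestOverlapAndTFs:
    def test_identical_sets_fully_shared(self):
        ov = cross_stimulus_overlap({"a", "b"}, {"c"}, {"a", "b"}, {"c"})
        assert (ov.shared_up, ov.shared_down, ov.discordant) == (2, 1, 0)

    def test_disjoint_universes(self):
        ov = cross_stimulus_overlap({"a"}, {"b"}, {"x"}, {"y"})
        assert ov.shared_up == ov.shared_down == ov.discordant == 0

    def test_hand_set_arithmetic(self):
        ov = cross_stimulus_overlap({"g1", "g2", "g3"}, {"g5"},
                                    {"g2", "g3", "g4"}, {"g5"})
        assert ov.shared_up == 2 and ov.shared_down == 1
        assert ov.fractions["shared_up_of_a"] == pytest.approx(2 / 3)

    def test_id_map_translation(self):
        ov = cross_stimulus_overlap({"G1"}, set(), {"x1"}, set(),
                                    id_map={"x1": "G1"})
        assert ov.shared_up == 1

    def test_tf_count_intersection(self):
        res = call_genes(fcs_frame({f"g{i}": [1, 1, 1] for i in range(1, 11)}),
                         0.5, 3)
        assert count_regulated_tfs(res, {"g2", "g5", "g99"}) == 2

    def test_empty_tf_list_warns_zero(self):
        res = call_genes(fcs_frame({"g1": [1, 1, 1]}), 0.5, 3)
        with pytest.warns(UserWarning):
            assert count_regulated_tfs(res, set()) == 0


class TestModelInterface:
    def test_fit_equals_functional_path(self):
        matrix, _ = synthetic.gen_probe_matrix(
            synthetic.ArraySimConfig(n_genes=50, seed=3))
        model = StiffnessResponseModel(matrix)
        res = model.fit("ctrl-stiff", "ctrl-soft")
        manual = call_genes(probe_log2fc(filter_expressed(
            matrix, 5, ["ctrl-stiff", "ctrl-soft"]), "ctrl-stiff", "ctrl-soft"))
        assert res.up_genes == manual.up_genes
        assert res.down_genes == manual.down_genes
        assert "regulated transcripts" in res.summary()

    def test_determinism(self):
        matrix, _ = synthetic.gen_probe_matrix(
            synthetic.ArraySimConfig(n_genes=40, seed=5))
        model = StiffnessResponseModel(matrix)
        a = model.fit("ctrl-stiff", "ctrl-soft")
        b = model.fit("ctrl-stiff", "ctrl-soft")
        pd.testing.assert_frame_equal(a.calls, b.calls)
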