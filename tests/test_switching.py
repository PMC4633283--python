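"""Switch detection rules, protein-contrast classification, summaries."""

import numpy as np
import pandas as pd
import pytest

from switchgrain.data import Comparison, GeneModel, NON_CODING
from switchgrain.detest import DEConfig, DEResults, DispersionEstimate, NBExactTestModel
from switchgrain.exceptions import AnnotationError, DesignError
from switchgrain.simulate import SimulationConfig, simulate_dataset
from switchgrain.switching import (SwitchCall, classify_switch,
                                   cross_level_discordance, detect_switches,
                                   identical_protein_genes, summarize)

PAIR = Comparison("24Fe", "UT")


def results_from(statuses: dict, level="transcript", comparison=PAIR) -> DEResults:
    frame = pd.DataFrame(
        {
            "mean_rpm_num": 10.0,
            "mean_rpm_den": 10.0,
            "log2_fc": 0.0,
            "pvalue": 0.5,
            "padj": 0.5,
            "status": pd.Series(statuses, dtype=object),
            "filtered": False,
        },
        index=list(statuses),
    )
    return DEResults(frame=frame, comparison=comparison, level=level,
                     config=DEConfig(), dispersion=DispersionEstimate(0.1, "fixed", 0))


@pytest.fixture
def model():
    return GeneModel.from_records([
        ("g1", "t1", "P1", "MKLV"),
        ("g1", "t2", "P2", "MKLA"),
        ("g2", "t3", "P3", "MWWC"),
        ("g2", "t4", "P4", "MWWC"),     # identical sequence, distinct id -> merged
        ("g3", "t5", "P5", "MAAA"),
        ("g3", "t6", None, None),       # non-coding partner
        ("g4", "t7", "P7", "MCCC"),     # single isoform
    ])


class TestDetect:
    def test_opposite_directions_one_call(self, model):
        res = results_from({"t1": "Induced", "t2": "Repressed"})
        calls = detect_switches(res, model)
        assert len(calls) == 1
        assert calls[0].gene_id == "g1"
        assert calls[0].up_transcripts == ("t1",)
        assert calls[0].down_transcripts == ("t2",)

    def test_same_direction_no_call(self, model):
        res = results_from({"t1": "Induced", "t2": "Induced"})
        assert detect_switches(res, model) == []

    def test_single_isoform_gene_never_called(self, model):
        res = results_from({"t7": "Induced"})
        assert detect_switches(res, model) == []

    def test_unknown_transcript_raises(self, model):
        res = results_from({"tx_unknown": "Induced", "t2": "Repressed"})
        with pytest.raises(AnnotationError):
            detect_switches(res, model)

    def test_every_call_has_two_plus_isoforms(self, model):
        res = results_from({"t1": "Induced", "t2": "Repressed",
                            "t3": "Induced", "t4": "Repressed"})
        for call in detect_switches(res, model):
            assert len(model.transcripts_of[call.gene_id]) >= 2


class TestClassify:
    def test_distinct_proteins_is1(self, model):
        call = SwitchCall("g1", PAIR.name, ("t1",), ("t2",))
        out = classify_switch(call, model)
        assert out.switch_class == "IS1" and not out.identical_protein

    def test_identical_protein_is2(self, model):
        call = SwitchCall("g2", PAIR.name, ("t3",), ("t4",))
        out = classify_switch(call, model)
        assert out.switch_class == "IS2" and out.identical_protein

    def test_non_coding_partner_unclassified(self, model):
        call = SwitchCall("g3", PAIR.name, ("t5",), ("t6",))
        out = classify_switch(call, model)
        assert out.switch_class == "unclassified" and not out.identical_protein

    def test_agrees_with_sequence_comparison_oracle(self):
        """Classification equals an exhaustive pairwise protein-sequence
        comparison on a generated annotation."""
        cfg = SimulationConfig(n_genes=200, depth=300_000.0, seed=13,
                               isoforms_per_gene={2: 0.5, 3: 0.5},
                               fraction_identical_protein_pairs=0.2,
                               fraction_utr_only_pairs=0.2,
                               fraction_noncoding=0.15,
                               expression_range=(5.0, 300.0))
        ds = simulate_dataset(cfg)
        gm = ds.gene_model
        rng = np.random.default_rng(0)
        for gene, txs in gm.transcripts_of.items():
            if len(txs) < 2:
                continue
            up, down = (txs[0],), (txs[1],)
            out = classify_switch(SwitchCall(gene, PAIR.name, up, down), gm)
            # oracle: compare raw sequences
            seq_up = gm.protein_seq.get(gm.protein_of[up[0]])
            seq_down = gm.protein_seq.get(gm.protein_of[down[0]])
            if gm.protein_of[up[0]] == NON_CODING or gm.protein_of[down[0]] == NON_CODING:
                assert out.switch_class == "unclassified"
            elif seq_up == seq_down:
                assert out.switch_class == "IS2" and out.identical_protein
            else:
                assert out.switch_class == "IS1"

    def test_invariants_on_call(self):
        with pytest.raises(DesignError):
            SwitchCall("g", PAIR.name, (), ("t2",))
        with pytest.raises(DesignError):
            SwitchCall("g", PAIR.name, ("t1",), ("t1",))


class TestSummaries:
    def test_no_de_gives_all_zero_summary(self, model):
        gres = results_from({}, level="gene")
        tres = results_from({})
        gs, ts = summarize(gres, tres, [], model)
        assert (gs.de, gs.rep, gs.ind, gs.is_total) == (0, 0, 0, 0)
        assert (ts.de, ts.rep, ts.ind, ts.is_total) == (0, 0, 0, 0)
        assert gs.discordant_fraction == 0.0

    def test_de_equals_rep_plus_ind(self, model):
        gres = results_from({"g1": "Induced", "g2": "Repressed"}, level="gene")
        tres = results_from({"t1": "Induced", "t2": "Repressed", "t3": "Induced"})
        calls = detect_switches(tres, model, gres)
        gs, ts = summarize(gres, tres, calls, model)
        assert gs.de == gs.rep + gs.ind == 2
        assert ts.de == ts.rep + ts.ind == 3

    def test_gene_level_is_counts_de_switching_genes(self, model):
        gres = results_from({"g1": "Induced"}, level="gene")
        tres = results_from({"t1": "Induced", "t2": "Repressed",
                             "t3": "Induced", "t4": "Repressed"})
        calls = detect_switches(tres, model, gres)
        gs, ts = summarize(gres, tres, calls, model)
        # g1 and g2 switch, only g1 is gene-level DE
        assert gs.is_total == 1 and gs.is1 == 1
        # all four DE transcripts belong to switching genes; partition holds
        assert ts.is_total == 4 and ts.is1 + ts.is2 == 4

    def test_mismatched_comparisons_rejected(self, model):
        gres = results_from({}, level="gene", comparison=Comparison("24Zn", "UT"))
        tres = results_from({})
        with pytest.raises(DesignError):
            summarize(gres, tres, [], model)

    def test_gene_level_class_attached(self, model):
        gres = results_from({"g1": "Induced"}, level="gene")
        tres = results_from({"t1": "Induced", "t2": "Repressed"})
        calls = detect_switches(tres, model, gres)
        assert calls[0].gene_level_class == "Induced"

    def test_identical_protein_list(self, model):
        tres = results_from({"t1": "Induced", "t2": "Repressed",
                             "t3": "Induced", "t4": "Repressed"})
        calls = detect_switches(tres, model)
        assert identical_protein_genes(calls) == ["g2"]


class TestDiscordance:
    def test_concordant_levels_give_zero_gene_side(self, model):
        gres = results_from({"g1": "Induced"}, level="gene")
        tres = results_from({"t1": "Induced"})
        gene_side, tx_side = cross_level_discordance(gres, tres, model)
        assert gene_side == 0.0 and tx_side == 0.0

    def test_transcript_without_de_gene_is_discordant(self, model):
        gres = results_from({}, level="gene")
        tres = results_from({"t1": "Induced"})
        gene_side, tx_side = cross_level_discordance(gres, tres, model)
        assert tx_side == 1.0

    def test_bounded_on_random_inputs(self, model):
        rng = np.random.default_rng(14)
        txs = ["t1", "t2", "t3", "t4", "t5", "t6"]
        genes = ["g1", "g2", "g3"]
        for _ in range(20):
            tres = results_from({t: rng.choice(["Induced", "Repressed", "NotSignificant"])
                                 for t in txs})
            gres = results_from({g: rng.choice(["Induced", "Repressed", "NotSignificant"])
                                 for g in genes}, level="gene")
            g_side, t_side = cross_level_discordance(gres, tres, model)
            assert 0.0 <= g_side <= 1.0 and 0.0 <= t_side <= 1.0


def test_end_to_end_switch_detection_on_synthetic_truth():
    """Detected and classified switches agree with the generator's truth on
    one strong-switch dataset."""
    cfg = SimulationConfig(n_genes=250, depth=1_000_000.0, dispersion=0.1, seed=17,
                           isoforms_per_gene={1: 0.2, 2: 0.4, 3: 0.25, 4: 0.1, 5: 0.05},
                           fraction_switch=0.2, fraction_induced=0.02,
                           fraction_repressed=0.02, switch_shift=0.8,
                           expression_range=(50.0, 2000.0), low_expression_fraction=0.0)
    ds = simulate_dataset(cfg)
    txm = NBExactTestModel(ds.transcript_counts)
    gm = NBExactTestModel(ds.gene_counts)
    pair = Comparison("24Zn", "UT")
    calls = detect_switches(txm.fit(pair), ds.gene_model, gm.fit(pair))
    st = ds.truth.switch_truth(pair)
    true_sw = set(st.index[st["is_switch"]])
    called = {c.gene_id for c in calls}
    assert called, "expected some switches at these settings"
    assert len(called & true_sw) / max(len(true_sw), 1) >= 0.8
    for c in calls:
        if c.gene_id in true_sw:
            assert c.switch_class == st.at[c.gene_id, "switch_class"]
            assert bool(c.identical_protein) == bool(st.at[c.gene_id, "identical_protein"])
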