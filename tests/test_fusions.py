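import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_breakend
from svcis.fusions import (EXPR_CATEGORIES, FusionCandidate,
                           annotate_expression_support, annotate_sv_support,
                           filter_candidates, summarize_fusions)
from svcis.io import GeneModel, Matrix


def cand(sample="S1", g5="gA", g3="gB", caller="callerB",
         confidence="high", intergenic=False):
    return FusionCandidate(sample, g5, g3, caller, confidence, intergenic)


class TestFilterCandidates:
    def test_half_low_confidence_drops_identity(self):
        cands = [cand(f"S{i}", confidence=c)
                 for i, c in enumerate(["low", "low", "high", "high"])]
        assert filter_candidates(cands) == []

    def test_quarter_low_keeps_high_calls(self):
        cands = [cand(f"S{i}", confidence=c)
                 for i, c in enumerate(["low", "high", "high", "high"])]
        kept = filter_candidates(cands)
        assert len(kept) == 3
        assert all(c.confidence == "high" for c in kept)

    def test_intergenic_dropped_even_if_high(self):
        assert filter_candidates([cand(intergenic=True)]) == []

    def test_same_partners_rejected(self):
        with pytest.raises(ValueError):
            cand(g5="gA", g3="gA")


class TestSvSupport:
    genes = [GeneModel("gA", "chr1", 100, 1000, "+"),
             GeneModel("gB", "chr2", 100, 1000, "+")]

    def support(self, cands, breakends):
        return annotate_sv_support(cands, breakends, self.genes)

    def test_one_gene_vs_both_genes(self):
        be5 = make_breakend(sample="S1", chrom="chr1", pos=500)
        be3 = make_breakend(sample="S1", chrom="chr2", pos=500, sv_id="sv2")
        one = self.support([cand("S1")], [be5])
        both = self.support([cand("S1")], [be5, be3])
        assert one["sv_support"].tolist() == ["one_gene"]
        assert both["sv_support"].tolist() == ["both_genes"]

    def test_cross_sample_twenty_percent_rule(self):
        cands = [cand(f"S{i}") for i in range(1, 5)]
        be = make_breakend(sample="S1", chrom="chr1", pos=500)
        out = self.support(cands, [be])
        # 1 of 4 carriers supported: 25% >= 20% rescues the other three
        assert out.loc[0, "sv_support"] == "one_gene"
        assert (out.loc[1:, "sv_support"] == "cross_sample").all()

    def test_no_support_anywhere(self):
        out = self.support([cand("S1")], [])
        assert out["sv_support"].tolist() == ["none"]


def expr_matrix(data, genes, samples):
    return Matrix(pd.DataFrame(np.asarray(data, dtype=float),
                               index=genes, columns=samples))


class TestExpressionSupport:
    def events(self, samples=("S1",)):
        return pd.DataFrame({"sample_id": list(samples),
                             "gene5": "gA", "gene3": "gB",
                             "sv_support": "both_genes"})

    def test_mrna_and_protein_oe(self):
        prot = expr_matrix([[1.0], [0.0]], ["gA", "gB"], ["S1"])
        mrna = expr_matrix([[1.2], [0.0]], ["gA", "gB"], ["S1"])
        out = annotate_expression_support(self.events(), prot, mrna)
        assert out["expr_category"].tolist() == ["mrna_and_protein_OE"]

    def test_mrna_oe_no_protein_data(self):
        prot = expr_matrix([[np.nan], [np.nan]], ["gA", "gB"], ["S1"])
        mrna = expr_matrix([[1.0], [0.0]], ["gA", "gB"], ["S1"])
        out = annotate_expression_support(self.events(), prot, mrna)
        assert out["expr_category"].tolist() == ["mrna_OE_no_protein_data"]

    def test_either_gene_rule_uses_max_partner(self):
        prot = expr_matrix([[0.1], [0.9]], ["gA", "gB"], ["S1"])
        mrna = expr_matrix([[0.1], [1.1]], ["gA", "gB"], ["S1"])
        out = annotate_expression_support(self.events(), prot, mrna)
        assert out["expr_category"].tolist() == ["mrna_and_protein_OE"]

    def test_cross_sample_oe_rescue(self):
        samples = [f"S{i}" for i in range(1, 6)]
        prot = expr_matrix([[1.0] + [0.1] * 4, [0.0] * 5],
                           ["gA", "gB"], samples)
        mrna = expr_matrix([[1.0] + [0.2] * 4, [0.0] * 5],
                           ["gA", "gB"], samples)
        out = annotate_expression_support(self.events(samples), prot, mrna)
        assert out.loc[0, "expr_category"] == "mrna_and_protein_OE"
        # 1 of 5 identity tumors OE = 20% >= threshold
        assert (out.loc[1:, "expr_category"] == "cross_sample_OE").all()

    def test_not_oe_below_threshold(self):
        prot = expr_matrix([[0.3], [0.3]], ["gA", "gB"], ["S1"])
        mrna = expr_matrix([[0.3], [0.3]], ["gA", "gB"], ["S1"])
        out = annotate_expression_support(self.events(), prot, mrna)
        assert out["expr_category"].tolist() == ["none"]


class TestProperties:
    @given(st.lists(
        st.tuples(st.booleans(), st.booleans(), st.booleans(),
                  st.booleans()), min_size=1, max_size=8))
    @settings(max_examples=400, deadline=None)
    def test_categories_exhaustive_and_exclusive(self, flags):
        """Any combination of per-event mRNA/protein OE and availability
        lands in exactly one category."""
        samples = [f"S{i}" for i in range(len(flags))]
        prot_vals, mrna_vals = [], []
        for has_p, p_oe, has_m, m_oe in flags:
            prot_vals.append((1.0 if p_oe else 0.0) if has_p else np.nan)
            mrna_vals.append((1.0 if m_oe else 0.0) if has_m else np.nan)
        prot = expr_matrix([prot_vals, [0.0] * len(flags)],
                           ["gA", "gB"], samples)
        mrna = expr_matrix([mrna_vals, [0.0] * len(flags)],
                           ["gA", "gB"], samples)
        events = pd.DataFrame({"sample_id": samples, "gene5": "gA",
                               "gene3": "gB", "sv_support": "both_genes"})
        out = annotate_expression_support(events, prot, mrna)
        assert out["expr_category"].isin(EXPR_CATEGORIES).all()

    def test_row_shuffle_stable(self, rng):
        genes = [GeneModel("gA", "chr1", 100, 1000, "+"),
                 GeneModel("gB", "chr2", 100, 1000, "+"),
                 GeneModel("gC", "chr1", 5000, 9000, "+")]
        cands = []
        for i in range(12):
            cands.append(FusionCandidate(
                f"S{i % 5}", "gA" if i % 2 else "gC", "gB",
                "callerB", ["high", "low", "medium"][i % 3], False))
        bes = [make_breakend(sample=f"S{i % 5}", chrom="chr1",
                             pos=500 if i % 2 else 6000, sv_id=f"s{i}")
               for i in range(6)]
        base = filter_candidates(cands)
        out1 = annotate_sv_support(base, bes, genes)
        order = rng.permutation(len(cands))
        shuffled = filter_candidates([cands[i] for i in order])
        out2 = annotate_sv_support(shuffled, bes, genes)
        key = ["sample_id", "gene5", "gene3"]
        pd.testing.assert_frame_equal(
            out1.sort_values(key).reset_index(drop=True),
            out2.sort_values(key).reset_index(drop=True))


class TestSummary:
    def test_empty_and_additivity(self):
        empty = pd.DataFrame(columns=["sample_id", "gene5", "gene3",
                                      "sv_support", "expr_category"])
        s = summarize_fusions(empty)
        assert int(s["expr_counts"].sum()) == 0
        ev = pd.DataFrame({"sample_id": ["S1"], "gene5": ["gA"],
                           "gene3": ["gB"], "sv_support": ["both_genes"],
                           "expr_category": ["mrna_and_protein_OE"]})
        once = summarize_fusions(ev)["expr_counts"]
        twice = summarize_fusions(pd.concat([ev, ev]))["expr_counts"]
        assert (twice == 2 * once).all()

    def test_planted_fusions_all_supported(self, cohort_and_truth,
                                           pipeline_outputs):
        from svcis import pipeline
        cohort, truth = cohort_and_truth
        norm, _ = pipeline_outputs
        res = pipeline.stage_fusions(cohort, norm)
        ev = res["events"]
        supported = ev[(ev["sv_support"] != "none")
                       & (ev["expr_category"] != "none")]
        planted = {(r.gene_id, r.gene2) for r in truth.records
                   if r.kind == "fusion"}
        observed = {(g5, g3) for g5, g3 in
                    zip(supported["gene5"], supported["gene3"])}
        assert observed == planted  # all 12 planted, no false positives
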