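import numpy as np
import pandas as pd
import pytest

from conftest import make_breakend
from svcis.io import GeneModel, SVCall
from svcis.mechanisms import (enhancer_hijack, mechanism_enrichment,
                              meth_transfer_delta, retro_translocation,
                              tad_disrupting)


def intervals(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


TADS = intervals([("chr1", 0, 1_000_000, "T1"),
                  ("chr1", 1_000_000, 2_000_000, "T2"),
                  ("chr2", 0, 1_000_000, "T3")])


class TestTadDisrupting:
    def sv(self, pos1, pos2, chrom2="chr1"):
        return SVCall("S1", "chr1", pos1, "+", chrom2, pos2, "-", "DEL",
                      sv_id="sv1")

    def test_within_one_tad_not_disrupting(self):
        assert not tad_disrupting(self.sv(100, 900_000), TADS)

    def test_two_tads_disrupting(self):
        assert tad_disrupting(self.sv(900_000, 1_100_000), TADS)

    def test_interchromosomal_always_disrupting(self):
        assert tad_disrupting(self.sv(100, 100, chrom2="chr2"), TADS)

    def test_outside_any_tad_configurable(self):
        sv = self.sv(5_000_000, 5_500_000)
        assert tad_disrupting(sv, TADS)
        assert not tad_disrupting(sv, TADS, outside_is_disrupting=False)


class TestEnhancerHijack:
    gene = GeneModel("gA", "chr1", 2_000_000, 2_020_000, "+")

    def breakend(self, mate_orient="+", mate_pos=5_000_000):
        # breakend 100 kb upstream of the gene, mate on chr7
        return make_breakend(chrom="chr1", pos=1_900_000, orient="+",
                             mate_chrom="chr7", mate_pos=mate_pos,
                             mate_orient=mate_orient)

    def test_translocated_enhancer_detected(self):
        enh = intervals([("chr7", 4_800_000, 4_801_000, "enhancer")])
        hit, d = enhancer_hijack(self.breakend("+"), self.gene, enh)
        assert hit
        # junction path: 100 kb to the gene + 199,001 bp to the enhancer
        assert d == 100_000 + (5_000_000 - 4_800_999)

    def test_orientation_flip_loses_enhancer(self):
        """'-' retains the high-coordinate side, where no enhancer lies."""
        enh = intervals([("chr7", 4_800_000, 4_801_000, "enhancer")])
        hit, _ = enhancer_hijack(self.breakend("-"), self.gene, enh)
        assert not hit

    def test_enhancer_beyond_scan_window_ignored(self):
        enh = intervals([("chr7", 4_000_000, 4_001_000, "enhancer")])
        hit, _ = enhancer_hijack(self.breakend("+"), self.gene, enh)
        assert not hit

    def test_closer_native_enhancer_excludes_call(self):
        enh = intervals([
            ("chr7", 4_800_000, 4_801_000, "enhancer"),  # translocated
            ("chr1", 1_995_000, 1_996_000, "enhancer"),  # native, 4 kb away
        ])
        hit, _ = enhancer_hijack(self.breakend("+"), self.gene, enh)
        assert not hit

    def test_native_beyond_reference_window_does_not_exclude(self):
        enh = intervals([
            ("chr7", 4_990_000, 4_991_000, "enhancer"),
            ("chr1", 3_500_000, 3_501_000, "enhancer"),  # 1.5 Mb away
        ])
        hit, _ = enhancer_hijack(self.breakend("+"), self.gene, enh)
        assert hit

    def test_missing_mate_orientation_error(self):
        be = make_breakend(mate_orient="?")
        enh = intervals([("chr2", 100, 200, "enhancer")])
        with pytest.raises(ValueError, match="orientation"):
            enhancer_hijack(be, self.gene, enh)


class TestRetroTranslocation:
    def breakend(self, mate_orient="-", mate_pos=9_000_000):
        return make_breakend(chrom="chr1", pos=1_995_000,
                             mate_chrom="chr5", mate_pos=mate_pos,
                             mate_orient=mate_orient)

    def test_sine_within_window(self):
        reps = intervals([("chr5", 9_001_000, 9_002_000, "SINE")])
        hit, klass = retro_translocation(self.breakend("-"), reps)
        assert hit and klass == "SINE"

    def test_repeat_beyond_window_ignored(self):
        reps = intervals([("chr5", 9_025_000, 9_026_000, "LINE")])
        hit, _ = retro_translocation(self.breakend("-"), reps)
        assert not hit

    def test_non_retro_elements_ignored(self):
        reps = intervals([("chr5", 9_001_000, 9_002_000, "LTR")])
        hit, _ = retro_translocation(self.breakend("-"), reps)
        assert not hit

    def test_orientation_contract_flip(self):
        reps = intervals([("chr5", 9_001_000, 9_002_000, "LINE")])
        assert retro_translocation(self.breakend("-"), reps)[0]
        assert not retro_translocation(self.breakend("+"), reps)[0]


class TestMethTransfer:
    probes = pd.DataFrame({
        "probe_id": ["pr1", "pr2", "prG"],
        "chrom": ["chr4", "chr4", "chr1"],
        "pos": [10_050_000, 10_150_000, 1_999_800],
        "cgi_flag": [1, 1, 1],
        "gene_id": [".", ".", "gA"],
        "position_category": ["body", "body", "TSS200"],
    })

    def beta(self, region_mean, gene_mean, n=10):
        vals = np.vstack([np.full(n, region_mean),
                          np.full(n, region_mean),
                          np.full(n, gene_mean)])
        return pd.DataFrame(vals, index=["pr1", "pr2", "prG"],
                            columns=[f"S{i}" for i in range(n)])

    def breakend(self, mate_orient="-"):
        return make_breakend(chrom="chr1", pos=1_950_000,
                             mate_chrom="chr4", mate_pos=10_000_000,
                             mate_orient=mate_orient)

    def test_low_methylation_region_flagged(self):
        delta, flag = meth_transfer_delta(self.breakend(),
                                          self.beta(0.1, 0.6),
                                          self.probes, "prG")
        np.testing.assert_allclose(delta, -0.5, atol=1e-12)
        assert flag == "low_meth"

    def test_identical_means_no_flag(self):
        delta, flag = meth_transfer_delta(self.breakend(),
                                          self.beta(0.5, 0.5),
                                          self.probes, "prG")
        assert delta == 0.0 and flag == ""

    def test_no_probe_in_region_missing(self):
        be = self.breakend(mate_orient="+")  # retains the probe-free side
        delta, flag = meth_transfer_delta(be, self.beta(0.1, 0.6),
                                          self.probes, "prG")
        assert np.isnan(delta) and flag == "no_probes"


class TestEnrichment:
    def test_chi2_matches_hand_formula(self, rng):
        m = pd.Series(rng.random(500) < 0.3)
        o = pd.Series(rng.random(500) < 0.4)
        res = mechanism_enrichment(m, o)
        (a, b), (c, d) = res["table"]
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        np.testing.assert_allclose(res["chi2"], expected, atol=1e-10)

    def test_degenerate_all_yes_flagged(self):
        res = mechanism_enrichment(pd.Series([True] * 5),
                                   pd.Series([True, False] * 2 + [True]))
        assert res["degenerate"]

    def test_planted_truth_detectors_fire(self, cohort_and_truth):
        """Planted enhancer-hijack and retrotransposon truths are
        recovered by the detectors on the emitted annotation tracks."""
        from svcis.breakpoints import breakends_from_calls
        cohort, truth = cohort_and_truth
        genes = {g.gene_id: g for g in cohort.genes}
        bes = breakends_from_calls(cohort.svs)
        by_sv = {}
        for be in bes:
            by_sv.setdefault((be.sample_id, be.sv_id), []).append(be)
        for rec in truth.by_kind("enhancer_hijack"):
            gene = genes[rec.gene_id]
            for s, sv_id in zip(rec.sample_ids, rec.sv_ids):
                near = [b for b in by_sv[(s, sv_id)]
                        if b.chrom == gene.chrom]
                hit, _ = enhancer_hijack(near[0], gene, cohort.enhancers)
                assert hit
        for rec in truth.by_kind("retro_hijack"):
            gene = genes[rec.gene_id]
            for s, sv_id in zip(rec.sample_ids, rec.sv_ids):
                near = [b for b in by_sv[(s, sv_id)]
                        if b.chrom == gene.chrom]
                hit, klass = retro_translocation(near[0], cohort.repeats)
                # planted next to a LINE, but a random SINE may sit even
                # closer on the retained side
                assert hit and klass in ("LINE", "SINE")

    def test_planted_meth_transfer_truths(self, cohort_and_truth):
        from svcis.breakpoints import breakends_from_calls
        cohort, truth = cohort_and_truth
        genes = {g.gene_id: g for g in cohort.genes}
        bes = breakends_from_calls(cohort.svs)
        by_sv = {}
        for be in bes:
            by_sv.setdefault((be.sample_id, be.sv_id), []).append(be)
        for rec in truth.by_kind("meth_transfer"):
            gene = genes[rec.gene_id]
            probe = rec.details["probe_id"]
            for s, sv_id in zip(rec.sample_ids, rec.sv_ids):
                near = [b for b in by_sv[(s, sv_id)]
                        if b.chrom == gene.chrom]
                delta, flag = meth_transfer_delta(
                    near[0], cohort.meth_beta, cohort.probe_annotation,
                    probe)
                assert flag == "low_meth" and delta < -0.1
                # per-sample criteria: beta outlier plus over-expression
                row = cohort.meth_beta.loc[probe]
                assert row[s] < row.median() - 0.2
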