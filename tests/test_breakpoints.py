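import numpy as np
import pandas as pd
import pytest

from conftest import make_breakend
from svcis.breakpoints import (RegionSpec, breakends_from_calls,
                               build_binary_matrix,
                               build_relative_distance_matrix,
                               nearest_breakend, nearest_distance_vector,
                               region_interval, relative_distance_weight)
from svcis.io import GeneModel, SVCall


def brute_force_binary(breakends, genes, samples, region,
                       strand_aware=True):
    """All-pairs O(n*m) oracle for the occupancy matrix."""
    out = pd.DataFrame(0.0, index=[g.gene_id for g in genes],
                       columns=list(samples))
    for g in genes:
        lo, hi = region_interval(g, region, strand_aware)
        for be in breakends:
            if be.chrom == g.chrom and lo <= be.pos < hi \
                    and be.sample_id in samples:
                out.at[g.gene_id, be.sample_id] = 1.0
    return out


class TestBreakends:
    def test_every_call_yields_two_mutual_breakends(self):
        call = SVCall("S1", "chr1", 100, "+", "chr2", 900, "-", "TRA",
                      sv_id="sv9")
        a, b = breakends_from_calls([call])
        assert (a.pos, a.mate_pos) == (100, 900)
        assert (b.pos, b.mate_pos) == (900, 100)
        assert a.mate_orient == b.orient and b.mate_orient == a.orient


class TestBinaryMatrix:
    def test_upstream_hit_and_gene_body_miss(self, toy_genes):
        gene = toy_genes[0]  # + strand, start 1_000_000
        be = make_breakend(pos=gene.start - 50_000, chrom="chr1")
        up = build_binary_matrix([be], [gene], ["S1"],
                                 RegionSpec("upstream_100kb", 100_000))
        body = build_binary_matrix([be], [gene], ["S1"],
                                   RegionSpec("gene_body", 0))
        assert up.values.at["gA", "S1"] == 1
        assert body.values.at["gA", "S1"] == 0

    def test_upstream_is_strand_aware(self, toy_genes):
        gene = toy_genes[1]  # - strand, [5_000_000, 5_050_000)
        be = make_breakend(pos=gene.end + 10_000, chrom="chr1")
        up = build_binary_matrix([be], [gene], ["S1"],
                                 RegionSpec("upstream_100kb", 100_000))
        down = build_binary_matrix([be], [gene], ["S1"],
                                   RegionSpec("downstream_100kb", 100_000))
        assert up.values.at["gB", "S1"] == 1
        assert down.values.at["gB", "S1"] == 0
        # genomic-left mode flips the call
        up_lr = build_binary_matrix([be], [gene], ["S1"],
                                    RegionSpec("upstream_100kb", 100_000),
                                    strand_aware=False)
        assert up_lr.values.at["gB", "S1"] == 0

    def test_both_ends_in_body_count_once(self, toy_genes):
        gene = toy_genes[0]
        call = SVCall("S1", "chr1", gene.start + 100, "+",
                      "chr1", gene.end - 100, "-", "DEL", sv_id="sv1")
        m = build_binary_matrix(breakends_from_calls([call]), [gene],
                                ["S1"], RegionSpec("gene_body", 0))
        assert m.values.at["gA", "S1"] == 1

    def test_unknown_chromosome_ignored_with_counter(self, toy_genes):
        be = make_breakend(chrom="chrUn", pos=5)
        m = build_binary_matrix([be], toy_genes, ["S1"],
                                RegionSpec("flank_1mb", 1_000_000))
        assert m.n_ignored == 1
        assert (m.values.to_numpy() == 0).all()

    def test_cells_have_provenance(self, toy_genes):
        be = make_breakend(pos=toy_genes[0].start - 10, sv_id="svX")
        m = build_binary_matrix([be], toy_genes, ["S1"],
                                RegionSpec("flank_1mb", 1_000_000))
        hit = m.provenance[(m.provenance["gene_id"] == "gA")]
        assert hit["sv_id"].tolist() == ["svX"]

    def test_matches_all_pairs_oracle(self, rng):
        genes = [GeneModel(f"g{i}", f"chr{1 + i % 2}",
                           1_000_000 * (i + 1), 1_000_000 * (i + 1) + 30_000,
                           "+" if i % 2 else "-") for i in range(15)]
        samples = [f"S{j}" for j in range(12)]
        bes = [make_breakend(sample=samples[rng.integers(12)],
                             chrom=f"chr{1 + rng.integers(2)}",
                             pos=int(rng.integers(0, 17_000_000)),
                             sv_id=f"sv{k}") for k in range(200)]
        for kind, window in (("gene_body", 0), ("upstream_100kb", 100_000),
                             ("downstream_100kb", 100_000),
                             ("flank_1mb", 1_000_000)):
            spec = RegionSpec(kind, window)
            fast = build_binary_matrix(bes, genes, samples, spec)
            slow = brute_force_binary(bes, genes, samples, spec)
            pd.testing.assert_frame_equal(fast.values, slow)

    def test_sample_permutation_permutes_columns_only(self, toy_genes):
        bes = [make_breakend(sample="S1", pos=1_000_100),
               make_breakend(sample="S2", pos=400_000, sv_id="sv2")]
        m1 = build_binary_matrix(bes, toy_genes, ["S1", "S2"],
                                 RegionSpec("flank_1mb", 1_000_000))
        m2 = build_binary_matrix(bes, toy_genes, ["S2", "S1"],
                                 RegionSpec("flank_1mb", 1_000_000))
        pd.testing.assert_frame_equal(m1.values,
                                      m2.values[["S1", "S2"]])


class TestNearestBreakend:
    def test_picks_closest_to_anchor(self, toy_genes):
        gene = toy_genes[0]
        near = make_breakend(pos=gene.anchor + 10_000, sv_id="near")
        far = make_breakend(pos=gene.anchor + 500_000, sv_id="far")
        d, be = nearest_breakend([far, near], gene, "S1", 1_000_000)
        assert (d, be.sv_id) == (10_000, "near")

    def test_tie_broken_by_smaller_position(self, toy_genes):
        gene = toy_genes[0]
        left = make_breakend(pos=gene.anchor - 5_000, sv_id="zzz")
        right = make_breakend(pos=gene.anchor + 5_000, sv_id="aaa")
        _, be = nearest_breakend([right, left], gene, "S1", 1_000_000)
        assert be.sv_id == "zzz"

    def test_none_outside_window(self, toy_genes):
        be = make_breakend(pos=toy_genes[0].anchor + 2_000_000)
        assert nearest_breakend([be], toy_genes[0], "S1", 1_000_000) is None


class TestRelativeDistance:
    def test_closed_form_at_zero_distance(self):
        w = relative_distance_weight(0, 1_000_000)
        np.testing.assert_allclose(w, np.log2(1_000_002) - 1, atol=1e-12)
        assert abs(w - 18.93) < 0.01

    def test_zero_at_window_edge(self):
        assert relative_distance_weight(1_000_000, 1_000_000) == 0.0

    def test_strictly_decreasing(self):
        d = np.arange(0, 1_000_000, 57_731)
        w = relative_distance_weight(d, 1_000_000)
        assert (np.diff(w) < 0).all()

    def test_support_equals_binary_flank(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", 2_000_000 * (i + 1),
                           2_000_000 * (i + 1) + 20_000, "+")
                 for i in range(8)]
        samples = [f"S{j}" for j in range(10)]
        bes = [make_breakend(sample=samples[rng.integers(10)], chrom="chr1",
                             pos=int(rng.integers(0, 18_000_000)),
                             sv_id=f"sv{k}") for k in range(120)]
        rel = build_relative_distance_matrix(bes, genes, samples, 1_000_000)
        binary = build_binary_matrix(bes, genes, samples,
                                     RegionSpec("flank_1mb", 1_000_000))
        assert (rel.values > 0).equals(binary.values > 0)

    def test_count_breakpoint_samples(self, toy_genes):
        gene = toy_genes[0]
        bes = [make_breakend(sample=f"S{i}", pos=gene.anchor + 1000 * i,
                             sv_id=f"sv{i}") for i in range(4)]
        m = build_binary_matrix(bes, [gene], [f"S{i}" for i in range(6)],
                                RegionSpec("flank_1mb", 1_000_000))
        assert m.count_breakpoint_samples("gA") == 4


class TestDistanceVector:
    def test_ceiling_for_no_breakend_and_invariance_beyond_window(
            self, toy_genes):
        gene = toy_genes[0]
        near = make_breakend(sample="S1", pos=gene.anchor + 1_000)
        far = make_breakend(sample="S1", pos=gene.anchor + 5_000_000,
                            sv_id="far")
        v1 = nearest_distance_vector([near], gene, ["S1", "S2"], 1_000_000)
        v2 = nearest_distance_vector([near, far], gene, ["S1", "S2"],
                                     1_000_000)
        assert v1["S2"] == np.log2(1_000_002)
        np.testing.assert_allclose(v1["S1"], np.log2(1_002))
        pd.testing.assert_series_equal(v1, v2)
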