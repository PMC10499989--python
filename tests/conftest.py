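import numpy as np
import pandas as pd
import pytest

from svcis.breakpoints import Breakend
from svcis.io import GeneModel, Matrix, SVCall
from svcis.simulate import SimConfig, generate_cohort


def make_breakend(sample="S1", chrom="chr1", pos=1000, orient="+",
                  mate_chrom="chr2", mate_pos=5000, mate_orient="-",
                  sv_class="TRA", sv_id="sv1"):
    return Breakend(sample, chrom, pos, orient, mate_chrom, mate_pos,
                    mate_orient, sv_class, sv_id)


@pytest.fixture(scope="session")
def cohort_and_truth():
    """Default synthetic cohort, shared across tests (read-only)."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_outputs(cohort_and_truth):
    """Normalized matrices and breakpoint matrices for the shared cohort."""
    from svcis import pipeline
    cohort, _ = cohort_and_truth
    norm = pipeline.stage_normalize(cohort)
    mats = pipeline.stage_matrices(cohort)
    return norm, mats


@pytest.fixture
def toy_genes():
    return [
        GeneModel("gA", "chr1", 1_000_000, 1_020_000, "+"),
        GeneModel("gB", "chr1", 5_000_000, 5_050_000, "-"),
        GeneModel("gC", "chr2", 2_000_000, 2_010_000, "+"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
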