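import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from progeval import (
    DetectionParams,
    ErrorProfile,
    FrameIndex,
    SimParams,
    make_benchmark,
    map_all,
)


@pytest.fixture(scope="session")
def noiseless_bench(tmp_path_factory):
    """100 kb / 80-gene benchmark with 10 short + 10 missed + 10 wrong +
    3 mistagged-pseudogene + 2 untagged-frameshift plantings, noiseless
    peptide detection.  Shared across test modules (read-only)."""
    params = SimParams(genome_length=100_000, n_genes=80, seed=0)
    profile = ErrorProfile(
        "callerA", n_short=10, n_missed=10, n_wrong=10,
        n_pseudogene_mistag=3, n_untagged_frameshift=2,
    )
    det = DetectionParams(p_gene_expressed=1.0, p_peptide_detected=1.0,
                          false_match_rate=0.0)
    out = tmp_path_factory.mktemp("bench")
    return make_benchmark(params, [profile], det, seed=11, out_dir=out)


@pytest.fixture(scope="session")
def noiseless_mapped(noiseless_bench):
    index = FrameIndex([noiseless_bench.replicon])
    mapped, report = map_all(noiseless_bench.peptides, index)
    return index, mapped, report
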