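import numpy as np
import pytest

from cpuorf.engines import BuiltinEngine
from cpuorf.fixtures import (
    QUERY_ORDER,
    QUERY_SPECIES,
    FixtureSpec,
    make_fixture,
)
from cpuorf.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def engine():
    return BuiltinEngine()


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    return make_fixture(FixtureSpec(seed=0), tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def pipeline_result(default_fixture, tmp_path_factory):
    fx = default_fixture
    cfg = PipelineConfig(
        genome=fx.genome_path,
        gff3=fx.gff3_path,
        collection_fasta=fx.collection_fasta,
        taxonomy_tsv=fx.taxonomy_path,
        outdir=tmp_path_factory.mktemp("run"),
        query_species=QUERY_SPECIES,
        query_order=QUERY_ORDER,
        n_perm=199,
        seed=1,
    )
    return run_pipeline(cfg)


def brute_force_uorfs(utr: str, min_codons: int = 2) -> set[tuple[int, int]]:
    """Independent oracle: enumerate all (i, j) substrings and filter by
    the uORF definition (ATG start, stop end, no internal in-frame stop)."""
    stops = {"TAA", "TAG", "TGA"}
    seq = utr.upper()
    found = set()
    n = len(seq)
    for i in range(n):
        for j in range(i + 3 * min_codons, n + 1, 3):
            if seq[i : i + 3] != "ATG":
                continue
            if seq[j - 3 : j] not in stops:
                continue
            codons = [seq[k : k + 3] for k in range(i, j - 3, 3)]
            if any(c in stops for c in codons):
                continue
            found.add((i, j))
    return found


def random_utr(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGTN"), size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
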