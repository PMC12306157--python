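import pytest

import pefinder as pf

CLEAN_FIXTURE_SEED = 20240917


def build_clean_fixture(tmp_path, seed=CLEAN_FIXTURE_SEED, n_rep=20, n_rit=10):
    """100-kb clean fixture: GC-rich perfect palindromes in a 50%-GC
    background, 12xT tails on the terminators, genes every ~1.1 kb."""
    genome = pf.make_genome(100_000, 0.5, seed=seed)
    genes = pf.make_gene_layout(100_000, 80)
    specs = [
        pf.ImplantSpec(kind="REP", count=n_rep),
        pf.ImplantSpec(kind="RIT", tail="T" * 12, count=n_rit),
    ]
    return pf.implant(genome, genes, specs, seed=seed + 1, out_prefix=tmp_path / "fix")


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    return build_clean_fixture(tmp_path_factory.mktemp("clean"))


@pytest.fixture(scope="session")
def clean_result(clean_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("out") / "pred"
    return pf.run_pipeline(
        clean_fixture.paths["fasta"], clean_fixture.paths["gff"], out_prefix=out
    )
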