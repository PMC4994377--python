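import pytest
from hypothesis import settings

from genefam import family_table, motif_grammar, synthetic

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def family_records():
    return family_table.load_family_table()


@pytest.fixture(scope="session")
def family_summary(family_records):
    return family_table.summarize_family(family_records)


@pytest.fixture(scope="session")
def default_motifs():
    return motif_grammar.load_default_motifs()


@pytest.fixture(scope="session")
def layout_recovery():
    """Planted genome layout plus the duplication/homoeolog calls on it.

    Session-scoped because the all-vs-all alignment is the slowest step in
    the suite.
    """
    from genefam import align_dup

    spec = synthetic.SyntheticSpec(seed=42)
    layout = synthetic.gen_genome_layout(spec)
    pairs = align_dup.call_duplications(
        layout.sequences, layout.loci, tandem_window=spec.tandem_window
    )
    groups = align_dup.call_homoeolog_groups(pairs, layout.loci)
    return spec, layout, pairs, groups
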