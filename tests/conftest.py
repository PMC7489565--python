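import pytest

from pksmith.synthetic_data import (
    mad_architecture,
    make_cluster,
    tetromadurin_decomposition,
)


@pytest.fixture(scope="session")
def mad_spec():
    return mad_architecture()


@pytest.fixture(scope="session")
def mad_bundle(mad_spec):
    """The canonical synthetic cluster fixture, generated once per session."""
    return make_cluster(mad_spec, seed=1)


@pytest.fixture(scope="session")
def mad_target():
    return tetromadurin_decomposition()


@pytest.fixture(scope="session")
def mad_annotation(mad_bundle, mad_target):
    from pksmith.domain_annotator import annotate_cluster

    return annotate_cluster(mad_bundle.cluster, mad_target)


@pytest.fixture(scope="session")
def mad_chains(mad_bundle, mad_annotation, mad_target):
    from pksmith.chain_assembler import assemble_from_calls, chain_from_target

    order = [m.module_index for m in mad_bundle.cluster.pks_modules]
    chain13 = assemble_from_calls(mad_annotation.calls, order)
    chain14 = chain_from_target(mad_target)
    return chain13, chain14
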