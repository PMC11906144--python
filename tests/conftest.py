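import pytest

from odorcascade import (
    MoleculeRecord,
    PipelineConfig,
    ReceptorRecord,
    SynthConfig,
    generate_study,
    train_cascade,
)


@pytest.fixture(scope="session")
def default_study():
    """The default-scale synthetic study (63 molecules x 61 receptors)."""
    return generate_study(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_study():
    """A miniature study for fast pipeline tests."""
    cfg = SynthConfig(
        n_molecules=24,
        n_receptors=12,
        n_odor_labels=9,
        n_communities=3,
        seed=1,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def tiny_model(tiny_study):
    """A cascade trained on the miniature study (fast panel, small folds)."""
    cfg = PipelineConfig(
        seed=1, panel="fast", outer_folds=3, inner_folds=2,
        mol_variant_m1="morgan", prot_variant_m1="1AAF",
    )
    model, report = train_cascade(
        tiny_study.molecules,
        tiny_study.receptors,
        tiny_study.binding_samples,
        cfg,
    )
    return model, report


@pytest.fixture
def simple_molecules():
    return [
        MoleculeRecord("m1", "CCO", {"sweet", "caramel"}),
        MoleculeRecord("m2", "CCCO", {"caramel", "fruity"}),
        MoleculeRecord("m3", "c1ccccc1", {"solvent"}),
    ]


@pytest.fixture
def simple_receptors():
    return [
        ReceptorRecord("r1", "ACDEFGHIKLMNPQRSTVWY", "mouse"),
        ReceptorRecord("r2", "AAGGWWYYKKLLMMNNPPQQ", "human"),
    ]
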