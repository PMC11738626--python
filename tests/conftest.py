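import numpy as np
import pytest

from dockmil.backbones import BackboneConfig
from dockmil.synthdata import SyntheticSpec, generate_dataset
from dockmil.train import bag_instance_graphs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small in-memory dataset shared by structural tests."""
    spec = SyntheticSpec(
        n_entities=8,
        poses_per_entity=5,
        ligand_size_range=(6, 10),
        pocket_size_range=(14, 22),
        seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_instances(tiny_dataset):
    """Featurized+graphed instances (sgcnn flavor) of the tiny dataset."""
    config = BackboneConfig(architecture="sgcnn", embedding_dim=16, hidden_dim=8)
    return bag_instance_graphs(tiny_dataset.bags, config), config


@pytest.fixture(scope="session")
def noiseless_run():
    """Noiseless recovery setting: bags hold the true pose plus bad decoys."""
    from dockmil.pipeline import run_two_stage

    spec = SyntheticSpec(
        n_entities=700,
        poses_per_entity=9,
        n_informative=0,
        label_noise_sd=0.0,
        include_crystal=True,
        seed=0,
    )
    ds = generate_dataset(spec)
    train_bags, test_bags = ds.split_bags()
    return run_two_stage(
        train_bags,
        test_bags,
        architecture="sgcnn",
        embedding_dim=32,
        hidden_dim=16,
        seed=0,
        stage1_epochs=40,
        stage2_epochs=300,
        fc_widths=(16, 8),
    )


@pytest.fixture(scope="session")
def written_dataset(tmp_path_factory):
    """Tiny dataset emitted to disk (PDB + Mol2 + index) for IO round-trips."""
    out = tmp_path_factory.mktemp("synthdata")
    spec = SyntheticSpec(
        n_entities=4,
        poses_per_entity=4,
        ligand_size_range=(6, 9),
        pocket_size_range=(12, 18),
        seed=7,
    )
    return generate_dataset(spec, outdir=out)
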