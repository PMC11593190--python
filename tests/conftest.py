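import numpy as np
import pytest

from histofuse.deep_backbone import BackboneSpec
from histofuse.lbp_texture import LBPConfig
from histofuse.pipeline import PipelineConfig
from histofuse.synthetic_data import generate_dataset
from histofuse.vit_context import ViTConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def tiny_config():
    """Small extractor configuration for fast pipeline tests."""
    return PipelineConfig(
        lbp=LBPConfig(P=8, R=1.0),
        vit=ViTConfig(patch_size=16, embed_dim=16, n_heads=2, n_layers=1,
                      mlp_dim=32, weight_source=11),
        backbone=BackboneSpec(kind="seeded_test", out_shape=(7, 7, 32), seed=11),
        split_seed=5,
        classifier_seed=5,
        classifier_params={"boosted_trees_A": {"min_child_samples": 2}},
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """5 tiles/class generated directly at the pipeline resolution."""
    tiles, manifest = generate_dataset(5, seed=77, side=224)
    return tiles, manifest
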