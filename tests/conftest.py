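import numpy as np
import pytest

from readerprob.synthetic import (
    ImageConfig,
    sample_subjects,
    separable_config,
    simulate_annotations,
    render_images,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject separable cohort with annotations and 64x64 images."""
    cfg = separable_config(400, seed=101)
    truths = sample_subjects(cfg)
    annotations = simulate_annotations(truths, seed=102)
    images = render_images(truths, ImageConfig(), seed=103)
    labels = np.array(
        [[1 if a.merged_first(f) == "P" else 0 for f in cfg.finding_names]
         for a in annotations], dtype=float)
    return cfg, truths, annotations, images, labels


@pytest.fixture(scope="session")
def trained_model(small_cohort):
    """One SmallCNN trained on 300 separable images (3 epochs)."""
    from readerprob.classifier import SmallCNN, TrainConfig

    cfg, truths, annotations, images, labels = small_cohort
    model = SmallCNN(side=64, seed=7)
    model.fit(images[:300], labels[:300], TrainConfig(epochs=3, seed=11))
    return model
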