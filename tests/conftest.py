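"""Shared fixtures: synthetic corpora and a trained detector.

Everything is generated programmatically at test time; the expensive
fixtures (a trained model, a 25-image corpus) are session-scoped so the
cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from microdet.detector import DetectorConfig, FragmentViewDetector
from microdet.render import render_fragment_view, truth_boxes
from microdet.simulate import SyntheticSpec, make_dataset, simulate


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """25-image corpus with 2-4 planted domains each: 20 for training,
    5 held out (by sorted name order)."""
    out = tmp_path_factory.mktemp("corpus")
    spec = SyntheticSpec(seed=100, complexes_per_domain=20)
    make_dataset(spec, 25, out_dir=out, n_domains_per_image=[2, 3, 4])
    return out


@pytest.fixture(scope="session")
def corpus_split(corpus_dir):
    names = sorted(p.name for p in corpus_dir.glob("img_*.png"))
    return names[:20], names[20:]


@pytest.fixture(scope="session")
def trained_results(corpus_dir, corpus_split):
    """Detector trained on the 20 training images of the shared corpus."""
    train_names, _ = corpus_split
    config = DetectorConfig(epochs=60, seed=1)
    model = FragmentViewDetector.from_corpus(
        corpus_dir, config, image_names=train_names
    )
    return model.fit()


@pytest.fixture(scope="session")
def overfit_run():
    """Single-image overfit: (image array, truth annotations, results)."""
    spec = SyntheticSpec(seed=5)
    complexes, truths = simulate(spec)
    image, rmap = render_fragment_view(complexes, spec.region)
    annotations = truth_boxes(rmap, truths)
    arr = np.asarray(image)
    config = DetectorConfig(epochs=40, seed=1)
    results = FragmentViewDetector([(arr, annotations)], config).fit()
    return arr, annotations, results


@pytest.fixture()
def single_region():
    spec = SyntheticSpec(seed=7)
    complexes, truths = simulate(spec)
    image, rmap = render_fragment_view(complexes, spec.region)
    return spec, complexes, truths, image, rmap
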