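"""Shared fixtures: synthetic scenes and trained models reused across tests.

Everything is generated programmatically from fixed seeds; the expensive
artifacts (scene batches, the trained SVM) are session-scoped so the whole
suite builds them once.
"""

import numpy as np
import pytest

import weedvision as wv
from weedvision.lbp import LBPConfig, featurize_patch

#: descriptor geometry used for end-to-end classification tests: the
#: smallest grid of the study (fast) — 4 cells × 10 bins = 40 features
E2E_LBP = LBPConfig(n_points=8, radius=1, image_size=64, cell_size=32)


@pytest.fixture(scope="session")
def default_scene():
    """One 9-plant field scene at the default conditions."""
    return wv.generate_scene(wv.SceneParams(seed=3))


@pytest.fixture(scope="session")
def training_rois():
    """~400 labelled ROI patches extracted from 45 seeded scenes.

    Mirrors how the real dataset was built: scenes are segmented and the
    connected-component ROIs labelled from ground truth.
    """
    scenes = [wv.generate_scene(wv.SceneParams(seed=100 + k)) for k in range(45)]
    patches, manifest = wv.scene_to_dataset(scenes)
    assert manifest["matched"].all()
    return patches


@pytest.fixture(scope="session")
def svm_e2e(training_rois):
    """Linear one-vs-one SVM (C=5) trained on LBP(8,1)/64/32 features."""
    X = np.vstack([featurize_patch(p, E2E_LBP) for p in training_rois])
    y = np.array([p.class_label for p in training_rois])
    model = wv.MulticlassSVM(C=5.0)
    model.feature_fingerprint = E2E_LBP.fingerprint()
    model.fit(X, y)
    return model


@pytest.fixture(scope="session")
def held_out_scenes():
    """20 evaluation scenes drawn from seeds disjoint from the training ones."""
    return [wv.generate_scene(wv.SceneParams(seed=9000 + k)) for k in range(20)]
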