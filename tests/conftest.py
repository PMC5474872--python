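import warnings

import numpy as np
import pytest

from wmlquant import phantom as ph
from wmlquant import segment as seg
from wmlquant.image import TPMSet
from wmlquant.lesions import LobeAtlas

FIVE_CLASSES = ("gm", "wm", "csf", "wml", "background")


@pytest.fixture(scope="session")
def spec48():
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def plan5(spec48):
    return ph.plan_lesions(spec48, 5, 3.0, seed=3)


@pytest.fixture(scope="session")
def phantom48(spec48, plan5):
    """One default-noise phantom with 5 planted lesions."""
    return ph.generate_phantom(spec48, plan5, seed=2)


@pytest.fixture(scope="session")
def noiseless48(plan5):
    spec = ph.PhantomSpec(noise_sd=0)
    return ph.generate_phantom(spec, plan5, seed=2)


@pytest.fixture(scope="session")
def fit48(phantom48):
    """Two-channel flat-prior mixture fit of the default phantom."""
    img, _ = phantom48
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, tpms = seg.fit_mixture(img, channels=("t1w", "flair"),
                                      classes=FIVE_CLASSES,
                                      config=seg.FitConfig(max_iter=100))
    return model, tpms


@pytest.fixture(scope="session")
def atlas48(spec48):
    labels, names = spec48.lobe_atlas()
    return LobeAtlas(labels=labels, label_names=names,
                     voxel_size=spec48.voxel_size)


@pytest.fixture
def onehot_tpms(noiseless48):
    """One-hot TPMs built from the noiseless ground-truth labels."""
    _, gt = noiseless48
    codes = {"background": 0, "csf": 1, "gm": 2, "wm": 3, "wml": 4}
    probs = {c: (gt.label_volume == code).astype(float) for c, code in codes.items()}
    return TPMSet(probs=probs, voxel_size=gt.voxel_size)


def dice(pred, truth):
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    denom = pred.sum() + truth.sum()
    return 2.0 * (pred & truth).sum() / denom if denom else 1.0
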