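import numpy as np
import pytest

from sonoprint import synthetic as syn


@pytest.fixture(scope="session")
def small_phantom():
    return syn.make_head_phantom((32, 32, 32), spacing=1.0, skull_hu=1800.0,
                                 skull_thickness=2.0, seed=1)


@pytest.fixture(scope="session")
def tiny_bold_pair():
    """One-subject, one-run control/stim pair with the default planted effect."""
    return syn.make_bold_dataset(n_subjects=1, n_runs=1, n_volumes=200,
                                 seed=3, effect=syn.EffectSpec())


@pytest.fixture(scope="session")
def rois_and_targets(tiny_bold_pair):
    from sonoprint.connectivity import Roi

    control, _ = tiny_bold_pair
    rois = {name: Roi(name=name, left=control.roi_voxels[name]["left"],
                      right=control.roi_voxels[name]["right"])
            for name in control.roi_voxels}
    targets = [rois[n] for n in rois if n != "SMA"]
    return rois, targets
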