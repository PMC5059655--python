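"""Shared fixtures: phantoms, gradient tables and fitted fields.

Everything is generated programmatically with fixed seeds; heavier
fixtures are session-scoped so the phantom is rasterized once.
"""

import numpy as np
import pytest

from dtreg import phantom as ph
from dtreg.formats_io import RoiMask
from dtreg.tensor_model import fit_tensor


@pytest.fixture(scope="session")
def gtab():
    return ph.default_gradient_table()


@pytest.fixture(scope="session")
def two_shell_gtab():
    """Gradient table with two shells (no saturated design row)."""
    g1 = ph.default_gradient_table(n_dirs=9, b=1000.0)
    g2 = ph.default_gradient_table(n_dirs=6, b=700.0)
    from dtreg.formats_io import GradientTable

    bvecs = np.vstack([g1.bvecs, g2.bvecs[1:]])
    bvals = np.concatenate([g1.bvals, g2.bvals[1:]])
    return GradientTable(bvecs, bvals)


@pytest.fixture(scope="session")
def straight_phantom(gtab):
    """Noise-free single straight bundle with its DWI, fit and masks."""
    spec = ph.PhantomSpec(
        bundles=[ph.straight_bundle((2, 20, 10), (37, 20, 10), radius=4.0)],
        noise_sigma=0.0, seed=0,
    )
    tf_true, e1_true, masks = ph.build_tensor_phantom(spec)
    dwi = ph.simulate_dwi(tf_true, gtab, sigma=0.0, seed=0)
    return {"spec": spec, "tf_true": tf_true, "e1_true": e1_true,
            "bundle": masks[0], "dwi": dwi}


@pytest.fixture(scope="session")
def default_phantom(gtab):
    """The default two-bundle phantom (noise-free)."""
    spec = ph.default_phantom_spec(noise_sigma=0.0, seed=0)
    tf_true, e1_true, masks = ph.build_tensor_phantom(spec)
    dwi = ph.simulate_dwi(tf_true, gtab, sigma=0.0, seed=0)
    return {"spec": spec, "tf_true": tf_true, "e1_true": e1_true,
            "masks": masks, "dwi": dwi}


@pytest.fixture(scope="session")
def fitted_straight(straight_phantom, gtab):
    tf = fit_tensor(straight_phantom["dwi"], gtab)
    return tf


@pytest.fixture()
def full_mask(straight_phantom):
    return RoiMask(np.ones(straight_phantom["dwi"].shape3, dtype=bool), "full")


def single_voxel_dwi(gtab, D, s0=1000.0, sigma=0.0, seed=0, shape=(1, 1, 1)):
    """DWI volume of identical voxels with tensor D (helper, not a fixture)."""
    from dtreg.formats_io import Volume
    from dtreg.tensor_model import coeffs_from_tensors, design_matrix
    from dtreg.tensor_model import TensorField

    coeffs = np.broadcast_to(coeffs_from_tensors(np.asarray(D)), shape + (6,)).copy()
    tf = TensorField(
        coeffs=coeffs, s0=np.full(shape, s0),
        mask=RoiMask(np.ones(shape, dtype=bool)),
        design=design_matrix(gtab), gtab=gtab,
    )
    return ph.simulate_dwi(tf, gtab, sigma=sigma, seed=seed)
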