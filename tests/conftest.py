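import numpy as np
import pytest

from ficd import experiments as ex
from ficd import mapping as mp
from ficd import parcellation as pc
from ficd import synthetic as syn
from ficd import tractography as tr


@pytest.fixture(scope="session")
def sphere642():
    return syn.make_sphere_surface(642, radius_mm=50.0)


@pytest.fixture(scope="session")
def sphere2562():
    return syn.make_sphere_surface(2562, radius_mm=50.0)


@pytest.fixture(scope="session")
def parc2562(sphere2562):
    return pc.parcellate_surface(sphere2562, 256, seed=0)


@pytest.fixture(scope="session")
def straight_tracking():
    """80-mm straight-bundle phantom with its default-config tractogram."""
    spec = ex.straight_bundle_phantom(seed=0)
    tensors = syn.make_tensor_phantom(spec)
    fa = tr.compute_fa(tensors)
    config = tr.TrackingConfig(seed=1)
    tractogram = tr.track_streamlines(tensors, config)
    return spec, tensors, fa, config, tractogram


@pytest.fixture(scope="session")
def small_cortex():
    """A parcellated sphere embedded in a voxel grid, with CU voxel masks.

    Sphere of radius 15 mm centred at (20, 20, 20) inside a 41-voxel cube,
    eight CUs, 2-mm inward masks: a small but complete geometry for
    exercising fiber-to-CU assignment.
    """
    from ficd.io import VolumeGeometry
    from ficd.mesh import SurfaceMesh

    base = syn.make_sphere_surface(642, radius_mm=15.0)
    mesh = SurfaceMesh(base.vertices + 20.0, base.faces)
    geom = VolumeGeometry.from_spacing((41, 41, 41), (1.0, 1.0, 1.0))
    parc = pc.parcellate_surface(mesh, 8, seed=0)
    parc = pc.cu_voxel_masks(parc, mesh, geom, thickness_mm=2.0)
    return mesh, geom, parc


@pytest.fixture(scope="session")
def template_cohort(sphere2562, parc2562):
    template = ex.make_template_map(parc2562, sphere2562, seed=0)
    return sphere2562, parc2562, template
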