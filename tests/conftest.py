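import numpy as np
import pytest

from armsim.phantom import (
    BoneSpec,
    GrayIndex,
    PhantomSpec,
    build_phantom,
    render_slices,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A reduced five-tissue phantom for fast unit tests."""
    return PhantomSpec(
        n_slices=24,
        image_size=32,
        outer_radius_profile=tuple(np.linspace(13.0, 11.0, 24)),
        layer_thicknesses={"skin": 1.5, "fat": 2.0, "muscle": 1.0},
        bones=(BoneSpec(center=(1.5, 1.0), outer_radius=4.0,
                        cortical_thickness=1.5),),
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def gray_index() -> GrayIndex:
    return GrayIndex()


@pytest.fixture(scope="session")
def small_stack(small_truth, gray_index):
    return render_slices(small_truth, gray_index, seed=0)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return build_phantom(default_spec)


@pytest.fixture(scope="session")
def default_fem(default_truth):
    """Meshed default phantom with assembled operators and steady solves.

    Shared by the solver-level acceptance criteria so the expensive
    factorizations happen once per session.  Material frequency 1 kHz for both
    modes; 10 mA, 20×20 mm electrodes on the ±x skin surface.
    """
    from types import SimpleNamespace

    from armsim.cli import RunConfig, build_protocols
    from armsim.meshing import voxel_to_tet
    from armsim.solver import (
        assemble,
        default_tissue_properties,
        electrode_load,
        solve_phasor,
    )

    mesh = voxel_to_tet(default_truth)
    props = default_tissue_properties()
    k_sig, k_eps = assemble(mesh, props, 1000.0)
    dc, ac = build_protocols(default_truth, RunConfig())
    load = electrode_load(mesh, dc, dc.waveform.amplitude)
    sol_dc = solve_phasor(k_sig, k_eps, load.b, 0.0, mesh=mesh)
    sol_ac = solve_phasor(k_sig, k_eps, load.b, ac.waveform.frequency, mesh=mesh)
    return SimpleNamespace(
        mesh=mesh, props=props, k_sig=k_sig, k_eps=k_eps,
        dc=dc, ac=ac, load=load, sol_dc=sol_dc, sol_ac=sol_ac,
    )


@pytest.fixture(scope="session")
def default_recon_solid(default_truth, gray_index):
    """Full noiseless segment → clean → surface → solidify → compensate run
    on the default phantom (shared by reconstruction and acceptance tests)."""
    import numpy as np

    from armsim.phantom import BACKGROUND, SKIN
    from armsim.reconstruction import (
        GridSpec,
        clean_point_cloud,
        compensate_thin_layers,
        reconstruct_surface,
        solidify,
    )
    from armsim.segmentation import (
        ThresholdSpec,
        extract_point_cloud,
        threshold_segment,
    )

    stack = render_slices(default_truth, gray_index, seed=0)
    seg = threshold_segment(stack, ThresholdSpec.from_gray_index(gray_index))
    grid = GridSpec.from_label_volume(seg)
    surfaces = []
    for lab in sorted(np.unique(seg.labels))[::-1]:
        if lab == BACKGROUND:
            continue
        pc = clean_point_cloud(extract_point_cloud(seg, int(lab)))
        surfaces.append(reconstruct_surface(pc, voxel=1.0))
    solid = solidify(surfaces, grid)
    solid = compensate_thin_layers(solid, SKIN, 1.0)
    return seg, solid
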