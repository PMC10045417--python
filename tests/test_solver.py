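import numpy as np
import pytest
from scipy import sparse

from armsim.meshing import TetMesh, voxel_to_tet
from armsim.phantom import CORTICAL, FAT, MARROW, MUSCLE, SKIN, LabelVolume
from armsim.solver import (
    EPS0,
    ElectrodeSpec,
    SolverError,
    StimulusProtocol,
    StimulusWaveform,
    TissueProperties,
    assemble,
    complex_conductivity,
    current_density,
    default_tissue_properties,
    electrode_load,
    recovered_current,
    solve_phasor,
    solve_transient,
    tissue_properties_at,
)


@pytest.fixture(scope="module")
def props():
    return default_tissue_properties()


def make_box(n=8, h=2.0, label=MUSCLE):
    vol = LabelVolume(
        labels=np.full((n, n, n), label, dtype=int), spacing=(h, h, h),
        origin=(0.0, 0.0, 0.0),
    )
    return voxel_to_tet(vol)


def box_electrodes(size, slack=1.0, edge=None):
    edge = edge or (size, size)
    an = ElectrodeSpec(center=(size / 2, size / 2, size), polarity=1, axis=2,
                       sign=1, edge_lengths=edge, normal_slack=slack)
    ca = ElectrodeSpec(center=(size / 2, size / 2, 0.0), polarity=-1, axis=2,
                       sign=-1, edge_lengths=edge, normal_slack=slack)
    return an, ca


class TestTissueProperties:
    @pytest.mark.parametrize(
        "tissue,f,sigma,epsr",
        [
            ("skin", 1e4, 2.04e-4, 1.13e3),
            ("skin", 1e3, 2.00e-4, 1.14e3),
            ("muscle", 1e6, 5.00e-1, 1.80e3),
            ("muscle", 1e4, 3.40e-1, 2.60e4),
            ("fat", 1e4, 2.38e-2, 1.09e3),
            ("cortical_bone", 1e5, 2.08e-3, 2.27e2),
            ("marrow", 1e3, 2.02e-3, 2.70e3),
        ],
    )
    def test_tabulated_values_exact(self, props, tissue, f, sigma, epsr):
        s, e = tissue_properties_at(props, tissue, f)
        assert s == sigma
        assert e == epsr

    def test_loglog_interpolation_fat_midpoint(self, props):
        f = np.sqrt(1e3 * 1e4)  # geometric midpoint
        s, _ = tissue_properties_at(props, "fat", f)
        expected = np.exp((np.log(2.24e-2) + np.log(2.38e-2)) / 2.0)
        assert np.isclose(s, expected, rtol=1e-12)

    def test_out_of_range_rejected(self, props):
        with pytest.raises(ValueError, match="outside"):
            tissue_properties_at(props, "skin", 100.0)
        with pytest.raises(ValueError, match="outside"):
            tissue_properties_at(props, "skin", 1e7)

    def test_unknown_tissue(self, props):
        with pytest.raises(KeyError):
            tissue_properties_at(props, 77, 1e4)

    def test_complex_conductivity(self, props):
        sig = complex_conductivity(props, "muscle", 1e3)
        assert np.isclose(sig.real, 0.32)
        assert np.isclose(sig.imag, 2 * np.pi * 1e3 * EPS0 * 4.3e5)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            TissueProperties(table={1: ([1e4, 1e3], [0.1, 0.1], [1.0, 1.0])})


class TestAssemble:
    def test_row_sums_vanish(self, props):
        mesh = make_box(4)
        k_sig, k_eps = assemble(mesh, props, 1e4)
        for k in (k_sig, k_eps):
            rs = np.abs(np.asarray(k.sum(axis=1)).ravel())
            rowmax = np.abs(k).max(axis=1).toarray().ravel()
            assert np.all(rs <= 1e-12 * np.maximum(rowmax, 1e-300))

    def test_reference_tet_hand_stiffness(self):
        # unit right tet with 1 mm legs, σ = 1: K = σ V G Gᵀ with
        # ∇λ = rows of [[-1,-1,-1],[1,0,0],[0,1,0],[0,0,1]] / (1 mm)
        nodes = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        )
        mesh = TetMesh(nodes=nodes, tets=[[0, 1, 2, 3]], tissue_tags=[1])
        props1 = TissueProperties(table={1: ([1e3, 1e6], [1.0, 1.0], [1.0, 1.0])})
        k_sig, _ = assemble(mesh, props1, 1e3)
        g = np.array(
            [[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
        ) * 1e3  # 1/m
        v = (1e-3) ** 3 / 6.0
        expected = v * g @ g.T
        np.testing.assert_allclose(k_sig.toarray(), expected, rtol=1e-12)

    def test_linearity_in_sigma(self):
        labels = np.full((2, 2, 2), MUSCLE, dtype=int)
        labels[1] = FAT
        vol = LabelVolume(labels=labels, spacing=(1.0, 1.0, 1.0))
        mesh = voxel_to_tet(vol)
        t1 = TissueProperties(table={
            MUSCLE: ([1e3, 1e6], [0.3, 0.3], [1.0, 1.0]),
            FAT: ([1e3, 1e6], [0.02, 0.02], [1.0, 1.0]),
        })
        t2 = TissueProperties(table={
            MUSCLE: ([1e3, 1e6], [0.3, 0.3], [1.0, 1.0]),
            FAT: ([1e3, 1e6], [0.04, 0.04], [1.0, 1.0]),
        })
        k1, _ = assemble(mesh, t1, 1e3)
        k2, _ = assemble(mesh, t2, 1e3)
        d = k2 - k1
        # the difference is exactly the fat block, equal to the fat part of k1
        fat_only_1 = assemble(
            voxel_to_tet(LabelVolume(labels=np.where(labels == FAT, FAT, 0),
                                     spacing=(1.0, 1.0, 1.0))),
            t1, 1e3,
        )[0]
        assert np.isclose(sparse.linalg.norm(d), sparse.linalg.norm(fat_only_1))

    def test_missing_tissue_named(self, props):
        labels = np.full((2, 2, 2), 9, dtype=int)
        mesh = voxel_to_tet(LabelVolume(labels=labels, spacing=(1.0,) * 3))
        with pytest.raises(SolverError, match="9"):
            assemble(mesh, props, 1e4)


class TestElectrodeLoad:
    def test_realized_j_exact_patch(self, props):
        # 20×20 mm patch exactly covered on a flat box face: j = I/s = 25 A/m²
        mesh = make_box(n=10, h=2.0)
        an, ca = box_electrodes(20.0)
        load = electrode_load(mesh, [an, ca], 0.010)
        assert np.isclose(load.anode_area_m2, 4e-4)
        assert np.isclose(load.realized_j, 25.0)

    def test_zero_current_zero_load(self):
        mesh = make_box(4)
        an, ca = box_electrodes(8.0)
        load = electrode_load(mesh, [an, ca], 0.0)
        assert np.all(load.b == 0.0)

    def test_charge_balance(self):
        mesh = make_box(6)
        an, ca = box_electrodes(12.0, edge=(6.0, 6.0))
        load = electrode_load(mesh, [an, ca], 0.01)
        assert abs(load.b.sum()) <= 1e-12 * np.abs(load.b).sum()

    def test_no_face_diagnostic(self):
        mesh = make_box(4)
        an = ElectrodeSpec(center=(100.0, 100.0, 100.0), polarity=1, axis=2,
                           sign=1, edge_lengths=(2.0, 2.0), normal_slack=1.0)
        ca = ElectrodeSpec(center=(4.0, 4.0, 0.0), polarity=-1, axis=2,
                           sign=-1, edge_lengths=(8.0, 8.0), normal_slack=1.0)
        with pytest.raises(SolverError, match="nearest face"):
            electrode_load(mesh, [an, ca], 0.01)

    def test_protocol_polarity_validation(self):
        an, _ = box_electrodes(8.0)
        with pytest.raises(ValueError):
            StimulusProtocol(
                anode=an, cathode=an,
                waveform=StimulusWaveform("DC", 0.01),
            )

    def test_current_limit_enforced(self):
        with pytest.raises(ValueError, match="20 mA"):
            StimulusWaveform("DC", 0.021)


@pytest.fixture(scope="module")
def slab_system(props):
    mesh = make_box(n=8, h=2.0)
    k_sig, k_eps = assemble(mesh, props, 1e3)
    an, ca = box_electrodes(16.0)
    load = electrode_load(mesh, [an, ca], 0.010)
    return mesh, k_sig, k_eps, load


class TestSolvePhasor:
    def test_linearity(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        s1 = solve_phasor(k_sig, k_eps, load.b, 1e3, mesh=mesh)
        s2 = solve_phasor(k_sig, k_eps, 2 * load.b, 1e3, mesh=mesh)
        np.testing.assert_allclose(s2.phi, 2 * s1.phi, rtol=1e-10)

    def test_electrode_swap_antisymmetry(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        s1 = solve_phasor(k_sig, k_eps, load.b, 1e3, mesh=mesh)
        s2 = solve_phasor(k_sig, k_eps, -load.b, 1e3, mesh=mesh)
        np.testing.assert_allclose(
            s2.phi, -s1.phi, rtol=0, atol=1e-10 * np.abs(s1.phi).max()
        )

    def test_zero_mean_gauge(self, slab_system):
        from armsim.solver import lumped_node_volumes

        mesh, k_sig, k_eps, load = slab_system
        sol = solve_phasor(k_sig, k_eps, load.b, 1e3, mesh=mesh)
        w = lumped_node_volumes(mesh)
        mean = np.average(sol.phi, weights=w)
        assert abs(mean) <= 1e-10 * np.abs(sol.phi).max()

    def test_gauge_independence_of_differences(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        a = solve_phasor(k_sig, k_eps, load.b, 1e3, mesh=mesh,
                         gauge="lagrange")
        g = solve_phasor(k_sig, k_eps, load.b, 1e3, mesh=mesh, gauge="ground",
                         ground_node=mesh.n_nodes // 3)
        da = a.phi - a.phi[0]
        dg = g.phi - g.phi[0]
        np.testing.assert_allclose(
            da, dg, rtol=0, atol=1e-10 * np.abs(da).max()
        )

    def test_incompatible_load_rejected(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        bad = load.b.copy()
        bad[0] += 1e-3
        with pytest.raises(SolverError, match="incompatible"):
            solve_phasor(k_sig, k_eps, bad, 1e3, mesh=mesh)


class TestSolveTransient:
    def test_zero_amplitude_zero_field(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        wf = StimulusWaveform("AC", 0.0, frequency=1e3)
        sol = solve_transient(k_sig, k_eps, wf, load.b / 0.01, mesh=mesh,
                              t_end=2e-3)
        assert np.all(sol.phi == 0.0)

    def test_underresolved_ac_refused(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        wf = StimulusWaveform("AC", 0.01, frequency=1e3)
        with pytest.raises(SolverError, match="under-resolve"):
            solve_transient(k_sig, k_eps, wf, load.b / 0.01, mesh=mesh,
                            dt=1e-4, t_end=4e-3)

    def test_dc_converges_to_resistive(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        wf = StimulusWaveform("DC", 0.01)
        steady = solve_phasor(k_sig, k_eps, load.b, 0.0, mesh=mesh)
        tr = solve_transient(k_sig, k_eps, wf, load.b / 0.01, mesh=mesh)
        scale = np.abs(steady.phi).max()
        assert np.abs(tr.phi[-1] - steady.phi).max() <= 5e-3 * scale

    def test_ac_amplitude_matches_phasor(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        f = 1e3
        wf = StimulusWaveform("AC", 0.01, frequency=f)
        ph = solve_phasor(k_sig, k_eps, load.b, f, mesh=mesh)
        tr = solve_transient(k_sig, k_eps, wf, load.b / 0.01, mesh=mesh,
                             t_end=4.0 / f)
        # LSQ sinusoid amplitude per node over the final cycle
        sel = tr.times >= tr.times[-1] - 1.0 / f
        t = tr.times[sel]
        design = np.column_stack(
            [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
        )
        coef, *_ = np.linalg.lstsq(design, tr.phi[sel], rcond=None)
        amp = np.hypot(coef[0], coef[1])
        ref = np.abs(ph.phi)
        scale = ref.max()
        assert np.abs(amp - ref).max() <= 0.01 * scale

    def test_backward_euler_scheme_available(self, slab_system):
        mesh, k_sig, k_eps, load = slab_system
        wf = StimulusWaveform("DC", 0.01)
        tr = solve_transient(k_sig, k_eps, wf, load.b / 0.01, mesh=mesh,
                             scheme="be")
        steady = solve_phasor(k_sig, k_eps, load.b, 0.0, mesh=mesh)
        assert np.abs(tr.phi[-1] - steady.phi).max() <= 5e-3 * np.abs(
            steady.phi
        ).max()


class TestCurrentDensity:
    def test_constant_phi_zero_j(self, slab_system, props):
        from armsim.solver import FieldSolution

        mesh, *_ = slab_system
        sol = FieldSolution(mesh=mesh, phi=np.full(mesh.n_nodes, 3.7),
                            mode="phasor", frequency=0.0)
        j = current_density(sol, props, 1e3)
        assert np.abs(j).max() < 1e-12

    def test_linearity_in_current(self, slab_system, props):
        mesh, k_sig, k_eps, load = slab_system
        s1 = solve_phasor(k_sig, k_eps, load.b, 1e3, mesh=mesh)
        s2 = solve_phasor(k_sig, k_eps, 2 * load.b, 1e3, mesh=mesh)
        j1 = current_density(s1, props, 1e3)
        j2 = current_density(s2, props, 1e3)
        np.testing.assert_allclose(j2, 2 * j1, rtol=1e-9)

    def test_uniform_slab_j_equals_realized(self, slab_system, props):
        mesh, k_sig, k_eps, load = slab_system
        sol = solve_phasor(k_sig, k_eps, load.b, 0.0, mesh=mesh)
        j = current_density(sol, props, 1e3)
        jmag = np.linalg.norm(np.abs(j), axis=1)
        assert np.all(np.abs(jmag - load.realized_j) <= 0.01 * load.realized_j)

    def test_full_face_electrode_current_recovery(self, slab_system, props):
        mesh, k_sig, k_eps, load = slab_system
        sol = solve_phasor(k_sig, k_eps, load.b, 0.0, mesh=mesh)
        j = current_density(sol, props, 1e3)
        i_an = recovered_current(mesh, j, load.anode_faces)
        i_ca = recovered_current(mesh, j, load.cathode_faces)
        assert abs(i_an - load.current) <= 5e-3 * load.current
        assert abs(-i_ca - load.current) <= 5e-3 * load.current

    def test_transient_needs_two_steps(self, slab_system, props):
        from armsim.solver import FieldSolution

        mesh, *_ = slab_system
        sol = FieldSolution(
            mesh=mesh, phi=np.zeros((1, mesh.n_nodes)), mode="transient",
            times=np.array([0.0]),
        )
        with pytest.raises(SolverError, match="2 time steps"):
            current_density(sol, props, 1e3)
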