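"""Synthetic meshes: verification fixtures and the coronal joint."""

import numpy as np
import pytest

from poroknee.elements import CORNER_LOCAL, FEOperators
from poroknee.geometry import (
    GeometryError,
    JointGeometryParams,
    fibre_field,
    make_confined_column,
    make_coronal_joint,
    make_unconfined_strip,
)


def _exterior_edges(mesh):
    """Count boundary (shared by one element) corner-to-corner half edges."""
    edges = {}
    for el in mesh.elements:
        c = el[CORNER_LOCAL]
        for a, b in zip(c, np.roll(c, -1)):
            key = (min(a, b), max(a, b))
            edges[key] = edges.get(key, 0) + 1
    return [e for e, n in edges.items() if n == 1]


class TestConfinedColumn:
    def test_construction(self):
        mesh = make_confined_column(2.0, 10)
        assert len(mesh.elements) == 10
        assert mesh.nodes[:, 1].max() == pytest.approx(2.0)
        ops = FEOperators(mesh)          # raises on inverted elements
        assert ops.n_p == len(mesh.pressure_nodes)

    def test_single_element_valid(self):
        mesh = make_confined_column(2.0, 1)
        assert len(mesh.elements) == 1
        FEOperators(mesh)

    def test_boundary_tags_cover_exterior(self):
        mesh = make_confined_column(2.0, 5)
        top = mesh.tag("peripheral_draining")
        bottom = mesh.tag("fixed_base")
        assert len(top) == 3 and len(bottom) == 3
        assert np.all(mesh.nodes[top, 1] == pytest.approx(2.0))
        assert np.all(mesh.nodes[bottom, 1] == 0.0)
        # every node is on a roller (1-D confined kinematics)
        assert len(mesh.tag("roller_x")) == mesh.n_nodes

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            make_confined_column(2.0, 0)
        with pytest.raises(ValueError):
            make_confined_column(-1.0, 4)


class TestUnconfinedStrip:
    def test_construction_and_tags(self):
        mesh = make_unconfined_strip(4.0, 2.0, 8)
        assert len(mesh.elements) == 8 * 4
        lat = mesh.tag("peripheral_draining")
        assert np.all(np.isin(np.abs(mesh.nodes[lat, 0]), [2.0]))
        assert len(mesh.tag("platen_top")) == 17
        assert len(mesh.tag("platen_bottom")) == 17
        # platen interior nodes are impermeable; only the corner points that
        # also belong to the free lateral edges drain
        shared = np.intersect1d(mesh.tag("platen_top"), lat)
        assert np.all(np.abs(mesh.nodes[shared, 0]) == 2.0)


class TestCoronalJoint:
    def test_intact_regions_and_validity(self):
        mesh = make_coronal_joint(JointGeometryParams())
        assert sorted(mesh.region_names) == [
            "femoral_lat", "femoral_med", "meniscus_lat", "meniscus_med",
            "tibial"]
        FEOperators(mesh)    # positive Jacobians, mixed-order consistency
        assert set(mesh.pressure_nodes) <= set(range(mesh.n_nodes))

    def test_meniscectomy_shares_coordinates_with_intact(self):
        intact = make_coronal_joint(JointGeometryParams())
        menis = make_coronal_joint(JointGeometryParams(variant="meniscectomy"))
        assert sorted(menis.region_names) == ["femoral_lat", "femoral_med",
                                              "tibial"]
        # same alignment: shared regions occupy identical coordinates
        for name in menis.region_names:
            ni = intact.region_elements(name)
            nm = menis.region_elements(name)
            ci = intact.nodes[intact.elements[ni]].reshape(-1, 2)
            cm = menis.nodes[menis.elements[nm]].reshape(-1, 2)
            assert np.allclose(ci, cm, atol=0)

    def test_deterministic_regeneration(self):
        a = make_coronal_joint(JointGeometryParams())
        b = make_coronal_joint(JointGeometryParams())
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.elements, b.elements)
        assert np.array_equal(a.fibre_dir, b.fibre_dir)

    def test_mirror_symmetry(self):
        mesh = make_coronal_joint(JointGeometryParams())
        x = np.sort(mesh.nodes[:, 0])
        assert np.allclose(x + x[::-1], 0.0, atol=1e-9)

    def test_fixed_base_covers_bottom(self):
        mesh = make_coronal_joint(JointGeometryParams())
        base = mesh.tag("fixed_base")
        t = JointGeometryParams().tibial_cartilage_thickness
        assert np.all(mesh.nodes[base, 1] == pytest.approx(-t))
        assert np.ptp(mesh.nodes[base, 0]) == pytest.approx(
            JointGeometryParams().tibial_width)

    def test_wedge_too_low_raises(self):
        with pytest.raises(GeometryError):
            make_coronal_joint(JointGeometryParams(initial_gap=1.0,
                                                   meniscus_inner_height=0.5))

    def test_invalid_wedge_taper(self):
        with pytest.raises(ValueError):
            JointGeometryParams(meniscus_inner_height=3.0,
                                meniscus_outer_height=2.0)

    def test_wedge_clears_condyle_initially(self):
        # the reference configuration must be contact-free: no wedge-top
        # node may lie above the condyle articular arc
        p = JointGeometryParams()
        mesh = make_coronal_joint(p)
        xc = mesh.meta["condyle_centre_x"]
        yc = mesh.meta["condyle_centre_y"]
        R = mesh.meta["condyle_radius"]
        for side, s in (("med", 1), ("lat", -1)):
            top = mesh.surfaces[f"meniscus_{side}_top"]
            pts = mesh.nodes[top]
            r = np.hypot(pts[:, 0] - s * xc, pts[:, 1] - yc)
            assert np.all(r >= R - 1e-9)


class TestFibreField:
    def test_tibial_fibres_flat(self):
        mesh = fibre_field(make_coronal_joint(JointGeometryParams()))
        tib = mesh.region_elements("tibial")
        assert np.allclose(mesh.fibre_dir[tib], [1.0, 0.0])

    def test_unit_norms_everywhere(self):
        mesh = fibre_field(make_coronal_joint(JointGeometryParams()))
        assert np.allclose(np.linalg.norm(mesh.fibre_dir, axis=1), 1.0)

    def test_femoral_fibres_tangent_to_arc(self):
        mesh = fibre_field(make_coronal_joint(JointGeometryParams()))
        xc = mesh.meta["condyle_centre_x"]
        yc = mesh.meta["condyle_centre_y"]
        fem = mesh.region_elements("femoral_med")
        centroids = mesh.nodes[mesh.elements[fem]].mean(axis=1)
        radial = centroids - [xc, yc]
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.abs(np.einsum("ij,ij->i", radial, mesh.fibre_dir[fem]))
        assert dots.max() < 1e-9

    def test_meniscus_radial_modulus_label(self):
        mesh = make_coronal_joint(JointGeometryParams())
        labels = mesh.meta["fibre_label_by_region"]
        assert labels["meniscus_med"] == "radial"
        assert labels["femoral_lat"] == "tangent"
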