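import numpy as np
import pandas as pd
import pytest

from hotspotter import surface_geometry as sg
from hotspotter.errors import ConfigError, DegenerateStructureError
from hotspotter.surface_geometry import (DEFAULT_CONFIG, GeometryConfig, binding_deltas,
                                         classify_position, compute_asa,
                                         compute_depth_index, compute_protrusion_index,
                                         compute_rasa, compute_surface_profile,
                                         detect_interface, load_reference_areas,
                                         structural_features)

from conftest import make_structure
from dataclasses import replace


def single_atom(element="C"):
    return make_structure([("A", 1, "CA", element, (0.0, 0.0, 0.0))])


class TestAsa:
    def test_lone_sphere_matches_closed_form(self):
        s = single_atom("C")
        asa = compute_asa(s)
        r = DEFAULT_CONFIG.vdw_radii["C"] + DEFAULT_CONFIG.probe_radius
        expected = 4 * np.pi * r ** 2
        assert asa[0] == pytest.approx(expected, rel=0.02)

    def test_coincident_atoms_do_not_exceed_isolated_area(self):
        iso = compute_asa(single_atom("C"))[0]
        s = make_structure([("A", 1, "CA", "C", (0.0, 0.0, 0.0)),
                            ("A", 1, "CB", "C", (0.0, 0.0, 0.0))])
        asa = compute_asa(s)
        assert (asa <= iso + 1e-9).all()

    def test_collinear_triple_matches_dense_sampling_oracle(self):
        coords = [(0.0, 0.0, 0.0), (2.5, 0.0, 0.0), (5.0, 0.0, 0.0)]
        s = make_structure([("A", 1, n, "C", c)
                            for n, c in zip(("CA", "CB", "CG"), coords)])
        asa = compute_asa(s)
        dense = compute_asa(s, replace(DEFAULT_CONFIG, n_points=20000))
        assert np.allclose(asa, dense, rtol=0.01)

    def test_unknown_element_names_it(self):
        s = single_atom("XX")
        with pytest.raises(ConfigError, match="XX"):
            compute_asa(s)

    def test_occlusion_monotonicity_random_clusters(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pts = rng.uniform(0, 6, size=(6, 3))
            base = make_structure([("A", 1, f"C{i}", "C", p)
                                   for i, p in enumerate(pts)])
            extra = make_structure(
                [("A", 1, f"C{i}", "C", p) for i, p in enumerate(pts)]
                + [("A", 2, "CX", "C", rng.uniform(0, 6, size=3))])
            asa0 = compute_asa(base)
            asa1 = compute_asa(extra)[:len(pts)]
            assert (asa1 <= asa0 + 1e-6 * asa0.max() + 1e-9).all()


class TestProtrusionIndex:
    def test_isolated_atom_closed_form(self):
        pi = compute_protrusion_index(single_atom())
        sphere = 4.0 / 3.0 * np.pi * DEFAULT_CONFIG.pi_sphere_radius ** 3
        assert pi[0] == pytest.approx((sphere - 20.1) / 20.1)

    def test_filled_sphere_reaches_zero(self):
        # enough atoms inside the sphere to exceed its volume
        n_fill = int(np.ceil(4.0 / 3.0 * np.pi * 1000 / 20.1))
        rng = np.random.default_rng(0)
        pts = rng.uniform(-2, 2, size=(n_fill, 3))
        s = make_structure([("A", 1, f"C{i}", "C", p) for i, p in enumerate(pts)])
        pi = compute_protrusion_index(s)
        assert (pi == 0).all()

    def test_cluster_matches_brute_force_neighbor_count(self):
        coords = [(0, 0, 0), (3, 0, 0), (0, 4, 0), (12, 0, 0), (5, 5, 5)]
        s = make_structure([("A", 1, f"C{i}", "C", c) for i, c in enumerate(coords)])
        pi = compute_protrusion_index(s)
        sphere = 4.0 / 3.0 * np.pi * 1000.0
        arr = np.asarray(coords, float)
        for i in range(len(arr)):
            count = sum(np.linalg.norm(arr[i] - arr[j]) <= 10.0
                        for j in range(len(arr)))
            v_int = count * 20.1
            assert pi[i] == pytest.approx(max(sphere - v_int, 0) / v_int)


class TestDepthIndex:
    def test_exposed_atoms_have_zero_depth(self):
        s = make_structure([("A", 1, "CA", "C", (0, 0, 0)),
                            ("A", 1, "CB", "C", (3, 0, 0))])
        asa = compute_asa(s)
        di = compute_depth_index(s, asa)
        assert np.array_equal(di, [0.0, 0.0])

    def test_buried_atom_distance_to_shell(self):
        # central atom inside an icosahedral-ish shell of 30 atoms at 4 Å
        rng = np.random.default_rng(3)
        dirs = rng.standard_normal((30, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        atoms = [("A", 1, "CA", "C", (0.0, 0.0, 0.0))]
        atoms += [("A", 2, f"C{i}", "C", tuple(4.0 * d)) for i, d in enumerate(dirs)]
        s = make_structure(atoms)
        asa = compute_asa(s)
        di = compute_depth_index(s, asa)
        assert asa[0] <= DEFAULT_CONFIG.di_exposure_threshold  # centre is buried
        exposed = asa > DEFAULT_CONFIG.di_exposure_threshold
        coords = s.coords()
        expected = min(np.linalg.norm(coords[0] - coords[j])
                       for j in np.flatnonzero(exposed))
        assert di[0] == pytest.approx(expected)
        assert (di >= 0).all()

    def test_no_exposed_atom_is_degenerate(self):
        s = make_structure([("A", 1, "CA", "C", (0, 0, 0))])
        with pytest.raises(DegenerateStructureError):
            compute_depth_index(s, np.array([0.0]))


class TestRasa:
    def test_identity_and_zero(self):
        ref = load_reference_areas()
        row = pd.Series({f"asa_{c}": ref.at["LEU", c] for c in sg.ASA_CLASSES})
        rasa = compute_rasa(row, "LEU")
        assert all(v == pytest.approx(1.0) for v in rasa.values())
        zero = pd.Series({f"asa_{c}": 0.0 for c in sg.ASA_CLASSES})
        assert all(v == 0.0 for v in compute_rasa(zero, "LEU").values())

    def test_glycine_sidechain_class_is_zero(self):
        row = pd.Series({f"asa_{c}": 50.0 for c in sg.ASA_CLASSES})
        assert compute_rasa(row, "GLY")["rasa_sidechain"] == 0.0

    def test_missing_reference_entry(self):
        row = pd.Series({f"asa_{c}": 1.0 for c in sg.ASA_CLASSES})
        with pytest.raises(ConfigError):
            compute_rasa(row, "XYZ")


@pytest.mark.parametrize("bound,unbound,expected", [
    (0.0, 0.5, "core"),
    (0.4, 0.5, "rim"),
    (0.1, 0.1, "support"),
])
def test_classify_position(bound, unbound, expected):
    assert classify_position(bound, unbound) == expected


class TestBindingDeltas:
    def _profiles(self, unbound_pi, bound_pi):
        idx = pd.Index([("A", 1, "")])
        unb = pd.DataFrame({"pi_total_mean": [unbound_pi]}, index=idx)
        bnd = pd.DataFrame({"pi_total_mean": [bound_pi]}, index=idx)
        return unb, bnd

    def test_rctmpi_arithmetic(self):
        unb, bnd = self._profiles(1.0, 0.5)
        rel = binding_deltas(unb, bnd)
        assert rel["pi_total_mean_relchange"].iloc[0] == pytest.approx(0.5)

    def test_identity_gives_zero(self):
        unb, bnd = self._profiles(0.7, 0.7)
        rel = binding_deltas(unb, bnd)
        assert rel["pi_total_mean_relchange"].iloc[0] == 0.0

    def test_zero_unbound_flagged(self):
        unb, bnd = self._profiles(0.0, 0.3)
        rel = binding_deltas(unb, bnd)
        assert rel["pi_total_mean_relchange"].iloc[0] == 0.0
        assert bool(rel["relchange_flagged"].iloc[0])


class TestDetectInterface:
    def test_reproduces_construction_truth(self, toy_complex):
        complex_, truth = toy_complex
        annot = detect_interface(complex_)
        for _, row in truth.iterrows():
            key = (row["chain"], row["resnum"], "")
            assert annot.at[key, "is_interface"] == row["is_interface"], key

    def test_wide_gap_no_interface(self, far_complex):
        complex_, _ = far_complex
        annot = detect_interface(complex_)
        assert not annot["is_interface"].any()

    def test_dasa_nonnegative(self, toy_complex):
        complex_, _ = toy_complex
        annot = detect_interface(complex_)
        assert (annot["dasa"] >= -1e-6).all()


class TestStructuralFeatures:
    def test_55_columns_and_determinism(self, toy_complex):
        complex_, _ = toy_complex
        table = structural_features(complex_)
        assert list(table.columns) == sg.STRUCTURAL_COLUMNS
        assert len(sg.STRUCTURAL_COLUMNS) == 55
        again = structural_features(complex_)
        pd.testing.assert_frame_equal(table, again)

    def test_protruding_interface_has_higher_rctmpi_than_flat(self, toy_complex):
        # interface residues bury their protruding CB tips on binding; the
        # far residues bury nothing, so their relative PI change is 0
        complex_, truth = toy_complex
        table = structural_features(complex_)
        rct = table["pi_total_mean_relchange"]
        iface_keys = [(r["chain"], r["resnum"], "") for _, r in truth.iterrows()
                      if r["is_interface"]]
        flat_keys = [(r["chain"], r["resnum"], "") for _, r in truth.iterrows()
                     if not r["is_interface"]]
        assert rct.loc[iface_keys].median() > rct.loc[flat_keys].median()
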