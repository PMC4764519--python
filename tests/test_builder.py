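import numpy as np
import pytest
from scipy.spatial import cKDTree

from fgpore.builder import (
    MINIMAL_VARIANT_REMOVED,
    NupAnchor,
    ScaffoldGeometry,
    TopologyError,
    build_scaffold,
    build_system,
    generate_synthetic_fixture,
    graft_nups,
    make_inert_cargo,
    make_kap_complex,
    make_minimal_variant,
    realize_cargo,
)


class TestScaffold:
    def test_eightfold_symmetry(self):
        geom = ScaffoldGeometry(pore_diameter=20.0, pore_half_height=5.0)
        beads = build_scaffold(geom)
        theta = 2 * np.pi / geom.symmetry_order
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = beads @ R.T
        d, _ = cKDTree(beads).query(rotated)
        assert d.max() < 1e-9

    def test_wall_at_or_beyond_half_diameter(self):
        geom = ScaffoldGeometry(pore_diameter=20.0, pore_half_height=5.0)
        beads = build_scaffold(geom)
        assert np.hypot(beads[:, 0], beads[:, 1]).min() >= 10.0

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            ScaffoldGeometry(pore_diameter=4.0, scaffold_bead_diameter=5.0)

    def test_two_rings_of_eight_anchors_give_16_sites(self):
        geom, anchors, seqs = generate_synthetic_fixture(1 / 3, seed=0)
        assert sum(a.copies for a in anchors) == 16


class TestInertCargo:
    @pytest.mark.parametrize(
        "D,expected_sigma",
        [(4.2, 2.4), (2.0, 1.3)],
    )
    def test_single_bead_sigma(self, D, expected_sigma):
        spec = make_inert_cargo(D)
        assert spec.kind == "single"
        assert spec.sigma_c == pytest.approx(expected_sigma)

    def test_composite_radius(self):
        spec = make_inert_cargo(10.0)
        assert spec.kind == "composite"
        assert spec.sigma_c == pytest.approx(2.5)
        assert spec.r_c == pytest.approx(10.0 / 2 - 2.2)

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            make_inert_cargo(-1.0)

    @pytest.mark.parametrize("D", [6.0, 8.0, 10.0, 12.0])
    def test_composite_sphericity_within_5_percent(self, D):
        # effective contact radius for an FG probe, sampled over 1000
        # random directions, must match D/2 + r_b within 5%
        spec = make_inert_cargo(D)
        body = realize_cargo(spec)
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(1000, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        contact_pair = spec.sigma_c  # sub-bead repulsion distance for FG bead
        centers = body.local
        # contact distance along direction d: furthest rho with
        # |rho*d - c_k| = contact_pair for some sub-bead k
        proj = dirs @ centers.T  # (1000, m)
        perp2 = np.sum(centers**2, axis=0)[None, :] if False else None
        c2 = np.sum(centers**2, axis=1)[None, :]
        disc = contact_pair**2 - (c2 - proj**2)
        rho = np.where(disc > 0, proj + np.sqrt(np.maximum(disc, 0)), -np.inf)
        eff = rho.max(axis=1)
        ideal = D / 2 + 0.3
        assert np.all(np.abs(eff - ideal) / ideal < 0.05)


class TestKapComplex:
    def test_spot_count_and_arc(self):
        spec = make_kap_complex(10.0, 7, 1.3)
        body = realize_cargo(spec)
        assert body.codes.count("SPT") == 7
        assert 7 * 1.3 < np.pi * 10.0

    def test_adjacent_chord_distance(self):
        body = realize_cargo(make_kap_complex(10.0, 7, 1.3))
        spots = body.local[-7:]
        chord = np.linalg.norm(spots[1] - spots[0])
        assert chord == pytest.approx(10.0 * np.sin(1.3 / 10.0), rel=1e-9)

    def test_zero_spots_identical_to_inert(self):
        kap = realize_cargo(make_kap_complex(10.0, 0, 1.3))
        inert = realize_cargo(make_inert_cargo(10.0))
        assert np.array_equal(kap.local, inert.local)
        assert np.array_equal(kap.contact, inert.contact)
        assert np.array_equal(kap.hydrophobicity, inert.hydrophobicity)

    def test_overfull_stripe_rejected(self):
        with pytest.raises(TopologyError):
            make_kap_complex(10.0, 30, 1.3)

    def test_spots_on_surface(self):
        body = realize_cargo(make_kap_complex(10.0, 5, 1.3))
        spots = body.local[-5:]
        assert np.allclose(np.linalg.norm(spots, axis=1), 5.0)


class TestGrafting:
    def _mini(self, n_res=50, copies=8, seed=3):
        geom = ScaffoldGeometry(pore_diameter=20.0, pore_half_height=5.0)
        anchors = [NupAnchor("NupA", 0.0, 10.0, copies, "s1")]
        seqs = {"s1": "FSFG" + "STNQG" * ((n_res - 4) // 5)}
        seqs["s1"] += "S" * (n_res - len(seqs["s1"]))
        return geom, anchors, seqs, seed

    def test_counting_mobile_and_anchor_beads(self):
        geom, anchors, seqs, seed = self._mini(n_res=50)
        topo = graft_nups(geom, anchors, seqs, seed)
        chain_beads = topo.n_beads - len(topo.scaffold_index)
        assert topo.flexible.sum() == 8 * 50  # 400 mobile beads
        assert chain_beads == 8 * 51  # plus one fixed anchor bead per chain

    def test_determinism(self):
        geom, anchors, seqs, seed = self._mini()
        t1 = graft_nups(geom, anchors, seqs, seed)
        t2 = graft_nups(geom, anchors, seqs, seed)
        assert np.array_equal(t1.positions, t2.positions)

    def test_zero_anchors_gives_scaffold_only(self):
        geom = ScaffoldGeometry(pore_diameter=20.0, pore_half_height=5.0)
        topo = graft_nups(geom, [], {}, seed=0)
        assert topo.n_beads == len(topo.scaffold_index)

    def test_unknown_sequence_rejected(self):
        geom, anchors, _, seed = self._mini()
        with pytest.raises(TopologyError):
            graft_nups(geom, anchors, {"other": "FSFG"}, seed)

    def test_overlapping_anchors_rejected(self):
        # a ring of radius zero puts all its copies at the same point
        geom = ScaffoldGeometry(pore_diameter=20.0, pore_half_height=5.0)
        anchors = [NupAnchor("A", 0.0, 0.0, 8, "s1")]
        with pytest.raises(TopologyError):
            graft_nups(geom, anchors, {"s1": "FSFGS"}, 0)

    def test_anchored_bead_at_anchor_site(self):
        geom, anchors, seqs, seed = self._mini()
        topo = graft_nups(geom, anchors, seqs, seed)
        _, start, _ = topo.chains[0]
        r = np.hypot(*topo.positions[start, :2])
        assert r == pytest.approx(10.0, abs=1e-9)
        assert topo.group[start] == 1


class TestMinimalVariant:
    def _anchors(self, names):
        return [NupAnchor(n, 0.0, 10.0, 8, "s") for n in names]

    def test_removes_exactly_the_seven(self):
        names = list(MINIMAL_VARIANT_REMOVED) + ["Nup49", "Nup57"]
        out = make_minimal_variant(self._anchors(names))
        assert sorted(a.nup_name for a in out) == ["Nup49", "Nup57"]

    def test_empty_list(self):
        with pytest.warns(UserWarning):
            assert make_minimal_variant([]) == []

    def test_untouched_when_absent(self):
        anchors = self._anchors(["Nup49", "Nup57"])
        with pytest.warns(UserWarning):
            assert make_minimal_variant(anchors) == anchors

    def test_count_invariant(self):
        names = list(MINIMAL_VARIANT_REMOVED) + ["Nup49"]
        anchors = self._anchors(names)
        kept = make_minimal_variant(anchors)
        assert len(kept) + len(MINIMAL_VARIANT_REMOVED) == len(anchors)


class TestSyntheticFixture:
    def test_scaled_geometry(self, fixture_bundle):
        geom, anchors, seqs = fixture_bundle
        assert geom.pore_diameter == pytest.approx(20.0)
        assert geom.pore_half_height == pytest.approx(15.4 / 3)

    def test_chain_lengths_in_declared_range(self, fixture_bundle):
        _, _, seqs = fixture_bundle
        for s in seqs.values():
            assert 50 <= len(s) <= 100

    def test_determinism(self):
        a = generate_synthetic_fixture(0.5, seed=9)
        b = generate_synthetic_fixture(0.5, seed=9)
        assert a[2] == b[2]

    def test_fg_motif_fraction(self, fixture_bundle):
        _, _, seqs = fixture_bundle
        for s in seqs.values():
            frac = 2.0 * s.count("FG") / len(s)
            assert 0.08 <= frac <= 0.20

    def test_net_charge_zero(self, fixture_bundle):
        _, _, seqs = fixture_bundle
        for s in seqs.values():
            q = s.count("K") + s.count("R") - s.count("E") - s.count("D")
            assert q == 0

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            generate_synthetic_fixture(0.0, seed=0)


class TestBuildSystem:
    def test_cargo_placed_at_center(self, fixture_bundle, light_ff):
        geom, anchors, seqs = fixture_bundle
        topo = build_system(
            geom, anchors, seqs, seed=1,
            cargo_spec=make_inert_cargo(8.0),
            cargo_center=np.array([0.0, 0.0, 4.0]),
            params=light_ff,
        )
        assert topo.cargo is not None
        assert np.allclose(topo.cargo.center, [0, 0, 4.0])
        # chains avoid the cargo surface at build time
        d = np.linalg.norm(
            topo.positions[topo.flexible] - topo.cargo.center, axis=1
        )
        assert d.min() > 3.0
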