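"""Dihedrals, glycosidic torsions, Cremer-Pople puckering, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from g3k import geometry as g
from g3k import synthetic as syn


class TestDihedral:
    @pytest.mark.parametrize(
        "p4,expected",
        [((1, 1, 0), 0.0), ((1, -1, 0), 180.0), ((1, 0, 1), 90.0), ((1, 0, -1), -90.0)],
    )
    def test_planar_and_quadrant_cases(self, p4, expected):
        assert g.dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), p4) == pytest.approx(expected)

    def test_collinear_raises(self):
        with pytest.raises(g.GeometryError):
            g.dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_rigid_motion_invariance(self, seed):
        """The dihedral is unchanged by any global rotation + translation."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3))
        try:
            ref = g.dihedral_angle(*pts)
        except g.GeometryError:
            return
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.normal(size=3) * 10
        moved = pts @ R.T + t
        assert g.dihedral_angle(*moved) == pytest.approx(ref, abs=1e-8)


class TestGlycosidicTorsions:
    @pytest.mark.parametrize(
        "seq,torsions",
        [
            ("Galb1-4GlcNAc", {2: (-70.0, 120.0)}),
            ("Fuca1-2Gal", {2: (55.0, -130.0)}),
            ("Mana1-6Man", {2: (-70.0, 120.0, 60.0)}),
            ("Neu5Aca2-3Gal", {2: (-60.0, 130.0)}),
            ("Neu5Aca2-6Gal", {2: (-60.0, 130.0, 170.0)}),
            ("Xylb1-2Man", {2: (80.0, -80.0)}),
        ],
    )
    def test_builder_round_trip(self, seq, torsions):
        """Extracted (phi, psi, omega) match the prescribed build values."""
        model, comp, truth = syn.build_glycan(
            syn.GlycanBuildSpec(sequence=seq, torsions=torsions)
        )
        df = g.glycosidic_torsions(model, comp)
        row = df.iloc[0]
        want = torsions[2]
        assert row["phi"] == pytest.approx(want[0], abs=0.01)
        assert row["psi"] == pytest.approx(want[1], abs=0.01)
        if len(want) > 2:
            assert row["omega"] == pytest.approx(want[2], abs=0.01)
        else:
            assert np.isnan(row["omega"])

    def test_sialic_phi_uses_ring_oxygen_o6(self, ):
        """For sialic donors phi is O6-C2-Ox-Cx (ring oxygen under sialic numbering)."""
        model, comp, _ = syn.build_glycan(
            syn.GlycanBuildSpec(sequence="Neu5Aca2-3Gal", torsions={2: (-60.0, 130.0)})
        )
        neu = model.residue("A", 2)
        gal = model.residue("A", 1)
        direct = g.dihedral_angle(
            neu.atom("O6").position, neu.atom("C2").position,
            gal.atom("O3").position, gal.atom("C3").position,
        )
        df = g.glycosidic_torsions(model, comp)
        assert df.iloc[0]["phi"] == pytest.approx(direct, abs=0.01)

    def test_omega_present_iff_x6(self):
        model, comp, _ = syn.build_glycan("Mana1-3(Mana1-6)Man")
        df = g.glycosidic_torsions(model, comp)
        assert set(df.loc[df["omega"].notna(), "x"]) == {6}

    def test_missing_atom_skips_linkage_keeps_others(self, branched7):
        model, comp, _ = branched7
        model = model.copy()
        res = model.residue("A", 3)  # accepts a Gal at O4; break that linkage
        res.atoms = [a for a in res.atoms if a.name != "O4"]
        with pytest.warns(UserWarning, match="missing atom O4"):
            df = g.glycosidic_torsions(model, comp)
        assert len(df) == len(comp.linkages) - 1

    def test_glycopeptide_linker_torsions(self):
        model, comp, truth = syn.make_glycopeptide(
            "GlcNAcb1-4GlcNAc", site="ASN", linker_phi=-97.0, linker_psi=178.0
        )
        df = g.glycosidic_torsions(model, comp)
        aa = df[df["context"] == "sugar-aminoacid"].iloc[0]
        assert aa["phi"] == pytest.approx(-97.0, abs=0.01)
        assert aa["psi"] == pytest.approx(178.0, abs=0.01)


class TestRingPuckering:
    def test_planar_hexagon_gives_zero(self):
        ang = 2 * np.pi * np.arange(6) / 6
        coords = np.column_stack([1.5 * np.cos(ang), 1.5 * np.sin(ang), np.zeros(6)])
        p = g.ring_puckering(coords)
        assert p.Q < 1e-9 and p.planar

    def test_alternating_ring_is_pure_chair(self):
        """z_j = (-1)^j 0.25 A: q2 = 0, q3 = sqrt(6)*0.25, theta = 0 (hand-derived)."""
        ang = 2 * np.pi * np.arange(6) / 6
        z = 0.25 * (-1.0) ** np.arange(6)
        p = g.ring_puckering(np.column_stack([1.5 * np.cos(ang), 1.5 * np.sin(ang), z]))
        assert p.q2 == pytest.approx(0.0, abs=1e-12)
        assert p.Q == pytest.approx(math.sqrt(6) * 0.25, abs=1e-9)
        assert p.theta == pytest.approx(0.0, abs=1e-9)

    def test_pure_q2_ring_has_theta_90(self):
        ring = syn.build_ring("Glc", Q=0.45, theta=90.0, phi2=15.0)
        coords = np.array([ring[n] for n in ["C1", "C2", "C3", "C4", "C5", "O5"]])
        p = g.ring_puckering(coords)
        assert abs(p.q.get(3, 0.0)) < 1e-9
        assert p.theta == pytest.approx(90.0, abs=1e-6)

    def test_q_squared_equals_sum_of_amplitudes(self):
        ring = syn.build_ring("Glc", Q=0.6, theta=64.0, phi2=200.0)
        coords = np.array([ring[n] for n in ["C1", "C2", "C3", "C4", "C5", "O5"]])
        p = g.ring_puckering(coords)
        assert p.Q**2 == pytest.approx(sum(v**2 for v in p.q.values()), abs=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        Q, theta, phi2 = rng.uniform(0.2, 0.9), rng.uniform(1, 179), rng.uniform(0, 360)
        ring = syn.build_ring("Glc", Q=Q, theta=theta, phi2=phi2)
        coords = np.array([ring[n] for n in ["C1", "C2", "C3", "C4", "C5", "O5"]])
        R = Rotation.random(random_state=seed).as_matrix()
        p0 = g.ring_puckering(coords)
        p1 = g.ring_puckering(coords @ R.T + rng.normal(size=3) * 5)
        assert p1.Q == pytest.approx(p0.Q, abs=1e-9)
        assert p1.theta == pytest.approx(p0.theta, abs=1e-6)


def _oracle_label_6ring(theta, phi2, chirality="D", sialic=False):
    """Independent rule-table oracle for 6-ring conformation labels."""
    if theta < 45:
        return ("2C5" if sialic else ("4C1" if chirality == "D" else "1C4"))
    if theta > 135:
        return ("5C2" if sialic else ("1C4" if chirality == "D" else "4C1"))
    boats = {0: "1,4B", 60: "B2,5", 120: "3,6B", 180: "B1,4", 240: "2,5B", 300: "B3,6"}
    skews = {30: "1S5", 90: "6S2", 150: "3S1", 210: "5S1", 270: "2S6", 330: "1S3"}
    nearest_boat = min(boats, key=lambda a: abs((phi2 - a + 180) % 360 - 180))
    if abs((phi2 - nearest_boat + 180) % 360 - 180) <= 15:
        return "boat" if sialic else boats[nearest_boat]
    nearest_skew = min(skews, key=lambda a: abs((phi2 - a + 180) % 360 - 180))
    return "skew" if sialic else skews[nearest_skew]


def _oracle_label_5ring(phi2):
    envs = {0: "C1-endo", 72: "C3-endo", 144: "O4-endo", 216: "C2-endo", 288: "C4-endo"}
    tws = {36: "3T2", 108: "OT4", 180: "2T1", 252: "4T3", 324: "1TO"}
    nearest_env = min(envs, key=lambda a: abs((phi2 - a + 180) % 360 - 180))
    if abs((phi2 - nearest_env + 180) % 360 - 180) <= 18:
        return envs[nearest_env]
    return tws[min(tws, key=lambda a: abs((phi2 - a + 180) % 360 - 180))]


class TestClassification:
    def test_chair_thresholds(self):
        p = g.PuckeringParameters(n=6, q={2: 0.01, 3: 0.57}, phi={2: 0.0}, Q=0.57, theta=5.0)
        assert g.classify_conformation(p, "pyranose", "D") == "4C1"
        assert g.classify_conformation(p, "pyranose", "L") == "1C4"
        p.theta = 170.0
        assert g.classify_conformation(p, "pyranose", "L") == "4C1"
        assert g.classify_conformation(p, "sialic", "D") == "5C2"

    def test_boat_near_60_multiple(self):
        p = g.PuckeringParameters(n=6, q={2: 0.5, 3: 0.0}, phi={2: 62.0}, Q=0.5, theta=90.0)
        assert g.classify_conformation(p) == "B2,5"

    def test_planar_ring_labeled_planar(self):
        p = g.PuckeringParameters(n=6, planar=True, Q=0.0)
        assert g.classify_conformation(p) == "planar"

    def test_total_function_grid_sweep_matches_oracle(self):
        """A 1-degree grid over (theta, phi2) is fully covered and agrees
        with the independent rule-table oracle (chairs, boats at multiples
        of 60 deg, skews 30 deg off; envelopes/twists for 5-rings)."""
        thetas = np.arange(0.5, 180.0, 3.0)
        phis = np.arange(0.0, 360.0, 1.0)
        for sialic in (False, True):
            kind = "sialic" if sialic else "pyranose"
            for theta in thetas:
                q2 = 0.5 * math.sin(math.radians(theta))
                q3 = 0.5 * math.cos(math.radians(theta))
                for phi2 in phis[:: 7 if theta < 45 or theta > 135 else 1]:
                    p = g.PuckeringParameters(
                        n=6, q={2: q2, 3: q3}, phi={2: phi2}, Q=0.5, theta=theta
                    )
                    label = g.classify_conformation(p, kind, "D")
                    assert label is not None
                    assert label == _oracle_label_6ring(theta, phi2, "D", sialic)
        for phi2 in phis:
            p = g.PuckeringParameters(n=5, q={2: 0.35}, phi={2: phi2}, Q=0.35)
            assert g.classify_conformation(p, "furanose") == _oracle_label_5ring(phi2)


class TestHydroxylOrientation:
    def test_ideal_beta_glc_all_equatorial(self):
        res = syn.build_residue("Glc", anomer="b")
        orient = g.hydroxyl_orientation(res)
        for name in ("O1", "O2", "O3", "O4"):
            assert orient[name] == "equatorial"

    def test_oxygen_moved_to_axial_slot_detected(self):
        res = syn.build_residue("Glc", anomer="b")
        assert g.hydroxyl_orientation(res)["O2"] == "equatorial"
        # move O2 into the other tetrahedral slot at C2 (the axial one)
        names = res.ring_atoms
        i = names.index("C2")
        ring = res.coords(names)
        ax, _eq = syn._axial_equatorial(
            ring[i], ring[i - 1], ring[(i + 1) % len(names)], syn._ring_normal(ring)
        )
        res.atom("O2").position = ring[i] + 1.43 * ax
        assert g.hydroxyl_orientation(res)["O2"] == "axial"

    def test_boat_state_undetermined(self):
        res = syn.build_residue("Glc", anomer="b", puckering=(0.5, 90.0, 0.0))
        with pytest.warns(UserWarning, match="not in a chair"):
            orient = g.hydroxyl_orientation(res)
        assert set(orient.values()) == {"undetermined"}


class TestTorsionCorrelation:
    def test_self_correlation_is_one(self, rng):
        import pandas as pd

        a = rng.uniform(-180, 180, 50)
        wide = pd.DataFrame({"phi": a, "psi": a})
        out = g.torsion_torsion_correlation(wide)
        assert out["circular_r"].loc["phi", "psi"] == pytest.approx(1.0)

    def test_planted_dependence_high_mi(self, rng):
        """psi a deterministic function of phi: MI near its binning maximum."""
        import pandas as pd

        phi = rng.uniform(-180, 180, 50)
        psi = (2 * phi + 90) % 360 - 180
        wide = pd.DataFrame({"phi": phi, "psi": psi})
        out = g.torsion_torsion_correlation(wide, bins=8)
        mi = out["mutual_information"].loc["phi", "psi"]
        assert mi > 0.6 * math.log(8)

    def test_independent_angles_within_permutation_null(self, rng):
        a = rng.uniform(-180, 180, 500)
        b = rng.uniform(-180, 180, 500)
        observed = g.binned_mutual_information(a, b)
        null = np.array(
            [g.binned_mutual_information(a, rng.permutation(b)) for _ in range(200)]
        )
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= observed <= hi * 1.05

    def test_too_few_conformers_raise(self):
        import pandas as pd

        with pytest.raises(g.GeometryError):
            g.torsion_torsion_correlation(pd.DataFrame({"phi": [1.0, 2.0]}))
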