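"""PDB round trips, glycan detection, conformer selection, binding pockets."""

import numpy as np
import pytest

from g3k import pdb_io, synthetic as syn
from g3k.model import ConformerEnsemble


class TestParseWrite:
    def test_round_trip_coordinates_and_bfactors(self, branched7):
        model, comp, _ = branched7
        text = pdb_io.write_pdb(model)
        models, meta = pdb_io.parse_structure(text)
        assert len(models) == 1
        assert meta["source_kind"] == "md"
        assert np.abs(models[0].coords() - model.coords()).max() <= 5e-4
        assert [a.b_factor for a in models[0].atoms] == pytest.approx(
            [a.b_factor for a in model.atoms], abs=0.005
        )

    def test_multi_model_framing_preserved(self, small_ensemble):
        ens, _ = small_ensemble
        text = pdb_io.write_pdb(ens.conformers)
        assert text.count("MODEL") >= ens.n_conformers
        models, _ = pdb_io.parse_structure(text)
        assert len(models) == ens.n_conformers

    def test_empty_input_raises(self):
        with pytest.raises(pdb_io.ParseError):
            pdb_io.parse_structure("   \n")

    def test_malformed_coordinate_reports_line(self):
        bad = "HETATM    1  C1  NAG A   1      xx.xxx   6.134  -6.504  1.00 10.50           C\nEND\n"
        with pytest.raises(pdb_io.ParseError, match="line 1"):
            pdb_io.parse_structure(bad)

    def test_coordinate_overflow_raises(self, lacnac):
        model, _, _ = lacnac
        model = model.copy()
        model.residues[0].atoms[0].position = np.array([12345.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="overflow"):
            pdb_io.write_pdb(model)

    def test_single_atom_model(self):
        from g3k.model import AtomRecord, Model, Residue

        res = Residue(code="NAG", seq=1, chain="A")
        res.atoms.append(AtomRecord(1, "C1", "C", "NAG", 1, "A", np.zeros(3)))
        text = pdb_io.write_pdb(Model(residues=[res]))
        assert "HETATM" in text and text.strip().endswith("END")


class TestDetectGlycans:
    def test_lacnac_topology(self, lacnac):
        model, _, _ = lacnac
        models, _ = pdb_io.parse_structure(pdb_io.write_pdb(model))
        (comp,) = pdb_io.detect_glycans(models[0])
        assert len(comp.residues) == 2
        (lk,) = comp.linkages
        assert lk.x == 4
        root = comp.residue(comp.root)
        assert root.monosaccharide == "GlcNAc"
        assert pdb_io.to_iupac(comp) == "Galb1-4GlcNAc"

    def test_protein_only_gives_empty(self):
        model, _, _ = syn.make_complex("Galb1-4GlcNAc")
        model.residues = [r for r in model.residues if r.is_amino_acid]
        assert pdb_io.detect_glycans(model) == []

    def test_branched_tree_is_forest(self, branched7):
        """7 residues, 6 edges; detection always yields a rooted tree."""
        model, _, _ = branched7
        models, _ = pdb_io.parse_structure(pdb_io.write_pdb(model))
        (comp,) = pdb_io.detect_glycans(models[0])
        assert len(comp.residues) == 7
        assert len(comp.linkages) == len(comp.residues) - 1
        donors = [lk.donor for lk in comp.linkages]
        assert len(set(donors)) == len(donors)  # one outgoing bond per donor

    def test_two_separate_glycans_two_components(self):
        m1, _, _ = syn.build_glycan("Galb1-4GlcNAc")
        m2, _, _ = syn.build_glycan("Mana1-2Man")
        for res in m2.residues:
            res.seq += 10
            for a in res.atoms:
                a.position = a.position + np.array([50.0, 0, 0])
                a.residue_seq = res.seq
        m1.residues.extend(m2.residues)
        comps = pdb_io.detect_glycans(m1)
        assert len(comps) == 2
        assert sorted(len(c.residues) for c in comps) == [2, 2]

    def test_round_trip_iupac_matches_build(self, branched7):
        model, comp, truth = branched7
        models, _ = pdb_io.parse_structure(pdb_io.write_pdb(model))
        (detected,) = pdb_io.detect_glycans(models[0])
        assert pdb_io.to_iupac(detected) == truth["sequence"]


class TestSourceKind:
    def test_complex_inferred(self):
        model, _, _ = syn.make_complex("Galb1-4GlcNAc", pocket=[("TRP", 4.0)])
        _, meta = pdb_io.parse_structure(pdb_io.write_pdb(model))
        assert meta["source_kind"] == "complex"

    def test_glycoprotein_inferred(self):
        model, _, _ = syn.make_glycopeptide("GlcNAcb1-4GlcNAc", site="ASN")
        _, meta = pdb_io.parse_structure(pdb_io.write_pdb(model))
        assert meta["source_kind"] == "glycoprotein"


class TestConformerSelection:
    def _ens(self, seq, anomer):
        spec = syn.GlycanBuildSpec(sequence=seq, root_anomer=anomer)
        ens, _ = syn.make_ensemble(spec, syn.EnsembleSpec(n_conformers=3, kappa=None, seed=0))
        return ens

    def test_o_glycan_takes_alpha_group(self):
        groups = {"a": self._ens("Galb1-3GalNAc", "a"), "b": self._ens("Galb1-3GalNAc", "b")}
        chosen = pdb_io.select_physiological_conformers(groups, "O")
        assert chosen is not None
        assert chosen.weights.sum() == pytest.approx(1.0)
        assert chosen.glycan.residue(chosen.glycan.root).anomer == "a"

    def test_n_glycan_takes_beta_group(self):
        groups = {"a": self._ens("Mana1-6Man", "a"), "b": self._ens("Mana1-6Man", "b")}
        chosen = pdb_io.select_physiological_conformers(groups, "N")
        assert chosen.glycan.residue(chosen.glycan.root).anomer == "b"

    def test_fallback_with_warning(self):
        groups = {"b": self._ens("Galb1-3GalNAc", "b")}
        with pytest.warns(UserWarning, match="using b group"):
            chosen = pdb_io.select_physiological_conformers(groups, "O")
        assert chosen.n_conformers == 3

    def test_class_inference(self):
        _, comp_o, _ = syn.build_glycan("Galb1-3GalNAc")
        assert pdb_io.infer_glycan_class(comp_o) == "O"
        _, comp_n, _ = syn.build_glycan("Mana1-3(Mana1-6)Manb1-4GlcNAcb1-4GlcNAc")
        assert pdb_io.infer_glycan_class(comp_n) == "N"
        _, comp_l, _ = syn.build_glycan("Galb1-4Glc")
        assert pdb_io.infer_glycan_class(comp_l) == "lipid"


class TestBindingPocket:
    def test_planted_trp_found_at_prescribed_distance(self):
        model, comp, truth = syn.make_complex("Galb1-4GlcNAc", pocket=[("TRP", 3.5)])
        df = pdb_io.get_binding_pocket(model, comp, cutoff=5.0)
        assert set(df["code"]) == {"TRP"}
        assert df["distance"].min() == pytest.approx(3.5, abs=0.01)

    def test_cutoff_zero_empty(self):
        model, comp, _ = syn.make_complex("Galb1-4GlcNAc", pocket=[("TRP", 3.5)])
        assert pdb_io.get_binding_pocket(model, comp, cutoff=0.0).empty

    def test_only_residues_within_cutoff(self):
        """Brute-force check: residues at 4 and 8 A with cutoff 5 -> only the first."""
        model, comp, _ = syn.make_complex(
            "Galb1-4GlcNAc", pocket=[("TRP", 4.0), ("TYR", 8.0)]
        )
        df = pdb_io.get_binding_pocket(model, comp, cutoff=5.0)
        assert set(df["code"]) == {"TRP"}
        glycan_xyz = np.vstack([r.coords() for r in comp.residues])
        for res in model.residues:
            if not res.is_amino_acid:
                continue
            brute = min(
                float(np.linalg.norm(a.position - g)) for a in res.atoms for g in glycan_xyz
            )
            assert (brute <= 5.0) == (res.code in set(df["code"]))

    def test_no_protein_warns_empty(self, lacnac):
        model, comp, _ = lacnac
        with pytest.warns(UserWarning, match="no protein"):
            df = pdb_io.get_binding_pocket(model, comp, cutoff=5.0)
        assert df.empty


class TestEnsembleIO:
    def test_weights_sidecar_round_trip(self, tmp_path, small_ensemble):
        ens, truth = small_ensemble
        pdb = tmp_path / "e.pdb"
        wts = tmp_path / "w.tsv"
        pdb_io.write_pdb(ens.conformers, pdb)
        pdb_io.write_weights(ens.labels, ens.weights, wts)
        loaded = pdb_io.load_ensemble(pdb, wts)
        assert loaded.n_conformers == ens.n_conformers
        assert loaded.weights == pytest.approx(ens.weights, abs=1e-6)
        assert pdb_io.to_iupac(loaded.glycan) == truth["sequence"]

    def test_missing_sidecar_uniform_weights(self, tmp_path, small_ensemble):
        ens, _ = small_ensemble
        pdb = tmp_path / "e.pdb"
        pdb_io.write_pdb(ens.conformers, pdb)
        loaded = pdb_io.load_ensemble(pdb)
        assert loaded.weights == pytest.approx(np.full(ens.n_conformers, 1 / ens.n_conformers))

    def test_weights_renormalized(self):
        model, comp, _ = syn.build_glycan("Galb1-4GlcNAc")
        ens = ConformerEnsemble(glycan=comp, conformers=[model, model.copy()],
                                weights=np.array([2.0, 6.0]))
        assert ens.weights == pytest.approx([0.25, 0.75])
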