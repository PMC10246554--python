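"""Structure parsing, pLDDT gating, and site-to-coordinate joins."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketmap.seqmodel import ProteinRecord
from pocketmap.silacquant import QuantifiedSite
from pocketmap.structmap import (
    Residue,
    StructureError,
    StructureModel,
    classify_confidence,
    load_structure,
    map_sites,
    representative_atom,
    write_structure,
)


def pdb_atom(serial, name, resname, chain, resnum, x, y, z, b, element):
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00{b:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written K-Y-G model with pLDDT 91 / 75 / 40 in the B column."""
    lines = [
        pdb_atom(1, "N", "LYS", "A", 1, 0.0, 0.0, 0.0, 91.0, "N"),
        pdb_atom(2, "CA", "LYS", "A", 1, 1.5, 0.0, 0.0, 91.0, "C"),
        pdb_atom(3, "CB", "LYS", "A", 1, 2.0, 1.0, 0.0, 91.0, "C"),
        pdb_atom(4, "NZ", "LYS", "A", 1, 3.5, 2.0, 1.0, 91.0, "N"),
        pdb_atom(5, "CA", "TYR", "A", 2, 4.5, 0.0, 0.0, 75.0, "C"),
        pdb_atom(6, "OH", "TYR", "A", 2, 6.0, 2.5, 0.5, 75.0, "O"),
        pdb_atom(7, "CA", "GLY", "A", 3, 8.0, 0.0, 0.0, 40.0, "C"),
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadStructure:
    def test_plddt_read_from_temperature_factors(self, three_residue_pdb):
        model = load_structure(three_residue_pdb)
        assert model.sequence == "KYG"
        assert model.plddts == [91.0, 75.0, 40.0]
        assert np.allclose(model.residue(1).atoms["NZ"], [3.5, 2.0, 1.0])

    def test_mmcif_gives_identical_model(self, three_residue_pdb, tmp_path):
        model = load_structure(three_residue_pdb, format="PDB")
        cif_path = tmp_path / "toy.cif"
        write_structure(model, cif_path, format="mmCIF")
        again = load_structure(cif_path, format="mmCIF")
        assert again.sequence == model.sequence
        assert again.plddts == model.plddts
        for r1, r2 in zip(model.residues, again.residues):
            assert r1.residue_number == r2.residue_number
            assert set(r1.atoms) == set(r2.atoms)
            for name in r1.atoms:
                assert np.allclose(r1.atoms[name], r2.atoms[name], atol=1e-3)

    def test_out_of_range_b_factor_is_not_alphafold_style(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0, 250.0, "C") + "\nEND\n"
        )
        with pytest.raises(StructureError, match="not an AlphaFold-style"):
            load_structure(path)

    def test_multiple_chains_rejected_naming_them(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(
            "\n".join([
                pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0, 90.0, "C"),
                pdb_atom(2, "CA", "ALA", "B", 1, 5, 0, 0, 90.0, "C"),
                "END",
            ]) + "\n"
        )
        with pytest.raises(StructureError, match="A.*B"):
            load_structure(path)

    def test_unreadable_file_rejected(self, tmp_path):
        path = tmp_path / "junk.pdb"
        path.write_text("not a structure\n")
        with pytest.raises(StructureError):
            load_structure(path)

    def test_write_load_round_trip_exact(self, three_residue_pdb, tmp_path):
        model = load_structure(three_residue_pdb)
        out = tmp_path / "rt.pdb"
        write_structure(model, out)
        again = load_structure(out)
        assert [r.residue_number for r in again.residues] == [1, 2, 3]
        assert again.sequence == model.sequence
        assert again.plddts == model.plddts


class TestStructureModelInvariants:
    def test_residue_numbers_must_increase(self):
        res = [
            Residue(2, "A", 90.0, {"CA": np.zeros(3)}),
            Residue(1, "A", 90.0, {"CA": np.ones(3)}),
        ]
        with pytest.raises(StructureError, match="increasing"):
            StructureModel("m", res)

    def test_ca_required(self):
        with pytest.raises(StructureError, match="CA"):
            StructureModel("m", [Residue(1, "K", 90.0, {"NZ": np.zeros(3)})])


class TestClassifyConfidence:
    @pytest.mark.parametrize(
        "plddt, band",
        [
            (95.0, "very_high"),
            (90.0, "confident"),
            (75.0, "confident"),
            (70.0, "low"),  # boundary excluded from the confident band
            (50.0, "low"),
            (49.9, "very_low"),
            (0.0, "very_low"),
            (100.0, "very_high"),
        ],
    )
    def test_band_assignment(self, plddt, band):
        assert classify_confidence(plddt) == band

    @given(st.floats(0, 100, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_bands_partition_the_range(self, plddt):
        assert classify_confidence(plddt) in {
            "very_high", "confident", "low", "very_low"
        }

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 100.1):
            with pytest.raises(ValueError):
                classify_confidence(bad)


class TestRepresentativeAtom:
    def test_lys_nz_and_tyr_oh_preferred(self):
        lys = Residue(1, "K", 90.0, {"CA": np.zeros(3), "CB": np.ones(3),
                                     "NZ": np.full(3, 2.0)})
        tyr = Residue(2, "Y", 90.0, {"CA": np.zeros(3), "OH": np.ones(3)})
        assert representative_atom(lys)[0] == "NZ"
        assert representative_atom(tyr)[0] == "OH"

    def test_fallback_order_cb_then_ca(self):
        tyr = Residue(1, "Y", 90.0, {"CA": np.zeros(3), "CB": np.ones(3)})
        assert representative_atom(tyr)[0] == "CB"
        bare = Residue(1, "Y", 90.0, {"CA": np.zeros(3)})
        assert representative_atom(bare)[0] == "CA"

    def test_distances_match_independent_euclidean(self, rng):
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        ra = Residue(1, "K", 90.0, {"CA": np.zeros(3), "NZ": a})
        rb = Residue(2, "Y", 90.0, {"CA": np.zeros(3), "OH": b})
        _, xa = representative_atom(ra)
        _, xb = representative_atom(rb)
        direct = float(np.linalg.norm(xa - xb))
        oracle = sum((u - v) ** 2 for u, v in zip(a, b)) ** 0.5
        assert abs(direct - oracle) < 1e-9


def make_site(resnum, restype="K", pid="P1"):
    return QuantifiedSite(
        protein_id=pid, residue_number=resnum, residue_type=restype,
        sr_per_replicate={"rep1": 12.0}, best_score=800.0, max_abs_ppm=1.0,
        n_replicates_detected=1,
    )


class TestMapSites:
    @pytest.fixture
    def model_and_protein(self, three_residue_pdb):
        return load_structure(three_residue_pdb), ProteinRecord("P1", "KYG")

    def test_low_confidence_site_retained_but_excluded(
        self, model_and_protein
    ):
        model, protein = model_and_protein
        model.residues[1].plddt = 60.0  # Tyr residue below the gate
        mapped = map_sites(
            [make_site(1), make_site(2, "Y")], model, protein
        )
        assert mapped[0].included is True
        assert mapped[1].included is False  # kept in output, out of clustering
        assert len(mapped) == 2

    def test_plddt_exactly_70_excluded(self, model_and_protein):
        model, protein = model_and_protein
        model.residues[0].plddt = 70.0
        mapped = map_sites([make_site(1)], model, protein)
        assert mapped[0].included is False
        assert mapped[0].confidence_band == "low"

    def test_sequence_mismatch_is_a_hard_error(self, model_and_protein):
        model, _ = model_and_protein
        wrong = ProteinRecord("P1", "KWG")
        with pytest.raises(StructureError, match="position 2"):
            map_sites([make_site(1)], model, wrong)

    def test_missing_residue_flagged_unresolved(self, model_and_protein):
        model, protein = model_and_protein
        mapped = map_sites([make_site(9)], model, protein)
        assert mapped[0].unresolved is True
        assert mapped[0].included is False

    def test_join_only_contract_preserves_site_fields(
        self, model_and_protein
    ):
        model, protein = model_and_protein
        site = make_site(1)
        before = (site.residue_number, site.residue_type,
                  dict(site.sr_per_replicate))
        mapped = map_sites([site], model, protein)
        after = (mapped[0].site.residue_number, mapped[0].site.residue_type,
                 dict(mapped[0].site.sr_per_replicate))
        assert before == after
        assert mapped[0].representative_atom == "NZ"
        assert np.allclose(mapped[0].coordinates, [3.5, 2.0, 1.0])
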