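"""Predicted-structure parsing, pLDDT confidence gating, and site mapping.

AlphaFold-style models store the per-residue confidence score pLDDT
(0-100) in the atom temperature-factor (B-factor) field.  This module
reads single-chain PDB/mmCIF models into a light-weight container, checks
that the model sequence agrees with the protein record, classifies
residues into the standard confidence bands, and joins quantified covalent
sites to 3-D coordinates.

Only confidently predicted residues (pLDDT strictly greater than 70, the
"Confident" and "Very high" bands) are admitted to downstream spatial
clustering; lower-confidence sites are retained in the output but flagged
``included = False``.  A pLDDT of exactly 70 is excluded — the inclusion
criterion is strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np
import pandas as pd

from .seqmodel import ProteinRecord
from .silacquant import QuantifiedSite

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Preferred representative atom per residue type, with fallbacks.
#: Lys NZ and Tyr OH are the nucleophilic side-chain atoms the probe
#: actually modifies; CB then CA stand in when a side chain is truncated.
REPRESENTATIVE_ATOMS = {"K": ("NZ", "CB", "CA"), "Y": ("OH", "CB", "CA")}
FALLBACK_ATOMS = ("CB", "CA")


class StructureError(ValueError):
    """Unparseable or non-AlphaFold-style structure input."""


@dataclass
class Residue:
    residue_number: int
    amino_acid: str  # 1-letter
    plddt: float
    atoms: dict[str, np.ndarray]  # name -> xyz (Angstrom)


@dataclass
class StructureModel:
    """An ordered single-chain model with per-residue pLDDT."""

    structure_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        nums = [r.residue_number for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise StructureError(
                f"{self.structure_id}: residue numbers not strictly "
                "increasing"
            )
        for r in self.residues:
            if not 0 <= r.plddt <= 100:
                raise StructureError(
                    f"{self.structure_id}: pLDDT {r.plddt} outside [0, 100]"
                )
            if "CA" not in r.atoms:
                raise StructureError(
                    f"{self.structure_id}: residue {r.residue_number} "
                    "lacks a CA atom"
                )
        self._by_number = {r.residue_number: r for r in self.residues}

    def residue(self, number: int) -> Optional[Residue]:
        return self._by_number.get(number)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def plddts(self) -> list[float]:
        return [r.plddt for r in self.residues]


@dataclass
class MappedSite:
    """A QuantifiedSite joined to model coordinates and confidence."""

    site: QuantifiedSite
    coordinates: Optional[np.ndarray]  # representative atom, Angstrom
    representative_atom: Optional[str]
    plddt: Optional[float]
    confidence_band: Optional[str]
    included: bool
    unresolved: bool = False

    @property
    def protein_id(self) -> str:
        return self.site.protein_id

    @property
    def residue_number(self) -> int:
        return self.site.residue_number

    @property
    def residue_type(self) -> str:
        return self.site.residue_type


def load_structure(
    path: Union[str, Path], format: Optional[str] = None
) -> StructureModel:
    """Read a single-chain PDB or mmCIF model, pLDDT from B-factors.

    ``format`` may be "PDB" or "mmCIF"; by default it is detected from the
    file.  Temperature factors must lie in [0, 100] (the pLDDT convention)
    or the file is rejected as not AlphaFold-style.  Within a residue all
    atoms should carry the same value; if not, the CA value is used and a
    warning logged.
    """
    path = Path(path)
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        elif format.upper() == "PDB":
            st = gemmi.read_pdb(str(path))
        elif format.lower() in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(
                gemmi.cif.read(str(path)).sole_block()
            )
        else:
            raise StructureError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    chains = [ch.name for ch in model]
    if len(chains) != 1:
        raise StructureError(
            f"{path}: expected a single chain, found {chains}"
        )
    residues = []
    for res in model[chains[0]]:
        aa = THREE_TO_ONE.get(res.name.upper())
        if aa is None:
            raise StructureError(
                f"{path}: non-standard residue {res.name}"
            )
        atoms: dict[str, np.ndarray] = {}
        bvals: dict[str, float] = {}
        for atom in res:
            atoms[atom.name] = np.array(
                [atom.pos.x, atom.pos.y, atom.pos.z]
            )
            bvals[atom.name] = atom.b_iso
        for b in bvals.values():
            if not 0 <= b <= 100:
                raise StructureError(
                    f"{path}: temperature factor {b} outside [0, 100] — "
                    "not an AlphaFold-style model"
                )
        unique_b = {round(b, 2) for b in bvals.values()}
        if len(unique_b) > 1:
            logger.warning(
                "%s residue %d: differing B-factors %s; using CA value",
                path.name, res.seqid.num, sorted(unique_b),
            )
            plddt = bvals.get("CA", next(iter(bvals.values())))
        else:
            plddt = next(iter(bvals.values()))
        residues.append(
            Residue(
                residue_number=res.seqid.num,
                amino_acid=aa,
                plddt=float(plddt),
                atoms=atoms,
            )
        )
    return StructureModel(structure_id=path.stem, residues=residues)


def write_structure(
    model: StructureModel, path: Union[str, Path], format: str = "PDB"
) -> None:
    """Write a StructureModel, pLDDT to the temperature-factor field."""
    st = gemmi.Structure()
    st.name = model.structure_id
    md = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in model.residues:
        g_res = gemmi.Residue()
        g_res.name = ONE_TO_THREE[res.amino_acid]
        g_res.seqid = gemmi.SeqId(res.residue_number, " ")
        for name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.b_iso = res.plddt
            atom.occ = 1.0
            g_res.add_atom(atom)
        chain.add_residue(g_res)
    md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    path = Path(path)
    if format.upper() == "PDB":
        st.write_pdb(str(path))
    elif format.lower() in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise StructureError(f"unknown format {format!r}")


def classify_confidence(plddt: float) -> str:
    """Standard pLDDT bands: very_high > 90 >= confident > 70 >= low >= 50 > very_low."""
    if not 0 <= plddt <= 100:
        raise ValueError(f"pLDDT {plddt} outside [0, 100]")
    if plddt > 90:
        return "very_high"
    if plddt > 70:
        return "confident"
    if plddt >= 50:
        return "low"
    return "very_low"


def representative_atom(
    residue: Residue,
) -> tuple[str, np.ndarray]:
    """Pick the site's point coordinate: Lys NZ / Tyr OH, else CB, else CA."""
    order = REPRESENTATIVE_ATOMS.get(residue.amino_acid, FALLBACK_ATOMS)
    for name in order:
        if name in residue.atoms:
            if name != order[0]:
                logger.info(
                    "residue %d %s: preferred atom %s absent, using %s",
                    residue.residue_number, residue.amino_acid, order[0],
                    name,
                )
            return name, residue.atoms[name]
    raise StructureError(
        f"residue {residue.residue_number} has none of {order}"
    )


def verify_sequence(
    model: StructureModel,
    protein: ProteinRecord,
    numbering_offset: int = 0,
) -> None:
    """Check model residues against the protein sequence position-by-position.

    Model residue numbers are taken as authoritative 1-based sequence
    positions (the AlphaFold full-length convention); ``numbering_offset``
    shifts them for trimmed models.  Any mismatch is a hard error listing
    every offending position.
    """
    mismatches = []
    for res in model.residues:
        pos = res.residue_number + numbering_offset
        if not 1 <= pos <= len(protein):
            mismatches.append(f"residue {res.residue_number} outside protein")
            continue
        if protein.residue(pos) != res.amino_acid:
            mismatches.append(
                f"position {pos}: model {res.amino_acid} vs protein "
                f"{protein.residue(pos)}"
            )
    if mismatches:
        raise StructureError(
            f"{model.structure_id} disagrees with {protein.protein_id}: "
            + "; ".join(mismatches[:20])
        )


def map_sites(
    sites: Sequence[QuantifiedSite],
    model: StructureModel,
    protein: ProteinRecord,
    plddt_min: float = 70.0,
    numbering_offset: int = 0,
) -> list[MappedSite]:
    """Join sites to coordinates and pLDDT; gate inclusion on confidence.

    Join-only contract: residue numbers, types, and SRs are never altered.
    Sites at residues missing from the model are flagged unresolved and
    excluded; sites with pLDDT <= ``plddt_min`` are kept in the output but
    excluded from clustering.
    """
    verify_sequence(model, protein, numbering_offset)
    mapped = []
    for site in sites:
        res = model.residue(site.residue_number - numbering_offset)
        if res is None:
            logger.warning(
                "site %s:%d not resolved in %s",
                site.protein_id, site.residue_number, model.structure_id,
            )
            mapped.append(
                MappedSite(
                    site=site, coordinates=None, representative_atom=None,
                    plddt=None, confidence_band=None, included=False,
                    unresolved=True,
                )
            )
            continue
        atom_name, xyz = representative_atom(res)
        mapped.append(
            MappedSite(
                site=site,
                coordinates=xyz,
                representative_atom=atom_name,
                plddt=res.plddt,
                confidence_band=classify_confidence(res.plddt),
                included=res.plddt > plddt_min,
            )
        )
    return mapped


def mapped_sites_to_frame(mapped: Sequence[MappedSite]) -> pd.DataFrame:
    """Sites TSV plus x, y, z, plddt, band, included columns."""
    from .silacquant import sites_to_frame

    base = sites_to_frame([m.site for m in mapped])
    base["x"] = [
        m.coordinates[0] if m.coordinates is not None else np.nan
        for m in mapped
    ]
    base["y"] = [
        m.coordinates[1] if m.coordinates is not None else np.nan
        for m in mapped
    ]
    base["z"] = [
        m.coordinates[2] if m.coordinates is not None else np.nan
        for m in mapped
    ]
    base["plddt"] = [m.plddt for m in mapped]
    base["band"] = [m.confidence_band for m in mapped]
    base["included"] = [m.included for m in mapped]
    return base


def write_mapped_tsv(
    mapped: Sequence[MappedSite], path: Union[str, Path]
) -> None:
    mapped_sites_to_frame(mapped).to_csv(path, sep="\t", index=False)
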