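"""Tryptic digestion, covalent-site localization, and peptide mass checks.

A covalent probe labels a specific Tyr or Lys side chain; the search engine
reports the modified residue as an offset within a tryptic peptide.  This
module turns that peptide-local evidence into absolute 1-based protein
residue numbers, and computes theoretical monoisotopic masses so that each
evidence row's precursor mass error (ppm) can be evaluated against a
quality filter.

Digestion follows the trypsin rule — cleave C-terminal to K or R except
when the next residue is P.  Monoisotopic residue masses come from
pyteomics; SILAC heavy labels add fixed increments on K (+8.014199 Da,
13C6 15N2) and R (+10.008269 Da, 13C6 15N4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from pyteomics import mass as _pymass
from pyteomics import parser as _pyparser

from .seqmodel import ProteinRecord

logger = logging.getLogger(__name__)

TRYPSIN_RULE = r"[KR](?!P)"

#: Monoisotopic residue masses (Da), overridable via theoretical_mass(aa_masses=...)
AA_MONO = dict(_pymass.std_aa_mass)
WATER_MONO = _pymass.calculate_mass(formula="H2O")

#: SILAC heavy-label increments (Da): 13C6,15N2-Lys and 13C6,15N4-Arg
HEAVY_INCREMENTS = {"K": 8.014199, "R": 10.008269}


class LocalizationError(ValueError):
    """Peptide absent from, or ambiguous within, the protein sequence."""


@dataclass
class PeptideEvidence:
    """One probe-modified-peptide observation from the search-engine output.

    ``mod_offset`` is the 0-based index of the modified residue within
    ``peptide_sequence``; ``mod_residue`` must match that position.
    Intensities are a single (light, heavy) pair — one evidence row per
    replicate, keyed by ``replicate_id``.
    """

    peptide_sequence: str
    protein_id: str
    mod_offset: int
    mod_residue: str
    mod_mass: float
    light_intensity: float
    heavy_intensity: float
    score: float
    observed_mass: float
    charge: int
    replicate_id: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.mod_offset < len(self.peptide_sequence):
            raise ValueError(
                f"mod_offset {self.mod_offset} outside peptide "
                f"{self.peptide_sequence!r}"
            )
        if self.peptide_sequence[self.mod_offset] != self.mod_residue:
            raise ValueError(
                f"peptide {self.peptide_sequence!r} has "
                f"{self.peptide_sequence[self.mod_offset]!r} at offset "
                f"{self.mod_offset}, not {self.mod_residue!r}"
            )
        if self.light_intensity < 0 or self.heavy_intensity < 0:
            raise ValueError("negative intensity")
        if self.observed_mass <= 0:
            raise ValueError("observed_mass must be positive")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


@dataclass(frozen=True)
class LocalizedSite:
    """A probe-modified residue in absolute protein coordinates."""

    protein_id: str
    residue_number: int  # 1-based
    residue_type: str  # Y or K


def digest(
    sequence: str, missed_cleavages: int = 0
) -> list[tuple[int, str]]:
    """In-silico tryptic digest returning ``(start, peptide)`` pairs.

    ``start`` is the peptide's 1-based position in ``sequence``.  With
    ``missed_cleavages = m`` every concatenation of up to ``m + 1``
    adjacent fully-cleaved fragments is returned.  Peptides are ordered by
    start position, then length.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not sequence:
        return []
    seen = {
        (start + 1, pep)
        for start, pep in _pyparser.icleave(
            sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages
        )
    }
    return sorted(seen, key=lambda sp: (sp[0], len(sp[1])))


def localize_site(
    evidence: PeptideEvidence, protein: ProteinRecord
) -> LocalizedSite:
    """Resolve an evidence row's modified residue to protein coordinates.

    The peptide must occur exactly once in the protein sequence; multiple
    matches raise an ambiguous-localization error (caller drops and logs
    the row — site-level claims need unique placement).
    """
    seq = protein.sequence
    pep = evidence.peptide_sequence
    first = seq.find(pep)
    if first < 0:
        raise LocalizationError(
            f"peptide {pep!r} not found in {protein.protein_id}"
        )
    if seq.find(pep, first + 1) >= 0:
        raise LocalizationError(
            f"ambiguous localization: peptide {pep!r} occurs more than "
            f"once in {protein.protein_id}"
        )
    residue_number = first + 1 + evidence.mod_offset
    assert protein.residue(residue_number) == evidence.mod_residue
    return LocalizedSite(
        protein_id=protein.protein_id,
        residue_number=residue_number,
        residue_type=evidence.mod_residue,
    )


def theoretical_mass(
    peptide_sequence: str,
    mod_mass: float = 0.0,
    heavy_label: bool = False,
    aa_masses: Optional[dict[str, float]] = None,
    heavy_increments: Optional[dict[str, float]] = None,
) -> float:
    """Monoisotopic peptide mass: residues + water + adduct (+ heavy labels).

    With ``heavy_label`` every K and R carries its SILAC isotope increment.
    An empty peptide with no adduct is the mass of water.
    """
    masses = aa_masses if aa_masses is not None else AA_MONO
    increments = (
        heavy_increments if heavy_increments is not None else HEAVY_INCREMENTS
    )
    total = WATER_MONO + mod_mass
    for aa in peptide_sequence:
        try:
            total += masses[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
        if heavy_label:
            total += increments.get(aa, 0.0)
    return total


def ppm_error(observed_mass: float, theoretical: float) -> float:
    """Signed precursor mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed_mass - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# Evidence TSV IO

EVIDENCE_COLUMNS = [
    "replicate_id",
    "protein_id",
    "peptide_sequence",
    "mod_offset",
    "mod_residue",
    "mod_mass",
    "light_intensity",
    "heavy_intensity",
    "score",
    "observed_mass",
    "charge",
    "is_decoy",
]


def evidence_to_frame(rows: Iterable[PeptideEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(r, c) for c in EVIDENCE_COLUMNS] for r in rows],
        columns=EVIDENCE_COLUMNS,
    )


def frame_to_evidence(df: pd.DataFrame) -> list[PeptideEvidence]:
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            PeptideEvidence(
                replicate_id=str(rec.replicate_id),
                protein_id=str(rec.protein_id),
                peptide_sequence=str(rec.peptide_sequence),
                mod_offset=int(rec.mod_offset),
                mod_residue=str(rec.mod_residue),
                mod_mass=float(rec.mod_mass),
                light_intensity=float(rec.light_intensity),
                heavy_intensity=float(rec.heavy_intensity),
                score=float(rec.score),
                observed_mass=float(rec.observed_mass),
                charge=int(rec.charge),
                is_decoy=bool(rec.is_decoy),
            )
        )
    return rows


def write_evidence_tsv(
    rows: Iterable[PeptideEvidence], path: Union[str, Path]
) -> None:
    evidence_to_frame(rows).to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path: Union[str, Path]) -> list[PeptideEvidence]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence TSV missing columns {sorted(missing)}")
    return frame_to_evidence(df[EVIDENCE_COLUMNS])
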