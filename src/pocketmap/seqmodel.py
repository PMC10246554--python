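"""Protein sequences, domain architecture, and domain-swap chimera construction.

Diacylglycerol kinases (DGKs) and their engineered chimeras are multidomain
proteins: a conserved split catalytic domain (DAGKc + DAGKa) plus
isoform-specific regulatory domains (tandem C1A/C1B, EF hands, PH, SAM,
ankyrin repeats, ...).  Everything downstream of this module — covalent-site
localization, structure mapping, pocket clustering — lives in the 1-based
residue coordinate frame defined here.

Chimeras are built by replacing an explicit backbone interval with an
explicit donor interval (junctions are inputs, never inferred), and carry an
exact bidirectional residue-coordinate map so that covalent sites observed
on a parent protein can be lifted onto the chimera and back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

DOMAIN_VOCABULARY = {
    "C1A", "C1B", "DAGKc", "DAGKa", "EF", "PH", "SAM", "ANK", "RA", "PDZ",
    "OTHER",
}

UNMAPPED = "unmapped"


class SequenceError(ValueError):
    """Invalid sequence or residue alphabet."""


class IntervalError(ValueError):
    """Interval outside a sequence or otherwise ill-formed."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain occupying a 1-based inclusive residue interval."""

    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.domain_name not in DOMAIN_VOCABULARY:
            raise ValueError(
                f"unknown domain name {self.domain_name!r}; "
                f"expected one of {sorted(DOMAIN_VOCABULARY)}"
            )
        if self.start < 1 or self.start > self.end:
            raise IntervalError(
                f"bad domain interval [{self.start}, {self.end}]"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class ProteinRecord:
    """A protein sequence with non-overlapping domain annotations.

    Residue positions are 1-based inclusive throughout.  ``epitope_tag`` is
    a purely descriptive label (e.g. FLAG or HA); tag residues, if present,
    are ordinary sequence.
    """

    protein_id: str
    sequence: str
    name: str = ""
    domains: list[DomainAnnotation] = field(default_factory=list)
    epitope_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise SequenceError(
                f"{self.protein_id}: non-standard residues {sorted(bad)}"
            )
        n = len(self.sequence)
        self.domains = sorted(self.domains, key=lambda d: d.start)
        prev: Optional[DomainAnnotation] = None
        for dom in self.domains:
            if dom.end > n:
                raise IntervalError(
                    f"{self.protein_id}: domain {dom.domain_name} "
                    f"[{dom.start},{dom.end}] exceeds length {n}"
                )
            if prev is not None and dom.start <= prev.end:
                raise IntervalError(
                    f"{self.protein_id}: domains {prev.domain_name} and "
                    f"{dom.domain_name} overlap"
                )
            prev = dom

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """1-based residue lookup."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"position {pos} outside [1, {len(self)}]")
        return self.sequence[pos - 1]

    def domain_at(self, pos: int) -> str:
        """Name of the domain covering ``pos``, or ``"linker"``."""
        for dom in self.domains:
            if dom.contains(pos):
                return dom.domain_name
        return "linker"


@dataclass
class ChimeraRecord:
    """A backbone protein with one interval replaced by a donor interval.

    ``coordinate_map`` is a piecewise bijection keyed by
    ``(source_protein_id, source_position)`` with values in chimera
    coordinates; ``inverse_map`` goes the other way.  Backbone positions
    inside the replaced interval and donor positions outside the inserted
    interval are unmapped.
    """

    chimera_id: str
    backbone_id: str
    donor_id: str
    backbone_replaced: tuple[int, int]
    donor_inserted: tuple[int, int]
    sequence: str
    domains: list[DomainAnnotation] = field(default_factory=list)
    coordinate_map: dict[tuple[str, int], int] = field(default_factory=dict)
    inverse_map: dict[int, tuple[str, int]] = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def as_protein(self) -> ProteinRecord:
        """View the chimera as an ordinary ProteinRecord (lifted domains)."""
        return ProteinRecord(
            protein_id=self.chimera_id,
            sequence=self.sequence,
            name=f"{self.backbone_id} backbone with {self.donor_id} insert",
            domains=list(self.domains),
        )


def _check_interval(interval: tuple[int, int], n: int, label: str) -> None:
    start, end = interval
    if not (1 <= start <= end <= n):
        raise IntervalError(
            f"{label} interval [{start},{end}] invalid for length {n}"
        )


def build_chimera(
    backbone: ProteinRecord,
    donor: ProteinRecord,
    backbone_replaced: tuple[int, int],
    donor_inserted: tuple[int, int],
    chimera_id: Optional[str] = None,
) -> ChimeraRecord:
    """Replace ``backbone_replaced`` in the backbone by ``donor_inserted``.

    The chimera sequence is
    ``backbone[1..start-1] + donor[donor_inserted] + backbone[end+1..]``
    and the coordinate map covers every chimera position exactly once.
    Retained backbone domains and donor domains inside the inserted
    interval are lifted over; a backbone domain that straddles a junction
    is dropped with a warning annotation (never an error).
    """
    _check_interval(backbone_replaced, len(backbone), "backbone_replaced")
    _check_interval(donor_inserted, len(donor), "donor_inserted")
    b_start, b_end = backbone_replaced
    d_start, d_end = donor_inserted

    prefix = backbone.sequence[: b_start - 1]
    insert = donor.sequence[d_start - 1 : d_end]
    suffix = backbone.sequence[b_end:]
    sequence = prefix + insert + suffix

    coordinate_map: dict[tuple[str, int], int] = {}
    inverse_map: dict[int, tuple[str, int]] = {}

    for pos in range(1, b_start):  # backbone prefix: identity
        coordinate_map[(backbone.protein_id, pos)] = pos
        inverse_map[pos] = (backbone.protein_id, pos)
    donor_offset = (b_start - 1) - (d_start - 1)
    for pos in range(d_start, d_end + 1):  # donor insert: constant offset
        cpos = pos + donor_offset
        coordinate_map[(donor.protein_id, pos)] = cpos
        inverse_map[cpos] = (donor.protein_id, pos)
    suffix_shift = (d_end - d_start) - (b_end - b_start)
    for pos in range(b_end + 1, len(backbone) + 1):
        cpos = pos + suffix_shift
        coordinate_map[(backbone.protein_id, pos)] = cpos
        inverse_map[cpos] = (backbone.protein_id, pos)

    notes: list[str] = []
    domains: list[DomainAnnotation] = []
    for dom in backbone.domains:
        if dom.end < b_start or dom.start > b_end:
            lifted = DomainAnnotation(
                dom.domain_name,
                coordinate_map[(backbone.protein_id, dom.start)],
                coordinate_map[(backbone.protein_id, dom.end)],
            )
            domains.append(lifted)
        elif dom.start >= b_start and dom.end <= b_end:
            pass  # fully replaced; donor domains take its place
        else:
            notes.append(
                f"backbone domain {dom.domain_name} [{dom.start},{dom.end}] "
                f"overlaps the replaced interval [{b_start},{b_end}]; dropped"
            )
    for dom in donor.domains:
        if dom.start >= d_start and dom.end <= d_end:
            domains.append(
                DomainAnnotation(
                    dom.domain_name,
                    coordinate_map[(donor.protein_id, dom.start)],
                    coordinate_map[(donor.protein_id, dom.end)],
                )
            )
    for note in notes:
        warnings.warn(note, stacklevel=2)

    chimera = ChimeraRecord(
        chimera_id=chimera_id
        or f"{backbone.protein_id}-C-{donor.protein_id}",
        backbone_id=backbone.protein_id,
        donor_id=donor.protein_id,
        backbone_replaced=backbone_replaced,
        donor_inserted=donor_inserted,
        sequence=sequence,
        domains=sorted(domains, key=lambda d: d.start),
        coordinate_map=coordinate_map,
        inverse_map=inverse_map,
        warnings_=notes,
    )
    assert len(chimera) == len(backbone) - (b_end - b_start + 1) + (
        d_end - d_start + 1
    )
    return chimera


def map_residue(
    chimera: ChimeraRecord, source_protein_id: str, source_pos: int
) -> Union[int, str]:
    """Map a parent-protein residue into chimera coordinates.

    Returns the unique chimera position, or ``"unmapped"`` for backbone
    positions inside the replaced interval and donor positions outside the
    inserted interval.  Unknown protein ids raise ``KeyError``.
    """
    if source_protein_id not in (chimera.backbone_id, chimera.donor_id):
        raise KeyError(
            f"protein {source_protein_id!r} is not a parent of "
            f"{chimera.chimera_id!r}"
        )
    return chimera.coordinate_map.get(
        (source_protein_id, source_pos), UNMAPPED
    )


def map_back(chimera: ChimeraRecord, chimera_pos: int) -> tuple[str, int]:
    """Inverse of :func:`map_residue`; every chimera position has a source."""
    try:
        return chimera.inverse_map[chimera_pos]
    except KeyError:
        raise IndexError(
            f"position {chimera_pos} outside [1, {len(chimera)}]"
        ) from None


def locate_donor_insert(
    chimera_sequence: str, donor_subsequence: str
) -> tuple[int, int]:
    """Recover junctions by exact, unique substring match.

    Helper for reconstructing a chimera's coordinate map when only the
    final chimera sequence (e.g. from a supplementary file) and the donor
    segment are known.  Returns the 1-based inclusive interval occupied by
    the donor segment; raises if absent or ambiguous.
    """
    first = chimera_sequence.find(donor_subsequence)
    if first < 0:
        raise ValueError("donor subsequence not found in chimera sequence")
    if chimera_sequence.find(donor_subsequence, first + 1) >= 0:
        raise ValueError("donor subsequence occurs more than once")
    return first + 1, first + len(donor_subsequence)


# ---------------------------------------------------------------------------
# IO: FASTA for sequences, TSV for domain annotations


def write_fasta(
    records: Iterable[Union[ProteinRecord, ChimeraRecord]],
    path: Union[str, Path],
) -> None:
    """Write records as FASTA; the ID line carries the protein/chimera id."""
    seqrecords = []
    for rec in records:
        rid = rec.protein_id if isinstance(rec, ProteinRecord) else rec.chimera_id
        desc = rec.name if isinstance(rec, ProteinRecord) else ""
        seqrecords.append(
            SeqRecord(Seq(rec.sequence), id=rid, description=desc or "")
        )
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read FASTA into ProteinRecords (no domains; join via the TSV)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            ProteinRecord(
                protein_id=rec.id,
                sequence=str(rec.seq).upper(),
                name=rec.description.removeprefix(rec.id).strip(),
            )
        )
    return out


DOMAIN_TSV_HEADER = ["protein_id", "domain_name", "start", "end"]


def write_domain_tsv(
    proteins: Iterable[ProteinRecord], path: Union[str, Path]
) -> None:
    lines = ["\t".join(DOMAIN_TSV_HEADER)]
    for prot in proteins:
        for dom in prot.domains:
            lines.append(
                f"{prot.protein_id}\t{dom.domain_name}\t{dom.start}\t{dom.end}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_tsv(path: Union[str, Path]) -> dict[str, list[DomainAnnotation]]:
    """Parse the domain table; header row required."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != DOMAIN_TSV_HEADER:
        raise ValueError(
            f"domain TSV must start with header {DOMAIN_TSV_HEADER}"
        )
    out: dict[str, list[DomainAnnotation]] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        pid, name, start, end = line.split("\t")
        out.setdefault(pid, []).append(
            DomainAnnotation(name, int(start), int(end))
        )
    return out


def attach_domains(
    proteins: Iterable[ProteinRecord],
    domains: dict[str, list[DomainAnnotation]],
) -> list[ProteinRecord]:
    """Return new records with the annotation table's domains attached."""
    return [
        ProteinRecord(
            protein_id=p.protein_id,
            sequence=p.sequence,
            name=p.name,
            domains=list(domains.get(p.protein_id, [])),
            epitope_tag=p.epitope_tag,
        )
        for p in proteins
    ]
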