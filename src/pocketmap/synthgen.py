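"""Seeded generator of synthetic pipeline inputs with ground-truth manifests.

The real study's raw inputs — SILAC LC-MS/MS evidence for probe-treated
cells and AlphaFold models of multidomain lipid kinases — are emulated
here with the statistical structure the analysis assumes, so every stage
is testable without downloads:

* multidomain protein sequences (tandem C1A/C1B plus split DAGKc/DAGKa
  catalytic regions) with Tyr/Lys frequencies near natural abundance;
* probe-modified-peptide evidence in which planted true sites draw a high
  light/heavy SILAC ratio (enrichment), background sites sit near 1:1,
  and reversed-sequence decoys carry low search scores; plus a 1:1
  probe/probe mixing-control table;
* compact toy 3-D models (confined Calpha random walk, 3.8 Angstrom
  steps) whose planted pocket members' representative side-chain atoms
  lie within a small radius of a pocket center, with pLDDT written to the
  temperature-factor field (high in domains, low in linkers).

The structures are geometric stand-ins, not physical folds — the pipeline
consumes only coordinates and confidence values, which is exactly what
they provide.  Everything is deterministic for a given config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import peptides as pep
from .seqmodel import (
    DomainAnnotation,
    ProteinRecord,
    write_domain_tsv,
    write_fasta,
)
from .structmap import (
    ONE_TO_THREE,
    Residue,
    StructureModel,
    write_structure,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults mirror the emulated study design."""

    seed: int = 0
    n_proteins: int = 10  # one family's worth of isoforms
    length_range: tuple[int, int] = (360, 520)
    n_true_sites: int = 6
    pocket_sizes: tuple[int, ...] = (4, 2)  # per pocket-forming protein
    fraction_diffuse: float = 0.3
    # SILAC ratio distributions (lognormal location/scale on the natural log)
    enrichment_location: float = float(np.log(12.0))
    enrichment_scale: float = 0.4
    background_location: float = 0.0
    background_scale: float = 0.3
    control_scale: float = 0.2
    # search-engine score distributions (normal loc/scale)
    score_true: tuple[float, float] = (800.0, 100.0)
    score_background: tuple[float, float] = (750.0, 120.0)
    score_decoy: tuple[float, float] = (250.0, 80.0)
    ppm_noise_sd: float = 1.5
    # pLDDT profile
    plddt_domain: tuple[float, float] = (85.0, 95.0)
    plddt_linker: tuple[float, float] = (45.0, 65.0)
    # geometry (Angstrom)
    pocket_radius: float = 5.0
    diffuse_floor: float = 25.0
    # amino-acid composition targets (fractions)
    tyr_freq: float = 0.02
    lys_freq: float = 0.06
    # misc
    mod_mass: float = 313.06  # arbitrary fixed probe-adduct mass
    sr_cap: float = 20.0
    n_replicates: int = 3  # n = 3 biologically independent experiments
    n_background_sites: int = 20  # per protein
    n_decoys_per_protein: int = 4
    max_peptide_length: int = 40

    def __post_init__(self) -> None:
        for name in ("enrichment_scale", "background_scale", "control_scale",
                     "ppm_noise_sd"):
            if getattr(self, name) < 0:  # zero = noise off
                raise ValueError(f"{name} must be non-negative")
        for name in ("pocket_radius", "diffuse_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pocket_radius >= self.diffuse_floor:
            raise ValueError("pocket_radius must be < diffuse_floor")


@dataclass
class ProteinTruth:
    """Ground truth for one synthetic protein."""

    protein_id: str
    diffuse: bool
    true_sites: list[tuple[int, str]]  # (residue_number, residue_type)
    pockets: list[list[int]]  # residue numbers per planted pocket
    background_sites: list[tuple[int, str]]


@dataclass
class GroundTruth:
    """Manifest tying every generated record to its origin class."""

    config: SimConfig
    proteins: dict[str, ProteinTruth] = field(default_factory=dict)

    def origin(self, protein_id: str, residue_number: int) -> str:
        """Origin class of an evidence row localizing to this residue."""
        if protein_id.startswith("rev_"):
            return "decoy"
        pt = self.proteins[protein_id]
        if any(r == residue_number for r, _ in pt.true_sites):
            return "true"
        if any(r == residue_number for r, _ in pt.background_sites):
            return "background"
        raise KeyError(f"{protein_id}:{residue_number} not in manifest")

    def to_json(self) -> dict:
        return {
            "config": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in asdict(self.config).items()
            },
            "proteins": {
                pid: {
                    "diffuse": pt.diffuse,
                    "true_sites": [[r, t] for r, t in pt.true_sites],
                    "pockets": pt.pockets,
                    "background_sites": [
                        [r, t] for r, t in pt.background_sites
                    ],
                }
                for pid, pt in self.proteins.items()
            },
        }


# ---------------------------------------------------------------------------
# Proteins


def _domain_layout(length: int) -> list[DomainAnnotation]:
    """Tandem C1 pair plus split catalytic domain, linkers in between."""
    frac = [
        ("C1A", 0.12, 0.20),
        ("C1B", 0.24, 0.32),
        ("DAGKc", 0.40, 0.58),
        ("DAGKa", 0.66, 0.92),
    ]
    return [
        DomainAnnotation(name, max(1, int(a * length)), int(b * length))
        for name, a, b in frac
    ]


def gen_proteins(
    config: SimConfig, seed: Optional[int] = None
) -> list[ProteinRecord]:
    """Random multidomain proteins; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    other = [a for a in AA20 if a not in "YK"]
    p_other = (1.0 - config.tyr_freq - config.lys_freq) / len(other)
    alphabet = list("YK") + other
    probs = [config.tyr_freq, config.lys_freq] + [p_other] * len(other)
    proteins = []
    for i in range(config.n_proteins):
        length = int(rng.integers(*config.length_range, endpoint=True))
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        proteins.append(
            ProteinRecord(
                protein_id=f"SYN{i + 1:02d}",
                name=f"synthetic multidomain kinase {i + 1}",
                sequence=seq,
                domains=_domain_layout(length),
            )
        )
    return proteins


# ---------------------------------------------------------------------------
# Site selection


def _usable_residue(protein: ProteinRecord, pos: int,
                    max_peptide_length: int) -> bool:
    """A site is usable if its fully-cleaved tryptic peptide is short and
    occurs exactly once in the protein (unique localization)."""
    for start, peptide in pep.digest(protein.sequence, 0):
        if start <= pos < start + len(peptide):
            if len(peptide) > max_peptide_length:
                return False
            return protein.sequence.count(peptide) == 1
    return False


def select_sites(
    protein: ProteinRecord,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, str]], list[tuple[int, str]]]:
    """Pick true sites (Tyr/Lys inside domains) and background sites.

    True sites must lie on short, uniquely localizable tryptic peptides —
    the generator re-draws candidates that fail — and at most one site per
    peptide so sites quantify independently.
    """
    in_domain = [
        i + 1
        for i, aa in enumerate(protein.sequence)
        if aa in "YK" and protein.domain_at(i + 1) != "linker"
    ]
    anywhere = [
        i + 1 for i, aa in enumerate(protein.sequence) if aa in "YK"
    ]
    rng.shuffle(in_domain)
    rng.shuffle(anywhere)

    def peptide_of(pos: int) -> Optional[str]:
        for start, peptide in pep.digest(protein.sequence, 0):
            if start <= pos < start + len(peptide):
                return peptide
        return None

    used_peptides: set[str] = set()
    true_sites: list[tuple[int, str]] = []
    for pos in in_domain:
        if len(true_sites) == config.n_true_sites:
            break
        if not _usable_residue(protein, pos, config.max_peptide_length):
            continue
        peptide = peptide_of(pos)
        if peptide in used_peptides:
            continue
        used_peptides.add(peptide)
        true_sites.append((pos, protein.residue(pos)))
    background: list[tuple[int, str]] = []
    chosen = {p for p, _ in true_sites}
    for pos in anywhere:
        if len(background) == config.n_background_sites:
            break
        if pos in chosen:
            continue
        if not _usable_residue(protein, pos, config.max_peptide_length):
            continue
        peptide = peptide_of(pos)
        if peptide in used_peptides:
            continue
        used_peptides.add(peptide)
        background.append((pos, protein.residue(pos)))
    true_sites.sort()
    background.sort()
    return true_sites, background


# ---------------------------------------------------------------------------
# Structures


def _confined_walk(
    n: int, rng: np.random.Generator, step: float = 3.8
) -> np.ndarray:
    """Calpha trace: fixed-step random walk rejection-sampled to stay
    inside a sphere sized for compactness (radius ~ n^(1/3))."""
    radius = max(12.0, 4.0 * n ** (1.0 / 3.0))
    coords = np.zeros((n, 3))
    pos = np.zeros(3)
    for i in range(1, n):
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = pos + step * direction
            if np.linalg.norm(cand) <= radius:
                break
        pos = cand
        coords[i] = pos
    return coords


def _sample_in_ball(
    center: np.ndarray,
    radius: float,
    n: int,
    rng: np.random.Generator,
    min_separation: float = 1.5,
    max_tries: int = 5000,
) -> np.ndarray:
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"infeasible geometry: cannot place {n} atoms with "
                f"separation {min_separation} inside radius {radius}"
            )
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = radius * rng.random() ** (1.0 / 3.0)
        cand = center + r * direction
        if all(np.linalg.norm(cand - q) >= min_separation for q in points):
            points.append(cand)
    return np.array(points)


def gen_structure(
    protein: ProteinRecord,
    truth: ProteinTruth,
    config: SimConfig,
    seed: Optional[int] = None,
) -> StructureModel:
    """Toy model with planted spatial site geometry and a pLDDT profile.

    Pocket members' representative atoms (Lys NZ / Tyr OH) fall within
    ``pocket_radius`` of their pocket center; pocket centers, and the
    sites of diffuse proteins, are mutually separated by at least
    ``diffuse_floor``.  Non-site residues get a CB one Angstrom off the
    Calpha.  pLDDT is high inside domains and low in linkers, rounded to
    the 2 decimals the PDB B-factor field preserves.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(protein)
    ca = np.round(_confined_walk(n, rng), 3)

    planted: dict[int, np.ndarray] = {}
    if truth.diffuse:
        for k, (pos, _) in enumerate(truth.true_sites):
            planted[pos] = np.array([k * config.diffuse_floor, 60.0, 60.0])
    else:
        centers = [
            np.array([60.0 + j * 2.0 * config.diffuse_floor, 60.0, 0.0])
            for j in range(len(truth.pockets))
        ]
        for center, members in zip(centers, truth.pockets):
            pts = _sample_in_ball(center, config.pocket_radius,
                                  len(members), rng)
            for pos, xyz in zip(members, pts):
                planted[pos] = xyz
        extras = [
            (p, t) for p, t in truth.true_sites
            if not any(p in members for members in truth.pockets)
        ]
        for k, (pos, _) in enumerate(extras):
            planted[pos] = np.array(
                [-(k + 2) * config.diffuse_floor, -60.0, 60.0]
            )

    residues = []
    for i, aa in enumerate(protein.sequence):
        resnum = i + 1
        in_domain = protein.domain_at(resnum) != "linker"
        lo, hi = config.plddt_domain if in_domain else config.plddt_linker
        plddt = round(float(rng.uniform(lo, hi)), 2)
        atoms = {"CA": ca[i]}
        if resnum in planted:
            name = "NZ" if aa == "K" else "OH"
            atoms[name] = np.round(planted[resnum], 3)
        elif aa != "G":
            offset = rng.normal(size=3)
            offset /= np.linalg.norm(offset)
            atoms["CB"] = np.round(ca[i] + offset, 3)
        residues.append(
            Residue(
                residue_number=resnum, amino_acid=aa, plddt=plddt,
                atoms=atoms,
            )
        )
    return StructureModel(
        structure_id=f"{protein.protein_id}-model", residues=residues
    )


# ---------------------------------------------------------------------------
# Evidence


def _evidence_for_site(
    protein: ProteinRecord,
    pos: int,
    restype: str,
    sr_location: float,
    sr_scale: float,
    score_loc_scale: tuple[float, float],
    config: SimConfig,
    rng: np.random.Generator,
    replicate_id: str,
) -> pep.PeptideEvidence:
    for start, peptide in pep.digest(protein.sequence, 0):
        if start <= pos < start + len(peptide):
            break
    else:  # pragma: no cover - sites are pre-screened
        raise RuntimeError("site not on any tryptic peptide")
    sr = float(rng.lognormal(sr_location, sr_scale))
    heavy = float(rng.lognormal(np.log(1e5), 0.5))
    light = sr * heavy
    score = max(1.0, float(rng.normal(*score_loc_scale)))
    theo = pep.theoretical_mass(peptide, config.mod_mass)
    ppm = float(rng.normal(0.0, config.ppm_noise_sd))
    return pep.PeptideEvidence(
        replicate_id=replicate_id,
        protein_id=protein.protein_id,
        peptide_sequence=peptide,
        mod_offset=pos - start,
        mod_residue=restype,
        mod_mass=config.mod_mass,
        light_intensity=round(light, 1),
        heavy_intensity=round(heavy, 1),
        score=round(score, 1),
        observed_mass=round(theo * (1.0 + ppm * 1e-6), 6),
        charge=int(rng.integers(2, 4)),
        is_decoy=False,
    )


def gen_evidence(
    protein: ProteinRecord,
    truth: ProteinTruth,
    config: SimConfig,
    seed: Optional[int] = None,
) -> tuple[list[pep.PeptideEvidence], list[pep.PeptideEvidence]]:
    """Evidence for the enrichment design plus the 1:1 control design.

    True sites draw SR from the enrichment distribution, background sites
    from the ~1:1 distribution; decoy rows come from the reversed sequence
    with the decoy score distribution.  Returns (enrichment_rows,
    control_rows); decoys are embedded in the enrichment rows with
    ``is_decoy = True``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    reps = [f"rep{i + 1}" for i in range(config.n_replicates)]
    rows: list[pep.PeptideEvidence] = []
    control: list[pep.PeptideEvidence] = []
    for rep in reps:
        for pos, restype in truth.true_sites:
            rows.append(
                _evidence_for_site(
                    protein, pos, restype,
                    config.enrichment_location, config.enrichment_scale,
                    config.score_true, config, rng, rep,
                )
            )
        for pos, restype in truth.background_sites:
            rows.append(
                _evidence_for_site(
                    protein, pos, restype,
                    config.background_location, config.background_scale,
                    config.score_background, config, rng, rep,
                )
            )
        for pos, restype in truth.true_sites + truth.background_sites:
            control.append(
                _evidence_for_site(
                    protein, pos, restype,
                    0.0, config.control_scale,
                    config.score_true, config, rng, rep,
                )
            )
        # decoys: peptides from the reversed sequence, low scores
        reversed_protein = ProteinRecord(
            protein_id=f"rev_{protein.protein_id}",
            sequence=protein.sequence[::-1],
        )
        decoy_peps = [
            (s, p) for s, p in pep.digest(reversed_protein.sequence, 0)
            if any(a in "YK" for a in p) and len(p) <= config.max_peptide_length
        ]
        for _ in range(config.n_decoys_per_protein):
            start, peptide = decoy_peps[int(rng.integers(len(decoy_peps)))]
            offset = next(
                i for i, a in enumerate(peptide) if a in "YK"
            )
            heavy = float(rng.lognormal(np.log(1e5), 0.5))
            theo = pep.theoretical_mass(peptide, config.mod_mass)
            rows.append(
                pep.PeptideEvidence(
                    replicate_id=rep,
                    protein_id=reversed_protein.protein_id,
                    peptide_sequence=peptide,
                    mod_offset=offset,
                    mod_residue=peptide[offset],
                    mod_mass=config.mod_mass,
                    light_intensity=round(
                        heavy * float(rng.lognormal(0.0, 0.5)), 1
                    ),
                    heavy_intensity=round(heavy, 1),
                    score=round(
                        max(1.0, float(rng.normal(*config.score_decoy))), 1
                    ),
                    observed_mass=round(theo, 6),
                    charge=2,
                    is_decoy=True,
                )
            )
    return rows, control


# ---------------------------------------------------------------------------
# Protein-level score simulator for FDR calibration


def gen_protein_scores(
    n_proteins: int,
    frac_true: float,
    seed: int,
    score_true: tuple[float, float] = (800.0, 100.0),
    score_false: tuple[float, float] = (300.0, 100.0),
) -> tuple[dict[str, float], list[float], set[str]]:
    """Target/decoy protein best-score draws with known true/false labels.

    Embodies the target-decoy estimator's core assumption: false-target
    and decoy best scores are i.i.d. from the same null distribution and
    arise in equal numbers (each spurious target identification has a
    matched decoy competitor).  Returns (target best scores, decoy best
    scores, true-protein ids).
    """
    rng = np.random.default_rng(seed)
    n_true = int(round(frac_true * n_proteins))
    targets: dict[str, float] = {}
    truth: set[str] = set()
    for i in range(n_proteins):
        pid = f"P{i + 1:04d}"
        if i < n_true:
            targets[pid] = float(rng.normal(*score_true))
            truth.add(pid)
        else:
            targets[pid] = float(rng.normal(*score_false))
    n_false = n_proteins - n_true
    decoys = [float(rng.normal(*score_false)) for _ in range(n_false)]
    return targets, decoys, truth


# ---------------------------------------------------------------------------
# Bundle writer


def generate_bundle(
    config: SimConfig,
    out_dir: Union[str, Path],
    with_structures: bool = True,
) -> GroundTruth:
    """Emit a complete input set: FASTA, domain TSV, evidence and control
    TSVs per replicate, structure PDBs, and the ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    proteins = gen_proteins(config, int(rng.integers(2**31)))
    truth = GroundTruth(config=config)

    n_diffuse = int(round(config.fraction_diffuse * len(proteins)))
    diffuse_ids = {p.protein_id for p in proteins[:n_diffuse]}

    for protein in proteins:
        site_rng = np.random.default_rng(int(rng.integers(2**31)))
        true_sites, background = select_sites(protein, config, site_rng)
        diffuse = protein.protein_id in diffuse_ids
        pockets: list[list[int]] = []
        if not diffuse:
            cursor = 0
            for size in config.pocket_sizes:
                members = [p for p, _ in true_sites[cursor:cursor + size]]
                if len(members) >= 2:
                    pockets.append(members)
                cursor += size
        truth.proteins[protein.protein_id] = ProteinTruth(
            protein_id=protein.protein_id,
            diffuse=diffuse,
            true_sites=true_sites,
            pockets=pockets,
            background_sites=background,
        )

    write_fasta(proteins, out / "proteins.fasta")
    write_domain_tsv(proteins, out / "domains.tsv")

    all_rows: list[pep.PeptideEvidence] = []
    all_control: list[pep.PeptideEvidence] = []
    for protein in proteins:
        rows, control = gen_evidence(
            protein, truth.proteins[protein.protein_id], config,
            int(rng.integers(2**31)),
        )
        all_rows.extend(rows)
        all_control.extend(control)
    for rep in sorted({r.replicate_id for r in all_rows}):
        pep.write_evidence_tsv(
            [r for r in all_rows if r.replicate_id == rep],
            out / f"evidence_{rep}.tsv",
        )
        pep.write_evidence_tsv(
            [r for r in all_control if r.replicate_id == rep],
            out / f"control_{rep}.tsv",
        )

    if with_structures:
        (out / "structures").mkdir(exist_ok=True)
        for protein in proteins:
            model = gen_structure(
                protein, truth.proteins[protein.protein_id], config,
                int(rng.integers(2**31)),
            )
            write_structure(
                model, out / "structures" / f"{protein.protein_id}.pdb"
            )

    (out / "truth.json").write_text(
        json.dumps(truth.to_json(), indent=2) + "\n"
    )
    return truth
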