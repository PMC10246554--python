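"""Family-level summary statistics over covalent-site profiles.

Small descriptive metrics reported alongside the site maps: the Tyr/Lys
site-count ratio (the probe's residue preference), per-protein Tyr/Lys
amino-acid composition (the natural-abundance baseline the ratio is read
against), per-domain site counts, and ligand efficiency for comparing
fragments of different size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .seqmodel import ProteinRecord
from .silacquant import QuantifiedSite


@dataclass(frozen=True)
class SiteSummary:
    n_tyr_sites: int
    n_lys_sites: int
    yk_ratio: float  # NaN when no Lys sites


@dataclass(frozen=True)
class CompositionRow:
    protein_id: str
    fraction_tyr: float  # percent of sequence length
    fraction_lys: float


@dataclass(frozen=True)
class LigandEfficiencyInput:
    """Binding free energy (kcal/mol, negative favorable) and heavy-atom count."""

    delta_g: float
    n_heavy: int

    def __post_init__(self) -> None:
        if self.n_heavy < 1:
            raise ValueError("n_heavy must be >= 1")


def yk_ratio(passing_sites: Sequence[QuantifiedSite]) -> SiteSummary:
    """Distinct modified-Tyr over distinct modified-Lys site counts.

    Counts sites, not evidence rows; callers pass filtered sites.  With no
    Lys sites the ratio is undefined and reported as NaN.
    """
    distinct = {
        (s.protein_id, s.residue_number, s.residue_type)
        for s in passing_sites
    }
    n_y = sum(t == "Y" for _, _, t in distinct)
    n_k = sum(t == "K" for _, _, t in distinct)
    ratio = n_y / n_k if n_k > 0 else float("nan")
    return SiteSummary(n_tyr_sites=n_y, n_lys_sites=n_k, yk_ratio=ratio)


def aa_composition(
    proteins: Iterable[ProteinRecord],
) -> tuple[list[CompositionRow], float, float]:
    """Per-protein Tyr/Lys percent composition and unweighted means."""
    rows = []
    for p in proteins:
        n = len(p.sequence)
        rows.append(
            CompositionRow(
                protein_id=p.protein_id,
                fraction_tyr=100.0 * p.sequence.count("Y") / n,
                fraction_lys=100.0 * p.sequence.count("K") / n,
            )
        )
    if not rows:
        return rows, float("nan"), float("nan")
    mean_y = sum(r.fraction_tyr for r in rows) / len(rows)
    mean_k = sum(r.fraction_lys for r in rows) / len(rows)
    return rows, mean_y, mean_k


def ligand_efficiency(inp: LigandEfficiencyInput) -> float:
    """|delta G| per non-hydrogen atom, kcal/mol."""
    return abs(inp.delta_g) / inp.n_heavy


def domain_assignment_report(
    sites: Sequence[QuantifiedSite],
    proteins: dict[str, ProteinRecord],
) -> pd.DataFrame:
    """Count sites per (protein, domain); uncovered residues go to "linker".

    Every site lands in exactly one row's count (domains are
    non-overlapping by construction), so the column sum equals the number
    of sites.
    """
    counts: dict[tuple[str, str], int] = {}
    for s in sites:
        protein = proteins.get(s.protein_id)
        domain = (
            protein.domain_at(s.residue_number)
            if protein is not None
            else s.domain_name
        )
        counts[(s.protein_id, domain)] = counts.get(
            (s.protein_id, domain), 0
        ) + 1
    return pd.DataFrame(
        [
            {"protein_id": pid, "domain_name": dom, "n_sites": n}
            for (pid, dom), n in sorted(counts.items())
        ],
        columns=["protein_id", "domain_name", "n_sites"],
    )


def write_summary_report(
    path_json: Union[str, Path],
    path_txt: Union[str, Path],
    summary: SiteSummary,
    composition: tuple[list[CompositionRow], float, float],
    domain_report: pd.DataFrame,
    profile_labels: dict[str, str],
) -> None:
    """One machine-readable JSON + one human-readable text summary."""
    rows, mean_y, mean_k = composition
    payload = {
        "sites": {
            "n_tyr": summary.n_tyr_sites,
            "n_lys": summary.n_lys_sites,
            "yk_ratio": None
            if math.isnan(summary.yk_ratio)
            else round(summary.yk_ratio, 4),
        },
        "composition": {
            "per_protein": [
                {
                    "protein_id": r.protein_id,
                    "tyr_pct": round(r.fraction_tyr, 3),
                    "lys_pct": round(r.fraction_lys, 3),
                }
                for r in rows
            ],
            "mean_tyr_pct": round(mean_y, 3),
            "mean_lys_pct": round(mean_k, 3),
        },
        "per_domain_counts": domain_report.to_dict(orient="records"),
        "profiles": profile_labels,
    }
    Path(path_json).write_text(json.dumps(payload, indent=2) + "\n")

    lines = [
        "Covalent-site summary",
        "=====================",
        f"Tyr sites: {summary.n_tyr_sites}   Lys sites: {summary.n_lys_sites}"
        f"   Y/K ratio: {summary.yk_ratio:.2f}"
        if not math.isnan(summary.yk_ratio)
        else f"Tyr sites: {summary.n_tyr_sites}   Lys sites: "
        f"{summary.n_lys_sites}   Y/K ratio: undefined (no Lys sites)",
        f"Mean composition: Tyr {mean_y:.2f}%  Lys {mean_k:.2f}%",
        "",
        "Per-domain site counts:",
        domain_report.to_string(index=False)
        if len(domain_report)
        else "  (none)",
        "",
        "Protein profiles:",
    ]
    for pid, label in sorted(profile_labels.items()):
        lines.append(f"  {pid}: {label}")
    Path(path_txt).write_text("\n".join(lines) + "\n")
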