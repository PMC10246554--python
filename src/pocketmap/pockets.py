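"""Spatial clustering of mapped covalent sites into candidate binding regions.

Covalent probe modification marks surface-accessible nucleophiles; when
several modified residues sit close together in the predicted structure
they outline a candidate small-molecule binding region ("pocket" in the
operational sense of a spatial cluster of labeled residues — no cavity
detection or druggability scoring is attempted).

Clustering is single linkage on representative-atom Euclidean distances:
two sites share a region iff they are connected by a chain of pairwise
distances at most ``cluster_distance`` (default 12 Angstrom).  Clusters
with at least ``min_cluster_size`` members (default 2) become
BindingRegions; a protein with no region is labeled diffuse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .seqmodel import ProteinRecord
from .structmap import MappedSite

DEFAULT_CLUSTER_DISTANCE = 12.0  # Angstrom, representative-atom spacing
DEFAULT_MIN_CLUSTER_SIZE = 2

POCKET_FORMING = "pocket_forming"
DIFFUSE = "diffuse"

#: Viewer coloring scheme: modified Lys dark blue, modified Tyr red.
SITE_COLORS = {"K": "0x00008B", "Y": "0xFF0000"}


@dataclass
class BindingRegion:
    """A spatial cluster of included covalent sites on one protein."""

    region_id: str
    protein_id: str
    member_sites: list[MappedSite]
    centroid: np.ndarray
    max_pairwise_distance: float
    domains_spanned: frozenset[str]
    n_tyr: int
    n_lys: int

    @property
    def size(self) -> int:
        return len(self.member_sites)

    @property
    def member_residues(self) -> list[str]:
        return [
            f"{m.residue_type}{m.residue_number}" for m in self.member_sites
        ]


@dataclass
class ProteinProfile:
    """Per-protein clustering outcome: regions, leftovers, and a label."""

    protein_id: str
    regions: list[BindingRegion]
    unclustered_sites: list[MappedSite]
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = POCKET_FORMING if self.regions else DIFFUSE


def cluster_sites(
    mapped_sites: Sequence[MappedSite],
    cluster_distance: float = DEFAULT_CLUSTER_DISTANCE,
) -> list[list[MappedSite]]:
    """Partition included sites by single-linkage at a distance threshold.

    Returns clusters sorted by their smallest member residue number, each
    cluster's members sorted by residue number — the same partition for
    any input order.  Excluded (low-confidence or unresolved) sites never
    enter the partition.
    """
    if cluster_distance <= 0:
        raise ValueError("cluster_distance must be positive")
    included = [m for m in mapped_sites if m.included]
    included.sort(key=lambda m: m.residue_number)
    if len(included) <= 1:
        return [[m] for m in included]
    coords = np.array([m.coordinates for m in included])
    labels = fcluster(
        linkage(pdist(coords), method="single"),
        t=cluster_distance,
        criterion="distance",
    )
    clusters: dict[int, list[MappedSite]] = {}
    for lab, m in zip(labels, included):
        clusters.setdefault(int(lab), []).append(m)
    return sorted(
        clusters.values(), key=lambda c: min(m.residue_number for m in c)
    )


def make_regions(
    clusters: Sequence[Sequence[MappedSite]],
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    protein: ProteinRecord | None = None,
) -> tuple[list[BindingRegion], list[MappedSite]]:
    """Promote large-enough clusters to BindingRegions.

    The centroid is the mean of representative-atom coordinates; the
    extent is the maximum pairwise member distance; the domain span is the
    union of the members' domain assignments (recomputed from ``protein``
    when given, else taken from the sites).  Undersized clusters'
    members are returned as unclustered.
    """
    regions: list[BindingRegion] = []
    unclustered: list[MappedSite] = []
    for members in clusters:
        if len(members) < min_cluster_size:
            unclustered.extend(members)
            continue
        members = sorted(members, key=lambda m: m.residue_number)
        coords = np.array([m.coordinates for m in members])
        if len(members) > 1:
            extent = float(pdist(coords).max())
        else:
            extent = 0.0
        if protein is not None:
            domains = frozenset(
                protein.domain_at(m.residue_number) for m in members
            )
        else:
            domains = frozenset(m.site.domain_name for m in members)
        pid = members[0].protein_id
        regions.append(
            BindingRegion(
                region_id=f"{pid}:R{min(m.residue_number for m in members)}",
                protein_id=pid,
                member_sites=list(members),
                centroid=coords.mean(axis=0),
                max_pairwise_distance=extent,
                domains_spanned=domains,
                n_tyr=sum(m.residue_type == "Y" for m in members),
                n_lys=sum(m.residue_type == "K" for m in members),
            )
        )
    regions.sort(key=lambda r: r.member_sites[0].residue_number)
    return regions, unclustered


def classify_profile(
    protein_id: str,
    regions: Sequence[BindingRegion],
    unclustered: Sequence[MappedSite],
) -> ProteinProfile:
    """Label a protein pocket-forming iff it has at least one region."""
    return ProteinProfile(
        protein_id=protein_id,
        regions=list(regions),
        unclustered_sites=list(unclustered),
    )


def find_regions(
    mapped_sites: Sequence[MappedSite],
    protein: ProteinRecord | None = None,
    cluster_distance: float = DEFAULT_CLUSTER_DISTANCE,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> ProteinProfile:
    """Convenience: cluster one protein's mapped sites and classify it."""
    if not mapped_sites:
        raise ValueError("no mapped sites")
    pids = {m.protein_id for m in mapped_sites}
    if len(pids) != 1:
        raise ValueError(f"sites from multiple proteins: {sorted(pids)}")
    clusters = cluster_sites(mapped_sites, cluster_distance)
    regions, unclustered = make_regions(clusters, min_cluster_size, protein)
    return classify_profile(pids.pop(), regions, unclustered)


# ---------------------------------------------------------------------------
# Output writers


def profiles_to_dict(profiles: Sequence[ProteinProfile]) -> dict:
    out: dict = {"proteins": []}
    for p in profiles:
        out["proteins"].append(
            {
                "protein_id": p.protein_id,
                "label": p.label,
                "regions": [
                    {
                        "region_id": r.region_id,
                        "protein_id": r.protein_id,
                        "members": r.member_residues,
                        "centroid": [round(float(v), 3) for v in r.centroid],
                        "max_pairwise_distance": round(
                            r.max_pairwise_distance, 3
                        ),
                        "domains_spanned": sorted(r.domains_spanned),
                        "n_tyr": r.n_tyr,
                        "n_lys": r.n_lys,
                    }
                    for r in p.regions
                ],
                "unclustered_sites": [
                    f"{m.residue_type}{m.residue_number}"
                    for m in sorted(
                        p.unclustered_sites, key=lambda m: m.residue_number
                    )
                ],
            }
        )
    return out


def write_regions_json(
    profiles: Sequence[ProteinProfile], path: Union[str, Path]
) -> None:
    Path(path).write_text(
        json.dumps(profiles_to_dict(profiles), indent=2) + "\n"
    )


def write_viewer_commands(
    mapped: Sequence[MappedSite], path: Union[str, Path]
) -> None:
    """Per-residue coloring commands for a molecular viewer (PyMOL syntax)."""
    lines = ["# modified Lys dark blue, modified Tyr red"]
    for m in sorted(mapped, key=lambda m: m.residue_number):
        if not m.included:
            continue
        lines.append(
            f"color {SITE_COLORS[m.residue_type]}, resi {m.residue_number}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
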