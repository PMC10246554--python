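"""End-to-end orchestration: evidence tables in, binding regions out.

Stage order: localize evidence to residues and aggregate to sites, apply
the enrichment/QC filters, join passing sites to structure coordinates
under the pLDDT gate, cluster included sites into candidate binding
regions, and write the summary reports.  Each stage logs its record
counts; any stage error aborts with a stage-named message, retaining
partial outputs next to a FAILED marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import metrics, peptides, pockets, silacquant, structmap
from .seqmodel import (
    ProteinRecord,
    attach_domains,
    read_domain_tsv,
    read_fasta,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths plus every tunable threshold for one pipeline run."""

    proteins: Path
    domains: Optional[Path]
    evidence: list[Path]
    structures: Optional[Path]  # directory of <protein_id>.pdb / .cif
    out_dir: Path
    filters: silacquant.FilterConfig = field(
        default_factory=silacquant.FilterConfig
    )
    plddt_min: float = 70.0
    cluster_distance: float = pockets.DEFAULT_CLUSTER_DISTANCE
    min_cluster_size: int = pockets.DEFAULT_MIN_CLUSTER_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        self.proteins = Path(self.proteins)
        self.domains = Path(self.domains) if self.domains else None
        self.evidence = [Path(p) for p in self.evidence]
        self.structures = Path(self.structures) if self.structures else None
        self.out_dir = Path(self.out_dir)
        for p in [self.proteins, self.domains, *self.evidence,
                  self.structures]:
            if p is not None and not p.exists():
                raise FileNotFoundError(p)
        for name in ("plddt_min", "cluster_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        filter_keys = {
            "sr_min", "score_min", "protein_fdr_max", "ppm_max", "sr_cap",
            "min_replicates",
        }
        fc = silacquant.FilterConfig(
            **{k: raw.pop(k) for k in list(raw) if k in filter_keys}
        )
        return cls(filters=fc, **raw)


@dataclass
class RunResult:
    sites: list[silacquant.QuantifiedSite]
    mapped: dict[str, list[structmap.MappedSite]]
    profiles: list[pockets.ProteinProfile]
    out_dir: Path
    counts: dict[str, int]


def _load_proteins(config: RunConfig) -> dict[str, ProteinRecord]:
    proteins = read_fasta(config.proteins)
    if config.domains is not None:
        proteins = attach_domains(proteins, read_domain_tsv(config.domains))
    return {p.protein_id: p for p in proteins}


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write the run directory.

    Outputs: ``sites.tsv`` (all quantified sites with filter flags),
    ``mapped_sites.tsv`` (passing sites with coordinates/pLDDT),
    ``regions.json`` (binding regions and per-protein profile labels),
    ``summary.json`` / ``summary.txt``, and ``run.log``.  Deterministic:
    identical inputs and config give byte-identical outputs.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pocketmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    stage = "load"
    try:
        logger.info(
            "thresholds: sr>%s score>=%s fdr<=%s ppm<=%s plddt>%s "
            "cluster<=%sA min_size=%s seed=%s",
            config.filters.sr_min, config.filters.score_min,
            config.filters.protein_fdr_max, config.filters.ppm_max,
            config.plddt_min, config.cluster_distance,
            config.min_cluster_size, config.seed,
        )
        proteins = _load_proteins(config)
        evidence: list[peptides.PeptideEvidence] = []
        for path in config.evidence:
            evidence.extend(peptides.read_evidence_tsv(path))
        counts["evidence_rows"] = len(evidence)
        logger.info("load: %d proteins, %d evidence rows",
                    len(proteins), len(evidence))

        stage = "aggregate"
        sites = silacquant.aggregate_sites(
            evidence, proteins, sr_cap=config.filters.sr_cap
        )
        counts["sites"] = len(sites)
        assert counts["sites"] <= counts["evidence_rows"]
        logger.info("aggregate: %d sites", len(sites))

        stage = "filter"
        decoys = [r for r in evidence if r.is_decoy]
        sites = silacquant.apply_filters(sites, decoys, config.filters)
        passing = [s for s in sites if s.pass_overall]
        counts["passing_sites"] = len(passing)
        logger.info("filter: %d/%d sites pass", len(passing), len(sites))
        silacquant.write_sites_tsv(sites, out / "sites.tsv")

        stage = "map"
        mapped: dict[str, list[structmap.MappedSite]] = {}
        if config.structures is not None:
            for pid in sorted({s.protein_id for s in passing}):
                model_path = None
                for ext in (".pdb", ".cif"):
                    cand = config.structures / f"{pid}{ext}"
                    if cand.exists():
                        model_path = cand
                        break
                if model_path is None:
                    logger.warning("map: no structure for %s", pid)
                    continue
                model = structmap.load_structure(model_path)
                mapped[pid] = structmap.map_sites(
                    [s for s in passing if s.protein_id == pid],
                    model,
                    proteins[pid],
                    plddt_min=config.plddt_min,
                )
        counts["mapped_sites"] = sum(len(v) for v in mapped.values())
        all_mapped = [m for v in mapped.values() for m in v]
        structmap.write_mapped_tsv(all_mapped, out / "mapped_sites.tsv")
        logger.info("map: %d sites on %d structures",
                    counts["mapped_sites"], len(mapped))

        stage = "cluster"
        profiles = []
        for pid in sorted(mapped):
            profiles.append(
                pockets.find_regions(
                    mapped[pid],
                    protein=proteins[pid],
                    cluster_distance=config.cluster_distance,
                    min_cluster_size=config.min_cluster_size,
                )
            )
        counts["regions"] = sum(len(p.regions) for p in profiles)
        pockets.write_regions_json(profiles, out / "regions.json")
        logger.info("cluster: %d regions over %d proteins",
                    counts["regions"], len(profiles))

        stage = "report"
        summary = metrics.yk_ratio(passing)
        composition = metrics.aa_composition(proteins.values())
        domain_report = metrics.domain_assignment_report(passing, proteins)
        metrics.write_summary_report(
            out / "summary.json",
            out / "summary.txt",
            summary,
            composition,
            domain_report,
            {p.protein_id: p.label for p in profiles},
        )
        logger.info("report: counts %s", counts)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return RunResult(
        sites=sites, mapped=mapped, profiles=profiles, out_dir=out,
        counts=counts,
    )
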