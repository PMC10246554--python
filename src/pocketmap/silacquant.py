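"""SILAC ratio quantification, enrichment/QC filters, and target-decoy FDR.

The experimental design mixes a light probe-treated proteome with a heavy
vehicle-treated one, so probe-specific covalent sites show a high
light/heavy SILAC ratio (SR) while background peptides sit near 1:1.  A
site is accepted when it clears four filters together:

* enrichment:     any replicate SR strictly greater than ``sr_min`` (5)
* identification: best search-engine score >= ``score_min`` (500)
* mass accuracy:  worst supporting |ppm error| <= ``ppm_max`` (5)
* protein FDR:    the site's protein survives a target-decoy protein-level
                  false discovery rate <= ``protein_fdr_max`` (0.01)

A parallel 1:1 mixing control (probe in both channels) sanity-checks the
quantification: control SRs should sit near 1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .peptides import (
    LocalizationError,
    PeptideEvidence,
    localize_site,
    ppm_error,
    theoretical_mass,
)
from .seqmodel import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for site acceptance; defaults follow the study design."""

    sr_min: float = 5.0  # strict >
    score_min: float = 500.0  # >=
    protein_fdr_max: float = 0.01  # <=
    ppm_max: float = 5.0  # <=
    sr_cap: float = 20.0  # ratio assigned when heavy channel is absent
    min_replicates: int = 1

    def __post_init__(self) -> None:
        for name in ("sr_min", "score_min", "protein_fdr_max", "ppm_max",
                     "sr_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


@dataclass
class QuantifiedSite:
    """A protein-residue-level covalent site with per-replicate SRs."""

    protein_id: str
    residue_number: int
    residue_type: str
    sr_per_replicate: dict[str, float]
    best_score: float
    max_abs_ppm: float
    n_replicates_detected: int
    domain_name: str = "linker"
    passes: dict[str, bool] = field(default_factory=dict)

    @property
    def pass_overall(self) -> bool:
        return bool(self.passes) and all(self.passes.values())

    @property
    def max_sr(self) -> float:
        return max(self.sr_per_replicate.values())


def silac_ratio(light: float, heavy: float, cap: float = 20.0) -> float:
    """Light/heavy ratio, capped; singletons follow a fixed convention.

    heavy = 0 with light > 0 (probe-only detection) maps to ``cap``;
    light = 0 maps to 0.
    """
    if light < 0 or heavy < 0:
        raise ValueError("negative intensity")
    if cap <= 0:
        raise ValueError("cap must be positive")
    if light == 0:
        return 0.0
    if heavy == 0:
        return cap
    return min(light / heavy, cap)


def aggregate_sites(
    evidence: Iterable[PeptideEvidence],
    proteins: dict[str, ProteinRecord],
    sr_cap: float = 20.0,
) -> list[QuantifiedSite]:
    """Roll evidence rows up to one QuantifiedSite per (protein, residue).

    Within a replicate the site SR is the ratio of summed light to summed
    heavy intensities across supporting rows (robust for low-count
    evidence).  Decoy rows never produce sites — they only feed the FDR
    estimate.  Rows whose peptide cannot be uniquely localized are dropped
    and logged.
    """
    buckets: dict[tuple[str, int, str], list[PeptideEvidence]] = {}
    n_dropped = 0
    for row in evidence:
        if row.is_decoy:
            continue
        protein = proteins.get(row.protein_id)
        if protein is None:
            logger.warning("evidence for unknown protein %s dropped",
                           row.protein_id)
            n_dropped += 1
            continue
        try:
            site = localize_site(row, protein)
        except LocalizationError as exc:
            logger.warning("dropped evidence row: %s", exc)
            n_dropped += 1
            continue
        buckets.setdefault(
            (site.protein_id, site.residue_number, site.residue_type), []
        ).append(row)
    if n_dropped:
        logger.info("aggregate_sites dropped %d unlocalizable rows", n_dropped)

    sites = []
    for (pid, resnum, restype), rows in sorted(buckets.items()):
        sr: dict[str, float] = {}
        for rep, rep_rows in itertools.groupby(
            sorted(rows, key=lambda r: r.replicate_id),
            key=lambda r: r.replicate_id,
        ):
            rep_rows = list(rep_rows)
            light = sum(r.light_intensity for r in rep_rows)
            heavy = sum(r.heavy_intensity for r in rep_rows)
            sr[rep] = silac_ratio(light, heavy, cap=sr_cap)
        ppms = [
            abs(ppm_error(
                r.observed_mass,
                theoretical_mass(r.peptide_sequence, r.mod_mass),
            ))
            for r in rows
        ]
        sites.append(
            QuantifiedSite(
                protein_id=pid,
                residue_number=resnum,
                residue_type=restype,
                sr_per_replicate=sr,
                best_score=max(r.score for r in rows),
                max_abs_ppm=max(ppms),
                n_replicates_detected=len(sr),
                domain_name=proteins[pid].domain_at(resnum),
            )
        )
    return sites


def protein_fdr(
    target_best_scores: Sequence[float],
    decoy_best_scores: Sequence[float],
    score_threshold: float,
) -> float:
    """Target-decoy protein-level FDR estimate at one score threshold.

    FDR = (#decoy proteins >= threshold) / max(1, #target proteins >=
    threshold).  No pseudo-count by default.
    """
    n_decoy = sum(s >= score_threshold for s in decoy_best_scores)
    n_target = sum(s >= score_threshold for s in target_best_scores)
    return n_decoy / max(1, n_target)


def fdr_passing_proteins(
    target_best_scores: dict[str, float],
    decoy_best_scores: Sequence[float],
    protein_fdr_max: float,
) -> set[str]:
    """Proteins surviving the FDR gate.

    Candidate thresholds are the observed target scores; raw FDR estimates
    are monotonized into q-values (each protein's q is the minimum raw FDR
    over the acceptance sets containing it) and proteins with q <=
    ``protein_fdr_max`` pass.  With no targets the result is empty.
    """
    if not target_best_scores:
        return set()
    targets = np.asarray(sorted(target_best_scores.values()))
    decoys = np.asarray(sorted(decoy_best_scores))
    # at threshold t: counts of scores >= t via right-side search
    raw = []
    for t in targets:
        n_d = len(decoys) - np.searchsorted(decoys, t, side="left")
        n_t = len(targets) - np.searchsorted(targets, t, side="left")
        raw.append(n_d / max(1, n_t))
    # q-value of a protein scoring t: minimum raw FDR over all acceptance
    # sets containing it (thresholds <= t) -> prefix min over ascending
    # thresholds; non-increasing in the threshold by construction
    qvals = np.minimum.accumulate(np.asarray(raw))
    passing_idx = np.nonzero(qvals <= protein_fdr_max)[0]
    if len(passing_idx) == 0:
        return set()
    threshold = targets[passing_idx[0]]
    return {
        pid for pid, s in target_best_scores.items() if s >= threshold
    }


def apply_filters(
    sites: list[QuantifiedSite],
    decoy_evidence: Iterable[PeptideEvidence],
    config: FilterConfig = FilterConfig(),
) -> list[QuantifiedSite]:
    """Set per-filter flags on each site; overall pass is their conjunction.

    Inequality senses are literal: SR strictly > sr_min, score >=
    score_min, |ppm| <= ppm_max, protein FDR <= protein_fdr_max.
    """
    target_best: dict[str, float] = {}
    for s in sites:
        target_best[s.protein_id] = max(
            target_best.get(s.protein_id, -math.inf), s.best_score
        )
    decoy_best: dict[str, float] = {}
    for row in decoy_evidence:
        if not row.is_decoy:
            continue
        decoy_best[row.protein_id] = max(
            decoy_best.get(row.protein_id, -math.inf), row.score
        )
    surviving = fdr_passing_proteins(
        target_best, list(decoy_best.values()), config.protein_fdr_max
    )
    for s in sites:
        s.passes = {
            "sr": any(v > config.sr_min for v in s.sr_per_replicate.values()),
            "score": s.best_score >= config.score_min,
            "ppm": s.max_abs_ppm <= config.ppm_max,
            "fdr": s.protein_id in surviving,
            "replicates": s.n_replicates_detected >= config.min_replicates,
        }
    return sites


@dataclass(frozen=True)
class ControlCheck:
    """Outcome of the 1:1 mixing-control sanity check."""

    median_sr: float
    flagged: tuple[tuple[str, int], ...]  # (protein_id, residue_number)
    n_sites: int


def control_channel_check(
    control_sites: Sequence[QuantifiedSite],
    low: float = 0.5,
    high: float = 2.0,
) -> ControlCheck:
    """Flag control-condition sites whose SR leaves [low, high].

    Under a 1:1 probe/probe mix every site should quantify near SR = 1;
    large deviations indicate channel imbalance or quantification trouble.
    """
    ratios = []
    flagged = []
    for s in control_sites:
        for sr in s.sr_per_replicate.values():
            ratios.append(sr)
            if not low <= sr <= high:
                flagged.append((s.protein_id, s.residue_number))
                break
    median = float(np.median(ratios)) if ratios else float("nan")
    return ControlCheck(
        median_sr=median, flagged=tuple(sorted(set(flagged))),
        n_sites=len(control_sites),
    )


def replicate_correlation(
    sites: Sequence[QuantifiedSite], min_shared: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson r of log2 SR between replicates over shared sites.

    Returns a tidy frame (replicate_a, replicate_b, r, n_shared); pairs
    with fewer than ``min_shared`` shared sites get r = NaN rather than a
    silent 0.  SRs of 0 (light channel absent) are excluded from the log
    transform.
    """
    by_rep: dict[str, dict[tuple[str, int], float]] = {}
    for s in sites:
        for rep, sr in s.sr_per_replicate.items():
            if sr > 0:
                by_rep.setdefault(rep, {})[
                    (s.protein_id, s.residue_number)
                ] = math.log2(sr)
    reps = sorted(by_rep)
    if len(reps) < 2:
        raise ValueError("replicate_correlation needs >= 2 replicates")
    records = []
    for a, b in itertools.combinations(reps, 2):
        shared = sorted(set(by_rep[a]) & set(by_rep[b]))
        if len(shared) < min_shared:
            r = float("nan")
        else:
            xa = [by_rep[a][k] for k in shared]
            xb = [by_rep[b][k] for k in shared]
            r = float(stats.pearsonr(xa, xb).statistic)
        records.append(
            {"replicate_a": a, "replicate_b": b, "r": r,
             "n_shared": len(shared)}
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Sites TSV

def sites_to_frame(sites: Sequence[QuantifiedSite]) -> pd.DataFrame:
    reps = sorted({r for s in sites for r in s.sr_per_replicate})
    records = []
    for s in sites:
        rec = {
            "protein_id": s.protein_id,
            "residue_number": s.residue_number,
            "residue_type": s.residue_type,
            "domain_name": s.domain_name,
        }
        for rep in reps:
            rec[f"sr_{rep}"] = s.sr_per_replicate.get(rep, float("nan"))
        rec.update(
            best_score=s.best_score,
            max_abs_ppm=s.max_abs_ppm,
            pass_overall=s.pass_overall,
        )
        records.append(rec)
    return pd.DataFrame(records)


def write_sites_tsv(
    sites: Sequence[QuantifiedSite], path: Union[str, Path]
) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)
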