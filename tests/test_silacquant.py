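"""SILAC ratios, filter semantics, target-decoy FDR, and QC checks."""

import math

import numpy as np
import pytest

from pocketmap.peptides import PeptideEvidence
from pocketmap.seqmodel import ProteinRecord
from pocketmap.silacquant import (
    ControlCheck,
    FilterConfig,
    QuantifiedSite,
    aggregate_sites,
    apply_filters,
    control_channel_check,
    fdr_passing_proteins,
    protein_fdr,
    replicate_correlation,
    silac_ratio,
    sites_to_frame,
)


def evidence_row(protein_id="P1", peptide="YAK", offset=0, light=1200.0,
                 heavy=100.0, score=800.0, rep="rep1", decoy=False,
                 observed_mass=None, mod_mass=0.0):
    from pocketmap.peptides import theoretical_mass

    if observed_mass is None:
        observed_mass = theoretical_mass(peptide, mod_mass)
    return PeptideEvidence(
        peptide_sequence=peptide,
        protein_id=protein_id,
        mod_offset=offset,
        mod_residue=peptide[offset],
        mod_mass=mod_mass,
        light_intensity=light,
        heavy_intensity=heavy,
        score=score,
        observed_mass=observed_mass,
        charge=2,
        replicate_id=rep,
        is_decoy=decoy,
    )


class TestSilacRatio:
    @pytest.mark.parametrize(
        "light, heavy, expected",
        [
            (1000.0, 1000.0, 1.0),
            (1200.0, 100.0, 12.0),  # 12 < cap, passes SR > 5
            (500.0, 0.0, 20.0),  # heavy-missing singleton -> cap
            (0.0, 500.0, 0.0),
            (50000.0, 100.0, 20.0),  # capped
        ],
    )
    def test_ratio_and_cap_conventions(self, light, heavy, expected):
        assert silac_ratio(light, heavy, cap=20.0) == expected

    def test_unit_ratio_for_equal_channels(self, rng):
        for x in rng.uniform(1e-3, 1e8, size=50):
            assert silac_ratio(x, x) == 1.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            silac_ratio(-1.0, 5.0)


class TestAggregateSites:
    def test_intensity_sum_rollup_within_replicate(self):
        protein = {"P1": ProteinRecord("P1", "MKYAK")}
        rows = [
            evidence_row(light=600.0, heavy=50.0),
            evidence_row(light=400.0, heavy=50.0),
        ]
        sites = aggregate_sites(rows, protein)
        assert len(sites) == 1
        assert sites[0].sr_per_replicate == {"rep1": 10.0}  # 1000/100
        assert sites[0].residue_number == 3
        assert sites[0].best_score == 800.0

    def test_single_row_equals_its_own_ratio(self):
        protein = {"P1": ProteinRecord("P1", "MKYAK")}
        sites = aggregate_sites([evidence_row()], protein)
        assert sites[0].sr_per_replicate == {"rep1": 12.0}
        assert sites[0].n_replicates_detected == 1

    def test_decoy_rows_never_become_sites(self):
        protein = {"P1": ProteinRecord("P1", "MKYAK")}
        assert aggregate_sites([evidence_row(decoy=True)], protein) == []

    def test_unlocalizable_rows_dropped_not_guessed(self, caplog):
        protein = {"P1": ProteinRecord("P1", "AYAAYA")}
        rows = [evidence_row(peptide="AYA", offset=1)]
        with caplog.at_level("WARNING"):
            assert aggregate_sites(rows, protein) == []
        assert "ambiguous" in caplog.text

    def test_empty_input_gives_empty_output(self):
        assert aggregate_sites([], {}) == []

    def test_domain_assignment_from_annotations(self, toy_protein):
        rows = [evidence_row(protein_id="TOY1", peptide="YAK", offset=0)]
        sites = aggregate_sites(rows, {"TOY1": toy_protein})
        assert sites[0].domain_name == "C1A"  # residue 3 in C1A [2,6]


class TestProteinFdr:
    def test_direct_counts(self):
        assert protein_fdr([600.0] * 100, [], 500.0) == 0.0
        assert protein_fdr([600.0] * 100, [550.0, 560.0], 500.0) == 0.02

    def test_passing_set_excludes_low_q_proteins(self):
        targets = {"A": 800.0, "B": 810.0, "C": 820.0, "D": 830.0,
                   "E": 600.0, "F": 499.0}
        decoys = [700.0] * 30
        passing = fdr_passing_proteins(targets, decoys, 0.01)
        assert passing == {"A", "B", "C", "D"}

    def test_no_decoys_passes_everything(self):
        targets = {"A": 10.0, "B": 20.0}
        assert fdr_passing_proteins(targets, [], 0.01) == {"A", "B"}


def make_site(pid="P1", resnum=3, restype="Y", sr=(12.0,), score=800.0,
              ppm=1.0):
    return QuantifiedSite(
        protein_id=pid,
        residue_number=resnum,
        residue_type=restype,
        sr_per_replicate={f"rep{i+1}": v for i, v in enumerate(sr)},
        best_score=score,
        max_abs_ppm=ppm,
        n_replicates_detected=len(sr),
    )


class TestApplyFilters:
    def _decoys(self, n=30, score=700.0):
        return [
            evidence_row(protein_id=f"rev_{i}", score=score, decoy=True)
            for i in range(n)
        ]

    def test_toy_table_exactly_one_survivor(self):
        """Six sites: five each violate exactly one criterion, one clean."""
        sites = [
            make_site("PA", 3),                      # clean
            make_site("PB", 3, sr=(5.0,)),           # SR boundary: fails
            make_site("PC", 3, sr=(2.0,)),           # unenriched
            make_site("PD", 3, score=499.9),         # score fail
            make_site("PE", 3, ppm=5.1),             # mass accuracy fail
            make_site("PF", 3, score=600.0),         # FDR fail (below decoys)
        ]
        # 30 decoy proteins scoring 700 sit between PF (600) and the rest
        # (800): only proteins scoring >= 800 survive FDR <= 1%
        out = apply_filters(sites, self._decoys(), FilterConfig())
        survivors = [s for s in out if s.pass_overall]
        assert len(survivors) == 1
        assert survivors[0].protein_id == "PA"
        # each intended violation is the site's only failing flag
        # (PD additionally fails FDR since its score is below the decoys)
        assert not out[1].passes["sr"]
        assert not out[2].passes["sr"]
        assert not out[3].passes["score"]
        assert not out[4].passes["ppm"]
        assert not out[5].passes["fdr"]

    @pytest.mark.parametrize(
        "kw, flag, expected",
        [
            ({"sr": (5.0,)}, "sr", False),     # SR 5.0 exactly: strict >
            ({"sr": (5.01,)}, "sr", True),
            ({"score": 500.0}, "score", True),  # score 500 exactly: >=
            ({"ppm": 5.0}, "ppm", True),        # ppm 5.0 exactly: <=
        ],
    )
    def test_boundary_semantics(self, kw, flag, expected):
        out = apply_filters([make_site(**kw)], [], FilterConfig())
        assert out[0].passes[flag] is expected

    def test_any_replicate_sr_suffices(self):
        out = apply_filters(
            [make_site(sr=(1.0, 1.2, 8.0))], [], FilterConfig()
        )
        assert out[0].passes["sr"]

    def test_empty_site_list(self):
        assert apply_filters([], [], FilterConfig()) == []

    def test_tightening_thresholds_never_adds_survivors(self, rng):
        sites = [
            make_site(
                pid=f"P{i}",
                resnum=3,
                sr=tuple(rng.lognormal(1.5, 1.0, size=3)),
                score=float(rng.uniform(300, 1000)),
                ppm=float(abs(rng.normal(0, 3))),
            )
            for i in range(60)
        ]
        decoys = self._decoys(10, score=float(rng.uniform(400, 600)))

        def survivors(config):
            out = apply_filters([s for s in sites], decoys, config)
            return {s.protein_id for s in out if s.pass_overall}

        base = survivors(FilterConfig())
        for tighter in [
            FilterConfig(sr_min=8.0),
            FilterConfig(score_min=700.0),
            FilterConfig(ppm_max=2.0),
            FilterConfig(protein_fdr_max=0.001),
        ]:
            assert survivors(tighter) <= base


class TestControlCheck:
    def test_all_unit_ratios_unflagged(self):
        sites = [make_site(pid=f"P{i}", sr=(1.0,)) for i in range(5)]
        check = control_channel_check(sites)
        assert check.flagged == ()
        assert check.median_sr == 1.0

    def test_threefold_deviation_flagged(self):
        sites = [make_site(pid="P1", sr=(1.0,)),
                 make_site(pid="P2", sr=(3.0,))]
        check = control_channel_check(sites)
        assert check.flagged == (("P2", 3),)

    def test_lognormal_noise_rarely_flagged(self, rng):
        # sigma = 0.2 on the natural log: |log SR| > log 2 is a 3.5-sigma event
        sites = [
            make_site(pid=f"P{i}", sr=tuple(rng.lognormal(0.0, 0.2, 3)))
            for i in range(200)
        ]
        check = control_channel_check(sites)
        assert len(check.flagged) / len(sites) < 0.05
        assert 0.9 <= check.median_sr <= 1.1


class TestReplicateCorrelation:
    def test_duplicated_replicate_is_perfectly_correlated(self):
        sites = [
            make_site(pid=f"P{i}", sr=(v, v))
            for i, v in enumerate([2.0, 4.0, 8.0, 16.0])
        ]
        df = replicate_correlation(sites)
        assert df.loc[0, "r"] == pytest.approx(1.0)

    def test_reversed_ranks_anticorrelated(self):
        sites = [
            make_site(pid=f"P{i}", sr=(2.0 ** a, 2.0 ** b))
            for i, (a, b) in enumerate([(1, 3), (2, 2), (3, 1)])
        ]
        df = replicate_correlation(sites)
        assert df.loc[0, "r"] == pytest.approx(-1.0)

    def test_five_site_hand_table(self):
        # log2 SRs rep1 = [0,1,2,3,4], rep2 = [1,0,2,4,3]
        # deviations: [-2,-1,0,1,2] and [-1,-2,0,2,1]; r = 8/10 = 0.8
        pairs = [(0, 1), (1, 0), (2, 2), (3, 4), (4, 3)]
        sites = [
            make_site(pid=f"P{i}", sr=(2.0 ** a, 2.0 ** b))
            for i, (a, b) in enumerate(pairs)
        ]
        df = replicate_correlation(sites)
        assert df.loc[0, "r"] == pytest.approx(0.8)
        assert df.loc[0, "n_shared"] == 5

    def test_insufficient_overlap_flagged_not_zero(self):
        sites = [make_site(pid=f"P{i}", sr=(2.0, 2.0)) for i in range(2)]
        df = replicate_correlation(sites, min_shared=3)
        assert math.isnan(df.loc[0, "r"])
        with pytest.raises(ValueError):
            replicate_correlation([make_site(sr=(2.0,))])


def test_sites_frame_has_per_replicate_columns():
    frame = sites_to_frame([make_site(sr=(1.0, 6.0))])
    assert {"sr_rep1", "sr_rep2", "pass_overall"} <= set(frame.columns)
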