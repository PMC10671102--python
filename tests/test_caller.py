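"""Thresholded haplotype calling: per-position rules, reporting rules,
coverage classification and QC metrics."""

import numpy as np
import pytest

from mitopop.caller import (
    BASES,
    CallConfig,
    PileupTable,
    PositionCall,
    average_vf,
    call_haplotype,
    call_position,
    call_with_fallback,
    classify_coverage,
    flag_mixture,
)
from mitopop.refmodel import HOMOPOLYMER_REGIONS, synthetic_reference
from mitopop.synthetic_data import (
    LHP_ANCHORS,
    SampleTruth,
    SimConfig,
    simulate_pileup,
    simulate_population,
)


def uniform_pileup(reference, depth=1000, sample_id="s"):
    """All-reference pileup at constant depth."""
    L = reference.length
    counts = np.zeros((L, 4), dtype=np.int64)
    idx = np.array([BASES.index(b) for b in reference.bases])
    counts[np.arange(L), idx] = depth
    return PileupTable(
        sample_id=sample_id,
        depth=np.full(L, depth, dtype=np.int64),
        base_counts=counts,
        del_counts=np.zeros(L, dtype=np.int64),
    )


def set_counts(pileup, pos, **base_counts):
    row = np.zeros(4, dtype=np.int64)
    for base, n in base_counts.items():
        row[BASES.index(base)] = n
    pileup.base_counts[pos - 1] = row
    pileup.depth[pos - 1] = row.sum()


class TestCallPosition:
    def test_reported_php_at_hotspot_edge_frequency(self):
        # two alleles above 10%: G at 15.3%, A at 84.7% -> symbol R
        cfg = CallConfig()
        call = call_position(
            13_105, 1000, [847, 0, 153, 0], 0, "G", cfg
        )
        assert call.observed == "R"
        assert call.is_php
        assert call.minor_fraction == pytest.approx(0.153)

    def test_unanimous_reference_base(self):
        call = call_position(100, 500, [500, 0, 0, 0], 0, "A", CallConfig())
        assert call.observed == "A" and not call.is_php

    def test_three_alleles_counts_toward_mixture(self):
        call = call_position(100, 1000, [400, 350, 250, 0], 0, "A", CallConfig())
        assert call.n_alleles_above_threshold == 3
        assert call.observed == "A" and not call.is_php

    def test_minor_below_threshold_not_called(self):
        call = call_position(100, 1000, [905, 95, 0, 0], 0, "A", CallConfig())
        assert call.observed == "A" and not call.is_php

    def test_zero_depth_uncovered(self):
        call = call_position(100, 0, [0, 0, 0, 0], 0, "A", CallConfig())
        assert call.uncovered

    def test_deletion_called_at_threshold(self):
        call = call_position(100, 1000, [50, 0, 0, 0], 950, "A", CallConfig())
        assert call.deletion_called and call.deletion_major
        assert call.major_fraction == pytest.approx(0.95)

    def test_threshold_sharpness_against_bruteforce(self):
        """Biallelic position is a PHP iff the minor fraction >= min_vf."""
        cfg = CallConfig()
        for depth in (100, 1000):
            for minor in range(0, depth // 2 + 1, max(1, depth // 50)):
                call = call_position(
                    100, depth, [depth - minor, minor, 0, 0], 0, "A", cfg
                )
                assert call.is_php == (minor / depth >= cfg.min_vf)


class TestClassifyCoverage:
    @pytest.mark.parametrize(
        "n_below,expected",
        [(0, "complete"), (1, "nearly_complete"), (4, "nearly_complete"),
         (5, "incomplete"), (100, "incomplete")],
    )
    def test_boundaries(self, n_below, expected):
        assert classify_coverage(n_below, CallConfig()) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_coverage(-1, CallConfig())


class TestCallHaplotype:
    def test_all_reference_pileup(self, reference):
        result = call_haplotype(uniform_pileup(reference), reference)
        assert result.haplotype.variants == ()
        assert result.coverage_class == "complete"
        assert not result.mixture_flag

    def test_printed_haplotype_recovered_from_clean_pileup(
        self, adapted_reference, u5b1b1a
    ):
        """Zero-noise simulation of the published U5b1b1a haplotype calls
        back the identical substitution set plus the major length molecule
        in the HVS2 C-stretch."""
        cfg = SimConfig(n_samples=1, seed=0, error_rate=0.0,
                        depth_range=(1500, 1500))
        subs = [
            v for v in u5b1b1a.variants if v.kind == "substitution"
        ]
        truth = SampleTruth(
            sample_id="u5", clade=0,
            haplotype=u5b1b1a.with_(variants=tuple(
                subs
                + [v for v in u5b1b1a.variants
                   if v.kind == "insertion" and v.insertion_index == 1
                   and v.position == 315]
            )),
            lhp={"HVS2-C": {"C": 0.6, "": 0.25, "CC": 0.15}},
            mean_depth=1500.0,
        )
        pileup = simulate_pileup(truth, adapted_reference, cfg)
        result = call_haplotype(pileup, adapted_reference)
        assert result.haplotype.substitutions == u5b1b1a.substitutions
        ins = [v.token() for v in result.haplotype.variants if v.is_indel]
        assert ins == ["315.1C"]
        assert result.haplotype.lhp_regions == {"HVS2-C"}

    def test_low_coverage_fallback_rescues_sample(self, reference):
        pileup = uniform_pileup(reference, depth=1000)
        for pos in (10, 20, 30, 40, 50):
            set_counts(pileup, pos, **{reference.base_at(pos): 80})
        cfg = CallConfig()
        strict = call_haplotype(pileup, reference, cfg)
        assert strict.coverage_class == "incomplete"
        assert strict.n_positions_below_min_depth == 5
        rescued = call_haplotype(
            pileup, reference, cfg, min_depth=cfg.fallback_min_depth
        )
        assert rescued.coverage_class == "complete"
        assert call_with_fallback(pileup, reference, cfg).coverage_class == (
            "complete"
        )

    def test_suppressed_php_positions_report_major_base(self, reference):
        pileup = uniform_pileup(reference)
        ref302 = reference.base_at(302)
        other = "A" if ref302 != "A" else "G"
        set_counts(pileup, 302, **{ref302: 700, other: 300})
        result = call_haplotype(pileup, reference)
        assert 302 not in result.haplotype.substitutions

    def test_numt_hotspot_php_flagged_and_excluded(self, reference):
        pileup = uniform_pileup(reference)
        ref = reference.base_at(12_600)
        alt = "A" if ref != "A" else "G"
        set_counts(pileup, 12_600, **{ref: 850, alt: 150})
        result = call_haplotype(pileup, reference)
        assert result.numt_flags == [(12_600, alt, pytest.approx(0.15))]
        assert 12_600 not in result.haplotype.substitutions
        # same evidence outside the hotspot is an ordinary PHP
        set_counts(pileup, 12_600, **{ref: 1000})
        ref2 = reference.base_at(5_000)
        alt2 = "A" if ref2 != "A" else "G"
        set_counts(pileup, 5_000, **{ref2: 850, alt2: 150})
        result = call_haplotype(pileup, reference)
        assert 5_000 in result.haplotype.substitutions
        assert not result.numt_flags

    def test_lhp_major_molecule_rule(self, reference):
        pileup = uniform_pileup(reference, depth=1000)
        anchor = LHP_ANCHORS["HVS1-C"]
        pileup.insertions[anchor] = {"C": 550, "CC": 150}
        result = call_haplotype(pileup, reference)
        assert "HVS1-C" in result.haplotype.lhp_regions
        ins = [v.token() for v in result.haplotype.variants if v.is_indel]
        assert ins == [f"{anchor}.1C"]

    def test_lhp_not_flagged_without_length_variation(self, reference):
        pileup = uniform_pileup(reference, depth=1000)
        anchor = LHP_ANCHORS["HVS1-C"]
        pileup.insertions[anchor] = {"C": 950}  # near-fixed single molecule
        result = call_haplotype(pileup, reference)
        assert result.haplotype.lhp_regions == frozenset()
        ins = [v.token() for v in result.haplotype.variants if v.is_indel]
        assert ins == [f"{anchor}.1C"]

    def test_insertion_outside_homopolymer(self, reference):
        pileup = uniform_pileup(reference, depth=1000)
        pileup.insertions[2_000] = {"CT": 980}
        result = call_haplotype(pileup, reference)
        ins = [v.token() for v in result.haplotype.variants if v.is_indel]
        assert ins == ["2000.1C", "2000.2T"]

    def test_deletion_run(self, reference):
        pileup = uniform_pileup(reference, depth=1000)
        for pos in range(8_281, 8_290):
            pileup.base_counts[pos - 1] = 0
            pileup.del_counts[pos - 1] = 995
            pileup.base_counts[pos - 1, 0] = 5
            pileup.depth[pos - 1] = 1000
        result = call_haplotype(pileup, reference)
        dels = [v.position for v in result.haplotype.variants
                if v.kind == "deletion"]
        assert dels == list(range(8_281, 8_290))
        assert not result.mixture_flag

    def test_depth_scaling_invariance(self, reference):
        """Calls depend on frequencies, not absolute counts."""
        pileup = uniform_pileup(reference, depth=500)
        ref = reference.base_at(4_000)
        alt = "C" if ref != "C" else "T"
        set_counts(pileup, 4_000, **{ref: 400, alt: 100})
        r1 = call_haplotype(pileup, reference)
        scaled = PileupTable(
            sample_id="s", depth=pileup.depth * 7,
            base_counts=pileup.base_counts * 7,
            del_counts=pileup.del_counts * 7,
        )
        r2 = call_haplotype(scaled, reference)
        assert r1.haplotype.variants == r2.haplotype.variants

    def test_pileup_size_mismatch_rejected(self, reference):
        short = PileupTable(
            sample_id="s", depth=np.full(100, 50),
            base_counts=np.zeros((100, 4)), del_counts=np.zeros(100),
        )
        with pytest.raises(ValueError, match="positions"):
            call_haplotype(short, reference)


class TestMetrics:
    def test_average_vf_arithmetic_mean(self):
        calls = [
            PositionCall(i, "A", "G", f, "G")
            for i, f in enumerate([0.99, 1.00, 0.995], start=1)
        ]
        assert average_vf(calls, exclude_hp=False) == pytest.approx(0.995)

    def test_php_depresses_avg_vf_all_only(self, reference):
        pileup = uniform_pileup(reference)
        ref = reference.base_at(6_000)
        alt = "A" if ref != "A" else "G"
        set_counts(pileup, 6_000, **{ref: 500, alt: 500})
        ref2 = reference.base_at(7_000)
        alt2 = "A" if ref2 != "A" else "G"
        set_counts(pileup, 7_000, **{alt2: 1000})
        result = call_haplotype(pileup, reference)
        assert result.avg_vf_all < result.avg_vf_excluding_hp

    def test_clean_simulation_exceeds_98_percent(self, reference):
        cfg = SimConfig(n_samples=3, seed=8, depth_range=(1000, 3000))
        _, truth = simulate_population(cfg, reference)
        rng = np.random.default_rng(3)
        for s in truth.samples:
            pileup = simulate_pileup(s, reference, cfg, rng)
            result = call_haplotype(pileup, reference)
            assert result.avg_vf_excluding_hp > 0.98

    @pytest.mark.parametrize(
        "n_mixed,avg_vf,expected",
        [(1, 0.996, False), (10, 0.999, True), (0, None, False),
         (0, 0.95, True), (3, 0.99, False), (4, 0.99, True)],
    )
    def test_flag_mixture_rule(self, n_mixed, avg_vf, expected):
        assert flag_mixture(n_mixed, avg_vf, CallConfig()) is expected


class TestPileupIO:
    def test_tsv_roundtrip(self, reference, tmp_path):
        pileup = uniform_pileup(reference, depth=200)
        pileup.insertions[315] = {"C": 120, "CC": 40}
        path = tmp_path / "s.tsv"
        pileup.to_tsv(path)
        back = PileupTable.from_tsv(path)
        assert np.array_equal(back.depth, pileup.depth)
        assert np.array_equal(back.base_counts, pileup.base_counts)
        assert back.insertions == pileup.insertions

    def test_missing_positions_rejected(self, tmp_path, reference):
        pileup = uniform_pileup(reference, depth=200)
        df = pileup.to_frame().drop(index=[4, 5])
        path = tmp_path / "gap.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing positions"):
            PileupTable.from_tsv(path)
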