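from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from crassrecruit import (
    FilterConfig, anir, best_hit, detection_call, filter_hits,
    horizontal_coverage, normalize_abundance, query_coverage,
    recruitment_profile, recruitment_table, sequencing_depth,
)
from crassrecruit.io import ALN_COLUMNS

from conftest import make_hits, oracle_anir, oracle_coverage, oracle_depth


def _hit(qseqid="r1", sseqid="g1", pident=97.0, bitscore=180.0, qstart=1,
         qend=100, qlen=100, sstart=1, send=100, evalue=1e-30, length=100):
    return pd.DataFrame(
        [[qseqid, sseqid, pident, length, 0, 0, qstart, qend, sstart, send,
          evalue, bitscore]],
        columns=ALN_COLUMNS,
    ).assign(qlen=qlen)


class TestQueryCoverageAndFilter:
    @pytest.mark.parametrize(
        "qstart,qend,qlen,expected",
        [(1, 70, 100, 0.70), (1, 100, 100, 1.0), (31, 100, 100, 0.70)],
    )
    def test_query_coverage_values(self, qstart, qend, qlen, expected):
        df = _hit(qstart=qstart, qend=qend, qlen=qlen)
        assert query_coverage(df).iloc[0] == pytest.approx(expected)

    def test_coverage_boundary_inclusive_evalue_boundary_inclusive(self):
        cfg = FilterConfig()
        at = _hit(qstart=1, qend=70, evalue=0.1)
        below = _hit(qstart=1, qend=69)
        assert len(filter_hits(at, cfg)) == 1
        assert len(filter_hits(below, cfg)) == 0

    def test_high_evalue_dropped_and_order_preserved(self):
        df = pd.concat(
            [_hit("r1"), _hit("r2", evalue=0.5), _hit("r3")], ignore_index=True
        )
        out = filter_hits(df, FilterConfig())
        assert list(out["qseqid"]) == ["r1", "r3"]

    def test_empty_input(self):
        df = _hit().iloc[0:0]
        assert len(filter_hits(df, FilterConfig())) == 0

    def test_missing_qlen_raises(self):
        df = _hit().drop(columns="qlen")
        with pytest.raises(ValueError, match="qlen"):
            query_coverage(df)


class TestBestHit:
    def test_highest_bitscore_wins(self):
        df = pd.concat(
            [_hit("r1", "g1", bitscore=50), _hit("r1", "g2", bitscore=60)],
            ignore_index=True,
        )
        assert best_hit(df)["sseqid"].tolist() == ["g2"]

    def test_single_hit_unchanged(self):
        df = _hit("r1", "g1")
        pd.testing.assert_frame_equal(best_hit(df), df)

    def test_tie_break_stable_under_any_input_order(self):
        # same bitscore: higher pident wins; still tied: smaller sseqid
        rows = [
            _hit("r1", "g2", pident=98.0, bitscore=60),
            _hit("r1", "g1", pident=97.0, bitscore=60),
            _hit("r1", "g3", pident=98.0, bitscore=60),
            _hit("r1", "g0", pident=95.0, bitscore=59),
        ]
        expected = None
        for perm in permutations(range(4)):
            df = pd.concat([rows[i] for i in perm], ignore_index=True)
            kept = best_hit(df)[["qseqid", "sseqid", "pident"]].reset_index(drop=True)
            if expected is None:
                expected = kept
            pd.testing.assert_frame_equal(kept, expected)
        assert expected["sseqid"].iloc[0] == "g2"


class TestDepthAndAbundance:
    def test_two_hits_on_kilobase_genome(self):
        hits = make_hits([("r1", "g", 100, 200, 1, 100),
                          ("r2", "g", 100, 200, 301, 400)])
        assert sequencing_depth(hits, 1000) == pytest.approx(0.2)

    def test_no_hits_zero_depth(self):
        assert sequencing_depth(make_hits([]), 1000) == 0.0

    def test_depth_matches_per_position_pileup(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(1, 9901, size=50)
        hits = make_hits([(f"r{i}", "g", 100, 200, s, s + 199)
                          for i, s in enumerate(starts)], qlen=200)
        assert sequencing_depth(hits, 10000) == pytest.approx(
            oracle_depth(hits, 10000)
        )
        # 50 hits x 200 bp on 10 kb -> exactly 1x
        assert sequencing_depth(hits, 10000) == pytest.approx(1.0)

    def test_normalization_arithmetic(self):
        # 0.2x depth, 1e6 bp dataset (0.001 Gbp), 1 kb genome -> 200
        assert normalize_abundance(0.2, 10**6, 1000) == pytest.approx(200.0)
        assert normalize_abundance(0.0, 10**6, 1000) == 0.0
        assert normalize_abundance(0.2, 2 * 10**6, 1000) == pytest.approx(100.0)

    def test_plain_sd_per_gbp_flag(self):
        assert normalize_abundance(0.2, 10**6, 1000, per_kbp=False) == pytest.approx(200.0)
        assert normalize_abundance(0.2, 10**6, 2000, per_kbp=False) == pytest.approx(200.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sequencing_depth(make_hits([]), 0)
        with pytest.raises(ValueError):
            normalize_abundance(0.2, 0, 1000)


class TestAnir:
    def test_equal_lengths_both_weightings(self):
        hits = make_hits([("r1", "g", 96.0, 1, 1, 100),
                          ("r2", "g", 98.0, 1, 1, 100),
                          ("r3", "g", 100.0, 1, 1, 100)])
        assert anir(hits, "length") == pytest.approx(98.0)
        assert anir(hits, "uniform") == pytest.approx(98.0)

    def test_single_hit_identity(self):
        assert anir(make_hits([("r1", "g", 97.3, 1, 1, 100)])) == pytest.approx(97.3)

    def test_length_weighting(self):
        hits = make_hits([("r1", "g", 90.0, 1, 1, 100),
                          ("r2", "g", 100.0, 1, 1, 300)], qlen=300)
        assert anir(hits, "length") == pytest.approx(97.5)  # (90*100+100*300)/400
        assert anir(hits, "uniform") == pytest.approx(95.0)

    def test_no_hits_is_nan(self):
        assert np.isnan(anir(make_hits([])))


class TestHorizontalCoverage:
    def test_overlap_counted_once(self):
        hits = make_hits([("r1", "g", 100, 1, 1, 30), ("r2", "g", 100, 1, 21, 50)])
        assert horizontal_coverage(hits, 100) == pytest.approx(50.0)

    def test_tiling_gives_full_coverage(self):
        hits = make_hits([(f"r{i}", "g", 100, 1, 1 + 100 * i, 100 * (i + 1))
                          for i in range(10)])
        assert horizontal_coverage(hits, 1000) == pytest.approx(100.0)

    def test_matches_boolean_mask_oracle(self):
        rng = np.random.default_rng(42)
        starts = rng.integers(1, 9901, size=200)
        hits = make_hits([(f"r{i}", "g", 100, 1, s, s + 99)
                          for i, s in enumerate(starts)])
        assert horizontal_coverage(hits, 10000) == pytest.approx(
            oracle_coverage(hits, 10000)
        )

    def test_minus_strand_intervals_normalized(self):
        hits = make_hits([("r1", "g", 100, 1, 30, 1)])
        assert horizontal_coverage(hits, 100) == pytest.approx(30.0)

    def test_interval_beyond_genome_rejected(self):
        hits = make_hits([("r1", "g", 100, 1, 95, 120)])
        with pytest.raises(ValueError, match="unwrap"):
            horizontal_coverage(hits, 100)


class TestProfileAndDetection:
    def test_window_boundaries(self):
        hits = make_hits([("r1", "g", 94.9, 1, 1, 100),
                          ("r2", "g", 95.0, 1, 201, 300)])
        prof = recruitment_profile(hits, 1000, (95.0, 100.0))
        assert len(prof) == 1
        assert prof["position"].iloc[0] == pytest.approx(250.5)

    def test_profiling_has_no_side_effects_on_metrics(self):
        hits = make_hits([("r1", "g", 90.0, 1, 1, 100),
                          ("r2", "g", 99.0, 1, 101, 200)])
        before = (sequencing_depth(hits, 1000), anir(hits))
        recruitment_profile(hits, 1000, (95.0, 100.0))
        after = (sequencing_depth(hits, 1000), anir(hits))
        assert before == after
        assert before[0] == pytest.approx(0.2)  # both hits still counted

    @pytest.mark.parametrize(
        "value,expected", [(0.000009, False), (0.00001, True), (3.7, True)]
    )
    def test_detection_boundary_inclusive(self, value, expected):
        assert detection_call(value, FilterConfig()) is expected


class TestRecruitmentTable:
    def _study(self):
        aln = pd.concat(
            [
                make_hits([("v1_r1", "gA", 97.0, 180, 1, 100),
                           ("v1_r2", "gA", 99.0, 190, 201, 300),
                           ("v1_r3", "gB", 95.0, 170, 51, 150)]).assign(virome="v1"),
                make_hits([("v2_r1", "gA", 96.0, 175, 501, 600)]).assign(virome="v2"),
            ],
            ignore_index=True,
        )
        meta = pd.DataFrame({
            "virome_name": ["v1", "v2"],
            "pool": ["human_gut", "human_gut"],
            "country": ["Spain", "Spain"],
            "dataset_bp": [10**6, 10**6],
            "sample_kind": ["VLP", "VLP"],
        })
        return aln, meta

    def test_row_per_genome_per_group_with_zero_fill(self):
        aln, meta = self._study()
        out = recruitment_table(aln, {"gA": 1000, "gB": 1000, "gC": 1000}, meta)
        assert len(out) == 6  # 3 genomes x 2 viromes
        zero = out[(out["genome_id"] == "gC") & (out["virome"] == "v1")].iloc[0]
        assert zero["n_reads"] == 0 and zero["depth_SD"] == 0.0
        assert not zero["detected"] and np.isnan(zero["anir"])

    def test_pool_metrics_equal_concatenated_recomputation(self):
        aln, meta = self._study()
        lengths = {"gA": 1000, "gB": 1000}
        pooled = recruitment_table(aln, lengths, meta, group_by="pool")
        row = pooled[(pooled["genome_id"] == "gA")].iloc[0]
        # oracle: concatenate hits of both viromes, dataset_bp summed
        merged = best_hit(filter_hits(aln, FilterConfig()), by=["virome", "qseqid"])
        ghits = merged[merged["sseqid"] == "gA"]
        assert row["depth_SD"] == pytest.approx(oracle_depth(ghits, 1000))
        assert row["norm_abundance"] == pytest.approx(
            normalize_abundance(oracle_depth(ghits, 1000), 2 * 10**6, 1000)
        )
        assert row["anir"] == pytest.approx(oracle_anir(ghits))

    def test_raising_coverage_cutoff_never_increases_metrics(self):
        aln, meta = self._study()
        aln.loc[0, "qend"] = 75  # partial-coverage hit
        lengths = {"gA": 1000, "gB": 1000}
        loose = recruitment_table(aln, lengths, meta,
                                  FilterConfig(min_query_coverage=0.5))
        strict = recruitment_table(aln, lengths, meta,
                                   FilterConfig(min_query_coverage=0.9))
        for col in ("n_reads", "depth_SD", "horizontal_coverage"):
            assert (strict[col].to_numpy() <= loose[col].to_numpy() + 1e-12).all()
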