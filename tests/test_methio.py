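"""Methylation I/O, QC, CpG enumeration, aggregation and binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncatspipe import methio
from ncatspipe.methio import (
    DomainError,
    FormatError,
    MethFilterParams,
    MethylationBins,
    QCParams,
    ReadRecord,
    RegionWindow,
    aggregate_site_frequency,
    classify_methylation_level,
    enumerate_cpgs,
    mean_read_quality,
    qc_filter_reads,
    region_mean,
)


def make_calls(llrs_by_site, chrom="chr", num_motifs=1, sequence="NNNNNCGNNNNN"):
    rows = []
    for start, llrs in llrs_by_site.items():
        for i, llr in enumerate(llrs):
            rows.append(
                {
                    "chromosome": chrom,
                    "strand": "+",
                    "start": start,
                    "end": start,
                    "read_name": f"r{start}_{i}",
                    "log_lik_ratio": float(llr),
                    "log_lik_methylated": llr / 2,
                    "log_lik_unmethylated": -llr / 2,
                    "num_calling_strands": 1,
                    "num_motifs": num_motifs,
                    "sequence": sequence,
                }
            )
    return pd.DataFrame(rows, columns=methio.METH_CALL_COLUMNS)


class TestQCFilter:
    def test_short_read_rejected_regardless_of_quality(self):
        read = ReadRecord("a", "A" * 150, tuple([40] * 150))
        passing, counts = qc_filter_reads([read])
        assert not passing and counts.failed_length == 1

    def test_good_read_accepted(self):
        read = ReadRecord("b", "A" * 300, tuple([20] * 300))
        passing, _ = qc_filter_reads([read])
        assert len(passing) == 1

    def test_quality_threshold_is_strict(self):
        # all bases exactly Q8: mean quality == 8, "higher than" fails
        read = ReadRecord("c", "A" * 300, tuple([8] * 300))
        passing, counts = qc_filter_reads([read])
        assert not passing and counts.failed_quality == 1

    def test_mean_quality_uses_error_probabilities(self):
        # mean of error probs, not of Phred scores: one terrible base drags
        # the mean far more than the arithmetic mean of Q would suggest
        q = [40] * 99 + [0]
        assert mean_read_quality(q) < 20 < np.mean(q)

    def test_length_threshold_is_strict(self):
        read = ReadRecord("d", "A" * 200, tuple([30] * 200))
        passing, _ = qc_filter_reads([read], QCParams(min_length=200))
        assert not passing


class TestEnumerateCpgs:
    def test_hand_scan(self):
        df = enumerate_cpgs("ACGTCG")
        assert df["start"].tolist() == [1, 4]
        assert df["panel_index"].tolist() == [1, 2]

    def test_no_cg_empty(self):
        assert enumerate_cpgs("ATATATA").empty

    def test_standard_has_52_sites(self, standard52):
        df = enumerate_cpgs(standard52.sequence)
        assert len(df) == 52
        assert df["start"].tolist() == list(standard52.cpg_starts)

    def test_case_insensitive_and_n_never_matches(self):
        df = enumerate_cpgs("acgtNCgNG")
        assert df["start"].tolist() == [1, 5]

    def test_interval_restricts_and_renumbers(self):
        df = enumerate_cpgs("CGACGACG", interval=(2, 8))
        assert df["start"].tolist() == [3, 6]
        assert df["panel_index"].tolist() == [1, 2]

    def test_interval_out_of_bounds(self):
        with pytest.raises(ValueError):
            enumerate_cpgs("ACGT", interval=(0, 10))


class TestAggregateSiteFrequency:
    def test_all_confident_methylated(self):
        calls = make_calls({100: [5.0] * 10})
        out = aggregate_site_frequency(calls)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["called_sites"] == 10
        assert row["methylated_frequency"] == 1.0

    def test_nine_qualifying_dropped(self):
        calls = make_calls({100: [5.0] * 9})
        assert aggregate_site_frequency(calls).empty

    def test_ambiguous_calls_excluded_from_both_sides(self):
        calls = make_calls({7: [3.0] * 8 + [-3.0] * 8 + [1.0] * 4})
        out = aggregate_site_frequency(calls)
        row = out.iloc[0]
        assert row["called_sites"] == 16
        assert row["methylated_frequency"] == 0.5

    def test_empty_input(self):
        out = aggregate_site_frequency(pd.DataFrame(columns=methio.METH_CALL_COLUMNS))
        assert out.empty

    def test_motif_group_contributes_to_every_motif(self):
        # one call covering 2 CpGs (offsets 5 and 9 in its context)
        calls = make_calls(
            {50: [4.0] * 10}, num_motifs=2, sequence="AAAAACGTACGAA"
        )
        out = aggregate_site_frequency(calls)
        assert out["start"].tolist() == [50, 54]
        assert (out["called_sites"] == 10).all()
        assert (out["methylated_frequency"] == 1.0).all()

    def test_motif_group_with_bad_context_raises(self):
        calls = make_calls({50: [4.0] * 10}, num_motifs=3, sequence="AAACGAAA")
        with pytest.raises(FormatError):
            aggregate_site_frequency(calls)

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=4),  # site id
                st.floats(min_value=-8, max_value=8, allow_nan=False),
            ),
            min_size=0,
            max_size=120,
        ),
        st.floats(min_value=0.5, max_value=5.0),
        st.integers(min_value=1, max_value=12),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_oracle_equivalence(self, items, cutoff, min_reads):
        """Aggregation equals a brute-force per-site count for any table."""
        sites = {}
        for sid, llr in items:
            sites.setdefault(sid * 10, []).append(llr)
        calls = make_calls(sites)
        params = MethFilterParams(llr_cutoff=cutoff, min_reads=min_reads)
        out = aggregate_site_frequency(calls, params)
        expected = {}
        for start, llrs in sites.items():
            qual = [x for x in llrs if abs(x) >= cutoff]
            meth = [x for x in qual if x >= cutoff]
            if len(qual) >= min_reads:
                expected[start] = (len(qual), len(meth))
        got = {
            int(r["start"]): (int(r["called_sites"]), int(r["called_sites_methylated"]))
            for _, r in out.iterrows()
        }
        assert got == expected

    @given(
        st.lists(
            st.floats(min_value=-8, max_value=8, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_raising_cutoff_never_adds_qualifying_reads(self, llrs):
        calls = make_calls({0: llrs})
        lo = aggregate_site_frequency(calls, MethFilterParams(2.0, 1))
        hi = aggregate_site_frequency(calls, MethFilterParams(3.0, 1))
        n_lo = int(lo["called_sites"].iloc[0]) if len(lo) else 0
        n_hi = int(hi["called_sites"].iloc[0]) if len(hi) else 0
        assert n_hi <= n_lo

    def test_frequencies_in_unit_interval(self, small_pools):
        pool0, pool100 = small_pools
        for pool in (pool0, pool100):
            out = aggregate_site_frequency(pool)
            assert ((out["methylated_frequency"] >= 0) & (out["methylated_frequency"] <= 1)).all()


class TestRegionMean:
    def _annotated(self, freqs_by_index):
        return pd.DataFrame(
            {
                "panel_index": list(freqs_by_index),
                "methylated_frequency": list(freqs_by_index.values()),
            }
        )

    def test_dmr2_window_spans_12_indices(self):
        assert RegionWindow("DMR2", 70, 81).width == 12

    def test_constant_window(self):
        freq = self._annotated({i: 0.4 for i in range(70, 82)})
        res = region_mean(freq, RegionWindow("DMR2", 70, 81))
        assert res.mean == pytest.approx(0.4)
        assert res.n_sites_used == 12

    def test_split_window_mean(self):
        freqs = {i: 0.2 for i in range(70, 76)} | {i: 0.6 for i in range(76, 82)}
        res = region_mean(self._annotated(freqs), RegionWindow("DMR2", 70, 81))
        assert res.mean == pytest.approx(0.4)

    def test_empty_window_is_undefined_not_zero(self):
        res = region_mean(self._annotated({1: 0.5}), RegionWindow("DMR2", 70, 81))
        assert res.mean is None and not res.defined and res.n_sites_used == 0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            RegionWindow("w", 5, 4)


class TestClassifyMethylation:
    @pytest.mark.parametrize(
        "freq,expected",
        [
            (0.0, "not_detected"),
            (0.099, "not_detected"),
            (0.10, "low"),
            (0.20, "low"),
            (0.30, "low"),
            (0.301, "detected"),
            (0.38, "detected"),
            (1.0, "detected"),
        ],
    )
    def test_bins(self, freq, expected):
        assert classify_methylation_level(freq) == expected

    def test_boundaries_configurable(self):
        bins = MethylationBins(low_inclusive=False)
        assert classify_methylation_level(0.10, bins) == "not_detected"

    def test_domain_error(self):
        with pytest.raises(DomainError):
            classify_methylation_level(1.5)

    @given(st.floats(min_value=0, max_value=1))
    @settings(derandomize=True, max_examples=60)
    def test_total_and_order_preserving(self, f):
        order = {c: i for i, c in enumerate(methio.METHYLATION_CATEGORIES)}
        a = classify_methylation_level(f)
        assert a in order
        if f <= 0.995:
            b = classify_methylation_level(min(1.0, f + 0.005))
            assert order[a] <= order[b]


class TestTSVDialects:
    def test_call_roundtrip(self, tmp_path):
        calls = make_calls({1: [2.5, -3.0], 11: [4.0]})
        path = tmp_path / "calls.tsv"
        methio.write_meth_calls(calls, path)
        back = methio.read_meth_calls(path)
        pd.testing.assert_frame_equal(calls.reset_index(drop=True), back)

    def test_freq_roundtrip(self, tmp_path):
        calls = make_calls({1: [5.0] * 10, 11: [-5.0] * 12})
        freq = aggregate_site_frequency(calls)
        path = tmp_path / "freq.tsv"
        methio.write_meth_freq(freq, path)
        back = methio.read_meth_freq(path)
        pd.testing.assert_frame_equal(freq.reset_index(drop=True), back)

    def test_strict_mode_reports_first_bad_line(self, tmp_path):
        calls = make_calls({1: [5.0] * 5})
        path = tmp_path / "calls.tsv"
        methio.write_meth_calls(calls, path)
        lines = path.read_text().splitlines()
        lines.insert(3, "garbage\twith\tthree")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError) as exc:
            methio.read_meth_calls(path)
        assert exc.value.line == 4

    def test_permissive_mode_skips_bad_lines(self, tmp_path):
        calls = make_calls({1: [5.0] * 10})
        path = tmp_path / "calls.tsv"
        methio.write_meth_calls(calls, path)
        lines = path.read_text().splitlines()
        lines.insert(3, "bad\tline")
        lines.insert(7, "another\tbad\tone")
        path.write_text("\n".join(lines) + "\n")
        back = methio.read_meth_calls(path, strict=False)
        assert len(back) == 10

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text("not\ta\theader\n")
        with pytest.raises(FormatError):
            methio.read_meth_calls(path)
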