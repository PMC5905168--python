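"""Ploidy estimation, calling rules and the 50-SNP breakpoint filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumourprint.calling import (
    PloidyCall,
    call_alterations,
    combined_label,
    estimate_ploidy,
    filter_small_segments,
)
from tumourprint.karyotype import Chromosome, Karyotype

from conftest import states_frame


def full_cover_states(karyotype, cn=2, major=1, n_probes=1000):
    rows = [
        (c.name, 0, c.length, n_probes, cn, major) for c in karyotype.chromosomes
    ]
    return states_frame(rows)


class TestPloidy:
    def test_all_diploid_female(self, karyotype):
        states = full_cover_states(karyotype, cn=2, major=1)
        call = estimate_ploidy(states, karyotype)
        assert call.chromosome_number == 46
        assert call.ploidy_class == "near-diploid"

    def test_all_tetraploid(self, karyotype):
        states = full_cover_states(karyotype, cn=4, major=2)
        call = estimate_ploidy(states, karyotype)
        assert call.chromosome_number == 92
        assert call.ploidy_class == "near-tetraploid"

    def test_mixed_threshold_case(self, karyotype):
        """12 chromosomes at cn 4 and 11 at cn 3: 81 >= 69, tetraploid."""
        rows = []
        for i, c in enumerate(karyotype.chromosomes):
            cn = 4 if i < 12 else 3
            rows.append((c.name, 0, c.length, 1000, cn, cn - 1))
        call = estimate_ploidy(states_frame(rows), karyotype)
        assert call.chromosome_number == 81
        assert call.ploidy_class == "near-tetraploid"

    def test_uncovered_pericentric_window_names_chromosome(self, toy_karyotype):
        rows = [("chrA", 0, 100_000_000, 1000, 2, 1),
                ("chrB", 0, 10_000_000, 100, 2, 1)]  # chrB centromere at 30 Mb
        with pytest.raises(ValueError, match="chrB"):
            estimate_ploidy(states_frame(rows), toy_karyotype)


class TestCallingRules:
    @pytest.mark.parametrize("ploidy_class", ["near-diploid", "near-tetraploid"])
    def test_exhaustive_truth_table(self, ploidy_class):
        """The calling rules as a pure function of (cn, minor, class), checked
        over the complete state grid cn 0..8, minor 0..4."""
        rows = []
        expected = []
        pos = 0
        for cn in range(9):
            for minor in range(0, min(cn // 2, 4) + 1):
                major = cn - minor
                rows.append(("chr1", pos, pos + 10, 100, cn, major))
                pos += 10
                if ploidy_class == "near-diploid":
                    loss, gain = cn <= 1, cn >= 4
                else:
                    loss, gain = cn <= 2, cn >= 6
                loh = minor == 0 and cn >= 1
                expected.append((loss, gain, loh))
        ploidy = PloidyCall(
            chromosome_number=46 if ploidy_class == "near-diploid" else 92,
            ploidy_class=ploidy_class, n_chromosomes=23,
        )
        calls = call_alterations(states_frame(rows), ploidy)
        got = list(zip(calls["loss"], calls["gain"], calls["loh"]))
        assert got == expected
        for r, (loss, gain, loh) in zip(calls.itertuples(), expected):
            assert r.call == combined_label(loss, gain, loh)

    def test_fig2_legend_examples(self):
        diploid = PloidyCall(46, "near-diploid", 23)
        tetra = PloidyCall(92, "near-tetraploid", 23)
        s = states_frame([("chr1", 0, 10, 100, 1, 1)])
        assert call_alterations(s, diploid).iloc[0]["call"] == "Loss/LOH"
        s = states_frame([("chr1", 0, 10, 100, 4, 4)])
        assert call_alterations(s, tetra).iloc[0]["call"] == "LOH"
        s = states_frame([("chr1", 0, 10, 100, 3, 2)])
        assert call_alterations(s, diploid).iloc[0]["call"] == "none"
        # cn 0 is loss only, never LOH
        s = states_frame([("chr1", 0, 10, 100, 0, 0)])
        assert call_alterations(s, diploid).iloc[0]["call"] == "Loss"


class TestFilter:
    def test_identical_flanks_merge_to_one(self):
        states = states_frame([
            ("chr1", 0, 200, 200, 2, 1),
            ("chr1", 200, 230, 30, 3, 2),
            ("chr1", 230, 430, 200, 2, 1),
        ])
        out = filter_small_segments(states, min_snps=50)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 430
        assert out.iloc[0]["n_probes"] == 430

    def test_all_large_identity(self):
        states = states_frame([
            ("chr1", 0, 100, 100, 2, 1),
            ("chr1", 100, 200, 100, 3, 2),
        ])
        out = filter_small_segments(states, min_snps=50)
        pd.testing.assert_frame_equal(out, states)

    def test_merge_prefers_nearer_state(self):
        """A 30-probe (3,2) segment between (3,3) and (1,1) flanks joins the
        left (nearer) neighbour."""
        states = states_frame([
            ("chr1", 0, 100, 100, 3, 3),
            ("chr1", 100, 130, 30, 3, 2),
            ("chr1", 130, 230, 100, 1, 1),
        ])
        out = filter_small_segments(states, min_snps=50)
        assert len(out) == 2
        assert out.iloc[0]["end"] == 130
        assert out.iloc[0]["cn"] == 3 and out.iloc[0]["major"] == 3

    def test_tie_goes_left(self):
        states = states_frame([
            ("chr1", 0, 100, 100, 2, 1),
            ("chr1", 100, 130, 30, 3, 2),
            ("chr1", 130, 230, 100, 4, 3),
        ])
        out = filter_small_segments(states, min_snps=50)
        assert out.iloc[0]["end"] == 130  # equidistant: merged left

    def test_whole_chromosome_subthreshold_collapses_to_modal(self):
        states = states_frame([
            ("chr1", 0, 10, 10, 2, 1),
            ("chr1", 10, 40, 30, 3, 2),
            ("chr1", 40, 45, 5, 2, 2),
        ])
        out = filter_small_segments(states, min_snps=50)
        assert len(out) == 1
        assert out.iloc[0]["cn"] == 3 and out.iloc[0]["major"] == 2

    @given(st.lists(
        st.tuples(st.integers(1, 300),  # n_probes
                  st.integers(0, 5),    # cn
                  st.integers(0, 5)),   # minor candidate
        min_size=1, max_size=12,
    ))
    @settings(max_examples=50, deadline=None)
    def test_filter_preserves_cover_and_reduces_breakpoints(self, raw):
        pos = 0
        rows = []
        for n, cn, minor in raw:
            minor = min(minor, cn // 2)
            rows.append(("chr1", pos, pos + n * 10, n, cn, cn - minor))
            pos += n * 10
        states = states_frame(rows)
        out = filter_small_segments(states, min_snps=50)
        assert out["start"].iloc[0] == 0
        assert out["end"].iloc[-1] == pos
        assert (out["start"].to_numpy()[1:] == out["end"].to_numpy()[:-1]).all()
        assert len(out) <= len(states)
        assert out["n_probes"].sum() == states["n_probes"].sum()
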