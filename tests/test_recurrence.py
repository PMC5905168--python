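"""Segment grid, recurrence detection, Jaccard/Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from tumourprint.recurrence import (
    alteration_matrix,
    build_grid,
    cluster_tumours,
    jaccard_distances,
    linkage_to_newick,
    locus_frequency,
    profile_concordance,
    project_calls,
    recurrent_regions,
)


def calls_frame(rows):
    """rows: (chrom, start, end, loss, gain, loh)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "loss", "gain", "loh"])
    from tumourprint.calling import combined_label

    df["call"] = [combined_label(l, g, h)
                  for l, g, h in zip(df["loss"], df["gain"], df["loh"])]
    return df


def brute_force_atoms(profiles):
    """Oracle: per chromosome, sort all breakpoints and pair them up."""
    cuts = {}
    for p in profiles.values():
        for r in p.itertuples():
            cuts.setdefault(r.chrom, set()).update((r.start, r.end))
    out = []
    for chrom, s in cuts.items():
        b = sorted(s)
        out.extend((chrom, a, c) for a, c in zip(b[:-1], b[1:]))
    return out


class TestGrid:
    def test_single_tumour_grid_is_own_segmentation(self):
        p = calls_frame([("chr1", 0, 50, True, False, True),
                         ("chr1", 50, 100, False, False, False)])
        grid = build_grid({"T1": p})
        assert list(map(tuple, grid.to_numpy())) == [("chr1", 0, 50),
                                                     ("chr1", 50, 100)]

    def test_interleaved_breakpoints_split_at_all_four(self):
        a = calls_frame([("chr1", 10, 30, True, False, False),
                         ("chr1", 30, 90, False, False, False)])
        b = calls_frame([("chr1", 10, 50, False, True, False),
                         ("chr1", 50, 90, False, False, False)])
        grid = build_grid({"A": a, "B": b})
        expected = set(brute_force_atoms({"A": a, "B": b}))
        assert set(map(tuple, grid.to_numpy())) == expected
        assert sorted(grid["start"]) == [10, 30, 50]

    def test_identical_segmentations_unchanged(self):
        p = calls_frame([("chr1", 0, 40, True, False, False),
                         ("chr1", 40, 100, False, False, False)])
        grid = build_grid({"A": p, "B": p.copy()})
        assert len(grid) == 2

    def test_overlapping_profile_rejected(self):
        p = calls_frame([("chr1", 0, 60, True, False, False),
                         ("chr1", 50, 100, False, False, False)])
        with pytest.raises(ValueError, match="overlapping"):
            build_grid({"A": p})

    def test_projection_lossless(self):
        """Reconstructing calls from the matrix reproduces the input."""
        a = calls_frame([("chr1", 0, 30, True, False, True),
                         ("chr1", 30, 100, False, True, False)])
        b = calls_frame([("chr1", 0, 60, False, False, True),
                         ("chr1", 60, 100, False, False, False)])
        grid = build_grid({"A": a, "B": b})
        proj = project_calls(a, grid)
        for r in proj.itertuples():
            src = a[(a["start"] <= r.start) & (a["end"] >= r.end)].iloc[0]
            assert (r.loss, r.gain, r.loh) == \
                (src["loss"], src["gain"], src["loh"])


class TestRecurrentRegions:
    def make_matrix(self, lost_counts, n=10):
        """One chromosome, len(lost_counts) atoms, given loss counts."""
        profiles = {}
        k = len(lost_counts)
        for i in range(n):
            rows = []
            for j, c in enumerate(lost_counts):
                rows.append(("chr1", j * 10, (j + 1) * 10, i < c, False, False))
            profiles[f"T{i:02d}"] = calls_frame(rows)
        return alteration_matrix(profiles)

    def test_boundary_inclusive_at_70pct(self):
        m = self.make_matrix([7])
        regions = [r for r in recurrent_regions(m, 0.70) if r.kind == "loss"]
        assert len(regions) == 1
        assert regions[0].frequency == pytest.approx(0.7)
        assert regions[0].n_altered == 7

    def test_below_threshold_not_reported(self):
        m = self.make_matrix([6])
        assert not [r for r in recurrent_regions(m, 0.70) if r.kind == "loss"]

    def test_interrupted_run_splits_into_two_regions(self):
        m = self.make_matrix([8, 3, 9])
        regions = [r for r in recurrent_regions(m, 0.70) if r.kind == "loss"]
        assert len(regions) == 2
        assert [(r.start, r.end) for r in regions] == [(0, 10), (20, 30)]

    def test_threshold_monotonicity(self):
        m = self.make_matrix([10, 7, 10, 8])
        strict = {(r.chrom, r.start, r.end, r.kind)
                  for r in recurrent_regions(m, 1.0)}
        loose_cover = [r for r in recurrent_regions(m, 0.70)]
        for c, s, e, k in strict:
            assert any(r.chrom == c and r.start <= s and r.end >= e
                       and r.kind == k for r in loose_cover)

    def test_locus_frequency_counts_all_tumours(self):
        m_profiles = {}
        for i in range(10):
            m_profiles[f"T{i}"] = calls_frame(
                [("chr1", 0, 100, i < 7, False, False)]
            )
        freq, n_alt, n_tot = locus_frequency(m_profiles, ("chr1", 0, 100))
        assert (freq, n_alt, n_tot) == (0.7, 7, 10)


class TestClustering:
    def test_jaccard_examples(self):
        m = pd.DataFrame(
            [[1, 1, 1, 0, 0], [0, 1, 1, 1, 0], [0, 0, 0, 0, 1],
             [1, 1, 1, 0, 0]],
            index=["A", "B", "C", "A2"],
        )
        d = squareform(jaccard_distances(m))
        assert d[0, 1] == pytest.approx(0.5)  # {1,2,3} vs {2,3,4}
        assert d[0, 2] == pytest.approx(1.0)  # disjoint
        assert d[0, 3] == pytest.approx(0.0)  # identical

    def test_all_zero_row_conventions(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 0]], index=["A", "B", "C"])
        d = squareform(jaccard_distances(m))
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_brute_force_distance_oracle(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 2, size=(6, 12)),
                         index=[f"T{i}" for i in range(6)])
        d = jaccard_distances(m)
        # oracle: set arithmetic per pair
        sets = [set(np.flatnonzero(row)) for row in m.to_numpy()]
        k = 0
        for i in range(6):
            for j in range(i + 1, 6):
                u = sets[i] | sets[j]
                expect = 1 - len(sets[i] & sets[j]) / len(u) if u else 0.0
                assert d[k] == pytest.approx(expect)
                k += 1

    def test_ward_linkage_deterministic_newick(self):
        m = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 1, 0], [0, 0, 1, 1], [0, 1, 1, 1]],
            index=["T1", "T2", "T3", "T4"],
        )
        z1, l1 = cluster_tumours(m)
        z2, l2 = cluster_tumours(m)
        assert np.array_equal(z1, z2) and l1 == l2
        nwk = linkage_to_newick(z1, l1)
        assert nwk.endswith(";")
        for label in l1:
            assert label in nwk

    def test_cluster_needs_two_tumours_and_signal(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_tumours(pd.DataFrame([[1]], index=["A"]))
        with pytest.raises(ValueError, match="nonzero"):
            cluster_tumours(pd.DataFrame([[0], [0]], index=["A", "B"]))


class TestConcordance:
    LOCI = {"L1": ("chr1", 0, 100)}

    def test_identical_profiles_concordant(self):
        p = calls_frame([("chr1", 0, 100, True, False, True)])
        assert profile_concordance(p, p.copy(), self.LOCI) == {"L1": "concordant"}

    def test_loss_vs_neutral_discordant(self):
        a = calls_frame([("chr1", 0, 100, True, False, False)])
        b = calls_frame([("chr1", 0, 100, False, False, False)])
        assert profile_concordance(a, b, self.LOCI) == {"L1": "discordant"}

    def test_60pct_agreement_concordant(self):
        """Same label over 60% of the locus passes the >= 50% rule."""
        a = calls_frame([("chr1", 0, 60, True, False, True),
                         ("chr1", 60, 100, False, False, False)])
        b = calls_frame([("chr1", 0, 70, True, False, True),
                         ("chr1", 70, 100, False, True, False)])
        assert profile_concordance(a, b, self.LOCI) == {"L1": "concordant"}

    def test_uncovered_locus_flagged(self):
        a = calls_frame([("chr1", 0, 30, True, False, False)])
        b = calls_frame([("chr1", 0, 100, True, False, False)])
        assert profile_concordance(a, b, self.LOCI) == {"L1": "uncovered"}
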