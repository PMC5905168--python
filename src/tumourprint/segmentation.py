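"""Joint change-point segmentation of LRR and mirrored-BAF probe tracks.

Binary segmentation per chromosome on two standardized tracks: the LRR of
every probe and the mirrored BAF (max(baf, 1 - baf)) of germline-heterozygous
probes.  A split is accepted when it reduces the within-segment sum of
squares by more than a BIC-style penalty; the procedure is deterministic and
needs no tuning beyond the penalty multiplier.

Segment boundaries are placed at midpoints between flanking probes so each
chromosome is covered contiguously.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["segment_probes", "segment_cost"]

DEFAULT_MIN_PROBES = 10
DEFAULT_PENALTY_MULT = 6.0  # per-changepoint penalty = mult * log(n) * n_tracks


def segment_cost(lrr: np.ndarray, mbaf: np.ndarray, het: np.ndarray) -> float:
    """Within-segment cost: SSE of lrr plus SSE of mirrored BAF over het probes.

    This is the same objective the segmenter minimises; exposed for the
    exhaustive-scan oracle used in testing.
    """
    cost = float(np.sum((lrr - lrr.mean()) ** 2)) if lrr.size else 0.0
    mb = mbaf[het]
    if mb.size:
        cost += float(np.sum((mb - mb.mean()) ** 2))
    return cost


def _sse_interval(csum: np.ndarray, csum2: np.ndarray, i: int, j: int) -> float:
    """SSE of x[i:j] from cumulative sums (csum[k] = sum of x[:k])."""
    n = j - i
    if n <= 0:
        return 0.0
    s = csum[j] - csum[i]
    s2 = csum2[j] - csum2[i]
    return float(s2 - s * s / n)


def _best_split(
    cl: np.ndarray, cl2: np.ndarray, cb: np.ndarray, cb2: np.ndarray,
    ch: np.ndarray, i: int, j: int, min_probes: int,
) -> tuple[int, float]:
    """Best split point k in (i, j) and the resulting cost reduction."""
    ks = np.arange(i + min_probes, j - min_probes + 1)
    if ks.size == 0:
        return -1, 0.0
    base = _sse_interval(cl, cl2, i, j)
    nh = ch[j] - ch[i]
    if nh > 0:
        s = cb[j] - cb[i]
        s2 = cb2[j] - cb2[i]
        base += float(s2 - s * s / nh)

    # vectorised left/right SSEs for every candidate split
    nl = ks - i
    nr = j - ks
    sl = cl[ks] - cl[i]
    sl2 = cl2[ks] - cl2[i]
    sr = cl[j] - cl[ks]
    sr2 = cl2[j] - cl2[ks]
    cost = (sl2 - sl**2 / nl) + (sr2 - sr**2 / nr)
    nhl = ch[ks] - ch[i]
    nhr = ch[j] - ch[ks]
    bl = cb[ks] - cb[i]
    bl2 = cb2[ks] - cb2[i]
    br = cb[j] - cb[ks]
    br2 = cb2[j] - cb2[ks]
    cost = cost + np.where(nhl > 0, bl2 - bl**2 / np.maximum(nhl, 1), 0.0)
    cost = cost + np.where(nhr > 0, br2 - br**2 / np.maximum(nhr, 1), 0.0)
    best = int(np.argmin(cost))
    return int(ks[best]), base - float(cost[best])


def _interval_sse(cl, cl2, cb, cb2, ch, i, j) -> float:
    """Joint SSE (lrr + het mbaf) of interval [i, j)."""
    out = _sse_interval(cl, cl2, i, j)
    nh = ch[j] - ch[i]
    if nh > 0:
        s = cb[j] - cb[i]
        s2 = cb2[j] - cb2[i]
        out += float(s2 - s * s / nh)
    return out


def _best_bump(
    cl, cl2, cb, cb2, ch, i: int, j: int, min_probes: int
) -> tuple[int, int, float]:
    """Best interior window [t, t+w) to carve out of [i, j) as its own
    segment, over a sqrt(2)-spaced ladder of window widths.

    A single split cannot detect a short event embedded in a long segment
    (the means of the two halves barely move); carving a window and testing
    window-vs-rest at multiple scales can.  Returns (t, w, gain).
    """
    n = j - i
    base = _interval_sse(cl, cl2, cb, cb2, ch, i, j)
    tot_l = cl[j] - cl[i]
    tot_l2 = cl2[j] - cl2[i]
    tot_b = cb[j] - cb[i]
    tot_b2 = cb2[j] - cb2[i]
    tot_h = ch[j] - ch[i]
    best = (-1, -1, 0.0)
    w = min_probes
    while w <= n - 2 * min_probes:
        ts = np.arange(i + min_probes, j - w - min_probes + 1)
        if ts.size:
            sw = cl[ts + w] - cl[ts]
            sw2 = cl2[ts + w] - cl2[ts]
            sse_win = sw2 - sw**2 / w
            rs = tot_l - sw
            rs2 = tot_l2 - sw2
            sse_rest = rs2 - rs**2 / (n - w)
            hw = ch[ts + w] - ch[ts]
            bw = cb[ts + w] - cb[ts]
            bw2 = cb2[ts + w] - cb2[ts]
            sse_win = sse_win + np.where(hw > 0, bw2 - bw**2 / np.maximum(hw, 1), 0.0)
            hr = tot_h - hw
            br = tot_b - bw
            br2 = tot_b2 - bw2
            sse_rest = sse_rest + np.where(hr > 0, br2 - br**2 / np.maximum(hr, 1), 0.0)
            gain = base - (sse_win + sse_rest)
            k = int(np.argmax(gain))
            if gain[k] > best[2]:
                best = (int(ts[k]), w, float(gain[k]))
        w = max(w + 1, int(round(w * 1.4142)))
    return best


def _segment_chromosome(
    lrr: np.ndarray, mbaf: np.ndarray, het: np.ndarray,
    min_probes: int, penalty: float,
) -> list[int]:
    """Return sorted interior changepoint indices (probe index boundaries)."""
    n = lrr.size
    cl = np.concatenate([[0.0], np.cumsum(lrr)])
    cl2 = np.concatenate([[0.0], np.cumsum(lrr**2)])
    mb = np.where(het, mbaf, 0.0)
    cb = np.concatenate([[0.0], np.cumsum(mb)])
    cb2 = np.concatenate([[0.0], np.cumsum(mb**2)])
    ch = np.concatenate([[0], np.cumsum(het.astype(np.int64))])

    changepoints: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 * min_probes:
            continue
        k, gain1 = _best_split(cl, cl2, cb, cb2, ch, i, j, min_probes)
        t, w, gain2 = _best_bump(cl, cl2, cb, cb2, ch, i, j, min_probes)
        # carving inserts two changepoints, hence pays the penalty twice
        if max(gain1 - penalty, gain2 - 2 * penalty) <= 0:
            continue
        if gain1 - penalty >= gain2 - 2 * penalty:
            changepoints.append(k)
            stack.append((i, k))
            stack.append((k, j))
        else:
            changepoints.extend([t, t + w])
            stack.append((i, t))
            stack.append((t, t + w))
            stack.append((t + w, j))
    return sorted(changepoints)


def segment_probes(
    probes: pd.DataFrame,
    min_probes: int = DEFAULT_MIN_PROBES,
    penalty_mult: float = DEFAULT_PENALTY_MULT,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Segment one tumour's probes into constant-state intervals.

    Parameters
    ----------
    probes : DataFrame with columns chrom, pos, baf, lrr, genotype,
        sorted by (chrom, pos).  A single sample only.
    min_probes : minimum probes per emitted segment.
    penalty_mult : multiplier of the log(n) per-changepoint penalty on the
        standardized tracks.
    chrom_lengths : optional {chrom: length}; when given, the first/last
        segment of each chromosome is extended to the chromosome ends.

    Returns
    -------
    DataFrame with columns chrom, start, end, n_probes, n_het, mean_lrr,
    mirrored_baf (NaN when a segment has no heterozygous probes).
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    required = {"chrom", "pos", "baf", "lrr", "genotype"}
    missing = required - set(probes.columns)
    if missing:
        raise ValueError(f"probes missing columns: {sorted(missing)}")
    if "sample" in probes.columns and probes["sample"].nunique() > 1:
        raise ValueError("segment_probes expects a single sample")

    # global standardization so both tracks weigh comparably
    lrr_all = probes["lrr"].to_numpy(float)
    het_all = (probes["genotype"] == "AB").to_numpy()
    baf_all = probes["baf"].to_numpy(float)
    mbaf_all = np.maximum(baf_all, 1 - baf_all)
    s_l = lrr_all.std() or 1.0
    s_b = mbaf_all[het_all].std() if het_all.any() else 1.0
    s_b = s_b or 1.0

    rows = []
    for chrom, grp in probes.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"probes on {chrom} not sorted by position")
        lrr = grp["lrr"].to_numpy(float) / s_l
        het = (grp["genotype"] == "AB").to_numpy()
        baf = grp["baf"].to_numpy(float)
        mbaf = np.maximum(baf, 1 - baf) / s_b
        n = pos.size
        penalty = penalty_mult * np.log(max(n, 2)) * 2
        cps = _segment_chromosome(lrr, mbaf, het, min_probes, penalty)
        bounds = [0] + cps + [n]
        # genomic boundaries at midpoints between flanking probes
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        for a, b in zip(bounds[:-1], bounds[1:]):
            start = int(pos[0]) if a == 0 else int((pos[a - 1] + pos[a]) // 2)
            end = int(pos[-1]) + 1 if b == n else int((pos[b - 1] + pos[b]) // 2)
            if length is not None:
                if a == 0:
                    start = 0
                if b == n:
                    end = int(length)
            seg_het = het[a:b]
            seg_baf = baf[a:b][seg_het]
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_probes": int(b - a),
                    "n_het": int(seg_het.sum()),
                    "mean_lrr": float(grp["lrr"].to_numpy(float)[a:b].mean()),
                    "mirrored_baf": float(np.maximum(seg_baf, 1 - seg_baf).mean())
                    if seg_baf.size
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
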