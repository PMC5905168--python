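"""Cohort segment grid, alteration matrix, recurrent regions, clustering.

All tumour profiles are projected onto the atomic segment grid formed by the
union of every profile's breakpoints; the binary tumour x (atom, kind)
alteration matrix then drives recurrent-region detection (maximal runs of
atoms altered in at least 70% of tumours by default) and hierarchical
clustering with the Jaccard distance on altered-column sets and Ward
linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

__all__ = [
    "build_grid",
    "project_calls",
    "alteration_matrix",
    "RecurrentRegion",
    "recurrent_regions",
    "locus_frequency",
    "jaccard_distances",
    "cluster_tumours",
    "linkage_to_newick",
    "profile_concordance",
]

ALTERATION_KINDS = ("loss", "gain", "loh", "loss_loh")
RECURRENCE_THRESHOLD = 0.70


def _check_profile(calls: pd.DataFrame) -> None:
    for chrom, grp in calls.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments within one profile on {chrom}")


def build_grid(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Atomic intervals from the union of all tumours' breakpoints.

    Returns a DataFrame (chrom, start, end) ordered by chromosome appearance
    then position.  Projection of any input profile onto the grid is
    lossless because every profile breakpoint is a grid boundary.
    """
    if not profiles:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    chrom_order: list[str] = []
    cuts: dict[str, set[int]] = {}
    for calls in profiles.values():
        _check_profile(calls)
        for r in calls.itertuples():
            if r.chrom not in cuts:
                cuts[r.chrom] = set()
                chrom_order.append(r.chrom)
            cuts[r.chrom].add(int(r.start))
            cuts[r.chrom].add(int(r.end))
    rows = []
    for chrom in chrom_order:
        bounds = sorted(cuts[chrom])
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append({"chrom": chrom, "start": a, "end": b})
    return pd.DataFrame(rows)


def project_calls(calls: pd.DataFrame, grid: pd.DataFrame) -> pd.DataFrame:
    """Project one tumour's calls onto grid atoms (one row per atom)."""
    out = grid.copy()
    loss = np.zeros(len(grid), dtype=bool)
    gain = np.zeros(len(grid), dtype=bool)
    loh = np.zeros(len(grid), dtype=bool)
    covered = np.zeros(len(grid), dtype=bool)
    mid = ((grid["start"] + grid["end"]) // 2).to_numpy()
    for chrom, grp in calls.groupby("chrom", sort=False):
        sel = (grid["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        idx = np.searchsorted(starts, mid[sel], side="right") - 1
        valid = idx >= 0
        ends = g["end"].to_numpy()
        valid &= mid[sel] < ends[np.clip(idx, 0, None)]
        tgt = np.flatnonzero(sel)
        loss[tgt[valid]] = g["loss"].to_numpy()[idx[valid]]
        gain[tgt[valid]] = g["gain"].to_numpy()[idx[valid]]
        loh[tgt[valid]] = g["loh"].to_numpy()[idx[valid]]
        covered[tgt[valid]] = True
    out["loss"] = loss
    out["gain"] = gain
    out["loh"] = loh
    out["loss_loh"] = loss & loh
    out["covered"] = covered
    return out


def alteration_matrix(profiles: dict[str, pd.DataFrame],
                      grid: pd.DataFrame | None = None) -> pd.DataFrame:
    """Binary tumours x (atom, kind) matrix.

    Columns are a MultiIndex (chrom, start, end, kind) in deterministic grid
    order; rows are tumour ids in sorted order.
    """
    if grid is None:
        grid = build_grid(profiles)
    data = {}
    for tid in sorted(profiles):
        proj = project_calls(profiles[tid], grid)
        row = np.concatenate([proj[k].to_numpy(int) for k in ALTERATION_KINDS])
        data[tid] = row
    cols = pd.MultiIndex.from_tuples(
        [
            (r.chrom, int(r.start), int(r.end), kind)
            for kind in ALTERATION_KINDS
            for r in grid.itertuples()
        ],
        names=["chrom", "start", "end", "kind"],
    )
    mat = pd.DataFrame.from_dict(data, orient="index")
    mat.columns = cols
    return mat.sort_index()


@dataclass(frozen=True)
class RecurrentRegion:
    chrom: str
    start: int
    end: int
    kind: str
    frequency: float
    n_altered: int
    n_total: int


def recurrent_regions(
    matrix: pd.DataFrame, threshold: float = RECURRENCE_THRESHOLD
) -> list[RecurrentRegion]:
    """Maximal runs of consecutive atoms altered in >= threshold of tumours.

    Run frequency/n_altered are reported for the atom with the smallest
    frequency in the run (the run qualifies as a whole).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n_total = len(matrix)
    if n_total == 0:
        return []
    freq = matrix.mean(axis=0)
    counts = matrix.sum(axis=0)
    regions: list[RecurrentRegion] = []
    for kind in ALTERATION_KINDS:
        sub = freq.xs(kind, level="kind")
        csub = counts.xs(kind, level="kind")
        # iterate atoms in grid order, tracking runs per chromosome
        run: list[tuple[str, int, int, float, int]] = []

        def flush():
            if not run:
                return
            fmin = min(x[3] for x in run)
            cmin = min(x[4] for x in run)
            regions.append(
                RecurrentRegion(
                    chrom=run[0][0],
                    start=run[0][1],
                    end=run[-1][2],
                    kind=kind,
                    frequency=float(fmin),
                    n_altered=int(cmin),
                    n_total=n_total,
                )
            )
            run.clear()

        prev = None
        for (chrom, start, end), f in sub.items():
            c = csub[(chrom, start, end)]
            qualifies = f >= threshold
            if qualifies:
                if run and (chrom != prev[0] or start != prev[1]):
                    flush()
                run.append((chrom, start, end, float(f), int(c)))
                prev = (chrom, end)
            else:
                flush()
                prev = None
        flush()
    return regions


def locus_frequency(
    profiles: dict[str, pd.DataFrame],
    locus: tuple[str, int, int],
    kind: str = "loss",
    min_cover: float = 0.5,
) -> tuple[float, int, int]:
    """Fraction of tumours whose ``kind`` calls cover >= min_cover of a locus.

    Returns (frequency, n_altered, n_total); the denominator is all tumours.
    """
    chrom, lo, hi = locus
    n_alt = 0
    for tid, calls in profiles.items():
        seg = calls[(calls["chrom"] == chrom) & calls[kind]]
        cov = (np.minimum(seg["end"], hi) - np.maximum(seg["start"], lo)).clip(lower=0)
        if cov.sum() >= min_cover * (hi - lo):
            n_alt += 1
    n = len(profiles)
    return (n_alt / n if n else 0.0), n_alt, n


def jaccard_distances(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed pairwise Jaccard distances on altered-column sets.

    A tumour with an all-zero row is at distance 1 from any non-empty row;
    two all-zero rows are at distance 0.
    """
    x = matrix.to_numpy(bool)
    n = x.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.logical_and(x[i], x[j]).sum()
            union = np.logical_or(x[i], x[j]).sum()
            out.append(0.0 if union == 0 else 1.0 - inter / union)
    return np.asarray(out)


def cluster_tumours(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward-linkage hierarchical clustering on Jaccard distances.

    Returns (scipy linkage matrix, leaf labels in row order).  Rows are
    sorted by tumour id, which fixes leaf order deterministically.
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 tumours")
    if not matrix.to_numpy().any():
        raise ValueError("clustering needs at least one nonzero column")
    d = jaccard_distances(matrix)
    z = linkage(d, method="ward")
    return z, list(matrix.index)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(z, labels)
    return str(tree).strip()


def profile_concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    loci: dict[str, tuple[str, int, int]],
) -> dict[str, str]:
    """Per-locus concordance of the combined call label between two profiles.

    A locus is concordant iff both profiles assign the same combined label to
    >= 50% of its length; loci uncovered in either profile are flagged
    'uncovered' and not counted either way.
    """

    def majority_label(calls: pd.DataFrame, chrom: str, lo: int, hi: int) -> str | None:
        seg = calls[calls["chrom"] == chrom]
        cov = (np.minimum(seg["end"], hi) - np.maximum(seg["start"], lo)).clip(lower=0)
        total = cov.sum()
        if total < 0.5 * (hi - lo):
            return None
        lengths = cov.groupby(seg["call"]).sum()
        top = lengths.idxmax()
        if lengths[top] >= 0.5 * (hi - lo):
            return str(top)
        return "_mixed"

    out = {}
    for name, (chrom, lo, hi) in loci.items():
        la = majority_label(a, chrom, lo, hi)
        lb = majority_label(b, chrom, lo, hi)
        if la is None or lb is None:
            out[name] = "uncovered"
        elif la == lb and la != "_mixed":
            out[name] = "concordant"
        else:
            out[name] = "discordant"
    return out
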