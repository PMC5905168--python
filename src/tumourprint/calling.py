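"""Ploidy classification and ploidy-conditional alteration calling.

Chromosome number is estimated as the sum over chromosomes of the
probe-weighted modal copy number in a pericentric window (centromere
midpoint +/- 1 Mb by default); a tumour is near-tetraploid when that sum
reaches three times the number of chromosomes (the 2n/4n midpoint).

Calling rules are conditional on ploidy class:

==============  ==========  ==========
ploidy class    loss        gain
==============  ==========  ==========
near-diploid    cn <= 1     cn >= 4
near-tetraploid cn <= 2     cn >= 6
==============  ==========  ==========

LOH is ascribed to any segment with monoallelic content (minor = 0),
regardless of copy number; a cn-0 segment is labelled loss only.  Segments
with fewer than 50 probes are merged into a neighbour before calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .karyotype import Karyotype

__all__ = [
    "PloidyCall",
    "estimate_ploidy",
    "call_alterations",
    "filter_small_segments",
    "combined_label",
    "TETRAPLOID_FACTOR",
]

PERICENTRIC_HALF_WIDTH = 1_000_000  # bp
MIN_SNPS = 50
TETRAPLOID_FACTOR = 3  # near-tetraploid iff chromosome_number >= 3 * n_chrom


@dataclass(frozen=True)
class PloidyCall:
    chromosome_number: int
    ploidy_class: str  # {near-diploid, near-tetraploid}
    n_chromosomes: int

    def __post_init__(self) -> None:
        if self.chromosome_number < 0:
            raise ValueError("chromosome_number must be >= 0")


def estimate_ploidy(
    states: pd.DataFrame,
    karyotype: Karyotype,
    window: int = PERICENTRIC_HALF_WIDTH,
) -> PloidyCall:
    """Sum of pericentric modal copy numbers, classified against 3n.

    Raises a calling error naming any chromosome whose pericentric window is
    not covered by the segment table.
    """
    total = 0
    for chrom in karyotype.names:
        lo, hi = karyotype.pericentric_window(chrom, window)
        seg = states[states["chrom"] == chrom]
        overlap = np.minimum(seg["end"], hi) - np.maximum(seg["start"], lo)
        mask = overlap > 0
        if not mask.any():
            raise ValueError(f"pericentric window of {chrom} not covered by segments")
        seg = seg[mask]
        frac = (overlap[mask] / (seg["end"] - seg["start"])).to_numpy(float)
        weights = seg["n_probes"].to_numpy(float) * frac if "n_probes" in seg else \
            overlap[mask].to_numpy(float)
        modal = (
            pd.Series(weights)
            .groupby(seg["cn"].to_numpy())
            .sum()
            .sort_values(ascending=False)
        )
        # deterministic tie-break toward lower cn
        top = modal[modal == modal.iloc[0]].index.min()
        total += int(top)
    cls = (
        "near-tetraploid"
        if total >= TETRAPLOID_FACTOR * karyotype.n_chromosomes
        else "near-diploid"
    )
    return PloidyCall(chromosome_number=total, ploidy_class=cls,
                      n_chromosomes=karyotype.n_chromosomes)


def combined_label(loss: bool, gain: bool, loh: bool) -> str:
    if loss and loh:
        return "Loss/LOH"
    if gain and loh:
        return "Gain/LOH"
    if loss:
        return "Loss"
    if gain:
        return "Gain"
    if loh:
        return "LOH"
    return "none"


def call_alterations(states: pd.DataFrame, ploidy: PloidyCall) -> pd.DataFrame:
    """Apply the ploidy-conditional calling rules to a state table.

    Adds boolean columns loss/gain/loh and a combined ``call`` label.
    """
    cn = states["cn"].to_numpy(int)
    minor = states["minor"].to_numpy(int)
    if ploidy.ploidy_class == "near-tetraploid":
        loss = cn <= 2
        gain = cn >= 6
    else:
        loss = cn <= 1
        gain = cn >= 4
    loh = (minor == 0) & (cn >= 1)
    out = states.copy()
    out["loss"] = loss
    out["gain"] = gain
    out["loh"] = loh
    out["call"] = [combined_label(l, g, h) for l, g, h in zip(loss, gain, loh)]
    return out


def _merge_run(seg: pd.DataFrame, min_snps: int) -> pd.DataFrame:
    """Merge sub-threshold segments within one chromosome."""
    rows = seg.to_dict("records")
    if all(r["n_probes"] >= min_snps for r in rows):
        return seg
    if all(r["n_probes"] < min_snps for r in rows):
        # chromosome consists solely of sub-threshold segments: collapse to
        # the probe-weighted modal state
        w = {}
        for r in rows:
            key = (r["cn"], r["major"])
            w[key] = w.get(key, 0) + r["n_probes"]
        (cn, major) = max(w, key=lambda k: (w[k], -k[0], -k[1]))
        merged = {
            **rows[0],
            "end": rows[-1]["end"],
            "n_probes": sum(r["n_probes"] for r in rows),
            "cn": cn,
            "major": major,
            "minor": cn - major,
        }
        return pd.DataFrame([merged])
    while True:
        small = [i for i, r in enumerate(rows) if r["n_probes"] < min_snps]
        if not small:
            break
        # smallest first; ties toward the left
        i = min(small, key=lambda j: (rows[j]["n_probes"], j))
        left = rows[i - 1] if i > 0 else None
        right = rows[i + 1] if i < len(rows) - 1 else None

        def dist(nb):
            return (nb["cn"] - rows[i]["cn"]) ** 2 + (nb["major"] - rows[i]["major"]) ** 2

        if left is not None and (right is None or dist(left) <= dist(right)):
            target, ti = left, i - 1
        else:
            target, ti = right, i + 1
        merged = dict(target)
        merged["start"] = min(target["start"], rows[i]["start"])
        merged["end"] = max(target["end"], rows[i]["end"])
        merged["n_probes"] = target["n_probes"] + rows[i]["n_probes"]
        if "n_het" in merged:
            merged["n_het"] = target.get("n_het", 0) + rows[i].get("n_het", 0)
        lo, hi = sorted((i, ti))
        rows[lo:hi + 1] = [merged]
    # coalesce identical-state neighbours
    out = [rows[0]]
    for r in rows[1:]:
        prev = out[-1]
        if (prev["cn"], prev["major"]) == (r["cn"], r["major"]) and prev["end"] == r["start"]:
            prev["end"] = r["end"]
            prev["n_probes"] += r["n_probes"]
            if "n_het" in prev:
                prev["n_het"] = prev.get("n_het", 0) + r.get("n_het", 0)
        else:
            out.append(r)
    return pd.DataFrame(out)


def filter_small_segments(states: pd.DataFrame, min_snps: int = MIN_SNPS) -> pd.DataFrame:
    """Merge segments with fewer than ``min_snps`` probes into a neighbour.

    The receiving neighbour is the one with the nearer (cn, major) state;
    ties go left.  Total covered genome length is preserved and the number
    of breakpoints never increases.
    """
    if "n_probes" not in states.columns:
        raise ValueError("states must carry n_probes")
    parts = []
    for chrom, seg in states.groupby("chrom", sort=False):
        parts.append(_merge_run(seg.sort_values("start").reset_index(drop=True),
                                min_snps))
    return pd.concat(parts, ignore_index=True)
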