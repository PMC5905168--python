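"""Large-scale state transition (LST) count and HRD classification.

An LST is a chromosomal breakpoint (change in total or major allele copy
number) whose two flanking segments each span at least 10 Mb, counted per
chromosome arm after smoothing away segments shorter than 3 Mb.  Genomes of
homologous-recombination-deficient tumours accumulate many such transitions;
the positivity cutoff depends on ploidy: 15 for near-diploid and 20 for
near-tetraploid genomes (boundary inclusive).  Breaks spanning the
centromere are not counted.  Parameters live in config, not call sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .karyotype import Karyotype

__all__ = ["LstConfig", "LstResult", "smooth_segments", "count_lst", "classify_hrd",
           "lst_for_tumour"]

MB = 1_000_000


@dataclass(frozen=True)
class LstConfig:
    min_segment_mb: float = 3.0
    flank_mb: float = 10.0
    cutoff_diploid: int = 15
    cutoff_tetraploid: int = 20


@dataclass(frozen=True)
class LstResult:
    lst_count: int
    ploidy_class: str
    hrd_positive: bool
    cutoff_used: int


def _split_at_centromere(states: pd.DataFrame, karyotype: Karyotype) -> pd.DataFrame:
    """Annotate each segment with its arm, splitting centromere-spanning ones."""
    rows = []
    for r in states.to_dict("records"):
        cen = karyotype[r["chrom"]].centromere
        if r["start"] < cen < r["end"]:
            rows.append({**r, "end": cen, "arm": "p"})
            rows.append({**r, "start": cen, "arm": "q"})
        else:
            rows.append({**r, "arm": "p" if r["end"] <= cen else "q"})
    return pd.DataFrame(rows)


def _smooth_arm(rows: list[dict], min_len: float) -> list[dict]:
    def coalesce(rs: list[dict]) -> list[dict]:
        out = [dict(rs[0])]
        for r in rs[1:]:
            prev = out[-1]
            if (prev["cn"], prev["major"]) == (r["cn"], r["major"]):
                prev["end"] = r["end"]
            else:
                out.append(dict(r))
        return out

    rows = coalesce(rows)
    while len(rows) > 1:
        lens = [r["end"] - r["start"] for r in rows]
        small = [i for i, ln in enumerate(lens) if ln < min_len]
        if not small:
            break
        i = min(small, key=lambda j: (lens[j], j))
        left = rows[i - 1] if i > 0 else None
        right = rows[i + 1] if i < len(rows) - 1 else None

        def same(nb):
            return nb is not None and (nb["cn"], nb["major"]) == (rows[i]["cn"], rows[i]["major"])

        def dist(nb):
            return (nb["cn"] - rows[i]["cn"]) ** 2 + (nb["major"] - rows[i]["major"]) ** 2

        if same(left) or same(right):
            target = i - 1 if same(left) else i + 1
        elif left is not None and (right is None or dist(left) <= dist(right)):
            target = i - 1
        else:
            target = i + 1
        t = rows[target]
        t["start"] = min(t["start"], rows[i]["start"])
        t["end"] = max(t["end"], rows[i]["end"])
        del rows[i]
        rows = coalesce(rows)
    return rows


def smooth_segments(
    states: pd.DataFrame, karyotype: Karyotype, min_len_mb: float = 3.0
) -> pd.DataFrame:
    """Merge sub-3-Mb segments per arm into the neighbour with identical
    state when possible, else the nearer state; coalesce identical runs."""
    annotated = _split_at_centromere(states, karyotype)
    parts = []
    for (chrom, arm), grp in annotated.groupby(["chrom", "arm"], sort=False):
        rows = grp.sort_values("start").to_dict("records")
        parts.extend(_smooth_arm(rows, min_len_mb * MB))
    return pd.DataFrame(parts)


def count_lst(smoothed: pd.DataFrame, flank_mb: float = 10.0) -> int:
    """Count state transitions whose two flanking segments are each >= flank."""
    flank = flank_mb * MB
    total = 0
    for (_, _), grp in smoothed.groupby(["chrom", "arm"], sort=False):
        rows = grp.sort_values("start").to_dict("records")
        for a, b in zip(rows[:-1], rows[1:]):
            if (a["cn"], a["major"]) == (b["cn"], b["major"]):
                continue
            if (a["end"] - a["start"]) >= flank and (b["end"] - b["start"]) >= flank:
                total += 1
    return total


def classify_hrd(lst_count: int, ploidy_class: str, config: LstConfig = LstConfig()
                 ) -> LstResult:
    if ploidy_class not in ("near-diploid", "near-tetraploid"):
        raise ValueError(f"unknown ploidy class {ploidy_class!r}")
    cutoff = (config.cutoff_tetraploid if ploidy_class == "near-tetraploid"
              else config.cutoff_diploid)
    return LstResult(
        lst_count=lst_count,
        ploidy_class=ploidy_class,
        hrd_positive=lst_count >= cutoff,
        cutoff_used=cutoff,
    )


def lst_for_tumour(
    states: pd.DataFrame,
    ploidy_class: str,
    karyotype: Karyotype,
    config: LstConfig = LstConfig(),
) -> LstResult:
    smoothed = smooth_segments(states, karyotype, config.min_segment_mb)
    n = count_lst(smoothed, config.flank_mb)
    return classify_hrd(n, ploidy_class, config)
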