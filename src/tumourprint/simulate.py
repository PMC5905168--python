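"""Synthetic allele-specific SNP-array tumour simulator.

Generates probe-level BAF/LRR observations for a tumour with planted
copy-number events, under the standard two-component admixture model: a
fraction ``p`` (tumour purity) of aberrant cells mixed with ``1 - p`` normal
diploid cells.  For a probe inside a tumour segment carrying ``n_B`` copies
of the B allele out of ``cn`` total copies, a germline-heterozygous probe has

    E[BAF] = ((1 - p) * 1 + p * n_B) / ((1 - p) * 2 + p * cn)
    raw LRR = log2(((1 - p) * 2 + p * cn) / 2)

and the emitted LRR is recentred so the genome-wide median is 0 (mimicking
array normalisation, which cannot see absolute ploidy).  Gaussian noise is
added to both observables; BAF is clipped to [0, 1].

Events are applied sequentially to per-allele copy counts (whole-genome
duplication first, then segmental events), so ground truth is exact and
recorded per interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .karyotype import Karyotype

__all__ = [
    "EventSpec",
    "TumourSimSpec",
    "MicrosatAssaySim",
    "simulate_tumour",
    "simulate_microsatellite_assay",
    "expected_baf",
    "expected_lrr_raw",
]

DEFAULT_PROBE_SPACING = 100_000  # bp; desk-scale stand-in for array density
DEFAULT_NOISE_SD_BAF = 0.02
DEFAULT_NOISE_SD_LRR = 0.15
P_HETEROZYGOUS = 1.0 / 3.0  # P(AB) per probe; AA and BB split the rest evenly


@dataclass(frozen=True)
class EventSpec:
    """One planted genomic event.

    ``wgd`` doubles every allele genome-wide and carries no locus. Segmental
    kinds modify allele copy counts on ``(chrom, start, end)``:

    - ``loss``: remove ``|copies_delta|`` copies of the hit allele,
    - ``gain``: add ``copies_delta`` copies of the hit allele,
    - ``cn_loh``: transfer all copies of the hit allele to the other allele
      (copy-neutral loss of heterozygosity).
    """

    event_kind: str  # {loss, gain, cn_loh, wgd}
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    copies_delta: int = 0
    allele_hit: str = "B"  # {A, B, random}

    def __post_init__(self) -> None:
        if self.event_kind not in ("loss", "gain", "cn_loh", "wgd"):
            raise ValueError(f"unknown event kind {self.event_kind!r}")
        if self.event_kind == "wgd":
            if self.chrom is not None:
                raise ValueError("wgd events carry no locus")
        else:
            if self.chrom is None or self.start is None or self.end is None:
                raise ValueError(f"{self.event_kind} event requires a locus")
            if not self.start < self.end:
                raise ValueError("event start must be < end")
        if self.allele_hit not in ("A", "B", "random"):
            raise ValueError(f"allele_hit must be A, B or random, got {self.allele_hit!r}")


@dataclass(frozen=True)
class TumourSimSpec:
    tumour_id: str
    purity: float
    events: tuple[EventSpec, ...] = ()
    ground_truth_ploidy_class: str = "near-diploid"
    noise_sd_baf: float = DEFAULT_NOISE_SD_BAF
    noise_sd_lrr: float = DEFAULT_NOISE_SD_LRR
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if self.ground_truth_ploidy_class not in ("near-diploid", "near-tetraploid"):
            raise ValueError(
                f"unknown ploidy class {self.ground_truth_ploidy_class!r}"
            )
        has_wgd = any(e.event_kind == "wgd" for e in self.events)
        if has_wgd != (self.ground_truth_ploidy_class == "near-tetraploid"):
            raise ValueError(
                "wgd event present iff ground_truth_ploidy_class is near-tetraploid"
            )


@dataclass(frozen=True)
class MicrosatAssaySim:
    """Simulated two-peak microsatellite assay for one marker."""

    marker: str
    normal_peaks: tuple[float, float]
    tumour_peaks: tuple[float, float]
    truth_loh: bool
    informative: bool = True


def expected_baf(purity: float, n_b: int, cn: int, germline_b: int) -> float:
    """Expected BAF under the admixture model for a probe with germline B
    count ``germline_b`` (0, 1 or 2) inside a tumour segment (cn, n_b)."""
    if germline_b == 0:
        t_b = 0.0
        g_b = 0.0
    elif germline_b == 2:
        t_b = float(cn)
        g_b = 2.0
    else:
        t_b = float(n_b)
        g_b = 1.0
    denom = (1 - purity) * 2 + purity * cn
    if denom == 0:
        return 0.5
    return ((1 - purity) * g_b + purity * t_b) / denom


def expected_lrr_raw(purity: float, cn: int) -> float:
    """Raw (uncentred) expected LRR for total copy number ``cn``."""
    return float(np.log2(((1 - purity) * 2 + purity * cn) / 2.0))


def _apply_events(
    karyotype: Karyotype, events: tuple[EventSpec, ...], rng: np.random.Generator
) -> dict[str, list[tuple[int, int, int, int]]]:
    """Apply events sequentially; return {chrom: [(start, end, nA, nB), ...]}.

    WGD events are applied first regardless of position in the list (documented
    sequential-event semantics); segmental events then apply in list order.
    """
    segs: dict[str, list[tuple[int, int, int, int]]] = {
        c.name: [(0, c.length, 1, 1)] for c in karyotype.chromosomes
    }
    ordered = [e for e in events if e.event_kind == "wgd"] + [
        e for e in events if e.event_kind != "wgd"
    ]
    for ev in ordered:
        if ev.event_kind == "wgd":
            for chrom in segs:
                segs[chrom] = [(s, e, 2 * a, 2 * b) for s, e, a, b in segs[chrom]]
            continue
        karyotype.validate_interval(ev.chrom, ev.start, ev.end)
        hit = ev.allele_hit
        if hit == "random":
            hit = "A" if rng.random() < 0.5 else "B"
        out: list[tuple[int, int, int, int]] = []
        for s, e, a, b in segs[ev.chrom]:
            pieces = []
            lo, hi = max(s, ev.start), min(e, ev.end)
            if lo >= hi:  # no overlap
                out.append((s, e, a, b))
                continue
            if s < lo:
                pieces.append((s, lo, a, b))
            na, nb = a, b
            if ev.event_kind == "cn_loh":
                if hit == "A":
                    nb, na = a + b, 0
                else:
                    na, nb = a + b, 0
            elif ev.event_kind == "loss":
                delta = -abs(ev.copies_delta)
                if hit == "A":
                    na = a + delta
                else:
                    nb = b + delta
            else:  # gain
                delta = abs(ev.copies_delta)
                if hit == "A":
                    na = a + delta
                else:
                    nb = b + delta
            if na < 0 or nb < 0:
                raise ValueError(
                    f"event {ev.event_kind} at {ev.chrom}:{ev.start}-{ev.end} "
                    f"would yield negative allele copy number"
                )
            pieces.append((lo, hi, na, nb))
            if hi < e:
                pieces.append((hi, e, a, b))
            out.extend(pieces)
        segs[ev.chrom] = out
    # coalesce identical adjacent intervals
    for chrom, lst in segs.items():
        merged = [lst[0]]
        for s, e, a, b in lst[1:]:
            ps, pe, pa, pb = merged[-1]
            if (pa, pb) == (a, b) and pe == s:
                merged[-1] = (ps, e, a, b)
            else:
                merged.append((s, e, a, b))
        segs[chrom] = merged
    return segs


def truth_segments_frame(
    segs: dict[str, list[tuple[int, int, int, int]]], tumour_id: str
) -> pd.DataFrame:
    rows = []
    for chrom, lst in segs.items():
        for s, e, a, b in lst:
            cn = a + b
            rows.append(
                {
                    "sample": tumour_id,
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "cn": cn,
                    "major": max(a, b),
                    "minor": min(a, b),
                    "n_b": b,
                }
            )
    return pd.DataFrame(rows)


def simulate_tumour(
    spec: TumourSimSpec,
    karyotype: Karyotype,
    probe_spacing: int = DEFAULT_PROBE_SPACING,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate probe-level observations and exact truth segments.

    Returns
    -------
    probes : DataFrame with columns sample, chrom, pos, baf, lrr, genotype
        (lrr recentred to genome-wide median 0).
    truth : DataFrame with columns sample, chrom, start, end, cn, major,
        minor, n_b (exact planted allele-specific states).
    """
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be > 0")
    rng = np.random.default_rng(spec.seed)
    segs = _apply_events(karyotype, spec.events, rng)
    truth = truth_segments_frame(segs, spec.tumour_id)

    frames = []
    for chrom in karyotype.names:
        length = karyotype[chrom].length
        pos = np.arange(probe_spacing // 2, length, probe_spacing, dtype=np.int64)
        n = pos.size
        u = rng.random(n)
        # genotype: AB with prob 1/3, AA/BB split the remainder
        geno_b = np.where(u < P_HETEROZYGOUS, 1, np.where(u < (1 + P_HETEROZYGOUS) / 2, 0, 2))
        # map probes to truth intervals
        bounds = np.array([s for s, _, _, _ in segs[chrom]] + [length])
        idx = np.searchsorted(bounds, pos, side="right") - 1
        seg_arr = np.array([(a + b, b) for _, _, a, b in segs[chrom]], dtype=float)
        cn = seg_arr[idx, 0]
        n_b = seg_arr[idx, 1]
        p = spec.purity
        denom = (1 - p) * 2 + p * cn
        g_b = geno_b.astype(float)
        t_b = np.where(geno_b == 1, n_b, np.where(geno_b == 2, cn, 0.0))
        baf = ((1 - p) * g_b + p * t_b) / np.where(denom == 0, 1.0, denom)
        baf = np.where(denom == 0, 0.5, baf)
        lrr = np.log2(denom / 2.0)
        if spec.noise_sd_baf > 0:
            baf = baf + rng.normal(0.0, spec.noise_sd_baf, n)
        if spec.noise_sd_lrr > 0:
            lrr = lrr + rng.normal(0.0, spec.noise_sd_lrr, n)
        baf = np.clip(baf, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "sample": spec.tumour_id,
                    "chrom": chrom,
                    "pos": pos,
                    "baf": baf,
                    "lrr": lrr,
                    "genotype": np.array(["AA", "AB", "BB"])[geno_b],
                }
            )
        )
    probes = pd.concat(frames, ignore_index=True)
    # centre the genome-wide median LRR at 0 (array-style normalisation)
    probes["lrr"] = probes["lrr"] - probes["lrr"].median()
    return probes, truth


def simulate_microsatellite_assay(
    truth_loh: bool,
    informative: bool = True,
    noise_cv: float = 0.0,
    seed: int = 0,
    marker: str = "D11S1113",
    residual_fraction: float = 0.0,
    base_height: float = 1000.0,
) -> MicrosatAssaySim:
    """Simulate a two-peak microsatellite assay.

    With ``truth_loh`` the lost allele's tumour peak is attenuated to
    ``residual_fraction`` of its balanced height (0 = complete loss; normal
    contamination of an impure sample yields an intermediate fraction).
    Uninformative markers are homozygous in the normal: a single peak.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not 0 <= residual_fraction <= 1:
        raise ValueError("residual_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def jitter(h: float) -> float:
        if noise_cv == 0 or h == 0:
            return h
        return max(0.0, h * (1 + rng.normal(0.0, noise_cv)))

    if not informative:
        h = jitter(base_height * 2)
        return MicrosatAssaySim(
            marker=marker,
            normal_peaks=(h, 0.0),
            tumour_peaks=(jitter(base_height * 2), 0.0),
            truth_loh=truth_loh,
            informative=False,
        )
    n_a = jitter(base_height)
    n_b = jitter(base_height)
    if truth_loh:
        t_a = jitter(base_height)
        t_b = jitter(base_height * residual_fraction)
    else:
        t_a = jitter(base_height)
        t_b = jitter(base_height)
    return MicrosatAssaySim(
        marker=marker,
        normal_peaks=(n_a, n_b),
        tumour_peaks=(t_a, t_b),
        truth_loh=truth_loh,
        informative=True,
    )
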