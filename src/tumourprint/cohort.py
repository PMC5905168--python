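"""Cohort-level simulation: presets with known ground truth.

The bundled ``paper_cohort`` preset emulates a 23-tumour FFPE breast-tumour
series from carriers of deleterious ATM variants: 16 near-tetraploid and 7
near-diploid tumours; 21 tumours from heterozygous carriers of which 14 carry
LOH across the ATM locus at 11q22.3 (the other two tumours are from biallelic
A-T patients); and four hallmark loss loci (13q14.11-q14.3, 17p13.2-p12,
21p11.2-p11.1, 22q11.23) each planted in 18/23 tumours (78%).  Ground-truth
composition (ploidy classes, event membership) is fixed by the preset; the
seed drives only purities, noise and genotype draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .karyotype import (
    ATM_LOCUS,
    HALLMARK_LOSS_LOCI,
    Karyotype,
    default_female_karyotype,
)
from .simulate import (
    EventSpec,
    MicrosatAssaySim,
    TumourSimSpec,
    simulate_microsatellite_assay,
    simulate_tumour,
)

__all__ = ["CohortBundle", "CohortPreset", "paper_cohort_preset", "simulate_cohort",
           "MICROSAT_MARKERS"]

MICROSAT_MARKERS = ("D11S1113", "D11S1819", "D11S2179", "D11S1778")

# broad background-event intervals (hg19-like coordinates)
_REGION_8P = ("chr8", 0, 43_000_000)
_REGION_8Q = ("chr8", 48_000_000, 146_364_022)
_REGION_16Q = ("chr16", 38_000_000, 90_354_753)
_REGION_17P_BROAD = ("chr17", 0, 22_000_000)
_REGION_1Q = ("chr1", 128_000_000, 249_250_621)
_REGION_11Q_BROAD = ("chr11", 86_000_000, 135_006_516)  # 11q14.1-qter

# whole-chromosome aneuploidies for post-WGD genomes (chromosomal instability
# after genome doubling leaves near-tetraploid tumours with odd copy numbers
# on several chromosomes)
_ANEUPLOIDY_LOSS = (
    ("chr4", 0, 191_154_276),
    ("chr9", 0, 141_213_431),
    ("chr14", 0, 107_349_540),
    ("chr18", 0, 78_077_248),
)
_ANEUPLOIDY_GAIN = (
    ("chr7", 0, 159_138_663),
    ("chr20", 0, 63_025_520),
)


@dataclass(frozen=True)
class CohortPreset:
    name: str
    tumours: tuple[TumourSimSpec, ...]  # purity/seed filled at simulation time
    carrier_status: dict[str, str]  # tumour_id -> {"HetAT", "A-T"}
    atm_loh_truth: dict[str, bool]
    hallmark_truth: dict[str, dict[str, bool]]  # locus -> tumour_id -> planted
    probe_spacing: int
    purity_range: tuple[float, float] = (0.4, 0.9)
    wgs_subset: tuple[str, ...] = ()


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces."""

    preset: str
    seed: int
    karyotype: Karyotype
    probes: pd.DataFrame  # all tumours stacked
    truth_segments: pd.DataFrame
    purities: dict[str, float]
    clinical: pd.DataFrame
    microsat: pd.DataFrame  # long table, one row per (tumour, marker)
    variants: pd.DataFrame  # one row per (tumour, variant)
    carrier_status: dict[str, str]
    atm_loh_truth: dict[str, bool]
    hallmark_truth: dict[str, dict[str, bool]]

    @property
    def tumour_ids(self) -> list[str]:
        return sorted(self.carrier_status)


def _paper_cohort_composition() -> tuple[list[str], dict[str, str], dict[str, bool],
                                         dict[str, dict[str, bool]], list[str]]:
    ids = [f"T{i:02d}" for i in range(1, 24)]
    tetraploid = {"T01"} | {f"T{i:02d}" for i in range(3, 18)}  # 16 tumours
    carrier = {t: ("A-T" if t in ("T01", "T02") else "HetAT") for t in ids}
    # 14 of the 21 HetAT tumours carry ATM-locus LOH (A-T tumours are biallelic
    # by germline and carry none here)
    atm_loh = {t: False for t in ids}
    for t in [f"T{i:02d}" for i in range(3, 13)] + ["T18", "T19", "T20", "T21"]:
        atm_loh[t] = True
    # each hallmark locus lost in 18/23 tumours; excluded sets rotate
    excluded = {
        "13q14.11-q14.3": {"T05", "T10", "T15", "T20", "T23"},
        "17p13.2-p12": {"T03", "T08", "T13", "T18", "T22"},
        "21p11.2-p11.1": {"T04", "T09", "T14", "T19", "T23"},
        "22q11.23": {"T06", "T11", "T16", "T21", "T22"},
    }
    hallmark = {
        locus: {t: (t not in excl) for t in ids} for locus, excl in excluded.items()
    }
    ploidy = [("near-tetraploid" if t in tetraploid else "near-diploid") for t in ids]
    return ids, carrier, atm_loh, hallmark, ploidy


def _events_for_tumour(
    tumour_id: str,
    ploidy_class: str,
    atm_loh: bool,
    hallmark: dict[str, dict[str, bool]],
    index: int,
) -> tuple[EventSpec, ...]:
    tetra = ploidy_class == "near-tetraploid"
    ev: list[EventSpec] = []
    if tetra:
        ev.append(EventSpec("wgd"))
    d = 2 if tetra else 1  # copies to remove so the loss is called at this ploidy
    for locus, members in hallmark.items():
        if members[tumour_id]:
            chrom, s, e = HALLMARK_LOSS_LOCI[locus]
            ev.append(EventSpec("loss", chrom, s, e, copies_delta=d, allele_hit="B"))
    if atm_loh:
        # alternate broad 11q loss/LOH with the focal 11q22.3 band; one in
        # three LOH tumours is copy-neutral at the locus
        chrom, s, e = _REGION_11Q_BROAD if index % 2 == 0 else ATM_LOCUS
        if index % 3 == 0:
            ev.append(EventSpec("cn_loh", chrom, s, e, allele_hit="B"))
        else:
            ev.append(EventSpec("loss", chrom, s, e, copies_delta=d, allele_hit="B"))
    # background events; odd-copy states in tetraploids anchor absolute ploidy
    ev.append(EventSpec("loss", *_REGION_16Q, copies_delta=1, allele_hit="B"))
    if tetra:
        ev.append(EventSpec("loss", *_ANEUPLOIDY_LOSS[index % 4], copies_delta=1,
                            allele_hit="A"))
        ev.append(EventSpec("loss", *_ANEUPLOIDY_LOSS[(index + 2) % 4],
                            copies_delta=1, allele_hit="B"))
        ev.append(EventSpec("gain", *_ANEUPLOIDY_GAIN[index % 2], copies_delta=1,
                            allele_hit="A"))
    if index % 2 == 0:
        ev.append(EventSpec("gain", *_REGION_8Q, copies_delta=2, allele_hit="A"))
    else:
        ev.append(EventSpec("gain", *_REGION_8Q, copies_delta=1, allele_hit="A"))
    if not tetra:
        ev.append(EventSpec("loss", *_REGION_8P, copies_delta=1, allele_hit="A"))
    if index % 3 == 0:
        ev.append(EventSpec("gain", *_REGION_1Q, copies_delta=1, allele_hit="B"))
    return tuple(ev)


def paper_cohort_preset(probe_spacing: int = 20_000) -> CohortPreset:
    """The bundled 23-tumour preset mirroring the study composition.

    Probe spacing defaults to 20 kb here (denser than the generic simulator
    default) so that the smallest hallmark locus (1.2 Mb at 21p11) retains
    >= 50 probes and survives the 50-SNP breakpoint filter.
    """
    ids, carrier, atm_loh, hallmark, ploidy = _paper_cohort_composition()
    tumours = tuple(
        TumourSimSpec(
            tumour_id=t,
            purity=0.7,  # placeholder; drawn per-seed in simulate_cohort
            events=_events_for_tumour(t, pc, atm_loh[t], hallmark, i),
            ground_truth_ploidy_class=pc,
        )
        for i, (t, pc) in enumerate(zip(ids, ploidy))
    )
    return CohortPreset(
        name="paper_cohort",
        tumours=tumours,
        carrier_status=carrier,
        atm_loh_truth=atm_loh,
        hallmark_truth=hallmark,
        probe_spacing=probe_spacing,
        wgs_subset=("T03", "T07", "T22", "T23"),
    )


def empty_preset() -> CohortPreset:
    return CohortPreset(
        name="empty",
        tumours=(),
        carrier_status={},
        atm_loh_truth={},
        hallmark_truth={},
        probe_spacing=100_000,
    )


_PRESETS = {"paper_cohort": paper_cohort_preset, "empty": empty_preset}


def _clinical_for(ids: list[str], carrier: dict[str, str], rng: np.random.Generator
                  ) -> pd.DataFrame:
    """Clinical table echoing the study's IHC distribution: almost all ER+,
    mostly luminal B, a few HER2+ and one triple negative."""
    rows = []
    for i, t in enumerate(ids):
        er, pr, her2 = "+", "+", "-"
        ki67: float | str = 30.0
        if i == 0:
            er, pr, her2, ki67 = "-", "-", "-", 40.0  # triple negative
        elif i in (1, 2, 3):
            her2 = "+"  # luminal B/HER2+
        elif i in range(4, 12):
            ki67 = 10.0  # luminal A block
        if i in (5, 13):
            pr = "-"
        rows.append(
            {
                "patient_id": t,
                "sex": "F",
                "age_at_diagnosis": int(rng.integers(35, 72)),
                "invasive": True,
                "histology": "lobular" if i == 12 else ("other" if i == 19 else "ductal"),
                "er": er,
                "pr": pr,
                "her2": her2,
                "her2_ihc_score": 3 if her2 == "+" else 1,
                "fish_amplified": "unknown",
                "ki67_pct": ki67,
                "carrier_status": carrier[t],
            }
        )
    cols = ["patient_id", "sex", "age_at_diagnosis", "invasive", "histology",
            "er", "pr", "her2", "her2_ihc_score", "fish_amplified", "ki67_pct",
            "carrier_status"]
    return pd.DataFrame(rows, columns=cols)


def _atm_major_copies(truth: pd.DataFrame, tumour_id: str) -> int:
    """Length-weighted modal major allele count over the ATM locus."""
    chrom, lo, hi = ATM_LOCUS
    seg = truth[(truth["sample"] == tumour_id) & (truth["chrom"] == chrom)]
    ov = np.minimum(seg["end"], hi) - np.maximum(seg["start"], lo)
    seg = seg[ov > 0]
    if not len(seg):
        return 1
    w = ov[ov > 0].groupby(seg["major"]).sum()
    return int(w.idxmax())


def _microsat_for(
    ids: list[str],
    atm_loh: dict[str, bool],
    purities: dict[str, float],
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for t in ids:
        p = purities[t]
        # retained-allele copies per tumour cell at the ATM locus
        k = _atm_major_copies(truth, t)
        residual = (1 - p) / ((1 - p) + p * k) if atm_loh[t] else 0.0
        informative = rng.random(len(MICROSAT_MARKERS)) < 0.7
        while informative.sum() < 2:  # keep each tumour assayable
            informative = rng.random(len(MICROSAT_MARKERS)) < 0.7
        for m, inf in zip(MICROSAT_MARKERS, informative):
            assay = simulate_microsatellite_assay(
                truth_loh=atm_loh[t],
                informative=bool(inf),
                noise_cv=0.05,
                seed=int(rng.integers(0, 2**31 - 1)),
                marker=m,
                residual_fraction=residual,
            )
            rows.append(
                {
                    "sample": t,
                    "marker": m,
                    "n_height_a": assay.normal_peaks[0],
                    "n_height_b": assay.normal_peaks[1],
                    "t_height_a": assay.tumour_peaks[0],
                    "t_height_b": assay.tumour_peaks[1],
                    "truth_loh": assay.truth_loh,
                }
            )
    cols = ["sample", "marker", "n_height_a", "n_height_b", "t_height_a",
            "t_height_b", "truth_loh"]
    return pd.DataFrame(rows, columns=cols)


_WGS_GENES = ["MYO1A", "DNAH11", "SH2D5", "ATM", "MUC4", "ROS1"]


def _variants_for(wgs_ids: tuple[str, ...], rng: np.random.Generator) -> pd.DataFrame:
    """Scaled-down somatic-variant lists for the WGS subset: mostly private
    SNVs, a handful shared by two tumours, one by three, none by all four;
    six coding genes altered in exactly two tumours."""
    if not wgs_ids:
        return pd.DataFrame(
            columns=["sample", "chrom", "pos", "ref", "alt", "gene", "coding",
                     "predicted_deleterious"]
        )
    bases = np.array(list("ACGT"))
    rows = []
    counter = [0]

    def new_variant(coding: bool, gene: str | None) -> dict:
        counter[0] += 1
        pos = 1_000_000 + counter[0] * 1_000
        ref, alt = rng.choice(bases, size=2, replace=False)
        return {
            "chrom": "chr2",
            "pos": pos,
            "ref": str(ref),
            "alt": str(alt),
            "gene": gene or f"IGR{counter[0]}",
            "coding": coding,
            "predicted_deleterious": bool(coding and rng.random() < 0.3),
        }

    # private variants (~120 per tumour, a few coding with private genes)
    for t in wgs_ids:
        for j in range(120):
            v = new_variant(coding=(j < 10), gene=f"PRIV_{t}_{j}" if j < 10 else None)
            rows.append({"sample": t, **v})
    # 10 shared by exactly two tumours: 8 in the "bilateral" pair, 2 elsewhere;
    # six of them coding, in the six recurrently altered genes
    pair = wgs_ids[-2:]
    others = (wgs_ids[0], wgs_ids[1])
    share2 = [pair] * 8 + [others] * 2
    for j, members in enumerate(share2):
        gene = _WGS_GENES[j] if j < len(_WGS_GENES) else None
        v = new_variant(coding=j < len(_WGS_GENES), gene=gene)
        for t in members:
            rows.append({"sample": t, **v})
    # one shared by exactly three (non-coding)
    v = new_variant(coding=False, gene=None)
    for t in wgs_ids[:3]:
        rows.append({"sample": t, **v})
    return pd.DataFrame(rows)


def simulate_cohort(
    preset: str | CohortPreset, seed: int, probe_spacing: int | None = None
) -> CohortBundle:
    """Simulate a full cohort bundle, deterministic given (preset, seed)."""
    if isinstance(preset, str):
        if preset not in _PRESETS:
            raise KeyError(
                f"unknown preset {preset!r}; available: {sorted(_PRESETS)}"
            )
        preset = _PRESETS[preset]()
    if probe_spacing is None:
        probe_spacing = preset.probe_spacing
    karyotype = default_female_karyotype()
    root = np.random.default_rng(seed)
    ids = [t.tumour_id for t in preset.tumours]
    lo, hi = preset.purity_range
    purities = {t: float(root.uniform(lo, hi)) for t in ids}
    tumour_seeds = {t: int(root.integers(0, 2**31 - 1)) for t in ids}

    probe_frames, truth_frames = [], []
    ploidy = {}
    from dataclasses import replace

    for spec in preset.tumours:
        t = spec.tumour_id
        ploidy[t] = spec.ground_truth_ploidy_class
        spec = replace(spec, purity=purities[t], seed=tumour_seeds[t])
        probes, truth = simulate_tumour(spec, karyotype, probe_spacing)
        probe_frames.append(probes)
        truth_frames.append(truth)

    empty_probes = pd.DataFrame(
        columns=["sample", "chrom", "pos", "baf", "lrr", "genotype"]
    )
    empty_truth = pd.DataFrame(
        columns=["sample", "chrom", "start", "end", "cn", "major", "minor", "n_b"]
    )
    probes = pd.concat(probe_frames, ignore_index=True) if probe_frames else empty_probes
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else empty_truth

    clin_rng = np.random.default_rng(seed + 1)
    ms_rng = np.random.default_rng(seed + 2)
    var_rng = np.random.default_rng(seed + 3)
    clinical = _clinical_for(ids, preset.carrier_status, clin_rng)
    microsat = _microsat_for(ids, preset.atm_loh_truth, purities, truth, ms_rng)
    variants = _variants_for(preset.wgs_subset, var_rng)

    return CohortBundle(
        preset=preset.name,
        seed=seed,
        karyotype=karyotype,
        probes=probes,
        truth_segments=truth,
        purities=purities,
        clinical=clinical,
        microsat=microsat,
        variants=variants,
        carrier_status=dict(preset.carrier_status),
        atm_loh_truth=dict(preset.atm_loh_truth),
        hallmark_truth={k: dict(v) for k, v in preset.hallmark_truth.items()},
    )
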