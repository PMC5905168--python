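"""End-to-end orchestration: simulate -> infer -> call -> lst -> recurrence
-> microsatellite LOH -> cohort statistics.

`analyse_cohort` is the in-memory engine; `run_pipeline` wraps it with file
outputs, stage logging to stderr and a YAML manifest of what was written.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .ascn import GenomeAlterationModel
from .calling import (
    MIN_SNPS,
    PERICENTRIC_HALF_WIDTH,
    call_alterations,
    estimate_ploidy,
    filter_small_segments,
)
from .cohort import CohortBundle, simulate_cohort
from .karyotype import ATM_LOCUS, HALLMARK_LOSS_LOCI, Karyotype
from .lst import LstConfig, lst_for_tumour
from .microsat import call_peak_table
from .recurrence import (
    RECURRENCE_THRESHOLD,
    alteration_matrix,
    build_grid,
    cluster_tumours,
    linkage_to_newick,
    locus_frequency,
    recurrent_regions,
)
from .clinical import descriptive_table, variant_sharing

log = logging.getLogger("tumourprint")

__all__ = ["RunConfig", "TumourAnalysis", "CohortAnalysis", "analyse_tumour",
           "analyse_cohort", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline thresholds, each defaulting to its quoted study value
    where one exists (50-SNP filter, 70% recurrence, 50% microsat ratio,
    20% Ki-67, 8-copy cap)."""

    seed: int = 0
    preset: str = "paper_cohort"
    probe_spacing: int | None = None
    min_snps: int = MIN_SNPS
    recurrence_threshold: float = RECURRENCE_THRESHOLD
    pericentric_window: int = PERICENTRIC_HALF_WIDTH
    segmentation_min_probes: int = 10
    lst: LstConfig = field(default_factory=LstConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class TumourAnalysis:
    sample: str
    purity: float
    centering: float
    fit_score: float
    flags: tuple[str, ...]
    ploidy_class: str
    chromosome_number: int
    states: pd.DataFrame  # filtered states
    calls: pd.DataFrame
    lst_count: int
    hrd_positive: bool


@dataclass
class CohortAnalysis:
    config: RunConfig
    bundle: CohortBundle
    tumours: dict[str, TumourAnalysis]
    grid: pd.DataFrame
    matrix: pd.DataFrame
    regions: list
    linkage: np.ndarray | None
    leaf_labels: list[str]
    msloh: pd.DataFrame
    clinical_table: pd.DataFrame
    sharing: pd.DataFrame

    def atm_loh_samples(self) -> set[str]:
        """Tumours with an LOH call overlapping the ATM locus."""
        chrom, lo, hi = ATM_LOCUS
        out = set()
        for tid, ta in self.tumours.items():
            seg = ta.calls
            seg = seg[(seg["chrom"] == chrom) & seg["loh"]]
            if ((seg["start"] < hi) & (seg["end"] > lo)).any():
                out.add(tid)
        return out

    def hallmark_frequencies(self) -> dict[str, float]:
        profiles = {tid: ta.calls for tid, ta in self.tumours.items()}
        return {
            name: locus_frequency(profiles, locus, kind="loss")[0]
            for name, locus in HALLMARK_LOSS_LOCI.items()
        }


def analyse_tumour(
    probes: pd.DataFrame, karyotype: Karyotype, config: RunConfig
) -> TumourAnalysis:
    chrom_lengths = {c.name: c.length for c in karyotype.chromosomes}
    model = GenomeAlterationModel.from_probes(
        probes, min_probes=config.segmentation_min_probes,
        chrom_lengths=chrom_lengths,
    )
    res = model.fit()
    states = filter_small_segments(res.states, min_snps=config.min_snps)
    ploidy = estimate_ploidy(states, karyotype, window=config.pericentric_window)
    calls = call_alterations(states, ploidy)
    lst_res = lst_for_tumour(states, ploidy.ploidy_class, karyotype, config.lst)
    return TumourAnalysis(
        sample=model.sample or "?",
        purity=res.purity,
        centering=res.centering,
        fit_score=res.fit_score,
        flags=res.flags,
        ploidy_class=ploidy.ploidy_class,
        chromosome_number=ploidy.chromosome_number,
        states=states,
        calls=calls,
        lst_count=lst_res.lst_count,
        hrd_positive=lst_res.hrd_positive,
    )


def analyse_cohort(bundle: CohortBundle, config: RunConfig) -> CohortAnalysis:
    tumours: dict[str, TumourAnalysis] = {}
    for tid, probes in bundle.probes.groupby("sample", sort=True):
        log.info("analysing %s (%d probes)", tid, len(probes))
        tumours[tid] = analyse_tumour(probes.reset_index(drop=True),
                                      bundle.karyotype, config)
    profiles = {tid: ta.calls for tid, ta in tumours.items()}
    grid = build_grid(profiles)
    if profiles:
        matrix = alteration_matrix(profiles, grid)
        regions = recurrent_regions(matrix, config.recurrence_threshold)
    else:
        matrix = pd.DataFrame()
        regions = []
    if len(matrix) >= 2 and matrix.to_numpy().any():
        z, labels = cluster_tumours(matrix)
    else:
        z, labels = None, list(matrix.index)
    msloh = call_peak_table(bundle.microsat) if len(bundle.microsat) else \
        pd.DataFrame(columns=["sample", "status", "discordant", "n_informative"])
    clin = descriptive_table(bundle.clinical)
    if len(bundle.variants):
        sharing = variant_sharing(
            {tid: df for tid, df in bundle.variants.groupby("sample")}
        )
    else:
        sharing = pd.DataFrame(columns=["shared_by", "n_variants", "n_genes"])
    return CohortAnalysis(
        config=config,
        bundle=bundle,
        tumours=tumours,
        grid=grid,
        matrix=matrix,
        regions=regions,
        linkage=z,
        leaf_labels=labels,
        msloh=msloh,
        clinical_table=clin,
        sharing=sharing,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all stages, write per-stage outputs under ``out_dir`` and return
    the manifest (also written as manifest.yaml)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("stage simulate: preset=%s seed=%d", config.preset, config.seed)
    bundle = simulate_cohort(config.preset, config.seed,
                             probe_spacing=config.probe_spacing)
    analysis = analyse_cohort(bundle, config)

    files: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        files[name] = _sha256(path)
        log.info("stage output %s", name)

    emit("probes.tsv", lambda p: tio.write_probe_tsv(bundle.probes, p))
    emit("truth_segments.seg.tsv",
         lambda p: tio.write_seg_tsv(bundle.truth_segments, p,
                                     extra_cols=["cn", "major", "minor"]))

    states = []
    fits = {}
    for tid, ta in analysis.tumours.items():
        s = ta.calls.copy()
        s["sample"] = tid
        states.append(s)
        fits[tid] = {
            "purity": round(ta.purity, 4),
            "centering": round(ta.centering, 4),
            "fit_score": round(ta.fit_score, 6),
            "flags": list(ta.flags),
            "ploidy_class": ta.ploidy_class,
            "chromosome_number": ta.chromosome_number,
            "lst_count": ta.lst_count,
            "hrd_positive": bool(ta.hrd_positive),
        }
    if states:
        all_states = pd.concat(states, ignore_index=True)
        emit("calls.seg.tsv",
             lambda p: tio.write_seg_tsv(
                 all_states, p,
                 extra_cols=["n_probes", "cn", "major", "minor", "call"]))
    emit("fits.yaml", lambda p: tio.write_yaml(fits, p))
    if len(analysis.matrix):
        emit("alteration_matrix.tsv",
             lambda p: tio.write_matrix_tsv(analysis.matrix, p))
    emit("recurrent_regions.tsv",
         lambda p: tio.write_regions_tsv(analysis.regions, p))
    if analysis.linkage is not None:
        emit("clustering.nwk",
             lambda p: tio.write_newick(
                 linkage_to_newick(analysis.linkage, analysis.leaf_labels), p))
    emit("msloh.tsv", lambda p: analysis.msloh.to_csv(p, sep="\t", index=False))
    emit("clinical_summary.tsv",
         lambda p: analysis.clinical_table.to_csv(p, sep="\t", index=False))
    emit("variant_sharing.tsv",
         lambda p: analysis.sharing.to_csv(p, sep="\t", index=False))
    if len(bundle.variants):
        emit("somatic_variants.vcf",
             lambda p: tio.write_minimal_vcf(bundle.variants, p))

    manifest = {
        "config": config.to_dict(),
        "n_tumours": len(analysis.tumours),
        "outputs": files,
    }
    tio.write_yaml(manifest, out / "manifest.yaml")
    log.info("pipeline complete: %d outputs", len(files))
    return manifest
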