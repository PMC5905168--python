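"""Absolute allele-specific copy-number inference from segment summaries.

The estimator follows the pattern-recognition idea behind genome-alteration
"print" methods: in the (mirrored-BAF, LRR) plane, segments of an aberrant
genome concentrate on a lattice of points indexed by integer allele-specific
states (cn, major).  For purity ``p`` and LRR recentring ``c`` the lattice
coordinates are

    LRR(cn)        = log2(((1 - p) * 2 + p * cn) / 2) - c
    mBAF(cn,major) = ((1 - p) + p * major) / ((1 - p) * 2 + p * cn)

A grid search over p (0.10..1.00, step 0.01) and data-driven centring
candidates scores each segment against its nearest lattice point; the
best-fitting (p, c) minimises the probe-weighted squared distance plus a
small ploidy-parsimony penalty lambda * |mean cn - 2| that breaks the exact
diploid/tetraploid alias when, and only when, the data are silent about it.
Copy numbers are capped at 8: anything beyond is ascribed eight-copy status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import segment_probes

__all__ = [
    "PurityFit",
    "fit_purity_ploidy",
    "assign_states",
    "GenomeAlterationModel",
    "GenomeAlterationResults",
    "state_lattice",
]

MAX_CN = 8
PURITY_GRID = np.round(np.arange(0.10, 1.001, 0.01), 2)
LRR_SCALE = 0.25  # log2 units; distance scale for the LRR coordinate
BAF_SCALE = 0.05  # distance scale for the mirrored-BAF coordinate
PLOIDY_PENALTY = 0.015  # lambda, per unit |mean cn - 2| of normalised score
N_CENTERING_MODES = 5


@dataclass(frozen=True)
class PurityFit:
    purity: float
    centering: float
    fit_score: float
    flags: tuple[str, ...] = ()

    @property
    def degenerate(self) -> bool:
        return "purity_unidentifiable" in self.flags


def state_lattice(max_cn: int = MAX_CN) -> tuple[np.ndarray, np.ndarray]:
    """All (cn, major) states with major >= minor, ordered by (cn, major)."""
    cns, majors = [], []
    for cn in range(max_cn + 1):
        # major runs from ceil(cn/2) to cn; cn=0 yields the single state (0,0)
        for major in range((cn + 1) // 2, cn + 1) if cn else [0]:
            cns.append(cn)
            majors.append(major)
    return np.array(cns), np.array(majors)


_LAT_CN, _LAT_MAJOR = state_lattice()


def _predicted(p: float, c: float) -> tuple[np.ndarray, np.ndarray]:
    denom = (1 - p) * 2 + p * _LAT_CN
    # at p = 1 the cn-0 state has no signal: floor the denominator so the
    # state sits far below every observable LRR instead of at -inf
    safe = np.maximum(denom, 1e-4)
    lrr = np.log2(safe / 2.0) - c
    mbaf = np.where(denom > 0, ((1 - p) + p * _LAT_MAJOR) / safe, 0.5)
    return lrr, mbaf


def _segment_arrays(segments: pd.DataFrame):
    lrr = segments["mean_lrr"].to_numpy(float)
    mbaf = segments["mirrored_baf"].to_numpy(float)
    w = segments["n_probes"].to_numpy(float)
    informative = segments["n_het"].to_numpy(int) > 0
    mbaf = np.where(informative, mbaf, 0.0)
    return lrr, mbaf, w, informative


def _score(p: float, c: float, lrr, mbaf, w, informative) -> tuple[float, np.ndarray]:
    pred_lrr, pred_baf = _predicted(p, c)
    d2 = ((lrr[:, None] - pred_lrr[None, :]) / LRR_SCALE) ** 2
    d2 = d2 + informative[:, None] * ((mbaf[:, None] - pred_baf[None, :]) / BAF_SCALE) ** 2
    best = np.argmin(d2, axis=1)
    dmin = d2[np.arange(d2.shape[0]), best]
    wsum = w.sum()
    mean_cn = float((w * _LAT_CN[best]).sum() / wsum)
    score = float((w * dmin).sum() / wsum) + PLOIDY_PENALTY * abs(mean_cn - 2.0)
    return score, best


def _centering_candidates(segments: pd.DataFrame, p: float) -> np.ndarray:
    """Centring candidates: align each of the K most probe-heavy LRR modes
    with an assumed copy number 1..4."""
    lrr = segments["mean_lrr"].to_numpy(float)
    w = segments["n_probes"].to_numpy(float)
    lo, hi = lrr.min() - 0.05, lrr.max() + 0.05
    nbins = max(int((hi - lo) / 0.025), 1)
    histw, edges = np.histogram(lrr, bins=nbins, range=(lo, hi), weights=w)
    order = np.argsort(histw)[::-1]
    modes = []
    for b in order:
        if histw[b] <= 0:
            break
        centre = 0.5 * (edges[b] + edges[b + 1])
        if all(abs(centre - m) > 0.1 for m in modes):
            modes.append(centre)
        if len(modes) >= N_CENTERING_MODES:
            break
    cands = []
    for m in modes:
        for cn0 in (1, 2, 3, 4):
            cands.append(np.log2(((1 - p) * 2 + p * cn0) / 2.0) - m)
    cands = np.unique(np.round(np.array(cands), 3))
    return cands


def fit_purity_ploidy(
    segments: pd.DataFrame, purity_grid: np.ndarray | None = None
) -> PurityFit:
    """Grid-search purity and LRR centring against the state lattice.

    ``segments`` needs columns n_probes, n_het, mean_lrr, mirrored_baf.
    Raises ValueError on an uninformative (all-homozygous) profile.  The fit
    is a sum over segments, hence invariant to their order.
    """
    if purity_grid is None:
        purity_grid = PURITY_GRID
    if not (segments["n_het"] > 0).any():
        raise ValueError("uninformative profile: no segment has heterozygous probes")
    lrr, mbaf, w, informative = _segment_arrays(segments)

    best = (np.inf, np.nan, np.nan)  # score, p, c
    per_p_best = np.full(purity_grid.size, np.inf)
    for i, p in enumerate(purity_grid):
        for c in _centering_candidates(segments, float(p)):
            s, _ = _score(float(p), float(c), lrr, mbaf, w, informative)
            if s < per_p_best[i]:
                per_p_best[i] = s
            if s < best[0] - 1e-12:
                best = (s, float(p), float(c))
    score, p_hat, c_hat = best

    flags: list[str] = []
    near = per_p_best <= score + max(1e-8, 1e-3 * score)
    if near.any():
        span = purity_grid[near].max() - purity_grid[near].min()
        if span > 0.3:
            flags.append("purity_unidentifiable")
    return PurityFit(purity=p_hat, centering=c_hat, fit_score=score,
                     flags=tuple(flags))


def assign_states(segments: pd.DataFrame, fit: PurityFit) -> pd.DataFrame:
    """Map each segment to its nearest lattice state under the fitted model.

    Copy number is capped at 8; ties break toward lower cn, then lower major.
    Segments without heterozygous probes are scored on LRR alone, their major
    imputed as cn and flagged allele-uninformative.
    """
    lrr, mbaf, w, informative = _segment_arrays(segments)
    pred_lrr, pred_baf = _predicted(fit.purity, fit.centering)
    d2 = ((lrr[:, None] - pred_lrr[None, :]) / LRR_SCALE) ** 2
    d2b = d2 + ((mbaf[:, None] - pred_baf[None, :]) / BAF_SCALE) ** 2
    out = segments.copy()
    cn = np.empty(len(out), dtype=int)
    major = np.empty(len(out), dtype=int)
    for i in range(len(out)):
        row = d2b[i] if informative[i] else d2[i]
        # lattice is ordered by (cn, major): the first index attaining the
        # minimum implements the tie rule
        k = int(np.flatnonzero(row <= row.min() + 1e-12)[0])
        cn[i] = _LAT_CN[k]
        if informative[i]:
            major[i] = _LAT_MAJOR[k]
        else:
            major[i] = cn[i]
    out["cn"] = cn
    out["major"] = major
    out["minor"] = out["cn"] - out["major"]
    out["allele_informative"] = informative
    return out


class GenomeAlterationModel:
    """Purity / absolute allele-specific copy-number model for one tumour.

    Built either from probe-level data (which is segmented first) or from an
    existing segment-summary table.  ``fit()`` returns a
    :class:`GenomeAlterationResults` carrying the purity and centring
    estimates, the per-segment state assignments and diagnostics.
    """

    def __init__(
        self,
        segments: pd.DataFrame,
        sample: str | None = None,
        purity_grid: np.ndarray | None = None,
    ):
        self.segments = segments.reset_index(drop=True)
        self.sample = sample
        self.purity_grid = PURITY_GRID if purity_grid is None else purity_grid

    @classmethod
    def from_probes(
        cls,
        probes: pd.DataFrame,
        min_probes: int = 10,
        chrom_lengths: dict[str, int] | None = None,
        **kwargs,
    ) -> "GenomeAlterationModel":
        sample = None
        if "sample" in probes.columns and len(probes):
            sample = str(probes["sample"].iloc[0])
        segs = segment_probes(probes, min_probes=min_probes,
                              chrom_lengths=chrom_lengths)
        return cls(segs, sample=sample, **kwargs)

    def fit(self) -> "GenomeAlterationResults":
        pf = fit_purity_ploidy(self.segments, purity_grid=self.purity_grid)
        states = assign_states(self.segments, pf)
        return GenomeAlterationResults(self, pf, states)


class GenomeAlterationResults:
    """Fit results: estimates, per-segment states, diagnostics."""

    def __init__(self, model: GenomeAlterationModel, fit: PurityFit,
                 states: pd.DataFrame):
        self.model = model
        self.purity_fit = fit
        self.states = states

    @property
    def purity(self) -> float:
        return self.purity_fit.purity

    @property
    def centering(self) -> float:
        return self.purity_fit.centering

    @property
    def fit_score(self) -> float:
        return self.purity_fit.fit_score

    @property
    def flags(self) -> tuple[str, ...]:
        return self.purity_fit.flags

    def mean_copy_number(self) -> float:
        w = (self.states["end"] - self.states["start"]).to_numpy(float)
        return float((w * self.states["cn"]).sum() / w.sum())

    def summary(self) -> str:
        s = self.states
        lines = [
            "Genome alteration fit",
            "=" * 42,
            f"sample:            {self.model.sample or '-'}",
            f"purity:            {self.purity:.2f}",
            f"LRR centring:      {self.centering:+.3f}",
            f"fit score:         {self.fit_score:.4f}",
            f"segments:          {len(s)}",
            f"mean copy number:  {self.mean_copy_number():.2f}",
            f"flags:             {', '.join(self.flags) or 'none'}",
            "-" * 42,
            "state histogram (cn,major : n segments)",
        ]
        counts = s.groupby(["cn", "major"]).size()
        for (cn, major), n in counts.items():
            lines.append(f"  ({cn},{major}) : {n}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Segments in the (mirrored BAF, LRR) plane over the fitted lattice."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        pred_lrr, pred_baf = _predicted(self.purity, self.centering)
        ax.scatter(pred_baf, pred_lrr, marker="+", c="grey", label="lattice")
        s = self.states
        ax.scatter(s["mirrored_baf"], s["mean_lrr"],
                   s=np.sqrt(s["n_probes"]), c="crimson", alpha=0.6,
                   label="segments")
        ax.set_xlabel("mirrored BAF")
        ax.set_ylabel("LRR")
        ax.legend(frameon=False)
        return ax
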