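"""PCR microsatellite LOH assay logic at the ATM locus.

Allele ratios are computed from tumour and matched-normal peak heights:
``r = (T_a / T_b) / (N_a / N_b)``, folded to ``min(r, 1/r)`` so the
"allele ratio fell below 50%" rule reads as a two-sided imbalance test
independent of allele orientation.  A marker is informative when the normal
sample shows two peaks with a height ratio within [0.5, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["MarkerCall", "marker_loh", "locus_loh", "LOH_THRESHOLD",
           "RETENTION_THRESHOLD", "ATM_MARKERS"]

LOH_THRESHOLD = 0.5  # loh iff folded allele ratio < 0.5
RETENTION_THRESHOLD = 0.8  # an informative index > 0.8 asserts retention
INFORMATIVE_BAND = (0.5, 2.0)  # normal peak balance for a usable marker
ATM_MARKERS = ("D11S1113", "D11S1819", "D11S2179", "D11S1778")


@dataclass(frozen=True)
class MarkerCall:
    marker: str
    informative: bool
    loh_index: float | None = None
    loh: bool | None = None


def marker_loh(
    normal: tuple[float, float], tumour: tuple[float, float], marker: str = ""
) -> MarkerCall:
    """Call LOH for one marker from normal and tumour peak heights.

    Raises an assay-failure error when an informative marker shows no tumour
    signal at all (that is a failed PCR, not LOH).
    """
    n_a, n_b = normal
    t_a, t_b = tumour
    if min(n_a, n_b, t_a, t_b) < 0:
        raise ValueError("peak heights must be >= 0")
    informative = (
        n_a > 0 and n_b > 0 and INFORMATIVE_BAND[0] <= n_a / n_b <= INFORMATIVE_BAND[1]
    )
    if not informative:
        return MarkerCall(marker=marker, informative=False)
    if t_a == 0 and t_b == 0:
        raise ValueError(f"assay failure at marker {marker or '?'}: no tumour signal")
    if t_a == 0 or t_b == 0:
        index = 0.0
    else:
        r = (t_a / t_b) / (n_a / n_b)
        index = min(r, 1.0 / r)
    return MarkerCall(marker=marker, informative=True, loh_index=index,
                      loh=index < LOH_THRESHOLD)


def locus_loh(calls: list[MarkerCall]) -> tuple[str, bool]:
    """Combine marker calls into a locus-level status.

    Returns (status, discordant) with status in {"LOH", "no-LOH",
    "uninformative"}.  LOH requires at least one informative marker calling
    LOH and no informative marker asserting retention (index > 0.8); a
    marker set containing both kinds of evidence is flagged discordant and
    left unadjudicated (status "no-LOH" until resolved).
    """
    if not calls:
        raise ValueError("locus_loh needs at least one marker call")
    informative = [c for c in calls if c.informative]
    if not informative:
        return "uninformative", False
    any_loh = any(c.loh for c in informative)
    any_retained = any(c.loh_index > RETENTION_THRESHOLD for c in informative)
    if any_loh and not any_retained:
        return "LOH", False
    return "no-LOH", any_loh and any_retained


def call_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Locus calls for a long peak table (one row per sample x marker).

    Expects columns sample, marker, n_height_a, n_height_b, t_height_a,
    t_height_b; returns one row per sample with status and flags.
    """
    rows = []
    for sample, grp in peaks.groupby("sample", sort=True):
        calls = [
            marker_loh(
                (r.n_height_a, r.n_height_b),
                (r.t_height_a, r.t_height_b),
                marker=r.marker,
            )
            for r in grp.itertuples()
        ]
        status, discordant = locus_loh(calls)
        rows.append(
            {
                "sample": sample,
                "status": status,
                "discordant": discordant,
                "n_informative": sum(c.informative for c in calls),
            }
        )
    return pd.DataFrame(rows)
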