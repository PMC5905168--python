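"""Clinical-table statistics, molecular subtyping and variant sharing.

St. Gallen IHC-based molecular subtypes are assigned deterministically from
ER, PR, HER2 and Ki-67: triple-negative (ER-, PR-, HER2-),
HER2-overexpressing (ER-, PR-, HER2+), luminal A (ER+, HER2-, Ki-67 < 20%),
luminal B (ER+, HER2-, Ki-67 >= 20%) and luminal B/HER2+ (ER+, HER2+,
Ki-67 >= 20%).  PR does not discriminate luminal A from B.  HER2 positivity
resolves from IHC score 3+, or 2+ with FISH amplification.

Descriptive percentages are computed among known values and rounded
half-up to integers.  Fisher's exact test is the two-sided conditional test
by point-probability summation; group comparisons use logistic regression
adjusted for sex and age with two-tailed Wald p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "classify_subtype",
    "resolve_her2",
    "descriptive_table",
    "fisher_exact",
    "logistic_assoc",
    "variant_sharing",
    "KI67_CUTOFF",
    "load_atm_series_table",
]

KI67_CUTOFF = 20.0  # percent

SUBTYPES = (
    "triple-negative",
    "HER2-overexpressing",
    "luminal A",
    "luminal B",
    "luminal B/HER2+",
    "unknown",
)


def _is_unknown(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return str(v).lower() in ("unknown", "na", "nan", "")


def resolve_her2(her2=None, ihc_score=None, fish_amplified=None) -> str:
    """Resolve HER2 status to '+', '-' or 'unknown'.

    A direct '+'/'-' takes precedence; otherwise IHC 3+ is positive, IHC 2+
    resolves by FISH (unknown FISH leaves HER2 unresolved), IHC 0/1+ is
    negative.
    """
    if not _is_unknown(her2) and str(her2) in ("+", "-"):
        return str(her2)
    if _is_unknown(ihc_score):
        return "unknown"
    score = int(ihc_score)
    if score == 3:
        return "+"
    if score == 2:
        if _is_unknown(fish_amplified):
            return "unknown"
        return "+" if str(fish_amplified).lower() == "yes" else "-"
    return "-"


def classify_subtype(record) -> str:
    """St. Gallen molecular subtype from one clinical record (mapping or
    namedtuple-like with er, pr, her2[, her2_ihc_score, fish_amplified],
    ki67_pct)."""
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)
    er = get("er")
    pr = get("pr")
    her2 = resolve_her2(get("her2"), get("her2_ihc_score"), get("fish_amplified"))
    ki67 = get("ki67_pct")

    if _is_unknown(er):
        return "unknown"
    if er == "-":
        if _is_unknown(pr) or her2 == "unknown":
            return "unknown"
        if pr == "-":
            return "triple-negative" if her2 == "-" else "HER2-overexpressing"
        return "unknown"  # ER-/PR+ falls outside the rule set
    # ER positive
    if her2 == "unknown":
        return "unknown"
    if _is_unknown(ki67):
        return "unknown"
    ki67 = float(ki67)
    if her2 == "-":
        return "luminal A" if ki67 < KI67_CUTOFF else "luminal B"
    return "luminal B/HER2+" if ki67 >= KI67_CUTOFF else "unknown"


def _pct(n: int, d: int) -> int:
    """Percentage among known values, rounded half-up to integer."""
    if d == 0:
        return 0
    exact = Decimal(100 * n) / Decimal(d)
    return int(exact.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def descriptive_table(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per clinical variable.

    Ki-67 is dichotomised at 20%; the molecular subtype is derived from the
    IHC fields.  Unknowns are reported as separate rows and excluded from
    the percentage denominator.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["variable", "category", "count", "pct"])
    df = records.copy()
    out = []

    def tally(variable: str, series: pd.Series, categories: list[str]):
        known = series[~series.map(_is_unknown)]
        d = len(known)
        for cat in categories:
            n = int((known == cat).sum())
            out.append({"variable": variable, "category": cat, "count": n,
                        "pct": _pct(n, d)})
        n_unk = len(series) - d
        out.append({"variable": variable, "category": "unknown",
                    "count": int(n_unk), "pct": np.nan})

    if "histology" in df:
        tally("histology", df["histology"], ["ductal", "lobular", "other"])
    for col, cats in (("er", ["+", "-"]), ("pr", ["+", "-"]), ("her2", ["+", "-"])):
        if col in df:
            tally(col, df[col].astype(object), cats)
    if "ki67_pct" in df:
        ki = df["ki67_pct"].map(
            lambda v: "unknown" if _is_unknown(v)
            else ("≥20%" if float(v) >= KI67_CUTOFF else "<20%")
        )
        tally("ki67", ki, ["<20%", "≥20%"])
    subtype = df.apply(classify_subtype, axis=1)
    tally("subtype", subtype.map(lambda s: "unknown" if s == "unknown" else s),
          [s for s in SUBTYPES if s != "unknown"])
    return pd.DataFrame(out)


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of a 2xk table under the conditional hypergeometric."""
    t = np.asarray(table)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact test for a 2xk contingency table.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed one.  Returns p = 1 with
    a warning for degenerate (zero-margin) tables.
    """
    import warnings

    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("fisher_exact expects a 2xk table, k >= 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        warnings.warn("zero-margin table: p = 1", stacklevel=2)
        return 1.0
    logp_obs = _log_table_prob(t)
    k = t.shape[1]
    total = 0.0

    def rec(j: int, remaining: int, first_row: list[int]):
        nonlocal total
        if j == k - 1:
            if remaining <= col[j]:
                cand = first_row + [remaining]
                tab = np.array([cand, col - np.array(cand)])
                if (tab >= 0).all():
                    lp = _log_table_prob(tab)
                    if lp <= logp_obs + 1e-9:
                        total += math.exp(lp)
            return
        for v in range(0, min(col[j], remaining) + 1):
            rec(j + 1, remaining - v, first_row + [v])

    rec(0, int(row[0]), [])
    return min(total, 1.0)


@dataclass(frozen=True)
class LogisticAssoc:
    odds_ratio: float | None
    p_value: float | None
    coef: float | None
    separation: bool


def logistic_assoc(
    outcome: np.ndarray,
    group: np.ndarray,
    sex: np.ndarray | None = None,
    age: np.ndarray | None = None,
    maxiter: int = 200,
    tol: float = 1e-8,
) -> LogisticAssoc:
    """Odds ratio and two-tailed Wald p for ``group`` from a logistic fit,
    optionally adjusted for sex and age.  Complete separation is flagged and
    no p-value reported."""
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must not be constant")
    cols = [np.asarray(group, dtype=float)]
    names = ["group"]
    if sex is not None:
        sx = np.asarray(
            [0.0 if str(s).upper() in ("F", "FEMALE", "0") else 1.0 for s in sex]
        )
        if len(np.unique(sx)) > 1:
            cols.append(sx)
            names.append("sex")
    if age is not None:
        cols.append(np.asarray(age, dtype=float))
        names.append("age")
    x = sm.add_constant(np.column_stack(cols), prepend=True)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, x).fit(disp=0, maxiter=maxiter, tol=tol)
    except Exception:
        return LogisticAssoc(None, None, None, separation=True)
    coef = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or abs(coef) > 15 or se > 100:
        return LogisticAssoc(None, None, coef, separation=True)
    return LogisticAssoc(
        odds_ratio=float(np.exp(coef)),
        p_value=float(res.pvalues[1]),
        coef=coef,
        separation=False,
    )


def variant_sharing(variant_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts of variants (and coding genes) shared by exactly m tumours.

    Variant identity is (chrom, pos, ref, alt); duplicates within one tumour
    are dropped with a warning.  Gene-level sharing uses the gene field of
    coding variants only.
    """
    import warnings

    n = len(variant_sets)
    var_members: dict[tuple, set[str]] = {}
    gene_members: dict[str, set[str]] = {}
    for tid, df in variant_sets.items():
        keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
        if len(keys) != len(set(keys)):
            warnings.warn(f"duplicate variants within {tid}; deduplicated",
                          stacklevel=2)
        for key in set(keys):
            var_members.setdefault(key, set()).add(tid)
        if "coding" in df:
            coding = df[df["coding"].astype(bool)]
            for g in set(coding["gene"]):
                gene_members.setdefault(g, set()).add(tid)
    rows = []
    for m in range(1, n + 1):
        rows.append(
            {
                "shared_by": m,
                "n_variants": sum(1 for v in var_members.values() if len(v) == m),
                "n_genes": sum(1 for v in gene_members.values() if len(v) == m),
            }
        )
    return pd.DataFrame(rows)


def load_atm_series_table() -> pd.DataFrame:
    """Packaged 36-tumour clinical table whose marginal counts transcribe
    the study series; the row-level joint assignment is synthetic (the
    source publishes only the margins)."""
    from importlib import resources

    with resources.files("tumourprint.data").joinpath("atm_series_table2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
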