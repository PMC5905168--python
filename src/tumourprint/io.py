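"""File formats: probe TSV, SEG TSV, matrices, regions, Newick, minimal VCF.

Intervals are 0-based half-open in memory and 1-based inclusive in SEG files
on disk; the conversion happens only here.  Every writer/reader pair
round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_probe_tsv", "write_probe_tsv",
    "read_seg_tsv", "write_seg_tsv",
    "read_regions_tsv", "write_regions_tsv",
    "read_matrix_tsv", "write_matrix_tsv",
    "write_newick", "read_newick",
    "write_minimal_vcf", "read_minimal_vcf",
    "read_yaml", "write_yaml",
]

PROBE_COLUMNS = ["sample", "chrom", "pos", "baf", "lrr", "genotype"]
VCF_INFO_TAGS = ("GENE", "CODING", "DELET")


class ParseError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing} "
                         f"(line 1: header {list(df.columns)})")


def write_probe_tsv(probes: pd.DataFrame, path) -> None:
    probes.to_csv(path, sep="\t", index=False, columns=PROBE_COLUMNS,
                  float_format="%.6g")


def read_probe_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PROBE_COLUMNS, path)
    return df


def write_seg_tsv(segments: pd.DataFrame, path, extra_cols: list[str] | None = None
                  ) -> None:
    """SEG-like TSV, converting to 1-based inclusive starts/ends on disk."""
    cols = ["sample", "chrom", "start", "end"] + (extra_cols or
                                                  ["n_probes", "cn", "major", "minor"])
    out = segments.copy()
    if "sample" not in out.columns:
        out["sample"] = "."
    out["start"] = out["start"].astype(np.int64) + 1  # 0-based -> 1-based
    out["end"] = out["end"].astype(np.int64)  # half-open end == inclusive end
    out.to_csv(path, sep="\t", index=False,
               columns=[c for c in cols if c in out.columns] +
                       [c for c in (extra_cols or []) if c not in cols])


def read_seg_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "chrom", "start", "end"], path)
    df["start"] = df["start"].astype(np.int64) - 1  # 1-based -> 0-based
    df["end"] = df["end"].astype(np.int64)
    return df


def write_regions_tsv(regions, path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start + 1,
            "end": r.end,
            "kind": r.kind,
            "frequency": round(r.frequency, 6),
            "n_altered": r.n_altered,
            "n_total": r.n_total,
        }
        for r in regions
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "kind", "frequency",
                       "n_altered", "n_total"]
    ).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path):
    from .recurrence import RecurrentRegion

    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "start", "end", "kind", "frequency",
                          "n_altered", "n_total"], path)
    return [
        RecurrentRegion(
            chrom=r.chrom, start=int(r.start) - 1, end=int(r.end), kind=r.kind,
            frequency=float(r.frequency), n_altered=int(r.n_altered),
            n_total=int(r.n_total),
        )
        for r in df.itertuples()
    ]


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Alteration matrix with 'chrom:start-end:kind' column names (1-based)."""
    out = matrix.copy()
    out.columns = [f"{c}:{s + 1}-{e}:{k}" for c, s, e, k in matrix.columns]
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    tuples = []
    for name in df.columns:
        try:
            chrom, span, kind = name.split(":")
            s, e = span.split("-")
            tuples.append((chrom, int(s) - 1, int(e), kind))
        except ValueError as exc:
            raise ParseError(f"{path}: malformed matrix column {name!r}") from exc
    df.columns = pd.MultiIndex.from_tuples(tuples,
                                           names=["chrom", "start", "end", "kind"])
    return df


def write_newick(newick: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def read_newick(path) -> str:
    with open(path) as fh:
        return fh.read().strip()


def write_minimal_vcf(variants: pd.DataFrame, path) -> None:
    """Minimal VCF 4.2 with INFO tags GENE, CODING, DELET per record.

    ``variants`` is the long per-tumour table (sample, chrom, pos, ref, alt,
    gene, coding, predicted_deleterious); one file per sample is the usual
    layout, but multiple samples are allowed and recorded via a SAMPLE tag.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CODING,Number=1,Type=Integer,Description="Coding variant">\n')
        fh.write('##INFO=<ID=DELET,Number=1,Type=Integer,Description="Predicted deleterious">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumour id">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        df = variants.sort_values(["chrom", "pos", "sample"])
        for r in df.itertuples():
            info = (
                f"GENE={r.gene};CODING={int(bool(r.coding))};"
                f"DELET={int(bool(r.predicted_deleterious))};SAMPLE={r.sample}"
            )
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info}\n"
            )


def read_minimal_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF back through cyvcf2, validating required tags."""
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for i, rec in enumerate(vcf, start=1):
        info = dict(rec.INFO)
        for tag in VCF_INFO_TAGS:
            if tag not in info:
                raise ParseError(
                    f"{path}: record {i} ({rec.CHROM}:{rec.POS}) missing INFO tag {tag}"
                )
        rows.append(
            {
                "sample": info.get("SAMPLE", "."),
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "gene": info["GENE"],
                "coding": bool(int(info["CODING"])),
                "predicted_deleterious": bool(int(info["DELET"])),
            }
        )
    vcf.close()
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "gene", "coding",
                       "predicted_deleterious"]
    )


def write_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_yaml(path) -> dict:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    with open(p) as fh:
        return yaml.safe_load(fh)
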