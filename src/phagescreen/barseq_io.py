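"""Tabular I/O and barcode extraction from raw reads.

All library and count tables are tab-separated UTF-8 text with a header
line; ``write`` followed by ``read`` is the identity on valid tables.
Barcode extraction locates two fixed flanking sequences (allowing a small
number of mismatches and a short leading spacer) and counts the exact
intervening 20-mer — no error-correction clustering is attempted, since at
20 nt random-barcode collisions are negligible and the sequencing protocol
relies on exact barcode identity.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable

import pandas as pd

from phagescreen.containers import CountTable, SampleQCReport, TableFormatError

#: sample read-count gate used for deep-sequencing (CRISPRi-style) screens
DEFAULT_MIN_SAMPLE_READS = 2_000_000

_POOL_COLUMNS = ["barcode", "scaffold", "position", "strand",
                 "gene_id", "fraction_within_gene", "central_flag"]
_FRAGMENT_COLUMNS = ["up_barcode", "dn_barcode", "scaffold", "start", "end", "covered_genes"]
_GUIDE_COLUMNS = ["guide_id", "sequence", "target_id", "feature_class", "strand"]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")


def _require_unique(df: pd.DataFrame, key, path) -> None:
    keys = df[key] if isinstance(key, str) else df[list(key)].apply(tuple, axis=1)
    dup = keys.duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # header is line 1
        raise TableFormatError(f"{path}: duplicate {key} at line {line}")


# ---------------------------------------------------------------------------
# barcode pool


def write_barcode_pool(pool: pd.DataFrame, path) -> None:
    pool.to_csv(path, sep="\t", index=False)


def read_barcode_pool(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": "object"})
    _require_columns(df, _POOL_COLUMNS, path)
    _require_unique(df, "barcode", path)
    df["gene_id"] = df["gene_id"].where(df["gene_id"].notna(), None)
    has_gene = df["gene_id"].notna()
    has_frac = df["fraction_within_gene"].notna()
    if (has_gene ^ has_frac).any():
        line = int((has_gene ^ has_frac).idxmax()) + 2
        raise TableFormatError(
            f"{path}: fraction_within_gene must be present iff gene_id is (line {line})"
        )
    df["central_flag"] = df["central_flag"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# fragment map


def write_fragment_map(fmap: pd.DataFrame, path) -> None:
    out = fmap.copy()
    out["covered_genes"] = [",".join(genes) for genes in out["covered_genes"]]
    out.to_csv(path, sep="\t", index=False)


def read_fragment_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"covered_genes": str})
    _require_columns(df, _FRAGMENT_COLUMNS, path)
    _require_unique(df, ("up_barcode", "dn_barcode"), path)
    bad = df["start"] > df["end"]
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise TableFormatError(f"{path}: start > end at line {line}")
    df["covered_genes"] = [
        tuple(s.split(",")) if s else tuple() for s in df["covered_genes"]
    ]
    return df


# ---------------------------------------------------------------------------
# guide library


def write_guide_library(guides: pd.DataFrame, path) -> None:
    guides.to_csv(path, sep="\t", index=False)


def read_guide_library(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _GUIDE_COLUMNS, path)
    _require_unique(df, "sequence", path)
    bad = ~df["feature_class"].isin(["gene", "promoter", "tfbs"])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise TableFormatError(f"{path}: unknown feature_class at line {line}")
    return df


# ---------------------------------------------------------------------------
# count tables


def write_count_table(table: CountTable, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.counts.tsv`` and ``<prefix>.samples.tsv``."""
    prefix = Path(prefix)
    counts_path = prefix.with_suffix(".counts.tsv")
    samples_path = prefix.with_suffix(".samples.tsv")
    table.counts.rename_axis("key").to_csv(counts_path, sep="\t")
    table.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")
    return counts_path, samples_path


def read_count_table(prefix) -> CountTable:
    prefix = Path(prefix)
    counts_path = prefix.with_suffix(".counts.tsv")
    samples_path = prefix.with_suffix(".samples.tsv")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    for col in counts.columns:
        if not pd.api.types.is_integer_dtype(counts[col]):
            nonint = counts[col].astype(float) % 1 != 0
            row = counts.index[0] if counts.empty else counts.index[int(nonint.to_numpy().argmax())]
            raise TableFormatError(
                f"{counts_path}: non-integer count in sample {col!r} at row {row!r}"
            )
    neg = counts < 0
    if neg.to_numpy().any():
        col = neg.any(axis=0).idxmax()
        row = counts.index[int(neg[col].to_numpy().argmax())]
        raise TableFormatError(f"{counts_path}: negative count in sample {col!r} at row {row!r}")
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise TableFormatError(f"{counts_path}: duplicate row key {dup!r}")
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountTable(counts, samples)


# ---------------------------------------------------------------------------
# raw reads -> counts


def read_fastq(path) -> list[str]:
    """Sequences of a single-end FASTQ file, in file order."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[str], path, quality: int = 30) -> None:
    """Write reads as FASTQ with a constant quality score."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i + 1}\n{read}\n+\n{chr(quality + 33) * len(read)}\n")


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_barcodes(
    reads: Iterable[str],
    flank_before: str,
    flank_after: str,
    barcode_len: int = 20,
    max_flank_mismatches: int = 2,
    max_spacer: int = 4,
    sample_id: str = "sample",
    min_sample_reads: int = DEFAULT_MIN_SAMPLE_READS,
) -> tuple[Counter, SampleQCReport]:
    """Count exact barcodes between two flanking sequences.

    The flank pair is searched at offsets 0..``max_spacer`` from the read
    start (sequencing constructs carry a variable 1–4 nt spacer before the
    priming site).  A read contributes iff both flanks match within
    ``max_flank_mismatches`` each and the intervening segment has exactly
    ``barcode_len`` bases; the first matching offset wins.
    """
    if not flank_before or not flank_after:
        raise ValueError("flanks must be nonempty")
    f1, f2 = len(flank_before), len(flank_after)
    counts: Counter = Counter()
    total = 0
    extracted = 0
    for read in reads:
        total += 1
        for offset in range(max_spacer + 1):
            end = offset + f1 + barcode_len + f2
            if end > len(read):
                break
            if _mismatches(read[offset : offset + f1], flank_before) > max_flank_mismatches:
                continue
            tail = read[offset + f1 + barcode_len : end]
            if _mismatches(tail, flank_after) > max_flank_mismatches:
                continue
            barcode = read[offset + f1 : offset + f1 + barcode_len]
            counts[barcode] += 1
            extracted += 1
            break
    report = SampleQCReport(
        sample_id=sample_id, total_reads=total, extracted_reads=extracted,
        min_reads=min_sample_reads,
    )
    return counts, report


def counts_to_table(
    per_sample_counts: dict[str, Counter], samples: pd.DataFrame
) -> CountTable:
    """Assemble per-sample extraction results into a :class:`CountTable`."""
    counts = pd.DataFrame(per_sample_counts).fillna(0).astype(int)
    counts = counts.reindex(columns=list(samples.index))
    return CountTable(counts, samples)


def attach_counts_to_pool(
    counts: pd.DataFrame, pool: pd.DataFrame, drop_unmapped: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict counts to barcodes present in the pool.

    Returns the (optionally restricted) counts and the per-sample fraction
    of reads on barcodes absent from the pool.  The key column is
    ``barcode`` for insertion pools and ``up_barcode`` for fragment maps.
    """
    key = "up_barcode" if "up_barcode" in pool.columns else "barcode"
    known = pd.Index(pool[key])
    mapped = counts.index.isin(known)
    totals = counts.sum(axis=0).astype(float)
    mapped_totals = counts.loc[mapped].sum(axis=0).astype(float)
    unmapped_fraction = 1.0 - (mapped_totals / totals.where(totals > 0, 1.0)).where(
        totals > 0, 1.0
    )
    unmapped_fraction.name = "unmapped_fraction"
    out = counts.loc[mapped] if drop_unmapped else counts
    return out, unmapped_fraction
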