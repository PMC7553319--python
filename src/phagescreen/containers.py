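"""Core in-memory containers shared across the screen analyses.

The central object is :class:`CountTable`: a nonnegative integer matrix of
barcode (or guide) counts per sequencing sample, together with per-sample
metadata describing the selection each sample came from.  Samples taken
before selection ("start", also called time-zero) serve as the abundance
reference for the matching post-selection ("end") samples; samples
processed together form a *set*, and every end sample must have at least
one start sample in its set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["phage", "moi", "format", "role", "set_label", "replicate"]

VALID_ROLES = {"start", "end"}
VALID_FORMATS = {"liquid", "solid"}


class TableFormatError(ValueError):
    """A tabular input violated its schema (missing column, bad cell, duplicate key)."""


@dataclass
class SampleQCReport:
    """Per-sample quality summary from barcode extraction.

    ``pass_flag`` is a pure function of ``total_reads`` and the configured
    read-count threshold (deep-sequencing screens are conventionally gated
    at 2 million reads per sample).
    """

    sample_id: str
    total_reads: int
    extracted_reads: int
    min_reads: int

    @property
    def extraction_rate(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.extracted_reads / self.total_reads

    @property
    def pass_flag(self) -> bool:
        return self.total_reads >= self.min_reads


class CountTable:
    """Counts (rows = barcodes/guides, columns = samples) plus sample metadata.

    Parameters
    ----------
    counts
        Integer DataFrame; index holds barcode or guide keys, columns hold
        sample identifiers.
    samples
        DataFrame indexed by sample identifier with columns
        ``phage, moi, format, role, set_label, replicate``.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame, validate: bool = True):
        self.counts = counts
        self.samples = samples
        if validate:
            self.validate()

    def validate(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise TableFormatError(f"sample table missing columns: {missing}")
        if set(self.counts.columns) != set(self.samples.index):
            raise TableFormatError(
                "count columns and sample table disagree: "
                f"{sorted(set(self.counts.columns) ^ set(self.samples.index))}"
            )
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableFormatError(f"duplicate count row key: {dup!r}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(np.equal(np.mod(values, 1), 0)):
                    bad = np.argwhere(np.mod(values, 1) != 0)[0]
                    raise TableFormatError(
                        f"non-integer count at row {self.counts.index[bad[0]]!r}, "
                        f"sample {self.counts.columns[bad[1]]!r}"
                    )
            if (values < 0).any():
                bad = np.argwhere(values < 0)[0]
                raise TableFormatError(
                    f"negative count at row {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
        bad_role = set(self.samples["role"]) - VALID_ROLES
        if bad_role:
            raise TableFormatError(f"unknown sample role(s): {sorted(bad_role)}")
        for sid, row in self.samples[self.samples["role"] == "end"].iterrows():
            starts = self.start_samples(row["set_label"])
            if len(starts) == 0:
                raise TableFormatError(
                    f"end sample {sid!r} has no start sample in set {row['set_label']!r}"
                )

    # -- sample selection helpers -------------------------------------------------

    def start_samples(self, set_label: str | None = None) -> list[str]:
        mask = self.samples["role"] == "start"
        if set_label is not None:
            mask &= self.samples["set_label"] == set_label
        return list(self.samples.index[mask])

    def end_samples(self, set_label: str | None = None) -> list[str]:
        mask = self.samples["role"] == "end"
        if set_label is not None:
            mask &= self.samples["set_label"] == set_label
        return list(self.samples.index[mask])

    def start_reference(self, set_label: str) -> pd.Series:
        """Summed counts over the set's start (time-zero) samples."""
        starts = self.start_samples(set_label)
        if not starts:
            raise ValueError(f"no start samples in set {set_label!r}")
        ref = self.counts[starts].sum(axis=1)
        ref.name = f"{set_label}:start"
        return ref

    def subset_rows(self, keys) -> "CountTable":
        return CountTable(self.counts.loc[keys], self.samples, validate=False)

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountTable({self.counts.shape[0]} rows x {self.counts.shape[1]} samples, "
            f"{len(self.start_samples())} start / {len(self.end_samples())} end)"
        )
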