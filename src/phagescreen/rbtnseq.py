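"""Strain and gene fitness for barcoded transposon (loss-of-function) screens.

A strain's fitness is the normalized log2 ratio of its barcode abundance at
the end of a selection experiment to its abundance at the start (time
zero).  Gene fitness is the inverse-variance weighted mean over the gene's
central-insertion strains (insertions at 10–90% of the ORF), normalized so
the median gene fitness of the experiment is zero.  Phage selection is an
extreme positive screen — a handful of resistant mutants absorb most reads
— so hit calling uses stringent filters: ``fit >= 5``, t-like statistic
``t >= 5``, standard error ``fit/t <= 2``, and ``fit >= maxFit - 8`` where
``maxFit`` is the top gene fitness of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from phagescreen.containers import CountTable

LN2_SQ = np.log(2) ** 2

#: additive pseudocount applied to depth-scaled counts before the log ratio
DEFAULT_PSEUDOCOUNT = 0.125

#: variance floor for the t-like statistic; under sweep-like selection the
#: member strains of a hit gene can agree almost exactly, which would
#: otherwise send t to infinity
V_FLOOR = 0.04

DEFAULT_THRESHOLDS = {"fit_min": 5.0, "t_min": 5.0, "se_max": 2.0, "max_gap": 8.0}


@dataclass
class ExperimentQC:
    """Coverage gate for one experiment: mean time-zero reads per scored gene >= 10."""

    experiment_id: str
    mean_reads_per_gene: float
    max_fit: float
    min_mean_reads: float = 10.0

    @property
    def pass_flag(self) -> bool:
        return self.mean_reads_per_gene >= self.min_mean_reads


#: reference depth both samples are scaled to before the log ratio
TARGET_DEPTH = 1_000_000.0


def strain_fitness(
    start_counts: pd.Series,
    end_counts: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    target_depth: float = TARGET_DEPTH,
) -> pd.DataFrame:
    """Raw (pre-normalization) per-strain log2 fitness.

    Both samples are scaled to a common fixed depth (counts per million by
    default), then ``log2((end + pc) / (start + pc))``.  Scaling to a fixed
    reference rather than to the observed totals makes every downstream
    quantity exactly invariant to multiplying a sample's counts by a
    constant.  The depth-scaled counts are kept for the weighting.
    """
    start_counts, end_counts = start_counts.align(end_counts, join="outer", fill_value=0)
    ts, te = float(start_counts.sum()), float(end_counts.sum())
    if ts == 0:
        raise ValueError(f"start sample {start_counts.name!r} has zero total reads")
    if te == 0:
        raise ValueError(f"end sample {end_counts.name!r} has zero total reads")
    s = start_counts.astype(float) * (target_depth / ts)
    e = end_counts.astype(float) * (target_depth / te)
    fitness = np.log2((e + pseudocount) / (s + pseudocount))
    return pd.DataFrame(
        {
            "fitness": fitness,
            "reads_start": start_counts.astype(int),
            "reads_end": end_counts.astype(int),
            "reads_start_scaled": s,
            "reads_end_scaled": e,
        }
    ).rename_axis("barcode")


def _strain_weights(sf: pd.DataFrame) -> pd.Series:
    """Inverse of the per-strain count-noise variance proxy."""
    var = (1.0 / (1.0 + sf["reads_start_scaled"]) + 1.0 / (1.0 + sf["reads_end_scaled"])) / LN2_SQ
    return 1.0 / var


def _weighted_gene_table(sf: pd.DataFrame, pool: pd.DataFrame, v_floor: float) -> pd.DataFrame:
    """Weighted per-gene aggregation of central-insertion strain fitness."""
    central = pool[pool["central_flag"].astype(bool)][["barcode", "gene_id"]]
    merged = sf.reset_index().merge(central, on="barcode", how="inner")
    if merged.empty:
        return pd.DataFrame(
            columns=["gene_id", "fit", "t", "se", "n_strains", "reads_start", "reads_end"]
        )
    merged["weight"] = _strain_weights(merged.set_index("barcode")).to_numpy()
    rows = []
    for gene_id, grp in merged.groupby("gene_id", sort=True):
        w = grp["weight"].to_numpy()
        f = grp["fitness"].to_numpy()
        wsum = w.sum()
        fit = float(np.sum(w * f) / wsum)
        n = len(f)
        if n >= 2:
            vw = float(np.sum(w * (f - fit) ** 2) / ((n - 1) * wsum))
        else:
            vw = float(1.0 / wsum)
        v = max(vw, v_floor)
        t = fit / np.sqrt(v)
        rows.append(
            {
                "gene_id": gene_id,
                "fit": fit,
                "t": float(t),
                # se == fit/t whenever t != 0; sqrt(v) extends that to fit == 0
                "se": float(np.sqrt(v)),
                "n_strains": n,
                "reads_start": int(grp["reads_start"].sum()),
                "reads_end": int(grp["reads_end"].sum()),
            }
        )
    return pd.DataFrame(rows)


def normalize_experiment(
    sf: pd.DataFrame, pool: pd.DataFrame, min_genes: int = 50, v_floor: float = V_FLOOR
) -> tuple[pd.DataFrame, float]:
    """Shift strain fitness so the median preliminary gene fitness is zero.

    A single additive constant per experiment; returns the shifted table
    and the constant.  Requires at least ``min_genes`` scoreable genes —
    the median of a handful of genes is not a usable location estimate.
    """
    prelim = _weighted_gene_table(sf, pool, v_floor)
    if len(prelim) < min_genes:
        raise ValueError(
            f"only {len(prelim)} scoreable genes (< {min_genes}); cannot normalize"
        )
    offset = float(prelim["fit"].median())
    out = sf.copy()
    out["fitness"] = out["fitness"] - offset
    return out, offset


def gene_fitness(
    sf_normalized: pd.DataFrame, pool: pd.DataFrame, v_floor: float = V_FLOOR
) -> pd.DataFrame:
    """Per-gene fitness with t-like statistic.

    ``fit`` is the inverse-variance weighted mean of the gene's central
    strains; ``t = fit / sqrt(max(Vw, v_floor))`` with ``Vw`` the weighted
    variance of the mean; ``se = fit / t``.  Genes with no central strain
    are absent from the output.
    """
    return _weighted_gene_table(sf_normalized, pool, v_floor)


def half_gene_consistency(
    sf_normalized: pd.DataFrame, pool: pd.DataFrame, v_floor: float = V_FLOOR
) -> pd.DataFrame:
    """Gene fitness computed separately from each half of the ORF.

    Splits central strains at fractional position 0.5 and scores each half
    exactly as :func:`gene_fitness` does; genes lacking a central strain in
    either half are omitted.  Agreement between halves is the internal
    consistency check used to justify the stringent hit filters.
    """
    halves = []
    for lo, hi, name in [(0.0, 0.5, "fit_first_half"), (0.5, 1.0, "fit_second_half")]:
        sub = pool[
            pool["central_flag"].astype(bool)
            & (pool["fraction_within_gene"] >= lo)
            & (pool["fraction_within_gene"] < (hi if hi < 1.0 else 1.01))
        ]
        gf = _weighted_gene_table(sf_normalized, sub, v_floor)
        halves.append(gf.set_index("gene_id")["fit"].rename(name))
    out = pd.concat(halves, axis=1, join="inner").reset_index()
    return out


def fit_experiment(
    table: CountTable,
    pool: pd.DataFrame,
    end_sample: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_genes: int = 50,
    v_floor: float = V_FLOOR,
) -> tuple[pd.DataFrame, ExperimentQC]:
    """Full pipeline for one experiment (one end sample vs its set's time zero).

    The start reference is the summed counts over the set's start samples.
    Returns the per-gene fitness table and the experiment QC record.
    """
    meta = table.samples.loc[end_sample]
    start = table.start_reference(meta["set_label"])
    end = table.counts[end_sample]
    sf = strain_fitness(start, end, pseudocount)
    sf_norm, _ = normalize_experiment(sf, pool, min_genes=min_genes, v_floor=v_floor)
    gf = gene_fitness(sf_norm, pool, v_floor=v_floor)
    mean_reads = float(gf["reads_start"].mean()) if len(gf) else 0.0
    qc = ExperimentQC(
        experiment_id=end_sample,
        mean_reads_per_gene=mean_reads,
        max_fit=float(gf["fit"].max()) if len(gf) else np.nan,
    )
    return gf, qc


def fit_all_experiments(
    table: CountTable,
    pool: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_genes: int = 50,
    v_floor: float = V_FLOOR,
) -> tuple[pd.DataFrame, list[ExperimentQC]]:
    """Score every end sample; returns a long gene-fitness table plus QC records."""
    frames = []
    qcs = []
    for end_sample in table.end_samples():
        gf, qc = fit_experiment(
            table, pool, end_sample, pseudocount=pseudocount,
            min_genes=min_genes, v_floor=v_floor,
        )
        meta = table.samples.loc[end_sample]
        gf = gf.assign(
            experiment=end_sample, phage=meta["phage"], moi=meta["moi"], format=meta["format"],
        )
        frames.append(gf)
        qcs.append(qc)
    if not frames:
        return pd.DataFrame(), qcs
    return pd.concat(frames, ignore_index=True), qcs


def call_hits(
    gene_fits: pd.DataFrame,
    fit_min: float = 5.0,
    t_min: float = 5.0,
    se_max: float = 2.0,
    max_gap: float = 8.0,
    qc: list[ExperimentQC] | None = None,
    background: str = "K-12",
) -> pd.DataFrame:
    """Stringent positive-selection hit calling over a long gene-fitness table.

    A gene-experiment record is a hit iff ``fit >= fit_min``,
    ``t >= t_min``, ``fit/t <= se_max`` and ``fit >= maxFit - max_gap``
    with ``maxFit`` the top gene fitness of the same experiment.
    Experiments failing QC (mean time-zero reads per gene < 10) are
    excluded entirely.
    """
    if gene_fits.empty:
        return pd.DataFrame(
            columns=["screen", "background", "phage", "moi", "format",
                     "feature_id", "score", "t", "se", "experiment"]
        )
    df = gene_fits.copy()
    if qc is not None:
        passing = {q.experiment_id for q in qc if q.pass_flag}
        df = df[df["experiment"].isin(passing)]
    max_fit = df.groupby("experiment")["fit"].transform("max")
    mask = (
        (df["fit"] >= fit_min)
        & (df["t"] >= t_min)
        & (df["fit"] / df["t"] <= se_max)
        & (df["fit"] >= max_fit - max_gap)
    )
    hits = df[mask]
    return pd.DataFrame(
        {
            "screen": "rbtnseq",
            "background": background,
            "phage": hits["phage"].to_numpy(),
            "moi": hits["moi"].to_numpy(),
            "format": hits["format"].to_numpy(),
            "feature_id": hits["gene_id"].to_numpy(),
            "score": hits["fit"].to_numpy(),
            "t": hits["t"].to_numpy(),
            "se": (hits["fit"] / hits["t"]).to_numpy(),
            "experiment": hits["experiment"].to_numpy(),
        }
    )
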