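"""Gain-of-function fragment fitness and NNLS gene-score deconvolution.

In a dual-barcoded shotgun expression (Dub-seq) screen each strain carries
a random ~2.5-kb genomic fragment on a multicopy vector.  A fragment's
fitness is the normalized log2 ratio of its counts in a treatment sample to
its summed counts across the set's time-zero samples.  Because a fragment
typically covers 2–3 genes, per-gene effects are deconvolved by regressing
fragment scores on the binary full-coverage design (fragment x gene) under
a nonnegativity constraint: the NNLS solution attributes shared enrichment
to the causal gene rather than its neighbours and cannot overfit with
negative compensations.  An empirical false-discovery rate is estimated by
shuffling the barcode-to-fragment assignment and re-calling hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse import csgraph

from phagescreen.containers import CountTable

DEFAULT_PSEUDOCOUNT = 0.125

#: a barcode is usable iff it has >= 10 reads in at least one time-zero sample
MIN_T0_READS = 10

DEFAULT_THRESHOLDS = {"score_min": 4.0, "effect_min": 2.0, "p_max": 0.05, "reads_min": 10.0}


@dataclass
class ShuffleFdrReport:
    """Observed vs barcode-shuffled hit counts at fixed thresholds.

    ``fdr = mean(shuffled_hits) / observed_hits``; defined as 0 when both
    the observed and every shuffled count are zero, and infinity when only
    the observed count is zero.
    """

    thresholds: dict
    observed_hits: int
    shuffled_hits: list[int] = field(default_factory=list)

    @property
    def fdr(self) -> float:
        mean_shuffled = float(np.mean(self.shuffled_hits)) if self.shuffled_hits else 0.0
        if self.observed_hits == 0:
            return 0.0 if mean_shuffled == 0 else float("inf")
        return mean_shuffled / self.observed_hits


def select_valid_barcodes(
    table: CountTable, set_label: str, min_reads: int = MIN_T0_READS
) -> pd.Index:
    """Barcodes with at least ``min_reads`` in >= 1 time-zero sample of the set."""
    starts = table.start_samples(set_label)
    if not starts:
        raise ValueError(f"set {set_label!r} has no time-zero samples")
    ok = (table.counts[starts] >= min_reads).any(axis=1)
    return table.counts.index[ok]


def fragment_scores(
    table: CountTable,
    treatment_sample: str,
    valid_barcodes: pd.Index | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-fragment fitness for one treatment sample.

    Treatment counts and the summed time-zero counts (restricted to valid
    barcodes) are scaled to equal totals, log2-ratioed with a pseudocount,
    and median-shifted so the typical fragment scores 0.
    """
    meta = table.samples.loc[treatment_sample]
    if valid_barcodes is None:
        valid_barcodes = select_valid_barcodes(table, meta["set_label"])
    if len(valid_barcodes) == 0:
        raise ValueError("no valid barcodes for this set")
    t0 = table.start_reference(meta["set_label"]).loc[valid_barcodes].astype(float)
    tr = table.counts.loc[valid_barcodes, treatment_sample].astype(float)
    target = (t0.sum() + tr.sum()) / 2.0
    t0s = t0 * (target / t0.sum())
    trs = tr * (target / tr.sum()) if tr.sum() > 0 else tr
    raw = np.log2((trs + pseudocount) / (t0s + pseudocount))
    score = raw - np.median(raw)
    return pd.DataFrame(
        {
            "score": score,
            "reads_treatment": tr.astype(int),
            "reads_t0_total": t0.astype(int),
        }
    ).rename_axis("barcode")


def _component_labels(design: sparse.csr_matrix) -> np.ndarray:
    """Connected-component label per gene of the fragment-gene bipartite graph."""
    n_frag, n_gene = design.shape
    adj = sparse.bmat(
        [[None, design], [design.T, None]], format="csr"
    )
    _, labels = csgraph.connected_components(adj, directed=False)
    return labels[n_frag:]


def gene_scores_nnls(frag_scores: pd.DataFrame, fmap: pd.DataFrame) -> pd.DataFrame:
    """Deconvolve fragment scores into nonnegative per-gene effects.

    The design matrix has a 1 where a fragment fully covers a gene (start
    to stop codon); partial overlap contributes nothing.  NNLS is solved
    independently per connected component of the fragment-gene graph,
    which yields the same solution as the genome-wide problem at bounded
    size.  Alongside ``score_nnls`` each gene gets the plain mean score of
    its covering fragments, a one-sample t-test p-value of those scores
    against 0 (the between-fragment consistency gate), and the summed
    treatment reads supporting it.
    """
    fm = fmap[fmap["up_barcode"].isin(frag_scores.index)]
    pairs = [
        (bc, g) for bc, genes in zip(fm["up_barcode"], fm["covered_genes"]) for g in genes
    ]
    if not pairs:
        return pd.DataFrame(
            columns=["gene_id", "score_nnls", "score_mean", "n_fragments",
                     "consistency_p", "reads_support"]
        )
    pair_df = pd.DataFrame(pairs, columns=["up_barcode", "gene_id"]).drop_duplicates()
    frag_ids = pd.Index(pair_df["up_barcode"].unique())
    gene_ids = pd.Index(sorted(pair_df["gene_id"].unique()))
    fi = frag_ids.get_indexer(pair_df["up_barcode"])
    gi = gene_ids.get_indexer(pair_df["gene_id"])
    design = sparse.csr_matrix(
        (np.ones(len(pair_df)), (fi, gi)), shape=(len(frag_ids), len(gene_ids))
    )
    f = frag_scores.loc[frag_ids, "score"].to_numpy()

    score_nnls = np.zeros(len(gene_ids))
    gene_comp = _component_labels(design)
    design_csc = design.tocsc()
    for comp in np.unique(gene_comp):
        gsel = np.nonzero(gene_comp == comp)[0]
        fsel = np.unique(design_csc[:, gsel].nonzero()[0])
        sub = design_csc[:, gsel][fsel, :].toarray()
        sol, _ = optimize.nnls(sub, f[fsel])
        score_nnls[gsel] = sol

    # vectorized per-gene summaries of the covering fragments
    r = frag_scores.loc[frag_ids, "reads_treatment"].to_numpy(dtype=float)
    n = np.asarray(design.sum(axis=0)).ravel()
    s1 = design.T @ f
    s2 = design.T @ (f**2)
    mean = s1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(n >= 2, (s2 - n * mean**2) / np.maximum(n - 1, 1), np.nan)
        var = np.maximum(var, 0.0)
        tstat = mean / np.sqrt(var / n)
    # one-sample t test of covering-fragment scores against 0
    pvals = np.full(len(gene_ids), np.nan)
    testable = (n >= 2) & (var > 0)
    pvals[testable] = 2.0 * stats.t.sf(np.abs(tstat[testable]), n[testable] - 1)
    degenerate = (n >= 2) & (var == 0)
    pvals[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "score_nnls": score_nnls,
            "score_mean": mean,
            "n_fragments": n.astype(int),
            "consistency_p": pvals,
            "reads_support": (design.T @ r).astype(int),
        }
    ).reset_index(drop=True)


def call_gene_hits(
    gene_scores: pd.DataFrame,
    score_min: float = 4.0,
    effect_min: float = 2.0,
    p_max: float = 0.05,
    reads_min: float = 10.0,
    score_col: str = "score_nnls",
) -> pd.DataFrame:
    """High-confidence gene effects.

    A gene is a hit iff its deconvolved score passes ``score_min``, the
    mean covering-fragment score passes ``effect_min`` in magnitude, the
    covering fragments are consistent (t-test ``p <= p_max``; genes covered
    by a single fragment cannot be tested and instead need doubled read
    support), and the supporting reads pass ``reads_min``.
    """
    if gene_scores.empty:
        return gene_scores.copy()
    g = gene_scores
    multi = g["n_fragments"] >= 2
    consistent = np.where(
        multi,
        g["consistency_p"].fillna(1.0) <= p_max,
        g["reads_support"] >= 2 * reads_min,
    )
    mask = (
        (g[score_col] >= score_min)
        & (g["score_mean"].abs() >= effect_min)
        & consistent
        & (g["reads_support"] >= reads_min)
    )
    return g[mask].reset_index(drop=True)


def score_experiment(
    table: CountTable,
    fmap: pd.DataFrame,
    treatment_sample: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_t0_reads: int = MIN_T0_READS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fragment scores and gene scores for one treatment sample."""
    meta = table.samples.loc[treatment_sample]
    valid = select_valid_barcodes(table, meta["set_label"], min_reads=min_t0_reads)
    fs = fragment_scores(table, treatment_sample, valid, pseudocount)
    gs = gene_scores_nnls(fs, fmap)
    return fs, gs


def score_all_experiments(
    table: CountTable,
    fmap: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_t0_reads: int = MIN_T0_READS,
    thresholds: dict | None = None,
    background: str = "K-12",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene scores and hit table across every treatment (end) sample."""
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    gene_frames = []
    hit_frames = []
    for end_sample in table.end_samples():
        meta = table.samples.loc[end_sample]
        _, gs = score_experiment(
            table, fmap, end_sample, pseudocount=pseudocount, min_t0_reads=min_t0_reads
        )
        gs = gs.assign(
            experiment=end_sample, phage=meta["phage"], moi=meta["moi"], format=meta["format"]
        )
        gene_frames.append(gs)
        hits = call_gene_hits(gs, **thresholds)
        if len(hits):
            hit_frames.append(
                pd.DataFrame(
                    {
                        "screen": "dubseq",
                        "background": background,
                        "phage": hits["phage"].to_numpy(),
                        "moi": hits["moi"].to_numpy(),
                        "format": hits["format"].to_numpy(),
                        "feature_id": hits["gene_id"].to_numpy(),
                        "score": hits["score_nnls"].to_numpy(),
                        "experiment": hits["experiment"].to_numpy(),
                    }
                )
            )
    genes = pd.concat(gene_frames, ignore_index=True) if gene_frames else pd.DataFrame()
    hit_cols = ["screen", "background", "phage", "moi", "format", "feature_id", "score", "experiment"]
    hits = pd.concat(hit_frames, ignore_index=True) if hit_frames else pd.DataFrame(columns=hit_cols)
    return genes, hits


def shuffle_fdr(
    frag_scores: pd.DataFrame,
    fmap: pd.DataFrame,
    thresholds: dict | None = None,
    n_shuffles: int = 10,
    seed: int = 0,
    score_col: str = "score_nnls",
) -> ShuffleFdrReport:
    """Empirical FDR by shuffling the barcode-to-fragment assignment.

    Each shuffle permutes which barcode (score + read support) is attached
    to which genomic fragment, destroying any genuine gene effect while
    preserving the score distribution; gene scores and hits are then
    recomputed with identical thresholds.  ``score_col`` selects whether
    hits are called on the deconvolved NNLS score (the same gate as the
    genuine data) or on the plain mean covering-fragment score.
    """
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    rng = np.random.default_rng(seed)
    observed = len(call_gene_hits(gene_scores_nnls(frag_scores, fmap), score_col=score_col, **thresholds))
    shuffled_counts = []
    index = frag_scores.index.to_numpy()
    for _ in range(n_shuffles):
        perm = rng.permutation(len(index))
        shuffled = frag_scores.copy()
        shuffled.index = pd.Index(index[perm], name=frag_scores.index.name)
        n = len(call_gene_hits(gene_scores_nnls(shuffled, fmap), score_col=score_col, **thresholds))
        shuffled_counts.append(n)
    return ShuffleFdrReport(
        thresholds=dict(thresholds, score_col=score_col),
        observed_hits=observed,
        shuffled_hits=shuffled_counts,
    )


def fragment_plot_table(
    frag_scores: pd.DataFrame,
    fmap: pd.DataFrame,
    gene_id: str,
    gene_start: int | None = None,
    gene_end: int | None = None,
) -> pd.DataFrame:
    """Gene-browser style interval list for fragments around a gene.

    ``full_coverage`` marks fragments containing the gene start-to-stop;
    when the gene interval is supplied, partially overlapping fragments are
    included too (they are the visual control that the effect tracks full
    coverage).
    """
    fm = fmap[fmap["up_barcode"].isin(frag_scores.index)].copy()
    full = fm["covered_genes"].map(lambda genes: gene_id in genes)
    fm = fm.assign(full_coverage=full)
    if gene_start is not None and gene_end is not None:
        fm = fm[(fm["end"] >= gene_start) & (fm["start"] <= gene_end)]
    else:
        fm = fm[fm["full_coverage"]]
    fm = fm.merge(
        frag_scores["score"].rename("score"), left_on="up_barcode", right_index=True
    )
    return fm[["up_barcode", "start", "end", "score", "full_coverage"]].reset_index(drop=True)
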