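"""Guide-level enrichment scoring for CRISPRi knockdown screens.

Guides are counted before (time-zero) and after phage selection.  After a
low-count filter and median-of-ratios depth normalization, each guide's
enrichment is tested with a conditional negative-binomial exact test: the
replicate-summed, depth-equalized counts of the two groups are compared
conditional on their total, under a common dispersion estimated by the
method of moments from the time-zero replicates.  At dispersion zero the
test reduces to the conditional binomial (Poisson) exact test.  P-values
are Benjamini-Hochberg adjusted, and per-feature fitness is the median
log2 fold-change over the feature's retained guides.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from phagescreen.containers import CountTable

#: a guide is dropped only if its count is below this in EVERY sample
MIN_GUIDE_COUNT = 10

#: common-dispersion floor; pure-Poisson counts still show this much
#: extra-binomial spread after normalization in practice
DISPERSION_FLOOR = 0.01

DEFAULT_THRESHOLDS = {"lfc_min": 2.0, "q_max": 0.05}


def filter_guides(
    table: CountTable, min_count: int = MIN_GUIDE_COUNT, require_all: bool = False
) -> pd.Index:
    """Retained guides after the read-count gate.

    By default a guide is removed only when its count is below
    ``min_count`` in *every* sample (time-zero and end combined).  With
    ``require_all=True`` the stricter reading applies: the guide must reach
    ``min_count`` in all samples.
    """
    if require_all:
        keep = (table.counts >= min_count).all(axis=1)
    else:
        keep = (table.counts >= min_count).any(axis=1)
    return table.counts.index[keep]


def depth_normalize(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled so the factors multiply to 1.

    Per sample, the factor is the median over guides of the guide's count
    ratio to the across-sample geometric-mean reference; guides with a zero
    anywhere are excluded from the reference.  Normalized counts are
    ``count / factor``.
    """
    if (counts.sum(axis=0) == 0).any():
        bad = counts.sum(axis=0).idxmin()
        raise ValueError(f"sample {bad!r} has zero total reads")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no guide has nonzero counts in every sample")
    logc = np.log(counts.loc[positive].astype(float))
    ref = logc.mean(axis=1)
    factors = np.exp((logc.sub(ref, axis=0)).median(axis=0))
    factors = factors / np.exp(np.log(factors).mean())
    factors.name = "size_factor"
    return factors


def estimate_dispersion(
    t0_normalized: pd.DataFrame, floor: float = DISPERSION_FLOOR
) -> float:
    """Method-of-moments common NB dispersion from time-zero replicates.

    Per guide, ``phi = (var - mean) / mean^2``; the common value is the
    median over guides with positive mean, floored at ``floor``.  With a
    single replicate the floor is returned.
    """
    if t0_normalized.shape[1] < 2:
        return floor
    m = t0_normalized.mean(axis=1)
    v = t0_normalized.var(axis=1, ddof=1)
    ok = m > 0
    if not ok.any():
        return floor
    phi = ((v[ok] - m[ok]) / m[ok] ** 2).median()
    return float(max(phi, floor))


def _exact_count_test_many(
    count_before: np.ndarray,
    count_after: np.ndarray,
    dispersion: float,
    n_before: int,
    n_after: int,
) -> np.ndarray:
    """Vectorized conditional exact test (see :func:`exact_count_test`)."""
    a = np.asarray(count_before, dtype=np.int64)
    b = np.asarray(count_after, dtype=np.int64)
    n = a + b
    p = np.ones(a.shape, dtype=float)
    nz = n > 0
    if not nz.any():
        return p
    an, nn = a[nz], n[nz]
    if dispersion <= 0:
        # binomial limit of the conditional NB
        p_null = n_before / (n_before + n_after)
        lower = stats.binom.cdf(an, nn, p_null)
        upper = stats.binom.sf(an - 1, nn, p_null)
    else:
        # conditional on the total, the before-count is beta-binomial with
        # shape parameters r = n_replicates / dispersion
        r1 = n_before / dispersion
        r2 = n_after / dispersion
        lower = stats.betabinom.cdf(an, nn, r1, r2)
        upper = stats.betabinom.sf(an - 1, nn, r1, r2)
    p[nz] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p


def exact_count_test(
    count_before: int,
    count_after: int,
    dispersion: float,
    n_before: int = 1,
    n_after: int = 1,
) -> float:
    """Conditional NB exact test on a depth-equalized count pair.

    ``count_before``/``count_after`` are the replicate-summed equalized
    counts of the two groups (``n_before``/``n_after`` replicates).  Under
    the null of equal per-replicate means, the before-count given the pair
    total follows a beta-binomial law with shape parameters
    ``r = n_replicates / dispersion``; its binomial limit is used at
    dispersion 0.  Two-sided by doubling the smaller tail, capped at 1.
    A zero total gives p = 1.
    """
    return float(
        _exact_count_test_many(
            np.array([count_before]), np.array([count_after]),
            dispersion, n_before, n_after,
        )[0]
    )


def guide_fitness(
    table: CountTable,
    library: pd.DataFrame,
    min_count: int = MIN_GUIDE_COUNT,
    require_all: bool = False,
    dispersion: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-guide log2 fold-change, exact-test p-value and BH q-value.

    Guides failing the read-count gate get ``filtered_flag=True`` and no
    statistics; the BH adjustment runs over the retained guides only.
    """
    counts = table.counts
    starts = table.start_samples()
    ends = table.end_samples()
    if not starts or not ends:
        raise ValueError("need at least one start and one end sample")
    retained = filter_guides(table, min_count=min_count, require_all=require_all)
    factors = depth_normalize(counts)
    norm = counts.astype(float) / factors
    if dispersion is None:
        dispersion = estimate_dispersion(norm[starts])

    t0_sum = norm.loc[retained, starts].sum(axis=1)
    end_sum = norm.loc[retained, ends].sum(axis=1)
    log2fc = np.log2(
        (end_sum / len(ends) + pseudocount) / (t0_sum / len(starts) + pseudocount)
    )
    t0_int = np.round(t0_sum).astype(int).to_numpy()
    end_int = np.round(end_sum).astype(int).to_numpy()
    pvals = _exact_count_test_many(
        t0_int, end_int, dispersion, n_before=len(starts), n_after=len(ends)
    )
    qvals = bh_adjust(pvals)

    stats_df = pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "fdr_q": qvals}, index=retained
    )
    present = library[library["sequence"].isin(counts.index)].set_index("sequence")
    out = present[["guide_id", "target_id", "feature_class"]].copy()
    out["log2fc"] = stats_df["log2fc"].reindex(out.index)
    out["p_value"] = stats_df["p_value"].reindex(out.index)
    out["fdr_q"] = stats_df["fdr_q"].reindex(out.index)
    out["filtered_flag"] = ~out.index.isin(retained)
    out.index.name = "sequence"
    return out.reset_index()


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def feature_fitness(
    guide_table: pd.DataFrame,
    library: pd.DataFrame,
    lfc_min: float = 2.0,
    q_max: float = 0.05,
    background: str = "K-12",
    phage: str = "",
    moi: float = np.nan,
    assay_format: str = "liquid",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-of-guides feature fitness and per-feature hit calls.

    A feature (gene, promoter or TFBS) is a hit iff at least one of its
    retained guides has ``log2fc >= lfc_min`` and ``fdr_q < q_max``; its
    fitness is the median log2 fold-change of the retained guides.
    Features whose guides were all filtered are absent from the output.
    """
    g = guide_table[~guide_table["filtered_flag"]]
    rows = []
    for (target, fclass), grp in g.groupby(["target_id", "feature_class"], sort=True):
        passing = (grp["log2fc"] >= lfc_min) & (grp["fdr_q"] < q_max)
        rows.append(
            {
                "feature_id": target,
                "feature_class": fclass,
                "fitness": float(grp["log2fc"].median()),
                "n_guides": len(grp),
                "hit_flag": bool(passing.any()),
            }
        )
    features = pd.DataFrame(
        rows, columns=["feature_id", "feature_class", "fitness", "n_guides", "hit_flag"]
    )
    hit_rows = features[features["hit_flag"]] if len(features) else features
    hits = pd.DataFrame(
        {
            "screen": "crispri",
            "background": background,
            "phage": phage,
            "moi": moi,
            "format": assay_format,
            "feature_id": hit_rows["feature_id"].to_numpy(),
            "feature_class": hit_rows["feature_class"].to_numpy(),
            "score": hit_rows["fitness"].to_numpy(),
        }
    )
    return features, hits
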