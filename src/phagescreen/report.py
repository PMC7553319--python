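"""Cross-screen hit integration: summary counts, heatmap matrices, reproducibility.

A hit table is a long DataFrame with one row per significant
(screen, background, phage, MOI, format, feature) record.  Summaries count
raw records, unique features, and unique feature-phage combinations — the
latter deduplicated over MOI, format and replicate but not over strain
background, since different host strains are tallied separately.
"""

from __future__ import annotations

import pandas as pd


def summarize_hits(hits: pd.DataFrame) -> dict:
    """Record / unique-feature / feature-phage-pair counts, plus per-class counts."""
    if hits.empty:
        return {
            "n_hit_records": 0,
            "n_unique_features": 0,
            "n_unique_feature_phage_pairs": 0,
            "per_class": {},
        }
    bg = hits["background"] if "background" in hits.columns else ""
    features = pd.DataFrame({"bg": bg, "feature": hits["feature_id"]})
    pairs = features.assign(phage=hits["phage"])
    per_class: dict[str, int] = {}
    if "feature_class" in hits.columns:
        per_class = {
            str(cls): int(n)
            for cls, n in hits.drop_duplicates(
                subset=[c for c in ("background", "feature_id", "feature_class") if c in hits.columns]
            )["feature_class"].value_counts().items()
        }
    return {
        "n_hit_records": int(len(hits)),
        "n_unique_features": int(len(features.drop_duplicates())),
        "n_unique_feature_phage_pairs": int(len(pairs.drop_duplicates())),
        "per_class": per_class,
    }


def fitness_matrix(
    gene_fits: pd.DataFrame,
    threshold: float = 6.5,
    high_confidence_features: pd.Index | None = None,
) -> pd.DataFrame:
    """Feature x experiment fitness matrix for heatmap export.

    Rows are features whose fitness reaches ``threshold`` in at least one
    experiment (optionally restricted to a high-confidence feature list);
    columns are labeled ``phage|moi|format``.  Cells carry the upstream
    fitness values unchanged; missing cells are NaN.
    """
    if gene_fits.empty:
        return pd.DataFrame()
    df = gene_fits.copy()
    key = "gene_id" if "gene_id" in df.columns else "feature_id"
    value = "fit" if "fit" in df.columns else "fitness"
    df["column"] = (
        df["phage"].astype(str) + "|" + df["moi"].astype(str) + "|" + df["format"].astype(str)
    )
    mat = df.pivot_table(index=key, columns="column", values=value, aggfunc="mean")
    keep = mat.max(axis=1) >= threshold
    mat = mat.loc[keep]
    if high_confidence_features is not None:
        mat = mat.loc[mat.index.intersection(pd.Index(high_confidence_features))]
    return mat.sort_index()


def replicate_correlation(gene_fits: pd.DataFrame, phage: str) -> tuple[list, float]:
    """Pairwise Pearson correlations of gene fitness between a phage's experiments.

    Correlations are computed over the genes scored in both experiments of
    each pair.  Returns the pair list ``(exp_a, exp_b, r)`` and their
    median; fewer than two experiments gives an empty list and NaN.
    """
    df = gene_fits[gene_fits["phage"] == phage]
    key = "gene_id" if "gene_id" in df.columns else "feature_id"
    value = "fit" if "fit" in df.columns else "fitness"
    experiments = sorted(df["experiment"].unique())
    if len(experiments) < 2:
        return [], float("nan")
    wide = df.pivot_table(index=key, columns="experiment", values=value)
    pairs = []
    for i, a in enumerate(experiments):
        for b in experiments[i + 1 :]:
            both = wide[[a, b]].dropna()
            if len(both) < 3:
                continue
            r = float(both[a].corr(both[b]))
            pairs.append((a, b, r))
    if not pairs:
        return [], float("nan")
    median = float(pd.Series([r for _, _, r in pairs]).median())
    return pairs, median
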