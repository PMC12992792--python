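"""Downstream statistics for co-IP/MS protein-group intensity tables.

Starting from a raw protein-group x sample intensity matrix (DIA-style
label-free quantification) with sample metadata (bait/control group,
biological replicate, technical replicate), the pipeline

1. log2-transforms and normalizes intensities across samples
   (per-sample median centering by default),
2. keeps a protein group in a sample only if it was detected in all
   technical replicates of that sample, then averages technical
   replicates,
3. computes per-group abundance ratios relative to a tagged-GFP
   reference within each sample group,
4. tests bait-vs-control enrichment per protein group (Welch t test on
   biological replicates, Benjamini-Hochberg adjustment) and classifies
   volcano hits at >1.5-fold change with -log10(adjusted p) > 2,
5. summarizes distributions with Tukey's fences (Q1 - 1.5 IQR,
   Q3 + 1.5 IQR) for boxplot-style outlier flagging.

Missing values are never imputed; protein groups with insufficient
replicate support are flagged untestable rather than silently dropped.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FOLD_CHANGE_THRESHOLD",
    "NEG_LOG10_P_THRESHOLD",
    "preprocess",
    "gfp_relative",
    "differential_enrichment",
    "tukey_fences",
    "volcano_plot",
    "ratio_boxplot",
]

#: linear fold-change threshold for volcano hits (strict: ratio > 1.5)
FOLD_CHANGE_THRESHOLD = 1.5
#: -log10 adjusted-p threshold for volcano hits (strict: > 2)
NEG_LOG10_P_THRESHOLD = 2.0

META_COLUMNS = ("sample", "group", "bio_rep", "tech_rep")


def _check_meta(intensities: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"sample metadata lacks columns: {sorted(missing_cols)}")
    uncovered = set(intensities.columns) - set(meta["sample"])
    if uncovered:
        raise ValueError(f"samples without metadata: {sorted(uncovered)}")
    return meta.set_index("sample").loc[list(intensities.columns)].reset_index()


def preprocess(
    intensities: pd.DataFrame,
    meta: pd.DataFrame,
    normalization: str = "median",
    already_log: bool = False,
) -> pd.DataFrame:
    """Log-transform, normalize, tech-replicate-filter and -average.

    Parameters
    ----------
    intensities
        Protein groups x samples; missing values as NaN; raw (linear)
        intensities unless ``already_log``.
    meta
        Sample metadata with columns sample, group, bio_rep, tech_rep.
    normalization
        ``median`` (subtract per-sample median of log2 values) or
        ``quantile`` (map each sample to the mean sorted profile).

    Returns a log2-scale matrix with one column per (group, bio_rep)
    (MultiIndex columns); a protein group is kept in a sample only when
    detected in every technical replicate of that (group, bio_rep).
    Protein groups missing everywhere are removed (logged).
    """
    meta = _check_meta(intensities, meta)
    mat = intensities.astype(float).copy()
    if (mat.fillna(0) < 0).any().any() and not already_log:
        raise ValueError("raw intensities must be >= 0")
    if not already_log:
        mat = np.log2(mat.where(mat > 0))

    if normalization == "median":
        mat = mat.sub(mat.median(axis=0, skipna=True), axis=1)
    elif normalization == "quantile":
        ranked = mat.rank(axis=0, method="average")
        mean_profile = np.nanmean(np.sort(mat.to_numpy(), axis=0), axis=1)
        n = mat.shape[0]
        mat = ranked.apply(
            lambda col: pd.Series(
                np.interp(col, np.arange(1, n + 1), mean_profile), index=col.index
            )
        )
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    all_missing = mat.isna().all(axis=1)
    if all_missing.any():
        logger.info("removing %d all-missing protein groups", int(all_missing.sum()))
        mat = mat[~all_missing]

    cols = {}
    for (group, bio_rep), sub in meta.groupby(["group", "bio_rep"]):
        samples = list(sub["sample"])
        block = mat[samples]
        detected_in_all = block.notna().all(axis=1)
        col = block.mean(axis=1).where(detected_in_all)
        cols[(group, int(bio_rep))] = col
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["group", "bio_rep"])
    return out


def gfp_relative(
    processed: pd.DataFrame, reference_id: str
) -> pd.DataFrame:
    """Per-group abundance relative to the GFP reference protein group.

    For each sample group, every protein's log2 value is reduced by the
    group-average log2 abundance of ``reference_id``; the reference's own
    group-averaged ratio is therefore 0 (linear ratio 1). Groups where
    the reference was not detected are skipped with a warning.

    Returns a long table: protein_group, group, bio_rep, log2_ratio.
    """
    if reference_id not in processed.index:
        raise ValueError(f"reference {reference_id!r} not in table")
    records = []
    for group in processed.columns.get_level_values("group").unique():
        block = processed[group]
        ref = block.loc[reference_id]
        if ref.isna().all():
            logger.warning("reference %r missing in group %r; skipped", reference_id, group)
            continue
        ref_mean = float(ref.mean(skipna=True))
        rel = block - ref_mean
        for bio_rep in rel.columns:
            for protein, value in rel[bio_rep].items():
                if not math.isnan(value):
                    records.append(
                        {
                            "protein_group": protein,
                            "group": group,
                            "bio_rep": bio_rep,
                            "log2_ratio": value,
                        }
                    )
    return pd.DataFrame(records)


def differential_enrichment(
    processed: pd.DataFrame,
    bait_group: str,
    control_group: str,
    fold_change_threshold: float = FOLD_CHANGE_THRESHOLD,
    neg_log10_p_threshold: float = NEG_LOG10_P_THRESHOLD,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Per-protein bait-vs-control enrichment with volcano hit calls.

    For every protein group with at least two biological-replicate
    values on each side, the mean log2 fold change (bait minus control)
    and a Welch (unequal-variance) t test are computed; p values are
    Benjamini-Hochberg-adjusted across tested proteins. A protein is a
    ``hit`` when |fold change| exceeds ``fold_change_threshold`` on the
    linear scale (strict) and -log10(adjusted p) exceeds
    ``neg_log10_p_threshold`` (strict); ``direction`` reports the
    enrichment side. Proteins with insufficient replicates are flagged
    ``untestable`` (p NaN, never a hit).
    """
    for g in (bait_group, control_group):
        if g not in processed.columns.get_level_values("group"):
            raise ValueError(f"group {g!r} not in table")
    bait = processed[bait_group]
    ctrl = processed[control_group]
    rows = []
    for protein in processed.index:
        b = bait.loc[protein].dropna().to_numpy()
        c = ctrl.loc[protein].dropna().to_numpy()
        row = {
            "protein_group": protein,
            "n_bait_reps": len(b),
            "n_control_reps": len(c),
        }
        if len(b) >= 2 and len(c) >= 2:
            row["log2fc"] = float(b.mean() - c.mean())
            t, p = stats.ttest_ind(b, c, equal_var=False)
            if not two_sided:
                p = p / 2 if t > 0 else 1 - p / 2
            row["p_value"] = float(p)
            row["status"] = "tested"
        else:
            row["log2fc"] = float(b.mean() - c.mean()) if len(b) and len(c) else np.nan
            row["p_value"] = np.nan
            row["status"] = "untestable"
        rows.append(row)
    table = pd.DataFrame(rows).set_index("protein_group")

    tested = table["status"] == "tested"
    table["adj_p"] = np.nan
    if tested.any():
        pvals = table.loc[tested, "p_value"].to_numpy()
        # constant-input t tests can yield NaN p; treat as 1 for adjustment
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        table.loc[tested, "adj_p"] = multipletests(pvals, method="fdr_bh")[1]
    log2_thr = math.log2(fold_change_threshold)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(table["adj_p"])
    table["hit"] = (
        tested
        & (table["log2fc"].abs() > log2_thr)
        & (neglog > neg_log10_p_threshold)
    )
    table["direction"] = np.where(table["log2fc"] > 0, "enriched", "depleted")
    return table.reset_index()


def volcano_plot(enrichment: pd.DataFrame, path, title: str = "") -> None:
    """Volcano plot of one bait-vs-control contrast (hits highlighted)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tested = enrichment[enrichment["status"] == "tested"]
    with np.errstate(divide="ignore"):
        y = -np.log10(tested["adj_p"])
    fig, ax = plt.subplots(figsize=(5, 4))
    hit = tested["hit"].to_numpy()
    up = tested["log2fc"] > 0
    ax.scatter(tested.loc[~hit, "log2fc"], y[~hit], s=8, c="0.7")
    ax.scatter(tested.loc[hit & up, "log2fc"], y[hit & up], s=12, c="tab:red")
    ax.scatter(tested.loc[hit & ~up, "log2fc"], y[hit & ~up], s=12, c="tab:blue")
    thr = math.log2(FOLD_CHANGE_THRESHOLD)
    for x in (-thr, thr):
        ax.axvline(x, ls="--", lw=0.6, c="0.4")
    ax.axhline(NEG_LOG10_P_THRESHOLD, ls="--", lw=0.6, c="0.4")
    ax.set_xlabel("log2 fold change (bait / control)")
    ax.set_ylabel("-log10 adjusted p")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ratio_boxplot(ratios: pd.DataFrame, protein_groups, path) -> None:
    """Boxplot of GFP-relative log2 ratios, whiskers at Tukey's fences."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(protein_groups) + 2, 4))
    data = [
        ratios.loc[ratios["protein_group"] == p, "log2_ratio"].to_numpy()
        for p in protein_groups
    ]
    ax.boxplot(data, tick_labels=list(protein_groups), whis=1.5)
    ax.set_ylabel("log2 ratio to GFP reference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tukey_fences(values) -> tuple[float, float, np.ndarray]:
    """Tukey's fences and outliers of a sample.

    Fences are Q1 - 1.5 IQR and Q3 + 1.5 IQR with quartiles computed by
    linear interpolation (numpy default, type-7); values strictly beyond
    a fence are outliers. Requires at least 4 values.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 4:
        raise ValueError(f"need >= 4 values for Tukey fences, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = arr[(arr < lower) | (arr > upper)]
    return float(lower), float(upper), outliers
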