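"""Repeat-family RNA enrichment from RepeatMasker-style count tables.

Per-repeat read counts from a control and a knockout sample are normalized
to the total repeat-masked reads of each sample, giving a frequency of
detection per repeat type. Fold enrichment is the knockout frequency
divided by the control frequency. Types with too few reads (default: more
than 300 required) are excluded, and types whose fold change exceeds the
mean by more than k standard deviations (default k = 2) are flagged as
enriched outliers in a rank-ordered table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "parse_repeat_counts",
    "write_repeat_counts",
    "compute_frequencies",
    "fold_enrichment",
    "plot_enrichment",
]

REQUIRED_COLUMNS = ("repeat_type", "repeat_class", "reads_control", "reads_ko")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"repeat count table is missing columns: {sorted(missing)}")
    table = table.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("reads_control", "reads_ko"):
        reads = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[reads.isna() | (reads < 0)]
        if len(bad):
            raise ValueError(f"negative or non-numeric {col} at rows {bad.tolist()}")
        table[col] = reads.astype(float)
    dupes = table["repeat_type"][table["repeat_type"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicated repeat_type entries: {sorted(set(dupes))}")
    return table


def parse_repeat_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated repeat count table.

    Expected columns: ``repeat_type, repeat_class, reads_control, reads_ko``.
    """
    table = pd.read_csv(path, sep="\t")
    return _validate(table)


def write_repeat_counts(table: pd.DataFrame, path: str | Path) -> None:
    """Write a count table in the TSV dialect that ``parse_repeat_counts`` reads."""
    _validate(table).to_csv(path, sep="\t", index=False)


def compute_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample frequency of detection: reads / total reads of the sample."""
    table = _validate(table)
    out = table.copy()
    for col, freq in (("reads_control", "freq_control"), ("reads_ko", "freq_ko")):
        total = out[col].sum()
        if total <= 0:
            raise ValueError(f"total {col} must be positive")
        out[freq] = out[col] / total
    return out


def fold_enrichment(
    table: pd.DataFrame,
    min_reads: float = 300,
    sd_mult: float = 2.0,
    cutoff_mode: str = "both",
    log_scale: bool = False,
) -> pd.DataFrame:
    """Rank-ordered fold-enrichment table with read-cutoff and outlier flags.

    Frequencies are computed over the full table (so excluded types still
    contribute to the totals), then types must carry strictly more than
    ``min_reads`` reads to be included — in both samples by default
    (``cutoff_mode``: ``"both"``, ``"either"`` or ``"sum"``). The fold
    change is ``freq_ko / freq_control``; included rows whose control
    frequency is zero get an infinite fold and are excluded from the
    outlier statistics but reported. The outlier flag marks folds above
    ``mean + sd_mult * SD`` of the finite included folds (computed on raw
    folds, or on log folds when ``log_scale``). Rank 1 is the largest fold.
    """
    freq = compute_frequencies(table)
    ctrl_ok = freq["reads_control"] > min_reads
    ko_ok = freq["reads_ko"] > min_reads
    if cutoff_mode == "both":
        included = ctrl_ok & ko_ok
    elif cutoff_mode == "either":
        included = ctrl_ok | ko_ok
    elif cutoff_mode == "sum":
        included = (freq["reads_control"] + freq["reads_ko"]) > min_reads
    else:
        raise ValueError("cutoff_mode must be 'both', 'either' or 'sum'")

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(freq["freq_control"] > 0,
                        freq["freq_ko"] / freq["freq_control"], np.inf)
    freq["fold"] = fold
    freq["included"] = included

    sub = freq[included].copy()
    finite = np.isfinite(sub["fold"])
    vals = sub.loc[finite, "fold"].to_numpy()
    if log_scale:
        stats_vals = np.log(vals[vals > 0])
        mean, sd = stats_vals.mean(), stats_vals.std(ddof=1) if stats_vals.size > 1 else 0.0
        cut = np.exp(mean + sd_mult * sd)
    else:
        mean = vals.mean() if vals.size else np.nan
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        cut = mean + sd_mult * sd
    sub["outlier"] = np.isfinite(sub["fold"]) & (sub["fold"] > cut)
    sub = sub.sort_values("fold", ascending=False, kind="mergesort").reset_index(drop=True)
    sub["rank"] = np.arange(1, len(sub) + 1)
    cols = ["repeat_type", "repeat_class", "reads_control", "reads_ko",
            "freq_control", "freq_ko", "fold", "outlier", "rank"]
    return sub[cols]


def plot_enrichment(rows: pd.DataFrame, path: str | Path, label_outliers: bool = True):
    """Rank-order scatter of fold change, outliers labeled, classes colored."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    classes = rows["repeat_class"].unique()
    cmap = plt.get_cmap("tab10")
    for i, cls in enumerate(classes):
        sel = rows["repeat_class"] == cls
        ax.scatter(rows.loc[sel, "rank"], rows.loc[sel, "fold"],
                   s=18, color=cmap(i % 10), label=cls)
    if label_outliers:
        for _, row in rows[rows["outlier"]].iterrows():
            ax.annotate(row["repeat_type"], (row["rank"], row["fold"]),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("rank (descending fold change)")
    ax.set_ylabel("fold change (KO / control)")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
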