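"""Differential expression summaries and the Pscore pathogenicity statistic.

A lncRNA that regulates immune pathways in many cancers, and is strongly
differentially expressed between tumor and normal tissue in many of them, is
more likely pathogenic. The Pscore condenses this into one number per
irlncRNA:

    Pscore(l) = ( sum_w N(NC(l, w)) + R_DE(l) + R_FC(l) ) / (n_pathways + 2)

where ``NC(l, w)`` is the number of cancers in which the (lncRNA, pathway)
pair was extracted, ``R_DE(l) = N(NC(l))`` is the normalized count of
cancers in which l is differentially expressed (DE), and ``R_FC(l)`` is the
normalized mean |log2 fold change| over those DE cancers. ``N`` is
divide-by-maximum normalization (per pathway for NC(l, w); across lncRNAs
for the other two), which keeps zero meaning "not observed anywhere" and
maps the maximum to 1 so Pscore lies in [0, 1]. With the standard 17 immune
pathways the denominator is 19.

The DE stage is a deliberately simple, pluggable test: library-size (CPM)
normalization, log2(CPM + 1), log fold change as the difference of group
means on the log scale, a Wilcoxon rank-sum p-value and Benjamini-Hochberg
adjustment across the tested lncRNAs. A lncRNA is DE when ``adj_p < 0.01``
and ``|logFC| > 1.5``, both strict. This replaces a negative-binomial count
model; for rank-based downstream use the substitution is documented in the
methods note.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix
from .errors import ConfigurationError, InsufficientGroupError

DEFAULT_ADJ_P = 0.01
DEFAULT_LOGFC = 1.5

DE_COLUMNS = ["lncrna_id", "cancer_label", "logFC", "adj_p", "is_de"]


def de_flag(
    logfc: float,
    adj_p: float,
    adj_p_threshold: float = DEFAULT_ADJ_P,
    logfc_threshold: float = DEFAULT_LOGFC,
) -> bool:
    """Differential-expression call: ``adj_p < threshold`` AND
    ``|logFC| > threshold``, both strict — a gene sitting exactly on either
    boundary is not called DE."""
    return adj_p < adj_p_threshold and abs(logfc) > logfc_threshold


def differential_expression(
    expr: ExpressionMatrix,
    labels: pd.Series,
    lnc_ids: Iterable[str] | None = None,
    adj_p_threshold: float = DEFAULT_ADJ_P,
    logfc_threshold: float = DEFAULT_LOGFC,
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression for the given lncRNAs.

    ``expr`` is the (full) lncRNA matrix of one cancer — CPM library sizes
    are computed over all its genes — and ``lnc_ids`` restricts testing to
    the identified irlncRNAs (default: all genes). Requires at least 3
    samples per group.
    """
    groups = labels.reindex([s for s in expr.sample_ids if s in labels.index])
    tumor = [s for s, g in groups.items() if g == "tumor"]
    normal = [s for s, g in groups.items() if g == "normal"]
    if len(tumor) < 3 or len(normal) < 3:
        raise InsufficientGroupError(
            f"need >= 3 samples per group, got {len(tumor)} tumor / "
            f"{len(normal)} normal"
        )
    if lnc_ids is None:
        tested = list(expr.gene_ids)
    else:
        wanted = set(lnc_ids)
        tested = [g for g in expr.gene_ids if g in wanted]
    if not tested:
        return pd.DataFrame(columns=DE_COLUMNS)

    counts = expr.data[tumor + normal].to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise InsufficientGroupError("a sample has zero total expression")
    logcpm = np.log2(counts / lib * 1e6 + 1.0)
    logcpm = pd.DataFrame(logcpm, index=expr.gene_ids, columns=tumor + normal)

    rows = []
    for gene in tested:
        t = logcpm.loc[gene, tumor].to_numpy()
        n = logcpm.loc[gene, normal].to_numpy()
        logfc = float(t.mean() - n.mean())
        if np.ptp(np.concatenate([t, n])) == 0:
            p = 1.0  # identical constant expression: no evidence of change
        else:
            p = float(scipy.stats.ranksums(t, n).pvalue)
        rows.append({"lncrna_id": gene, "logFC": logfc, "p": p})
    table = pd.DataFrame(rows)
    table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
    table["is_de"] = [
        de_flag(row.logFC, row.adj_p, adj_p_threshold, logfc_threshold)
        for row in table.itertuples()
    ]
    table["cancer_label"] = expr.cancer_label
    return table[DE_COLUMNS]


def normalize_max(values: Mapping[str, float]) -> dict[str, float]:
    """Divide-by-maximum normalization; an all-zero input stays all zero."""
    if not values:
        return {}
    for key, v in values.items():
        if not math.isfinite(v) or v < 0:
            raise ConfigurationError(f"normalize_max: invalid value {v} for {key!r}")
    top = max(values.values())
    if top == 0:
        return {k: 0.0 for k in values}
    return {k: v / top for k, v in values.items()}


def r_de(nc_total: Mapping[str, int]) -> dict[str, float]:
    """Normalized breadth of differential expression, N(NC(l))."""
    return normalize_max({k: float(v) for k, v in nc_total.items()})


def r_fc(de_results: pd.DataFrame, lncrnas: Iterable[str] | None = None) -> dict[str, float]:
    """Normalized intensity of differential expression.

    Per lncRNA: mean |logFC| over the cancers in which it is DE (0 when it
    is DE nowhere — the guard for the division by NC(l)), then
    divide-by-maximum across lncRNAs.
    """
    if lncrnas is None:
        lncrnas = sorted(de_results["lncrna_id"].unique()) if not de_results.empty else []
    means = {l: 0.0 for l in lncrnas}
    if not de_results.empty:
        de_only = de_results[de_results["is_de"]]
        for lnc, group in de_only.groupby("lncrna_id"):
            if lnc in means:
                means[str(lnc)] = float(group["logFC"].abs().mean())
    return normalize_max(means)


def nc_de_counts(de_results: pd.DataFrame, lncrnas: Iterable[str]) -> dict[str, int]:
    """NC(l): number of cancers in which each lncRNA is DE."""
    counts = {l: 0 for l in lncrnas}
    if not de_results.empty:
        de_only = de_results[de_results["is_de"]]
        for lnc, group in de_only.groupby("lncrna_id"):
            if lnc in counts:
                counts[str(lnc)] = int(group["cancer_label"].nunique())
    return counts


def pscore(
    nc_per_pathway: pd.DataFrame,
    r_de_map: Mapping[str, float],
    r_fc_map: Mapping[str, float],
) -> pd.Series:
    """Pscore per lncRNA from raw pathway-cancer counts and normalized DE terms.

    ``nc_per_pathway`` is a lncRNA x pathway table of cancer counts (absent
    pathways must be present as zero columns); each pathway column is
    divide-by-maximum normalized, the normalized terms are summed with
    R_DE and R_FC, and the sum is divided by ``n_pathways + 2``.
    """
    if nc_per_pathway.shape[1] == 0:
        raise ConfigurationError("pscore needs at least one pathway column")
    norm = nc_per_pathway.astype(float).copy()
    for col in norm.columns:
        top = norm[col].max()
        if top > 0:
            norm[col] = norm[col] / top
    denom = nc_per_pathway.shape[1] + 2
    scores = {}
    for lnc in norm.index:
        total = float(norm.loc[lnc].sum())
        total += float(r_de_map.get(lnc, 0.0)) + float(r_fc_map.get(lnc, 0.0))
        scores[str(lnc)] = total / denom
    out = pd.Series(scores, name="pscore").sort_index()
    if ((out < -1e-12) | (out > 1 + 1e-12)).any():
        raise ConfigurationError("pscore left [0, 1]; check input normalization")
    return out.clip(0.0, 1.0)


def pathogenicity_table(
    nc_per_pathway: pd.DataFrame,
    de_results: pd.DataFrame,
    pathways: Sequence[str],
) -> pd.DataFrame:
    """Assemble the per-irlncRNA pathogenicity table.

    Returns columns ``lncrna_id, nc_total, r_de, r_fc, pscore`` followed by
    one raw NC count column per pathway (``NC_<pathway>``).
    """
    lncs = [str(l) for l in nc_per_pathway.index]
    counts = nc_de_counts(de_results, lncs)
    rde = r_de(counts)
    rfc = r_fc(de_results, lncs)
    scores = pscore(nc_per_pathway[list(pathways)], rde, rfc)
    table = pd.DataFrame(
        {
            "lncrna_id": lncs,
            "nc_total": [counts[l] for l in lncs],
            "r_de": [rde[l] for l in lncs],
            "r_fc": [rfc[l] for l in lncs],
            "pscore": [scores[l] for l in lncs],
        }
    )
    for pw in pathways:
        table[f"NC_{pw}"] = nc_per_pathway[pw].to_numpy()
    return table.sort_values("lncrna_id", kind="mergesort").reset_index(drop=True)


def rank_and_bin(
    pscores: Mapping[str, float], mode: str, k: int
) -> list[list[str]]:
    """Sort lncRNAs by descending Pscore and split them into ``k`` bins.

    ``equal_count`` bins have (near-)equal membership, the first bins
    absorbing the remainder; ``equal_range`` bins are k equal-width
    intervals of the observed Pscore range (highest interval first) and may
    be empty. Ties in Pscore are broken lexicographically by id.
    """
    if k < 1:
        raise ConfigurationError("number of bins must be >= 1")
    if mode not in ("equal_count", "equal_range"):
        raise ConfigurationError(f"unknown binning mode {mode!r}")
    items = sorted(pscores.items(), key=lambda kv: (-kv[1], kv[0]))
    ids = [i for i, _ in items]
    if not ids:
        return [[] for _ in range(k)]
    if mode == "equal_count":
        n = len(ids)
        base, rem = divmod(n, k)
        bins, start = [], 0
        for b in range(k):
            size = base + (1 if b < rem else 0)
            bins.append(ids[start : start + size])
            start += size
        return bins
    # equal_range
    values = [v for _, v in items]
    top, bottom = values[0], values[-1]
    width = (top - bottom) / k
    bins = [[] for _ in range(k)]
    for ident, value in items:
        if width == 0:
            idx = 0  # degenerate: identical scores all land in the first bin
        else:
            idx = min(int((top - value) / width), k - 1)
        bins[idx].append(ident)
    return bins


def overlap_with_reference(
    bins: Sequence[Sequence[str]],
    pscores: Mapping[str, float],
    reference: Iterable[str],
) -> pd.DataFrame:
    """Per-bin counts, reference overlap and Pscore summaries, plus totals.

    Mirrors the dataset tables used to compare scored lncRNAs against a
    curated disease-lncRNA list: each row gives the bin size, how many of
    its members appear in the reference, their ratio, and min/max/mean
    Pscore (NaN for empty bins).
    """
    ref = set(reference)
    rows = []
    for b, members in enumerate(bins, start=1):
        values = [pscores[m] for m in members]
        in_ref = sum(1 for m in members if m in ref)
        rows.append(
            {
                "bin": str(b),
                "count": len(members),
                "in_reference": in_ref,
                "ratio": in_ref / len(members) if members else float("nan"),
                "pscore_min": min(values) if values else float("nan"),
                "pscore_max": max(values) if values else float("nan"),
                "pscore_mean": float(np.mean(values)) if values else float("nan"),
            }
        )
    all_members = [m for members in bins for m in members]
    all_values = [pscores[m] for m in all_members]
    total_ref = sum(1 for m in all_members if m in ref)
    rows.append(
        {
            "bin": "total",
            "count": len(all_members),
            "in_reference": total_ref,
            "ratio": total_ref / len(all_members) if all_members else float("nan"),
            "pscore_min": min(all_values) if all_values else float("nan"),
            "pscore_max": max(all_values) if all_values else float("nan"),
            "pscore_mean": float(np.mean(all_values)) if all_values else float("nan"),
        }
    )
    return pd.DataFrame(rows)
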