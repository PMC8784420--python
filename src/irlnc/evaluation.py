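"""Validation statistics: infiltration-correlation rates and immune-cell
expression comparison.

Two external checks of an irlncRNA call set:

* **Infiltration rates.** A lncRNA is *infiltration-related* (infrlncRNA)
  when its expression correlates with at least one of six immune-cell
  infiltration levels (B cell, CD4+ T cell, CD8+ T cell, neutrophil,
  macrophage, myeloid dendritic cell): |correlation| above a threshold with
  a BH-adjusted p-value below a cutoff. Four rates summarize the agreement
  between the irlncRNA and infrlncRNA sets: IR (irlncRNAs among all
  lncRNAs), IRINF (irlncRNAs among infrlncRNAs), INFR (infrlncRNAs among all
  lncRNAs) and INFRI (infrlncRNAs among irlncRNAs). For a call set with real
  immune signal, IRINF should exceed IR and INFRI should exceed INFR.

* **Cell-group expression.** On a cell x gene single-cell matrix with
  immune / non-immune cell labels, irlncRNAs should be expressed higher than
  other lncRNAs specifically in immune cells. Per cell group we report the
  mean expression of irlncRNAs and of the remaining lncRNAs plus a two-sided
  rank-sum p comparing the per-cell means of the two gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix
from .errors import ConfigurationError, InsufficientSamplesError

DEFAULT_CORR_THRESHOLD = 0.2
DEFAULT_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class InfiltrationRates:
    """The four rates plus the underlying sets; undefined ratios are NaN."""

    ir: float
    irinf: float
    infr: float
    infri: float
    infr_lncrnas: frozenset[str]
    ir_lncrnas: frozenset[str]
    n_lncrnas: int

    def as_dict(self) -> dict[str, float]:
        return {
            "IR": self.ir,
            "IRINF": self.irinf,
            "INFR": self.infr,
            "INFRI": self.infri,
        }


def _safe_ratio(num: int, denom: int) -> float:
    return num / denom if denom else float("nan")


def infiltration_rates(
    lnc_expr: ExpressionMatrix,
    infiltration: pd.DataFrame,
    irlncrnas: Iterable[str],
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    method: str = "spearman",
) -> InfiltrationRates:
    """Compute IR, IRINF, INFR and INFRI for one cancer.

    A lncRNA is infiltration-related when, for at least one infiltration
    column, |correlation| > ``corr_threshold`` and the BH-adjusted p-value
    (adjusted jointly across all lncRNA x cell-type tests) is below
    ``p_threshold``, both strict. Spearman correlation by default (robust to
    the infiltration score scale); ``method="pearson"`` switches.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    shared = [s for s in lnc_expr.sample_ids if s in set(infiltration.index)]
    if len(shared) < 3:
        raise InsufficientSamplesError(
            f"only {len(shared)} samples shared with the infiltration table"
        )
    expr = lnc_expr.data[shared]
    infil = infiltration.loc[shared]

    tests: list[tuple[str, float, float]] = []  # (lncrna, |corr|, p)
    corr_fn = scipy.stats.spearmanr if method == "spearman" else scipy.stats.pearsonr
    for gene in expr.index:
        x = expr.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue  # constant lncRNA: no defined correlation
        for cell in infil.columns:
            y = infil[cell].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                continue
            res = corr_fn(x, y)
            tests.append((str(gene), abs(float(res.statistic)), float(res.pvalue)))

    infr: set[str] = set()
    if tests:
        adj = multipletests([t[2] for t in tests], method="fdr_bh")[1]
        for (gene, acorr, _), ap in zip(tests, adj):
            if acorr > corr_threshold and ap < p_threshold:
                infr.add(gene)

    all_lnc = set(lnc_expr.gene_ids)
    ir_set = set(irlncrnas) & all_lnc
    return InfiltrationRates(
        ir=_safe_ratio(len(ir_set), len(all_lnc)),
        irinf=_safe_ratio(len(ir_set & infr), len(infr)),
        infr=_safe_ratio(len(infr), len(all_lnc)),
        infri=_safe_ratio(len(infr & ir_set), len(ir_set)),
        infr_lncrnas=frozenset(infr),
        ir_lncrnas=frozenset(ir_set),
        n_lncrnas=len(all_lnc),
    )


def group_expression_compare(
    cell_expr: ExpressionMatrix,
    cell_labels: pd.Series,
    irlncrnas: Iterable[str],
) -> pd.DataFrame:
    """Compare irlncRNA vs non-irlncRNA expression within cell groups.

    ``cell_expr`` is a gene x cell matrix; ``cell_labels`` maps cell ids to
    ``immune`` / ``non-immune``. For each group, the per-cell mean over
    irlncRNA genes is compared with the per-cell mean over the remaining
    lncRNA genes by a two-sided rank-sum test. Groups with a single cell get
    means but a NaN p-value (flagged in ``p_defined``).

    Returns one row per cell group with columns ``group, n_cells,
    mean_irlnc, mean_non_irlnc, p, p_defined``.
    """
    ir = set(irlncrnas) & set(cell_expr.gene_ids)
    non_ir = [g for g in cell_expr.gene_ids if g not in ir]
    if not ir or not non_ir:
        raise ConfigurationError(
            "need both irlncRNA and non-irlncRNA genes in the matrix"
        )
    rows = []
    for group in ("immune", "non-immune"):
        cells = [
            c
            for c in cell_expr.sample_ids
            if cell_labels.get(c) == group
        ]
        if not cells:
            continue
        per_cell_ir = cell_expr.data.loc[sorted(ir), cells].mean(axis=0).to_numpy()
        per_cell_non = cell_expr.data.loc[non_ir, cells].mean(axis=0).to_numpy()
        if len(cells) >= 2 and (
            np.ptp(np.concatenate([per_cell_ir, per_cell_non])) > 0
        ):
            p = float(scipy.stats.ranksums(per_cell_ir, per_cell_non).pvalue)
            defined = True
        else:
            p = float("nan")
            defined = False
        rows.append(
            {
                "group": group,
                "n_cells": len(cells),
                "mean_irlnc": float(per_cell_ir.mean()),
                "mean_non_irlnc": float(per_cell_non.mean()),
                "p": p,
                "p_defined": defined,
            }
        )
    return pd.DataFrame(rows)
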