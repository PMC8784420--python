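"""End-to-end orchestration of the per-cancer and pan-cancer stages.

The CLI subcommands are thin wrappers over these functions; tests and the
reproduction script call them directly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import correlation, enrichment, pathogenicity
from .core_io import ExpressionMatrix
from .errors import ConfigurationError
from .synthetic import CancerBundle


@dataclass(frozen=True)
class RunConfig:
    """Every tunable parameter of the pipeline with its standard default.

    Defaults are the published operating point: logistic ``c = -15`` and
    ``d = ln(1999)``, rank threshold 0.5, 10 000 permutations with list
    sizes 1..5000, |lncRES| > 0.995 with FDR < 0.05, and DE thresholds
    adjusted p < 0.01 with |logFC| > 1.5.
    """

    logistic_c: float = correlation.DEFAULT_LOGISTIC.c
    logistic_d: float = correlation.DEFAULT_LOGISTIC.d
    rank_threshold: float = enrichment.DEFAULT_RANK_THRESHOLD
    lncres_threshold: float = enrichment.DEFAULT_LNCRES_THRESHOLD
    fdr_threshold: float = enrichment.DEFAULT_FDR_THRESHOLD
    n_perm: int = enrichment.DEFAULT_N_PERM
    min_size: int = 1
    max_size: int = 5000
    weight: float = 1.0
    global_fdr: bool = False
    de_adj_p: float = pathogenicity.DEFAULT_ADJ_P
    de_logfc: float = pathogenicity.DEFAULT_LOGFC
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rank_threshold < 1:
            raise ConfigurationError("rank_threshold must lie in [0, 1)")
        if not 0 < self.lncres_threshold < 1:
            raise ConfigurationError("lncres_threshold must lie in (0, 1)")
        if not 0 < self.fdr_threshold <= 1:
            raise ConfigurationError("fdr_threshold must lie in (0, 1]")
        if not 0 < self.de_adj_p <= 1:
            raise ConfigurationError("de_adj_p must lie in (0, 1]")
        if self.de_logfc < 0:
            raise ConfigurationError("de_logfc must be >= 0")
        if self.n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")
        if self.logistic_c >= 0:
            raise ConfigurationError("logistic_c must be negative")

    @property
    def logistic(self) -> correlation.LogisticParams:
        return correlation.LogisticParams(self.logistic_c, self.logistic_d)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CancerResult:
    """Stage outputs for one cancer."""

    cancer_label: str
    triples: pd.DataFrame
    records: pd.DataFrame
    irlnc: enrichment.IrlncRNASet
    de: pd.DataFrame | None = None


def run_cancer(
    mrna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    purity: pd.Series,
    gene_sets: Mapping[str, frozenset[str]],
    labels: pd.Series | None = None,
    config: RunConfig | None = None,
) -> CancerResult:
    """Correlation -> enrichment -> extraction (-> DE) for one cancer."""
    cfg = config or RunConfig()
    label = mrna.cancer_label or lncrna.cancer_label
    triples = correlation.heuristic_matrix(mrna, lncrna, purity, cfg.logistic)
    lists = enrichment.build_ranked_lists(
        triples, threshold=cfg.rank_threshold, cancer_label=label
    )
    records = enrichment.run_enrichment(
        lists,
        gene_sets,
        min_size=cfg.min_size,
        max_size=cfg.max_size,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        weight=cfg.weight,
        global_fdr=cfg.global_fdr,
    )
    irlnc = enrichment.extract_irlncrnas(
        records,
        lncres_threshold=cfg.lncres_threshold,
        fdr_threshold=cfg.fdr_threshold,
        cancer_label=label,
    )
    de = None
    if labels is not None and irlnc.lncrnas:
        de = pathogenicity.differential_expression(
            lncrna,
            labels,
            lnc_ids=irlnc.lncrnas,
            adj_p_threshold=cfg.de_adj_p,
            logfc_threshold=cfg.de_logfc,
        )
    return CancerResult(label, triples, records, irlnc, de)


@dataclass
class PanCancerResult:
    """Merged pan-cancer outputs."""

    per_cancer: list[CancerResult]
    union: enrichment.PanCancerUnion
    de: pd.DataFrame
    pathogenicity: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pan_cancer(
    bundles: Sequence[CancerBundle],
    config: RunConfig | None = None,
    pathways: Sequence[str] | None = None,
) -> PanCancerResult:
    """Run the full pipeline over per-cancer bundles and score pathogenicity.

    ``pathways`` fixes the pathway columns of the Pscore (default: the union
    of gene-set names across bundles, sorted). Differential expression is
    computed for every union irlncRNA in every cancer that has both tumor
    and normal labels, so the DE breadth NC(l) counts all analyzed cancers,
    not only those in which the lncRNA was extracted.
    """
    cfg = config or RunConfig()
    results = [
        run_cancer(b.mrna, b.lncrna, b.purity, b.gene_sets, config=cfg)
        for b in bundles
    ]
    union = enrichment.union_irlncrnas([r.irlnc for r in results])
    de_tables = []
    if union.lncrnas:
        for bundle, res in zip(bundles, results):
            if bundle.labels is None:
                continue
            groups = bundle.labels.value_counts()
            if groups.get("tumor", 0) < 3 or groups.get("normal", 0) < 3:
                continue
            res.de = pathogenicity.differential_expression(
                bundle.lncrna,
                bundle.labels,
                lnc_ids=union.lncrnas,
                adj_p_threshold=cfg.de_adj_p,
                logfc_threshold=cfg.de_logfc,
            )
            if not res.de.empty:
                de_tables.append(res.de)
    de = (
        pd.concat(de_tables, ignore_index=True)
        if de_tables
        else pd.DataFrame(columns=pathogenicity.DE_COLUMNS)
    )
    if pathways is None:
        pathways = sorted({pw for b in bundles for pw in b.gene_sets})
    if union.lncrnas:
        counts = union.pair_counts(list(pathways))
        table = pathogenicity.pathogenicity_table(counts, de, list(pathways))
    else:
        table = pd.DataFrame(
            columns=["lncrna_id", "nc_total", "r_de", "r_fc", "pscore"]
        )
    return PanCancerResult(results, union, de, table)
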