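"""Preranked immune-pathway enrichment and irlncRNA extraction.

For each lncRNA, the mRNAs whose heuristic coefficient H exceeds a rank
threshold (default 0.5, strict) form a ranked list, sorted by descending H
(ties broken lexicographically by mRNA id). Each list is tested against each
immune pathway with the standard preranked weighted running-sum statistic:
walking down the list, pathway members ("hits") increment the running sum by
``|score|^w / N_R`` (``N_R`` = sum of ``|score|^w`` over hits, weight
exponent ``w`` defaulting to 1) and non-members decrement it by
``1/(N - n_hits)``; the enrichment score ES is the signed maximum-magnitude
deviation from zero, in [-1, 1].

Significance comes from a gene-label permutation null: hit labels are
shuffled over list positions (scores fixed) and a one-sided p-value is taken
on the side of the observed ES sign with add-one smoothing,

    p = (1 + #{perm ES same sign, |perm ES| >= |obs ES|})
        / (1 + #{perm ES same sign}),

so p is always positive and permutation p-values of exactly 0 cannot occur.
Each (lncRNA, pathway) pair draws from its own generator seeded from the
master seed and the pair's identifiers, making results invariant to
iteration order.

The lncRNA enrichment score ``lncRES = 1 - 2p`` for ES >= 0 and ``2p - 1``
for ES < 0 lies in [-1, 1]; a (lncRNA, pathway) pair is called
immune-related when ``|lncRES| > 0.995`` (equivalently p < 0.0025) and its
Benjamini-Hochberg FDR (across the pathway tests of that lncRNA, by
default) is below 0.05, both strict.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, NoOverlapError

RECORD_COLUMNS = [
    "lncrna_id",
    "pathway",
    "ES",
    "nominal_p",
    "fdr",
    "lncres",
    "n_hits",
    "list_length",
    "cancer",
]

DEFAULT_RANK_THRESHOLD = 0.5
DEFAULT_LNCRES_THRESHOLD = 0.995
DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class RankedList:
    """A lncRNA's co-expressed mRNAs, sorted by descending heuristic score."""

    lncrna_id: str
    genes: tuple[str, ...]
    scores: np.ndarray
    cancer_label: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ConfigurationError("genes and scores must have equal length")
        if len(self.genes) == 0:
            raise ConfigurationError("ranked list may not be empty")
        if np.any(np.diff(self.scores) > 0):
            raise ConfigurationError("scores must be non-increasing")


def build_ranked_lists(
    triples: pd.DataFrame,
    threshold: float = DEFAULT_RANK_THRESHOLD,
    cancer_label: str = "",
) -> list[RankedList]:
    """Build one ranked list per lncRNA from a correlation table.

    Only pairs with ``H > threshold`` (strict) are kept; lncRNAs left with an
    empty list are omitted. Within a list, mRNAs are ordered by descending H
    with lexicographic tie-breaks on the mRNA id.
    """
    kept = triples.loc[triples["H"] > threshold, ["lncrna_id", "mrna_id", "H"]]
    lists: list[RankedList] = []
    for lnc, group in kept.groupby("lncrna_id", sort=True):
        ordered = group.sort_values(
            ["H", "mrna_id"], ascending=[False, True], kind="mergesort"
        )
        lists.append(
            RankedList(
                lncrna_id=str(lnc),
                genes=tuple(ordered["mrna_id"]),
                scores=ordered["H"].to_numpy(dtype=float),
                cancer_label=cancer_label,
            )
        )
    return lists


def _running_sum_steps(
    scores: np.ndarray, hits: np.ndarray, weight: float
) -> np.ndarray:
    """Per-position increments of the running sum for one hit arrangement."""
    n = scores.size
    n_hits = int(hits.sum())
    w = np.abs(scores) ** weight
    inc = np.where(hits, w, 0.0)
    nr = inc.sum()
    if nr == 0:  # all hit scores are exactly 0: fall back to unweighted hits
        inc = hits / n_hits
    else:
        inc = inc / nr
    return inc - (~hits) / (n - n_hits)


def enrichment_score(
    scores: np.ndarray, hits: np.ndarray, weight: float = 1.0
) -> float:
    """Signed maximum-deviation ES for one ranked list and hit mask.

    ``hits`` marks pathway members along the (already sorted) list. Raises
    :class:`NoOverlapError` for an empty hit set; returns exactly 1.0 when
    every list gene is a hit (the running sum can only rise to 1).
    """
    scores = np.asarray(scores, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    if hits.size != scores.size:
        raise ConfigurationError("hit mask length must match score length")
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise NoOverlapError("gene set shares no genes with the ranked list")
    if n_hits == hits.size:
        return 1.0
    running = np.cumsum(_running_sum_steps(scores, hits, weight))
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak])


def _permutation_es(
    scores: np.ndarray,
    n_hits: int,
    n_perm: int,
    rng: np.random.Generator,
    weight: float,
) -> np.ndarray:
    """ES of ``n_perm`` random hit placements (labels shuffled, scores fixed)."""
    n = scores.size
    w = np.abs(scores) ** weight
    # random n_hits-subsets via argsort of uniforms, one row per permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hits]
    hits = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hits, order, True, axis=1)
    inc = np.where(hits, w[None, :], 0.0)
    nr = inc.sum(axis=1, keepdims=True)
    uniform = hits / n_hits
    nr_safe = np.where(nr > 0, nr, 1.0)
    inc = np.where(nr > 0, inc / nr_safe, uniform)
    steps = inc - (~hits) / (n - n_hits)
    running = np.cumsum(steps, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), peaks]


def permutation_pvalue(
    ranked: RankedList,
    gene_set: Iterable[str],
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    weight: float = 1.0,
) -> tuple[float, float, int]:
    """Observed ES and one-sided permutation p for one (list, gene set) pair.

    Returns ``(ES, p, n_hits)``. With every list gene a hit, all
    permutations coincide with the observation and p degenerates to 1.
    """
    if n_perm < 100:
        raise ConfigurationError(f"n_perm must be >= 100, got {n_perm}")
    if rng is None:
        rng = np.random.default_rng(seed)
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked.genes), bool, len(ranked.genes))
    es = enrichment_score(ranked.scores, hits, weight)
    n_hits = int(hits.sum())
    if n_hits == hits.size:
        return es, 1.0, n_hits
    perm_es = _permutation_es(ranked.scores, n_hits, n_perm, rng, weight)
    same_sign = (perm_es >= 0) if es >= 0 else (perm_es < 0)
    k = int(same_sign.sum())
    extreme = int((same_sign & (np.abs(perm_es) >= abs(es))).sum())
    p = (1 + extreme) / (1 + k)
    return es, p, n_hits


def lncres(es: float, p: float) -> float:
    """lncRES transform: ``1 - 2p`` for ES >= 0, ``2p - 1`` for ES < 0."""
    if not 0.0 < p <= 1.0:
        raise ConfigurationError(f"p must lie in (0, 1], got {p}")
    if not -1.0 - 1e-12 <= es <= 1.0 + 1e-12:
        raise ConfigurationError(f"ES must lie in [-1, 1], got {es}")
    return 1.0 - 2.0 * p if es >= 0 else 2.0 * p - 1.0


def _pair_rng(master_seed: int, lncrna_id: str, pathway: str) -> np.random.Generator:
    """Generator for one (lncRNA, pathway) pair, independent of visit order."""
    digest = hashlib.sha256(f"{lncrna_id}\t{pathway}".encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *words]))


def run_enrichment(
    lists: Sequence[RankedList],
    pathways: Mapping[str, frozenset[str] | set[str]],
    min_size: int = 1,
    max_size: int = 5000,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weight: float = 1.0,
    global_fdr: bool = False,
) -> pd.DataFrame:
    """Test every ranked list against every pathway.

    ``min_size`` is the minimum number of pathway members present in the
    ranked list (pairs below it produce no record); ``max_size`` applies to
    the raw pathway size. FDR is Benjamini-Hochberg within each lncRNA's
    pathway tests by default, or across all tests with ``global_fdr``.

    Returns a DataFrame with columns ``lncrna_id, pathway, ES, nominal_p,
    fdr, lncres, n_hits, list_length, cancer``.
    """
    if min_size < 1:
        raise ConfigurationError("min_size must be >= 1")
    rows: list[dict] = []
    for ranked in lists:
        universe = set(ranked.genes)
        for name in sorted(pathways):
            members = pathways[name]
            if len(members) > max_size:
                continue
            overlap = universe & set(members)
            if len(overlap) < min_size:
                continue
            rng = _pair_rng(seed, ranked.lncrna_id, name)
            es, p, n_hits = permutation_pvalue(
                ranked, members, n_perm=n_perm, rng=rng, weight=weight
            )
            rows.append(
                {
                    "lncrna_id": ranked.lncrna_id,
                    "pathway": name,
                    "ES": es,
                    "nominal_p": p,
                    "lncres": lncres(es, p),
                    "n_hits": n_hits,
                    "list_length": len(ranked.genes),
                    "cancer": ranked.cancer_label,
                }
            )
    if not rows:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    table = pd.DataFrame(rows)
    if global_fdr:
        table["fdr"] = multipletests(table["nominal_p"], method="fdr_bh")[1]
    else:
        table["fdr"] = table.groupby("lncrna_id")["nominal_p"].transform(
            lambda p: multipletests(p, method="fdr_bh")[1]
        )
    table = table[RECORD_COLUMNS]
    return table.sort_values(["lncrna_id", "pathway"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class IrlncRNASet:
    """Immune-related (lncRNA, pathway) pairs extracted for one cancer."""

    cancer_label: str
    members: frozenset[tuple[str, str]]

    @property
    def lncrnas(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.members)


def extract_irlncrnas(
    records: pd.DataFrame,
    lncres_threshold: float = DEFAULT_LNCRES_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    cancer_label: str = "",
) -> IrlncRNASet:
    """Keep pairs with ``|lncRES| > lncres_threshold`` and ``fdr < fdr_threshold``.

    Both inequalities are strict: a pair sitting exactly on either threshold
    is excluded.
    """
    if records.empty:
        return IrlncRNASet(cancer_label, frozenset())
    keep = (records["lncres"].abs() > lncres_threshold) & (
        records["fdr"] < fdr_threshold
    )
    members = frozenset(
        (str(r.lncrna_id), str(r.pathway)) for r in records.loc[keep].itertuples()
    )
    return IrlncRNASet(cancer_label, members)


@dataclass(frozen=True)
class PanCancerUnion:
    """Union of per-cancer irlncRNA sets with per-pair cancer bookkeeping.

    ``per_lnc`` maps lncRNA -> cancer -> pathways, from which the number of
    cancers in which a (lncRNA, pathway) pair was extracted — the input to
    the pathogenicity score — is recovered.
    """

    per_lnc: Mapping[str, Mapping[str, frozenset[str]]] = field(default_factory=dict)

    @property
    def lncrnas(self) -> frozenset[str]:
        return frozenset(self.per_lnc)

    def nc(self, lncrna_id: str, pathway: str) -> int:
        """Number of cancers in which (lncrna, pathway) was extracted."""
        cancers = self.per_lnc.get(lncrna_id, {})
        return sum(1 for paths in cancers.values() if pathway in paths)

    def pair_counts(self, pathways: Sequence[str]) -> pd.DataFrame:
        """lncRNA x pathway table of cancer counts (absent pathways = 0)."""
        lncs = sorted(self.per_lnc)
        data = {pw: [self.nc(l, pw) for l in lncs] for pw in pathways}
        return pd.DataFrame(data, index=pd.Index(lncs, name="lncrna_id"))


def union_irlncrnas(sets: Iterable[IrlncRNASet]) -> PanCancerUnion:
    """Union the per-cancer irlncRNA sets, retaining cancer -> pathway maps."""
    per_lnc: dict[str, dict[str, frozenset[str]]] = {}
    for irset in sets:
        by_lnc: dict[str, set[str]] = {}
        for lnc, pathway in irset.members:
            by_lnc.setdefault(lnc, set()).add(pathway)
        for lnc, paths in by_lnc.items():
            per_lnc.setdefault(lnc, {})[irset.cancer_label] = frozenset(paths)
    return PanCancerUnion(per_lnc)
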