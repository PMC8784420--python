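"""Synthetic pan-cancer fixture data with known ground truth.

The generator emulates the structure of the pipeline's real inputs: paired
mRNA/lncRNA expression matrices per cancer, a tumor-purity table, tumor /
normal labels, immune pathway gene sets, and a record of which lncRNAs were
planted as immune-related.

Model
-----
Expression is log-normal: a per-gene baseline plus factor contributions plus
Gaussian noise on the log2 scale, exponentiated to non-negative units. Each
immune pathway ``w`` has a per-sample latent factor ``f_w``; one designated
pathway's factor is the standardized ``(1 - purity)``, so its members rise as
tumor purity falls (immune admixture), while the remaining factors are
independent standard normals. Pathway members load 1.0 on their factor;
each pathway also drives a small group of *background* mRNAs (members of no
pathway) at a moderate loading — these land in a planted lncRNA's ranked
list below the true members and supply the non-member "misses" a preranked
running-sum statistic needs for a non-degenerate permutation null.

Planted lncRNAs come in two modes: *direct* (loads 1.0 on a pathway factor,
independent of purity) and *purity-mediated* (tracks ``1 - purity`` itself,
so its correlation with the purity pathway's members runs entirely through
the purity covariate). Null lncRNAs are independent noise. Tumor samples of
DE-planted lncRNAs are multiplied by ``2**logfc``.

Purity is drawn uniform on (0.3, 0.9) and reported for tumor samples only,
mirroring real purity estimates; the correlation stage therefore runs on
tumor samples, where a tumor-wide fold change is a constant factor and
cannot distort correlations.

Defaults (the "strong" study conditions): 5 cancers, 3 pathways x 14 member
mRNAs + 6 background mRNAs each (60 mRNAs), 20 lncRNAs, 50 tumor + 20
normal samples, member/lncRNA noise SD 0.25. Background genes target a
lncRNA correlation of about 0.7 — above the 0.5 rank threshold yet clearly
below the ~0.93 of true members — so every planted list reliably carries
several misses; a list of pure hits has a degenerate permutation null
(every relabeling reproduces the observation and p = 1).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix
from .errors import ConfigurationError

DEFAULT_PATHWAY_NAMES = ("Cytokines", "Chemokines", "Interleukins")

#: Conventional ids for the pan-cancer planted lncRNAs.
LNC_HIGH = "LNC-HIGH"  # direct, many cancers, strong DE -> high Pscore
LNC_LOW = "LNC-LOW"  # direct, one cancer, no DE -> low Pscore
LNC_PM = "LNC-PM"  # purity-mediated, many cancers, no DE
LNC_D2 = "LNC-D2"  # direct, a few cancers, moderate DE


@dataclass(frozen=True)
class PlantedLnc:
    """One planted lncRNA in one cancer."""

    lncrna_id: str
    mode: str  # "direct" | "purity"
    pathway: str
    de_logfc: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "purity"):
            raise ConfigurationError(f"unknown planting mode {self.mode!r}")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the standard study conditions."""

    n_tumor: int = 50
    n_normal: int = 20
    n_lnc: int = 20
    pathway_names: tuple[str, ...] = DEFAULT_PATHWAY_NAMES
    purity_pathway: str = "Cytokines"
    pathway_size: int = 14
    bg_per_pathway: int = 6
    member_noise_sd: float = 0.25
    lnc_noise_sd: float = 0.25
    bg_loading: float = 0.75
    bg_noise_sd: float = 0.66
    null_noise_sd: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    purity_low: float = 0.3
    purity_high: float = 0.9
    planted: tuple[PlantedLnc, ...] = (
        PlantedLnc(LNC_HIGH, "direct", "Chemokines", de_logfc=2.5),
        PlantedLnc(LNC_PM, "purity", "Cytokines"),
        PlantedLnc(LNC_LOW, "direct", "Interleukins"),
    )
    #: optional explicit lncRNA namespace (length n_lnc, superset of the
    #: planted ids); lets multi-cancer designs share one namespace even when
    #: the per-cancer planted subsets differ
    lnc_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.lnc_ids is not None:
            if len(self.lnc_ids) != self.n_lnc:
                raise ConfigurationError(
                    f"lnc_ids has {len(self.lnc_ids)} entries, expected {self.n_lnc}"
                )
            if len(set(self.lnc_ids)) != len(self.lnc_ids):
                raise ConfigurationError("duplicate id in lnc_ids")
            missing = {p.lncrna_id for p in self.planted} - set(self.lnc_ids)
            if missing:
                raise ConfigurationError(
                    f"planted lncRNAs absent from lnc_ids: {sorted(missing)}"
                )
        if self.n_tumor + self.n_normal < 10:
            raise ConfigurationError("need at least 10 samples in total")
        if self.n_tumor < 3 or self.n_normal < 3:
            raise ConfigurationError("need >= 3 tumor and >= 3 normal samples")
        if self.purity_pathway not in self.pathway_names:
            raise ConfigurationError(
                f"purity pathway {self.purity_pathway!r} not among pathways"
            )
        if len(set(p.lncrna_id for p in self.planted)) != len(self.planted):
            raise ConfigurationError("duplicate planted lncRNA id")
        if len(self.planted) > self.n_lnc:
            raise ConfigurationError("more planted lncRNAs than total lncRNAs")
        for p in self.planted:
            if p.pathway not in self.pathway_names:
                raise ConfigurationError(f"planted pathway {p.pathway!r} unknown")
        if not 0 <= self.purity_low < self.purity_high <= 1:
            raise ConfigurationError("purity range must satisfy 0 <= low < high <= 1")

    @property
    def n_mrna(self) -> int:
        return len(self.pathway_names) * (self.pathway_size + self.bg_per_pathway)

    @property
    def n_samples(self) -> int:
        return self.n_tumor + self.n_normal


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a (pan-)cancer simulation."""

    planted_pairs: frozenset[tuple[str, str, str]]  # (lncrna, pathway, cancer)
    modes: dict[str, str] = field(default_factory=dict)  # lncrna -> mode
    planted_de: dict[tuple[str, str], float] = field(default_factory=dict)
    config: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    @property
    def planted_lncrnas(self) -> frozenset[str]:
        return frozenset(l for l, _, _ in self.planted_pairs)

    def null_lncrnas(self, all_lnc_ids: list[str]) -> frozenset[str]:
        return frozenset(all_lnc_ids) - self.planted_lncrnas


@dataclass(frozen=True)
class CancerBundle:
    """All inputs the pipeline needs for one cancer, plus its truth."""

    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    purity: pd.Series
    labels: pd.Series
    gene_sets: dict[str, frozenset[str]]
    truth: SyntheticTruth

    @property
    def cancer_label(self) -> str:
        return self.mrna.cancer_label


def _mrna_ids(config: SimConfig) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """(pathway -> member ids, pathway -> background ids), deterministic."""
    members: dict[str, list[str]] = {}
    background: dict[str, list[str]] = {}
    for pw in config.pathway_names:
        tag = pw[:3].upper()
        members[pw] = [f"M-{tag}-{i:02d}" for i in range(1, config.pathway_size + 1)]
        background[pw] = [
            f"M-BG-{tag}-{i:02d}" for i in range(1, config.bg_per_pathway + 1)
        ]
    return members, background


def _lnc_ids(config: SimConfig) -> list[str]:
    if config.lnc_ids is not None:
        return list(config.lnc_ids)
    ids = [p.lncrna_id for p in config.planted]
    nulls = [f"LNC-N{i:02d}" for i in range(1, config.n_lnc - len(ids) + 1)]
    return ids + nulls


def simulate_cancer(
    config: SimConfig | None = None,
    seed: int = 0,
    cancer_label: str = "C1",
) -> CancerBundle:
    """Simulate one cancer's full input bundle; deterministic given the seed."""
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    n = config.n_samples
    tumor_ids = [f"T{i:03d}" for i in range(1, config.n_tumor + 1)]
    normal_ids = [f"N{i:03d}" for i in range(1, config.n_normal + 1)]
    sample_ids = tumor_ids + normal_ids

    # purity drawn for every sample (factor construction) but reported for
    # tumor samples only, as real purity estimates are
    purity_all = rng.uniform(config.purity_low, config.purity_high, size=n)
    impurity = 1.0 - purity_all
    f_purity = (impurity - impurity.mean()) / impurity.std()

    factors: dict[str, np.ndarray] = {}
    for pw in config.pathway_names:
        if pw == config.purity_pathway:
            factors[pw] = f_purity
        else:
            factors[pw] = rng.standard_normal(n)

    members, background = _mrna_ids(config)
    rows: dict[str, np.ndarray] = {}
    for pw in config.pathway_names:
        for gene in members[pw]:
            mu = rng.normal(config.baseline_mean, config.baseline_sd)
            rows[gene] = (
                mu + factors[pw] + rng.normal(0, config.member_noise_sd, n)
            )
        for gene in background[pw]:
            mu = rng.normal(config.baseline_mean, config.baseline_sd)
            rows[gene] = (
                mu
                + config.bg_loading * factors[pw]
                + rng.normal(0, config.bg_noise_sd, n)
            )

    planted_by_id = {p.lncrna_id: p for p in config.planted}
    lnc_rows: dict[str, np.ndarray] = {}
    modes: dict[str, str] = {}
    for lnc in _lnc_ids(config):
        mu = rng.normal(config.baseline_mean, config.baseline_sd)
        plant = planted_by_id.get(lnc)
        if plant is None:
            lnc_rows[lnc] = mu + rng.normal(0, config.null_noise_sd, n)
            modes[lnc] = "null"
        else:
            factor = (
                f_purity if plant.mode == "purity" else factors[plant.pathway]
            )
            lnc_rows[lnc] = mu + factor + rng.normal(0, config.lnc_noise_sd, n)
            modes[lnc] = plant.mode

    mrna_log = pd.DataFrame(rows, index=sample_ids).T
    lnc_log = pd.DataFrame(lnc_rows, index=sample_ids).T
    mrna_values = np.power(2.0, mrna_log)
    lnc_values = np.power(2.0, lnc_log)

    planted_de: dict[tuple[str, str], float] = {}
    for plant in config.planted:
        if plant.de_logfc != 0.0:
            lnc_values.loc[plant.lncrna_id, tumor_ids] *= 2.0**plant.de_logfc
            planted_de[(plant.lncrna_id, cancer_label)] = plant.de_logfc

    truth = SyntheticTruth(
        planted_pairs=frozenset(
            (p.lncrna_id, p.pathway, cancer_label) for p in config.planted
        ),
        modes=modes,
        planted_de=planted_de,
        config=config,
        seed=int(seed),
    )
    return CancerBundle(
        mrna=ExpressionMatrix(mrna_values, cancer_label),
        lncrna=ExpressionMatrix(lnc_values, cancer_label),
        purity=pd.Series(
            purity_all[: config.n_tumor],
            index=pd.Index(tumor_ids, name="sample_id"),
            name="purity",
        ),
        labels=pd.Series(
            ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            index=pd.Index(sample_ids, name="sample_id"),
            name="group",
        ),
        gene_sets={pw: frozenset(members[pw]) for pw in config.pathway_names},
        truth=truth,
    )


def default_pan_planting(k_cancers: int) -> dict[int, tuple[PlantedLnc, ...]]:
    """Per-cancer planting scheme for the pan-cancer bundle.

    A designated high-pathogenicity lncRNA is planted in every cancer with
    strong differential expression; a low-pathogenicity one sits in a single
    cancer with none. A purity-mediated lncRNA spans all cancers and a
    second direct lncRNA covers a subset with moderate DE, giving the
    normalization terms a non-trivial spread.
    """
    scheme: dict[int, tuple[PlantedLnc, ...]] = {}
    for c in range(k_cancers):
        planted = [
            PlantedLnc(LNC_HIGH, "direct", "Chemokines", de_logfc=2.5),
            PlantedLnc(LNC_PM, "purity", "Cytokines"),
        ]
        if c < min(3, k_cancers):
            planted.append(
                PlantedLnc(LNC_D2, "direct", "Interleukins", de_logfc=1.8)
            )
        if c == 0:
            planted.append(PlantedLnc(LNC_LOW, "direct", "Interleukins"))
        scheme[c] = tuple(planted)
    return scheme


def simulate_pan_cancer(
    k_cancers: int = 5,
    config: SimConfig | None = None,
    seed: int = 0,
) -> tuple[list[CancerBundle], SyntheticTruth]:
    """Simulate ``k_cancers`` bundles over a shared gene namespace.

    Cancer labels are ``C1 .. Ck``. Per-cancer seeds are spawned from the
    master seed, so any prefix of cancers is reproducible. Returns the
    bundles and the merged truth. ``k_cancers = 1`` degenerates to a single
    :func:`simulate_cancer` call with the pan planting of cancer 0.
    """
    if k_cancers < 1:
        raise ConfigurationError("k_cancers must be >= 1")
    if config is None:
        config = SimConfig()
    scheme = default_pan_planting(k_cancers)
    # one lncRNA namespace shared by every cancer: all pan-planted ids plus
    # null fillers, regardless of which subset is planted in a given cancer
    all_planted_ids = sorted({p.lncrna_id for pls in scheme.values() for p in pls})
    if len(all_planted_ids) > config.n_lnc:
        raise ConfigurationError("more planted lncRNAs than total lncRNAs")
    n_nulls = config.n_lnc - len(all_planted_ids)
    namespace = tuple(all_planted_ids + [f"LNC-N{i:02d}" for i in range(1, n_nulls + 1)])

    master = np.random.SeedSequence(int(seed))
    child_seeds = master.generate_state(k_cancers) % (2**31)

    bundles: list[CancerBundle] = []
    pairs: set[tuple[str, str, str]] = set()
    modes: dict[str, str] = {}
    planted_de: dict[tuple[str, str], float] = {}
    for c in range(k_cancers):
        label = f"C{c + 1}"
        cfg_c = replace(config, planted=scheme[c], lnc_ids=namespace)
        bundle = simulate_cancer(cfg_c, seed=int(child_seeds[c]), cancer_label=label)
        bundles.append(bundle)
        pairs |= bundle.truth.planted_pairs
        planted_de.update(bundle.truth.planted_de)
        for lnc, mode in bundle.truth.modes.items():
            if mode != "null":
                modes[lnc] = mode
            else:
                modes.setdefault(lnc, "null")
    truth = SyntheticTruth(
        planted_pairs=frozenset(pairs),
        modes=modes,
        planted_de=planted_de,
        config=config,
        seed=int(seed),
    )
    return bundles, truth


def write_bundle(bundle: CancerBundle, outdir: str | Path) -> None:
    """Write one cancer bundle in the exact formats the pipeline consumes.

    Emits ``mrna.tsv``, ``lncrna.tsv``, ``purity.tsv``, ``labels.tsv``,
    ``pathways.gmt`` and ``truth.json`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.mrna.data.rename_axis("gene_id").to_csv(outdir / "mrna.tsv", sep="\t")
    bundle.lncrna.data.rename_axis("gene_id").to_csv(outdir / "lncrna.tsv", sep="\t")
    bundle.purity.rename_axis("sample_id").to_csv(outdir / "purity.tsv", sep="\t")
    bundle.labels.rename_axis("sample_id").to_csv(outdir / "labels.tsv", sep="\t")
    with open(outdir / "pathways.gmt", "w") as handle:
        for pw in sorted(bundle.gene_sets):
            genes = "\t".join(sorted(bundle.gene_sets[pw]))
            handle.write(f"{pw}\tsynthetic immune pathway\t{genes}\n")
    truth = bundle.truth
    payload = {
        "cancer_label": bundle.cancer_label,
        "seed": truth.seed,
        "planted_pairs": sorted(list(p) for p in truth.planted_pairs),
        "modes": dict(sorted(truth.modes.items())),
        "planted_de": {
            f"{l}|{c}": fc for (l, c), fc in sorted(truth.planted_de.items())
        },
    }
    with open(outdir / "truth.json", "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
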