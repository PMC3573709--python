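"""Synthetic expression, annotation and PPI generator with planted structure.

The generator emulates the statistical architecture the screening pipeline is
designed to detect in tumor-vs-normal microarray data: a growth-receptor /
adhesion axis anti-correlated (in tumor samples only) with a mevalonate /
cell-cycle proliferation axis, plus a transcription-factor (NF-Y-like) axis
whose target genes co-express both with the factor's subunit genes and with
the proliferation axis.

Three standard-normal latent factors are drawn per sample:

* ``growth`` — loads the growth_receptor and adhesion modules;
* ``mevalonate`` — loads the mevalonate anchors, the cell_cycle module and
  (jointly with ``nfy``) the nfy_targets module;
* ``nfy`` — loads the NF-Y subunit genes and nfy_targets.

``growth`` and ``mevalonate`` are correlated ``rho_tumor`` in tumor columns
and ``rho_normal`` in normal columns; ``nfy`` is independent of both.  A gene
value is baseline + sum(loading x factor) + Gaussian noise; genes outside all
modules are pure noise.  Module sizes and loadings were chosen so that
pairwise correlations fall either clearly inside or clearly outside the
empirical-null acceptance region at the default 58/49 sample sizes (see the
methods note), making end-to-end recovery a sharp test rather than a coin
flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, GeneSet

__all__ = [
    "ModuleSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_annotation",
    "generate_ppi",
]

FACTORS = ("growth", "mevalonate", "nfy")

#: gene names given to the first members of the named modules so that the
#: pipeline's default anchor/subunit lists work on synthetic data unchanged
SPECIAL_NAMES: dict[str, tuple[str, ...]] = {
    "growth_receptor": ("EGFR", "MET"),
    "mevalonate": ("FDFT1", "FDPS", "HMGCS1", "IDI1", "LSS", "EBP", "MVK"),
    "nfy_subunits": ("NFYA", "NFYB", "NFYC"),
}


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module: size and per-factor loadings."""

    size: int
    loadings: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("module size must be >= 0")
        unknown = set(self.loadings) - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors {unknown}; choose from {FACTORS}")


def default_modules() -> dict[str, ModuleSpec]:
    return {
        "growth_receptor": ModuleSpec(10, {"growth": 1.4}),
        "adhesion": ModuleSpec(20, {"growth": 0.8}),
        "mevalonate": ModuleSpec(7, {"mevalonate": 1.0}),
        "cell_cycle": ModuleSpec(60, {"mevalonate": 0.25}),
        "nfy_subunits": ModuleSpec(3, {"nfy": 1.0}),
        "nfy_targets": ModuleSpec(40, {"nfy": 1.0, "mevalonate": 1.0}),
    }


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 58 tumor / 49 normal samples, 2,000 genes,
    growth-vs-proliferation factor correlation -0.6 in tumor and 0 in normal."""

    n_tumor: int = 58
    n_normal: int = 49
    n_genes: int = 2000
    modules: dict[str, ModuleSpec] = field(default_factory=default_modules)
    rho_tumor: float = -0.6
    rho_normal: float = 0.0
    noise_sd: float = 0.6
    baseline: float = 7.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_tumor < 3 or self.n_normal < 3:
            raise ValueError("need >=3 samples per group")
        if sum(m.size for m in self.modules.values()) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not (abs(self.rho_tumor) < 1 and abs(self.rho_normal) < 1):
            raise ValueError("|rho| must be < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time."""

    modules: dict[str, list[str]]
    loadings: dict[str, dict[str, float]]
    config: SyntheticConfig
    factors: pd.DataFrame = field(repr=False)  # samples x factors

    @property
    def module_genes(self) -> set[str]:
        return {g for genes in self.modules.values() for g in genes}

    def to_json_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["modules"] = {k: {"size": v["size"], "loadings": dict(v["loadings"])}
                          for k, v in cfg["modules"].items()}
        return {"modules": self.modules, "loadings": self.loadings, "config": cfg}


def _gene_names(config: SyntheticConfig) -> tuple[list[str], dict[str, list[str]]]:
    names: list[str] = []
    modules: dict[str, list[str]] = {}
    for mod, spec in config.modules.items():
        special = SPECIAL_NAMES.get(mod, ())
        genes = [
            special[i] if i < len(special) else f"{mod.upper()}_{i + 1:03d}"
            for i in range(spec.size)
        ]
        modules[mod] = genes
        names.extend(genes)
    n_noise = config.n_genes - len(names)
    names.extend(f"GENE_{i + 1:04d}" for i in range(n_noise))
    return names, modules


def generate_expression(
    config: SyntheticConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Draw a planted-structure expression matrix.

    Returns ``(expression, sample_sheet, truth)``; the sheet labels the first
    ``n_tumor`` columns ``tumor`` and the rest ``normal``.
    """
    config = config or SyntheticConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names, modules = _gene_names(config)
    n_samples = config.n_tumor + config.n_normal
    sample_ids = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:03d}" for i in range(config.n_normal)
    ]
    groups = pd.Series(
        ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
        index=sample_ids, name="group",
    )

    # growth/mevalonate factors share a group-specific correlation; nfy is free
    f = np.empty((n_samples, 3))
    for sl, rho in ((slice(0, config.n_tumor), config.rho_tumor),
                    (slice(config.n_tumor, n_samples), config.rho_normal)):
        k = sl.stop - sl.start
        z = rng.standard_normal((k, 2))
        f[sl, 0] = z[:, 0]
        f[sl, 1] = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    f[:, 2] = rng.standard_normal(n_samples)
    factors = pd.DataFrame(f, index=sample_ids, columns=list(FACTORS))

    loading_mat = np.zeros((config.n_genes, 3))
    loadings: dict[str, dict[str, float]] = {}
    idx_of = {g: i for i, g in enumerate(names)}
    for mod, spec in config.modules.items():
        for g in modules[mod]:
            loadings[g] = dict(spec.loadings)
            for fac, a in spec.loadings.items():
                loading_mat[idx_of[g], FACTORS.index(fac)] = a

    values = (
        config.baseline
        + loading_mat @ f.T
        + rng.normal(scale=config.noise_sd, size=(config.n_genes, n_samples))
    )
    expr = pd.DataFrame(values, index=pd.Index(names, name="gene"),
                        columns=sample_ids)
    truth = SyntheticTruth(modules, loadings, config, factors)
    return expr, groups, truth


def generate_annotation(
    truth: SyntheticTruth,
    *,
    n_decoys: int = 10,
    decoy_size: int = 15,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> GeneSetCollection:
    """GMT collection: one term per planted module plus random decoy terms.

    Decoy members are drawn without replacement from genes outside every
    planted module, so decoys are disjoint from the real modules by
    construction.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sets = [
        GeneSet(f"MODULE:{mod.upper()}", f"planted {mod} module", frozenset(genes))
        for mod, genes in truth.modules.items()
        if genes
    ]
    n_noise = truth.config.n_genes - len(truth.module_genes)
    noise_genes = [f"GENE_{i + 1:04d}" for i in range(n_noise)]
    for d in range(n_decoys):
        members = rng.choice(noise_genes, size=min(decoy_size, len(noise_genes)),
                             replace=False)
        sets.append(GeneSet(f"DECOY:{d + 1:02d}", f"random decoy {d + 1}",
                            frozenset(members.tolist())))
    return GeneSetCollection(sets)


def generate_ppi(
    truth: SyntheticTruth,
    *,
    n_hubs: int = 6,
    n_secondary: int = 6,
    n_intermediates: int = 10,
    n_background_nodes: int = 60,
    hub_target_edges: int = 3,
    background_density: float = 0.002,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[nx.Graph, dict[str, list[str]]]:
    """Plant a PPI network around the NF-Y axis of a synthetic truth table.

    Primary hubs are wired to ``hub_target_edges`` (>=3) random nfy_target
    nodes and to one NF-Y subunit, so they sit on length-2 paths between the
    seed sets; secondary hubs get 2 target edges, 2 primary-hub edges and one
    subunit edge; plain intermediates bridge one subunit and one target.
    Erdos-Renyi background edges are added over all nodes at
    ``background_density``.  Returns the simple graph and the planted-role
    table.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    subunits = truth.modules.get("nfy_subunits", [])
    targets = truth.modules.get("nfy_targets", [])
    if not subunits or not targets:
        raise ValueError("truth must include nfy_subunits and nfy_targets modules")
    if hub_target_edges < 3:
        raise ValueError("hub_target_edges must be >=3 for hubs to be primary")

    hubs = [f"HUB_{i + 1:02d}" for i in range(n_hubs)]
    secondaries = [f"SECHUB_{i + 1:02d}" for i in range(n_secondary)]
    inters = [f"INTER_{i + 1:02d}" for i in range(n_intermediates)]
    background = [f"BG_{i + 1:03d}" for i in range(n_background_nodes)]

    edges: list[tuple[str, str]] = []
    for h in hubs:
        picked = rng.choice(targets, size=min(hub_target_edges, len(targets)),
                            replace=False)
        edges.extend((h, t) for t in picked)
        edges.append((h, str(rng.choice(subunits))))
    for s in secondaries:
        picked = rng.choice(targets, size=min(2, len(targets)), replace=False)
        edges.extend((s, t) for t in picked)
        if hubs:
            hpick = rng.choice(hubs, size=min(2, len(hubs)), replace=False)
            edges.extend((s, h) for h in hpick)
        edges.append((s, str(rng.choice(subunits))))
    for x in inters:
        edges.append((x, str(rng.choice(subunits))))
        edges.append((x, str(rng.choice(targets))))

    nodes = list(subunits) + list(targets) + hubs + secondaries + inters + background
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((u, v) for u, v in edges if u != v)
    if background_density > 0:
        n = len(nodes)
        n_extra = rng.binomial(n * (n - 1) // 2, background_density)
        for _ in range(int(n_extra)):
            u, v = rng.choice(nodes, size=2, replace=False)
            g.add_edge(str(u), str(v))
    planted = {
        "hubs": hubs,
        "secondary_hubs": secondaries,
        "intermediates": inters,
        "seeds_a": list(subunits),
        "seeds_b": list(targets),
    }
    return g, planted
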