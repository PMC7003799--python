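"""Synthetic multi-site survey generator with known assembly ground truth.

Emulates the structure of a multi-lake bloom-microbiome survey: a phylogeny
of a few hundred taxa, a heritable niche trait evolved along it, nine sites
sampled in triplicate, communities assembled under trait filtering / neutral
draw / limiting similarity, sequencing-depth count noise, and host-vs-
microbiome KO tables with partly complementary module content.  Every stage
records its ground truth so downstream statistics (alphaNTI/betaNTI,
distance-decay, Venn partition) have recovery tests.

Assembly modes map one-to-one onto the interpretive categories of community
phylogenetics:

* ``filtered`` — the ``richness`` taxa whose trait lies nearest the site
  optimum; produces phylogenetic clustering when the trait is conserved.
* ``neutral`` — a uniform draw without replacement; no structure.
* ``overdispersed`` — greedy max-min patristic spacing; limiting similarity.

The trait filter's half-width does not alter membership (membership is the
deterministic nearest-``richness`` set); it shapes *abundance*, weighting
expected abundances by a Gaussian kernel around the optimum.  A narrow
width therefore yields a few abundant, trait-matched (and mutually related)
taxa shared across sites plus a long rare tail — the regime where taxon-level
Bray-Curtis stays high while abundance-weighted UniFrac stays low.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import community as cio
from .functional import ModuleDef, write_module_defs, write_ko_table

__all__ = [
    "AssemblyConfig",
    "SyntheticTruth",
    "simulate_tree",
    "evolve_trait_bm",
    "assemble_community",
    "sample_abundances",
    "place_sites",
    "simulate_ko_tables",
    "random_modules",
    "default_module_sets",
    "synthetic_taxonomy",
    "simulate_survey",
    "write_bundle",
]

ASSEMBLY_MODES = ("filtered", "neutral", "overdispersed")
SPATIAL_MODES = ("shared_optimum", "autocorrelated")

# Trait range spanned by autocorrelated site optima.  Set against the
# Brownian tip-trait spread at the default scale (sigma=1 on a ~300-tip
# Yule tree gives tip sd ~ sqrt(H_n - 1) ~ 2.2), so the planted gradient
# moves optima across the realized trait range.
AUTOCORRELATED_OPTIMUM_SCALE = 3.0

# Class labels for synthetic lineages; the leading entries are the classes
# typical of bloom-associated freshwater communities, padded to ~35.
_CLASS_POOL = [
    "Alphaproteobacteria", "Bacteroidia", "Gammaproteobacteria", "Clostridia",
    "Campylobacteria", "Deltaproteobacteria", "Negativicutes", "Phycisphaerae",
    "Gemmatimonadetes", "Acidobacteriia", "Ignavibacteria", "SM1A07",
    "Melainabacteria", "Cytophagia", "Parcubacteria", "Anaerolineae",
    "Verrucomicrobiae", "Planctomycetacia", "Actinobacteria", "Bacilli",
    "Chlorobia", "Spirochaetia", "Fibrobacteria", "Deinococci",
    "Nitrospira", "Chloroflexia", "Dehalococcoidia", "Holophagae",
    "Thermoleophilia", "Rubrobacteria", "Coriobacteriia", "Erysipelotrichia",
    "Fusobacteriia", "Mollicutes", "Oligoflexia",
]


@dataclass(frozen=True)
class AssemblyConfig:
    """Study-design parameters of one synthetic survey."""

    n_tips: int = 300
    n_sites: int = 9
    n_replicates: int = 3
    richness_per_site: int = 60
    assembly_mode: str = "filtered"
    trait_sigma: float = 1.0
    filter_width: float = 0.15
    immigration_rate: float = 0.0
    site_jitter_sigma: float = 1.0
    trait_conservatism: float = 2.0
    spatial_mode: str = "shared_optimum"
    depth_mean: int = 20000
    abundance_lognormal_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (1 <= self.richness_per_site <= self.n_tips):
            raise ValueError("richness_per_site must be in [1, n_tips]")
        if self.assembly_mode not in ASSEMBLY_MODES:
            raise ValueError(f"assembly_mode must be one of {ASSEMBLY_MODES}")
        if self.spatial_mode not in SPATIAL_MODES:
            raise ValueError(f"spatial_mode must be one of {SPATIAL_MODES}")
        for name in ("trait_sigma", "filter_width", "abundance_lognormal_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.immigration_rate < 1):
            raise ValueError("immigration_rate must be in [0, 1)")
        if self.site_jitter_sigma < 0:
            raise ValueError("site_jitter_sigma must be >= 0")
        if self.trait_conservatism < 0:
            raise ValueError("trait_conservatism must be >= 0")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")


def _tip_label(i: int, n: int) -> str:
    return f"T{i + 1:0{len(str(n))}d}"


def simulate_tree(n_tips: int, seed: int) -> TreeNode:
    """Pure-birth (Yule, rate 1) tree with ``n_tips`` labelled tips.

    Lineages split at exponential waiting times; a final exponential wait is
    appended so every terminal branch has strictly positive length.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    # node = [children (list of node ids) or None, birth_time, split_time]
    nodes: list[list] = [[[1, 2], 0.0, 0.0], [None, 0.0, None], [None, 0.0, None]]
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        left, right = len(nodes), len(nodes) + 1
        nodes[parent][0] = [left, right]
        nodes[parent][2] = t
        nodes.append([None, t, None])
        nodes.append([None, t, None])
        active.extend([left, right])
    t_end = t + rng.exponential(1.0 / n_tips)
    labels = iter(_tip_label(i, n_tips) for i in range(n_tips))

    def build(i: int) -> str:
        children, birth, split = nodes[i]
        if children is None:
            return f"{next(labels)}:{t_end - birth:.10f}"
        inner = ",".join(build(c) for c in children)
        return f"({inner}):{split - birth:.10f}"

    newick = build(0) + ";"
    return TreeNode.read([newick])


def evolve_trait_bm(
    tree: TreeNode, sigma: float, seed: int, rate_decay: float = 0.0
) -> dict[str, float]:
    """Brownian-motion niche trait along branches, root value 0.

    With ``rate_decay=0`` (the default) this is plain Brownian motion: tip
    values have variance sigma^2 times root-to-tip path length, and shared
    ancestry induces covariance between relatives — which is what lets
    trait filtering generate phylogenetic clustering.

    ``rate_decay > 0`` switches to an early-burst process: the
    instantaneous rate decays as exp(-rate_decay * u) with relative depth
    u in [0, 1], concentrating trait variance on deep branches.  That
    models deep niche conservatism — trait-similar taxa then tend to share
    deep clades rather than converging across the tree.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    depth_max = max(
        (tip.accumulate_to_ancestor(tree) for tip in tree.tips()), default=0.0
    )
    if depth_max <= 0:
        depth_max = 1.0
    values: dict[int, float] = {id(tree): 0.0}
    depths: dict[int, float] = {id(tree): 0.0}
    traits: dict[str, float] = {}
    r = 2.0 * rate_decay / depth_max
    for node in tree.preorder(include_self=False):
        length = node.length or 0.0
        t0 = depths[id(node.parent)]
        t1 = t0 + length
        if rate_decay == 0.0:
            var = length
        else:
            # integral of exp(-r t) over the branch, r scaled to tree depth
            var = (np.exp(-r * t0) - np.exp(-r * t1)) / r
        val = values[id(node.parent)] + rng.normal(0.0, sigma * np.sqrt(var))
        values[id(node)] = val
        depths[id(node)] = t1
        if node.is_tip():
            traits[node.name] = float(val)
    return traits


def assemble_community(
    tree: TreeNode,
    trait: dict[str, float],
    optimum: float,
    config: AssemblyConfig,
    seed: int,
    candidates: list[str] | None = None,
    dist=None,
) -> list[str]:
    """Select a site's taxa under the configured assembly mode.

    ``candidates`` restricts the selectable pool (defaults to all tips);
    ``dist`` may carry a precomputed patristic DistanceMatrix for the
    overdispersed mode.  Ties break by taxon label order.  Returns sorted
    labels.
    """
    pool = sorted(candidates if candidates is not None else trait.keys())
    k = config.richness_per_site
    if k > len(pool):
        raise ValueError(f"richness {k} exceeds candidate pool of {len(pool)}")
    mode = config.assembly_mode
    if mode == "filtered":
        # Trait filter with weak immigration: selection probability is a
        # Gaussian kernel of half-width filter_width around the optimum,
        # mixed with a uniform component, drawn without replacement
        # (Gumbel top-k).  Sites sharing an optimum share the well-matched
        # core but differ in a rare, site-specific tail.
        rng = np.random.default_rng(seed)
        delta = np.array([trait[t] - optimum for t in pool])
        w = np.exp(-(delta**2) / (2.0 * config.filter_width**2))
        total = w.sum()
        eps = config.immigration_rate
        if total > 0:
            m = (1.0 - eps) * w / total + eps / len(pool)
        else:
            m = np.full(len(pool), 1.0 / len(pool))
        keys = np.log(m) + rng.gumbel(size=len(pool))
        order = np.lexsort((pool, -keys))
        return sorted(pool[i] for i in order[:k])
    if mode == "neutral":
        rng = np.random.default_rng(seed)
        return sorted(rng.choice(pool, size=k, replace=False).tolist())
    if mode == "overdispersed":
        if dist is None:
            dist = tree.tip_tip_distances()
        idx = {t: dist.index(t) for t in pool}
        d = dist.data
        first = min(pool, key=lambda t: (abs(trait[t] - optimum), t))
        chosen = [first]
        remaining = [t for t in pool if t != first]
        while len(chosen) < k:
            best = max(
                remaining,
                key=lambda t: (min(d[idx[t], idx[c]] for c in chosen), _neg(t)),
            )
            chosen.append(best)
            remaining.remove(best)
        return sorted(chosen)
    raise ValueError(f"unknown assembly mode {mode!r}")


class _neg(str):
    """Inverts string ordering so max() tie-breaks toward the smaller label."""

    def __lt__(self, other):
        return str.__gt__(self, other)


def expected_abundances(
    taxa: list[str],
    lognormal_sigma: float,
    seed: int,
    weights: dict[str, float] | None = None,
) -> pd.Series:
    """Per-taxon expected relative abundances: lognormal scatter times an
    optional deterministic weight (e.g. the trait-filter kernel).

    ``lognormal_sigma`` here is the total per-taxon scatter of one draw; the
    survey generator composes this from a survey-wide carrying capacity and
    a smaller per-site jitter instead, so abundances are correlated across
    sites.
    """
    if not taxa:
        raise ValueError("taxa set is empty")
    rng = np.random.default_rng(seed)
    taxa = sorted(taxa)
    vals = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(taxa))
    if weights is not None:
        vals = vals * np.array([max(weights[t], 1e-12) for t in taxa])
    return pd.Series(vals / vals.sum(), index=taxa)


def sample_abundances(
    taxa,
    depth_mean: int,
    lognormal_sigma: float,
    seed: int,
    weights: dict[str, float] | None = None,
    expected: pd.Series | None = None,
) -> pd.Series:
    """Draw one sample's counts: lognormal expected abundances, Poisson
    depth around ``depth_mean``, multinomial counts.  Total is >= 1."""
    rng = np.random.default_rng(seed)
    if expected is None:
        expected = expected_abundances(
            list(taxa), lognormal_sigma, int(rng.integers(2**31)), weights
        )
    depth = max(1, int(rng.poisson(depth_mean)))
    counts = rng.multinomial(depth, expected.to_numpy())
    return pd.Series(counts, index=expected.index)


def place_sites(
    n_sites: int,
    spatial_mode: str,
    seed: int,
    optimum_scale: float = AUTOCORRELATED_OPTIMUM_SCALE,
) -> tuple[pd.DataFrame, pd.Series]:
    """Uniform-on-the-sphere site coordinates plus per-site trait optima.

    ``shared_optimum`` gives every site the same optimum (no distance-decay
    ground truth); ``autocorrelated`` sets the optimum to a smooth function
    of position (scale times cos(lat)cos(lon), one coordinate of the unit
    3-vector), planting a decay of similarity with distance.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    if spatial_mode not in SPATIAL_MODES:
        raise ValueError(f"spatial_mode must be one of {SPATIAL_MODES}")
    rng = np.random.default_rng(seed)
    lat = np.degrees(np.arcsin(rng.uniform(-1.0, 1.0, size=n_sites)))
    lon = rng.uniform(-180.0, 180.0, size=n_sites)
    ids = [f"site{i + 1:02d}" for i in range(n_sites)]
    geo = pd.DataFrame({"latitude": lat, "longitude": lon}, index=pd.Index(ids, name="site"))
    if spatial_mode == "shared_optimum":
        optima = pd.Series(0.0, index=geo.index)
    else:
        x = np.cos(np.radians(lat)) * np.cos(np.radians(lon))
        optima = pd.Series(optimum_scale * x, index=geo.index)
    return geo, optima


def random_modules(
    n_modules: int,
    seed: int,
    prefix: str = "M",
    ko_start: int = 1,
    blocks_range: tuple[int, int] = (3, 5),
    alts_range: tuple[int, int] = (1, 3),
) -> tuple[list[ModuleDef], int]:
    """Generate modules with globally unique KO ids; returns (modules,
    next free KO number).  Blocks >= 3 keep the two gene pools identifiable
    under the <=1-missing-block completeness rule."""
    rng = np.random.default_rng(seed)
    modules = []
    ko = ko_start
    for i in range(n_modules):
        blocks = []
        for _ in range(int(rng.integers(blocks_range[0], blocks_range[1] + 1))):
            n_alt = int(rng.integers(alts_range[0], alts_range[1] + 1))
            blocks.append(frozenset(f"K{ko + j:05d}" for j in range(n_alt)))
            ko += n_alt
        modules.append(ModuleDef(f"{prefix}{i + 1:04d}", tuple(blocks)))
    return modules, ko


def default_module_sets(seed: int = 0):
    """Host-only, shared, and microbiome-only module lists with the
    qualitative proportions of a host-vs-microbiome comparison (the
    microbiome pool carries the most unique pathway content)."""
    host, nxt = random_modules(15, seed, prefix="MH")
    shared, nxt = random_modules(30, seed + 1, prefix="MS", ko_start=nxt)
    micro, _ = random_modules(40, seed + 2, prefix="MB", ko_start=nxt)
    return host, shared, micro


def simulate_ko_tables(
    host_modules: list[ModuleDef],
    microbiome_modules: list[ModuleDef],
    shared_modules: list[ModuleDef],
    n_sites: int,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site KO abundance tables for the two gene pools.

    The host table carries every KO of host and shared modules, the
    microbiome table those of microbiome and shared modules; ``noise`` is an
    independent per-KO, per-site dropout probability.  Abundances are
    positive lognormal where present.  Returns (host, microbiome), each
    sites x KOs.
    """
    if not (0 <= noise < 1):
        raise ValueError("noise must be in [0, 1)")
    ids = [m.module_id for m in host_modules + microbiome_modules + shared_modules]
    if len(ids) != len(set(ids)):
        raise ValueError("module ids overlap across the host/microbiome/shared lists")
    rng = np.random.default_rng(seed)
    sites = [f"site{i + 1:02d}" for i in range(n_sites)]

    def build(modules: list[ModuleDef]) -> pd.DataFrame:
        kos = sorted({ko for m in modules for b in m.blocks for ko in b})
        ab = rng.lognormal(0.0, 1.0, size=(n_sites, len(kos)))
        if noise > 0:
            ab[rng.random(size=ab.shape) < noise] = 0.0
        return pd.DataFrame(ab, index=pd.Index(sites, name="group"), columns=kos)

    host = build(host_modules + shared_modules)
    micro = build(microbiome_modules + shared_modules)
    return host, micro


def synthetic_taxonomy(
    tree: TreeNode,
    seed: int,
    cyanobacteria_tips: list[str] | None = None,
) -> pd.DataFrame:
    """SILVA-style lineages for every tip, phylogenetically coherent at the
    class rank (contiguous clades share classes), with the given tips
    labelled as the Cyanobacteria clade."""
    rng = np.random.default_rng(seed)
    cyano = set(cyanobacteria_tips or [])
    tips = [t.name for t in tree.tips() if t.name not in cyano]
    n_classes = min(len(_CLASS_POOL), max(1, len(tips)))
    chunks = np.array_split(np.arange(len(tips)), n_classes)
    records = {}
    for ci, chunk in enumerate(chunks):
        cls = _CLASS_POOL[ci]
        for j in chunk:
            taxon = tips[j]
            records[taxon] = (
                f"Bacteria;Phylum{ci % 12 + 1:02d};{cls};"
                f"Order{ci + 1:02d};Family{ci + 1:02d};Genus_{taxon}"
            )
    for taxon in sorted(cyano):
        records[taxon] = (
            f"Bacteria;Cyanobacteria;Cyanophyceae;Chroococcales;"
            f"Microcystaceae;Genus_{taxon}"
        )
    conf = np.round(rng.uniform(0.8, 1.0, size=len(records)), 3)
    taxa = [t.name for t in tree.tips()]
    return pd.DataFrame(
        {"lineage": [records[t] for t in taxa], "confidence": conf[: len(taxa)]},
        index=pd.Index(taxa, name="taxon_id"),
    )


@dataclass
class SyntheticTruth:
    """Everything a recovery test needs about one synthetic survey."""

    config: AssemblyConfig
    tree: TreeNode = field(repr=False)
    trait: dict[str, float] = field(repr=False)
    coordinates: pd.DataFrame = field(repr=False)
    site_optima: pd.Series = field(repr=False)
    communities: pd.DataFrame = field(repr=False)  # replicate samples x taxa
    taxonomy: pd.DataFrame = field(repr=False)
    replicate_map: dict[str, str] = field(repr=False)
    site_members: dict[str, list[str]] = field(repr=False)
    planted: dict[str, list[str]] = field(repr=False)
    host_modules: list[ModuleDef] = field(repr=False)
    shared_modules: list[ModuleDef] = field(repr=False)
    microbiome_modules: list[ModuleDef] = field(repr=False)
    host_ko: pd.DataFrame = field(repr=False)
    microbiome_ko: pd.DataFrame = field(repr=False)


def _contaminant_counts(
    rng: np.random.Generator, n_samples: int, scale: int
) -> np.ndarray:
    return rng.poisson(scale, size=n_samples)


def simulate_survey(
    config: AssemblyConfig,
    include_contaminants: bool = True,
    ko_noise: float = 0.0,
    n_planted_low_count: int = 8,
) -> SyntheticTruth:
    """Generate one full survey: tree, trait, sites, replicate communities,
    taxonomy (with a Cyanobacteria clade), contaminant taxa exercising the
    pre-analysis filters, and host/microbiome KO tables.

    Contaminants comprise an abundant cyanobacterial clade inside the tree
    (the host signal an amplicon survey removes), off-tree chloroplast/
    mitochondria/eukaryote taxa, and a handful of tree tips planted at a
    total count below 100.  All are recorded in ``planted``.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_tree, s_trait, s_geo, s_comm, s_abund, s_tax, s_ko, s_cont) = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)
    ]
    tree = simulate_tree(config.n_tips, s_tree)
    trait = evolve_trait_bm(
        tree, config.trait_sigma, s_trait, rate_decay=config.trait_conservatism
    )
    geo, optima = place_sites(config.n_sites, config.spatial_mode, s_geo)
    all_tips = sorted(trait)
    # Anchor site optima to the realized trait distribution so the filter
    # always targets a populated niche.  Shared mode: every site gets the
    # centre of the densest trait window (the regional pool's dominant
    # niche).  Autocorrelated mode: optima sweep the 10th-90th trait
    # percentile along the spatial score — a monotone transform, so the
    # planted distance-decay ground truth is preserved.
    tvals = np.sort(np.fromiter(trait.values(), dtype=float))
    if config.spatial_mode == "shared_optimum":
        window = np.array(
            [(np.abs(tvals - v) <= config.filter_width).sum() for v in tvals]
        )
        opt = float(tvals[int(np.argmax(window))])
        optima = pd.Series(opt, index=geo.index)
    else:
        x = np.clip(optima.to_numpy() / AUTOCORRELATED_OPTIMUM_SCALE, -1.0, 1.0)
        optima = pd.Series(np.quantile(tvals, 0.5 + 0.4 * x), index=geo.index)
    rng_cont = np.random.default_rng(s_cont)

    cyano: list[str] = []
    low_count: list[str] = []
    if include_contaminants:
        # a contiguous clade of ~8% of tips becomes the host (Cyanobacteria)
        n_cyano = max(2, config.n_tips // 12)
        target = None
        for node in tree.non_tips(include_self=False):
            k = node.count(tips=True)
            if k and abs(k - n_cyano) < (
                abs(target.count(tips=True) - n_cyano) if target is not None else 1e9
            ):
                target = node
        cyano = sorted(t.name for t in target.tips())
        pool = [t for t in all_tips if t not in cyano]
        low_count = sorted(
            rng_cont.choice(pool, size=min(n_planted_low_count, len(pool)), replace=False)
        )
    candidates = [t for t in all_tips if t not in cyano and t not in low_count]
    taxonomy = synthetic_taxonomy(tree, s_tax, cyanobacteria_tips=cyano)

    comm_ss = np.random.SeedSequence(s_comm).spawn(config.n_sites)
    ab_ss = np.random.SeedSequence(s_abund).spawn(config.n_sites + 1)
    # survey-wide carrying capacities: abundances of shared taxa are
    # correlated across sites, so spatial structure (when planted) is not
    # drowned by independent per-site scatter
    rng_cap = np.random.default_rng(ab_ss[0])
    capacity = pd.Series(
        rng_cap.lognormal(0.0, config.abundance_lognormal_sigma, size=len(all_tips)),
        index=all_tips,
    )
    rows = {}
    replicate_map = {}
    site_members = {}
    dist = tree.tip_tip_distances() if config.assembly_mode == "overdispersed" else None
    for i, site in enumerate(geo.index):
        members = assemble_community(
            tree,
            trait,
            float(optima[site]),
            config,
            int(comm_ss[i].generate_state(1)[0] % (2**31)),
            candidates=candidates,
            dist=dist,
        )
        site_members[site] = members
        weights = None
        if config.assembly_mode == "filtered":
            # Kernel-weighted expected abundances: well-matched taxa are
            # abundant, immigrants rare but detectable (floor keeps them
            # above the survey's low-count horizon in expectation).
            opt = float(optima[site])
            weights = {
                t: max(
                    float(
                        np.exp(-((trait[t] - opt) ** 2) / (2 * config.filter_width**2))
                    ),
                    0.05,
                )
                for t in members
            }
        site_rngs = np.random.SeedSequence(
            int(ab_ss[i + 1].generate_state(1)[0] % (2**31))
        ).spawn(config.n_replicates + 1)
        rng_site = np.random.default_rng(site_rngs[0])
        members_sorted = sorted(members)
        vals = capacity[members_sorted].to_numpy() * rng_site.lognormal(
            0.0, config.site_jitter_sigma, size=len(members_sorted)
        )
        if weights is not None:
            vals = vals * np.array([weights[t] for t in members_sorted])
        profile = pd.Series(vals / vals.sum(), index=members_sorted)
        for r in range(config.n_replicates):
            sample = f"{site}_r{r + 1}"
            rows[sample] = sample_abundances(
                members,
                config.depth_mean,
                config.abundance_lognormal_sigma,
                int(site_rngs[r + 1].generate_state(1)[0] % (2**31)),
                expected=profile,
            )
            replicate_map[sample] = site

    communities = (
        pd.DataFrame(rows).T.fillna(0).astype(np.int64).sort_index(axis=1)
    )
    communities.index.name = "sample"
    planted: dict[str, list[str]] = {
        "cyanobacteria": cyano,
        "low_count": low_count,
        "off_tree": [],
    }
    if include_contaminants:
        n_samples = communities.shape[0]
        # host clade: abundant everywhere, like the bloom former itself
        for t in cyano:
            communities[t] = _contaminant_counts(
                rng_cont, n_samples, max(1, config.depth_mean // max(1, len(cyano)))
            )
        # off-tree organellar / eukaryotic carryover
        off = {
            "CHLORO_1": "Bacteria;Cyanobacteria;Chloroplast;Chloroplast;Chloroplast;Chloroplast",
            "MITO_1": "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Mitochondria;Mitochondria",
            "EUK_1": "Eukaryota;Chlorophyta;Chlorophyceae;Chlamydomonadales;FamilyE;GenusE",
        }
        for taxon, lineage in off.items():
            communities[taxon] = _contaminant_counts(rng_cont, n_samples, 200)
            taxonomy.loc[taxon] = [lineage, 0.9]
        planted["off_tree"] = sorted(off)
        # planted rare tips: strictly below the 100-count floor in total
        for t in low_count:
            col = np.zeros(n_samples, dtype=np.int64)
            hits = rng_cont.choice(n_samples, size=3, replace=False)
            col[hits] = rng_cont.integers(1, 20, size=3)
            communities[t] = col
        communities = communities.sort_index(axis=1)
        # ground truth for the low-count rule covers every taxon under the
        # floor, including community members whose abundance tail fell there
        totals = communities.sum(axis=0)
        exempt = set(cyano) | set(planted["off_tree"])
        planted["low_count"] = sorted(
            t for t in communities.columns if totals[t] < 100 and t not in exempt
        )

    host_mod, shared_mod, micro_mod = default_module_sets(s_ko)
    host_ko, micro_ko = simulate_ko_tables(
        host_mod, micro_mod, shared_mod, config.n_sites, noise=ko_noise, seed=s_ko
    )
    host_ko.index = geo.index.copy()
    micro_ko.index = geo.index.copy()
    return SyntheticTruth(
        config=config,
        tree=tree,
        trait=trait,
        coordinates=geo,
        site_optima=optima,
        communities=communities,
        taxonomy=taxonomy,
        replicate_map=replicate_map,
        site_members=site_members,
        planted=planted,
        host_modules=host_mod,
        shared_modules=shared_mod,
        microbiome_modules=micro_mod,
        host_ko=host_ko,
        microbiome_ko=micro_ko,
    )


def write_bundle(truth: SyntheticTruth, outdir) -> dict[str, str]:
    """Write the survey as the on-disk formats the pipeline reads, plus a
    truth sidecar JSON; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": str(out / "otu_table.tsv"),
        "taxonomy": str(out / "taxonomy.tsv"),
        "tree": str(out / "tree.nwk"),
        "coordinates": str(out / "coordinates.csv"),
        "host_ko": str(out / "host_ko.tsv"),
        "microbiome_ko": str(out / "microbiome_ko.tsv"),
        "modules": str(out / "modules.tsv"),
        "truth": str(out / "truth.json"),
        "replicate_map": str(out / "replicate_map.tsv"),
    }
    cio.write_otu_table(truth.communities, paths["otu_table"])
    cio.write_taxonomy(truth.taxonomy, paths["taxonomy"])
    cio.write_tree(truth.tree, paths["tree"])
    cio.write_coordinates(truth.coordinates, paths["coordinates"])
    write_ko_table(truth.host_ko, paths["host_ko"])
    write_ko_table(truth.microbiome_ko, paths["microbiome_ko"])
    write_module_defs(
        truth.host_modules + truth.shared_modules + truth.microbiome_modules,
        paths["modules"],
    )
    with open(paths["replicate_map"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tsite\n")
        for sample, site in truth.replicate_map.items():
            fh.write(f"{sample}\t{site}\n")
    sidecar = {
        "config": asdict(truth.config),
        "site_optima": {k: float(v) for k, v in truth.site_optima.items()},
        "site_members": truth.site_members,
        "planted": truth.planted,
        "module_ids": {
            "host_only": [m.module_id for m in truth.host_modules],
            "shared": [m.module_id for m in truth.shared_modules],
            "microbiome_only": [m.module_id for m in truth.microbiome_modules],
        },
    }
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
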