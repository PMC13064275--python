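"""Synthetic longitudinal multi-site cohort generator with known ground truth.

Emulates a smoking-cessation airway-microbiome study design: three body
sites (nose, oropharynx, BAL) sampled from never-smokers (NS) and from
smokers followed longitudinally (AS at baseline, FS6w after six weeks of
cessation, FS1y after one year, where the one-year group is a subset of the
six-week group). Communities are assembled from a shared log-normal
metacommunity subject to phylogenetically conserved habitat filtering
(selection), mixed with subject-private pools (dispersal limitation),
modulated by subject random effects (individuality) and group effects on
designated responder taxa, and sequenced by multinomial draws at a
log-normally varying depth. BAL, the low-biomass compartment, additionally
receives reagent contaminants that dominate generated blank-control
samples.

Every output is a pure function of ``SimConfig.seed``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

SITES = ("nose", "oropharynx", "BAL")
GROUPS = ("NS", "AS", "FS6w", "FS1y")

#: timepoint at which each smoking group is observed
_GROUP_TIMEPOINT = {"NS": "baseline", "AS": "baseline", "FS6w": "week6", "FS1y": "year1"}

_GENUS_NAMES = (
    "Streptococcus", "Veillonella", "Prevotella", "Prevotella_7", "Haemophilus",
    "Moraxella", "Corynebacterium", "Staphylococcus", "Dolosigranulum",
    "Neisseria", "Rothia", "Fusobacterium", "Actinomyces", "Gemella",
    "Leptotrichia", "Megasphaera", "Alloprevotella", "Granulicatella",
    "Porphyromonas", "Campylobacter", "Selenomonas", "Capnocytophaga",
    "Parvimonas", "Stomatobaculum", "Lactobacillus", "Alistipes",
)


def _default_group_effects() -> dict[str, dict[str, float]]:
    # Active smoking perturbs responder taxa most strongly in nose and BAL,
    # the compartments the study design marks as most smoking-susceptible;
    # cessation halves (6 weeks) and quarters (1 year) the shift.
    base = {"nose": 1.5, "oropharynx": 0.5, "BAL": 1.5}
    return {
        "NS": {s: 0.0 for s in SITES},
        "AS": dict(base),
        "FS6w": {s: 0.5 * v for s, v in base.items()},
        "FS1y": {s: 0.25 * v for s, v in base.items()},
    }


def _default_site_selection_scale() -> dict[str, float]:
    # The lung (BAL) is the deterministically filtered, low-biomass
    # compartment; the upper airways are weakly filtered.
    return {"nose": 0.25, "oropharynx": 0.25, "BAL": 2.0}


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults mirror the emulated study design.

    ``n_subjects_per_group`` follows the cohort table of the emulated design
    (10 never-smokers, 15 smokers re-sampled at six weeks, 5 of whom
    complete one year); ``depth_mean`` the reported average reads/sample.
    """

    n_taxa_pool: int = 300
    n_subjects_per_group: dict[str, int] = field(
        default_factory=lambda: {"NS": 10, "AS": 15, "FS6w": 15, "FS1y": 5}
    )
    sites: tuple[str, ...] = SITES
    depth_mean: float = 43223.0
    depth_sigma: float = 0.3
    selection_strength: float = 1.0
    site_selection_scale: dict[str, float] = field(default_factory=_default_site_selection_scale)
    dispersal_rate: float = 0.7
    subject_sd: float = 0.8
    group_effects: dict[str, dict[str, float]] = field(default_factory=_default_group_effects)
    responder_fraction: float = 0.1
    trait_sigma: float = 1.0
    pool_sigma: float = 1.5
    contaminant_fraction: float = 0.05
    bal_contaminant_weight: float = 0.03
    n_blanks: int = 5
    blank_depth_fraction: float = 0.2
    metacommunity_sigma: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa_pool < 2:
            raise ValueError("n_taxa_pool must be >= 2")
        if not self.sites:
            raise ValueError("sites must be non-empty")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not 0.0 <= self.dispersal_rate <= 1.0:
            raise ValueError("dispersal_rate must lie in [0, 1]")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction must lie in [0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        if self.trait_sigma < 0:
            raise ValueError("trait_sigma must be non-negative")
        if self.pool_sigma < 0:
            raise ValueError("pool_sigma must be non-negative")
        n = self.n_subjects_per_group
        for g in n:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        if n.get("FS6w", 0) > n.get("AS", 0):
            raise ValueError("FS6w subjects must be a subset of AS subjects")
        if n.get("FS1y", 0) > n.get("FS6w", 0):
            raise ValueError("FS1y subjects must be a subset of FS6w subjects")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    site_regimes: dict[str, str]
    subject_individuality: dict[str, float]
    responders: dict[str, float]  # taxon -> signed log-fold unit (scaled by group x site effect)
    contaminants: list[str]

    def validate(self) -> None:
        if set(self.responders) & set(self.contaminants):
            raise ValueError("responder and contaminant taxa must be disjoint")


# ---------------------------------------------------------------------------
# tree simulation and trait evolution
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int) -> TreeNode:
    """Simulate a rooted bifurcating pure-birth tree with unit birth rate.

    Branch lengths are rescaled so the (ultrametric) root-to-tip depth is 1.
    Tips are labelled ``ASV_0001`` ... in left-to-right order. The newick
    serialization (:func:`to_newick`) is byte-identical for equal seeds.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    # active lineages as (node_id, birth_time); nodes stored as
    # id -> (children or None); lengths filled at speciation/termination
    children: dict[int, tuple[int, int] | None] = {0: None, 1: None}
    parent_of = {0: -1, 1: -1}
    birth = {0: 0.0, 1: 0.0}
    length: dict[int, float] = {}
    active = [0, 1]
    next_id = 2
    t = 0.0
    while len(active) < n_tips:
        t += max(rng.exponential(1.0 / len(active)), 1e-12)
        idx = int(rng.integers(len(active)))
        node = active[idx]
        length[node] = t - birth[node]
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = (a, b)
        for c in (a, b):
            children[c] = None
            parent_of[c] = node
            birth[c] = t
        active[idx] = a
        active.append(b)
    t += max(rng.exponential(1.0 / n_tips), 1e-12)
    for node in active:
        length[node] = t - birth[node]
    scale = 1.0 / t  # mean (here: exact) root-to-tip depth becomes 1

    tip_counter = [0]

    def build(node: int) -> str:
        ln = length[node] * scale
        if children[node] is None:
            tip_counter[0] += 1
            return f"ASV_{tip_counter[0]:04d}:{ln:.10f}"
        a, b = children[node]
        return f"({build(a)},{build(b)}):{ln:.10f}"

    newick = f"({build(0)},{build(1)})root;"
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree with fixed 10-decimal branch lengths (deterministic)."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            core = node.name or ""
        else:
            core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name and node.parent is None:
                core += node.name
        if node.length is not None:
            core += f":{node.length:.10f}"
        return core

    return render(tree) + ";"


def evolve_trait(tree: TreeNode, trait_sigma: float, seed: int) -> dict[str, float]:
    """Brownian motion along branches from a root value of 0.

    Increments on a branch of length ``l`` are N(0, trait_sigma^2 * l);
    ``trait_sigma = 0`` yields all-zero traits.
    """
    if trait_sigma < 0:
        raise ValueError("trait_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    traits: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        l = node.length or 0.0
        val = values[id(node.parent)] + trait_sigma * np.sqrt(l) * rng.standard_normal()
        values[id(node)] = val
        if node.is_tip():
            traits[node.name] = float(val)
    return traits


# ---------------------------------------------------------------------------
# assembly-regime presets
# ---------------------------------------------------------------------------

#: Fixed study conditions under which each assembly regime is expressed.
#: Homogeneous selection needs a narrow, phylogenetically conserved habitat
#: filter plus between-subject turnover inside the filtered clade (zero
#: dispersal, private pools); dispersal limitation needs compositionally
#: idiosyncratic subject pools (large pool_sigma); drift needs stochastic
#: occupancy with shared metacommunity abundances (pool_sigma = 0).
_REGIME_PRESETS: dict[str, dict] = {
    "homogeneous selection": dict(
        n_taxa_pool=500, depth_mean=10000.0, selection_strength=8.0,
        trait_sigma=1.0, dispersal_rate=0.0, subject_sd=0.0, pool_sigma=0.8,
        metacommunity_sigma=0.8,
    ),
    "dispersal limitation": dict(
        n_taxa_pool=120, depth_mean=2000.0, selection_strength=0.0,
        dispersal_rate=0.1, subject_sd=0.3, pool_sigma=1.5,
    ),
    "undominated drift": dict(
        n_taxa_pool=120, depth_mean=2000.0, selection_strength=0.0,
        dispersal_rate=0.0, subject_sd=0.1, pool_sigma=0.0,
    ),
}


def regime_preset(regime: str, seed: int) -> SimConfig:
    """A SimConfig whose within-site pairs should be dominated by ``regime``.

    The presets use a two-site, single-group design with no contaminants so
    the assembly statistics are the only thing under study.
    """
    if regime not in _REGIME_PRESETS:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(_REGIME_PRESETS)}")
    return SimConfig(
        n_subjects_per_group={"NS": 10},
        sites=("oropharynx", "BAL"),
        site_selection_scale={"oropharynx": 1.0, "BAL": 1.0},
        contaminant_fraction=0.0, n_blanks=0,
        seed=seed, **_REGIME_PRESETS[regime],
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _subject_roster(cfg: SimConfig, rng: np.random.Generator):
    """(subject_id, group, timepoint) rows of the longitudinal design."""
    n = {g: cfg.n_subjects_per_group.get(g, 0) for g in GROUPS}
    rows = []
    for i in range(n["NS"]):
        rows.append((f"NS_{i + 1:02d}", "NS", "baseline"))
    smokers = [f"SM_{i + 1:02d}" for i in range(n["AS"])]
    for s in smokers:
        rows.append((s, "AS", "baseline"))
    fs6w = list(rng.choice(smokers, size=n["FS6w"], replace=False)) if n["FS6w"] else []
    for s in sorted(fs6w):
        rows.append((s, "FS6w", "week6"))
    fs1y = list(rng.choice(sorted(fs6w), size=n["FS1y"], replace=False)) if n["FS1y"] else []
    for s in sorted(fs1y):
        rows.append((s, "FS1y", "year1"))
    return rows


def _intended_regimes(cfg: SimConfig) -> dict[str, str]:
    regimes = {}
    for site in cfg.sites:
        s_eff = cfg.selection_strength * cfg.site_selection_scale.get(site, 1.0)
        if s_eff >= 4.0 and cfg.trait_sigma > 0:
            regimes[site] = "homogeneous selection"
        elif cfg.dispersal_rate <= 0.3 and cfg.pool_sigma > 0:
            regimes[site] = "dispersal limitation"
        else:
            regimes[site] = "undominated drift"
    return regimes


def _assign_taxonomy(tree: TreeNode, rng: np.random.Generator) -> dict[str, str]:
    """Genus labels over contiguous blocks of the tip traversal order.

    Blocks follow the tree's left-to-right tip order, so genera are
    phylogenetically coherent clusters, as for real amplicon data.
    """
    tips = [t.name for t in tree.tips()]
    n_genera = max(2, len(tips) // 8)
    cuts = np.sort(rng.choice(np.arange(1, len(tips)), size=n_genera - 1, replace=False))
    blocks = np.split(np.arange(len(tips)), cuts)
    names = list(_GENUS_NAMES) + [f"Genus_{i:03d}" for i in range(len(blocks))]
    return {tips[i]: names[b] for b, block in enumerate(blocks) for i in block}


def simulate_cohort(cfg: SimConfig):
    """Generate (counts, metadata, tree, taxonomy, ground_truth).

    ``counts`` is a samples x taxa integer DataFrame including blank
    controls (sample ids ``BLANK_*``, site/group ``blank``); ``metadata``
    is indexed by sample id with columns subject_id, site, group,
    timepoint and smoking covariates.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    (ss_tree, ss_trait, ss_design, ss_struct, ss_counts) = root.spawn(5)
    tree = simulate_tree(cfg.n_taxa_pool, seed=int(ss_tree.generate_state(1)[0] % 2**31))
    traits_map = evolve_trait(tree, cfg.trait_sigma, seed=int(ss_trait.generate_state(1)[0] % 2**31))
    taxa = [t.name for t in tree.tips()]
    traits = np.array([traits_map[t] for t in taxa])
    P = len(taxa)

    rng_design = np.random.default_rng(ss_design)
    rng_struct = np.random.default_rng(ss_struct)
    rng_counts = np.random.default_rng(ss_counts)

    taxonomy = _assign_taxonomy(tree, rng_design)
    roster = _subject_roster(cfg, rng_design)
    subjects = sorted({r[0] for r in roster})

    # disjoint contaminant and responder pools
    n_cont = int(round(cfg.contaminant_fraction * P))
    n_resp = int(round(cfg.responder_fraction * P))
    perm = rng_design.permutation(P)
    cont_idx = np.sort(perm[:n_cont])
    resp_idx = np.sort(perm[n_cont:n_cont + n_resp])
    bio_mask = np.ones(P, bool)
    bio_mask[cont_idx] = False
    resp_sign = rng_design.choice([-1.0, 1.0], size=n_resp)

    # metacommunity baseline (biological channel only)
    meta_abund = np.zeros(P)
    meta_abund[bio_mask] = rng_struct.lognormal(0.0, cfg.metacommunity_sigma, size=int(bio_mask.sum()))

    # site habitat filters on the Brownian trait; optima at evenly spaced
    # trait quantiles so filters bite regardless of realized trait scale
    qs = np.linspace(0.1, 0.9, num=len(cfg.sites))
    optima = {site: float(np.quantile(traits, q)) for site, q in zip(cfg.sites, qs)}
    site_filter = {}
    for site in cfg.sites:
        s_eff = cfg.selection_strength * cfg.site_selection_scale.get(site, 1.0)
        site_filter[site] = np.exp(-s_eff * (traits - optima[site]) ** 2)

    # subject random effects and subject-private pools
    subj_effect = {
        s: np.exp(cfg.subject_sd * rng_struct.standard_normal(P)) for s in subjects
    }
    # Subject-private pools: a random half of the taxon pool, carrying the
    # shared metacommunity abundances perturbed by a subject-specific
    # log-normal factor of scale pool_sigma. pool_sigma -> 0 makes private
    # pools stochastic re-draws of the metacommunity (ecological drift);
    # large pool_sigma makes subjects compositionally idiosyncratic
    # (dispersal limitation).
    private_pool = {}
    for s in subjects:
        pool = np.zeros(P)
        support = rng_struct.random(P) < 0.5
        support &= bio_mask
        pool[support] = meta_abund[support] * np.exp(
            cfg.pool_sigma * rng_struct.standard_normal(int(support.sum())))
        private_pool[s] = pool

    cont_profile = np.zeros(P)
    if n_cont:
        cont_profile[cont_idx] = rng_struct.lognormal(0.0, 1.0, size=n_cont)
        cont_profile /= cont_profile.sum()

    resp_unit = np.zeros(P)
    resp_unit[resp_idx] = resp_sign

    def _normalize(v: np.ndarray) -> np.ndarray:
        s = v.sum()
        return v / s if s > 0 else v

    rows, sample_ids, meta_rows = [], [], []
    for subject, group, timepoint in roster:
        for site in cfg.sites:
            shift = cfg.group_effects.get(group, {}).get(site, 0.0)
            geff = np.exp(resp_unit * shift)
            shared = _normalize(meta_abund * site_filter[site] * subj_effect[subject] * geff)
            private = _normalize(private_pool[subject] * site_filter[site] * geff)
            p = cfg.dispersal_rate * shared + (1.0 - cfg.dispersal_rate) * private
            p = _normalize(p)
            if site == "BAL" and n_cont:
                p = (1.0 - cfg.bal_contaminant_weight) * p + cfg.bal_contaminant_weight * cont_profile
            depth = max(1, int(round(cfg.depth_mean * rng_counts.lognormal(0.0, cfg.depth_sigma))))
            rows.append(rng_counts.multinomial(depth, _normalize(p)))
            sample_ids.append(f"{subject}_{site}_{timepoint}")
            meta_rows.append((subject, site, group, timepoint))

    for b in range(cfg.n_blanks):
        depth = max(1, int(round(cfg.blank_depth_fraction * cfg.depth_mean)))
        counts = rng_counts.multinomial(depth, cont_profile) if n_cont else np.zeros(P, int)
        rows.append(counts)
        sample_ids.append(f"BLANK_{b + 1:02d}")
        meta_rows.append((f"BLANK_{b + 1:02d}", "blank", "blank", "blank"))

    counts = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=taxa).astype(int)
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(
        meta_rows, index=sample_ids, columns=["subject_id", "site", "group", "timepoint"]
    )
    metadata.index.name = "sample_id"
    # smoking covariates: pack-years etc. drawn once per subject
    packy = {s: (0.0 if s.startswith(("NS", "BLANK")) else float(rng_design.gamma(4.0, 5.0)))
             for s in metadata["subject_id"].unique()}
    metadata["pack_years"] = metadata["subject_id"].map(packy)

    truth = GroundTruth(
        site_regimes=_intended_regimes(cfg),
        subject_individuality={s: cfg.subject_sd for s in subjects},
        responders={taxa[i]: float(resp_sign[k]) for k, i in enumerate(resp_idx)},
        contaminants=[taxa[i] for i in cont_idx],
    )
    truth.validate()
    return counts, metadata, tree, taxonomy, truth


def write_fixture(bundle, out_dir) -> dict[str, Path]:
    """Write (counts, metadata, tree, taxonomy, truth) as TSV/newick/JSON files.

    The feature table uses the taxa-as-rows orientation with an ``ASV_ID``
    first column; re-reading through :mod:`~airway_recovery.io_preprocess`
    round-trips counts exactly.
    """
    counts, metadata, tree, taxonomy, truth = bundle
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "feature_table.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "tree": out / "tree.nwk",
        "truth": out / "ground_truth.json",
    }
    ft = counts.T
    ft.index.name = "ASV_ID"
    ft.to_csv(paths["table"], sep="\t")
    metadata.to_csv(paths["metadata"], sep="\t")
    pd.Series(taxonomy, name="genus").rename_axis("taxon_id").to_csv(paths["taxonomy"], sep="\t")
    paths["tree"].write_text(to_newick(tree) + "\n")
    paths["truth"].write_text(json.dumps({
        "site_regimes": truth.site_regimes,
        "subject_individuality": truth.subject_individuality,
        "responders": truth.responders,
        "contaminants": truth.contaminants,
    }, indent=2, sort_keys=True))
    return paths
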