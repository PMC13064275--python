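"""Calibration, oracle-agreement and parameter-recovery experiments.

Each function runs a self-contained, seeded experiment against the package
and returns plain numbers: brute-force oracle agreement for the distance
kernels, null-model calibration of betaNTI/RCbray, assembly-regime
recovery, PERMANOVA type-I error and power, monotonicity of the
individuality and recovery statistics in their generating parameters,
network-metric oracles, contaminant recovery, and pipeline determinism.
The problem sizes are desk-scale by design: large enough for the effects
under study, small enough to re-run routinely.
"""

from __future__ import annotations

import hashlib
import tempfile
from collections import Counter
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import assembly as asm
from . import diversity as dv
from . import io_preprocess as iop
from . import networks as nw
from . import synthetic_cohort as sc
from .pipeline import PipelineConfig, desk_scale_sim, run_pipeline

# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive, independent of the library paths)
# ---------------------------------------------------------------------------


def brute_weighted_unifrac(x: dict, y: dict, tree, normalized: bool = True) -> float:
    """Weighted UniFrac by explicit per-branch descendant-set enumeration."""
    tx, ty = sum(x.values()), sum(y.values())
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        tips = {node.name} if node.is_tip() else {t.name for t in node.tips()}
        a = sum(x.get(t, 0) for t in tips) / tx if tx else 0.0
        b = sum(y.get(t, 0) for t in tips) / ty if ty else 0.0
        l = node.length or 0.0
        num += l * abs(a - b)
        den += l * (a + b)
    if normalized:
        return num / den if den else 0.0
    return num


def brute_beta_mntd(x: dict, y: dict, dmat: pd.DataFrame) -> float:
    """Abundance-weighted betaMNTD by a double loop over all taxon pairs."""
    ia = [t for t, v in x.items() if v > 0]
    ib = [t for t, v in y.items() if v > 0]
    fa = {t: x[t] / sum(x[t] for t in ia) for t in ia}
    fb = {t: y[t] / sum(y[t] for t in ib) for t in ib}
    s1 = sum(fa[i] * min(dmat.loc[i, j] for j in ib) for i in ia)
    s2 = sum(fb[j] * min(dmat.loc[i, j] for i in ia) for j in ib)
    return 0.5 * (s1 + s2)


def brute_bray_curtis(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den if den else 0.0


def distance_oracle_check(n_instances: int = 50, seed: int = 0) -> dict[str, float]:
    """Max absolute deviation of the distance kernels from brute force
    over random small (tree, table) instances."""
    rng = np.random.default_rng(seed)
    max_wu = max_bm = max_bc = 0.0
    for k in range(n_instances):
        n_tips = int(rng.integers(4, 11))
        n_samp = int(rng.integers(3, 7))
        tree = sc.simulate_tree(n_tips, seed=int(rng.integers(2**31)))
        taxa = [t.name for t in tree.tips()]
        tab = pd.DataFrame(rng.integers(0, 20, size=(n_samp, n_tips)),
                           index=[f"s{i}" for i in range(n_samp)], columns=taxa)
        tab.iloc[:, 0] += 1  # keep every sample non-empty
        wu = dv.weighted_unifrac(tab, tree, normalized=True)
        bc = dv.bray_curtis(tab)
        dmat = asm.patristic_matrix(tree)
        for i in range(n_samp):
            for j in range(i + 1, n_samp):
                xi, yj = dict(tab.iloc[i]), dict(tab.iloc[j])
                max_wu = max(max_wu, abs(wu[f"s{i}", f"s{j}"]
                                         - brute_weighted_unifrac(xi, yj, tree)))
                max_bc = max(max_bc, abs(bc[f"s{i}", f"s{j}"]
                                         - brute_bray_curtis(tab.iloc[i], tab.iloc[j])))
                max_bm = max(max_bm, abs(asm.beta_mntd(tab.iloc[i], tab.iloc[j], dmat)
                                         - brute_beta_mntd(xi, yj, dmat)))
    return {"unifrac_max_abs_err": max_wu, "beta_mntd_max_abs_err": max_bm,
            "bray_curtis_max_abs_err": max_bc, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# null-model calibration
# ---------------------------------------------------------------------------


def _neutral_table(n_samples: int, n_tips: int, taxa, richness: int,
                   depth: int, rng) -> pd.DataFrame:
    """Communities assembled by uniform random draws from the tip pool."""
    rows = []
    for _ in range(n_samples):
        chosen = rng.choice(n_tips, size=richness, replace=False)
        counts = np.zeros(n_tips, int)
        counts[chosen] = rng.multinomial(depth, np.ones(richness) / richness)
        counts[chosen[0]] += 1  # guarantee non-empty support
        rows.append(counts)
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(n_samples)], columns=taxa)


def null_model_calibration(
    n_samples: int = 20, n_tips: int = 100, n_null: int = 199,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4), richness: int = 30, depth: int = 1000,
) -> dict[str, float]:
    """Under neutral assembly, |betaNTI| < 2 and |RCbray| < 0.95 should hold
    for the vast majority of pairs."""
    frac_z, frac_rc = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        tree = sc.simulate_tree(n_tips, seed=seed)
        taxa = [t.name for t in tree.tips()]
        tab = _neutral_table(n_samples, n_tips, taxa, richness, depth, rng)
        z = asm.bnti(tab, tree, n_null=n_null, seed=seed)
        rc = asm.rc_bray(tab, n_null=n_null, seed=seed)
        iu = np.triu_indices(n_samples, 1)
        frac_z.append(float((np.abs(z.values[iu]) < 2.0).mean()))
        frac_rc.append(float((np.abs(rc.values[iu]) < 0.95).mean()))
    return {"bnti_frac_within_2": float(np.mean(frac_z)),
            "rcbray_frac_within_095": float(np.mean(frac_rc)),
            "n_pairs_per_seed": n_samples * (n_samples - 1) // 2}


def regime_recovery(
    seeds: tuple[int, ...] = (1, 2, 3), n_null: int = 199
) -> dict[str, dict[str, float]]:
    """For each regime preset: does the intended process dominate the
    within-site pair classification? Returns per-regime the fraction of
    seeds recovering the intended modal class and the mean modal fraction."""
    out = {}
    for regime in sc._REGIME_PRESETS:
        hits, modal_fracs = 0, []
        for seed in seeds:
            cfg = sc.regime_preset(regime, seed)
            counts, meta, tree, _, truth = sc.simulate_cohort(cfg)
            bio = meta[meta["group"] != "blank"]
            pairs = asm.assembly_pairs(counts.loc[bio.index], tree, bio,
                                       grouping=("site",), n_null=n_null, seed=seed)
            tally = Counter(pairs["label"])
            modal, count = tally.most_common(1)[0]
            hits += modal == regime
            modal_fracs.append(tally.get(regime, 0) / len(pairs))
        out[regime] = {"modal_recovery_rate": hits / len(seeds),
                       "mean_intended_fraction": float(np.mean(modal_fracs))}
    return out


# ---------------------------------------------------------------------------
# PERMANOVA calibration
# ---------------------------------------------------------------------------


def permanova_calibration(
    n_sims: int = 200, n_subjects: int = 8, n_sites: int = 3,
    n_perm: int = 199, alpha: float = 0.05, effect: float = 3.0, seed: int = 0,
) -> dict[str, float]:
    """Type-I error under a structureless repeated-measures design with
    subject strata, and power under a large additive site effect."""
    rng = np.random.default_rng(seed)
    n = n_subjects * n_sites
    sites = np.tile(np.arange(n_sites), n_subjects)
    subjects = np.repeat(np.arange(n_subjects), n_sites)
    rejections = {"null": 0, "effect": 0}
    for case, shift in (("null", 0.0), ("effect", effect)):
        for _ in range(n_sims):
            pts = rng.normal(size=(n, 3))
            pts[:, 0] += shift * sites
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            dm = DistanceMatrix(d, ids=[str(i) for i in range(n)])
            res = dv.permanova(dm, sites, strata=subjects, n_perm=n_perm,
                               seed=int(rng.integers(2**31)))
            rejections[case] += res.p_value <= alpha
    return {"type_i_error": rejections["null"] / n_sims,
            "power_large_effect": rejections["effect"] / n_sims,
            "n_sims": n_sims}


# ---------------------------------------------------------------------------
# individuality and recovery parameter recovery
# ---------------------------------------------------------------------------


def individuality_monotonicity(
    subject_sds: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> dict[str, float]:
    """Mean distance-to-centroid should grow with the generator's
    subject random-effect SD, per seed."""
    monotone = 0
    curves = []
    for seed in seeds:
        means = []
        for sd in subject_sds:
            cfg = sc.SimConfig(n_taxa_pool=120, depth_mean=2000.0, sites=("oropharynx",),
                               n_subjects_per_group={"NS": 10}, contaminant_fraction=0.0,
                               n_blanks=0, subject_sd=sd, seed=seed)
            counts, meta, tree, _, _ = sc.simulate_cohort(cfg)
            bio = meta[meta["group"] != "blank"]
            wu = dv.weighted_unifrac(counts.loc[bio.index], tree)
            scores, _ = dv.individuality(wu, bio)
            means.append(scores["score"].mean())
        curves.append(means)
        monotone += bool(np.all(np.diff(means) >= -1e-12))
    return {"monotone_seed_fraction": monotone / len(seeds),
            "mean_scores_by_sd": [float(np.mean(c)) for c in zip(*curves)]}


def recovery_monotonicity(
    ws: tuple[float, ...] = (0.0, 0.5, 1.0), seed: int = 1, depth: int = 3000,
) -> dict[str, float]:
    """FS communities built as (1-w) AS + w NS compositional mixtures should
    show similarity-to-NS increasing in w."""
    cfg = sc.SimConfig(n_taxa_pool=120, depth_mean=float(depth), sites=("oropharynx",),
                       n_subjects_per_group={"NS": 8, "AS": 8},
                       contaminant_fraction=0.0, n_blanks=0, seed=seed)
    counts, meta, tree, _, _ = sc.simulate_cohort(cfg)
    bio = meta[meta["group"] != "blank"]
    rel = counts.loc[bio.index].div(counts.loc[bio.index].sum(axis=1), axis=0)
    ns_ids = bio.index[bio["group"] == "NS"]
    as_ids = bio.index[bio["group"] == "AS"]
    ns_mean = rel.loc[ns_ids].mean(axis=0).values
    rng = np.random.default_rng(seed)
    rows, idx, meta_rows = [], [], []
    for sid in bio.index:
        rows.append(counts.loc[sid].values)
        idx.append(sid)
        meta_rows.append(bio.loc[sid, ["subject_id", "site", "group"]].tolist())
    for w in ws:
        for k, sid in enumerate(as_ids):
            p = (1.0 - w) * rel.loc[sid].values + w * ns_mean
            rows.append(rng.multinomial(depth, p / p.sum()))
            name = f"mix_w{w}_{k}"
            idx.append(name)
            meta_rows.append([f"mix_{k}", "oropharynx", f"w={w}"])
    tab = pd.DataFrame(rows, index=idx, columns=counts.columns)
    meta2 = pd.DataFrame(meta_rows, index=idx, columns=["subject_id", "site", "group"])
    bc = dv.bray_curtis(tab)
    traj, _ = dv.recovery_trajectory(bc, meta2, baseline_group="NS")
    means = [float(traj.loc[traj["group"] == f"w={w}", "similarity"].mean()) for w in ws]
    return {"mean_similarity_by_w": means,
            "monotone": bool(np.all(np.diff(means) > 0))}


# ---------------------------------------------------------------------------
# network oracles
# ---------------------------------------------------------------------------


def _partitions(collection):
    collection = list(collection)
    if len(collection) == 1:
        yield [collection]
        return
    first, rest = collection[0], collection[1:]
    for smaller in _partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def exhaustive_modularity(g: nx.Graph) -> float:
    """Best modularity over every partition of the nodes (<= 8 nodes)."""
    best = -np.inf
    for part in _partitions(list(g.nodes)):
        best = max(best, nx.community.modularity(g, [set(p) for p in part]))
    return float(best)


def modularity_vs_exhaustive(n_graphs: int = 20, seed: int = 0) -> dict[str, float]:
    """The package's modularity search against the exhaustive-partition
    optimum on small random graphs."""
    rng = np.random.default_rng(seed)
    ratios = []
    made = 0
    while made < n_graphs:
        n = int(rng.integers(5, 9))
        g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
        if g.number_of_edges() < 2:
            continue
        opt = exhaustive_modularity(g)
        if opt <= 1e-9:
            continue
        assign = nw.modules(g, seed=seed)
        comms: dict[int, set] = {}
        for node, m in assign.items():
            comms.setdefault(m, set()).add(node)
        found = nx.community.modularity(g, comms.values())
        ratios.append(found / opt)
        made += 1
    return {"min_ratio": float(np.min(ratios)), "mean_ratio": float(np.mean(ratios)),
            "n_graphs": n_graphs}


def planted_hub_detection(n_rep: int = 50, seed: int = 1000) -> dict[str, float]:
    """Two high-centrality hubs planted in a core-periphery correlation
    network; detection = exact recovery of the planted hub set."""
    hits = 0
    for rep in range(n_rep):
        rng = np.random.default_rng(seed + rep)
        n, n_sat = 40, 28
        shared = rng.standard_normal(n)
        cols = {}
        for h in ("hub1", "hub2"):
            cols[h] = 0.9 * shared + 0.3 * rng.standard_normal(n)
        for k in range(n_sat):
            cols[f"sat{k}"] = 0.45 * shared + 0.85 * rng.standard_normal(n)
        vals = pd.DataFrame({k: 1000.0 * np.exp(v) for k, v in cols.items()})
        g = nw.build_network(vals, r_threshold=0.3)
        hits += nw.detect_hubs(g, quantile=0.95) == {"hub1", "hub2"}
    return {"detection_rate": hits / n_rep, "n_rep": n_rep}


def network_fixture_checks(seed: int = 0) -> dict[str, float]:
    """Closed-form topology values on K5, P4, two disjoint K4 cliques, and
    complete-graph robustness."""
    def from_edges(edges, nodes=None):
        g = nx.Graph()
        if nodes:
            g.add_nodes_from(nodes)
        for a, b in edges:
            g.add_edge(a, b, r=1.0, sign=1, abs_r=1.0, dissim=1.0)
        return g

    k5 = from_edges(combinations(range(5), 2))
    rec_k5 = nw.topology(k5, seed=seed)
    p4 = from_edges([(0, 1), (1, 2), (2, 3)])
    rec_p4 = nw.topology(p4, seed=seed)
    two_k4 = from_edges(list(combinations(range(4), 2))
                        + list(combinations(range(4, 8), 2)))
    mod_assign = nw.modules(two_k4)
    comms = {}
    for node, m in mod_assign.items():
        comms.setdefault(m, set()).add(node)
    mod_two_k4 = nx.community.modularity(two_k4, comms.values())
    k10 = from_edges(combinations(range(10), 2))
    return {
        "k5_density": rec_k5.edge_density,
        "k5_clustering": rec_k5.clustering_coefficient,
        "k5_pep": rec_k5.pep,
        "p4_avg_path_length": rec_p4.avg_path_length,
        "two_k4_modularity": float(mod_two_k4),
        "two_k4_exhaustive_optimum": exhaustive_modularity(two_k4),
        "k10_robustness": nw.robustness(k10, removal_fraction=0.5, n_rep=50, seed=seed),
    }


# ---------------------------------------------------------------------------
# decontamination recovery and pipeline determinism
# ---------------------------------------------------------------------------


def contaminant_recovery(seeds: tuple[int, ...] = (1, 2, 3, 4, 5)) -> dict[str, float]:
    """Recall and false-removal rate of blank-based decontamination on
    cohorts with 30 planted contaminants (300-taxon pool, 10% contaminant)."""
    recalls, false_rates = [], []
    for seed in seeds:
        cfg = sc.SimConfig(n_taxa_pool=300, contaminant_fraction=0.1,
                           depth_mean=3000.0, seed=seed)
        counts, meta, _, _, truth = sc.simulate_cohort(cfg)
        blanks = list(meta.index[meta["group"] == "blank"])
        _, rep = iop.remove_contaminants(counts, blanks)
        removed = set(rep.removed_taxon_ids)
        planted = set(truth.contaminants)
        recalls.append(len(removed & planted) / len(planted))
        clean_taxa = set(counts.columns) - planted
        false_rates.append(len(removed - planted) / len(clean_taxa))
    return {"recall": float(np.mean(recalls)),
            "false_removal_rate": float(np.mean(false_rates)),
            "n_planted": 30, "n_seeds": len(seeds)}


def _tree_digest(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*.tsv")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def pipeline_determinism(seed: int = 1) -> dict[str, float]:
    """Two pipeline runs with identical config must produce byte-identical
    numeric outputs."""
    digests = []
    for run in range(2):
        out = Path(tempfile.mkdtemp(prefix=f"awr_det{run}_"))
        cfg = PipelineConfig(sim=desk_scale_sim(seed), n_null=131, n_perm=99,
                             out_dir=str(out))
        run_pipeline(cfg)
        digests.append(_tree_digest(out))
    return {"identical": float(digests[0] == digests[1])}


def threshold_grid_check() -> dict[str, float]:
    """Decision-plane audit of the classification and filtering thresholds:
    every grid point gets exactly one label, selection wins only strictly
    beyond |betaNTI| = 2, dispersal only strictly beyond |RCbray| = 0.95,
    and the prevalence boundaries are inclusive."""
    ok = True
    grid_b = [-3.0, -2.5, -2.0, -1.0, 0.0, 1.0, 2.0, 2.5, 3.0]
    grid_r = [-1.0, -0.99, -0.95, -0.5, 0.0, 0.5, 0.95, 0.99, 1.0]
    for b in grid_b:
        for r in grid_r:
            label = asm.classify_assembly(b, r)
            if b > 2.0:
                expect = "variable selection"
            elif b < -2.0:
                expect = "homogeneous selection"
            elif r > 0.95:
                expect = "dispersal limitation"
            elif r < -0.95:
                expect = "homogenizing dispersal"
            else:
                expect = "undominated drift"
            ok &= label == expect
            ok &= label in asm.PROCESS_LABELS
    from .core_venn import core_taxa
    prev = {"a": 0.8, "b": 0.799999, "c": 1.0, "d": 0.5}
    ok &= core_taxa(prev, 0.8).members == frozenset({"a", "c"})
    ok &= core_taxa(prev, 0.5).members == frozenset({"a", "b", "c", "d"})
    return {"all_boundaries_correct": float(ok),
            "n_grid_points": len(grid_b) * len(grid_r)}
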