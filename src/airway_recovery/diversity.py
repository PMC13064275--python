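"""Alpha/beta diversity, restricted-permutation PERMANOVA, individuality,
recovery trajectories, within-subject site distances, log-fold baselines.

Distance matrices are ``skbio.DistanceMatrix`` objects throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def observed_richness(counts) -> int:
    """Number of taxa with a positive count."""
    return int((np.asarray(counts, float) > 0).sum())


def pielou_evenness(counts) -> float:
    """Shannon entropy (natural log) over ln(richness); 1 for a single taxon.

    Errors on an all-zero sample.
    """
    x = np.asarray(counts, float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("evenness undefined for an all-zero sample")
    if x.size == 1:
        return 1.0
    p = x / x.sum()
    h = -(p * np.log(p)).sum()
    return float(h / np.log(x.size))


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity; a pair of all-zero samples is 0."""
    x = np.asarray(table, float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(table.index))


def _branch_table(tree: TreeNode, taxa: list[str]):
    """(lengths, tip-membership matrix) over all non-root branches.

    Row b of the membership matrix flags which of ``taxa`` descend from
    branch b. Taxa must all be tree tips.
    """
    tip_pos = {t: i for i, t in enumerate(taxa)}
    missing = [t for t in taxa if t not in {tip.name for tip in tree.tips()}]
    if missing:
        raise ValueError(f"table taxa missing from tree: {missing}")
    lengths, members = [], []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        vec = np.zeros(len(taxa), bool)
        if node.is_tip():
            if node.name in tip_pos:
                vec[tip_pos[node.name]] = True
        else:
            for child in node.children:
                vec |= below[id(child)]
        below[id(node)] = vec
        if node.parent is not None:
            lengths.append(node.length or 0.0)
            members.append(vec)
    return np.asarray(lengths, float), np.asarray(members, bool)


def weighted_unifrac(
    table: pd.DataFrame, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac over all sample pairs.

    Each branch contributes its length times the absolute difference of the
    two samples' abundance fractions descending through it; the normalized
    variant divides by the branch-length-weighted sum of the fractions.
    Tree tips absent from the table contribute zero.
    """
    taxa = list(table.columns)
    lengths, members = _branch_table(tree, taxa)
    x = np.asarray(table, float)
    totals = x.sum(axis=1, keepdims=True)
    frac = np.divide(x, totals, out=np.zeros_like(x), where=totals > 0)
    # per-branch descendant fraction, branches x samples
    A = members.astype(float) @ frac.T
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(A[:, i, None] - A[:, i + 1:])
        raw = lengths @ diff
        if normalized:
            den = lengths @ (A[:, i, None] + A[:, i + 1:])
            raw = np.divide(raw, den, out=np.zeros_like(raw), where=den > 0)
        d[i, i + 1:] = raw
        d[i + 1:, i] = raw
    return DistanceMatrix(d, ids=list(table.index))


# ---------------------------------------------------------------------------
# PERMANOVA with restricted permutations
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_F: float
    r2: float
    p_value: float
    n_permutations: int
    strata: str | None


def _pseudo_f(d2: np.ndarray, labels: np.ndarray):
    """Anderson partition of squared distances into between/within components."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    a = np.unique(labels).size
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def _stratified_permutation(labels: np.ndarray, groups: list[np.ndarray],
                            rng: np.random.Generator) -> np.ndarray:
    """Shuffle labels independently within each stratum's index group."""
    out = labels.copy()
    for g in groups:
        out[g] = labels[g[rng.permutation(g.size)]]
    return out


def permanova(
    dist: DistanceMatrix,
    factor,
    strata=None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational MANOVA; with ``strata``, factor labels are permuted only
    within each stratum (repeated-measures designs: strata = subject).

    The p-value uses the add-one convention
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    labels = np.asarray(factor)
    if labels.size != len(dist.ids):
        raise ValueError("factor labels not aligned with distance matrix")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 factor levels")
    d2 = dist.data**2
    strata_arr = None
    if strata is not None:
        strata_arr = np.asarray(strata)
        groups = [np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)]
        if all(np.unique(labels[g]).size < 2 for g in groups):
            raise ValueError("factor constant within every stratum: no admissible permutations")
    f_obs, r2 = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if strata_arr is None:
            perm_labels = labels[rng.permutation(labels.size)]
        else:
            perm_labels = _stratified_permutation(labels, groups, rng)
        f_perm, _ = _pseudo_f(d2, perm_labels)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(
        pseudo_F=float(f_obs), r2=float(r2), p_value=float(p),
        n_permutations=n_perm, strata=None if strata is None else "strata",
    )


# ---------------------------------------------------------------------------
# individuality (distance to group centroid in PCoA space)
# ---------------------------------------------------------------------------


def _centroid_distances(d: np.ndarray) -> np.ndarray:
    """Distances of each point to the group centroid, via the Gower-centered
    eigendecomposition; negative-eigenvalue axes contribute subtractively to
    the squared distance, which is floored at 0 (the betadisper correction)."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    coords = vecs * np.sqrt(np.abs(vals))
    cent = coords.mean(axis=0)
    sq = (coords - cent) ** 2
    signed = np.where(vals >= 0, 1.0, -1.0)
    out = np.maximum((sq * signed).sum(axis=1), 0.0)
    return np.sqrt(out)


def individuality(
    dist: DistanceMatrix, meta: pd.DataFrame, grouping: tuple[str, ...] = ("site", "group")
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample distance to its (site x group) centroid; higher values mean
    more subject-specific community structure.

    Returns a tidy frame (sample_id, grouping columns, score) and a list of
    warnings for skipped singleton groups.
    """
    meta = meta.loc[list(dist.ids)]
    warnings: list[str] = []
    records = []
    for keys, sub in meta.groupby(list(grouping), sort=True):
        if len(sub) < 2:
            warnings.append(f"group {keys!r} skipped: fewer than 2 samples")
            continue
        subdm = dist.filter(list(sub.index))
        scores = _centroid_distances(subdm.data)
        for sid, sc in zip(subdm.ids, scores):
            records.append({"sample_id": sid, **dict(zip(grouping, np.atleast_1d(keys))),
                            "score": float(sc)})
    return pd.DataFrame(records), warnings


# ---------------------------------------------------------------------------
# recovery trajectories and within-subject site distances
# ---------------------------------------------------------------------------


def recovery_trajectory(
    dist: DistanceMatrix,
    meta: pd.DataFrame,
    baseline_group: str = "NS",
    stat: str = "median",
) -> tuple[pd.DataFrame, list[str]]:
    """Similarity of each non-baseline sample to the baseline (never-smoker)
    community at the same site: ``1 - median distance to baseline samples``.

    Returns a tidy frame ordered AS -> FS6w -> FS1y within site, plus
    warnings for sites lacking baseline samples.
    """
    meta = meta.loc[list(dist.ids)]
    agg = {"median": np.median, "mean": np.mean}[stat]
    warnings: list[str] = []
    records = []
    order = {g: i for i, g in enumerate(["AS", "FS6w", "FS1y"])}
    for site, sub in meta.groupby("site", sort=True):
        base_ids = sub.index[sub["group"] == baseline_group]
        if base_ids.empty:
            warnings.append(f"site {site!r} skipped: no {baseline_group} baseline samples")
            continue
        others = sub.index[sub["group"] != baseline_group]
        for sid in others:
            dvals = [dist[sid, b] for b in base_ids if b != sid]
            if not dvals:
                continue
            sim = float(np.clip(1.0 - agg(dvals), 0.0, 1.0))
            records.append({
                "sample_id": sid, "site": site, "group": meta.loc[sid, "group"],
                "similarity": sim,
            })
    frame = pd.DataFrame(records)
    if not frame.empty:
        frame = frame.sort_values(
            ["site", "group"], key=lambda s: s.map(order).fillna(99) if s.name == "group" else s
        ).reset_index(drop=True)
    return frame, warnings


def site_pair_distance(
    dist: DistanceMatrix, meta: pd.DataFrame, site_a: str, site_b: str
) -> tuple[pd.DataFrame, dict]:
    """Within-subject distance between two body sites at matched timepoints.

    Returns a tidy frame (subject_id, timepoint, group, distance) and a
    bookkeeping dict counting subject-timepoints lacking one of the sites.
    """
    meta = meta.loc[list(dist.ids)]
    records, excluded = [], 0
    for (subject, tp), sub in meta.groupby(["subject_id", "timepoint"], sort=True):
        a = sub.index[sub["site"] == site_a]
        b = sub.index[sub["site"] == site_b]
        if len(a) != 1 or len(b) != 1:
            excluded += 1
            continue
        records.append({
            "subject_id": subject, "timepoint": tp,
            "group": sub.loc[a[0], "group"],
            "distance": float(dist[a[0], b[0]]),
        })
    frame = pd.DataFrame(records)
    info = {"excluded_subject_timepoints": excluded, "n_pairs": len(records)}
    return frame, info


def logfold_to_baseline(
    genus_values: pd.DataFrame,
    meta: pd.DataFrame,
    baseline_group: str = "NS",
    pseudo: float | None = None,
) -> pd.DataFrame:
    """log2 fold change of each genus versus the never-smoker site baseline.

    ``log2((x + pseudo) / (baseline_mean + pseudo))`` with the baseline mean
    taken over baseline samples at the same site; pseudo defaults to half
    the smallest positive value in the table.
    """
    meta = meta.loc[genus_values.index]
    if pseudo is None:
        pos = genus_values.values[genus_values.values > 0]
        pseudo = 0.5 * float(pos.min()) if pos.size else 0.5
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    out = []
    for site, sub in meta.groupby("site", sort=True):
        base_ids = sub.index[sub["group"] == baseline_group]
        if base_ids.empty:
            continue
        base_mean = genus_values.loc[base_ids].mean(axis=0)
        others = sub.index[sub["group"] != baseline_group]
        lf = np.log2(genus_values.loc[others].add(pseudo).div(base_mean + pseudo, axis=1))
        out.append(lf)
    return pd.concat(out) if out else pd.DataFrame(columns=genus_values.columns)
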