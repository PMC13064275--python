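"""Reading/writing count tables, blank-based decontamination, CSS, genus rollup.

Count tables are pandas DataFrames oriented samples x taxa with unique,
aligned identifiers; the on-disk format is a QIIME-style TSV feature table
(taxa as rows, first column the ASV identifier), auto-transposed on read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.index.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    if table.columns.has_duplicates:
        raise ValueError("duplicate taxon identifiers")
    if (table.values < 0).any():
        r, c = np.argwhere(table.values < 0)[0]
        raise ValueError(f"negative count at row {table.index[r]!r}, column {table.columns[c]!r}")
    return table


@dataclass
class NormalizedTable:
    """CSS-normalized abundances with the per-sample scaling factors used."""

    values: pd.DataFrame  # samples x taxa, non-negative reals
    scaling_factors: pd.Series  # per sample, strictly positive
    quantile_l: float


@dataclass
class ContaminantReport:
    removed_taxon_ids: list[str]
    rule: str
    evidence: pd.DataFrame  # per taxon: blank prevalence, mean rel. abundance in blanks vs samples


def read_feature_table(path) -> pd.DataFrame:
    """Read a TSV count table, auto-detecting orientation, as samples x taxa.

    A table whose first (index) column holds the taxon identifiers
    (QIIME feature-table orientation) is transposed; one whose column
    header holds them is kept. Detection keys on which axis carries
    ``ASV``-style labels, falling back to the taxa-as-rows convention.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()][0]
        raise ValueError(f"ragged or missing cells in column {bad!r}")
    try:
        num = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in table: {exc}") from exc
    if (num.values < 0).any():
        r, c = np.argwhere(num.values < 0)[0]
        raise ValueError(f"negative count at row {num.index[r]!r}, column {num.columns[c]!r}")
    if not np.allclose(num.values, np.round(num.values)):
        raise ValueError("non-integer counts in feature table")
    num = num.round().astype(int)

    def _looks_taxonomic(labels) -> bool:
        return all(str(x).upper().startswith(("ASV", "OTU", "SV_")) for x in labels)

    taxa_as_rows = _looks_taxonomic(num.index) or not _looks_taxonomic(num.columns)
    table = num.T if taxa_as_rows else num
    table.index.name = "sample_id"
    table.columns.name = None
    return validate_count_table(table)


def write_feature_table(table: pd.DataFrame, path) -> None:
    ft = table.T
    ft.index.name = "ASV_ID"
    ft.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={"subject_id": str})
    for col in ("subject_id", "site", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    return meta


def read_taxonomy(path) -> dict[str, str]:
    tax = pd.read_csv(path, sep="\t", index_col=0)
    return tax.iloc[:, 0].astype(str).to_dict()


def remove_contaminants(
    table: pd.DataFrame,
    blank_ids: list[str],
    blank_prevalence_min: float = 0.5,
    ratio_min: float = 1.0,
) -> tuple[pd.DataFrame, ContaminantReport]:
    """Drop taxa that look like reagent contaminants, judged against blanks.

    A taxon is removed iff it is present (count > 0) in at least
    ``blank_prevalence_min`` of the blank samples AND its mean relative
    abundance across blanks is at least ``ratio_min`` times its mean
    relative abundance across biological samples. Blanks are dropped from
    the returned table.
    """
    blank_ids = list(blank_ids)
    if not blank_ids:
        raise ValueError("at least one blank sample is required")
    missing = set(blank_ids) - set(table.index)
    if missing:
        raise ValueError(f"blank ids not in table: {sorted(missing)}")
    bio_ids = [s for s in table.index if s not in set(blank_ids)]
    if not bio_ids:
        raise ValueError("at least one biological sample is required")

    blanks = table.loc[blank_ids]
    bio = table.loc[bio_ids]

    def _rel(df: pd.DataFrame) -> pd.DataFrame:
        totals = df.sum(axis=1).replace(0, 1)
        return df.div(totals, axis=0)

    prev_blank = (blanks > 0).mean(axis=0)
    mean_rel_blank = _rel(blanks).mean(axis=0)
    mean_rel_bio = _rel(bio).mean(axis=0)
    removed_mask = (prev_blank >= blank_prevalence_min) & (
        mean_rel_blank >= ratio_min * mean_rel_bio
    )
    removed = list(table.columns[removed_mask])
    evidence = pd.DataFrame({
        "blank_prevalence": prev_blank,
        "mean_rel_abundance_blanks": mean_rel_blank,
        "mean_rel_abundance_samples": mean_rel_bio,
        "removed": removed_mask,
    })
    report = ContaminantReport(
        removed_taxon_ids=removed,
        rule=(f"blank_prevalence>={blank_prevalence_min} and "
              f"mean_rel_blank>={ratio_min}x mean_rel_samples"),
        evidence=evidence,
    )
    cleaned = bio.drop(columns=removed)
    return cleaned, report


def css_normalize(table: pd.DataFrame, quantile_l: float = 0.5) -> NormalizedTable:
    """Cumulative-sum scaling: divide by each sample's cumulative count up to
    its ``quantile_l``-th quantile of positive counts, times 1000.

    The quantile is computed over positive counts only with linear (type-7)
    interpolation; zero counts map to zero.
    """
    if not 0.0 < quantile_l < 1.0:
        raise ValueError("quantile_l must lie in (0, 1)")
    validate_count_table(table)
    factors = {}
    for sample, row in table.iterrows():
        pos = row.values[row.values > 0]
        if pos.size == 0:
            raise ValueError(f"sample {sample!r} has zero total count")
        q = np.quantile(pos, quantile_l)
        factors[sample] = float(row.values[row.values <= q].sum())
    scaling = pd.Series(factors, name="css_scaling_factor").reindex(table.index)
    values = table.div(scaling, axis=0) * 1000.0
    return NormalizedTable(values=values, scaling_factors=scaling, quantile_l=quantile_l)


def aggregate_genus(table: pd.DataFrame, taxonomy: dict[str, str]) -> pd.DataFrame:
    """Sum ASV counts into genera; unlabelled ASVs fall into ``unassigned``.

    Per-sample totals are conserved exactly; genus columns are sorted
    lexicographically.
    """
    genera = [taxonomy.get(t, "unassigned") or "unassigned" for t in table.columns]
    agg = table.T.groupby(pd.Index(genera, name="genus")).sum().T
    return agg.reindex(sorted(agg.columns), axis=1)


def prevalence_by_subject(
    table: pd.DataFrame, meta: pd.DataFrame, group: str, site: str
) -> pd.Series:
    """Fraction of a stratum's *subjects* carrying each taxon.

    A subject counts as positive for a taxon if any of its samples in the
    group x site stratum has a non-zero count.
    """
    sel = meta.loc[table.index.intersection(meta.index)]
    stratum = sel[(sel["group"] == group) & (sel["site"] == site)]
    if stratum.empty:
        raise ValueError(f"empty stratum group={group!r} site={site!r}")
    sub = table.loc[stratum.index] > 0
    by_subject = sub.groupby(stratum["subject_id"]).any()
    return by_subject.mean(axis=0)
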