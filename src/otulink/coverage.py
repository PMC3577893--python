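"""Temporal coverage of OTU diversity and host associations.

Given a clustering of all database sequences and their deposition metadata,
these functions tabulate how the number of known clusters (species proxies),
the sequences per cluster, and the cluster/host association counts develop
with the year of deposition — and how sensitive those trends are to the
clustering parameters.

The default mode clusters the full dataset once and filters members by
deposition year (stable cluster identities over time); re-clustering each
cumulative subset is available for comparison.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterParams, Partition, f_linkage_cluster
from .distances import DistanceMatrix

__all__ = ["coverage_series", "sensitivity_grid"]

SERIES_COLUMNS = [
    "cumulative_clusters",
    "mean_sequences_per_cluster",
    "mean_host_genera_per_cluster",
    "mean_host_species_per_cluster",
    "mean_clusters_per_host_genus",
    "mean_clusters_per_host_species",
]


def coverage_series(partition: Partition, meta: pd.DataFrame, years: Sequence[float]) -> pd.DataFrame:
    """Cumulative diversity and host-association statistics per evaluation year.

    Parameters
    ----------
    partition : Partition
        Clustering of the full dataset.
    meta : DataFrame
        Columns ``accession``, ``host_genus``, ``host_species``,
        ``deposition_year``.  Elements without a deposition year are excluded
        (with a warning); absent host annotations simply contribute nothing
        to the host statistics, which is why the per-cluster host means can
        fall below 1.
    years : sequence of evaluation years

    Returns
    -------
    DataFrame indexed by year with one column per statistic:
    cumulative cluster count, mean sequences per cluster, mean distinct host
    genera and species per cluster, and mean clusters per host genus and
    species.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year grid")
    df = meta.copy()
    df = df[df["accession"].isin(partition.elements)]
    missing_year = df["deposition_year"].isna()
    if missing_year.any():
        warnings.warn(f"{int(missing_year.sum())} sequences without deposition year excluded")
        df = df[~missing_year]
    df = df.assign(cluster=df["accession"].map(partition.assignment))
    all_clusters = sorted(set(partition.assignment.values()))
    rows = []
    for y in years:
        sub = df[df["deposition_year"] <= y]
        present = sub.groupby("cluster").size()
        k = int((present > 0).sum())
        n_seq = int(len(sub))
        row = {"year": y, "cumulative_clusters": k}
        row["mean_sequences_per_cluster"] = n_seq / k if k else 0.0
        for col, out in (("host_genus", "mean_host_genera_per_cluster"), ("host_species", "mean_host_species_per_cluster")):
            if k:
                per_cluster = sub.groupby("cluster")[col].nunique(dropna=True)
                row[out] = float(per_cluster.reindex(present.index, fill_value=0).mean())
            else:
                row[out] = 0.0
        for col, out in (("host_genus", "mean_clusters_per_host_genus"), ("host_species", "mean_clusters_per_host_species")):
            known = sub.dropna(subset=[col])
            if known.empty:
                row[out] = 0.0
            else:
                row[out] = float(known.groupby(col)["cluster"].nunique().mean())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("year")
    return out[SERIES_COLUMNS]


def sensitivity_grid(
    D: DistanceMatrix,
    meta: pd.DataFrame,
    params_list: Sequence[ClusterParams],
    years: Sequence[float],
    recluster_per_year: bool = False,
) -> pd.DataFrame:
    """Coverage series for every clustering-parameter combination.

    Returns a long-format frame with columns ``F``, ``t``, ``year``,
    ``statistic``, ``value`` — ready for trend plots with one curve per
    parameter combination.  With ``recluster_per_year`` each cumulative
    year-subset is clustered afresh instead of filtering one full clustering.
    """
    if not params_list:
        raise ValueError("params_list must be non-empty")
    frames = []
    for params in params_list:
        if recluster_per_year:
            series = _reclustered_series(D, meta, params, years)
        else:
            part = f_linkage_cluster(D, params)
            series = coverage_series(part, meta, years)
        long = series.reset_index().melt(id_vars="year", var_name="statistic", value_name="value")
        long.insert(0, "t", params.t)
        long.insert(0, "F", params.F)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def _reclustered_series(D: DistanceMatrix, meta: pd.DataFrame, params: ClusterParams, years: Sequence[float]) -> pd.DataFrame:
    meta_idx = meta.set_index("accession")["deposition_year"]
    rows = []
    for y in list(years):
        keep = [i for i in D.ids if i in meta_idx.index and pd.notna(meta_idx[i]) and meta_idx[i] <= y]
        if len(keep) < 2:
            row = dict.fromkeys(SERIES_COLUMNS, 0.0)
            row["cumulative_clusters"] = len(keep)
            row["mean_sequences_per_cluster"] = float(len(keep))
            row["year"] = y
            rows.append(row)
            continue
        part = f_linkage_cluster(D.submatrix(keep), params)
        series = coverage_series(part, meta[meta["accession"].isin(keep)], [y])
        row = series.iloc[0].to_dict()
        row["year"] = y
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")[SERIES_COLUMNS]
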