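"""Summary statistics over integrated-map tables.

Ships the published common-carp integrated-map summaries as package data:
the per-linkage-group table (marker counts, genetic lengths, anchored
physical Mb) and the duplicated-marker table (each primer pair's two mapped
loci and the orthologous zebrafish chromosome).  The statistics functions
below recompute the derived quantities — mean LG length, average marker
spacing, mean anchored length per LG, mean anchored contig length — from
such per-LG rows, whether published or produced by this pipeline.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_published_lg_summary",
    "load_published_duplicated_markers",
    "lg_summary_stats",
    "duplicated_marker_pairs_from_table",
]


def _data_path(name: str):
    return resources.files("carpmap").joinpath("data", name)


def load_published_lg_summary() -> pd.DataFrame:
    """Per-LG marker counts, genetic length (cM) and anchored physical
    length (Mb) of the published common-carp integrated map (50 LGs)."""
    with resources.as_file(_data_path("carp_lg_summary.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_published_duplicated_markers() -> pd.DataFrame:
    """The published duplicated-marker loci: one row per mapped locus with
    its LG and the orthologous reference chromosome."""
    with resources.as_file(_data_path("carp_duplicated_markers.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def lg_summary_stats(df: pd.DataFrame) -> dict[str, float]:
    """Derived statistics from per-LG rows.

    Expects columns ``n_markers``, ``length_cm`` and optionally
    ``anchored_mb``.  Average spacing per LG is length / (n - 1); means are
    totals over the number of LGs.  Values are rounded the way integrated-map
    reports print them (cM and spacing to 2-3 decimals, Mb to 2).
    """
    n_lgs = len(df)
    total_markers = int(df["n_markers"].sum())
    total_cm = float(df["length_cm"].sum())
    out = {
        "n_lgs": n_lgs,
        "total_markers": total_markers,
        "total_length_cm": round(total_cm, 3),
        "mean_lg_length_cm": round(total_cm / n_lgs, 2),
    }
    if "anchored_mb" in df:
        total_mb = float(df["anchored_mb"].sum())
        out["total_anchored_mb"] = round(total_mb, 3)
        out["mean_anchored_mb_per_lg"] = round(total_mb / n_lgs, 2)
    return out


def lg_average_spacing(df: pd.DataFrame) -> pd.Series:
    """Average adjacent-marker spacing per LG row: length_cm / (n_markers-1),
    rounded to 3 decimals."""
    spacing = df["length_cm"] / (df["n_markers"] - 1)
    return spacing.round(3)


def duplicated_marker_pairs_from_table(
    df: pd.DataFrame,
) -> tuple[list[tuple[str, str, str]], dict[str, str]]:
    """Turn a long duplicated-locus table (marker_id with -1/-2 suffix,
    lg_id, orthologous_chromosome) into (base_id, lg_a, lg_b) pairs plus an
    LG -> chromosome homology mapping induced by the table."""
    loci: dict[str, dict[str, str]] = {}
    homology: dict[str, str] = {}
    for row in df.itertuples():
        base, suffix = row.marker_id[:-2], row.marker_id[-1]
        loci.setdefault(base, {})[suffix] = row.lg_id
        chrom = getattr(row, "orthologous_chromosome", None)
        if isinstance(chrom, str):
            homology.setdefault(row.lg_id, chrom)
    pairs = [
        (base, loci[base]["1"], loci[base]["2"])
        for base in sorted(loci)
        if set(loci[base]) == {"1", "2"}
    ]
    return pairs, homology
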