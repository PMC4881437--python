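"""Integrate the recurrence and survival CNA maps, map regions to genes,
and exclude genes whose aberrations overlap copy-number variants common in
healthy genomes (which are unlikely to be somatic drivers).

All coordinates are 0-based half-open; overlap arithmetic is exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REGION_COLUMNS = ["chrom", "start", "end", "direction", "provenance", "p_stac", "p_spps"]


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def intersect_maps(stac_regions: pd.DataFrame, spps_regions: pd.DataFrame) -> pd.DataFrame:
    """Base-pair intersection of same-direction regions from the two maps.

    The output carries provenance 'both' and the p-values from each side.
    Commutative and idempotent.
    """
    rows = []
    for _, a in stac_regions.iterrows():
        for _, b in spps_regions.iterrows():
            if a["chrom"] != b["chrom"] or a["direction"] != b["direction"]:
                continue
            s = max(int(a["start"]), int(b["start"]))
            e = min(int(a["end"]), int(b["end"]))
            if s < e:
                rows.append(
                    {
                        "chrom": a["chrom"],
                        "start": s,
                        "end": e,
                        "direction": a["direction"],
                        "provenance": "both",
                        "p_stac": a.get("p_stac", np.nan),
                        "p_spps": b.get("p_spps", np.nan),
                    }
                )
    df = pd.DataFrame(rows, columns=REGION_COLUMNS)
    return df.drop_duplicates(subset=["chrom", "start", "end", "direction"]).reset_index(
        drop=True
    )


def map_genes(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map each gene onto overlapping regions (>= 1 bp overlap).

    Returns one row per (gene, region) pair with the region's direction; a
    gene hitting both a gain and a loss region is mapped to both and flagged
    ambiguous.
    """
    rows = []
    for _, g in genes.iterrows():
        for ri, r in regions.iterrows():
            if g["chrom"] != r["chrom"]:
                continue
            if int(g["start"]) < int(r["end"]) and int(g["end"]) > int(r["start"]):
                rows.append(
                    {
                        "symbol": g["symbol"],
                        "chrom": g["chrom"],
                        "gene_start": int(g["start"]),
                        "gene_end": int(g["end"]),
                        "region_index": ri,
                        "region_start": int(r["start"]),
                        "region_end": int(r["end"]),
                        "direction": r["direction"],
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "symbol", "chrom", "gene_start", "gene_end",
            "region_index", "region_start", "region_end", "direction",
        ],
    )
    if df.empty:
        df["ambiguous"] = pd.Series(dtype=bool)
        return df
    ndir = df.groupby("symbol")["direction"].transform("nunique")
    df["ambiguous"] = ndir > 1
    return df


def overlap_fraction(region, normal_cnvs: pd.DataFrame) -> float:
    """Fraction of the region's length covered by the union of the normal
    catalog's intervals (union first, so split catalog entries never double
    count)."""
    s0, e0 = int(region["start"]), int(region["end"])
    sub = normal_cnvs[
        (normal_cnvs["chrom"] == region["chrom"])
        & (normal_cnvs["start"] < e0)
        & (normal_cnvs["end"] > s0)
    ]
    ivs = _merge_intervals(
        [(max(int(s), s0), min(int(e), e0)) for s, e in zip(sub["start"], sub["end"])]
    )
    return sum(e - s for s, e in ivs) / (e0 - s0)


def filter_candidates(
    mapped: pd.DataFrame,
    regions: pd.DataFrame,
    normal_cnvs: pd.DataFrame,
    threshold: float = 0.05,
    whitelist: tuple[str, ...] = (),
    directions: tuple[str, ...] = ("gain", "loss"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove mapped genes whose CNA region overlaps the normal catalog by
    >= threshold (strictly below the threshold is retained), unless the gene
    is whitelisted. Gene-body overlap is also reported for the candidate
    table. Returns (kept, removal_log)."""
    if mapped.empty:
        empty = mapped.assign(region_overlap=pd.Series(dtype=float),
                              gene_overlap=pd.Series(dtype=float))
        return empty, pd.DataFrame(columns=["symbol", "overlap", "decision"])
    region_ov = {
        ri: overlap_fraction(regions.loc[ri], normal_cnvs)
        for ri in mapped["region_index"].unique()
    }
    out = mapped.copy()
    out["region_overlap"] = out["region_index"].map(region_ov)
    out["gene_overlap"] = [
        overlap_fraction(
            {"chrom": r["chrom"], "start": r["gene_start"], "end": r["gene_end"]},
            normal_cnvs,
        )
        for _, r in out.iterrows()
    ]
    removable = (
        (out["region_overlap"] >= threshold)
        & out["direction"].isin(directions)
        & ~out["symbol"].isin(whitelist)
    )
    log = pd.DataFrame(
        {
            "symbol": out["symbol"],
            "overlap": out["region_overlap"],
            "decision": np.where(
                removable,
                "removed",
                np.where(out["symbol"].isin(whitelist), "whitelisted", "kept"),
            ),
        }
    )
    return out[~removable].reset_index(drop=True), log


def read_bed(path, names=("chrom", "start", "end", "symbol")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]] + [
        f"col{i}" for i in range(len(names), df.shape[1])
    ]
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: tuple[str, ...] = ()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", index=False, header=False)
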