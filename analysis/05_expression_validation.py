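"""Validate candidate genes at the expression level.

Assembles the batch-standardized meta-cohort, fits univariate Cox OS/DFS
models on each candidate's standardized expression, applies the
direction-consistency and stringent (p < 0.005) rules, and runs the
joint-underexpression combination analysis on the top deleted genes,
writing Kaplan-Meier coordinates for the combination groups.
"""

from pathlib import Path

import pandas as pd

from crcmet import expression as xp

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = BASE / "expression"
    out.mkdir(parents=True, exist_ok=True)
    expr = pd.read_csv(BASE / "synthetic" / "expression.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(BASE / "synthetic" / "expression_meta.tsv", sep="\t")
    candidates = pd.read_csv(BASE / "genes" / "candidates.tsv", sep="\t")

    datasets = [
        (expr[meta.loc[meta["dataset"] == d, "sample_id"]],
         pd.Series(d, index=meta.loc[meta["dataset"] == d, "sample_id"]))
        for d in meta["dataset"].unique()
    ]
    std, _ = xp.assemble_meta_cohort(datasets)
    n_tumor = (meta["tissue"] == "tumor").sum()
    n_normal = (meta["tissue"] == "normal").sum()
    print(f"meta-cohort: {std.shape[0]} genes x {std.shape[1]} samples "
          f"({n_tumor} tumors, {n_normal} normals), per-batch standardized")

    screened = xp.screen_genes(candidates, std, meta)
    screened.to_csv(out / "screened.tsv", sep="\t", index=False, float_format="%.6g")
    primary = screened[screened["primary_pass"] == True]  # noqa: E712
    print(f"primary screen (Cox p < 0.05, direction-consistent sign): "
          f"{len(primary)}/{len(screened)} genes")

    stringent = xp.stringent_filter(primary.dropna(subset=["cox_os_p", "cox_dfs_p"]))
    stringent.to_csv(out / "stringent.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"stringent filter (min OS/DFS p < 0.005): {len(stringent)} genes: "
          f"{stringent['symbol'].tolist()}")

    loss_genes = stringent.loc[stringent["direction"] == "loss", "symbol"].tolist()
    if len(loss_genes) >= 2:
        combo = xp.combo_survival(loss_genes[:2], std, meta, endpoint="dfs")
        combo["km_joint_q1"].to_csv(out / "km_combo_joint_q1.tsv", sep="\t", index=False)
        combo["km_rest"].to_csv(out / "km_combo_rest.tsv", sep="\t", index=False)
        singles = [
            xp.combo_survival([g], std, meta, endpoint="dfs")["logrank_p"]
            for g in loss_genes[:2]
        ]
        print(f"combination {loss_genes[:2]}: joint-Q1 n={combo['n_joint_q1']}, "
              f"log-rank p={combo['logrank_p']:.3g} "
              f"(single-gene p: {', '.join(f'{p:.3g}' for p in singles)})")
    else:
        print("fewer than two stringent deleted genes; combination analysis skipped")


if __name__ == "__main__":
    main()
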