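"""End-to-end orchestration of the metastasis-gene nomination funnel.

Stages: sample QC (DLRS) -> segmentation and gain/loss calling -> per-arm
binarization -> permutation recurrence test (per arm and direction) ->
survival-predictive selection (SPPS) -> intersection of the two CNA maps ->
gene mapping -> normal-CNV exclusion -> expression screening (Cox OS/DFS,
direction consistency, stringent cut) -> EMT scoring -> combination
analysis -> funnel report. Each stage writes its artifact plus a manifest
(parameters, seed, output hashes) so any stage can be re-run and verified
in isolation.

One global seed fans out to per-stage seeds by fixed offsets so stages are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna, emt as emt_mod, expression as xp, genemap, simulate, stac, survival
from .fixtures import load_candidate_table

log = logging.getLogger(__name__)

_STAGE_SEED_STRIDE = 10_007  # stage k uses (seed + k * stride) % 2**31


def stage_seed(seed: int, stage_index: int) -> int:
    return (seed + stage_index * _STAGE_SEED_STRIDE) % (2**31)


@dataclass
class PipelineConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    bin_size: int = 1_000_000
    n_perm: int = 999
    freq_min: float = 0.35
    alpha_stac: float = 0.05
    min_cover: float = 0.5
    alpha_spps: float = 0.05
    spps_freq_min: float = 0.10  # cohort-wide frequency floor for SPPS candidates
    overlap_threshold: float = 0.05
    whitelist: tuple[str, ...] = ()
    screen_alpha: float = 0.05
    stringent_alpha: float = 0.005
    extreme_fraction: float = 0.25
    roc_min: float = 0.85
    emt_n_perm: int = 1000
    dlrs_threshold: float = cna.DLRS_QC_THRESHOLD
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("freq_min", 0, 1), ("alpha_stac", 0, 1), ("min_cover", 0, 1),
            ("alpha_spps", 0, 1), ("overlap_threshold", 0, 1),
            ("screen_alpha", 0, 1), ("stringent_alpha", 0, 1),
            ("extreme_fraction", 0, 0.5), ("roc_min", 0.5, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns the report bundle."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    funnel: list[tuple[str, str, int]] = []
    manifest: dict = {"seed": config.seed, "stages": {}}

    def _record(stage: str, rule: str, count: int, artifacts: dict[str, pd.DataFrame] = ()):
        funnel.append((stage, rule, count))
        entry = {"rule": rule, "count": count, "seed": stage_seed(config.seed, len(funnel))}
        if outdir and artifacts:
            hashes = {}
            for name, df in artifacts.items():
                path = outdir / name
                df.to_csv(path, sep="\t", index=False, float_format="%.6g")
                hashes[name] = _sha256(path)
            entry["outputs"] = hashes
        manifest["stages"][stage] = entry

    # --- simulate ---------------------------------------------------------
    sim = dataclasses.replace(config.sim, seed=stage_seed(config.seed, 0))
    profiles, clinical, truth = simulate.simulate_cohort(sim)
    expr_raw, meta = simulate.simulate_expression(sim, truth)
    genes = simulate.make_gene_annotation(sim)
    catalog = simulate.make_normal_cnv_catalog(sim)
    curated = simulate.make_curated_gene_sets(sim)
    _record("simulate", "synthetic cohort", len(profiles), {"clinical.tsv": clinical})

    # --- qc ---------------------------------------------------------------
    dlrs = {p.sample_id: cna.compute_dlrs(p) for p in profiles}
    eligible = [p for p in profiles if dlrs[p.sample_id] < config.dlrs_threshold]
    qc_table = pd.DataFrame(
        {"sample_id": list(dlrs), "dlrs": list(dlrs.values()),
         "pass": [v < config.dlrs_threshold for v in dlrs.values()]}
    )
    _record("qc", f"DLRS < {config.dlrs_threshold}", len(eligible), {"qc.tsv": qc_table})

    # local-recurrence cases are excluded from the metastasis contrast
    analysis_clin = clinical[clinical["group"] != "local_recurrence"]
    analysis_clin = analysis_clin[analysis_clin["sample_id"].isin(
        [p.sample_id for p in eligible])].reset_index(drop=True)
    analysis_profiles = [p for p in eligible
                         if p.sample_id in set(analysis_clin["sample_id"])]
    _record("exclude_local_recurrence", "metastasis analysis set",
            len(analysis_profiles))

    # --- segment ----------------------------------------------------------
    per_sample = [cna.segment_profile(p) for p in analysis_profiles]
    non_empty = [df for df in per_sample if not df.empty]
    calls = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty else pd.DataFrame(columns=cna.CALL_COLUMNS)
    )
    calls = cna.assign_arms(calls, sim.arm_table)
    _record("segment", "binary segmentation, |mean log2| >= 0.25",
            len(calls), {"calls.tsv": calls})

    # --- stac -------------------------------------------------------------
    # The recurrence map is built within the metastatic group: the question
    # is which aberrations stack in metastatic tumors beyond chance, with
    # the disease-free group entering through the survival scan below.
    samples = [p.sample_id for p in analysis_profiles]
    met_samples = [
        s for s in samples
        if s in set(analysis_clin.loc[analysis_clin["group"] == "metastatic", "sample_id"])
    ]
    met_calls = calls[calls["sample_id"].isin(met_samples)]
    stac_regions, freq_regions = [], []
    s_seed = stage_seed(config.seed, 4)
    i = 0
    for direction in ("gain", "loss"):
        met_mats = cna.binarize_calls(
            met_calls, sim.arm_table, config.bin_size, direction, met_samples)
        all_mats = cna.binarize_calls(
            calls, sim.arm_table, config.bin_size, direction, samples)
        for m_met, m_all in zip(met_mats, all_mats):
            res = stac.stac_test(m_met, n_perm=config.n_perm, seed=s_seed + i)
            i += 1
            stac_regions.append(
                stac.significant_regions(res, config.freq_min, config.alpha_stac))
            # survival-scan candidates: cohort-wide recurrent regions at a
            # lower frequency floor, independent of the permutation test
            freq_regions.append(stac.frequency_regions(m_all, config.spps_freq_min))
    def _concat(frames, cols):
        frames = [f for f in frames if not f.empty]
        return (
            pd.concat(frames, ignore_index=True)
            if frames else pd.DataFrame(columns=cols)
        )

    stac_regions = _concat(
        stac_regions, ["chrom", "arm", "start", "end", "direction", "freq", "p_stac"])
    freq_regions = _concat(
        freq_regions, ["chrom", "arm", "start", "end", "direction", "freq"])
    _record("stac", f"freq >= {config.freq_min} and p < {config.alpha_stac}",
            len(stac_regions), {"stac_regions.tsv": stac_regions})

    # --- spps -------------------------------------------------------------
    spps_all = survival.spps_select(
        freq_regions, calls, analysis_clin,
        min_cover=config.min_cover, alpha=config.alpha_spps,
    )
    spps_regions = (
        spps_all[spps_all["selected"]].reset_index(drop=True)
        if not spps_all.empty else spps_all
    )
    _record("spps", f"log-rank p < {config.alpha_spps}", len(spps_regions),
            {"spps_regions.tsv": spps_all} if not spps_all.empty else {})

    # --- integrate --------------------------------------------------------
    common = genemap.intersect_maps(stac_regions, spps_regions)
    _record("intersect", "STAC ∩ SPPS, same direction", len(common),
            {"common_regions.tsv": common} if not common.empty else {})

    mapped = genemap.map_genes(common, genes)
    _record("map_genes", ">=1 bp gene overlap", mapped["symbol"].nunique(),
            {"mapped_genes.tsv": mapped} if not mapped.empty else {})

    kept, removal_log = genemap.filter_candidates(
        mapped, common, catalog,
        threshold=config.overlap_threshold, whitelist=config.whitelist,
    )
    _record("normal_cnv_filter",
            f"normal-CNV overlap < {config.overlap_threshold} or whitelisted",
            kept["symbol"].nunique() if not kept.empty else 0,
            {"removal_log.tsv": removal_log} if not removal_log.empty else {})

    # --- expression screen ------------------------------------------------
    datasets = [
        (expr_raw[meta.loc[meta["dataset"] == d, "sample_id"]],
         pd.Series(d, index=meta.loc[meta["dataset"] == d, "sample_id"]))
        for d in meta["dataset"].unique()
    ]
    expr_std, _ = xp.assemble_meta_cohort(datasets)
    cand_in = (
        kept[["symbol", "direction"]].drop_duplicates("symbol")
        if not kept.empty else pd.DataFrame(columns=["symbol", "direction"])
    )
    screened = xp.screen_genes(cand_in, expr_std, meta, alpha=config.screen_alpha)
    primary = (
        screened[screened.get("primary_pass", pd.Series(dtype=bool)) == True]  # noqa: E712
        if not screened.empty else screened
    )
    _record("expression_screen",
            f"Cox p < {config.screen_alpha} with direction-consistent sign",
            len(primary), {"screened.tsv": screened} if not screened.empty else {})

    stringent = (
        xp.stringent_filter(primary.dropna(subset=["cox_os_p", "cox_dfs_p"]),
                            config.stringent_alpha)
        if not primary.empty else primary
    )
    _record("stringent",
            f"min(OS p, DFS p) < {config.stringent_alpha}", len(stringent))

    # --- emt --------------------------------------------------------------
    emt_seed = stage_seed(config.seed, 9)
    tumor_cols = meta.loc[meta["tissue"] == "tumor", "sample_id"].tolist()
    pair = emt_mod.GeneSetPair(curated["EPITHELIAL"], curated["MESENCHYMAL"])
    pres = emt_mod.phenotype_prescore(expr_std[tumor_cols], pair)
    try:
        refined = emt_mod.refine_signatures(
            expr_std[tumor_cols], pres,
            extreme_fraction=config.extreme_fraction,
            roc_min=config.roc_min, n_perm=config.emt_n_perm, seed=emt_seed,
        )
    except ValueError as err:
        log.warning("signature refinement failed (%s); using curated sets", err)
        refined = pair
    emt_scores = emt_mod.emt_score(expr_std[tumor_cols], refined)
    _record("emt", "ssGSEA EMT score", len(emt_scores),
            {"emt_scores.tsv": emt_scores})

    # annotate screened candidates with their EMT-score association
    if not screened.empty:
        assoc = []
        for sym in screened["symbol"]:
            try:
                vals = pd.Series(
                    expr_std.loc[sym, tumor_cols].to_numpy(), index=tumor_cols)
                assoc.append(emt_mod.gene_emt_association(vals, emt_scores))
            except (KeyError, ValueError):
                assoc.append((np.nan, np.nan))
        screened[["emt_spearman_rho", "emt_spearman_p"]] = assoc

    # --- combo ------------------------------------------------------------
    combo = None
    loss_hits = (
        stringent[stringent["direction"] == "loss"]["symbol"].tolist()
        if not stringent.empty else []
    )
    if len(loss_hits) >= 2:
        try:
            combo = xp.combo_survival(loss_hits[:2], expr_std, meta, endpoint="dfs")
        except ValueError as err:
            log.warning("combination analysis skipped: %s", err)
    _record("combo", "joint Q1 underexpression log-rank",
            0 if combo is None else combo["n_joint_q1"])

    report = funnel_report(funnel)
    if outdir:
        report.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "clinical": clinical,
        "calls": calls,
        "stac_regions": stac_regions,
        "spps_regions": spps_regions,
        "common_regions": common,
        "mapped_genes": mapped,
        "kept_genes": kept,
        "screened": screened,
        "stringent": stringent,
        "emt_scores": emt_scores,
        "combo": combo,
        "truth": truth,
        "funnel": report,
        "manifest": manifest,
    }


def funnel_report(stages: list[tuple[str, str, int]]) -> pd.DataFrame:
    """Per-stage record counts with the applied rule named."""
    return pd.DataFrame(stages, columns=["stage", "rule", "count"])


def replay_candidate_table(stringent_alpha: float = 0.005) -> dict:
    """Fixture replay: apply the bookkeeping and stringent rule to the
    published 42-gene candidate table (the CNA stages are skipped since the
    raw cohort data behind the table are not redistributable)."""
    t2 = load_candidate_table()
    best = t2[["cox_os_p", "cox_dfs_p"]].min(axis=1)
    stringent = t2[best < stringent_alpha]
    return {
        "n_records": len(t2),
        "n_loss": int((t2["cna_event"] == "Loss").sum()),
        "n_gain": int((t2["cna_event"] == "Gain").sum()),
        "n_stringent": len(stringent),
        "stringent_genes": stringent["gene"].tolist(),
        "max_normal_overlap_pct": float(t2["pct_normal_overlap"].max()),
        "max_overlap_gene": t2.loc[t2["pct_normal_overlap"].idxmax(), "gene"],
        "table": t2,
    }
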