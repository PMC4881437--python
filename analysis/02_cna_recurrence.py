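"""QC, segment and map recurrent aberrations in the metastatic group.

Reads the probe matrix written by 01, gates samples on DLRS < 0.5, segments
each profile, and runs the within-arm permutation recurrence test on the
metastatic samples' binarized calls (gains and losses separately) at the
stringent 35% frequency / p < 0.05 thresholds.
"""

from pathlib import Path

import pandas as pd

from crcmet import cna, stac
from crcmet.pipeline import stage_seed

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 11
BIN_SIZE = 1_000_000
N_PERM = 999


def main() -> None:
    out = BASE / "cna"
    out.mkdir(parents=True, exist_ok=True)
    profiles = cna.read_probe_matrix(BASE / "synthetic" / "probes.tsv")
    clinical = pd.read_csv(BASE / "synthetic" / "clinical.tsv", sep="\t")
    arm_table = cna.default_arm_table()

    qc = pd.DataFrame(
        {"sample_id": [p.sample_id for p in profiles],
         "dlrs": [cna.compute_dlrs(p) for p in profiles]}
    )
    qc["pass"] = qc["dlrs"] < cna.DLRS_QC_THRESHOLD
    qc.to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.4f")
    eligible = set(qc.loc[qc["pass"], "sample_id"])
    analysis = clinical[
        clinical["sample_id"].isin(eligible) & (clinical["group"] != "local_recurrence")
    ]
    print(f"QC: {len(eligible)}/{len(profiles)} samples below DLRS 0.5; "
          f"{len(analysis)} in the metastasis analysis set")

    keep = set(analysis["sample_id"])
    per_sample = [cna.segment_profile(p) for p in profiles if p.sample_id in keep]
    calls = pd.concat([c for c in per_sample if not c.empty], ignore_index=True)
    calls = cna.assign_arms(calls, arm_table)
    cna.write_seg(calls, out / "calls.seg")
    print(f"segmentation: {len(calls)} gain/loss calls across {calls['sample_id'].nunique()} samples")

    met = analysis.loc[analysis["group"] == "metastatic", "sample_id"].tolist()
    met_calls = calls[calls["sample_id"].isin(met)]
    regions = []
    i = 0
    for direction in ("gain", "loss"):
        for m in cna.binarize_calls(met_calls, arm_table, BIN_SIZE, direction, met):
            res = stac.stac_test(m, n_perm=N_PERM, seed=stage_seed(SEED, 4) + i)
            i += 1
            regions.append(stac.significant_regions(res))
    regions = pd.concat([r for r in regions if not r.empty], ignore_index=True)
    regions.to_csv(out / "stac_regions.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"recurrence map (metastatic group, freq>=0.35, p<0.05): {len(regions)} regions")
    print(regions.to_string(index=False))


if __name__ == "__main__":
    main()
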