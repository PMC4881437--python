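"""Generate the synthetic study inputs.

Writes a 96-sample aCGH cohort (78 disease-free / 11 metastatic / 7
local-recurrence), its clinical table, a multi-batch expression meta-cohort
with a normal-tissue batch, the gene annotation, the normal-CNV catalog,
the curated E/M gene sets, and the planted ground truth.
"""

from pathlib import Path

from crcmet.cna import write_probe_matrix
from crcmet.simulate import (
    SimConfig,
    make_curated_gene_sets,
    make_gene_annotation,
    make_normal_cnv_catalog,
    simulate_cohort,
    simulate_expression,
    write_clinical,
    write_expression,
    write_genes_bed,
    write_gmt,
    write_normal_cnv_bed,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    profiles, clinical, truth = simulate_cohort(cfg)
    expr, meta = simulate_expression(cfg, truth)

    write_probe_matrix(profiles, OUT / "probes.tsv")
    write_clinical(clinical, OUT / "clinical.tsv")
    write_expression(expr, OUT / "expression.tsv")
    meta.to_csv(OUT / "expression_meta.tsv", sep="\t", index=False, float_format="%.4f")
    truth.to_json(OUT / "truth.json")
    write_genes_bed(make_gene_annotation(cfg), OUT / "genes.bed")
    write_normal_cnv_bed(make_normal_cnv_catalog(cfg), OUT / "normal_cnv.bed")
    write_gmt(make_curated_gene_sets(cfg), OUT / "curated_emt.gmt")

    counts = clinical["group"].value_counts()
    print(f"wrote {len(profiles)} aCGH profiles "
          f"({counts['disease_free']} disease-free, {counts['metastatic']} metastatic, "
          f"{counts['local_recurrence']} local-recurrence)")
    print(f"expression meta-cohort: {expr.shape[0]} genes x {expr.shape[1]} samples "
          f"({(meta['tissue'] == 'normal').sum()} normals), "
          f"{meta.loc[meta['tissue'] == 'tumor', 'dataset'].nunique()} tumor batches")
    print(f"planted drivers: {[d.name for d in truth.drivers]}")


if __name__ == "__main__":
    main()
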