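"""Synthetic cohort generator: construction guarantees, determinism, and
planted-effect recovery."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from crcmet import cna
from crcmet.simulate import (
    DriverRegion,
    SimConfig,
    make_curated_gene_sets,
    make_gene_annotation,
    make_normal_cnv_catalog,
    simulate_cohort,
    simulate_expression,
    write_expression,
)
from crcmet.survival import cox_fit


def _small_config(**kw):
    defaults = dict(
        n_disease_free=12, n_metastatic=6, n_local_recurrence=2,
        n_probes=2000, seed=5, n_datasets=2, n_expr_per_dataset=30,
        n_expr_normal=15,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    def test_default_group_sizes_mirror_study_cohort(self):
        cfg = SimConfig()
        assert (cfg.n_disease_free, cfg.n_metastatic, cfg.n_local_recurrence) == (78, 11, 7)
        _, clinical, _ = simulate_cohort(SimConfig(seed=3))
        counts = clinical["group"].value_counts()
        assert counts["disease_free"] == 78
        assert counts["metastatic"] == 11
        assert counts["local_recurrence"] == 7

    def test_driver_outside_arm_rejected(self):
        with pytest.raises(ValueError, match="outside arm"):
            SimConfig(driver_regions=[DriverRegion("chr1", "p", 0, 70_000_000, "loss", 0.8, 0.05)])

    def test_opposite_direction_overlap_rejected(self):
        with pytest.raises(ValueError, match="opposite"):
            SimConfig(
                driver_regions=[
                    DriverRegion("chr1", "p", 10_000_000, 20_000_000, "loss", 0.8, 0.05),
                    DriverRegion("chr1", "p", 15_000_000, 25_000_000, "gain", 0.8, 0.05),
                ]
            )

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(censoring_rate=1.5)
        with pytest.raises(ValueError):
            SimConfig(driver_regions=[DriverRegion("chr1", "p", 0, 1_000, "loss", 1.2, 0.0)])


class TestCohort:
    def test_noise_free_single_driver_construction(self):
        cfg = _small_config(
            probe_noise_sd=0.0,
            passenger_rate=0.0,
            driver_regions=[DriverRegion("chr1", "p", 10_000_000, 25_000_000, "loss", 1.0, 0.0)],
        )
        profiles, clinical, truth = simulate_cohort(cfg)
        met = set(clinical.loc[clinical["group"] == "metastatic", "sample_id"])
        for p in profiles:
            v = p.probes["log2"].to_numpy()
            inside = (
                (p.probes["chrom"] == "chr1")
                & (p.probes["pos"] >= 10_000_000)
                & (p.probes["pos"] < 25_000_000)
            ).to_numpy()
            if p.sample_id in met:
                assert (v[inside] == -cfg.segment_amplitude).all()
                assert (v[~inside] == 0).all()
            else:
                assert (v == 0).all()

    def test_every_driver_in_at_least_one_metastatic_sample(self):
        cfg = _small_config(seed=9)
        _, clinical, truth = simulate_cohort(cfg)
        met = clinical.loc[clinical["group"] == "metastatic", "sample_id"]
        for di in range(len(truth.drivers)):
            assert any(di in truth.carriers[s] for s in met)

    def test_carrier_rates_match_penetrance_at_large_n(self):
        cfg = SimConfig(
            n_disease_free=2000, n_metastatic=2000, n_local_recurrence=1,
            n_probes=200, passenger_rate=0.0, probe_noise_sd=0.0, seed=2,
        )
        _, clinical, truth = simulate_cohort(cfg)
        for di, d in enumerate(truth.drivers):
            for group, rate in (("metastatic", d.penetrance), ("disease_free", d.background)):
                ids = clinical.loc[clinical["group"] == group, "sample_id"]
                frac = np.mean([di in truth.carriers[s] for s in ids])
                assert frac == pytest.approx(rate, abs=0.03)

    def test_cox_recovers_driver_hazard_ratio(self):
        # hazard_ratio_driver = 3 with one driver: the carrier-indicator Cox
        # coefficient should recover log(3) at large n without censoring
        cfg = SimConfig(
            n_disease_free=200, n_metastatic=200, n_local_recurrence=1,
            n_probes=200, passenger_rate=0.0, probe_noise_sd=0.0,
            hazard_ratio_driver=3.0, censoring_rate=0.0, seed=4,
            driver_regions=[DriverRegion("chr1", "p", 10_000_000, 25_000_000, "loss", 0.8, 0.1)],
        )
        _, clinical, truth = simulate_cohort(cfg)
        x = np.array([len(truth.carriers[s]) for s in clinical["sample_id"]], float)
        fit = cox_fit(x, clinical["dfs_time"], clinical["dfs_event"])
        assert fit.coef == pytest.approx(np.log(3.0), abs=0.15)

    def test_truth_round_trips_through_json(self, tmp_path):
        cfg = _small_config()
        _, _, truth = simulate_cohort(cfg)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = type(truth).from_json(path)
        assert back.carriers == truth.carriers
        assert back.passengers == truth.passengers
        assert back.dosage_genes == truth.dosage_genes
        assert back.emt_phenotype == truth.emt_phenotype
        assert [dataclasses.asdict(d) for d in back.drivers] == [
            dataclasses.asdict(d) for d in truth.drivers
        ]

    def test_deterministic_given_seed(self):
        cfg = _small_config(seed=21)
        p1, c1, _ = simulate_cohort(cfg)
        p2, c2, _ = simulate_cohort(_small_config(seed=21))
        pd.testing.assert_frame_equal(c1, c2)
        for a, b in zip(p1, p2):
            assert (a.probes["log2"].to_numpy() == b.probes["log2"].to_numpy()).all()


class TestExpression:
    def test_dosage_shift_exact_noise_free(self):
        cfg = _small_config(
            probe_noise_sd=0.0, expr_noise_sd=0.0, batch_shift_sd=0.0,
            batch_scale_sd=0.0, emt_shift=0.0, dosage_beta=1.0,
            expr_carrier_rate=0.5,
        )
        _, _, truth = simulate_cohort(cfg)
        expr, meta = simulate_expression(cfg, truth)
        gene = truth.dosage_genes[0]
        # which driver hosts this gene, and its direction
        genes = make_gene_annotation(cfg)
        g = genes[genes["symbol"] == gene].iloc[0]
        di = next(
            i for i, d in enumerate(truth.drivers)
            if d.chrom == g["chrom"] and d.start <= g["start"] < d.end
        )
        sign = 1 if truth.drivers[di].direction == "gain" else -1
        tumor = meta[meta["tissue"] == "tumor"]
        carrier = tumor["sample_id"].map(lambda s: di in truth.carriers[s])
        vals = expr.loc[gene, tumor["sample_id"]].to_numpy()
        diff = vals[carrier.to_numpy()].mean() - vals[~carrier.to_numpy()].mean()
        assert diff == pytest.approx(sign * 1.0, abs=1e-9)

    def test_null_tumor_normal_type_one_error(self):
        # with batch effects, dosage and EMT all off, tumor-vs-normal
        # Mann-Whitney should reject at the nominal rate across many genes
        from crcmet.expression import mannwhitney_test

        cfg = _small_config(
            batch_shift_sd=0.0, batch_scale_sd=0.0, dosage_beta=0.0,
            emt_shift=0.0, n_background_genes=1000, expr_carrier_rate=0.0,
            n_datasets=2, n_expr_per_dataset=40, n_expr_normal=40, seed=6,
        )
        _, _, truth = simulate_cohort(cfg)
        expr, meta = simulate_expression(cfg, truth)
        tumor_ids = meta.loc[meta["tissue"] == "tumor", "sample_id"]
        normal_ids = meta.loc[meta["tissue"] == "normal", "sample_id"]
        rej = 0
        bg = [g for g in expr.index if g.startswith("BG")]
        for g in bg:
            _, p = mannwhitney_test(expr.loc[g, tumor_ids], expr.loc[g, normal_ids])
            rej += p < 0.05
        assert rej / len(bg) == pytest.approx(0.05, abs=0.02)

    def test_too_many_dosage_genes_rejected(self):
        cfg = _small_config(n_dosage_genes=1000)
        with pytest.raises(ValueError, match="dosage-coupled"):
            simulate_cohort(cfg)

    def test_expression_tsv_byte_identical_across_runs(self):
        def render():
            cfg = _small_config(seed=31)
            _, _, truth = simulate_cohort(cfg)
            expr, _ = simulate_expression(cfg, truth)
            buf = io.StringIO()
            write_expression(expr, buf)
            return buf.getvalue()

        assert render() == render()


class TestAnnotationArtifacts:
    def test_gene_annotation_deterministic_and_roles_complete(self):
        cfg = _small_config()
        g1, g2 = make_gene_annotation(cfg), make_gene_annotation(cfg)
        pd.testing.assert_frame_equal(g1, g2)
        counts = g1["role"].value_counts()
        assert counts["driver"] == cfg.genes_per_driver * len(cfg.driver_regions)
        assert counts["background"] == cfg.n_background_genes
        assert counts["epithelial"] == cfg.n_epithelial_genes
        assert counts["mesenchymal"] == cfg.n_mesenchymal_genes

    def test_normal_catalog_covers_tenth_of_background_genes(self):
        cfg = _small_config()
        cat = make_normal_cnv_catalog(cfg)
        genes = make_gene_annotation(cfg)
        n_bg = (genes["role"] == "background").sum()
        assert len(cat) == int(np.ceil(n_bg / 10))

    def test_curated_sets_disjoint_with_decoys(self):
        sets = make_curated_gene_sets(_small_config())
        assert not set(sets["EPITHELIAL"]) & set(sets["MESENCHYMAL"])
        assert any(g.startswith("BG") for g in sets["EPITHELIAL"])
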