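"""Synthetic aCGH + expression cohorts with known ground truth.

The generator emulates the structure of a ~96-sample stage II colorectal
cancer cohort: 78 disease-free, 11 metastatic and 7 local-recurrence cases
(the local-recurrence cases are generated but flagged, mirroring their
exclusion from the metastasis analysis). Each sample is a probe-level log2
ratio profile: a zero diploid baseline plus planted driver and passenger
segments plus i.i.d. Gaussian probe noise. Driver regions are carried with
a high penetrance in the metastatic group and a low background rate in the
disease-free group; disease-free survival follows an exponential
proportional-hazards model whose hazard multiplies by ``hazard_ratio_driver``
per driver carried.

A companion expression meta-cohort spreads tumors over several batches with
location/scale batch effects, couples expression of driver-resident genes to
copy state (``dosage_beta`` units per copy), and shifts a mesenchymal gene
block up / an epithelial block down in mesenchymal-phenotype samples. A
normal-tissue batch supports tumor-vs-normal testing.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cna import ProbeProfile, default_arm_table

# baseline yearly hazards; disease-free samples then have mean DFS near the
# ~10-year follow-up horizon of the emulated study
BASE_DFS_HAZARD = 0.08
BASE_OS_HAZARD = 0.05
MES_HAZARD_FACTOR = 1.5


@dataclass
class DriverRegion:
    chrom: str
    arm: str
    start: int
    end: int
    direction: str  # gain | loss
    penetrance: float  # carrier rate in the metastatic group
    background: float  # carrier rate in the disease-free group

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}:{self.start}-{self.end}:{self.direction}"


def _default_drivers() -> list[DriverRegion]:
    return [
        DriverRegion("chr1", "p", 10_000_000, 25_000_000, "loss", 0.8, 0.05),
        DriverRegion("chr2", "q", 70_000_000, 85_000_000, "gain", 0.8, 0.05),
        DriverRegion("chr3", "q", 50_000_000, 62_000_000, "loss", 0.7, 0.05),
    ]


@dataclass
class SimConfig:
    n_disease_free: int = 78
    n_metastatic: int = 11
    n_local_recurrence: int = 7
    n_probes: int = 8000
    arm_table: pd.DataFrame | None = None  # defaults to the packaged table
    driver_regions: list[DriverRegion] = field(default_factory=_default_drivers)
    passenger_rate: float = 2.0  # expected passenger aberrations per sample
    probe_noise_sd: float = 0.15  # log2-ratio units
    segment_amplitude: float = 0.8  # |log2| of a single-copy change after purity
    hazard_ratio_driver: float = 3.0  # DFS hazard multiplier per driver carried
    censoring_rate: float = 0.3
    # expression meta-cohort
    n_datasets: int = 4
    n_expr_per_dataset: int = 60
    n_expr_normal: int = 40
    expr_carrier_rate: float = 0.3  # per-driver carrier rate among expression tumors
    mesenchymal_rate: float = 0.25
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.1
    dosage_beta: float = 1.0  # expression units per copy-state unit
    emt_shift: float = 1.5  # mesenchymal program activation in mesenchymal samples
    expr_noise_sd: float = 1.0
    # gene annotation
    genes_per_driver: int = 4
    n_dosage_genes: int | None = None  # None = all driver-resident genes
    n_background_genes: int = 60
    n_epithelial_genes: int = 15
    n_mesenchymal_genes: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm_table is None:
            self.arm_table = default_arm_table()
        for name in ("n_disease_free", "n_metastatic", "n_local_recurrence", "n_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")
        arms = {
            (r["chrom"], r["arm"]): (int(r["start"]), int(r["end"]))
            for _, r in self.arm_table.iterrows()
        }
        for d in self.driver_regions:
            if not 0 <= d.penetrance <= 1 or not 0 <= d.background <= 1:
                raise ValueError(f"driver {d.name}: rates must be in [0, 1]")
            key = (d.chrom, d.arm)
            if key not in arms:
                raise ValueError(f"driver {d.name}: no arm {key} in arm table")
            lo, hi = arms[key]
            if not (lo <= d.start < d.end <= hi):
                raise ValueError(f"driver {d.name}: outside arm bounds {lo}-{hi}")
        for i, a in enumerate(self.driver_regions):
            for b in self.driver_regions[i + 1 :]:
                if (
                    (a.chrom, a.arm) == (b.chrom, b.arm)
                    and a.direction != b.direction
                    and a.start < b.end
                    and b.start < a.end
                ):
                    raise ValueError(
                        f"drivers {a.name} and {b.name} overlap with opposite "
                        "directions on the same arm"
                    )

    @property
    def n_samples(self) -> int:
        return self.n_disease_free + self.n_metastatic + self.n_local_recurrence


@dataclass
class GroundTruth:
    """What was planted: consumed by tests, never by the pipeline."""

    drivers: list[DriverRegion]
    carriers: dict  # sample_id -> list of carried driver indices
    passengers: dict  # sample_id -> list of (chrom, start, end, direction)
    dosage_genes: list  # symbols whose expression is copy-state coupled
    emt_phenotype: dict  # sample_id -> 1 if mesenchymal-like else 0

    def to_json(self, path) -> None:
        payload = {
            "drivers": [asdict(d) for d in self.drivers],
            "carriers": self.carriers,
            "passengers": self.passengers,
            "dosage_genes": list(self.dosage_genes),
            "emt_phenotype": self.emt_phenotype,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            drivers=[DriverRegion(**d) for d in payload["drivers"]],
            carriers={k: list(v) for k, v in payload["carriers"].items()},
            passengers={k: [tuple(x) for x in v] for k, v in payload["passengers"].items()},
            dosage_genes=list(payload["dosage_genes"]),
            emt_phenotype=payload["emt_phenotype"],
        )


# ---------------------------------------------------------------------------
# gene annotation / catalogs (deterministic functions of the config)


def make_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Deterministic synthetic gene annotation.

    ``genes_per_driver`` genes sit inside each driver region (these are the
    dosage-coupled candidates); background, epithelial-block and
    mesenchymal-block genes are spread evenly over the rest of the genome.
    Columns: chrom, start, end, symbol, strand, role.
    """
    rows = []
    gene_len = 50_000
    for i, d in enumerate(config.driver_regions):
        span = d.end - d.start
        for j in range(config.genes_per_driver):
            s = d.start + int(span * (j + 0.5) / config.genes_per_driver)
            rows.append((d.chrom, s, s + gene_len, f"DRV{i + 1}_G{j + 1}", "+", "driver"))
    others = (
        [(f"BG{i + 1:03d}", "background") for i in range(config.n_background_genes)]
        + [(f"EPI{i + 1:02d}", "epithelial") for i in range(config.n_epithelial_genes)]
        + [(f"MES{i + 1:02d}", "mesenchymal") for i in range(config.n_mesenchymal_genes)]
    )
    arms = config.arm_table
    total = int((arms["end"] - arms["start"]).sum())
    # lay candidate slots on a fine grid, drop those inside driver regions,
    # then thin to an evenly spread subset of the required size
    step = max(gene_len * 2, total // (4 * len(others)))
    slots = []
    for _, a in arms.iterrows():
        pos = int(a["start"]) + step // 2
        while pos + gene_len < int(a["end"]):
            inside_driver = any(
                d.chrom == a["chrom"] and d.start - gene_len < pos < d.end
                for d in config.driver_regions
            )
            if not inside_driver:
                slots.append((a["chrom"], pos))
            pos += step
    if len(slots) < len(others):
        raise ValueError("genome too small for the requested gene count")
    pick = np.linspace(0, len(slots) - 1, len(others)).round().astype(int)
    for (sym, role), i in zip(others, pick):
        chrom, pos = slots[i]
        rows.append((chrom, pos, pos + gene_len, sym, "+", role))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol", "strand", "role"])


def make_normal_cnv_catalog(config: SimConfig) -> pd.DataFrame:
    """Normal-population CNV catalog: intervals over every 10th background
    gene (plus flanks), so ~10% of background genes fall inside catalog CNVs."""
    genes = make_gene_annotation(config)
    bg = genes[genes["role"] == "background"].reset_index(drop=True)
    picked = bg.iloc[::10]
    return pd.DataFrame(
        {
            "chrom": picked["chrom"],
            "start": (picked["start"] - 10_000).clip(lower=0),
            "end": picked["end"] + 10_000,
            "name": "normalCNV_" + picked["symbol"],
        }
    ).reset_index(drop=True)


def make_curated_gene_sets(config: SimConfig) -> dict[str, list[str]]:
    """Curated epithelial / mesenchymal sets: the planted blocks plus a few
    background decoys (imperfect curation, as with any literature set)."""
    genes = make_gene_annotation(config)
    epi = genes.loc[genes["role"] == "epithelial", "symbol"].tolist()
    mes = genes.loc[genes["role"] == "mesenchymal", "symbol"].tolist()
    bg = genes.loc[genes["role"] == "background", "symbol"].tolist()
    return {"EPITHELIAL": epi + bg[:3], "MESENCHYMAL": mes + bg[3:6]}


# ---------------------------------------------------------------------------
# cohort simulation


def _probe_grid(config: SimConfig) -> pd.DataFrame:
    arms = config.arm_table
    lengths = (arms["end"] - arms["start"]).to_numpy(float)
    counts = np.maximum(1, np.round(config.n_probes * lengths / lengths.sum())).astype(int)
    frames = []
    for (_, a), n in zip(arms.iterrows(), counts):
        spacing = (int(a["end"]) - int(a["start"])) / n
        pos = (int(a["start"]) + (np.arange(n) + 0.5) * spacing).astype(np.int64)
        frames.append(pd.DataFrame({"chrom": a["chrom"], "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def _exp_survival(rng, hazard: float, censoring_rate: float) -> tuple[float, int]:
    t = float(rng.exponential(1.0 / hazard))
    if rng.random() < censoring_rate:
        return float(rng.uniform(0, t)), 0
    return t, 1


def simulate_cohort(config: SimConfig):
    """Generate (profiles, clinical table, ground truth) for the aCGH cohort."""
    rng = np.random.default_rng(config.seed)
    grid = _probe_grid(config)
    chrom = grid["chrom"].to_numpy()
    pos = grid["pos"].to_numpy()

    groups = (
        [("DF", "disease_free")] * config.n_disease_free
        + [("MET", "metastatic")] * config.n_metastatic
        + [("LR", "local_recurrence")] * config.n_local_recurrence
    )
    counters: dict[str, int] = {}
    sample_ids, group_labels = [], []
    for prefix, label in groups:
        counters[prefix] = counters.get(prefix, 0) + 1
        sample_ids.append(f"{prefix}{counters[prefix]:02d}")
        group_labels.append(label)

    amp = config.segment_amplitude
    drivers = config.driver_regions
    carriers: dict[str, list[int]] = {}
    passengers: dict[str, list] = {}
    profiles = []
    clinical_rows = []

    # carrier draws first so the metastatic-coverage guarantee is seed-stable
    carrier_mat = np.zeros((len(sample_ids), len(drivers)), dtype=bool)
    for si, label in enumerate(group_labels):
        for di, d in enumerate(drivers):
            rate = d.penetrance if label == "metastatic" else d.background
            carrier_mat[si, di] = rng.random() < rate
    met_idx = [i for i, g in enumerate(group_labels) if g == "metastatic"]
    for di in range(len(drivers)):
        if met_idx and not carrier_mat[met_idx, di].any():
            carrier_mat[met_idx[0], di] = True  # every driver hits >=1 metastatic case

    arms = config.arm_table
    for si, (sid, label) in enumerate(zip(sample_ids, group_labels)):
        values = np.zeros(len(grid))
        events = []
        for di, d in enumerate(drivers):
            if carrier_mat[si, di]:
                events.append((d.chrom, d.start, d.end, d.direction))
        carriers[sid] = [di for di in range(len(drivers)) if carrier_mat[si, di]]
        n_pass = rng.poisson(config.passenger_rate)
        plist = []
        for _ in range(n_pass):
            a = arms.iloc[int(rng.integers(0, len(arms)))]
            alen = int(a["end"]) - int(a["start"])
            length = int(alen * rng.uniform(0.02, 0.15))
            start = int(rng.integers(int(a["start"]), int(a["end"]) - length))
            direction = "gain" if rng.random() < 0.5 else "loss"
            plist.append((a["chrom"], start, start + length, direction))
        passengers[sid] = plist
        for c, s, e, direction in events + plist:
            mask = (chrom == c) & (pos >= s) & (pos < e)
            values[mask] += amp if direction == "gain" else -amp
        if config.probe_noise_sd > 0:
            values = values + rng.normal(0, config.probe_noise_sd, len(values))
        profiles.append(
            ProbeProfile(sid, pd.DataFrame({"chrom": chrom, "pos": pos, "log2": values}))
        )

        n_carried = len(carriers[sid])
        hr = config.hazard_ratio_driver**n_carried
        dfs_t, dfs_e = _exp_survival(rng, BASE_DFS_HAZARD * hr, config.censoring_rate)
        os_t, os_e = _exp_survival(rng, BASE_OS_HAZARD * hr, config.censoring_rate)
        clinical_rows.append(
            {
                "sample_id": sid,
                "dfs_time": round(dfs_t, 4),
                "dfs_event": dfs_e,
                "os_time": round(os_t, 4),
                "os_event": os_e,
                "group": label,
                "msi": "MSI" if rng.random() < 0.16 else "MSS",
                "stage": "II",
                "grade": ["Well", "Moderate", "Poor"][int(rng.integers(0, 3))],
            }
        )

    genes = make_gene_annotation(config)
    drv = genes.loc[genes["role"] == "driver", "symbol"].tolist()
    if config.n_dosage_genes is not None:
        if config.n_dosage_genes > len(drv):
            raise ValueError(
                f"requested {config.n_dosage_genes} dosage-coupled genes but only "
                f"{len(drv)} driver-resident genes are planted"
            )
        drv = drv[: config.n_dosage_genes]
    truth = GroundTruth(
        drivers=list(drivers),
        carriers=carriers,
        passengers=passengers,
        dosage_genes=drv,
        emt_phenotype={
            sid: int(lab == "metastatic") for sid, lab in zip(sample_ids, group_labels)
        },
    )
    clinical = pd.DataFrame(clinical_rows)
    return profiles, clinical, truth


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(config: SimConfig, truth: GroundTruth):
    """Generate (expression matrix genes x samples, sample metadata).

    Tumor samples span ``n_datasets`` batches; each batch gets a location
    shift ~N(0, batch_shift_sd) and a log-normal scale. Dosage-coupled genes
    shift by dosage_beta * (copy state - 2); mesenchymal-phenotype samples
    have the mesenchymal block up- and the epithelial block down-shifted by
    emt_shift. A normal-tissue batch (diploid, epithelial) is appended.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = make_gene_annotation(config)
    symbols = genes["symbol"].tolist()
    role = dict(zip(genes["symbol"], genes["role"]))
    mu = pd.Series(rng.normal(7.0, 1.0, len(symbols)), index=symbols)
    dosage = set(truth.dosage_genes)
    gene_driver = {}
    for _, g in genes[genes["role"] == "driver"].iterrows():
        for di, d in enumerate(truth.drivers):
            if g["chrom"] == d.chrom and d.start <= g["start"] < d.end:
                gene_driver[g["symbol"]] = (di, +1 if d.direction == "gain" else -1)

    batch_shift = rng.normal(0, config.batch_shift_sd, config.n_datasets + 1)
    batch_scale = np.exp(rng.normal(0, config.batch_scale_sd, config.n_datasets + 1))

    cols, meta_rows = {}, []
    for b in range(config.n_datasets):
        for k in range(config.n_expr_per_dataset):
            sid = f"T{b + 1}_{k + 1:03d}"
            carried = [
                di
                for di in range(len(truth.drivers))
                if rng.random() < config.expr_carrier_rate
            ]
            mes = int(rng.random() < config.mesenchymal_rate)
            vals = mu.copy()
            for sym, (di, sign) in gene_driver.items():
                if di in carried and sym in dosage:
                    vals[sym] += config.dosage_beta * sign
            if mes:
                for sym in symbols:
                    if role[sym] == "mesenchymal":
                        vals[sym] += config.emt_shift
                    elif role[sym] == "epithelial":
                        vals[sym] -= config.emt_shift
            noise = rng.normal(0, config.expr_noise_sd, len(symbols)) if config.expr_noise_sd > 0 else 0.0
            cols[sid] = batch_shift[b] + batch_scale[b] * (vals.to_numpy() + noise)
            hr = config.hazard_ratio_driver ** len(carried) * (
                MES_HAZARD_FACTOR if mes else 1.0
            )
            dfs_t, dfs_e = _exp_survival(rng, BASE_DFS_HAZARD * hr, config.censoring_rate)
            os_t, os_e = _exp_survival(rng, BASE_OS_HAZARD * hr, config.censoring_rate)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "dataset": f"DS{b + 1}",
                    "tissue": "tumor",
                    "dfs_time": round(dfs_t, 4),
                    "dfs_event": dfs_e,
                    "os_time": round(os_t, 4),
                    "os_event": os_e,
                    "msi": "MSI" if rng.random() < 0.16 else "MSS",
                    "stage": ["I", "II", "III", "IV"][int(rng.integers(0, 4))],
                    "grade": ["Well", "Moderate", "Poor"][int(rng.integers(0, 3))],
                    "mesenchymal": mes,
                    "n_drivers": len(carried),
                }
            )
            truth.emt_phenotype[sid] = mes
            truth.carriers[sid] = carried
    for k in range(config.n_expr_normal):
        sid = f"N_{k + 1:03d}"
        noise = rng.normal(0, config.expr_noise_sd, len(symbols)) if config.expr_noise_sd > 0 else 0.0
        cols[sid] = batch_shift[-1] + batch_scale[-1] * (mu.to_numpy() + noise)
        meta_rows.append(
            {
                "sample_id": sid,
                "dataset": "NORM",
                "tissue": "normal",
                "dfs_time": np.nan,
                "dfs_event": 0,
                "os_time": np.nan,
                "os_event": 0,
                "msi": "MSS",
                "stage": "",
                "grade": "",
                "mesenchymal": 0,
                "n_drivers": 0,
            }
        )
        truth.emt_phenotype[sid] = 0
    expr = pd.DataFrame(cols, index=symbols)
    expr.index.name = "gene"
    return expr, pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# writers (all plain text, deterministic formatting)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format="%.6f")


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "symbol", "role"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_normal_cnv_bed(catalog: pd.DataFrame, path) -> None:
    catalog[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
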