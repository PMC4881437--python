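"""Probe-level copy-number handling: QC, segmentation, calling, binarization.

An aCGH profile is a set of ordered genomic probes with log2 tumor/reference
ratios. This module computes the derivative log-ratio spread (DLRS) noise
metric used as a sample-quality gate, segments each chromosome by recursive
binary splitting with a BIC-style penalty, thresholds segment means into
gain/loss calls, and projects calls onto per-arm bin grids for the
permutation analysis downstream.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: samples at or above this DLRS are ineligible for downstream analysis
DLRS_QC_THRESHOLD = 0.5

CALL_COLUMNS = ["sample_id", "chrom", "arm", "start", "end", "direction", "mean_log2"]


@dataclass
class ProbeProfile:
    """One sample's ordered probes: columns ``chrom``, ``pos`` (bp), ``log2``."""

    sample_id: str
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.probes
        required = {"chrom", "pos", "log2"}
        if not required.issubset(p.columns):
            raise ValueError(f"probe table needs columns {sorted(required)}")
        if not np.isfinite(p["log2"].to_numpy(float)).all():
            raise ValueError(f"{self.sample_id}: non-finite log2 ratios")
        for chrom, sub in p.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"{self.sample_id}: positions not strictly increasing on {chrom}"
                )

    @property
    def n_probes(self) -> int:
        return len(self.probes)


def default_arm_table() -> pd.DataFrame:
    """Packaged synthetic arm table (chrom, arm, start, end)."""
    ref = importlib.resources.files("crcmet.data") / "arm_table.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def compute_dlrs(profile: ProbeProfile) -> float:
    """Derivative log-ratio spread: a robust per-sample noise estimate.

    Differences between consecutive probes are taken within each chromosome
    (never across a chromosome boundary); their interquartile range is scaled
    by 1.349 to estimate the SD of the differences, and by a further sqrt(2)
    because differencing doubles the probe-level variance. For i.i.d. probe
    noise with SD sigma the statistic estimates sigma.
    """
    if profile.n_probes < 3:
        raise ValueError("DLRS requires at least 3 probes")
    diffs = []
    for _, sub in profile.probes.groupby("chrom", sort=False):
        v = sub["log2"].to_numpy(float)
        if len(v) > 1:
            diffs.append(np.diff(v))
    if not diffs:
        raise ValueError("no within-chromosome probe pairs")
    d = np.concatenate(diffs)
    q75, q25 = np.percentile(d, [75, 25])
    return float((q75 - q25) / (1.349 * np.sqrt(2.0)))


def qc_pass(profile: ProbeProfile, threshold: float = DLRS_QC_THRESHOLD) -> bool:
    return compute_dlrs(profile) < threshold


# ---------------------------------------------------------------------------
# segmentation


def _best_split(prefix: np.ndarray, prefix2: np.ndarray, lo: int, hi: int):
    """Best single changepoint in x[lo:hi); returns (gain_in_SSE, split)."""
    n = hi - lo
    if n < 2:
        return 0.0, None
    total = prefix[hi] - prefix[lo]
    total2 = prefix2[hi] - prefix2[lo]
    sse_whole = total2 - total * total / n
    ks = np.arange(lo + 1, hi)
    left_n = ks - lo
    right_n = hi - ks
    left_sum = prefix[ks] - prefix[lo]
    right_sum = total - left_sum
    sse_children = (
        total2 - left_sum * left_sum / left_n - right_sum * right_sum / right_n
    )
    i = int(np.argmin(sse_children))
    return float(sse_whole - sse_children[i]), int(ks[i])


def _binary_segment(x: np.ndarray, threshold: float) -> list[int]:
    """Recursive binary segmentation; returns sorted breakpoints (internal)."""
    prefix = np.concatenate(([0.0], np.cumsum(x)))
    prefix2 = np.concatenate(([0.0], np.cumsum(x * x)))
    breaks: list[int] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        gain, k = _best_split(prefix, prefix2, lo, hi)
        if k is not None and gain > threshold:
            breaks.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
    return sorted(breaks)


def segment_profile(
    profile: ProbeProfile,
    penalty: float = 3.0,
    gain_threshold: float = 0.25,
    loss_threshold: float = 0.25,
) -> pd.DataFrame:
    """Segment a profile and call gains/losses.

    Per chromosome, recursive binary segmentation minimizes within-segment
    squared error; a split is accepted when it reduces the SSE by more than
    ``penalty * sigma^2 * log(n)`` (BIC-style), with sigma estimated robustly
    from the profile's DLRS. Segments with mean >= +gain_threshold are called
    gains, <= -loss_threshold losses; abutting same-direction calls merge.

    Returns a call table with columns sample_id, chrom, arm (empty; see
    :func:`assign_arms`), start, end, direction, mean_log2.
    """
    sigma = compute_dlrs(profile)
    thr = penalty * max(sigma, 1e-9) ** 2 * np.log(max(profile.n_probes, 2))
    rows = []
    for chrom, sub in profile.probes.groupby("chrom", sort=False):
        x = sub["log2"].to_numpy(float)
        pos = sub["pos"].to_numpy()
        bounds = [0] + _binary_segment(x, thr) + [len(x)]
        segs = []  # (start_idx, end_idx, direction, mean)
        for a, b in zip(bounds[:-1], bounds[1:]):
            m = float(x[a:b].mean())
            if m >= gain_threshold:
                d = "gain"
            elif m <= -loss_threshold:
                d = "loss"
            else:
                continue
            if segs and segs[-1][2] == d and segs[-1][1] == a:
                # merge abutting same-direction calls, probe-weighted mean
                a0, _, _, m0 = segs[-1]
                segs[-1] = (a0, b, d, (m0 * (a - a0) + m * (b - a)) / (b - a0))
            else:
                segs.append((a, b, d, m))
        for a, b, d, m in segs:
            rows.append(
                (profile.sample_id, chrom, "", int(pos[a]), int(pos[b - 1]) + 1, d, m)
            )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def assign_arms(calls: pd.DataFrame, arm_table: pd.DataFrame) -> pd.DataFrame:
    """Split calls at arm boundaries and annotate the arm.

    Any portion of a call not covered by a declared arm raises an error
    naming the call.
    """
    out = []
    for _, c in calls.iterrows():
        arms = arm_table[arm_table["chrom"] == c["chrom"]]
        covered = 0
        for _, a in arms.iterrows():
            s = max(int(c["start"]), int(a["start"]))
            e = min(int(c["end"]), int(a["end"]))
            if s < e:
                covered += e - s
                r = c.copy()
                r["arm"], r["start"], r["end"] = a["arm"], s, e
                out.append(r)
        if covered < int(c["end"]) - int(c["start"]):
            raise ValueError(
                f"call {c['sample_id']} {c['chrom']}:{c['start']}-{c['end']} "
                "falls outside every declared arm"
            )
    return pd.DataFrame(out, columns=CALL_COLUMNS).reset_index(drop=True)


# ---------------------------------------------------------------------------
# binarization


@dataclass
class AberrationMatrix:
    """Binary occupancy of same-direction calls on one arm's bin grid."""

    chrom: str
    arm: str
    start: int
    end: int
    direction: str
    bin_edges: np.ndarray
    samples: list[str] = field(default_factory=list)
    occupancy: np.ndarray = None  # bool, samples x bins

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def binarize_calls(
    calls: pd.DataFrame,
    arm_table: pd.DataFrame,
    bin_size: int,
    direction: str,
    samples: list[str],
) -> list[AberrationMatrix]:
    """Tile each arm with ``bin_size`` bins (last bin may be short) and mark
    a sample/bin entry 1 iff a same-direction call of that sample overlaps
    the bin. One matrix per arm; samples with no calls get all-zero rows."""
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    sub = calls[calls["direction"] == direction]
    unplaced = ~sub["chrom"].isin(arm_table["chrom"])
    if unplaced.any():
        bad = sub[unplaced].iloc[0]
        raise ValueError(f"call on undeclared chromosome {bad['chrom']}")
    idx = {s: i for i, s in enumerate(samples)}
    out = []
    for _, a in arm_table.iterrows():
        astart, aend = int(a["start"]), int(a["end"])
        edges = np.arange(astart, aend, bin_size, dtype=np.int64)
        edges = np.append(edges, aend)
        occ = np.zeros((len(samples), len(edges) - 1), dtype=bool)
        on_arm = sub[
            (sub["chrom"] == a["chrom"])
            & (sub["start"] < aend)
            & (sub["end"] > astart)
        ]
        for _, c in on_arm.iterrows():
            if c["sample_id"] not in idx:
                raise ValueError(f"call sample {c['sample_id']} not in sample roster")
            lo = int(np.searchsorted(edges, max(int(c["start"]), astart), "right")) - 1
            hi = int(np.searchsorted(edges, min(int(c["end"]), aend), "left"))
            occ[idx[c["sample_id"]], lo:hi] = True
        out.append(
            AberrationMatrix(
                chrom=a["chrom"],
                arm=a["arm"],
                start=astart,
                end=aend,
                direction=direction,
                bin_edges=edges,
                samples=list(samples),
                occupancy=occ,
            )
        )
    return out


# ---------------------------------------------------------------------------
# file formats


def read_probe_matrix(path) -> list[ProbeProfile]:
    """Read a probe TSV: chrom, start, end, probe_id, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["chrom", "start", "end", "probe_id"]
    profiles = []
    for s in [c for c in df.columns if c not in fixed]:
        probes = pd.DataFrame(
            {"chrom": df["chrom"], "pos": df["start"], "log2": df[s].astype(float)}
        )
        profiles.append(ProbeProfile(sample_id=s, probes=probes))
    return profiles


def write_probe_matrix(profiles: list[ProbeProfile], path) -> None:
    base = profiles[0].probes
    out = pd.DataFrame(
        {
            "chrom": base["chrom"],
            "start": base["pos"],
            "end": base["pos"] + 1,
            "probe_id": [f"P{i:06d}" for i in range(len(base))],
        }
    )
    for p in profiles:
        out[p.sample_id] = p.probes["log2"].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_seg(path) -> pd.DataFrame:
    """Read SEG-like file (sample, chrom, start, end, n_probes, seg_mean) and
    threshold means into calls; pre-segmented input thus bypasses the
    in-package segmenter."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    direction = np.where(df["seg_mean"] >= 0, "gain", "loss")
    return pd.DataFrame(
        {
            "sample_id": df["sample"],
            "chrom": df["chrom"],
            "arm": "",
            "start": df["start"],
            "end": df["end"],
            "direction": direction,
            "mean_log2": df["seg_mean"],
        }
    )


def write_seg(calls: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "sample": calls["sample_id"],
            "chrom": calls["chrom"],
            "start": calls["start"],
            "end": calls["end"],
            "n_probes": -1,
            "seg_mean": calls["mean_log2"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_calls_bed(calls: pd.DataFrame, path) -> None:
    out = calls[["chrom", "start", "end"]].copy()
    out["name"] = calls["sample_id"] + "|" + calls["direction"]
    out["score"] = (calls["mean_log2"] * 1000).round().astype(int).clip(-1000, 1000)
    out.to_csv(path, sep="\t", index=False, header=False)
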