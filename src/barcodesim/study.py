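"""Orchestration of the full simulation study.

The default protocol generates ten independent 500-sequence datasets plus
one of 300 and one of 1000 sequences: for each, a constant-size coalescent
genealogy, 1,500-bp Jukes-Cantor sequences rescaled so the maximum
pairwise JC distance stays below 3%, a min-max-normalized distance matrix,
and the four estimator subsampling schedules with their summary tables.

Everything is driven by one root seed.  Per-dataset and per-schedule
streams are derived from documented integer offsets, so a study re-run
from its manifest reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import distances as dist
from . import estimators as est
from . import genealogy as gen
from . import resampling as rs
from . import seqsim as seq
from ._rng import derive_seedseq
from .errors import InvalidArgumentError

__all__ = [
    "DatasetSpec",
    "StudyConfig",
    "default_config",
    "smoke_config",
    "run_study",
    "summarize_table1",
    "load_manifest",
]

logger = logging.getLogger("barcodesim.study")

# stream offsets for deriving per-dataset seeds from the root seed
_GENEALOGY_STREAM = 1
_SEQUENCE_STREAM = 2
_SCHEDULE_STREAM = 3


def _derived_int_seed(root_seed: int, stream: int, dataset_index: int) -> int:
    """A 31-bit integer seed for (stream, dataset) derived from the root seed."""
    ss = derive_seedseq(root_seed, stream, dataset_index)
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


@dataclass
class DatasetSpec:
    id: str
    n_sequences: int
    schedule_group: str = "main"  # "main" (500-seq protocol) or "additional"


@dataclass
class ScheduleSpec:
    sizes: tuple[int, ...]
    replicates: int


@dataclass
class StudyConfig:
    dataset_spec: list[DatasetSpec]
    theta: float = seq.DEFAULT_THETA
    seq_length: int = seq.DEFAULT_SEQ_LENGTH
    divergence_cap: float = seq.DEFAULT_DIVERGENCE_CAP
    schedules: dict[str, dict[str, ScheduleSpec]] = field(default_factory=dict)
    root_seed: int = 0
    output_dir: str = "study_output"

    def __post_init__(self) -> None:
        ids = [d.id for d in self.dataset_spec]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("dataset ids must be unique")
        for d in self.dataset_spec:
            group = self.schedules.get(d.schedule_group, {})
            for name, sched in group.items():
                if sched.sizes and max(sched.sizes) > d.n_sequences:
                    raise InvalidArgumentError(
                        f"{name} schedule size {max(sched.sizes)} exceeds "
                        f"dataset {d.id} (n={d.n_sequences})"
                    )

    def schedule_for(self, dataset: DatasetSpec, estimator: str) -> ScheduleSpec:
        return self.schedules[dataset.schedule_group][estimator]


MAIN_SCHEDULES = {
    "mismatch": ScheduleSpec(sizes=(5, 10, 20, 30, 50, 100), replicates=10),
    "diversity": ScheduleSpec(
        sizes=(2, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100), replicates=10_000
    ),
    "maxdist": ScheduleSpec(
        sizes=(2, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100), replicates=10_000
    ),
    "haplotypes": ScheduleSpec(
        sizes=(2, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120, 130, 140, 150),
        replicates=100,
    ),
}

ADDITIONAL_SCHEDULES = {
    "mismatch": ScheduleSpec(sizes=(5, 10, 20, 30, 50, 100), replicates=10),
    "diversity": ScheduleSpec(sizes=(2, 5, 10, 20, 30, 40, 50, 60), replicates=10_000),
    "maxdist": ScheduleSpec(sizes=(2, 5, 10, 20, 30, 40, 50, 60), replicates=10_000),
    "haplotypes": ScheduleSpec(sizes=(2, 20, 40, 60, 80, 100, 120, 140), replicates=100),
}


def default_config(root_seed: int = 0, output_dir: str = "study_output") -> StudyConfig:
    """The full study protocol: ten 500-sequence datasets plus one of 300
    (seq_K) and one of 1000 (seq_L), with the per-estimator schedules
    applied to each group."""
    datasets = [DatasetSpec(f"seq_{c}", 500, "main") for c in "ABCDEFGHIJ"]
    datasets.append(DatasetSpec("seq_K", 300, "additional"))
    datasets.append(DatasetSpec("seq_L", 1000, "additional"))
    return StudyConfig(
        dataset_spec=datasets,
        schedules={"main": dict(MAIN_SCHEDULES), "additional": dict(ADDITIONAL_SCHEDULES)},
        root_seed=root_seed,
        output_dir=output_dir,
    )


def smoke_config(
    root_seed: int = 0,
    output_dir: str = "study_output",
    n_datasets: int = 2,
    n_sequences: int = 30,
    replicates: int = 100,
) -> StudyConfig:
    """A miniature configuration exercising every pipeline stage quickly."""
    sizes_small = tuple(s for s in (2, 5, 10, 20) if s <= n_sequences)
    schedules = {
        "main": {
            "mismatch": ScheduleSpec(sizes=sizes_small[1:], replicates=3),
            "diversity": ScheduleSpec(sizes=sizes_small, replicates=replicates),
            "maxdist": ScheduleSpec(sizes=sizes_small, replicates=replicates),
            "haplotypes": ScheduleSpec(sizes=sizes_small, replicates=min(replicates, 50)),
        }
    }
    datasets = [
        DatasetSpec(f"smoke_{chr(ord('A') + i)}", n_sequences, "main")
        for i in range(n_datasets)
    ]
    return StudyConfig(dataset_spec=datasets, schedules=schedules, root_seed=root_seed, output_dir=output_dir)


# -- single-dataset pipeline ----------------------------------------------


def generate_dataset(
    n_sequences: int,
    genealogy_seed: int,
    sequence_seed: int,
    seq_length: int = seq.DEFAULT_SEQ_LENGTH,
    divergence_cap: float = seq.DEFAULT_DIVERGENCE_CAP,
) -> tuple[gen.Genealogy, gen.Genealogy, seq.Alignment, dist.DistanceMatrix, dist.DistanceMatrix]:
    """Genealogy -> capped alignment -> raw and normalized JC matrices."""
    g = gen.simulate_genealogy(n_sequences, genealogy_seed)
    g_scaled, aln = seq.enforce_divergence_cap(
        g, L=seq_length, cap=divergence_cap, seed=sequence_seed
    )
    raw = dist.pairwise_matrix(aln)
    normalized = dist.minmax_normalize(raw, 0.0, divergence_cap)
    return g, g_scaled, aln, raw, normalized


def _run_dataset(cfg: StudyConfig, spec: DatasetSpec, index: int, outdir: Path, plots: bool) -> dict:
    t0 = time.perf_counter()
    gseed = _derived_int_seed(cfg.root_seed, _GENEALOGY_STREAM, index)
    sseed = _derived_int_seed(cfg.root_seed, _SEQUENCE_STREAM, index)
    rseed = _derived_int_seed(cfg.root_seed, _SCHEDULE_STREAM, index)

    g, g_scaled, aln, raw, normalized = generate_dataset(
        spec.n_sequences, gseed, sseed, cfg.seq_length, cfg.divergence_cap
    )
    aln = seq.Alignment(aln.codes, [f"{spec.id}_{lab}" for lab in aln.labels], aln.provenance)
    raw = dist.DistanceMatrix(raw.values, list(aln.labels), raw.scale_tag)
    normalized = dist.DistanceMatrix(
        normalized.values, list(aln.labels), normalized.scale_tag, normalized.norm_params
    )

    ddir = outdir / spec.id
    ddir.mkdir(parents=True, exist_ok=True)
    gen.write_newick(g, ddir / "genealogy_coalescent.nwk")
    gen.write_newick(g_scaled, ddir / "genealogy_rescaled.nwk")
    seq.write_fasta(aln, ddir / "alignment.fasta")
    dist.write_csv(raw, ddir / "distances_jc.csv")
    dist.write_csv(normalized, ddir / "distances_normalized.csv")

    # tree-shape report
    profile = gen.aldous_split_profile(g, min(7, spec.n_sequences - 1))
    pd.DataFrame(
        {
            "node_rank": [r for r, _ in profile.entries],
            "larger_daughter_size": [s for _, s in profile.entries],
            "balanced_reference": gen.balanced_reference_profile(
                spec.n_sequences, len(profile.entries)
            ).sizes(),
        }
    ).to_csv(ddir / "split_profile.csv", index=False)
    shape = {
        "dataset_id": spec.id,
        "n_sequences": spec.n_sequences,
        "colless_raw": gen.colless_index(g),
        "colless_normalized": gen.colless_index(g, normalized=True),
        "tmrca": gen.tmrca(g),
        "max_jc_distance": float(raw.offdiag().max()),
    }
    pd.DataFrame([shape]).to_csv(ddir / "tree_shape.csv", index=False)

    # mismatch distribution: full dataset + subsample pools
    values = normalized.offdiag()
    full_summary = est.mismatch_histogram(values)
    full_summary.to_frame().to_csv(ddir / "mismatch_full.csv", index=False)
    gaps = est.gap_report(values)
    pd.DataFrame(gaps, columns=["gap_start", "gap_end"]).to_csv(
        ddir / "mismatch_gaps.csv", index=False
    )
    msched = cfg.schedule_for(spec, "mismatch")
    pools = rs.subsample_distance_sets(
        normalized, msched.sizes, msched.replicates, rseed, dataset_id=spec.id
    )
    mismatch_rows = []
    for size, reps in pools.items():
        for rep, pool in enumerate(reps):
            summ = est.mismatch_histogram(pool)
            for left, right, count in zip(summ.bin_edges[:-1], summ.bin_edges[1:], summ.counts):
                mismatch_rows.append(
                    {
                        "dataset_id": spec.id,
                        "size": size,
                        "replicate": rep,
                        "bin_left": left,
                        "bin_right": right,
                        "count": count,
                    }
                )
    pd.DataFrame(mismatch_rows).to_csv(ddir / "mismatch_subsamples.csv", index=False)

    # diversity
    dsched = cfg.schedule_for(spec, "diversity")
    div = rs.run_schedule(
        rs.SubsampleSchedule("diversity", dsched.sizes, dsched.replicates, rseed),
        m=normalized,
        dataset_id=spec.id,
    )
    div.to_frame().to_csv(ddir / "resample_diversity.csv", index=False)
    summary = est.DiversitySummary.from_matrix(normalized)
    bands = rs.band_summary(div, summary.beta)
    pd.DataFrame([asdict(b) for b in bands]).to_csv(ddir / "diversity_bands.csv", index=False)
    rs.clt_diagnostics(div, summary.beta).to_csv(ddir / "diversity_clt.csv", index=False)

    # haplotypes
    hsched = cfg.schedule_for(spec, "haplotypes")
    hap = rs.run_schedule(
        rs.SubsampleSchedule("haplotypes", hsched.sizes, hsched.replicates, rseed),
        aln=aln,
        dataset_id=spec.id,
    )
    hap.to_frame().to_csv(ddir / "resample_haplotypes.csv", index=False)
    quart = rs.quartile_summary(hap)
    quart.to_csv(ddir / "haplotype_quartiles.csv", index=False)
    mm = rs.fit_michaelis_menten(quart["size"], quart["median"])
    pd.DataFrame(
        [
            {
                "dataset_id": spec.id,
                "a": mm.a,
                "b": mm.b,
                "residual_variance": mm.residual_variance,
                "asymptote": mm.asymptote,
                "slope_at_20": rs.mm_slope(mm, 20.0),
                "n_points": mm.n_points,
            }
        ]
    ).to_csv(ddir / "mm_fit.csv", index=False)

    # maximum pairwise distance
    xsched = cfg.schedule_for(spec, "maxdist")
    mx = rs.run_schedule(
        rs.SubsampleSchedule("maxdist", xsched.sizes, xsched.replicates, rseed),
        m=normalized,
        dataset_id=spec.id,
    )
    mx.to_frame().to_csv(ddir / "resample_maxdist.csv", index=False)
    full_max = est.max_pairwise(normalized)
    mx_rows = []
    for si, size in enumerate(mx.sizes):
        vals = mx.values[si]
        mx_rows.append(
            {
                "size": size,
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "pct_at_full_max": float(100.0 * np.mean(vals >= full_max - 1e-12)),
                "full_max": full_max,
            }
        )
    pd.DataFrame(mx_rows).to_csv(ddir / "maxdist_summary.csv", index=False)

    if plots:
        _render_plots(ddir, full_summary, hap, quart, mm)

    elapsed = time.perf_counter() - t0
    logger.info("dataset %s finished in %.1fs (seeds g=%d s=%d r=%d)", spec.id, elapsed, gseed, sseed, rseed)
    return {
        "dataset_id": spec.id,
        "n_sequences": spec.n_sequences,
        "schedule_group": spec.schedule_group,
        "genealogy_seed": gseed,
        "sequence_seed": sseed,
        "schedule_seed": rseed,
        "beta": summary.beta,
        "sigma2": summary.sigma2,
        "max_jc_distance": shape["max_jc_distance"],
        "colless_normalized": shape["colless_normalized"],
        "wall_time_s": elapsed,
    }


def _render_plots(ddir: Path, full_summary, hap, quart, mm) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    widths = np.diff(full_summary.bin_edges)
    ax.bar(full_summary.bin_edges[:-1], full_summary.counts, width=widths, align="edge", alpha=0.6)
    ax2 = ax.twinx()
    ax2.plot(full_summary.kde_grid, full_summary.kde_density, color="C1")
    ax.set_xlabel("normalized JC distance")
    ax.set_ylabel("count")
    fig.savefig(ddir / "mismatch_full.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.boxplot([hap.values[i] for i in range(len(hap.sizes))], tick_labels=list(hap.sizes))
    xs = np.linspace(1, max(hap.sizes), 200)
    ax.plot(
        (xs - 1) / (max(hap.sizes) - 1) * (len(hap.sizes) - 1) + 1,
        mm.predict(xs),
        color="C1",
    )
    ax.set_xlabel("sample size")
    ax.set_ylabel("haplotypes")
    fig.savefig(ddir / "haplotypes.png", dpi=120)
    plt.close(fig)


def run_study(cfg: StudyConfig, plots: bool = False) -> dict:
    """Run every dataset of the study; returns the manifest dictionary.

    A failing dataset is logged and skipped; its id is recorded under
    ``"failures"`` and the caller decides the exit status.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "study.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "root_seed": cfg.root_seed,
        "theta": cfg.theta,
        "seq_length": cfg.seq_length,
        "divergence_cap": cfg.divergence_cap,
        "schedules": {
            group: {name: asdict(s) for name, s in group_scheds.items()}
            for group, group_scheds in cfg.schedules.items()
        },
        "datasets": [],
        "failures": [],
    }
    try:
        for index, spec in enumerate(cfg.dataset_spec):
            try:
                manifest["datasets"].append(_run_dataset(cfg, spec, index, outdir, plots))
            except Exception as exc:  # noqa: BLE001 - isolate per-dataset failures
                logger.exception("dataset %s failed: %s", spec.id, exc)
                manifest["failures"].append({"dataset_id": spec.id, "error": str(exc)})
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    summarize_table1(outdir).to_csv(outdir / "table1.csv", index=False)
    return manifest


def load_manifest(path) -> StudyConfig:
    """Rebuild a :class:`StudyConfig` from a run manifest for exact re-runs."""
    with open(path) as fh:
        manifest = json.load(fh)
    datasets = [
        DatasetSpec(d["dataset_id"], d["n_sequences"], d.get("schedule_group", "main"))
        for d in manifest["datasets"]
    ]
    schedules = {
        group: {
            name: ScheduleSpec(tuple(s["sizes"]), s["replicates"])
            for name, s in group_scheds.items()
        }
        for group, group_scheds in manifest["schedules"].items()
    }
    return StudyConfig(
        dataset_spec=datasets,
        theta=manifest["theta"],
        seq_length=manifest["seq_length"],
        divergence_cap=manifest["divergence_cap"],
        schedules=schedules,
        root_seed=manifest["root_seed"],
        output_dir=str(Path(path).parent),
    )


def summarize_table1(outdir) -> pd.DataFrame:
    """Per-dataset diversity summary: beta, per-size mean pi, per-size
    percentage of subsample diversities within beta ± 0.001.

    Sizes absent from a dataset's schedule appear as NA, mirroring how
    smaller datasets truncate the size grid.
    """
    outdir = Path(outdir)
    all_sizes: list[int] = []
    per_dataset = []
    for bands_path in sorted(outdir.glob("*/diversity_bands.csv")):
        bands = pd.read_csv(bands_path)
        dataset_id = bands_path.parent.name
        dmat = dist.read_csv(bands_path.parent / "distances_normalized.csv", scale_tag="normalized")
        beta = est.DiversitySummary.from_matrix(dmat).beta
        per_dataset.append((dataset_id, beta, bands))
        all_sizes.extend(int(s) for s in bands["size"])
    sizes = sorted(set(all_sizes))
    rows = []
    for dataset_id, beta, bands in per_dataset:
        row: dict = {"dataset_id": dataset_id, "beta": round(beta, 3)}
        by_size = {int(r["size"]): r for _, r in bands.iterrows()}
        for s in sizes:
            if s in by_size:
                row[f"mean_{s}"] = round(float(by_size[s]["mean"]), 3)
                row[f"pct_{s}"] = round(float(by_size[s]["pct_in_band"]), 2)
            else:
                row[f"mean_{s}"] = np.nan
                row[f"pct_{s}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
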