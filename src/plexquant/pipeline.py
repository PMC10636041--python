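"""End-to-end orchestration: simulate -> demux -> normalize -> curves -> QC.

A run is fully described by a :class:`RunConfig`; rerunning the same
config reproduces every output bit for bit.  Each stage writes its tables
under the run directory, and a provenance manifest records the config
hash, seed and package version alongside them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import (K_MULTIPLEX, K_SINGLEPLEX, AssayLimits, StandardSeries,
                     assay_limits, fit_4pl)
from .demux import demux
from .normalize import ic_normalize, ipc_normalize
from .pools import design_pools, pool_sizes
from .qc import DETECTABILITY_CUTOFF, detectability, precision
from .simulate import (NoiseModel, make_panel, make_plate_plan,
                       simulate_counts, simulate_dilution_series,
                       simulate_reads, write_fastq)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and sizes for a full synthetic run.

    Defaults are the platform's published constants: LOD multiplier 2.5
    (single-plex qPCR) or 3 (multiplex NGS), 30% CV and 30% recovery
    limits with one interior recovery exception, a strict 50% sample
    detectability cutoff, the 1e4 rescale inside NPQ and the 37-cycle
    offset in the qPCR signal transform.
    """

    seed: int = 0
    mode: str = "multiplex"  # singleplex -> k=2.5, multiplex -> k=3
    n_targets: int = 20
    n_wells: int = 96
    barcode_length: int = 12
    min_barcode_distance: int = 5
    curve_targets: int = 3        # dilution series fitted per run
    curve_levels: int = 12
    curve_reps: int = 3
    curve_blanks: int = 3
    curve_top_factor: float = 1e3  # top standard = factor * half-max C
    cv_limit: float = 30.0
    recovery_limit: float = 30.0
    max_recovery_exceptions: int = 1
    detectability_cutoff: float = DETECTABILITY_CUTOFF
    amplitude_range: tuple[float, float] = (2e3, 5e4)
    floor_range: tuple[float, float] = (5.0, 50.0)
    ic_mean: float = 10_000.0
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def lod_k(self) -> float:
        if self.mode == "singleplex":
            return K_SINGLEPLEX
        if self.mode == "multiplex":
            return K_MULTIPLEX
        raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"] = dataclasses.asdict(self.noise)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        noise = NoiseModel(**raw.pop("noise", {}))
        return cls(noise=noise, **raw)


def summarize_panel(limits: dict[str, AssayLimits]) -> dict:
    """Per-target limits table plus the panel's cumulative dynamic range.

    The cumulative range is ``log10(max ULOQ / min LLOQ)`` over all
    targets with determined limits -- the span from the panel's most
    sensitive lower limit to its highest upper limit.
    """
    rows = {}
    lloqs, uloqs = [], []
    for name, lim in limits.items():
        rows[name] = {"lod": lim.lod, "lloq": lim.lloq, "uloq": lim.uloq,
                      "dynamic_range_log10": lim.dynamic_range_log10}
        if lim.lloq is not None:
            lloqs.append(lim.lloq)
        if lim.uloq is not None:
            uloqs.append(lim.uloq)
    if not lloqs or not uloqs:
        raise ValueError("no determined quantitation limits to summarize")
    return {
        "per_target": rows,
        "cumulative_dynamic_range_log10": math.log10(max(uloqs) / min(lloqs)),
    }


def _feasible_pool_count(n_targets: int) -> int | None:
    """Largest pool count giving pools of 4-5 that can satisfy
    pair-uniqueness (pool size never above the pool count), or None."""
    for n_pools in range(n_targets // 4, 0, -1):
        if 4 * n_pools <= n_targets <= 5 * n_pools and \
                max(pool_sizes(n_targets, n_pools)) <= n_pools:
            return n_pools
    return None


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute simulate -> demux -> normalize -> curves -> QC.

    Returns a summary dict (also written as ``summary.json``); every
    intermediate table lands in ``outdir``.  A stage failure raises with
    the stage named, leaving earlier outputs in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "setup"
    summary: dict = {"config": config.to_dict(), "config_hash": config.digest(),
                     "version": __version__, "stages": {}}
    try:
        stage = "simulate"
        t0 = time.time()
        panel = make_panel(config.n_targets, seed=config.seed,
                           barcode_length=config.barcode_length,
                           min_distance=config.min_barcode_distance,
                           amplitude_range=config.amplitude_range,
                           floor_range=config.floor_range)
        plan = make_plate_plan(panel, seed=config.seed + 1,
                               n_wells=config.n_wells)
        counts_true = simulate_counts(panel, plan, noise=config.noise,
                                      seed=config.seed + 2,
                                      ic_mean=config.ic_mean)
        manifest = panel.manifest(plan)
        reads = simulate_reads(counts_true, panel, plan, noise=config.noise,
                               seed=config.seed + 3)
        fastq = outdir / "reads.fastq"
        n_reads = write_fastq(reads, fastq)
        panel.to_json(outdir / "panel_truth.json")
        plan.to_tsv(outdir / "plate_layout.tsv")
        manifest.to_tsv(outdir / "manifest.tsv")
        counts_true.to_tsv(outdir / "counts_true.tsv")
        summary["stages"]["simulate"] = {"n_reads": n_reads,
                                         "seconds": time.time() - t0}

        stage = "demux"
        t0 = time.time()
        counts = demux(fastq, manifest)
        counts.to_tsv(outdir / "counts.tsv", outdir / "counts_qc.tsv")
        summary["stages"]["demux"] = {
            "reads_processed": counts.total_reads(),
            "assigned": int(counts.counts.to_numpy().sum()),
            "chimeric": int(counts.chimeric.sum()),
            "seconds": time.time() - t0}

        stage = "normalize"
        t0 = time.time()
        ic = ic_normalize(counts, internal_control=panel.internal_control_name,
                          plate_id=plan.plate_id)
        npq = ipc_normalize(ic, plan.ipc_wells)
        ic.to_tsv(outdir / "ic_normalized.tsv")
        npq.to_tsv(outdir / "npq.tsv")
        summary["stages"]["normalize"] = {"ipc_wells": plan.ipc_wells,
                                          "seconds": time.time() - t0}

        stage = "curves"
        t0 = time.time()
        limits: dict[str, AssayLimits] = {}
        fits: dict[str, dict] = {}
        for i, target in enumerate(panel.targets[:config.curve_targets]):
            dil_plan, dil_counts = simulate_dilution_series(
                target, top_conc=target.half_max_C * config.curve_top_factor,
                n_levels=config.curve_levels, n_reps=config.curve_reps,
                n_blanks=config.curve_blanks, noise=config.noise,
                seed=config.seed + 10 + i, ic_mean=config.ic_mean,
                internal_control=panel.internal_control)
            series = series_from_dilution(dil_counts, dil_plan, target.name,
                                          panel.internal_control_name)
            params = fit_4pl(series)
            fits[target.name] = {"A": params.A, "D": params.D,
                                 "C": params.C, "B": params.B}
            limits[target.name] = assay_limits(
                params, series, k=config.lod_k, cv_limit=config.cv_limit,
                recovery_limit=config.recovery_limit,
                max_recovery_exceptions=config.max_recovery_exceptions)
        panel_summary = summarize_panel(limits)
        (outdir / "curve_fits.json").write_text(json.dumps(fits, indent=2))
        (outdir / "assay_limits.json").write_text(
            json.dumps(panel_summary, indent=2))
        summary["stages"]["curves"] = {
            "n_fitted": len(fits),
            "cumulative_dynamic_range_log10":
                panel_summary["cumulative_dynamic_range_log10"],
            "seconds": time.time() - t0}

        stage = "qc"
        t0 = time.time()
        sample_wells = [w.well_id for w in plan.wells
                        if w.role in ("sample", "sample_control")]
        groups = {"sample_controls": [w.well_id for w in plan.wells
                                      if w.role == "sample_control"]}
        prec = precision(ic.values[sample_wells], groups, scope="intra")
        prec.table.to_csv(outdir / "precision.tsv", sep="\t")
        # Plate-specific LOD on the NPQ scale from the plate's blank wells:
        # mean blank NPQ + k * sd, the same blank rule used in molar units.
        blank_wells = [w.well_id for w in plan.wells if w.role == "blank"]
        blank_npq = npq.values[blank_wells]
        npq_lods = pd.DataFrame(
            {plan.plate_id: blank_npq.mean(axis=1)
             + config.lod_k * blank_npq.std(axis=1, ddof=1)})
        det = detectability(npq.values[sample_wells], npq_lods,
                            {w: plan.plate_id for w in sample_wells})
        det.table.to_csv(outdir / "detectability.tsv", sep="\t")
        summary["stages"]["qc"] = {
            "n_detectable": det.n_detectable,
            "seconds": time.time() - t0}

        stage = "pools"
        t0 = time.time()
        n_pools = _feasible_pool_count(config.n_targets)
        if n_pools is not None:
            design = design_pools([t.name for t in panel.targets], n_pools,
                                  seed=config.seed + 20)
            design.to_tsv(outdir / "pool_design.tsv")
            summary["stages"]["pools"] = {"n_pools": design.n_pools,
                                          "seconds": time.time() - t0}
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["seconds_total"] = time.time() - t_start
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "provenance.json").write_text(json.dumps(
        {"config_hash": config.digest(), "seed": config.seed,
         "version": __version__}, indent=2))
    return summary


def series_from_dilution(counts, plan, target: str,
                         internal_control: str = "mCherry") -> StandardSeries:
    """Build a :class:`StandardSeries` from a simulated dilution plate.

    Signals are internal-control-normalized counts, the scale on which
    multiplexed standard curves are fitted.
    """
    ic = ic_normalize(counts, internal_control=internal_control,
                      plate_id=plan.plate_id)
    by_level: dict[float, list[float]] = {}
    blanks: list[float] = []
    for well in plan.wells:
        v = float(ic.values.loc[target, well.well_id])
        if well.role == "blank":
            blanks.append(v)
        elif well.role == "standard":
            conc = well.concentrations[target]
            by_level.setdefault(conc, []).append(v)
    return StandardSeries(
        levels=[(c, np.array(v)) for c, v in by_level.items()],
        blanks=np.array(blanks))
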