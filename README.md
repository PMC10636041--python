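# plexquant

Simulation and analysis toolkit for highly multiplexed immunoassays with a
sequencing readout.

## The problem

In an NGS-readout sandwich immunoassay, each detected antigen molecule is
converted into a DNA reporter carrying three barcodes: a sample barcode
(SMI) identifying the well, and a matched pair of target barcodes (TMIs)
from the capture and detection antibodies of one assay. A sequencing run
over a pooled plate therefore yields millions of reads that must be turned
into a target-by-well count matrix, normalized across wells and plates,
calibrated against standard curves, and quality-controlled — all before any
biology can be read off. `plexquant` implements that full path:

- **Demultiplexing** with explicit error tolerance: a barcode field matches
  if it is within two substitutions, or one indel plus at most one
  substitution, of exactly one reference barcode. Ties are ambiguous;
  reads whose two TMIs name different targets are counted as chimeric
  reporters (antigen-independent ligation artifacts).
- **Normalization**: counts are divided well-by-well by a spiked-in
  internal control (mCherry) to remove per-well efficiency, then anchored
  across plates by inter-plate control (IPC) wells. The working unit is
  `NPQ = log2(IC-normalized value / per-target IPC median × 10⁴)`.
  An alternative intensity normalization rescales each plate's per-target
  median onto the global median. A `2^(37 − Cq)` transform maps single-plex
  qPCR output onto the same linear signal scale.
- **Calibration**: four-parameter logistic (4PL) standard curves
  `y = D + (A − D) / (1 + (x/C)^B)` fitted with 1/y² weighting, exact
  inverse backfitting, blank-based limits of detection
  (`mean(blanks) + k·sd`, k = 3 multiplexed / 2.5 single-plex), and a
  quantifiable range chosen as the widest contiguous dilution window whose
  levels hold CV < 30% with 70–130% backfit recovery at the endpoints.
- **QC**: intra/inter-plate precision with below-LOD exclusion, geometric
  CV from log2-scale SDs, per-target detectability (fraction of samples
  above the plate LOD, strict >50% cutoff) with exact Clopper–Pearson
  binomial confidence intervals, and cross-reactivity scoring.
- **Pool design**: partitions a 198-target panel twice into 45 pools of
  4–5 antigens such that no two targets ever share a pool in both sets.
  Any cross-reacting protein then lights up exactly two pools whose
  intersection names it uniquely.
- **Simulation**: a seeded generator producing ground-truth panels, plate
  plans, negative-binomial counts and FASTQ reads with substitution /
  indel / chimera errors, so every analysis step can be validated against
  a known truth.

## Worked example

```python
from plexquant import (NoiseModel, assay_limits, demux, fit_4pl, ic_normalize,
                       ipc_normalize, make_panel, make_plate_plan,
                       simulate_counts, simulate_reads)
from plexquant.pipeline import series_from_dilution
from plexquant.simulate import simulate_dilution_series

panel = make_panel(n_targets=12, seed=7)
plan = make_plate_plan(panel, seed=8, n_wells=24)
counts = simulate_counts(panel, plan, seed=9)
reads = simulate_reads(counts, panel, plan,
                       noise=NoiseModel(substitution_rate=0.005,
                                        indel_rate=0.001),
                       seed=10)
observed = demux(reads, panel.manifest(plan))
print("reads processed:", observed.total_reads())
print("assigned:", int(observed.counts.to_numpy().sum()),
      "unassigned:", int(observed.unassigned.sum()),
      "ambiguous:", int(observed.ambiguous.sum()),
      "chimeric:", int(observed.chimeric.sum()))

npq = ipc_normalize(ic_normalize(observed), plan.ipc_wells)
print("NPQ of T001 in first sample well:",
      round(float(npq.values.loc["T001",
                                 plan.wells_by_role("sample")[0].well_id]), 3))

target = panel.targets[0]
dil_plan, dil_counts = simulate_dilution_series(
    target, top_conc=target.half_max_C * 1e3, seed=11,
    internal_control=panel.internal_control)
series = series_from_dilution(dil_counts, dil_plan, target.name)
params = fit_4pl(series)
limits = assay_limits(params, series, k=3.0)
print(f"4PL fit for {target.name}: C = {params.C:.3e} M "
      f"(truth {target.half_max_C:.3e} M)")
print(f"LOD = {limits.lod:.3e} M, LLOQ = {limits.lloq:.3e} M, "
      f"ULOQ = {limits.uloq:.3e} M, "
      f"dynamic range = {limits.dynamic_range_log10:.1f} logs")
```

Output:

```text
reads processed: 1772762
assigned: 1711820 unassigned: 48536 ambiguous: 0 chimeric: 0
NPQ of T001 in first sample well: 14.22
4PL fit for T001: C = 3.322e-12 M (truth 2.625e-12 M)
LOD = 2.669e-14 M, LLOQ = 2.625e-14 M, ULOQ = 2.625e-11 M, dynamic range = 3.0 logs
```

The full simulate → demux → normalize → calibrate → QC → pool-design chain
is also available as one call (`run_pipeline(RunConfig(...), outdir)`) or
from the command line:

```sh
plexquant run --config run.yaml --out results/run1
plexquant ci 195 204
plexquant design-pools --n-targets 198 --n-pools 45 --out pools.tsv
```

## Layout

- `src/plexquant/simulate.py` — ground-truth panels, plates, counts, reads
- `src/plexquant/demux.py` — error-tolerant demultiplexer and count matrix
- `src/plexquant/normalize.py` — IC / IPC (NPQ) / intensity normalization
- `src/plexquant/curves.py` — 4PL fitting, backfit, LOD/LLOQ/ULOQ
- `src/plexquant/qc.py` — precision, detectability, exact CIs, cross-reactivity
- `src/plexquant/pools.py` — two-set pooling design and deconvolution
- `src/plexquant/pipeline.py`, `src/plexquant/cli.py` — orchestration and CLI
- `docs/methods.md` — model and methods note
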