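"""Synthetic plates, counts and reads for an NGS-readout immunoassay.

The generative model mirrors the statistical structure the downstream
pipeline assumes rather than any physical chemistry:

* each target responds to antigen concentration along a four-parameter
  logistic (Hill-shaped) curve in expected counts,
* "hot/cold" antibody tuning scales the concentration-dependent part of
  the signal linearly by the hot fraction,
* every well carries a multiplicative efficiency factor that a spiked-in
  internal control (mCherry by default) can correct,
* observed counts are negative-binomially overdispersed around their
  expectation,
* reads carry the well (SMI) and target (TMI pair) barcodes and are
  corrupted by iid per-base substitutions and indels plus a chimera
  probability that swaps the detection TMI between targets.

All draws come from a seeded ``numpy.random.Generator``; the same seed
reproduces bit-identical panels, counts and reads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .demux import BarcodeManifest, CountMatrix, ReadLayout

BASES = np.array(list("ACGT"))

DEFAULT_INTERNAL_CONTROL = "mCherry"
DEFAULT_IC_MEAN = 10_000.0  # expected internal-control counts at efficiency 1
DEFAULT_SPACERS = ("TCAG", "GATC")


class SimulationError(ValueError):
    """Raised when a simulation request is infeasible or ill-posed."""


# ---------------------------------------------------------------------------
# Panel ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetSpec:
    """Ground truth for one assay target.

    The response in expected counts at antigen concentration ``x`` (molar)
    is ``D + h * A * x^B / (x^B + C^B)`` before well-efficiency scaling,
    where ``D`` is the zero-concentration floor, ``A`` the amplitude,
    ``C`` the half-maximal concentration, ``B`` the Hill slope and ``h``
    the hot-antibody fraction used to attenuate high-abundance targets.
    ``cross_affinity`` maps antigen names to relative affinities in [0, 1]
    (self = 1); off-target entries generate cross-reactive signal.
    """

    name: str
    floor_D: float
    amplitude_A: float
    half_max_C: float
    slope_B: float
    hot_fraction_h: float
    tmi_capture: str
    tmi_detection: str
    cross_affinity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.floor_D < 0:
            raise SimulationError(f"{self.name}: floor_D must be >= 0")
        if self.amplitude_A <= 0 or self.half_max_C <= 0 or self.slope_B <= 0:
            raise SimulationError(f"{self.name}: A, C, B must be positive")
        if not 0 < self.hot_fraction_h <= 1:
            raise SimulationError(f"{self.name}: hot_fraction_h must be in (0, 1]")

    def affinities(self) -> dict[str, float]:
        aff = dict(self.cross_affinity)
        aff.setdefault(self.name, 1.0)
        return aff


@dataclass
class PanelDefinition:
    """A target panel plus its internal-control target and barcode book."""

    targets: list[TargetSpec]
    internal_control: TargetSpec
    barcode_length: int
    min_pairwise_edit_distance: int

    def __post_init__(self) -> None:
        names = [t.name for t in self.all_targets]
        if len(set(names)) != len(names):
            raise SimulationError("target names are not unique")
        tmis = [s for t in self.all_targets
                for s in (t.tmi_capture, t.tmi_detection)]
        if len(set(tmis)) != len(tmis):
            raise SimulationError("TMI sequences are not unique")

    @property
    def all_targets(self) -> list[TargetSpec]:
        return self.targets + [self.internal_control]

    @property
    def internal_control_name(self) -> str:
        return self.internal_control.name

    def target(self, name: str) -> TargetSpec:
        for t in self.all_targets:
            if t.name == name:
                return t
        raise KeyError(name)

    def validate_distances(self) -> None:
        """Check the pairwise edit-distance floor on all TMIs (O(n^2))."""
        tmis = [s for t in self.all_targets
                for s in (t.tmi_capture, t.tmi_detection)]
        for i, a in enumerate(tmis):
            for b in tmis[i + 1:]:
                d = edlib.align(a, b)["editDistance"]
                if d < self.min_pairwise_edit_distance:
                    raise SimulationError(
                        f"TMI pair at edit distance {d} < "
                        f"{self.min_pairwise_edit_distance}")

    def manifest(self, plan: "PlatePlan",
                 spacers: tuple[str, str] = DEFAULT_SPACERS) -> BarcodeManifest:
        layout = make_layout(smi_length=len(plan.wells[0].smi),
                             tmi_length=self.barcode_length, spacers=spacers)
        return BarcodeManifest(
            targets={t.name: (t.tmi_capture, t.tmi_detection)
                     for t in self.all_targets},
            wells={w.well_id: w.smi for w in plan.wells},
            layout=layout,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "barcode_length": self.barcode_length,
            "min_pairwise_edit_distance": self.min_pairwise_edit_distance,
            "internal_control": self.internal_control.__dict__ | {
                "cross_affinity": self.internal_control.cross_affinity},
            "targets": [t.__dict__ | {"cross_affinity": t.cross_affinity}
                        for t in self.targets],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class WellSpec:
    """One well: role, barcodes, efficiency and true antigen concentrations."""

    well_id: str
    role: str  # sample | blank | standard | ipc | sample_control
    smi: str
    efficiency_e: float = 1.0
    standard_level: int | None = None
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in {"sample", "blank", "standard", "ipc",
                             "sample_control"}:
            raise SimulationError(f"unknown well role {self.role!r}")
        if self.efficiency_e <= 0:
            raise SimulationError("efficiency_e must be positive")
        if self.role == "blank" and any(v != 0 for v in
                                        self.concentrations.values()):
            raise SimulationError("blank wells must have zero concentrations")


@dataclass
class PlatePlan:
    wells: list[WellSpec]
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        smis = [w.smi for w in self.wells]
        if len(set(smis)) != len(smis):
            raise SimulationError("SMI sequences are not unique on the plate")
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise SimulationError("well ids are not unique")

    @property
    def well_ids(self) -> list[str]:
        return [w.well_id for w in self.wells]

    def wells_by_role(self, role: str) -> list[WellSpec]:
        return [w for w in self.wells if w.role == role]

    @property
    def ipc_wells(self) -> list[str]:
        return [w.well_id for w in self.wells if w.role == "ipc"]

    def to_tsv(self, path: str | Path) -> None:
        rows = [(w.well_id, w.role,
                 "" if w.standard_level is None else w.standard_level,
                 w.smi) for w in self.wells]
        pd.DataFrame(rows, columns=["well_id", "role", "standard_level",
                                    "smi"]).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class NoiseModel:
    """Count overdispersion and read-error rates.

    ``nb_dispersion`` is the negative-binomial size parameter (variance
    ``mu + mu^2/size``); ``math.inf`` gives Poisson counts.
    ``reads_per_count`` must be a positive integer so read emission is an
    exact multiple of the count matrix.
    """

    nb_dispersion: float = 100.0
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    chimera_rate: float = 0.0
    reads_per_count: int = 1

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate, self.chimera_rate):
            if not 0 <= r < 1:
                raise SimulationError("error rates must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be positive")
        if int(self.reads_per_count) != self.reads_per_count or \
                self.reads_per_count < 1:
            raise SimulationError("reads_per_count must be a positive integer")


NOISELESS = NoiseModel(nb_dispersion=math.inf)


# ---------------------------------------------------------------------------
# Barcode and panel generation
# ---------------------------------------------------------------------------

def _random_barcodes(n: int, length: int, min_distance: int,
                     rng: np.random.Generator,
                     avoid: Sequence[str] = (),
                     max_draws_per_barcode: int = 2000) -> list[str]:
    if n > 1 and min_distance > length:
        raise SimulationError(
            f"min edit distance {min_distance} cannot be achieved between "
            f"distinct barcodes of length {length}")
    accepted: list[str] = list(avoid)
    out: list[str] = []
    draws = 0
    budget = max_draws_per_barcode * n
    while len(out) < n:
        if draws >= budget:
            raise SimulationError(
                f"could not place {n} barcodes of length {length} at pairwise "
                f"edit distance >= {min_distance} after {budget} draws; "
                "increase barcode_length or relax min_distance")
        draws += 1
        cand = "".join(rng.choice(BASES, size=length))
        if all(edlib.align(cand, b, k=min_distance - 1)["editDistance"] < 0
               for b in accepted):
            accepted.append(cand)
            out.append(cand)
    return out


def make_panel(n_targets: int, seed: int, barcode_length: int = 12,
               min_distance: int = 5,
               half_max_range: tuple[float, float] = (1e-16, 1e-9),
               amplitude_range: tuple[float, float] = (2e3, 5e4),
               floor_range: tuple[float, float] = (5.0, 50.0),
               slope_range: tuple[float, float] = (0.8, 1.5),
               attenuated_fraction: float = 0.15,
               internal_control_name: str = DEFAULT_INTERNAL_CONTROL,
               ) -> PanelDefinition:
    """Draw a ground-truth panel with distance-separated barcodes.

    Half-maximal concentrations are log-spaced (with jitter) across
    ``half_max_range`` so the panel spans >= 6 decades of abundance, as a
    broad plasma-protein panel does.  The most abundant targets (the top
    ``attenuated_fraction`` by half-max concentration) get a hot fraction
    below 1, emulating hot/cold signal attenuation.
    """
    if n_targets < 1:
        raise SimulationError("n_targets must be >= 1")
    rng = np.random.default_rng(seed)
    barcodes = _random_barcodes(2 * (n_targets + 1), barcode_length,
                                min_distance, rng)
    lo, hi = (math.log10(half_max_range[0]), math.log10(half_max_range[1]))
    if n_targets == 1:
        log_c = np.array([(lo + hi) / 2.0])
    else:
        log_c = np.linspace(lo, hi, n_targets) + \
            rng.uniform(-0.2, 0.2, n_targets)
    order = rng.permutation(n_targets)  # decouple index from abundance
    log_c = log_c[order]
    n_hot = int(round(attenuated_fraction * n_targets))
    hot = np.ones(n_targets)
    if n_hot:
        top = np.argsort(log_c)[-n_hot:]  # highest-abundance targets
        hot[top] = rng.uniform(0.02, 0.5, n_hot)
    targets = []
    for i in range(n_targets):
        targets.append(TargetSpec(
            name=f"T{i + 1:03d}",
            floor_D=float(rng.uniform(*floor_range)),
            amplitude_A=float(10 ** rng.uniform(math.log10(amplitude_range[0]),
                                                math.log10(amplitude_range[1]))),
            half_max_C=float(10 ** log_c[i]),
            slope_B=float(rng.uniform(*slope_range)),
            hot_fraction_h=float(hot[i]),
            tmi_capture=barcodes[2 * i],
            tmi_detection=barcodes[2 * i + 1],
        ))
    ic = TargetSpec(name=internal_control_name, floor_D=0.0,
                    amplitude_A=DEFAULT_IC_MEAN, half_max_C=1.0,
                    slope_B=1.0, hot_fraction_h=1.0,
                    tmi_capture=barcodes[-2], tmi_detection=barcodes[-1])
    return PanelDefinition(targets=targets, internal_control=ic,
                           barcode_length=barcode_length,
                           min_pairwise_edit_distance=min_distance)


def make_layout(smi_length: int, tmi_length: int,
                spacers: tuple[str, str] = DEFAULT_SPACERS) -> ReadLayout:
    s1, s2 = spacers
    start_cap = smi_length + len(s1)
    return ReadLayout(
        smi_span=(0, smi_length),
        tmi_capture_span=(start_cap, tmi_length),
        tmi_detection_span=(start_cap + tmi_length, tmi_length),
        spacers=(s1, s2),
    )


def make_plate_plan(panel: PanelDefinition, seed: int,
                    n_wells: int = 96, n_blanks: int = 3, n_ipc: int = 3,
                    n_sample_controls: int = 2,
                    smi_length: int = 10, smi_min_distance: int = 5,
                    efficiency_sigma: float = 0.15,
                    sample_log10_spread: float = 1.0,
                    plate_id: str = "plate1") -> PlatePlan:
    """Default plate: blanks, IPC wells, sample controls, then samples.

    IPC wells share a fixed pooled composition (every antigen at its
    half-max concentration) so their per-target medians are stable anchors
    for inter-plate normalization.  Sample wells draw each antigen
    log-normally around its half-max concentration.
    """
    if n_blanks + n_ipc + n_sample_controls > n_wells:
        raise SimulationError("more control wells than wells on the plate")
    rng = np.random.default_rng(seed)
    smis = _random_barcodes(n_wells, smi_length, smi_min_distance, rng)
    ipc_conc = {t.name: t.half_max_C for t in panel.targets}
    control_conc = {t.name: t.half_max_C * 0.5 for t in panel.targets}
    wells: list[WellSpec] = []
    roles = (["blank"] * n_blanks + ["ipc"] * n_ipc
             + ["sample_control"] * n_sample_controls)
    roles += ["sample"] * (n_wells - len(roles))
    for i, role in enumerate(roles):
        row, col = divmod(i, 12)
        well_id = f"{chr(ord('A') + row)}{col + 1:02d}"
        e = float(np.exp(rng.normal(0.0, efficiency_sigma)))
        if role == "blank":
            conc: dict[str, float] = {t.name: 0.0 for t in panel.targets}
        elif role == "ipc":
            conc = dict(ipc_conc)
        elif role == "sample_control":
            conc = dict(control_conc)
        else:
            conc = {t.name: float(t.half_max_C *
                                  10 ** rng.normal(0.0, sample_log10_spread))
                    for t in panel.targets}
        wells.append(WellSpec(well_id=well_id, role=role, smi=smis[i],
                              efficiency_e=e, concentrations=conc))
    return PlatePlan(wells=wells, plate_id=plate_id)


# ---------------------------------------------------------------------------
# Expected counts and count simulation
# ---------------------------------------------------------------------------

def expected_counts(target: TargetSpec, well: WellSpec) -> float:
    """Expected counts for one (target, well) under the logistic model.

    ``e_w * (D + h * A * sum_a K_a * x_a^B / (x_a^B + C^B))`` summed over
    antigens with nonzero cross-affinity ``K_a`` present in the well.
    """
    bound = 0.0
    B, C = target.slope_B, target.half_max_C
    for antigen, k in target.affinities().items():
        if k == 0.0:
            continue
        x = well.concentrations.get(antigen, 0.0)
        if x > 0:
            xb = x ** B
            bound += k * xb / (xb + C ** B)
    return well.efficiency_e * (target.floor_D +
                                target.hot_fraction_h * target.amplitude_A * bound)


def _draw_counts(mu: np.ndarray, dispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if math.isinf(dispersion):
        return rng.poisson(mu).astype(np.int64)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p).astype(np.int64)


def simulate_counts(panel: PanelDefinition, plan: PlatePlan,
                    noise: NoiseModel = NoiseModel(), seed: int = 0,
                    ic_mean: float = DEFAULT_IC_MEAN) -> CountMatrix:
    """Draw the (target x well) count matrix, including the internal control.

    Counts are negative-binomial around ``expected_counts``; the internal
    control draws around ``efficiency_e * ic_mean`` in every well.
    """
    rng = np.random.default_rng(seed)
    names = [t.name for t in panel.all_targets]
    mu = np.empty((len(names), len(plan.wells)))
    for i, t in enumerate(panel.targets):
        for j, w in enumerate(plan.wells):
            mu[i, j] = expected_counts(t, w)
    mu[-1, :] = [w.efficiency_e * ic_mean for w in plan.wells]
    counts = _draw_counts(mu, noise.nb_dispersion, rng)
    out = CountMatrix.zeros(names, plan.well_ids)
    out.counts.iloc[:, :] = counts
    return out


def expected_count_matrix(panel: PanelDefinition, plan: PlatePlan,
                          ic_mean: float = DEFAULT_IC_MEAN) -> pd.DataFrame:
    """Noiseless expectation of :func:`simulate_counts` (real-valued)."""
    names = [t.name for t in panel.all_targets]
    mu = np.empty((len(names), len(plan.wells)))
    for i, t in enumerate(panel.targets):
        for j, w in enumerate(plan.wells):
            mu[i, j] = expected_counts(t, w)
    mu[-1, :] = [w.efficiency_e * ic_mean for w in plan.wells]
    return pd.DataFrame(mu, index=pd.Index(names, name="target"),
                        columns=pd.Index(plan.well_ids, name="well"))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _corrupt(read: str, sub_rate: float, indel_rate: float,
             rng: np.random.Generator) -> str:
    """Apply iid per-base substitutions, then insertions/deletions."""
    arr = list(read)
    if sub_rate > 0:
        n = len(arr)
        hits = np.nonzero(rng.random(n) < sub_rate)[0]
        for i in hits:
            alternatives = [b for b in "ACGT" if b != arr[i]]
            arr[i] = alternatives[rng.integers(3)]
    if indel_rate > 0:
        out = []
        for b in arr:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            if r < indel_rate:
                out.append("ACGT"[rng.integers(4)])  # insertion before base
            out.append(b)
        arr = out
    return "".join(arr)


def simulate_reads(counts: CountMatrix, panel: PanelDefinition,
                   plan: PlatePlan, noise: NoiseModel = NoiseModel(),
                   seed: int = 0,
                   spacers: tuple[str, str] = DEFAULT_SPACERS):
    """Yield read sequences for every count unit.

    Read layout is ``[SMI][spacer][TMI_capture][TMI_detection][spacer]``.
    Each count unit emits ``reads_per_count`` reads; with probability
    ``chimera_rate`` a read carries the detection TMI of a different
    target.  Substitutions and indels apply per base across the whole read.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = spacers
    smi_of = {w.well_id: w.smi for w in plan.wells}
    specs = {t.name: t for t in panel.all_targets}
    names = list(counts.counts.index)
    other = {n: [m for m in names if m != n] for n in names}
    noisy = (noise.substitution_rate > 0 or noise.indel_rate > 0)
    rpc = int(noise.reads_per_count)
    for target_name, row in counts.counts.iterrows():
        t = specs[target_name]
        for well_id, c in row.items():
            if c <= 0:
                continue
            smi = smi_of[well_id]
            base = smi + s1 + t.tmi_capture + t.tmi_detection + s2
            for _ in range(int(c) * rpc):
                read = base
                if noise.chimera_rate > 0 and rng.random() < noise.chimera_rate:
                    donor = specs[other[target_name][
                        rng.integers(len(other[target_name]))]]
                    read = smi + s1 + t.tmi_capture + donor.tmi_detection + s2
                if noisy:
                    read = _corrupt(read, noise.substitution_rate,
                                    noise.indel_rate, rng)
                yield read


def write_fastq(reads: Iterable[str], path: str | Path) -> int:
    """Write reads as 4-line FASTQ records with placeholder qualities."""
    n = 0
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Dilution series
# ---------------------------------------------------------------------------

def simulate_dilution_series(target: TargetSpec, top_conc: float,
                             fold: float = 10.0, n_levels: int = 12,
                             n_reps: int = 3, n_blanks: int = 3,
                             noise: NoiseModel = NoiseModel(), seed: int = 0,
                             ic_mean: float = DEFAULT_IC_MEAN,
                             internal_control: TargetSpec | None = None,
                             ) -> tuple[PlatePlan, CountMatrix]:
    """Standards at ``top_conc / fold**k`` (k = 0..n_levels-1) plus blanks.

    Every level and the blank set gets ``n_reps`` / ``n_blanks`` replicate
    wells.  Blanks are required: without them the blank-based limit of
    detection is undefined downstream.
    """
    if n_levels < 4:
        raise SimulationError("need >= 4 dilution levels for 4PL fitting")
    if fold <= 1:
        raise SimulationError("fold must be > 1")
    if n_blanks < 1:
        raise SimulationError(
            "n_blanks must be >= 1: blank wells define the limit of detection")
    rng = np.random.default_rng(seed)
    if internal_control is not None:
        ic = internal_control
    else:
        # draw control barcodes distinct from the target's own TMIs
        ic_tmis = _random_barcodes(
            2, len(target.tmi_capture), 1, rng,
            avoid=[target.tmi_capture, target.tmi_detection])
        ic = TargetSpec(
            name=DEFAULT_INTERNAL_CONTROL, floor_D=0.0, amplitude_A=ic_mean,
            half_max_C=1.0, slope_B=1.0, hot_fraction_h=1.0,
            tmi_capture=ic_tmis[0], tmi_detection=ic_tmis[1])
    panel = PanelDefinition(targets=[target], internal_control=ic,
                            barcode_length=len(target.tmi_capture),
                            min_pairwise_edit_distance=1)
    n_wells = n_levels * n_reps + n_blanks
    smis = _random_barcodes(n_wells, 10, 3, rng)
    wells = []
    k = 0
    for level in range(n_levels):
        conc = top_conc / fold ** level
        for rep in range(n_reps):
            wells.append(WellSpec(
                well_id=f"S{level + 1:02d}r{rep + 1}", role="standard",
                smi=smis[k], standard_level=level + 1,
                concentrations={target.name: conc}))
            k += 1
    for rep in range(n_blanks):
        wells.append(WellSpec(well_id=f"B_r{rep + 1}", role="blank",
                              smi=smis[k],
                              concentrations={target.name: 0.0}))
        k += 1
    plan = PlatePlan(wells=wells, plate_id="dilution")
    counts = simulate_counts(panel, plan, noise=noise,
                             seed=int(rng.integers(2 ** 31)), ic_mean=ic_mean)
    return plan, counts
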