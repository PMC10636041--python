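"""Normalization cascade for multiplexed immunoassay count matrices.

The cascade is raw counts -> internal-control (IC) normalization within a
plate -> one of two inter-plate steps:

* inter-plate control (IPC) normalization, whose log2 output is the NPQ
  (normalized protein quantification) unit used for statistics, or
* intensity normalization (IN), which rescales every plate's per-target
  median onto the global per-target median.

A fourth utility converts single-plex qPCR quantification cycles to the
linear "normalized signal" scale used for standard-curve fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .demux import CountMatrix

IPC_RESCALE = 1e4
CQ_OFFSET = 37.0

STAGES = ("IC", "NPQ", "IN", "IN_log2")


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """A (target x well) matrix tagged with its normalization stage.

    ``NPQ`` and ``IN_log2`` values are log2-scale; ``IC`` and ``IN`` are
    linear.
    """

    values: pd.DataFrame
    stage: str
    plate_id: str = "plate1"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise NormalizationError(f"unknown stage {self.stage!r}")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def ic_normalize(counts: CountMatrix,
                 internal_control: str = "mCherry",
                 plate_id: str = "plate1") -> NormalizedMatrix:
    """Divide (counts + 1) by the well's (internal-control counts + 1).

    The +1 offsets keep zero-count cells finite and make an all-zero well
    normalize to exactly 1.  The internal-control row is consumed by the
    operation and removed from the output.
    """
    if internal_control not in counts.counts.index:
        raise NormalizationError(
            f"internal-control row {internal_control!r} missing from counts")
    ic_row = counts.counts.loc[internal_control].astype(float)
    values = (counts.counts.drop(index=internal_control) + 1.0).div(
        ic_row + 1.0, axis=1)
    assert (values.to_numpy() > 0).all()
    return NormalizedMatrix(values=values, stage="IC", plate_id=plate_id)


def ipc_normalize(ic: NormalizedMatrix,
                  ipc_wells: Sequence[str]) -> NormalizedMatrix:
    """IC-normalized values -> NPQ (log2 IPC-normalized, rescaled by 1e4).

    ``NPQ[t, w] = log2(ic[t, w] / median_{w' in ipc_wells} ic[t, w'] * 1e4)``.
    A well sitting exactly at the per-target IPC median thus has
    NPQ = log2(1e4) ~ 13.2877.
    """
    if ic.stage != "IC":
        raise NormalizationError("ipc_normalize expects an IC-stage matrix")
    ipc_wells = list(ipc_wells)
    if not ipc_wells:
        raise NormalizationError("need at least one IPC well")
    missing = [w for w in ipc_wells if w not in ic.values.columns]
    if missing:
        raise NormalizationError(f"IPC wells not in matrix: {missing}")
    med = ic.values[ipc_wells].median(axis=1)
    bad = med.index[~(med > 0)]
    if len(bad):
        raise NormalizationError(
            f"zero or undefined IPC median for target(s): {list(bad)}")
    values = np.log2(ic.values.div(med, axis=0) * IPC_RESCALE)
    return NormalizedMatrix(values=values, stage="NPQ", plate_id=ic.plate_id)


def intensity_normalize(plates: Iterable[NormalizedMatrix],
                        log2_output: bool = False) -> list[NormalizedMatrix]:
    """Rescale each plate's per-target median onto the global median.

    ``IN[t, w] = ic[t, w] / median_plate(t) * median_global(t)`` where the
    plate median is over that plate's wells and the global median is over
    all wells of all plates.  With a single plate the operation is the
    identity.  The step is idempotent: per-target plate medians already
    equal the global median after one application.
    """
    plates = list(plates)
    if not plates:
        raise NormalizationError("no plates given")
    for p in plates:
        # IN output is accepted again: the step is idempotent on the
        # linear scale
        if p.stage not in ("IC", "IN"):
            raise NormalizationError(
                "intensity_normalize expects linear-scale (IC or IN) input")
    targets = plates[0].values.index
    for p in plates[1:]:
        if not p.values.index.equals(targets):
            raise NormalizationError("plates do not share a target set")
    global_med = pd.concat([p.values for p in plates], axis=1).median(axis=1)
    out = []
    for p in plates:
        plate_med = p.values.median(axis=1)
        if (plate_med <= 0).any():
            bad = list(plate_med.index[plate_med <= 0])
            raise NormalizationError(f"zero plate median for target(s): {bad}")
        values = p.values.div(plate_med, axis=0).mul(global_med, axis=0)
        stage = "IN"
        if log2_output:
            values = np.log2(values)
            stage = "IN_log2"
        out.append(NormalizedMatrix(values=values, stage=stage,
                                    plate_id=p.plate_id))
    return out


def cq_to_signal(cq):
    """qPCR quantification cycle -> linear normalized signal 2**(37 - Cq)."""
    return 2.0 ** (CQ_OFFSET - np.asarray(cq, dtype=float)) if \
        not np.isscalar(cq) else 2.0 ** (CQ_OFFSET - cq)
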