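"""Error-tolerant demultiplexing of barcoded immunoassay reads.

Each sequencing read from an NGS-readout multiplexed immunoassay carries a
sample barcode (SMI) identifying the well and a pair of target barcodes
(TMIs) identifying the antibody pair that formed the reporter.  A read is
counted for a target in a well only when the SMI and *both* TMIs are
recognized and the two TMIs belong to the same target; TMI pairs from two
different targets indicate an antigen-independent ligation or PCR artifact
and are tallied as chimeric.

Barcode recognition tolerates up to two substitutions, or one indel plus
one substitution, per barcode field.  Ties between candidate barcodes are
never broken arbitrarily: a read whose observed barcode is equally close to
two references is dropped as ambiguous.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import edlib
import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

# Indel cost in the weighted alignment DP.  Any value larger than the
# longest barcode makes the scalar cost order lexicographic in
# (indels, substitutions), which is what the acceptance rule needs.
_INDEL_COST = 1024

MAX_SUBSTITUTIONS = 2   # accepted alone
MAX_INDEL_COMBO = (1, 1)  # one indel may be combined with one substitution


class DemuxError(ValueError):
    """Raised for inconsistent manifests or layouts."""


@dataclass(frozen=True)
class EditProfile:
    """Alignment summary: number of substitutions and indels (unit costs)."""

    substitutions: int
    indels: int

    def __post_init__(self) -> None:
        if self.substitutions < 0 or self.indels < 0:
            raise ValueError("EditProfile counts must be nonnegative")


def accept(profile: EditProfile) -> bool:
    """Barcode acceptance envelope.

    A barcode match is accepted with up to two substitutions and no indel,
    or with one indel and at most one substitution.
    """
    if profile.indels == 0:
        return profile.substitutions <= MAX_SUBSTITUTIONS
    if profile.indels == 1:
        return profile.substitutions <= 1
    return False


def edit_profile(observed: str, reference: str) -> EditProfile:
    """Minimal (indels, substitutions) profile over all global alignments.

    Indels are minimized first, then substitutions, with unit costs.  ``N``
    bases match nothing and always count as substitutions.
    """
    if not observed or not reference:
        raise ValueError("edit_profile requires nonempty sequences")
    n, m = len(observed), len(reference)
    # Weighted Needleman-Wunsch; the indel weight dominates so the scalar
    # optimum is the lexicographic (indels, substitutions) optimum.
    prev = np.arange(m + 1, dtype=np.int64) * _INDEL_COST
    cur = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        oi = observed[i - 1]
        cur[0] = i * _INDEL_COST
        for j in range(1, m + 1):
            sub = 0 if (oi == reference[j - 1] and oi != "N") else 1
            cur[j] = min(prev[j - 1] + sub,
                         prev[j] + _INDEL_COST,
                         cur[j - 1] + _INDEL_COST)
        prev, cur = cur, prev
    cost = int(prev[m])
    return EditProfile(substitutions=cost % _INDEL_COST,
                       indels=cost // _INDEL_COST)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one observed barcode against a candidate set."""

    name: str | None
    profile: EditProfile | None
    status: str  # "assigned" | "unassigned" | "ambiguous"


def match_barcode(observed: str, candidates: Mapping[str, str]) -> MatchResult:
    """Best accepted candidate under the (indels, substitutions) cost.

    ``candidates`` maps barcode sequence to label.  Returns ``status
    "ambiguous"`` when two candidates tie at the minimal cost, and
    ``"unassigned"`` when no candidate is accepted.
    """
    if not candidates:
        raise DemuxError("candidate set is empty")
    hit = candidates.get(observed)
    if hit is not None:
        return MatchResult(hit, EditProfile(0, 0), "assigned")
    best: tuple[int, int] | None = None
    best_name: str | None = None
    tied = False
    for seq, name in candidates.items():
        # Any accepted profile has total edit distance <= 2; edlib's banded
        # search rejects hopeless candidates cheaply before the exact DP.
        if edlib.align(observed, seq, k=2)["editDistance"] < 0:
            continue
        prof = edit_profile(observed, seq)
        if not accept(prof):
            continue
        key = (prof.indels, prof.substitutions)
        if best is None or key < best:
            best, best_name, tied = key, name, False
        elif key == best:
            tied = True
    if best is None:
        return MatchResult(None, None, "unassigned")
    if tied:
        return MatchResult(None, EditProfile(best[1], best[0]), "ambiguous")
    return MatchResult(best_name, EditProfile(best[1], best[0]), "assigned")


@dataclass(frozen=True)
class ReadLayout:
    """Fixed positions of the barcode fields within a read.

    Spans are (start, length) pairs; the spacer sequences between fields are
    recorded so simulated reads and manifests stay self-describing.
    """

    smi_span: tuple[int, int]
    tmi_capture_span: tuple[int, int]
    tmi_detection_span: tuple[int, int]
    spacers: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        spans = sorted([self.smi_span, self.tmi_capture_span,
                        self.tmi_detection_span])
        for (s1, l1), (s2, _) in zip(spans, spans[1:]):
            if s1 + l1 > s2:
                raise DemuxError("read layout spans overlap")

    @property
    def total_length(self) -> int:
        return max(s + l for s, l in (self.smi_span, self.tmi_capture_span,
                                      self.tmi_detection_span)) + len(self.spacers[1])

    def extract(self, read: str) -> tuple[str, str, str]:
        s = self.smi_span
        c = self.tmi_capture_span
        d = self.tmi_detection_span
        return (read[s[0]:s[0] + s[1]],
                read[c[0]:c[0] + c[1]],
                read[d[0]:d[0] + d[1]])


@dataclass
class BarcodeManifest:
    """Barcode book for one plate: target TMI pairs and per-well SMIs."""

    targets: dict[str, tuple[str, str]]  # name -> (tmi_capture, tmi_detection)
    wells: dict[str, str]                # well_id -> smi
    layout: ReadLayout

    def __post_init__(self) -> None:
        tmis = [t for pair in self.targets.values() for t in pair]
        if len(set(tmis)) != len(tmis):
            raise DemuxError("TMI sequences are not unique across the manifest")
        if len(set(self.wells.values())) != len(self.wells):
            raise DemuxError("SMI sequences are not unique within the plate")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(n, c, d) for n, (c, d) in self.targets.items()],
            columns=["target", "tmi_capture", "tmi_detection"],
        )
        df.to_csv(path, sep="\t", index=False)

    @staticmethod
    def wells_to_tsv(wells: Mapping[str, str], path: str | Path) -> None:
        pd.DataFrame(list(wells.items()), columns=["well_id", "smi"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class CountMatrix:
    """Integer counts per (target, well) plus per-well rejection tallies.

    ``counts`` rows include the internal-control target.  Reads whose sample
    barcode cannot be resolved have no well to charge, so those are kept in
    the plate-level ``unassigned_no_well`` / ``ambiguous_no_well`` tallies;
    together with the per-well tallies the total equals the number of reads
    processed.
    """

    counts: pd.DataFrame
    unassigned: pd.Series
    ambiguous: pd.Series
    chimeric: pd.Series
    unassigned_no_well: int = 0
    ambiguous_no_well: int = 0

    @classmethod
    def zeros(cls, targets: Iterable[str], wells: Iterable[str]) -> "CountMatrix":
        targets = list(targets)
        wells = list(wells)
        return cls(
            counts=pd.DataFrame(0, index=pd.Index(targets, name="target"),
                                columns=pd.Index(wells, name="well"), dtype=np.int64),
            unassigned=pd.Series(0, index=list(wells), dtype=np.int64),
            ambiguous=pd.Series(0, index=list(wells), dtype=np.int64),
            chimeric=pd.Series(0, index=list(wells), dtype=np.int64),
        )

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum()
                   + self.unassigned.sum() + self.ambiguous.sum()
                   + self.chimeric.sum()
                   + self.unassigned_no_well + self.ambiguous_no_well)

    def to_tsv(self, path: str | Path, qc_path: str | Path | None = None) -> None:
        self.counts.to_csv(path, sep="\t")
        if qc_path is not None:
            qc = pd.DataFrame({"unassigned": self.unassigned,
                               "ambiguous": self.ambiguous,
                               "chimeric": self.chimeric})
            qc.index.name = "well"
            qc.to_csv(qc_path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = "target"
        counts.columns.name = "well"
        wells = list(counts.columns)
        zero = pd.Series(0, index=wells, dtype=np.int64)
        return cls(counts=counts.astype(np.int64), unassigned=zero.copy(),
                   ambiguous=zero.copy(), chimeric=zero.copy())


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a plain or gzipped FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            yield seq


def demux(reads: Iterable[str] | str | Path,
          manifest: BarcodeManifest) -> CountMatrix:
    """Count reads per (target, well) with error-tolerant barcode matching.

    A read increments ``counts[target, well]`` only when the SMI and both
    TMIs are each accepted and the two TMIs name the same target.  Mixed
    TMI pairs are chimeric; unmatched or ambiguous fields go to the
    corresponding tally.  Reads shorter than the layout are unassigned.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    layout = manifest.layout
    smi_book = {smi: well for well, smi in manifest.wells.items()}
    cap_book = {pair[0]: name for name, pair in manifest.targets.items()}
    det_book = {pair[1]: name for name, pair in manifest.targets.items()}

    target_names = list(manifest.targets)
    well_names = list(manifest.wells)
    t_idx = {n: i for i, n in enumerate(target_names)}
    w_idx = {w: i for i, w in enumerate(well_names)}
    counts = np.zeros((len(target_names), len(well_names)), dtype=np.int64)
    unassigned = np.zeros(len(well_names), dtype=np.int64)
    ambiguous = np.zeros(len(well_names), dtype=np.int64)
    chimeric = np.zeros(len(well_names), dtype=np.int64)
    unassigned_no_well = 0
    ambiguous_no_well = 0
    min_len = layout.total_length - len(layout.spacers[1])
    short_warned = False

    # Memoize per-field matches: erroneous barcodes repeat across reads.
    smi_cache: dict[str, MatchResult] = {}
    cap_cache: dict[str, MatchResult] = {}
    det_cache: dict[str, MatchResult] = {}

    for read in reads:
        if len(read) < min_len:
            if not short_warned:
                logger.warning("read shorter than layout (%d < %d nt); "
                               "counting such reads as unassigned",
                               len(read), min_len)
                short_warned = True
            smi_obs = read[layout.smi_span[0]:layout.smi_span[0] + layout.smi_span[1]]
            res = smi_cache.get(smi_obs)
            if res is None:
                res = match_barcode(smi_obs, smi_book) if smi_obs else \
                    MatchResult(None, None, "unassigned")
                smi_cache[smi_obs] = res
            if res.status == "assigned":
                unassigned[w_idx[res.name]] += 1
            else:
                unassigned_no_well += 1
            continue
        smi_obs, cap_obs, det_obs = layout.extract(read)

        smi_res = smi_cache.get(smi_obs)
        if smi_res is None:
            smi_res = match_barcode(smi_obs, smi_book)
            smi_cache[smi_obs] = smi_res
        if smi_res.status != "assigned":
            if smi_res.status == "ambiguous":
                ambiguous_no_well += 1
            else:
                unassigned_no_well += 1
            continue
        well = w_idx[smi_res.name]

        cap_res = cap_cache.get(cap_obs)
        if cap_res is None:
            cap_res = match_barcode(cap_obs, cap_book)
            cap_cache[cap_obs] = cap_res
        det_res = det_cache.get(det_obs)
        if det_res is None:
            det_res = match_barcode(det_obs, det_book)
            det_cache[det_obs] = det_res

        if cap_res.status == "ambiguous" or det_res.status == "ambiguous":
            ambiguous[well] += 1
        elif cap_res.status == "unassigned" or det_res.status == "unassigned":
            unassigned[well] += 1
        elif cap_res.name != det_res.name:
            chimeric[well] += 1
        else:
            counts[t_idx[cap_res.name], well] += 1

    return CountMatrix(
        counts=pd.DataFrame(counts,
                            index=pd.Index(target_names, name="target"),
                            columns=pd.Index(well_names, name="well")),
        unassigned=pd.Series(unassigned, index=well_names),
        ambiguous=pd.Series(ambiguous, index=well_names),
        chimeric=pd.Series(chimeric, index=well_names),
        unassigned_no_well=unassigned_no_well,
        ambiguous_no_well=ambiguous_no_well,
    )
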