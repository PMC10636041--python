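"""Precision, detectability, confidence-interval and cross-reactivity QC.

These statistics summarize how well a multiplexed immunoassay panel
performs: replicate coefficients of variation on the linear scale (with a
log2-scale conversion for platforms that only report log-scale data),
the fraction of real samples above the limit of detection, exact binomial
confidence intervals for detectability proportions, and the pooled-antigen
cross-reactivity score with its pool-deconvolution rule.  A small utility
bins longitudinal samples relative to the day of peak viral-antigen load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta

from .pools import PoolDesign

DETECTABILITY_CUTOFF = 50.0  # percent of samples above LOD, strict


class QCError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Coefficients of variation
# ---------------------------------------------------------------------------

def cv_linear(values: Sequence[float]) -> float:
    """Percent CV of unlogged values: 100 * sd / mean (sample sd, n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise QCError("CV needs at least two values")
    m = v.mean()
    if m <= 0:
        raise QCError("CV undefined for non-positive mean")
    return 100.0 * v.std(ddof=1) / m


def cv_from_log2(sd_log2: float) -> float:
    """Geometric CV from a log2-scale standard deviation.

    For lognormal data with natural-log sd sigma, the linear-scale CV is
    ``100 * sqrt(exp(sigma**2) - 1)``; a standard deviation measured on
    the log2 scale converts as ``sigma = sd_log2 * ln 2``.
    """
    if sd_log2 < 0:
        raise QCError("standard deviation must be nonnegative")
    sigma = sd_log2 * math.log(2.0)
    return 100.0 * math.sqrt(math.expm1(sigma * sigma))


@dataclass
class PrecisionReport:
    """Per-target mean replicate CV with exclusion bookkeeping."""

    table: pd.DataFrame  # columns: cv_percent, n_groups, n_values, n_excluded
    scope: str  # "intra" | "inter"


def precision(matrix: pd.DataFrame,
              replicate_groups: Mapping[str, Sequence[str]],
              lods: Mapping[str, float] | pd.Series | None = None,
              scope: str = "intra") -> PrecisionReport:
    """Mean per-target CV across replicate groups of wells.

    ``matrix`` holds unlogged normalized values (targets x wells);
    ``replicate_groups`` maps a group label to its member wells.  Values
    at or below the target's LOD are excluded before computing each
    group's CV; groups left with fewer than two values contribute nothing.
    Targets with no usable group are reported with a missing CV.
    """
    if scope not in ("intra", "inter"):
        raise QCError("scope must be 'intra' or 'inter'")
    rows = {}
    for target in matrix.index:
        lod_t = None if lods is None else float(
            lods[target] if not isinstance(lods, Mapping) else lods[target])
        cvs = []
        n_values = 0
        n_excluded = 0
        for wells in replicate_groups.values():
            vals = matrix.loc[target, list(wells)].to_numpy(dtype=float)
            if lod_t is not None:
                keep = vals > lod_t
                n_excluded += int((~keep).sum())
                vals = vals[keep]
            n_values += vals.size
            if vals.size >= 2:
                cvs.append(cv_linear(vals))
        rows[target] = {
            "cv_percent": float(np.mean(cvs)) if cvs else float("nan"),
            "n_groups": len(cvs),
            "n_values": n_values,
            "n_excluded": n_excluded,
        }
    return PrecisionReport(table=pd.DataFrame.from_dict(rows, orient="index"),
                           scope=scope)


# ---------------------------------------------------------------------------
# Detectability
# ---------------------------------------------------------------------------

@dataclass
class DetectabilityReport:
    table: pd.DataFrame  # columns: percent_above_lod, n_samples, detectable

    @property
    def n_detectable(self) -> int:
        return int(self.table["detectable"].sum())


def detectability(npq: pd.DataFrame,
                  plate_lods: pd.DataFrame,
                  well_to_plate: Mapping[str, str]) -> DetectabilityReport:
    """Percent of sample wells above their plate-specific LOD, per target.

    ``plate_lods`` is (targets x plates) on the same scale as ``npq``.
    A target is detectable when strictly more than 50% of samples lie
    strictly above the LOD.
    """
    missing = [w for w in npq.columns if w not in well_to_plate]
    if missing:
        raise QCError(f"wells with no plate assignment: {missing}")
    plates = [well_to_plate[w] for w in npq.columns]
    for t in npq.index:
        if t not in plate_lods.index:
            raise QCError(f"no LOD for target {t!r}")
    for p in set(plates):
        if p not in plate_lods.columns:
            raise QCError(f"no LODs for plate {p!r}")
    lod_mat = plate_lods.loc[npq.index, plates].to_numpy()
    above = npq.to_numpy() > lod_mat
    percent = 100.0 * above.sum(axis=1) / npq.shape[1]
    table = pd.DataFrame({
        "percent_above_lod": percent,
        "n_samples": npq.shape[1],
        "detectable": percent > DETECTABILITY_CUTOFF,
    }, index=npq.index)
    return DetectabilityReport(table=table)


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, in percent.

    lower = BetaInv(alpha/2; x, n-x+1), upper = BetaInv(1-alpha/2; x+1, n-x),
    with the conventional closures lower=0 at x=0 and upper=100 at x=n.
    """
    if n < 1 or not 0 <= x <= n:
        raise QCError("need 0 <= x <= n with n >= 1")
    lower = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return 100.0 * lower, 100.0 * upper


# ---------------------------------------------------------------------------
# Cross-reactivity
# ---------------------------------------------------------------------------

@dataclass
class CrossReactivityResult:
    target: str
    score_percent: float | None
    max_nontarget: float
    mean_target: float
    background: float
    flags: list[str] = field(default_factory=list)


def cross_reactivity_score(target: str,
                           pool_signals: Mapping[str, float],
                           target_pools: Sequence[str]) -> CrossReactivityResult:
    """Cross-reactivity of one assay across pooled-antigen samples.

    ``score = (max nontarget signal - background) /
    (mean target signal - background) * 100`` where background is the
    median signal over nontarget pools.  Undefined (assay failed) when the
    mean target signal does not exceed background.
    """
    target_pools = list(target_pools)
    if len(target_pools) < 2:
        raise QCError("need >= 2 target pools")
    nontarget = {p: s for p, s in pool_signals.items()
                 if p not in target_pools}
    if len(nontarget) < 3:
        raise QCError("need >= 3 nontarget pools")
    missing = [p for p in target_pools if p not in pool_signals]
    if missing:
        raise QCError(f"missing signals for target pools: {missing}")
    bg = float(np.median(list(nontarget.values())))
    max_nt = float(max(nontarget.values()))
    mean_t = float(np.mean([pool_signals[p] for p in target_pools]))
    if mean_t <= bg:
        return CrossReactivityResult(target, None, max_nt, mean_t, bg,
                                     flags=["assay_failed"])
    score = 100.0 * (max_nt - bg) / (mean_t - bg)
    return CrossReactivityResult(target, score, max_nt, mean_t, bg)


def identify_cross_reactant(hit_pools: Sequence[str],
                            design: PoolDesign) -> str | None:
    """Deconvolve elevated pools to the unique shared protein.

    Every protein occurs in exactly two pools (one per set) and is the
    only protein those two pools share, so exactly two hit pools -- one
    from each set -- sharing exactly one protein identify it.  Any other
    hit pattern returns ``None``.
    """
    hits = list(dict.fromkeys(hit_pools))
    if len(hits) != 2:
        return None
    members = []
    sets = []
    for pool_id in hits:
        found = design.pool_members(pool_id)
        if found is None:
            return None
        members.append(found)
        sets.append(design.pool_set(pool_id))
    if sets[0] == sets[1]:
        return None
    shared = set(members[0]) & set(members[1])
    if len(shared) == 1:
        return shared.pop()
    return None


# ---------------------------------------------------------------------------
# Longitudinal time binning
# ---------------------------------------------------------------------------

def time_bin(day_offset: int) -> str:
    """Bin a sampling day relative to the peak viral-antigen day (day 0).

    Day 0 is ``t0``; 2-7 days before is ``t-1``; 2-7 days after is ``t1``;
    8-20 days after is ``t2``.  Offsets in the gaps (e.g. +/-1 day) or
    beyond the windows are unclassified.
    """
    d = int(day_offset)
    if d == 0:
        return "t0"
    if -7 <= d <= -2:
        return "t-1"
    if 2 <= d <= 7:
        return "t1"
    if 8 <= d <= 20:
        return "t2"
    return "unclassified"
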