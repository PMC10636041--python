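"""Two-set antigen pooling design for cross-reactivity screening.

All panel targets are partitioned twice into pools of four or five
antigens.  The second partition is constrained so that no two targets
share a pool in both partitions; every target then appears in exactly two
pools (one per set) and is the *only* protein those two pools share.
That pair-uniqueness property is what lets a cross-reacting protein be
read off directly from the two elevated pools.  Additional "homolog"
pools of off-panel proteins may be appended for homology screening.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_POOL_CONC_PM = 20.0  # antigen concentration per pool, picomolar


class PoolDesignError(ValueError):
    pass


@dataclass
class PoolDesign:
    """Two constrained partitions of the target list, plus homolog pools.

    Pool ids are ``S1_P01 ... S1_P45`` and ``S2_P01 ...`` for the two
    sets and ``H1 ...`` for homolog pools.
    """

    set1: list[list[str]]
    set2: list[list[str]]
    homolog_pools: list[list[str]] = field(default_factory=list)
    concentration_pM: float = DEFAULT_POOL_CONC_PM

    def __post_init__(self) -> None:
        self._index: dict[str, tuple[str, list[str]]] = {}
        for set_name, pools in (("set1", self.set1), ("set2", self.set2)):
            prefix = "S1_P" if set_name == "set1" else "S2_P"
            for i, pool in enumerate(pools):
                self._index[f"{prefix}{i + 1:02d}"] = (set_name, list(pool))
        for i, pool in enumerate(self.homolog_pools):
            self._index[f"H{i + 1}"] = ("homolog", list(pool))

    @property
    def pool_ids(self) -> list[str]:
        return list(self._index)

    @property
    def n_pools(self) -> int:
        return len(self._index)

    def pool_members(self, pool_id: str) -> list[str] | None:
        entry = self._index.get(pool_id)
        return None if entry is None else entry[1]

    def pool_set(self, pool_id: str) -> str | None:
        entry = self._index.get(pool_id)
        return None if entry is None else entry[0]

    def pools_of(self, target: str) -> list[str]:
        """The (normally two) pool ids containing a target."""
        return [pid for pid, (_, members) in self._index.items()
                if target in members]

    def membership(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid, (_, members) in self._index.items():
            for t in members:
                out.setdefault(t, []).append(pid)
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = [(pid, set_name, ",".join(members))
                for pid, (set_name, members) in self._index.items()]
        pd.DataFrame(rows, columns=["pool_id", "set", "members"]).to_csv(
            path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "set1": self.set1, "set2": self.set2,
            "homolog_pools": self.homolog_pools,
            "concentration_pM": self.concentration_pM}, indent=2))


def pool_sizes(n_targets: int, n_pools: int) -> list[int]:
    """Pool sizes for one set: as many 5s as the remainder demands, rest 4s."""
    if not 4 * n_pools <= n_targets <= 5 * n_pools:
        raise PoolDesignError(
            f"{n_targets} targets cannot fill {n_pools} pools of 4-5")
    n_fives = n_targets - 4 * n_pools
    return [5] * n_fives + [4] * (n_pools - n_fives)


def _partition(targets: Sequence[str], sizes: Sequence[int],
               rng: np.random.Generator) -> list[list[str]]:
    order = list(rng.permutation(np.array(targets, dtype=object)))
    pools, k = [], 0
    for s in sizes:
        pools.append([str(t) for t in order[k:k + s]])
        k += s
    return pools


def _pairs(pool: Iterable[str]) -> set[frozenset[str]]:
    return {frozenset(p) for p in itertools.combinations(sorted(pool), 2)}


def design_pools(targets: Sequence[str], n_pools: int, seed: int = 0,
                 max_attempts: int = 100_000,
                 homolog_pools: Sequence[Sequence[str]] = (),
                 concentration_pM: float = DEFAULT_POOL_CONC_PM) -> PoolDesign:
    """Randomized two-set design with the no-repeated-pair constraint.

    Set 1 is a uniform random partition into pools of 4-5.  Set 2 starts
    as another random partition and is repaired by swapping targets
    between its pools until no unordered pair of targets co-occurs in
    both sets.  Deterministic given ``seed``.
    """
    targets = [str(t) for t in targets]
    if len(set(targets)) != len(targets):
        raise PoolDesignError("target names must be unique")
    sizes = pool_sizes(len(targets), n_pools)
    # Pigeonhole feasibility: a set-2 pool of size s must draw each member
    # from a different set-1 pool, so s can never exceed the pool count.
    if max(sizes) > n_pools:
        raise PoolDesignError(
            f"pair-uniqueness is infeasible: a pool of {max(sizes)} targets "
            f"needs {max(sizes)} distinct partner pools but only {n_pools} "
            f"exist")
    rng = np.random.default_rng(seed)
    set1 = _partition(targets, sizes, rng)
    forbidden = set().union(*(_pairs(p) for p in set1))
    set2 = _partition(targets, sizes, rng)

    def violations(pool: Sequence[str]) -> list[frozenset[str]]:
        return [pr for pr in _pairs(pool) if pr in forbidden]

    for _attempt in range(max_attempts):
        bad = [(i, v) for i, pool in enumerate(set2)
               if (v := violations(pool))]
        if not bad:
            break
        i, viol = bad[rng.integers(len(bad))]
        a = sorted(viol[rng.integers(len(viol))])[rng.integers(2)]
        j = int(rng.integers(n_pools - 1))
        if j >= i:
            j += 1
        b = set2[j][rng.integers(len(set2[j]))]
        # Swap only if it does not increase the violation count.
        before = len(violations(set2[i])) + len(violations(set2[j]))
        set2[i][set2[i].index(a)], set2[j][set2[j].index(b)] = b, a
        after = len(violations(set2[i])) + len(violations(set2[j]))
        if after > before:
            set2[i][set2[i].index(b)], set2[j][set2[j].index(a)] = a, b
    else:
        raise PoolDesignError(
            f"could not satisfy the pair-uniqueness constraint within "
            f"{max_attempts} swap attempts")

    design = PoolDesign(set1=set1, set2=set2,
                        homolog_pools=[list(p) for p in homolog_pools],
                        concentration_pM=concentration_pM)
    report = validate_design(design, targets)
    if report:
        raise PoolDesignError(f"internal error, invalid design: {report}")
    return design


def validate_design(design: PoolDesign,
                    targets: Sequence[str] | None = None) -> list[str]:
    """Enumerate invariant violations; an empty list means valid.

    Checks: each set partitions the target list, pool sizes are 4 or 5,
    no unordered pair of targets co-occurs in a pool of both sets, and
    every target appears in exactly two pools across the two sets.
    """
    problems: list[str] = []
    flat1 = [t for p in design.set1 for t in p]
    flat2 = [t for p in design.set2 for t in p]
    if targets is None:
        targets = sorted(set(flat1))
    for name, flat in (("set1", flat1), ("set2", flat2)):
        if sorted(flat) != sorted(targets):
            problems.append(f"{name} is not a partition of the target list")
    for name, pools in (("set1", design.set1), ("set2", design.set2)):
        for i, p in enumerate(pools):
            if len(p) not in (4, 5):
                problems.append(f"{name} pool {i} has size {len(p)}")
            if len(set(p)) != len(p):
                problems.append(f"{name} pool {i} has duplicate members")
    pairs1 = set().union(*(_pairs(p) for p in design.set1)) if design.set1 else set()
    pairs2 = set().union(*(_pairs(p) for p in design.set2)) if design.set2 else set()
    for pr in sorted(pairs1 & pairs2, key=sorted):
        problems.append(f"pair {sorted(pr)} co-occurs in both sets")
    counts = {}
    for t in flat1 + flat2:
        counts[t] = counts.get(t, 0) + 1
    for t, c in counts.items():
        if c != 2:
            problems.append(f"target {t} appears in {c} pools, expected 2")
    return problems
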