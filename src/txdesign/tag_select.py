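"""Cross-population greedy tag-SNP selection and booster-module selection.

The selection problem is a multi-population set cover over pairwise LD: a
candidate marker *tags* a target in a population when their r² meets the
threshold there (a marker always tags itself where it is polymorphic —
direct genotyping counts as r² = 1). The greedy picks, at every step, the
candidate covering the most not-yet-covered targets *summed across all
populations simultaneously*, which carries the classic (1 - 1/e)
approximation guarantee of monotone submodular maximization. A target is
owed coverage only in populations where it is polymorphic.

Ties are broken by smaller genomic position, then lexicographic marker id,
so identical inputs always yield identical selection order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .containers import MarkerManifest
from .ld_engine import LDStore

#: community-standard pairwise tagging threshold
DEFAULT_R2_THRESHOLD = 0.8

# tagging_sets: candidate -> population -> {target: r2}
TaggingSets = dict[str, dict[str, dict[str, float]]]


@dataclass
class TagSelectionResult:
    """Ordered greedy selection with its per-population coverage audit."""

    selected: list[str]
    #: population -> target -> (best covering selected marker, r²)
    covered: dict[str, dict[str, tuple[str, float]]]
    #: population -> targets never covered at the threshold
    residual: dict[str, set[str]]
    #: one row per greedy step: (marker, {population: newly covered count})
    gain_log: list[tuple[str, dict[str, int]]]

    def coverage_fraction(self, population: str) -> float:
        n_cov = len(self.covered[population])
        n_tot = n_cov + len(self.residual[population])
        return n_cov / n_tot if n_tot else 1.0

    def total_covered(self) -> int:
        return sum(len(c) for c in self.covered.values())

    def to_frame(self) -> pd.DataFrame:
        pops = sorted(self.covered)
        rows = []
        cum = 0
        for rank, (marker, gains) in enumerate(self.gain_log, start=1):
            cum += sum(gains.values())
            rows.append([rank, marker] + [gains.get(p, 0) for p in pops] + [cum])
        return pd.DataFrame(rows, columns=["rank", "marker_id"] + [f"gain_{p}" for p in pops] + ["cumulative_covered"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tagging_sets(
    ld_stores: Mapping[str, LDStore],
    candidates: Sequence[str],
    targets: Sequence[str],
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> TaggingSets:
    """For every candidate and population, the targets it tags at the
    threshold (including itself where polymorphic).

    A candidate monomorphic in a population tags nothing there.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    target_set = set(targets)
    out: TaggingSets = {c: {p: {} for p in ld_stores} for c in candidates}
    for pop, store in ld_stores.items():
        cand_in_pop = {c for c in candidates if c in store.polymorphic}
        for (a, b), r2 in store.pairs.items():
            if r2 < r2_threshold:
                continue
            if a in cand_in_pop and b in target_set:
                out[a][pop][b] = r2
            if b in cand_in_pop and a in target_set:
                out[b][pop][a] = r2
        for c in cand_in_pop:
            if c in target_set:
                out[c][pop][c] = 1.0
    return out


def targets_by_population(
    ld_stores: Mapping[str, LDStore], targets: Sequence[str]
) -> dict[str, set[str]]:
    """Restrict the target list to each population's polymorphic set —
    coverage is owed only where a target is polymorphic."""
    return {pop: {t for t in targets if t in store.polymorphic} for pop, store in ld_stores.items()}


def greedy_multipop_select(
    tag_sets: TaggingSets,
    targets_by_pop: Mapping[str, set[str]],
    positions: Mapping[str, int],
    budget: int | None = None,
    initial_covered: Mapping[str, Mapping[str, tuple[str, float]]] | None = None,
) -> TagSelectionResult:
    """Greedy cross-population set cover.

    Iteratively selects the candidate with the largest summed count of
    not-yet-covered targets across all populations; stops when everything
    reachable is covered or the budget is exhausted. ``initial_covered``
    seeds coverage (used by :func:`booster_select`).
    """
    if budget is not None and budget < 1:
        raise ValueError("budget must be >= 1")
    covered: dict[str, dict[str, tuple[str, float]]] = {
        p: dict(initial_covered[p]) if initial_covered and p in initial_covered else {}
        for p in targets_by_pop
    }
    uncovered = {p: set(ts) - set(covered[p]) for p, ts in targets_by_pop.items()}

    def gains_of(cand: str) -> dict[str, int]:
        per_pop = tag_sets[cand]
        return {p: len(uncovered[p] & per_pop.get(p, {}).keys()) for p in uncovered}

    selected: list[str] = []
    gain_log: list[tuple[str, dict[str, int]]] = []
    # Lazy greedy: marginal gains only shrink as coverage grows (the
    # objective is monotone submodular), so a stale heap entry whose
    # recomputed key still beats the next entry is the true argmax. The
    # (-gain, position, id) key reproduces the eager tie-break exactly.
    heap: list[tuple[int, int, str]] = []
    for cand in tag_sets:
        total = sum(gains_of(cand).values())
        if total > 0:
            heap.append((-total, positions.get(cand, 0), cand))
    heapq.heapify(heap)
    while heap and any(uncovered.values()) and (budget is None or len(selected) < budget):
        _, pos, cand = heapq.heappop(heap)
        gains = gains_of(cand)
        total = sum(gains.values())
        if total == 0:
            continue
        key = (-total, pos, cand)
        if heap and heap[0] < key:
            heapq.heappush(heap, key)
            continue
        selected.append(cand)
        gain_log.append((cand, {p: g for p, g in gains.items() if g}))
        for p, tags in tag_sets[cand].items():
            newly = uncovered[p] & tags.keys()
            for t in newly:
                covered[p][t] = (cand, tags[t])
            uncovered[p] -= newly
    return TagSelectionResult(selected, covered, uncovered, gain_log)


def select_tags(
    ld_stores: Mapping[str, LDStore],
    manifest: MarkerManifest,
    candidates: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    budget: int | None = None,
) -> TagSelectionResult:
    """Convenience front end: build tagging sets from the LD stores and run
    the cross-population greedy over manifest markers."""
    ids = list(manifest.marker_ids)
    candidates = ids if candidates is None else list(candidates)
    targets = ids if targets is None else list(targets)
    tsets = tagging_sets(ld_stores, candidates, targets, r2_threshold)
    positions = dict(zip(manifest.marker_ids, (int(p) for p in manifest.positions)))
    return greedy_multipop_select(tsets, targets_by_population(ld_stores, targets), positions, budget)


def booster_select(
    existing_array: Iterable[str],
    ld_stores: Mapping[str, LDStore],
    manifest: MarkerManifest,
    maf_cutoffs: Mapping[str, float] | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    budget: int | None = None,
) -> TagSelectionResult:
    """Select the minimal booster set adding the most coverage of common
    variants on top of an existing array.

    Targets are the manifest markers exceeding their population's MAF
    cutoff (defaults: > 2 % in CEU, > 5 % in AFR, where those populations
    exist) that the existing array does not already cover at the r²
    threshold. The greedy is seeded with the existing coverage, so the
    gain log reports *incremental* coverage per booster marker.
    """
    if maf_cutoffs is None:
        maf_cutoffs = {p: c for p, c in (("CEU", 0.02), ("AFR", 0.05)) if p in ld_stores}
        maf_cutoffs.update({p: 0.05 for p in ld_stores if p not in maf_cutoffs})
    existing = set(existing_array)
    ids = list(manifest.marker_ids)

    targets_by_pop: dict[str, set[str]] = {}
    all_targets: set[str] = set()
    for pop, store in ld_stores.items():
        cutoff = maf_cutoffs.get(pop)
        if cutoff is None:
            raise ValueError(f"no MAF cutoff supplied for population {pop}")
        maf = manifest.maf(pop)
        pop_targets = {
            m for m in ids if m in store.polymorphic and float(maf[m]) > cutoff
        }
        targets_by_pop[pop] = pop_targets
        all_targets |= pop_targets

    candidates = [m for m in ids if m not in existing]
    tsets = tagging_sets(ld_stores, candidates, sorted(all_targets), r2_threshold)

    # coverage already provided by the existing array
    existing_sets = tagging_sets(ld_stores, sorted(existing & set(ids)), sorted(all_targets), r2_threshold)
    initial: dict[str, dict[str, tuple[str, float]]] = {p: {} for p in ld_stores}
    for marker, per_pop in existing_sets.items():
        for pop, tags in per_pop.items():
            for t, r2 in tags.items():
                prev = initial[pop].get(t)
                if prev is None or r2 > prev[1]:
                    initial[pop][t] = (marker, r2)

    positions = dict(zip(manifest.marker_ids, (int(p) for p in manifest.positions)))
    return greedy_multipop_select(tsets, targets_by_pop, positions, budget, initial_covered=initial)
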