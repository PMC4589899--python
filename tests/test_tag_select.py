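"""Greedy cross-population tag selection against an independent naive
oracle, exhaustive enumeration, and the classic set-cover bound."""

import itertools
import math

import numpy as np
import pytest

from txdesign import build_ld_store, select_tags, tagging_sets
from txdesign.ld_engine import LDStore
from txdesign.tag_select import booster_select, greedy_multipop_select, targets_by_population

from conftest import panel_from_haplotypes, toy_manifest


# ---------------------------------------------------------------------------
# independent oracles (sets-only, eager, no shared code with the library)
# ---------------------------------------------------------------------------

def naive_greedy(tag_sets, targets_by_pop, positions, budget=None):
    """Eager re-scan greedy with the documented (position, id) tie-break."""
    uncovered = {p: set(t) for p, t in targets_by_pop.items()}
    selected, gains_log = [], []
    candidates = set(tag_sets)
    while any(uncovered.values()) and (budget is None or len(selected) < budget):
        scored = []
        for c in candidates:
            gain = sum(len(uncovered[p] & set(tag_sets[c].get(p, {}))) for p in uncovered)
            if gain:
                scored.append((-gain, positions.get(c, 0), c))
        if not scored:
            break
        _, _, best = min(scored)
        selected.append(best)
        gains_log.append(
            {p: len(uncovered[p] & set(tag_sets[best].get(p, {}))) for p in uncovered}
        )
        for p in uncovered:
            uncovered[p] -= set(tag_sets[best].get(p, {}))
        candidates.discard(best)
    return selected, gains_log, uncovered


def coverage_value(tag_sets, targets_by_pop, subset):
    return sum(
        len(set(targets_by_pop[p]) & set().union(*(set(tag_sets[c].get(p, {})) for c in subset)))
        if subset
        else 0
        for p in targets_by_pop
    )


def random_instance(seed, n_candidates=10, n_targets=14, n_pops=2):
    rng = np.random.default_rng(seed)
    pops = [f"P{k}" for k in range(n_pops)]
    targets = [f"t{i}" for i in range(n_targets)]
    tag_sets = {}
    for i in range(n_candidates):
        cand = f"c{i}"
        tag_sets[cand] = {
            p: {t: 1.0 for t in targets if rng.random() < 0.25} for p in pops
        }
    targets_by_pop = {p: {t for t in targets if rng.random() < 0.9} for p in pops}
    positions = {f"c{i}": 100 * i for i in range(n_candidates)}
    return tag_sets, targets_by_pop, positions


# ---------------------------------------------------------------------------
# tagging sets
# ---------------------------------------------------------------------------

def test_perfect_block_members_tag_each_other(perfect_block_panel):
    store = build_ld_store(perfect_block_panel, "CEU", 10_000)
    ids = list(perfect_block_panel.manifest.marker_ids)
    block0 = [m for m in ids[:5] if m in store.polymorphic]
    tsets = tagging_sets({"CEU": store}, block0, block0, r2_threshold=1.0)
    for c in block0:
        assert set(tsets[c]["CEU"]) == set(block0)


def test_monomorphic_candidate_tags_nothing():
    """A candidate monomorphic in a population is absent from its store
    and tags nothing there — not even itself."""
    haps = np.array([[0, 0, 0, 0, 1, 0, 1, 0], [0, 0, 0, 0, 1, 0, 1, 0]])
    panel = panel_from_haplotypes(
        haps,
        populations={"s0": "A", "s1": "A", "s2": "B", "s3": "B"},
        manifest=toy_manifest(2),
    )
    stores = {p: build_ld_store(panel, p, 10_000) for p in ("A", "B")}
    tsets = tagging_sets(stores, ["m0", "m1"], ["m0", "m1"], 0.8)
    assert tsets["m0"]["A"] == {}
    assert set(tsets["m0"]["B"]) == {"m0", "m1"}


def test_tagging_sets_match_double_loop_oracle(two_pop_panel):
    from txdesign import pairwise_r2

    threshold = 0.8
    window = 30_000
    stores = {p: build_ld_store(two_pop_panel, p, window) for p in ("CEU", "AFR")}
    ids = list(two_pop_panel.manifest.marker_ids)
    tsets = tagging_sets(stores, ids, ids, threshold)
    man = two_pop_panel.manifest
    for pop in ("CEU", "AFR"):
        haps = two_pop_panel.population_haplotypes(pop)
        freqs = haps.mean(axis=1)
        for ci, c in enumerate(ids):
            expected = set()
            if 0 < freqs[ci] < 1:
                expected.add(c)
                for ti, t in enumerate(ids):
                    if ti == ci or not 0 < freqs[ti] < 1:
                        continue
                    if man.chroms[ci] != man.chroms[ti]:
                        continue
                    if abs(int(man.positions[ci]) - int(man.positions[ti])) > window:
                        continue
                    if pairwise_r2(haps[ci], haps[ti]) >= threshold:
                        expected.add(t)
            assert set(tsets[c][pop]) == expected, (c, pop)


# ---------------------------------------------------------------------------
# greedy selection
# ---------------------------------------------------------------------------

def test_single_self_tagging_target():
    tag_sets = {"c0": {"P": {"c0": 1.0}}}
    res = greedy_multipop_select(tag_sets, {"P": {"c0"}}, {"c0": 10})
    assert res.selected == ["c0"]
    assert res.residual == {"P": set()}


def test_empty_target_set_selects_nothing():
    tag_sets = {"c0": {"P": {"t0": 1.0}}}
    res = greedy_multipop_select(tag_sets, {"P": set()}, {})
    assert res.selected == []


def test_budget_must_be_positive():
    with pytest.raises(ValueError, match="budget"):
        greedy_multipop_select({}, {"P": set()}, {}, budget=0)


@pytest.mark.parametrize("seed", range(12))
def test_greedy_trace_equals_naive_oracle(seed):
    tag_sets, tbp, positions = random_instance(seed)
    res = greedy_multipop_select(tag_sets, tbp, positions)
    sel, gains, residual = naive_greedy(tag_sets, tbp, positions)
    assert res.selected == sel
    assert res.residual == residual
    for (marker, g), oracle_g in zip(res.gain_log, gains):
        assert g == {p: v for p, v in oracle_g.items() if v}


def test_gain_log_counts_sum_to_total_covered():
    tag_sets, tbp, positions = random_instance(99)
    res = greedy_multipop_select(tag_sets, tbp, positions)
    assert sum(sum(g.values()) for _, g in res.gain_log) == res.total_covered()
    assert len(res.selected) == len(set(res.selected))


@pytest.mark.parametrize("seed", range(8))
def test_greedy_meets_set_cover_bound(seed):
    """Coverage after b greedy picks >= (1 - 1/e) of the exhaustive-best
    b-subset on small instances."""
    budget = 3
    tag_sets, tbp, positions = random_instance(seed, n_candidates=12)
    res = greedy_multipop_select(tag_sets, tbp, positions, budget=budget)
    greedy_cov = res.total_covered()
    best = max(
        coverage_value(tag_sets, tbp, subset)
        for subset in itertools.combinations(tag_sets, budget)
    )
    assert greedy_cov >= (1 - 1 / math.e) * best - 1e-9


def test_first_pick_is_globally_optimal():
    for seed in range(6):
        tag_sets, tbp, positions = random_instance(seed)
        res = greedy_multipop_select(tag_sets, tbp, positions, budget=1)
        if not res.selected:
            continue
        best_single = max(coverage_value(tag_sets, tbp, (c,)) for c in tag_sets)
        assert res.total_covered() == best_single


def test_tie_break_by_position_then_id():
    tag_sets = {
        "b": {"P": {"t0": 1.0, "t1": 1.0}},
        "a": {"P": {"t0": 1.0, "t1": 1.0}},
    }
    res = greedy_multipop_select(tag_sets, {"P": {"t0", "t1"}}, {"a": 200, "b": 100})
    assert res.selected == ["b"]  # smaller position wins over id
    res2 = greedy_multipop_select(tag_sets, {"P": {"t0", "t1"}}, {"a": 100, "b": 100})
    assert res2.selected == ["a"]  # equal positions: lexicographic id


def test_unlimited_budget_covers_everything_reachable(two_pop_panel):
    stores = {p: build_ld_store(two_pop_panel, p, 30_000) for p in ("CEU", "AFR")}
    res = select_tags(stores, two_pop_panel.manifest, r2_threshold=0.8)
    # every target is a candidate and self-tags where polymorphic
    assert all(not residual for residual in res.residual.values())
    tbp = targets_by_population(stores, list(two_pop_panel.manifest.marker_ids))
    assert res.total_covered() == sum(len(t) for t in tbp.values())


def test_covered_targets_meet_threshold(two_pop_panel):
    threshold = 0.8
    stores = {p: build_ld_store(two_pop_panel, p, 30_000) for p in ("CEU", "AFR")}
    res = select_tags(stores, two_pop_panel.manifest, r2_threshold=threshold)
    for pop, cov in res.covered.items():
        for target, (tagger, r2) in cov.items():
            assert r2 >= threshold
            assert stores[pop].get(tagger, target) == pytest.approx(r2)


# ---------------------------------------------------------------------------
# booster
# ---------------------------------------------------------------------------

def test_booster_empty_when_array_already_covers(two_pop_panel):
    stores = {p: build_ld_store(two_pop_panel, p, 30_000) for p in ("CEU", "AFR")}
    full = select_tags(stores, two_pop_panel.manifest, r2_threshold=0.8)
    res = booster_select(full.selected, stores, two_pop_panel.manifest,
                         {"CEU": 0.02, "AFR": 0.05}, r2_threshold=0.8)
    assert res.selected == []


def test_booster_gain_log_non_increasing(two_pop_panel):
    stores = {p: build_ld_store(two_pop_panel, p, 30_000) for p in ("CEU", "AFR")}
    existing = list(two_pop_panel.manifest.marker_ids[:4])
    res = booster_select(existing, stores, two_pop_panel.manifest, r2_threshold=0.9)
    gains = [sum(g.values()) for _, g in res.gain_log]
    assert gains == sorted(gains, reverse=True)
    assert all(m not in existing for m in res.selected)


def test_booster_first_pick_beats_any_single_alternative(two_pop_panel):
    stores = {p: build_ld_store(two_pop_panel, p, 30_000) for p in ("CEU", "AFR")}
    man = two_pop_panel.manifest
    existing = list(man.marker_ids[:6])
    res = booster_select(existing, stores, man, {"CEU": 0.02, "AFR": 0.05},
                         r2_threshold=0.9, budget=1)
    if not res.selected:
        pytest.skip("array already covers every common target at this threshold")
    first_gain = sum(res.gain_log[0][1].values())
    # enumerate every alternative single pick
    baseline = booster_select(existing, stores, man, {"CEU": 0.02, "AFR": 0.05},
                              r2_threshold=0.9, budget=None)
    candidates = set(man.marker_ids) - set(existing)
    tsets = tagging_sets(stores, sorted(candidates), list(man.marker_ids), 0.9)
    for cand in candidates:
        alt_gain = 0
        for pop in stores:
            initially_uncovered = {
                t for t in baseline.covered[pop] if baseline.covered[pop][t][0] not in existing
            } | baseline.residual[pop]
            alt_gain += len(initially_uncovered & set(tsets[cand].get(pop, {})))
        assert first_gain >= alt_gain, cand
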