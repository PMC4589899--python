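"""Tiered, non-redundant assembly of an array design from prioritized
content modules, with content filters and a marker budget.

Modules are stacked in priority order; a marker already on the array is
skipped (no redundant content), and contribution stops when the budget is
reached. Identity for deduplication defaults to (chrom, pos, ref, alt) —
ids differ across source platforms, positions are the stable key — with an
id-based mode available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .containers import MarkerManifest, Region

#: full array capacity of the reference design (~782K markers)
DEFAULT_BUDGET = 782_000


class BudgetExceededError(RuntimeError):
    """A mandatory tier did not fit within the marker budget."""


@dataclass
class ModuleAudit:
    label: str
    n_input: int
    contributed: int
    skipped_duplicate: int
    truncated: int

    def __post_init__(self) -> None:
        assert self.contributed + self.skipped_duplicate + self.truncated == self.n_input


@dataclass
class ArrayDesign:
    """Final marker set plus the per-module audit trail."""

    manifest: MarkerManifest
    audit: list[ModuleAudit]
    budget: int

    @property
    def marker_ids(self) -> list[str]:
        return list(self.manifest.marker_ids)

    def __len__(self) -> int:
        return len(self.manifest)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (a.label, a.n_input, a.contributed, a.skipped_duplicate, a.truncated)
                for a in self.audit
            ],
            columns=["module", "n_input", "contributed", "skipped_duplicate", "truncated"],
        )

    def write_audit_tsv(self, path: str | Path) -> None:
        self.audit_frame().to_csv(path, sep="\t", index=False)


def _identity_keys(manifest: MarkerManifest, mode: str) -> list[tuple]:
    df = manifest.df
    if mode == "position":
        return list(zip(df["chrom"].astype(str), df["pos"], df["ref"], df["alt"]))
    if mode == "id":
        return [(m,) for m in df["marker_id"]]
    raise ValueError(f"unknown identity mode {mode!r}")


def assemble(
    modules: Sequence[tuple[str, MarkerManifest]],
    budget: int = DEFAULT_BUDGET,
    identity: str = "position",
    mandatory: Sequence[str] = (),
) -> ArrayDesign:
    """Stack content modules in priority order into one design.

    Parameters
    ----------
    modules
        ``(label, manifest)`` pairs, highest priority first.
    budget
        Maximum marker count of the final design.
    identity
        ``"position"`` dedups on (chrom, pos, ref, alt); ``"id"`` on
        marker_id.
    mandatory
        Module labels that must fit entirely; truncating one raises
        :class:`BudgetExceededError` naming it.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    seen: set[tuple] = set()
    seen_ids: set[str] = set()
    rows: list[pd.DataFrame] = []
    audit: list[ModuleAudit] = []
    total = 0
    for label, manifest in modules:
        keys = _identity_keys(manifest, identity)
        contributed = skipped = truncated = 0
        keep_idx: list[int] = []
        for i, key in enumerate(keys):
            mid = manifest.df["marker_id"].iat[i]
            if key in seen or mid in seen_ids:
                skipped += 1
                continue
            if total >= budget:
                truncated += 1
                continue
            seen.add(key)
            seen_ids.add(mid)
            keep_idx.append(i)
            contributed += 1
            total += 1
        if truncated and label in set(mandatory):
            raise BudgetExceededError(
                f"mandatory module {label!r} overflows the budget of {budget} "
                f"({truncated} markers did not fit)"
            )
        if keep_idx:
            sub = manifest.df.iloc[keep_idx].copy()
            sub["modules"] = [set(m) | {label} for m in sub["modules"]]
            rows.append(sub)
        audit.append(ModuleAudit(label, len(manifest), contributed, skipped, truncated))
    if rows:
        final = MarkerManifest(pd.concat(rows, ignore_index=True), validate=False)
    else:
        final = MarkerManifest(
            pd.DataFrame(columns=["marker_id", "chrom", "pos", "ref", "alt", "modules"]).astype({"pos": int}),
            validate=False,
        )
    return ArrayDesign(final, audit, budget)


@dataclass
class FilterAudit:
    kept: int
    dropped_low_mac: int
    dropped_missing: int


def mac_filter(
    manifest: MarkerManifest,
    reference_mac: Mapping[str, int],
    min_mac_exclusive: int = 5,
) -> tuple[MarkerManifest, FilterAudit]:
    """Keep markers observed *more than* ``min_mac_exclusive`` times in a
    reference count table (default: MAC > 5, the exclusive convention used
    for exonic/LoF content filtering).

    Markers absent from the reference table are dropped and counted
    separately in the audit.
    """
    keep, low, missing = [], 0, 0
    for i, mid in enumerate(manifest.marker_ids):
        mac = reference_mac.get(mid)
        if mac is None:
            missing += 1
        elif mac > min_mac_exclusive:
            keep.append(i)
        else:
            low += 1
    filtered = MarkerManifest(manifest.df.iloc[keep], validate=False)
    return filtered, FilterAudit(len(keep), low, missing)


def region_select(manifest: MarkerManifest, region: Region) -> MarkerManifest:
    """Sub-manifest of markers inside a closed 1-based interval."""
    return manifest.subset(manifest.in_region(region))
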