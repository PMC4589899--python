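"""Coverage of a reference haplotype panel by an array design.

For each eligible panel marker (polymorphic in the population and above
the MAF cutoff) the *max r²* to any array marker within the LD window is
computed, with self-inclusion: a target directly on the array scores 1.0.
Coverage at threshold t is the fraction of eligible targets with
max r² >= t; the mean of the max-r² values gives the mean-r² (regional)
coverage figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import EXTENDED_MHC, HaplotypePanel, Region

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))

#: named region presets usable from the CLI
REGION_PRESETS: dict[str, Region] = {"mhc": EXTENDED_MHC}


@dataclass
class CoverageReport:
    """Coverage curve of one population (optionally one region)."""

    population: str
    maf_cutoff: float
    thresholds: tuple[float, ...]
    fractions: tuple[float, ...]
    mean_max_r2: float
    n_eligible: int
    region_label: str | None = None
    #: whether array markers themselves count in the target denominator
    self_inclusion: bool = True

    def fraction_at(self, threshold: float) -> float:
        for t, f in zip(self.thresholds, self.fractions):
            if abs(t - threshold) < 1e-9:
                return f
        raise KeyError(f"threshold {threshold} not on the grid")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"threshold": self.thresholds, "fraction_covered": self.fractions})
        df.insert(0, "population", self.population)
        df.insert(1, "maf_cutoff", self.maf_cutoff)
        df.insert(2, "region", self.region_label or "genome")
        df["mean_max_r2"] = self.mean_max_r2
        df["n_eligible"] = self.n_eligible
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def max_r2_per_target(
    array_markers: Iterable[str],
    panel: HaplotypePanel,
    population: str,
    window_bp: int = 250_000,
    maf_cutoff: float = 0.0,
    region: Region | None = None,
) -> pd.Series:
    """Max r² from every eligible panel marker to the array.

    Eligible targets are polymorphic in ``population`` with MAF strictly
    above ``maf_cutoff`` (and inside ``region`` when given). A target on
    the array scores 1.0; a target with no array marker in the window
    scores 0.0.
    """
    manifest = panel.manifest
    haps = panel.population_haplotypes(population).astype(float)
    p_hat = haps.mean(axis=1)
    maf = np.minimum(p_hat, 1.0 - p_hat)
    eligible = (p_hat > 0.0) & (p_hat < 1.0) & (maf > maf_cutoff)
    if region is not None:
        eligible &= manifest.in_region(region)

    ids = manifest.marker_ids
    on_array = np.isin(ids, list(array_markers))
    chroms = manifest.chroms
    pos = manifest.positions

    centered = haps - p_hat[:, None]
    norms = np.sqrt((centered**2).sum(axis=1))

    values = np.zeros(len(ids))
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        cpos = pos[cidx]
        order = np.argsort(cpos, kind="mergesort")
        cidx, cpos = cidx[order], cpos[order]
        arr_mask = on_array[cidx]
        arr_idx, arr_pos = cidx[arr_mask], cpos[arr_mask]
        for k, i in enumerate(cidx):
            if not eligible[i]:
                continue
            if on_array[i]:
                values[i] = 1.0
                continue
            lo = np.searchsorted(arr_pos, cpos[k] - window_bp, side="left")
            hi = np.searchsorted(arr_pos, cpos[k] + window_bp, side="right")
            near = arr_idx[lo:hi]
            near = near[norms[near] > 0]
            if near.size == 0:
                continue
            r = centered[near] @ centered[i] / (norms[near] * norms[i])
            values[i] = float(np.clip((r * r).max(), 0.0, 1.0))
    return pd.Series(values[eligible], index=pd.Index(ids[eligible], name="marker_id"), name="max_r2")


def coverage_curve(
    max_r2: pd.Series | np.ndarray,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    population: str = "",
    maf_cutoff: float = 0.0,
    region_label: str | None = None,
) -> CoverageReport:
    """Fraction of targets at or above each grid threshold, plus the mean
    max-r²."""
    values = np.asarray(max_r2, dtype=float)
    n = values.size
    fractions = tuple(
        float((values >= t - 1e-12).mean()) if n else 0.0 for t in threshold_grid
    )
    mean = float(values.mean()) if n else 0.0
    return CoverageReport(
        population=population,
        maf_cutoff=maf_cutoff,
        thresholds=tuple(float(t) for t in threshold_grid),
        fractions=fractions,
        mean_max_r2=mean,
        n_eligible=int(n),
        region_label=region_label,
    )


def evaluate_coverage(
    array_markers: Iterable[str],
    panel: HaplotypePanel,
    population: str,
    maf_cutoff: float = 0.05,
    window_bp: int = 250_000,
    region: Region | None = None,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> CoverageReport:
    """Max-r² computation and curve in one call."""
    values = max_r2_per_target(array_markers, panel, population, window_bp, maf_cutoff, region)
    return coverage_curve(
        values, threshold_grid, population, maf_cutoff, region.label if region else None
    )


def regional_coverage(
    array_markers: Iterable[str],
    panel: HaplotypePanel,
    regions: Sequence[Region],
    population: str,
    maf_cutoff: float = 0.05,
    window_bp: int = 250_000,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> list[CoverageReport]:
    """Coverage restricted to each closed 1-based region in turn (e.g. the
    extended MHC preset, chr6:25,500,000-34,000,000)."""
    return [
        evaluate_coverage(
            array_markers, panel, population, maf_cutoff, window_bp, region, threshold_grid
        )
        for region in regions
    ]


def plot_coverage_curves(reports: Sequence[CoverageReport], path: str | Path) -> None:
    """Write a coverage-vs-threshold figure for a set of reports."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for rep in reports:
        label = f"{rep.population} MAF>{rep.maf_cutoff:g}"
        if rep.region_label:
            label += f" [{rep.region_label}]"
        ax.plot(rep.thresholds, rep.fractions, marker="o", ms=3, label=label)
    ax.set_xlabel("max $r^2$ threshold")
    ax.set_ylabel("fraction of panel markers covered")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
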