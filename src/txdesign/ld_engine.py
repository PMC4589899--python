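"""Allele frequencies and windowed pairwise linkage disequilibrium (r²)
from phased haplotypes.

For biallelic sites, r² = D²/(p_i(1-p_i)p_j(1-p_j)) with
D = p_ij - p_i p_j equals the squared Pearson correlation of the two 0/1
allele vectors; the windowed builder exploits that via centered dot
products. Monomorphic sites have undefined r² and are excluded from every
store (and hence from tagging candidacy in that population).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import HaplotypePanel, MarkerManifest

#: markers whose r² exceeds 1 by more than this are a logic error, not rounding
_CLAMP_TOL = 1e-9


def allele_frequency(panel: HaplotypePanel, population: str | None = None) -> pd.DataFrame:
    """Per-marker alt-allele frequency, MAF and MAC within one population
    (or the whole panel).

    Returns a DataFrame indexed by marker_id with columns ``af``, ``maf``,
    ``mac`` and ``n_haplotypes``.
    """
    haps = panel.population_haplotypes(population)
    two_n = haps.shape[1]
    counts = haps.sum(axis=1)
    af = counts / two_n
    return pd.DataFrame(
        {
            "af": af,
            "maf": np.minimum(af, 1.0 - af),
            "mac": np.minimum(counts, two_n - counts).astype(int),
            "n_haplotypes": two_n,
        },
        index=pd.Index(panel.manifest.marker_ids, name="marker_id"),
    )


def pairwise_r2(hap_i: np.ndarray, hap_j: np.ndarray) -> float:
    """r² between two equal-length binary haplotype vectors.

    Computed as D²/(p_i(1-p_i) p_j(1-p_j)) with D = p_ij - p_i p_j, clamped
    to [0, 1] against floating-point rounding. Raises on monomorphic input
    (r² undefined) — callers must exclude such sites.
    """
    hi = np.asarray(hap_i, dtype=float)
    hj = np.asarray(hap_j, dtype=float)
    if hi.shape != hj.shape or hi.ndim != 1:
        raise ValueError("haplotype vectors must be 1-D and equal length")
    p_i, p_j = hi.mean(), hj.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise ValueError("r^2 undefined for monomorphic sites")
    d = (hi * hj).mean() - p_i * p_j
    r2 = d * d / (p_i * (1 - p_i) * p_j * (1 - p_j))
    return float(min(max(r2, 0.0), 1.0))


@dataclass
class LDStore:
    """Sparse symmetric map of within-window r² for one population.

    Pairs are keyed by (marker_i, marker_j) in manifest order; lookups are
    symmetric and r²(i, i) = 1 for any polymorphic marker.
    """

    population: str
    window_bp: int
    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    polymorphic: frozenset[str] = frozenset()

    def get(self, marker_i: str, marker_j: str, default: float = 0.0) -> float:
        if marker_i == marker_j:
            return 1.0 if marker_i in self.polymorphic else default
        if (marker_i, marker_j) in self.pairs:
            return self.pairs[(marker_i, marker_j)]
        return self.pairs.get((marker_j, marker_i), default)

    def neighbors(self, marker: str, r2_min: float = 0.0) -> dict[str, float]:
        """All stored partners of ``marker`` with r² >= ``r2_min``."""
        out = {}
        for (a, b), r2 in self.pairs.items():
            if r2 < r2_min:
                continue
            if a == marker:
                out[b] = r2
            elif b == marker:
                out[a] = r2
        return out

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.population, a, b, r2) for (a, b), r2 in self.pairs.items()]
        return pd.DataFrame(rows, columns=["population", "marker_i", "marker_j", "r2"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ld_store(path: str | Path, window_bp: int, polymorphic: frozenset[str] | None = None) -> LDStore:
    df = pd.read_csv(path, sep="\t", dtype={"marker_i": str, "marker_j": str})
    pops = df["population"].unique()
    if len(pops) > 1:
        raise ValueError("LD store file mixes populations")
    pairs = {(r.marker_i, r.marker_j): float(r.r2) for r in df.itertuples()}
    poly = polymorphic
    if poly is None:
        poly = frozenset(df["marker_i"]) | frozenset(df["marker_j"])
    return LDStore(str(pops[0]) if len(pops) else "", window_bp, pairs, poly)


def build_ld_store(panel: HaplotypePanel, population: str, window_bp: int = 250_000) -> LDStore:
    """Compute r² for every polymorphic pair within ``window_bp`` on the
    same chromosome.

    The manifest must be sorted by (chrom, pos); pairs spanning
    chromosomes are never stored.
    """
    manifest = panel.manifest
    chroms = manifest.chroms
    pos = manifest.positions
    for chrom in pd.unique(chroms):
        p = pos[chroms == chrom]
        if (np.diff(p) < 0).any():
            raise ValueError("manifest must be position-sorted within each chromosome")

    haps = panel.population_haplotypes(population).astype(float)
    ids = manifest.marker_ids
    p_hat = haps.mean(axis=1)
    poly = (p_hat > 0.0) & (p_hat < 1.0)
    centered = haps - p_hat[:, None]
    norms = np.sqrt((centered**2).sum(axis=1))

    pairs: dict[tuple[str, str], float] = {}
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cpos = pos[idx]
        for a, i in enumerate(idx):
            if not poly[i]:
                continue
            hi = idx[a + 1 : a + 1 + int(np.searchsorted(cpos[a + 1 :], cpos[a] + window_bp, side="right"))]
            hi = hi[poly[hi]]
            if hi.size == 0:
                continue
            r = centered[hi] @ centered[i] / (norms[hi] * norms[i])
            r2 = np.clip(r * r, 0.0, 1.0 + _CLAMP_TOL)
            # snap perfect-copy pairs to exactly 1 (they are 1 - O(eps) here)
            r2[r2 >= 1.0 - 1e-12] = 1.0
            for j, val in zip(hi, r2):
                pairs[(ids[i], ids[j])] = float(min(val, 1.0))
    return LDStore(population, window_bp, pairs, frozenset(ids[poly]))
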