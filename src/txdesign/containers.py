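"""Core in-memory containers shared by every stage of the toolkit.

All containers follow the same conventions:

* marker positions are 1-based base pairs; interval predicates are closed;
* genotypes are alt-allele counts (0/1/2) with :data:`MISSING` (-1) as the
  missingness sentinel — never 0;
* haplotype panels store one column per haplotype (two per sample) in
  sample order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype in a :class:`GenotypeMatrix`.
MISSING: int = -1

MANIFEST_BASE_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt", "modules"]


def _norm_chrom(chrom: str) -> str:
    """Normalize a chromosome label ('chr6' and '6' compare equal)."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class Region:
    """A closed, 1-based genomic interval."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region bounds [{self.start}, {self.end}]")

    def contains(self, chrom: str, pos: int) -> bool:
        return _norm_chrom(chrom) == _norm_chrom(self.chrom) and self.start <= pos <= self.end


#: The extended MHC on hg19: chr6:25.5-34 Mb, spanning HLA and flanking immune loci.
EXTENDED_MHC = Region("6", 25_500_000, 34_000_000, "extended_MHC")


class MarkerManifest:
    """Per-marker metadata table: identity, position, content-module labels,
    per-population MAF/MAC.

    Backed by a :class:`pandas.DataFrame` with columns ``marker_id``,
    ``chrom``, ``pos``, ``ref``, ``alt``, ``modules`` (a ``set`` of labels)
    and optional ``maf_<POP>`` / ``mac_<POP>`` columns.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in MANIFEST_BASE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.df = df.reset_index(drop=True).copy()
        self.df["pos"] = self.df["pos"].astype(int)
        self.df["modules"] = self.df["modules"].apply(
            lambda m: set() if m is None or (isinstance(m, float) and np.isnan(m)) else set(m)
        )
        if validate:
            self._validate()

    def _validate(self) -> None:
        ids = self.df["marker_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5]
            raise ValueError(f"duplicate marker ids in manifest: {list(dupes)}")
        if (self.df["pos"] < 1).any():
            raise ValueError("manifest positions must be >= 1 (1-based)")
        for col in self.maf_columns:
            vals = self.df[col].dropna()
            if ((vals < 0) | (vals > 0.5)).any():
                raise ValueError(f"{col} outside [0, 0.5]")
        for col in self.mac_columns:
            vals = self.df[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"{col} must be non-negative")

    # -- accessors ---------------------------------------------------------
    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].astype(str).to_numpy()

    @property
    def maf_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("maf_")]

    @property
    def mac_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("mac_")]

    @property
    def populations(self) -> list[str]:
        return [c[4:] for c in self.maf_columns]

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in set(self.df["marker_id"])

    def index_of(self, marker_ids: Iterable[str]) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        return np.array([lookup[m] for m in marker_ids], dtype=int)

    def maf(self, population: str) -> pd.Series:
        col = f"maf_{population}"
        if col not in self.df.columns:
            raise KeyError(f"no MAF column for population {population!r}")
        return pd.Series(self.df[col].to_numpy(), index=self.marker_ids, name=col)

    def subset(self, mask_or_ids) -> "MarkerManifest":
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and np.asarray(mask_or_ids).dtype == bool:
            sub = self.df[np.asarray(mask_or_ids)]
        else:
            wanted = set(mask_or_ids)
            sub = self.df[self.df["marker_id"].isin(wanted)]
        return MarkerManifest(sub, validate=False)

    def in_region(self, region: Region) -> np.ndarray:
        """Boolean mask of markers inside ``region`` (closed interval)."""
        chrom_ok = np.array([_norm_chrom(c) == _norm_chrom(region.chrom) for c in self.chroms])
        pos = self.positions
        return chrom_ok & (pos >= region.start) & (pos <= region.end)

    def sorted_by_position(self) -> "MarkerManifest":
        sub = self.df.sort_values(["chrom", "pos", "marker_id"], kind="mergesort")
        return MarkerManifest(sub, validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerManifest):
            return NotImplemented
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if col == "modules":
                if not all(x == y for x, y in zip(a[col], b[col])):
                    return False
            elif col in self.maf_columns:
                if not np.allclose(a[col].astype(float), b[col].astype(float), equal_nan=True):
                    return False
            else:
                if not (a[col].to_numpy() == b[col].to_numpy()).all():
                    return False
        return True


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix: one row per marker, two haplotype columns
    per sample, with sample→population labels."""

    haplotypes: np.ndarray  # (n_markers, 2 * n_samples) int8, values {0, 1}
    samples: list[str]
    sample_population: dict[str, str]
    manifest: MarkerManifest

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[1] != 2 * len(self.samples):
            raise ValueError("haplotype matrix must have 2 columns per sample")
        if self.haplotypes.shape[0] != len(self.manifest):
            raise ValueError("haplotype rows must match manifest length")
        unknown = [s for s in self.samples if s not in self.sample_population]
        if unknown:
            raise ValueError(f"samples without population label: {unknown[:5]}")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.sample_population[s], None)
        return list(seen)

    def haplotype_columns(self, population: str | None = None) -> np.ndarray:
        """Column indices of the haplotypes belonging to ``population``
        (all columns when ``population`` is None)."""
        if population is None:
            return np.arange(self.haplotypes.shape[1])
        cols: list[int] = []
        for i, s in enumerate(self.samples):
            if self.sample_population[s] == population:
                cols.extend((2 * i, 2 * i + 1))
        if not cols:
            raise KeyError(f"population {population!r} not present in panel")
        return np.array(cols, dtype=int)

    def population_haplotypes(self, population: str | None = None) -> np.ndarray:
        return self.haplotypes[:, self.haplotype_columns(population)]

    def to_genotypes(self) -> "GenotypeMatrix":
        """Collapse phased haplotypes to unphased alt-allele counts."""
        g = self.haplotypes[:, 0::2] + self.haplotypes[:, 1::2]
        return GenotypeMatrix(g.astype(np.int8), list(self.samples), self.manifest)


@dataclass
class GenotypeMatrix:
    """Unphased biallelic genotypes coded as alt-allele counts 0/1/2;
    missing genotypes carry :data:`MISSING`."""

    genotypes: np.ndarray  # (n_markers, n_samples) int8 in {-1, 0, 1, 2}
    samples: list[str]
    manifest: MarkerManifest

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.manifest), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.manifest)} markers x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be in {-1, 0, 1, 2}")

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.genotypes[:, self.sample_index(sample_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(self.genotypes[:, idx], list(sample_ids), self.manifest)


@dataclass
class PedigreeTable:
    """PLINK .fam-dialect pedigree: families, parental links, and optional
    duplicate-pair linkage.

    A trio is *complete* iff both parental ids resolve to genotyped
    individuals.
    """

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]

    def __post_init__(self) -> None:
        if self.df.empty and not len(self.df.columns):
            self.df = pd.DataFrame(columns=self.COLUMNS)
        missing = [c for c in ("family_id", "individual_id", "father_id", "mother_id") if c not in self.df.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        for c in ("sex", "phenotype"):
            if c not in self.df.columns:
                self.df[c] = "0"
        self.df = self.df[self.COLUMNS].astype(str).reset_index(drop=True)
        if self.df["individual_id"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        self._check_no_ancestry_cycles()

    def _check_no_ancestry_cycles(self) -> None:
        parents = {
            r.individual_id: {p for p in (r.father_id, r.mother_id) if p not in ("0", "")}
            for r in self.df.itertuples()
        }
        for start in parents:
            frontier, seen = set(parents.get(start, ())), set()
            while frontier:
                node = frontier.pop()
                if node == start:
                    raise ValueError(f"pedigree cycle: {start} is its own ancestor")
                if node in seen:
                    continue
                seen.add(node)
                frontier |= parents.get(node, set())

    def complete_trios(self, genotyped: Iterable[str]) -> list[tuple[str, str, str, str]]:
        """Return ``(family_id, father, mother, child)`` for every trio whose
        three members are all genotyped."""
        have = set(genotyped)
        trios = []
        for r in self.df.itertuples():
            if r.father_id in ("0", "") or r.mother_id in ("0", ""):
                continue
            if r.individual_id in have and r.father_id in have and r.mother_id in have:
                trios.append((r.family_id, r.father_id, r.mother_id, r.individual_id))
        return trios
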