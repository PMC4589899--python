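"""Synthetic multi-population haplotype panels and QC fixtures.

The generator emulates the statistical structure the downstream stages
need — not realistic demography:

* **Block LD by founder copying.** Each block carries a two-founder
  backbone (reference vs alternate). Every haplotype copies one founder,
  chosen with a population-specific frequency, and each site is then
  flipped independently with probability ``(1 - within_block_correlation)/2``.
  At ``within_block_correlation = 1`` every intra-block polymorphic pair has
  r² = 1; backbones are drawn independently per block, so cross-block r² is
  ≈ 0 in expectation.
* **Population divergence.** The alternate-founder frequency drifts per
  population under a Balding–Nichols (beta) model with parameter ``fst``.
* **Trios** transmit one untouched parental haplotype per chromosome
  (recombination only at block/chromosome boundaries), then inject
  Mendelian errors by replacing the child genotype with a uniformly chosen
  *incompatible* genotype — guaranteeing every injected error is
  detectable, so the returned ledger is an exact oracle.
* **Duplicates** corrupt a copied sample with single-allele changes and
  missingness at controlled rates.
* **Imputation posteriors** blend a point mass on the true genotype with a
  symmetric Dirichlet draw, so best-guess accuracy degrades smoothly as
  the noise level rises from 0 (certain) to 1 (uninformative).

All randomness flows from a single seed through one named
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, HaplotypePanel, MarkerManifest, PedigreeTable

logger = logging.getLogger("txdesign")

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("A", "T"), ("C", "T"), ("C", "G"), ("G", "T")]


@dataclass
class SimulationSpec:
    """Parameters of a synthetic panel. Deterministic given ``seed``."""

    populations: list[tuple[str, int]] = field(default_factory=lambda: [("CEU", 100), ("ASN", 100), ("AFR", 100)])
    n_blocks: int = 20
    markers_per_block: int = 10
    within_block_correlation: float = 0.95
    maf_low: float = 0.05
    maf_high: float = 0.5
    fst: float = 0.05
    mendelian_error_rate: float = 0.0
    duplicate_error_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    imputation_noise: float = 0.0
    n_chromosomes: int = 1
    marker_spacing_bp: int = 1_000
    block_gap_bp: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.markers_per_block < 1:
            raise ValueError("a panel needs at least one block with at least one marker")
        if not self.populations or any(n < 1 for _, n in self.populations):
            raise ValueError("every population needs n_samples >= 1")
        for name, value in [
            ("within_block_correlation", self.within_block_correlation),
            ("fst", self.fst),
            ("mendelian_error_rate", self.mendelian_error_rate),
            ("duplicate_error_rate", self.duplicate_error_rate),
            ("genotype_missing_rate", self.genotype_missing_rate),
            ("imputation_noise", self.imputation_noise),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")


def _balding_nichols(rng: np.random.Generator, p0: float, fst: float) -> float:
    if fst <= 0.0:
        return p0
    shape = (1.0 - fst) / fst
    return float(np.clip(rng.beta(p0 * shape, (1.0 - p0) * shape), 1e-6, 1 - 1e-6))


def simulate_panel(spec: SimulationSpec) -> HaplotypePanel:
    """Generate a phased multi-population panel with block-structured LD.

    The returned panel's manifest carries per-population MAF/MAC computed
    from the *realized* haplotypes.
    """
    rng = np.random.default_rng(spec.seed)
    samples: list[str] = []
    sample_population: dict[str, str] = {}
    for pop, n in spec.populations:
        for i in range(n):
            sid = f"{pop}_{i:04d}"
            samples.append(sid)
            sample_population[sid] = pop
    n_hap_per_pop = {pop: 2 * n for pop, n in spec.populations}
    total_haps = 2 * len(samples)

    n_markers = spec.n_blocks * spec.markers_per_block
    haps = np.empty((n_markers, total_haps), dtype=np.int8)
    chroms = np.empty(n_markers, dtype=object)
    positions = np.empty(n_markers, dtype=int)
    flip_p = (1.0 - spec.within_block_correlation) / 2.0

    # haplotype column offsets per population, in sample order
    col_slices: dict[str, slice] = {}
    offset = 0
    for pop, n in spec.populations:
        col_slices[pop] = slice(offset, offset + 2 * n)
        offset += 2 * n

    blocks_per_chrom = -(-spec.n_blocks // spec.n_chromosomes)
    for b in range(spec.n_blocks):
        chrom = str(b // blocks_per_chrom + 1)
        b_on_chrom = b % blocks_per_chrom
        start = 1 + b_on_chrom * (
            spec.markers_per_block * spec.marker_spacing_bp + spec.block_gap_bp
        )
        rows = slice(b * spec.markers_per_block, (b + 1) * spec.markers_per_block)
        chroms[rows] = chrom
        positions[rows] = start + np.arange(spec.markers_per_block) * spec.marker_spacing_bp

        p0 = rng.uniform(spec.maf_low, spec.maf_high)
        backbone = np.empty(total_haps, dtype=np.int8)
        for pop, _ in spec.populations:
            p_pop = _balding_nichols(rng, p0, spec.fst)
            sl = col_slices[pop]
            backbone[sl] = rng.random(n_hap_per_pop[pop]) < p_pop
        orient = rng.random(spec.markers_per_block) < 0.5
        block = np.where(orient[:, None], 1 - backbone[None, :], backbone[None, :])
        if flip_p > 0:
            flips = rng.random(block.shape) < flip_p
            block = np.where(flips, 1 - block, block)
        haps[rows] = block.astype(np.int8)

    alleles = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), n_markers)]
    man_df = pd.DataFrame(
        {
            "marker_id": [f"snp{i:06d}" for i in range(n_markers)],
            "chrom": chroms,
            "pos": positions,
            "ref": [a[0] for a in alleles],
            "alt": [a[1] for a in alleles],
            "modules": [set() for _ in range(n_markers)],
        }
    )
    # realized per-population frequencies
    for pop, _ in spec.populations:
        sl = col_slices[pop]
        counts = haps[:, sl].sum(axis=1)
        two_n = n_hap_per_pop[pop]
        af = counts / two_n
        man_df[f"maf_{pop}"] = np.minimum(af, 1.0 - af)
        man_df[f"mac_{pop}"] = np.minimum(counts, two_n - counts)
    manifest = MarkerManifest(man_df)
    return HaplotypePanel(haps, samples, sample_population, manifest)


# ---------------------------------------------------------------------------
# Trios
# ---------------------------------------------------------------------------

# genotype -> set of alleles a parent can transmit
_TRANSMISSIBLE = {0: (0,), 1: (0, 1), 2: (1,)}


def _compatible_children(gf: int, gm: int) -> set[int]:
    return {a + b for a in _TRANSMISSIBLE[gf] for b in _TRANSMISSIBLE[gm]}


def simulate_trios(
    panel: HaplotypePanel,
    n_trios: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PedigreeTable, pd.DataFrame]:
    """Form parent-parent-child trios from panel founders and inject
    Mendelian errors at a controlled rate.

    Trios are assigned round-robin across the panel's populations; both
    parents come from the same population. The child inherits one parental
    haplotype per chromosome (no recombination within blocks). Each child
    genotype is then replaced, with probability ``error_rate``, by a
    uniformly chosen genotype *incompatible* with its parents; sites where
    every genotype is compatible (het x het) are skipped with a warning.

    Returns the trio genotype matrix, the pedigree, and the injected-error
    ledger (family_id, marker_id, father_gt, mother_gt, original_gt,
    injected_gt) — an exact oracle for downstream Mendelian-error counts.
    """
    rng = np.random.default_rng(seed)
    by_pop: dict[str, list[str]] = {}
    for s in panel.samples:
        by_pop.setdefault(panel.sample_population[s], []).append(s)
    pops = list(by_pop)
    trios_per_pop = [n_trios // len(pops) + (1 if i < n_trios % len(pops) else 0) for i in range(len(pops))]
    for pop, k in zip(pops, trios_per_pop):
        if len(by_pop[pop]) < 2 * k:
            raise ValueError(
                f"population {pop} has {len(by_pop[pop])} founders but {2 * k} are needed for {k} trios"
            )

    manifest = panel.manifest
    chrom_arr = manifest.chroms
    chrom_ids = pd.unique(chrom_arr)
    sample_idx = {s: i for i, s in enumerate(panel.samples)}

    samples: list[str] = []
    columns: list[np.ndarray] = []
    ped_rows: list[tuple] = []
    ledger_rows: list[tuple] = []
    fam_no = 0
    for pop, k in zip(pops, trios_per_pop):
        chosen = rng.choice(len(by_pop[pop]), size=2 * k, replace=False)
        for t in range(k):
            fam_no += 1
            fam = f"fam{fam_no:03d}"
            father = by_pop[pop][chosen[2 * t]]
            mother = by_pop[pop][chosen[2 * t + 1]]
            child = f"{fam}_child"
            fi, mi = sample_idx[father], sample_idx[mother]
            f_haps = panel.haplotypes[:, [2 * fi, 2 * fi + 1]]
            m_haps = panel.haplotypes[:, [2 * mi, 2 * mi + 1]]
            child_hap_f = np.empty(panel.n_markers, dtype=np.int8)
            child_hap_m = np.empty(panel.n_markers, dtype=np.int8)
            for chrom in chrom_ids:
                rows = chrom_arr == chrom
                child_hap_f[rows] = f_haps[rows, rng.integers(0, 2)]
                child_hap_m[rows] = m_haps[rows, rng.integers(0, 2)]
            gf = f_haps.sum(axis=1).astype(np.int8)
            gm = m_haps.sum(axis=1).astype(np.int8)
            gc = (child_hap_f + child_hap_m).astype(np.int8)

            if error_rate > 0:
                hit = np.flatnonzero(rng.random(panel.n_markers) < error_rate)
                n_skipped = 0
                for i in hit:
                    incompatible = sorted({0, 1, 2} - _compatible_children(int(gf[i]), int(gm[i])))
                    if not incompatible:
                        n_skipped += 1
                        continue
                    new = int(incompatible[rng.integers(0, len(incompatible))])
                    ledger_rows.append(
                        (fam, manifest.marker_ids[i], int(gf[i]), int(gm[i]), int(gc[i]), new)
                    )
                    gc[i] = new
                if n_skipped:
                    logger.warning(
                        "%s: %d error sites skipped (het x het has no incompatible genotype)",
                        fam, n_skipped,
                    )

            samples.extend([father, mother, child])
            columns.extend([gf, gm, gc])
            ped_rows.append((fam, father, "0", "0", "1", "-9"))
            ped_rows.append((fam, mother, "0", "0", "2", "-9"))
            ped_rows.append((fam, child, father, mother, "0", "-9"))

    matrix = GenotypeMatrix(np.column_stack(columns), samples, manifest)
    pedigree = PedigreeTable(pd.DataFrame(ped_rows, columns=PedigreeTable.COLUMNS))
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["family_id", "marker_id", "father_gt", "mother_gt", "original_gt", "injected_gt"],
    )
    return matrix, pedigree, ledger


# ---------------------------------------------------------------------------
# Duplicates
# ---------------------------------------------------------------------------

def simulate_duplicates(
    matrix: GenotypeMatrix,
    pairs: int,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    exclude: tuple[str, ...] = (),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Re-genotype ``pairs`` samples with controlled corruption.

    Each duplicate site suffers, independently, a single-allele change with
    probability ``error_rate`` (0→1, 1→0 or 2, 2→1) and is set missing with
    probability ``missing_rate``. Samples in ``exclude`` (e.g. trio
    founders) are not eligible for pairing.

    Returns the duplicate matrix (sample ids suffixed ``_dup``) and the
    pair table.
    """
    rng = np.random.default_rng(seed)
    eligible = [s for s in matrix.samples if s not in set(exclude)]
    if len(eligible) < pairs:
        raise ValueError(f"only {len(eligible)} eligible samples for {pairs} duplicate pairs")
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=pairs, replace=False)]

    cols = []
    for s in chosen:
        g = matrix.column(s).copy()
        observed = g != MISSING
        err = (rng.random(len(g)) < error_rate) & observed
        for i in np.flatnonzero(err):
            if g[i] == 1:
                g[i] = 0 if rng.random() < 0.5 else 2
            else:
                g[i] = 1
        miss = rng.random(len(g)) < missing_rate
        g[miss] = MISSING
        cols.append(g)
    dup_matrix = GenotypeMatrix(
        np.column_stack(cols), [f"{s}_dup" for s in chosen], matrix.manifest
    )
    pair_table = pd.DataFrame({"sample_id": chosen, "duplicate_id": [f"{s}_dup" for s in chosen]})
    return dup_matrix, pair_table


# ---------------------------------------------------------------------------
# Imputation posteriors
# ---------------------------------------------------------------------------

def simulate_posteriors(truth: GenotypeMatrix, noise: float = 0.0, seed: int = 0) -> np.ndarray:
    """Genotype posteriors (n_markers, n_samples, 3) around the truth.

    ``posterior = (1 - noise) * onehot(truth) + noise * Dirichlet(1,1,1)``:
    noise 0 gives posteriors degenerate on the true genotype, noise 1 gives
    posteriors uniformly distributed over the probability simplex. Missing
    truth receives the pure Dirichlet draw. Rows always sum to 1.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m, n = truth.genotypes.shape
    onehot = np.zeros((m, n, 3))
    g = truth.genotypes
    for k in (0, 1, 2):
        onehot[..., k] = g == k
    missing = g == MISSING
    onehot[missing] = 1.0 / 3.0
    jitter = rng.dirichlet(np.ones(3), size=(m, n))
    post = np.where(missing[..., None], jitter, (1.0 - noise) * onehot + noise * jitter)
    return post / post.sum(axis=2, keepdims=True)
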