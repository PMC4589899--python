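"""Genotyping QC battery: trio Mendelian consistency, parent-parent-child
(P-P-C) heritability, genotype concordance, INFO scoring, and
masked-imputation accuracy.

Definitions
-----------
Mendelian error
    A child genotype at a biallelic site that cannot be composed of one
    allele from each parent (e.g. both parents homozygous reference, child
    heterozygous). Sites with any missing member are skipped and counted
    separately.
P-P-C heritability
    Per-trio genotype consistency, ``100 * (total_snps - errors) /
    total_snps`` where the denominator is the fixed post-QC SNP total (the
    reporting convention of array-validation studies); the stricter
    non-missing-site version is reported alongside.
Concordance
    Unordered allele-multiset (identity-by-state) comparison of two
    genotype calls: 2 shared alleles = fully concordant, 1 = half
    concordant, 0 = fully discordant.
INFO score
    Ratio-of-variances imputation quality: with expected dosage
    e_i = p1_i + 2 p2_i and dosage variance v_i = p1_i + 4 p2_i - e_i²,
    and theta = sum(e_i) / 2N, INFO = 1 - (mean v_i) / (2 theta (1-theta)).
    1 means perfectly certain; at theta in {0, 1} the score is undefined
    (monomorphic).

Percentages are displayed rounded half-up to 2 decimals; raw fractions are
always retained in the report objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PedigreeTable


def round_half_up(value: float, decimals: int = 2) -> float:
    """Half-up decimal rounding (table-display convention; numpy/python
    round half-even)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def _mendel_error_table() -> np.ndarray:
    """table[gf, gm, gc] = 1 iff child gc is incompatible with parents."""
    transmissible = {0: (0,), 1: (0, 1), 2: (1,)}
    table = np.ones((3, 3, 3), dtype=np.int8)
    for gf in range(3):
        for gm in range(3):
            for a in transmissible[gf]:
                for b in transmissible[gm]:
                    table[gf, gm, a + b] = 0
    return table


_MENDEL_ERROR = _mendel_error_table()


def mendelian_errors(father_gt: int, mother_gt: int, child_gt: int) -> int:
    """1 iff the child genotype cannot be formed from one allele of each
    parent at a biallelic site; all three genotypes must be non-missing."""
    for g in (father_gt, mother_gt, child_gt):
        if g not in (0, 1, 2):
            raise ValueError(f"genotypes must be 0/1/2 and non-missing, got {g}")
    return int(_MENDEL_ERROR[father_gt, mother_gt, child_gt])


@dataclass
class TrioReport:
    """Mendelian consistency of one complete trio."""

    family_id: str
    father_id: str
    mother_id: str
    child_id: str
    snps_compared: int
    skipped_missing: int
    error_count: int
    total_snps: int

    @property
    def ppc_heritability(self) -> float:
        """Percent consistency against the fixed post-QC SNP total."""
        return 100.0 * (self.total_snps - self.error_count) / self.total_snps

    @property
    def ppc_heritability_nonmissing(self) -> float:
        """Percent consistency against the per-trio non-missing count."""
        if self.snps_compared == 0:
            return 100.0
        return 100.0 * (self.snps_compared - self.error_count) / self.snps_compared

    @property
    def ppc_heritability_display(self) -> float:
        return round_half_up(self.ppc_heritability, 2)


def ppc_heritability(error_count: int, total_snps: int) -> float:
    """P-P-C heritability percentage: ``100 * (total - errors) / total``."""
    if total_snps < 1 or not 0 <= error_count <= total_snps:
        raise ValueError("need 0 <= error_count <= total_snps and total_snps >= 1")
    return 100.0 * (total_snps - error_count) / total_snps


def trio_report(
    matrix: GenotypeMatrix,
    pedigree: PedigreeTable,
    total_snps: int | None = None,
) -> list[TrioReport]:
    """Mendelian-error counts for every complete trio in the pedigree.

    ``total_snps`` fixes the heritability denominator (post-QC SNP count);
    it defaults to the matrix's marker count.
    """
    total = matrix.n_markers if total_snps is None else int(total_snps)
    reports = []
    for fam, father, mother, child in pedigree.complete_trios(matrix.samples):
        gf, gm, gc = matrix.column(father), matrix.column(mother), matrix.column(child)
        ok = (gf != MISSING) & (gm != MISSING) & (gc != MISSING)
        errors = int(_MENDEL_ERROR[gf[ok], gm[ok], gc[ok]].sum())
        reports.append(
            TrioReport(
                family_id=fam,
                father_id=father,
                mother_id=mother,
                child_id=child,
                snps_compared=int(ok.sum()),
                skipped_missing=int((~ok).sum()),
                error_count=errors,
                total_snps=total,
            )
        )
    return reports


def trio_report_frame(reports: Sequence[TrioReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.family_id, r.father_id, r.mother_id, r.child_id,
                r.snps_compared, r.error_count, r.ppc_heritability_display,
            )
            for r in reports
        ],
        columns=[
            "family_id", "father_id", "mother_id", "child_id",
            "snps_compared", "snp_errors_observed", "ppc_heritability_pct",
        ],
    )


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

FULL, HALF, DISCORDANT = "full", "half", "discordant"


def concordance_classify(genotype_a: int, genotype_b: int) -> str:
    """IBS class of two alt-count genotypes at the same marker: ``full``
    (2 shared alleles), ``half`` (1) or ``discordant`` (0)."""
    for g in (genotype_a, genotype_b):
        if g not in (0, 1, 2):
            raise ValueError(f"genotypes must be 0/1/2 and non-missing, got {g}")
    return (FULL, HALF, DISCORDANT)[abs(genotype_a - genotype_b)]


@dataclass
class ConcordanceReport:
    """Sample-SNP concordance counts for one stratum."""

    stratum: str
    tested: int
    full: int
    half: int
    discordant: int

    def __post_init__(self) -> None:
        if self.full + self.half + self.discordant != self.tested:
            raise ValueError("full + half + discordant must equal tested")

    @property
    def concordance_pct(self) -> float:
        """Fully-concordant percentage, half-up to 2 decimals."""
        return round_half_up(self.concordance_fraction * 100.0, 2)

    @property
    def concordance_fraction(self) -> float:
        return self.full / self.tested if self.tested else 1.0

    @property
    def rates_pct(self) -> tuple[float, float, float]:
        if not self.tested:
            return (100.0, 0.0, 0.0)
        return tuple(100.0 * c / self.tested for c in (self.full, self.half, self.discordant))


def concordance_counts(numerator: int, denominator: int) -> float:
    """Concordance percentage from a printed numerator/denominator pair."""
    if denominator < 1 or not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator, denominator >= 1")
    return round_half_up(100.0 * numerator / denominator, 2)


def concordance_report(
    matrix_a: GenotypeMatrix,
    matrix_b: GenotypeMatrix,
    sample_pairs: Sequence[tuple[str, str]] | None = None,
    strata: Mapping[str, np.ndarray] | None = None,
) -> dict[str, ConcordanceReport]:
    """Aggregate IBS concordance between two genotype matrices over a
    harmonized marker set.

    ``sample_pairs`` maps samples of ``matrix_a`` to their counterpart in
    ``matrix_b`` (defaults to identical positional order). Pairs with a
    missing genotype in either matrix are excluded from the denominator.
    ``strata`` maps labels to boolean marker masks; a report is returned
    per stratum plus ``"ALL"``.
    """
    if not np.array_equal(matrix_a.manifest.marker_ids, matrix_b.manifest.marker_ids):
        raise ValueError("matrices must share a harmonized marker set in the same order")
    if sample_pairs is None:
        if matrix_a.n_samples != matrix_b.n_samples:
            raise ValueError("supply sample_pairs when sample sets differ")
        sample_pairs = list(zip(matrix_a.samples, matrix_b.samples))

    ai = [matrix_a.sample_index(a) for a, _ in sample_pairs]
    bi = [matrix_b.sample_index(b) for _, b in sample_pairs]
    ga = matrix_a.genotypes[:, ai]
    gb = matrix_b.genotypes[:, bi]
    ok = (ga != MISSING) & (gb != MISSING)
    diff = np.abs(ga.astype(np.int16) - gb.astype(np.int16))

    def _report(label: str, marker_mask: np.ndarray | None) -> ConcordanceReport:
        sel = ok if marker_mask is None else ok & np.asarray(marker_mask, bool)[:, None]
        d = diff[sel]
        return ConcordanceReport(
            stratum=label,
            tested=int(sel.sum()),
            full=int((d == 0).sum()),
            half=int((d == 1).sum()),
            discordant=int((d == 2).sum()),
        )

    out = {"ALL": _report("ALL", None)}
    for label, mask in (strata or {}).items():
        out[label] = _report(label, mask)
    return out


def concordance_report_frame(reports: Mapping[str, ConcordanceReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.stratum, r.tested, r.full, r.half, r.discordant, r.concordance_pct)
            for r in reports.values()
        ],
        columns=["stratum", "tested", "full", "half", "discordant", "concordance_pct"],
    )


# ---------------------------------------------------------------------------
# INFO score
# ---------------------------------------------------------------------------

@dataclass
class InfoScore:
    raw: float
    clipped: float
    theta: float
    monomorphic: bool


def info_score(posteriors: np.ndarray, atol: float = 1e-6) -> InfoScore:
    """Imputation INFO score of one marker from its (N, 3) genotype
    posteriors.

    Raises if any posterior triple fails to sum to 1 (within ``atol``).
    theta in {0, 1} flags the marker undefined-monomorphic (raw/clipped are
    NaN there).
    """
    p = np.asarray(posteriors, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 1:
        raise ValueError("posteriors must be an (N, 3) array with N >= 1")
    if not np.allclose(p.sum(axis=1), 1.0, atol=atol):
        raise ValueError("each posterior triple must sum to 1")
    e = p[:, 1] + 2.0 * p[:, 2]
    v = p[:, 1] + 4.0 * p[:, 2] - e**2
    theta = float(e.sum() / (2 * p.shape[0]))
    if theta <= 0.0 or theta >= 1.0:
        return InfoScore(float("nan"), float("nan"), theta, True)
    raw = 1.0 - float(v.mean()) / (2.0 * theta * (1.0 - theta))
    return InfoScore(raw, max(raw, 0.0), theta, False)


# ---------------------------------------------------------------------------
# Masked-imputation evaluation
# ---------------------------------------------------------------------------

def best_guess_genotypes(posteriors: np.ndarray) -> np.ndarray:
    """Argmax genotype per posterior triple; ties go to the smaller dosage."""
    return np.argmax(np.asarray(posteriors, float), axis=-1).astype(np.int8)


@dataclass
class ImputationEvalReport:
    """Masked-SNP imputation accuracy, stratified by MAF bin."""

    mask_fraction: float
    info_threshold: float
    masked_markers: list[str]
    per_marker: pd.DataFrame  # marker_id, maf, info, accuracy_pct, n_compared
    bin_table: pd.DataFrame  # maf_bin_low, maf_bin_high, n_markers, accuracy_pct
    overall_accuracy_pct: float
    overall_accuracy_pct_info_filtered: float
    n_masked_info_filtered: int


def masked_imputation_eval(
    truth: GenotypeMatrix,
    posteriors: np.ndarray,
    mask_fraction: float = 0.002,
    info_threshold: float = 0.8,
    seed: int = 0,
) -> ImputationEvalReport:
    """Hide a random fraction of markers and score best-guess imputed
    genotypes against the hidden truth.

    ``posteriors`` is an (n_markers, n_samples, 3) array aligned with
    ``truth`` (as produced by re-imputation without the masked markers).
    Accuracy is computed only at masked sites with non-missing truth, and
    stratified by MAF bins of width 0.01 over (0, 0.5]; the headline
    accuracy additionally restricts to markers with INFO above
    ``info_threshold``.
    """
    if not 0.0 < mask_fraction < 1.0:
        raise ValueError("mask_fraction must be in (0, 1)")
    p = np.asarray(posteriors, float)
    if p.shape != (truth.n_markers, truth.n_samples, 3):
        raise ValueError("posteriors must align with the truth matrix")
    rng = np.random.default_rng(seed)
    n_mask = max(1, int(round(truth.n_markers * mask_fraction)))
    masked_idx = np.sort(rng.choice(truth.n_markers, size=n_mask, replace=False))
    masked_ids = [truth.manifest.marker_ids[i] for i in masked_idx]

    g = truth.genotypes
    observed = g != MISSING
    two_n = 2 * observed.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(observed, g, 0).sum(axis=1) / np.where(two_n > 0, two_n, 1)
    maf = np.minimum(af, 1.0 - af)

    guesses = best_guess_genotypes(p)
    rows = []
    for i in masked_idx:
        ok = observed[i]
        n_cmp = int(ok.sum())
        correct = int((guesses[i, ok] == g[i, ok]).sum())
        acc = 100.0 * correct / n_cmp if n_cmp else float("nan")
        score = info_score(p[i])
        rows.append(
            (
                truth.manifest.marker_ids[i],
                float(maf[i]),
                score.clipped if not score.monomorphic else float("nan"),
                acc,
                n_cmp,
                correct,
            )
        )
    per_marker = pd.DataFrame(
        rows, columns=["marker_id", "maf", "info", "accuracy_pct", "n_compared", "n_correct"]
    )

    # MAF bins of width 0.01 partitioning (0, 0.5]
    edges = np.round(np.arange(0.0, 0.5001, 0.01), 10)
    polymorphic = per_marker[per_marker["maf"] > 0.0]
    bin_rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = polymorphic[(polymorphic["maf"] > lo) & (polymorphic["maf"] <= hi)]
        if not len(sel):
            continue
        acc = 100.0 * sel["n_correct"].sum() / sel["n_compared"].sum()
        bin_rows.append((lo, hi, len(sel), acc))
    bin_table = pd.DataFrame(bin_rows, columns=["maf_bin_low", "maf_bin_high", "n_markers", "accuracy_pct"])

    def _overall(df: pd.DataFrame) -> float:
        n = df["n_compared"].sum()
        return 100.0 * df["n_correct"].sum() / n if n else float("nan")

    info_ok = per_marker[per_marker["info"] > info_threshold]
    return ImputationEvalReport(
        mask_fraction=mask_fraction,
        info_threshold=info_threshold,
        masked_markers=masked_ids,
        per_marker=per_marker,
        bin_table=bin_table,
        overall_accuracy_pct=_overall(per_marker),
        overall_accuracy_pct_info_filtered=_overall(info_ok),
        n_masked_info_filtered=int(len(info_ok)),
    )
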