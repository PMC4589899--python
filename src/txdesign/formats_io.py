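"""Readers and writers for the standard interchange formats the toolkit
touches: VCF 4.x (GT only), PLINK .ped/.map, .fam-style pedigrees, TSV
marker manifests, genotype-posterior tables, and run configuration.

Conventions
-----------
* All positions are written and read 1-based.
* Genotypes are alt-allele counts; missing is a distinct sentinel
  (:data:`txdesign.containers.MISSING`), never 0.
* No strand flipping or allele harmonization is attempted: marker identity
  is (id, chrom, pos, ref, alt) and mismatches are errors.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix, HaplotypePanel, MarkerManifest, PedigreeTable

logger = logging.getLogger("txdesign")

_PED_ALLELES = {"A", "C", "G", "T", "0"}


class FormatError(ValueError):
    """A file violated the contract of its declared format."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(samples: list[str], contigs: list[str]) -> str:
    cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + samples)
    contig_lines = "".join(f"##contig=<ID={c}>\n" for c in contigs)
    return (
        "##fileformat=VCFv4.2\n"
        f"{contig_lines}"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        f"{cols}\n"
    )


def write_haplotype_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a phased panel as a GT-only VCF."""
    man = panel.manifest
    with open(path, "w") as fh:
        fh.write(_vcf_header(panel.samples, list(pd.unique(man.chroms))))
        for i in range(panel.n_markers):
            row = man.df.iloc[i]
            gts = "\t".join(
                f"{panel.haplotypes[i, 2 * j]}|{panel.haplotypes[i, 2 * j + 1]}"
                for j in range(panel.n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.marker_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_haplotype_vcf(
    path: str | Path,
    population_map: dict[str, str],
    on_invalid: str = "error",
) -> HaplotypePanel:
    """Read a phased, biallelic VCF into a :class:`HaplotypePanel`.

    Parameters
    ----------
    population_map
        Sample id → population label; every VCF sample must be labelled.
    on_invalid
        ``"error"`` (strict, default) raises on unphased or multiallelic
        records; ``"skip"`` drops them with a log message.
    """
    if on_invalid not in ("error", "skip"):
        raise ValueError("on_invalid must be 'error' or 'skip'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unlabelled = [s for s in samples if s not in population_map]
    if unlabelled:
        raise FormatError(f"samples without population label: {unlabelled[:5]}")

    rows, hap_rows, seen_ids = [], [], set()
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            if on_invalid == "skip":
                logger.warning("skipping multiallelic record %s", vid)
                continue
            raise FormatError(f"multiallelic record {vid} at {var.CHROM}:{var.POS}")
        if vid in seen_ids:
            raise FormatError(f"duplicate marker id {vid}")
        alleles = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        for j, g in enumerate(var.genotypes):
            if len(g) != 3:
                raise FormatError(f"non-diploid genotype for sample {samples[j]} at {vid}")
            a1, a2, phased = g
            if a1 < 0 or a2 < 0:
                raise FormatError(f"missing GT for sample {samples[j]} at {vid}")
            if not phased:
                if on_invalid == "skip":
                    logger.warning("skipping unphased record %s", vid)
                    ok = False
                    break
                raise FormatError(f"unphased genotype for sample {samples[j]} at record {vid}")
            alleles[2 * j] = a1
            alleles[2 * j + 1] = a2
        if not ok:
            continue
        seen_ids.add(vid)
        rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0], set()))
        hap_rows.append(alleles)

    manifest = MarkerManifest(
        pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "ref", "alt", "modules"])
    )
    haps = np.array(hap_rows, dtype=np.int8) if hap_rows else np.empty((0, 2 * len(samples)), np.int8)
    return HaplotypePanel(haps, samples, {s: population_map[s] for s in samples}, manifest)


def write_genotype_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased genotypes as a GT-only VCF (0/0, 0/1, 1/1, ./.)."""
    codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    man = matrix.manifest
    with open(path, "w") as fh:
        fh.write(_vcf_header(matrix.samples, list(pd.unique(man.chroms))))
        for i in range(matrix.n_markers):
            row = man.df.iloc[i]
            gts = "\t".join(codes[int(g)] for g in matrix.genotypes[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.marker_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, geno_rows = [], []
    seen = set()
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise FormatError(f"multiallelic record {vid}")
        if vid in seen:
            raise FormatError(f"duplicate marker id {vid}")
        seen.add(vid)
        g = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            a1, a2 = gt[0], gt[1]
            g[j] = MISSING if (a1 < 0 or a2 < 0) else a1 + a2
        rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0], set()))
        geno_rows.append(g)
    manifest = MarkerManifest(
        pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "ref", "alt", "modules"])
    )
    genos = np.array(geno_rows, dtype=np.int8) if geno_rows else np.empty((0, len(samples)), np.int8)
    return GenotypeMatrix(genos, samples, manifest)


# ---------------------------------------------------------------------------
# PLINK .ped / .map
# ---------------------------------------------------------------------------

def write_plink(matrix: GenotypeMatrix, prefix: str | Path, pedigree: PedigreeTable | None = None) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` (whitespace-delimited)."""
    prefix = Path(prefix)
    man = matrix.manifest
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in man.df.itertuples():
            fh.write(f"{r.chrom}\t{r.marker_id}\t0\t{r.pos}\n")
    ped_meta = {}
    if pedigree is not None:
        ped_meta = {r.individual_id: r for r in pedigree.df.itertuples()}
    ref = man.df["ref"].to_numpy()
    alt = man.df["alt"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for j, sample in enumerate(matrix.samples):
            meta = ped_meta.get(sample)
            head = (
                [meta.family_id, sample, meta.father_id, meta.mother_id, meta.sex, meta.phenotype]
                if meta is not None
                else [sample, sample, "0", "0", "0", "-9"]
            )
            alleles = []
            for i in range(matrix.n_markers):
                g = matrix.genotypes[i, j]
                if g == MISSING:
                    alleles.extend(("0", "0"))
                else:
                    alleles.extend((alt[i] if g >= 1 else ref[i], alt[i] if g == 2 else ref[i]))
            fh.write(" ".join(head + alleles) + "\n")


def _read_plink(prefix: str | Path, manifest: MarkerManifest) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_df = pd.read_csv(
        prefix.with_suffix(".map"), sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos"], dtype=str,
    )
    order = manifest.index_of(map_df["marker_id"])
    if sorted(order.tolist()) != list(range(len(manifest))):
        raise FormatError(".map markers do not match the supplied manifest")
    ref = manifest.df["ref"].to_numpy()
    alt = manifest.df["alt"].to_numpy()
    samples, columns = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(map_df):
                raise FormatError(
                    f".ped line for {fields[1] if len(fields) > 1 else '?'} has {len(fields) - 6} "
                    f"allele fields, expected {2 * len(map_df)}"
                )
            samples.append(fields[1])
            g = np.empty(len(manifest), dtype=np.int8)
            for k in range(len(map_df)):
                a1, a2 = fields[6 + 2 * k], fields[7 + 2 * k]
                if a1 not in _PED_ALLELES or a2 not in _PED_ALLELES:
                    raise FormatError(f"invalid allele symbol {a1!r}/{a2!r} in .ped")
                i = order[k]
                if a1 == "0" or a2 == "0":
                    g[i] = MISSING
                    continue
                count = 0
                for a in (a1, a2):
                    if a == alt[i]:
                        count += 1
                    elif a != ref[i]:
                        raise FormatError(
                            f"allele {a!r} at marker {manifest.marker_ids[i]} matches neither "
                            f"ref={ref[i]} nor alt={alt[i]}"
                        )
                g[i] = count
            columns.append(g)
    genos = np.column_stack(columns) if columns else np.empty((len(manifest), 0), np.int8)
    return GenotypeMatrix(genos, samples, manifest)


def read_genotypes(path: str | Path, dialect: str = "vcf", manifest: MarkerManifest | None = None) -> GenotypeMatrix:
    """Read unphased genotypes from VCF or PLINK .ped/.map.

    For the ``plink_ped`` dialect a manifest must be supplied: .ped carries
    allele letters, and ref/alt orientation comes from the manifest. When a
    manifest is supplied, marker order follows the manifest.
    """
    if dialect == "vcf":
        matrix = _read_genotype_vcf(path)
        if manifest is not None:
            order = manifest.index_of(matrix.manifest.marker_ids)
            inv = np.empty_like(order)
            inv[order] = np.arange(len(order))
            matrix = GenotypeMatrix(matrix.genotypes[inv], matrix.samples, manifest)
        return matrix
    if dialect == "plink_ped":
        if manifest is None:
            raise ValueError("plink_ped dialect requires a manifest for allele orientation")
        return _read_plink(Path(str(path)).with_suffix(""), manifest)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Pedigree (.fam dialect)
# ---------------------------------------------------------------------------

def write_pedigree(pedigree: PedigreeTable, path: str | Path) -> None:
    pedigree.df.to_csv(path, sep="\t", header=False, index=False)


def read_pedigree(path: str | Path) -> PedigreeTable:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=PedigreeTable.COLUMNS, dtype=str)
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# Marker manifest TSV
# ---------------------------------------------------------------------------

def write_manifest(manifest: MarkerManifest, path: str | Path) -> None:
    out = manifest.df.copy()
    out["modules"] = out["modules"].apply(lambda m: ",".join(sorted(m)))
    out.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> MarkerManifest:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str, "ref": str, "alt": str})
    df["modules"] = df["modules"].fillna("").apply(lambda s: set(s.split(",")) - {""})
    for col in df.columns:
        if col.startswith("mac_"):
            df[col] = df[col].astype("Int64")
    return MarkerManifest(df)


# ---------------------------------------------------------------------------
# Genotype posteriors TSV
# ---------------------------------------------------------------------------

def write_posteriors(
    posteriors: np.ndarray, marker_ids: np.ndarray, samples: list[str], path: str | Path
) -> None:
    """Write an (n_markers, n_samples, 3) posterior array as a long TSV with
    columns marker_id, sample_id, p0, p1, p2."""
    m, n, _ = posteriors.shape
    with open(path, "w") as fh:
        fh.write("marker_id\tsample_id\tp0\tp1\tp2\n")
        for i in range(m):
            for j in range(n):
                p = posteriors[i, j]
                fh.write(f"{marker_ids[i]}\t{samples[j]}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")


def read_posteriors(
    path: str | Path, marker_ids: np.ndarray, samples: list[str]
) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "sample_id": str})
    midx = {m: i for i, m in enumerate(marker_ids)}
    sidx = {s: j for j, s in enumerate(samples)}
    out = np.full((len(marker_ids), len(samples), 3), np.nan)
    rows = df["marker_id"].map(midx).to_numpy()
    cols = df["sample_id"].map(sidx).to_numpy()
    if np.isnan(rows.astype(float)).any() or np.isnan(cols.astype(float)).any():
        raise FormatError("posterior table contains markers/samples not in the target frame")
    out[rows.astype(int), cols.astype(int)] = df[["p0", "p1", "p2"]].to_numpy()
    if np.isnan(out).any():
        raise FormatError("posterior table does not cover every marker/sample combination")
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "ld_window_bp": 250_000,
    "r2_threshold": 0.8,
    "array_budget": 782_000,
    "min_mac_exclusive": 5,
    "maf_cutoffs": {"CEU": 0.02, "AFR": 0.05},
    "coverage_maf_cutoffs": [0.01, 0.05],
    "mask_fraction": 0.002,
    "info_threshold": 0.8,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a declarative run configuration, merged over defaults, and log
    the resolved values."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError("config must be a YAML mapping")
        config.update(user)
    logger.info("resolved config: %s", config)
    return config
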