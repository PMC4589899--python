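"""Published QC summary tables from the TxArray validation genotyping
experiment (85 HapMap samples, including eight trios, on the ~782K-marker
transplant genotyping array).

These are the printed summary *counts* — error counts, overlap and
concordant-call totals — from which the percentage columns of the
validation tables derive. They serve as worked-example inputs for the
qc_metrics formulas; no individual-level genotype data is included.
"""

from __future__ import annotations

import pandas as pd

#: genome-wide SNPs passing manufacturing/genotyping QC, the fixed
#: denominator for P-P-C heritability
TOTAL_POSTQC_SNPS = 767_203


def hapmap_trio_validation() -> pd.DataFrame:
    """Mendelian-error counts for the eight HapMap validation trios.

    Columns: ancestry, family_id, father, mother, child, snp_errors, and
    the published heritability percentage (``published_ppc_pct``).
    """
    rows = [
        ("CEU", "1334", "NA12144", "NA12145", "NA10846", 3757, 99.51),
        ("CEU", "1340", "NA06994", "NA07000", "NA07029", 3600, 99.53),
        ("CEU", "1340", "NA07022", "NA07056", "NA07019", 264, 99.97),
        ("CEU", "1463", "NA12891", "NA12892", "NA12878", 869, 99.89),
        ("YRI", "Y004", "NA18501", "NA18502", "NA18500", 4397, 99.43),
        ("YRI", "Y009", "NA18507", "NA18508", "NA18506", 4672, 99.39),
        ("YRI", "Y045", "NA19200", "NA19201", "NA19202", 602, 99.92),
        ("YRI", "Y058", "NA19223", "NA19222", "NA19221", 936, 99.88),
    ]
    return pd.DataFrame(
        rows,
        columns=["ancestry", "family_id", "father", "mother", "child", "snp_errors", "published_ppc_pct"],
    )


def reference_concordance_validation() -> pd.DataFrame:
    """Concordance of array calls against the HapMap2 and 1KGP reference
    panels: overlapping sample-SNP combinations tested, concordant calls,
    and the published percentage, per panel/ancestry/region stratum.
    """
    rows = [
        ("All", "HM2", "ALL", 85, 22_944_075, 22_843_908, 99.56),
        ("All", "HM2", "EUR", 48, 13_058_670, 12_986_021, 99.44),
        ("All", "HM2", "ASN", 24, 6_414_064, 6_396_803, 99.73),
        ("All", "HM2", "AFR", 13, 3_471_341, 3_461_084, 99.70),
        ("ChrX", "HM2", "ALL", 85, 515_791, 514_641, 99.78),
        ("MHC", "HM2", "ALL", 85, 619_108, 615_244, 99.38),
        ("All", "1KGP", "ALL", 55, 36_430_433, 36_241_576, 99.48),
        ("All", "1KGP", "EUR", 27, 17_830_297, 17_716_762, 99.36),
        ("All", "1KGP", "ASN", 21, 13_953_847, 13_905_332, 99.65),
        ("All", "1KGP", "AFR", 7, 4_646_289, 4_619_482, 99.42),
        ("ChrX", "1KGP", "ALL", 55, 937_853, 933_799, 99.57),
        ("MHC", "1KGP", "ALL", 55, 232_410, 230_458, 99.16),
    ]
    return pd.DataFrame(
        rows,
        columns=["snps", "reference_panel", "ancestry", "n_samples", "tested", "concordant", "published_pct"],
    )


def duplicate_concordance_validation() -> dict[str, float]:
    """Published duplicate-pair concordance rates (50 duplicate pairs,
    ~742K-765K SNPs compared per pair), as percentages."""
    return {"full": 99.657, "half": 0.341, "discordant": 0.002}
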