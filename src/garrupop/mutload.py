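"""Deleterious-load proportions and the divergence-based mutation rate.

Effect categories are consumed from an annotation table (the annotation
tool itself is out of scope) and mapped to two severity classes:
frameshift / stop-gain / stop-loss / splicing variants are *strong*
deleterious, missense / synonymous are *slight* deleterious; anything
else is unclassified.  Per-sample load is the proportion of classified
alt-carrying genotypes of each zygosity that fall in each class, and
groups are compared with a two-sided Wilcoxon rank-sum test.

The divergence-based mutation rate is mu = d * g / (2 T): genome-wide
nucleotide divergence d (fraction), generation time g (years), divergence
time T (years); units are mutations per site per generation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .vario import GenotypeMatrix

STRONG = frozenset({"frameshift", "stopgain", "stoploss", "splicing"})
SLIGHT = frozenset({"missense", "synonymous"})

#: Annotation-tool synonym normalization (SnpEff/VEP/ANNOVAR spellings).
CATEGORY_SYNONYMS = {
    "stop_gained": "stopgain",
    "stop gain": "stopgain",
    "stop_lost": "stoploss",
    "stop loss": "stoploss",
    "frameshift_variant": "frameshift",
    "splice": "splicing",
    "splicing_variant": "splicing",
    "splice_site": "splicing",
    "missense_variant": "missense",
    "nonsynonymous": "missense",
    "nonsynonymous snv": "missense",
    "synonymous_variant": "synonymous",
    "synonymous snv": "synonymous",
}


def normalize_category(category: str) -> str:
    c = str(category).strip().lower()
    return CATEGORY_SYNONYMS.get(c, c)


def classify_severity(category: str) -> str:
    """'strong', 'slight' or 'unclassified' for one effect category."""
    c = normalize_category(category)
    if c in STRONG:
        return "strong"
    if c in SLIGHT:
        return "slight"
    return "unclassified"


def load_proportions(
    gm: GenotypeMatrix,
    effects: pd.DataFrame,
    sample: str,
) -> pd.DataFrame:
    """Zygosity-stratified load profile for one sample.

    For each zygosity (dosage 2 = homozygous alt, 1 = heterozygous), the
    proportion of that sample's classified alt-carrying genotypes that are
    strong (resp. slight); reference-homozygous and missing genotypes are
    excluded.  Zero denominators leave the proportion NaN.

    ``effects`` columns: scaffold, pos, category.

    Returns rows (sample, zygosity, cls, count, denominator, proportion).
    """
    j = gm.sample_index(sample)
    eff = effects.copy()
    eff["severity"] = eff["category"].map(classify_severity)
    key = gm.sites[["scaffold", "pos"]].copy()
    key["dosage"] = gm.geno[:, j]
    merged = key.merge(eff[["scaffold", "pos", "severity"]], on=["scaffold", "pos"], how="inner")
    rows = []
    for zyg_name, dosage in (("homozygous", 2), ("heterozygous", 1)):
        sub = merged[(merged["dosage"] == dosage) & (merged["severity"] != "unclassified")]
        denom = len(sub)
        for cls in ("strong", "slight"):
            count = int((sub["severity"] == cls).sum())
            rows.append(
                {
                    "sample": sample,
                    "zygosity": zyg_name,
                    "cls": cls,
                    "count": count,
                    "denominator": denom,
                    "proportion": count / denom if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)


def load_profiles(gm: GenotypeMatrix, effects: pd.DataFrame, samples=None) -> pd.DataFrame:
    ids = list(samples) if samples is not None else list(gm.samples)
    return pd.concat([load_proportions(gm, effects, s) for s in ids], ignore_index=True)


def compare_groups(
    proportions_a,
    proportions_b,
    test: str = "ranksum",
):
    """Two-sided comparison of per-sample load proportions between groups.

    Default is the Wilcoxon rank-sum (Mann-Whitney U) test with an exact
    null for combined n <= 20 and the continuity-corrected normal
    approximation otherwise; ``test='ttest'`` switches to Welch's t.
    Undefined (NaN) proportions are dropped with a warning.

    Returns (statistic, p_value).
    """
    import logging

    a = np.asarray(list(proportions_a), dtype=float)
    b = np.asarray(list(proportions_b), dtype=float)
    n_bad = int(np.isnan(a).sum() + np.isnan(b).sum())
    if n_bad:
        logging.getLogger("garrupop").warning("compare_groups: dropping %d undefined proportions", n_bad)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 defined proportions per group")
    if test == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test != "ranksum":
        raise ValueError(f"unknown test {test!r}")
    method = "exact" if (len(a) + len(b) <= 20) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties in some versions; fall back
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def estimate_mutation_rate(d: float, g: float, T: float) -> float:
    """mu = d * g / (2 T), mutations per site per generation.

    d: genome-wide nucleotide divergence as a fraction in [0, 1];
    g: generation time in years; T: divergence time in years.
    """
    if T <= 0:
        raise ValueError("divergence time must be positive")
    if g <= 0:
        raise ValueError("generation time must be positive")
    if not 0 <= d <= 1:
        raise ValueError("divergence must be a fraction in [0, 1]")
    return d * g / (2.0 * T)
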