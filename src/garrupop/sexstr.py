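"""Depth-based sex-scaffold classification, sample sexing, and STR panels.

Birds are female-heterogametic (males ZZ, females ZW), so normalized read
depth separates scaffold classes cleanly: a W scaffold is near zero in
males and ~0.5 in females; a Z scaffold is ~1 in males and ~0.5 in
females; autosomes are ~1 in both.  The same W-depth signal sexes the
samples.  STR panels: autosomal kinship markers (4-bp unit, at least five
distinct alleles, complete calls) and W-linked sex markers (homozygous
calls in every female, missing in every male).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SexClassThresholds:
    """Depth-ratio windows for scaffold classification.

    Not tool-standardized anywhere; these follow ZW copy-number expectation
    with generous noise margins and are all adjustable.
    """

    w_male_max: float = 0.1
    half_lo: float = 0.3
    half_hi: float = 0.7
    full_lo: float = 0.8
    full_hi: float = 1.2
    min_len: int = 50_000


def normalize_depth(depths: pd.DataFrame, sexes: dict[str, str]) -> pd.DataFrame:
    """Two-pass per-sample depth normalization.

    Pass 1 normalizes by each sample's median depth over all scaffolds.
    W scaffolds are then spotted from the male side (near-zero male depth;
    the male median is robust because W scaffolds contribute nothing to
    it), the normalizer is recomputed without them, and a provisional
    classification on those ratios selects the autosomal scaffolds used for
    the final normalizer.  This keeps the female median from landing on the
    half-depth Z/W level; it assumes autosomes are the majority scaffold
    class, as in any real assembly.

    ``depths`` columns: sample, scaffold, mean_depth.  Returns the table
    with a ``norm_depth`` column added.
    """
    sex_vals = {sexes[s] for s in depths["sample"].unique()}
    if not {"M", "F"} <= sex_vals:
        raise ValueError("need at least one male and one female")
    if depths["scaffold"].nunique() < 2:
        raise ValueError("cannot normalize a single-scaffold depth table")

    def normalize(tbl, scaffold_subset=None):
        use = tbl if scaffold_subset is None else tbl[tbl["scaffold"].isin(scaffold_subset)]
        norm = use.groupby("sample")["mean_depth"].median()
        if (norm <= 0).any():
            bad = norm[norm <= 0].index.tolist()
            raise ValueError(f"all-zero depth for sample(s) {bad}")
        out = tbl.copy()
        out["norm_depth"] = out["mean_depth"] / out["sample"].map(norm)
        return out

    pass1 = normalize(depths)
    males = [s for s in depths["sample"].unique() if sexes.get(s) == "M"]
    male_ratio = (
        pass1[pass1["sample"].isin(males)].groupby("scaffold")["norm_depth"].mean()
    )
    w_like = set(male_ratio[male_ratio < 0.1].index)
    non_w = set(depths["scaffold"]) - w_like
    pass2 = normalize(depths, non_w) if non_w else pass1
    prov = classify_scaffolds(pass2, sexes, scaffold_lengths=None)
    autosomal = set(prov.loc[prov["cls"] == "autosome", "scaffold"])
    return normalize(depths, autosomal) if autosomal else pass2


def classify_scaffolds(
    norm: pd.DataFrame,
    sexes: dict[str, str],
    thresholds: SexClassThresholds | None = None,
    scaffold_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Z/W/autosome calls from sex-stratified mean normalized depth.

    W: male ratio < 0.1 and female ratio in [0.3, 0.7];
    Z: male ratio in [0.8, 1.2] and female ratio in [0.3, 0.7];
    autosome: both in [0.8, 1.2]; anything else (or scaffolds shorter than
    ``min_len`` when lengths are supplied) is ambiguous.

    Returns a DataFrame (scaffold, ratio_m, ratio_f, cls).
    """
    thr = thresholds or SexClassThresholds()
    t = norm.copy()
    t["sex"] = t["sample"].map(sexes)
    by = t.groupby(["scaffold", "sex"])["norm_depth"].mean().unstack()
    rows = []
    for scaf, r in by.iterrows():
        rm, rf = float(r.get("M", np.nan)), float(r.get("F", np.nan))
        if scaffold_lengths is not None and scaffold_lengths.get(scaf, np.inf) < thr.min_len:
            cls = "ambiguous"
        elif rm < thr.w_male_max and thr.half_lo <= rf <= thr.half_hi:
            cls = "W"
        elif thr.full_lo <= rm <= thr.full_hi and thr.half_lo <= rf <= thr.half_hi:
            cls = "Z"
        elif thr.full_lo <= rm <= thr.full_hi and thr.full_lo <= rf <= thr.full_hi:
            cls = "autosome"
        else:
            cls = "ambiguous"
        rows.append({"scaffold": scaf, "ratio_m": rm, "ratio_f": rf, "cls": cls})
    return pd.DataFrame(rows)


def call_sample_sex(
    norm: pd.DataFrame,
    w_scaffolds,
    male_max: float = 0.1,
    female_min: float = 0.3,
) -> pd.DataFrame:
    """Sex per sample from mean normalized depth over W scaffolds.

    w_ratio < male_max -> male (ZZ, no W copy); w_ratio > female_min ->
    female (one W copy); in between -> ambiguous.
    """
    w_scaffolds = set(w_scaffolds)
    if not w_scaffolds:
        raise ValueError("no W scaffolds: cannot call sex")
    sub = norm[norm["scaffold"].isin(w_scaffolds)]
    rows = []
    for sample, grp in sub.groupby("sample"):
        w_ratio = float(grp["norm_depth"].mean())
        if w_ratio < male_max:
            sex = "M"
        elif w_ratio > female_min:
            sex = "F"
        else:
            sex = "ambiguous"
        rows.append({"sample": sample, "w_ratio": w_ratio, "sex": sex})
    return pd.DataFrame(rows)


def apply_mapping_rate_veto(classes: pd.DataFrame, mapping_rates: pd.DataFrame, min_rate: float = 0.2) -> pd.DataFrame:
    """Optional external verification: demote depth-based Z/W calls whose
    precomputed alignment mapping rate (fraction) is <= ``min_rate``.

    ``mapping_rates`` columns: scaffold, mapping_rate.
    """
    out = classes.merge(mapping_rates, on="scaffold", how="left")
    veto = out["cls"].isin(["Z", "W"]) & out["mapping_rate"].notna() & (out["mapping_rate"] <= min_rate)
    out.loc[veto, "cls"] = "ambiguous"
    return out


# ---------------------------------------------------------------------------
# STR table handling


def _sample_columns(strs: pd.DataFrame) -> list[str]:
    return [c for c in strs.columns if c not in ("locus_id", "scaffold", "pos", "unit")]


def _parse_genotype(val):
    """'a1/a2' -> (int, int); './.' or malformed -> None."""
    if not isinstance(val, str) or "/" not in val:
        return None
    a, b = val.split("/", 1)
    if a == "." or b == ".":
        return None
    try:
        return int(a), int(b)
    except ValueError:
        return None


def allele_spectrum(strs_row, sample_cols) -> dict[int, int]:
    """Allele length -> observation count over called genotypes."""
    spec: dict[int, int] = {}
    for c in sample_cols:
        gt = _parse_genotype(strs_row[c])
        if gt is None:
            continue
        for a in gt:
            spec[a] = spec.get(a, 0) + 1
    return spec


def filter_kinship_strs(
    strs: pd.DataFrame,
    unit_len: int = 4,
    min_alleles: int = 5,
    require_complete: bool = True,
    samples=None,
) -> pd.DataFrame:
    """Kinship-marker panel: unit length 4 bp, at least ``min_alleles``
    distinct alleles ('greater than four' read strictly as >= 5), and —
    when ``require_complete`` — no missing genotype across the cohort."""
    cols = list(samples) if samples is not None else _sample_columns(strs)
    keep = []
    for _, row in strs.iterrows():
        if int(row["unit"]) != unit_len:
            keep.append(False)
            continue
        gts = [_parse_genotype(row[c]) for c in cols]
        if require_complete and any(g is None for g in gts):
            keep.append(False)
            continue
        alleles = {a for g in gts if g is not None for a in g}
        keep.append(len(alleles) >= min_alleles)
    return strs[np.array(keep, dtype=bool)].reset_index(drop=True)


def pic(allele_freqs) -> float:
    """Polymorphism information content (Botstein et al. 1980):

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(list(allele_freqs), dtype=float)
    if p.size == 0:
        raise ValueError("empty allele spectrum")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("allele frequencies must sum to 1")
    p2 = p**2
    cross = (p2.sum() ** 2 - (p2**2).sum()) / 2
    return float(1.0 - p2.sum() - 2 * cross)


def str_pic_table(strs: pd.DataFrame, samples=None) -> pd.DataFrame:
    """PIC and distinct-allele count per locus (from observed frequencies)."""
    cols = list(samples) if samples is not None else _sample_columns(strs)
    rows = []
    for _, row in strs.iterrows():
        spec = allele_spectrum(row, cols)
        tot = sum(spec.values())
        entry = {"locus_id": row["locus_id"], "n_alleles": len(spec)}
        entry["pic"] = pic([v / tot for v in spec.values()]) if tot else np.nan
        rows.append(entry)
    return pd.DataFrame(rows)


def select_sex_strs(strs: pd.DataFrame, w_scaffolds, sexes: dict[str, str]) -> pd.DataFrame:
    """W-linked sex-marker panel.

    Keeps loci on W scaffolds where every female has a called genotype with
    two EQUAL allele lengths (hemizygous, recorded homozygous) and every
    male is missing.
    """
    w_scaffolds = set(w_scaffolds)
    cols = _sample_columns(strs)
    females = [c for c in cols if sexes.get(c) == "F"]
    males = [c for c in cols if sexes.get(c) == "M"]
    keep = []
    for _, row in strs.iterrows():
        if row["scaffold"] not in w_scaffolds:
            keep.append(False)
            continue
        ok = True
        for c in males:
            if _parse_genotype(row[c]) is not None:
                ok = False
                break
        if ok:
            for c in females:
                gt = _parse_genotype(row[c])
                if gt is None or gt[0] != gt[1]:
                    ok = False
                    break
        keep.append(ok)
    return strs[np.array(keep, dtype=bool)].reset_index(drop=True)


def major_minor_diff(strs: pd.DataFrame, samples=None) -> float:
    """Mean |major - minor| allele-length difference (bp) over polymorphic loci.

    Major/minor are the most and second-most frequent allele lengths; a
    frequency tie makes the smaller length major.  Undefined (NaN) when all
    loci are monomorphic.
    """
    cols = list(samples) if samples is not None else _sample_columns(strs)
    diffs = []
    for _, row in strs.iterrows():
        spec = allele_spectrum(row, cols)
        if len(spec) < 2:
            continue
        ranked = sorted(spec.items(), key=lambda kv: (-kv[1], kv[0]))
        diffs.append(abs(ranked[0][0] - ranked[1][0]))
    if not diffs:
        return np.nan
    return float(np.mean(diffs))
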