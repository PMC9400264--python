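"""Dual-statistic selective-sweep scan.

Windowed pooled heterozygosity Hp within the focal population,
genome-wide zHp standardization, windowed Weir-Cockerham (1984) F_ST
between the focal and comparison populations, the top-1% dual-threshold
overlap procedure, 10-kb pi / Tajima's D flank profiling around hits, and
gene annotation of hit windows.

Hp for a window is 2 * (sum n_maj) * (sum n_min) / (sum n_maj + sum n_min)^2
where n_maj / n_min are the major/minor allele OBSERVATION COUNTS per SNP
within the focal population; windows need more than ``min_snps`` (10) SNPs
to be eligible.  zHp = (Hp - mu) / sigma with mu, sigma the genome-wide
mean and sample standard deviation over eligible windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vario import GenotypeMatrix, Window, assign_windows
from . import popdiv

MIN_WINDOW_SNPS = 10  # windows need > this many SNPs for Hp / Fst


def _major_minor_counts(gm: GenotypeMatrix, idx):
    """Per-site (n_maj, n_min) observation counts in the focal population.

    Equal counts tie-break: the alphabetically smaller allele is major
    (ref/alt labels only matter for the tie, counts are symmetric).
    """
    alt, m = gm.alt_counts(idx)
    ref_count = m - alt
    n_maj = np.maximum(ref_count, alt)
    n_min = np.minimum(ref_count, alt)
    return n_maj, n_min


def hp_windows(
    gm: GenotypeMatrix,
    windows: list[Window],
    pop=None,
    min_snps: int = MIN_WINDOW_SNPS,
) -> pd.DataFrame:
    """Pooled heterozygosity per window (NaN where <= min_snps SNPs)."""
    idx = gm.sample_indices(pop) if pop is not None else None
    if pop is not None and len(pop) == 0:
        raise ValueError("empty focal population")
    n_maj, n_min = _major_minor_counts(gm, idx)
    seg = (n_min + n_maj) > 0
    wi = assign_windows(gm, windows)
    rows = []
    for k, w in enumerate(windows):
        in_w = (wi == k) & seg
        n = int(in_w.sum())
        hp = np.nan
        if n > min_snps:
            smaj = float(n_maj[in_w].sum())
            smin = float(n_min[in_w].sum())
            hp = 2 * smaj * smin / (smaj + smin) ** 2
        rows.append({"scaffold": w.scaffold, "start": w.start, "end": w.end, "n_snps": n, "hp": hp})
    return pd.DataFrame(rows)


def hp_single_window(n_maj: np.ndarray, n_min: np.ndarray) -> float:
    """Hp from explicit per-site major/minor counts (no eligibility rule)."""
    smaj, smin = float(np.sum(n_maj)), float(np.sum(n_min))
    if smaj + smin == 0:
        return np.nan
    return 2 * smaj * smin / (smaj + smin) ** 2


def zhp_standardize(hp: np.ndarray) -> np.ndarray:
    """Genome-wide Z-score of window Hp: (x - mu) / sigma.

    mu and sigma (sample standard deviation, n-1) are taken over defined
    windows; NaN windows stay NaN.  A degenerate genome (sigma = 0, or
    fewer than 2 defined windows) is an error.
    """
    hp = np.asarray(hp, dtype=float)
    ok = np.isfinite(hp)
    if ok.sum() < 2:
        raise ValueError("need >= 2 defined Hp windows")
    mu = hp[ok].mean()
    sigma = hp[ok].std(ddof=1)
    if sigma <= 1e-12 * max(1.0, abs(mu)):  # constant up to rounding
        raise ValueError("sigma = 0: Hp is constant, zHp undefined")
    out = np.full_like(hp, np.nan)
    out[ok] = (hp[ok] - mu) / sigma
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def wc_site_components(gm: GenotypeMatrix, idx_a, idx_b):
    """Per-site Weir-Cockerham (1984) variance components (a, b, c) for two
    populations, from unphased diploid genotypes.

    Sites with fewer than 2 called diploids in either population are
    returned as NaN components.
    """
    comps = []
    for idx in (idx_a, idx_b):
        g = gm.geno[:, idx]
        called = g >= 0
        n_i = called.sum(axis=1).astype(float)  # diploids
        alt = np.where(called, g, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = alt / (2 * n_i)
            h_i = np.where(called, g == 1, False).sum(axis=1) / n_i
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c


def wc_fst_windows(
    gm: GenotypeMatrix,
    pop_a,
    pop_b,
    windows: list[Window],
    min_snps: int = MIN_WINDOW_SNPS,
) -> pd.DataFrame:
    """Windowed ratio-of-sums Weir-Cockerham F_ST = sum(a) / sum(a+b+c).

    Monomorphic sites contribute zero to both sums and are skipped; windows
    with fewer than ``min_snps`` usable SNPs (or non-positive denominator)
    are NaN.
    """
    ia, ib = gm.sample_indices(pop_a), gm.sample_indices(pop_b)
    a, b, c = wc_site_components(gm, ia, ib)
    pooled = gm.alt_freq(np.concatenate([ia, ib]))
    poly = (pooled > 0) & (pooled < 1)
    usable = np.isfinite(a) & poly
    wi = assign_windows(gm, windows)
    rows = []
    for k, w in enumerate(windows):
        in_w = (wi == k) & usable
        n = int(in_w.sum())
        fst = np.nan
        if n >= min_snps:
            num = float(a[in_w].sum())
            den = float((a[in_w] + b[in_w] + c[in_w]).sum())
            if den > 0:
                fst = num / den
        rows.append({"scaffold": w.scaffold, "start": w.start, "end": w.end, "n_snps": n, "fst": fst})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dual-threshold overlap


def dual_threshold_overlap(
    fst_stats: pd.DataFrame,
    zhp_stats: pd.DataFrame,
    quantile: float = 0.01,
):
    """Top-quantile overlap of high F_ST and low zHp windows.

    The F_ST threshold is the empirical (1 - quantile) quantile of defined
    window F_ST; the zHp threshold is the empirical ``quantile`` quantile
    of defined zHp (linear interpolation between order statistics,
    inclusive comparisons).  A window is a sweep candidate iff
    F_ST >= fst_threshold AND zHp <= zhp_threshold.

    Returns (DataFrame of all common windows with pass flags, thresholds
    dict); overlap windows sort first by ascending zHp.
    """
    keys = ["scaffold", "start", "end"]
    df = fst_stats.merge(zhp_stats[keys + ["zhp"]], on=keys)
    fst_ok = df["fst"].to_numpy(dtype=float)
    zhp_ok = df["zhp"].to_numpy(dtype=float)
    defined = np.isfinite(fst_ok) & np.isfinite(zhp_ok)
    if defined.sum() < 100:
        import logging

        logging.getLogger("garrupop").warning(
            "dual_threshold_overlap: only %d defined windows; quantile unstable", defined.sum()
        )
    if defined.sum() == 0:
        raise ValueError("no windows with both statistics defined")
    fst_thr = float(np.quantile(fst_ok[defined], 1 - quantile))
    zhp_thr = float(np.quantile(zhp_ok[defined], quantile))
    df["passes_fst"] = defined & (fst_ok >= fst_thr)
    df["passes_zhp"] = defined & (zhp_ok <= zhp_thr)
    df["is_overlap"] = df["passes_fst"] & df["passes_zhp"]
    df = pd.concat(
        [
            df[df["is_overlap"]].sort_values("zhp"),
            df[~df["is_overlap"]],
        ]
    ).reset_index(drop=True)
    return df, {"fst_threshold": fst_thr, "zhp_threshold": zhp_thr, "quantile": quantile}


def flank_profile(
    gm: GenotypeMatrix,
    pop,
    hit_scaffold: str,
    hit_start: int,
    hit_end: int,
    flank: int = 500_000,
    subwindow: int = 10_000,
) -> pd.DataFrame:
    """pi and Tajima's D in 10-kb tiles over the hit window +- flank.

    Tiles start at the clipped region start; the region is clipped at
    scaffold ends.
    """
    length = gm.scaffold_lengths.get(hit_scaffold)
    lo = max(0, hit_start - flank)
    hi = hit_end + flank
    if length is not None:
        hi = min(hi, length)
    tiles = []
    start = lo
    while start < hi:
        end = min(start + subwindow, hi)
        tiles.append(Window(hit_scaffold, start, end, partial=(end - start) < subwindow))
        start = end
    pi = popdiv.pi_windows(gm, tiles, samples=pop)
    td = popdiv.tajima_d_windows(gm, tiles, samples=pop)
    return pi.merge(td[["scaffold", "start", "end", "tajima_d"]], on=["scaffold", "start", "end"])


# ---------------------------------------------------------------------------
# Gene annotation


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: scaffold, start, end, name (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {ln}: {line!r}") from exc
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            rows.append({"scaffold": parts[0], "start": start, "end": end, "name": name})
    return pd.DataFrame(rows)


def annotate_genes(windows: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Any-overlap (>= 1 bp, half-open) gene lists per window.

    ``windows`` needs scaffold/start/end columns; ``genes`` needs
    scaffold/start/end/name.  Adds a ``genes`` column (sorted, deduplicated
    gene name list).
    """
    out = windows.copy()
    gene_lists = []
    for _, w in out.iterrows():
        g = genes[
            (genes["scaffold"] == w["scaffold"])
            & (genes["start"] < w["end"])
            & (genes["end"] > w["start"])
        ]
        gene_lists.append(sorted(set(g["name"])))
    out["genes"] = gene_lists
    return out
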