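"""Diversity and inbreeding statistics: windowed pi and Tajima's D,
per-sample heterozygosity, runs of homozygosity (ROH) and F_ROH, LROH
flagging, LD decay and the method-of-moments inbreeding coefficient F.

All estimators work on unphased diploid dosages.  Missing genotypes are
excluded site-wise from frequency denominators; pi uses the unbiased
per-site pairwise-difference form with the m/(m-1) correction (m = number
of called alleles at the site).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vario import GenotypeMatrix, Window, assign_windows


@dataclass
class ROHSegment:
    """One run of homozygosity; coordinates 0-based half-open, ending at the
    last homozygous site (+1)."""

    sample: str
    scaffold: str
    start: int
    end: int
    n_snps: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _site_pi(gm: GenotypeMatrix, sample_idx=None):
    """Unbiased per-site pairwise diversity 2*p*(1-p)*m/(m-1); 0 where m<2."""
    alt, m = gm.alt_counts(sample_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, alt / np.maximum(m, 1), 0.0)
        u = 2 * p * (1 - p) * m / np.maximum(m - 1, 1)
    u[m < 2] = 0.0
    return u, m


def pi_windows(gm: GenotypeMatrix, windows: list[Window], samples=None) -> pd.DataFrame:
    """Nucleotide diversity per window (per-bp), plus the SNP count.

    pi = sum over window sites of 2*p*(1-p)*m/(m-1), divided by window size;
    windows without variants get pi = 0.
    """
    idx = gm.sample_indices(samples) if samples is not None else None
    u, m = _site_pi(gm, idx)
    wi = assign_windows(gm, windows)
    seg = _segregating_mask(gm, idx)
    rows = []
    for k, w in enumerate(windows):
        in_w = wi == k
        rows.append(
            {
                "scaffold": w.scaffold,
                "start": w.start,
                "end": w.end,
                "n_snps": int((in_w & seg).sum()),
                "pi": float(u[in_w].sum() / w.size),
            }
        )
    return pd.DataFrame(rows)


def _segregating_mask(gm, sample_idx=None):
    alt, m = gm.alt_counts(sample_idx)
    return (alt > 0) & (alt < m)


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled chromosomes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_windows(gm: GenotypeMatrix, windows: list[Window], samples=None) -> pd.DataFrame:
    """Tajima's D per window; NaN where S < 3 or fewer than 4 chromosomes.

    n (chromosomes) is the site-wise minimum of called allele counts over
    the window's segregating sites; pi_abs is the window sum of unbiased
    per-site pairwise differences.
    """
    idx = gm.sample_indices(samples) if samples is not None else None
    u, m = _site_pi(gm, idx)
    seg = _segregating_mask(gm, idx)
    wi = assign_windows(gm, windows)
    rows = []
    for k, w in enumerate(windows):
        in_w = (wi == k) & seg
        s_count = int(in_w.sum())
        d = np.nan
        if s_count >= 3:
            n = int(m[in_w].min())
            if n >= 4:
                c = tajima_constants(n)
                pi_abs = float(u[in_w].sum())
                theta_w = s_count / c["a1"]
                var = c["e1"] * s_count + c["e2"] * s_count * (s_count - 1)
                if var > 0:
                    d = (pi_abs - theta_w) / np.sqrt(var)
        rows.append(
            {"scaffold": w.scaffold, "start": w.start, "end": w.end, "n_snps": s_count, "tajima_d": d}
        )
    return pd.DataFrame(rows)


def heterozygosity_rate(gm: GenotypeMatrix, sample: str, genome_length: float | None = None) -> float:
    """Heterozygous genotypes per bp of genome for one sample.

    Default denominator is the sum of scaffold lengths known to the matrix.
    """
    if genome_length is None:
        genome_length = sum(gm.scaffold_lengths.values())
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    j = gm.sample_index(sample)
    return float((gm.geno[:, j] == 1).sum() / genome_length)


# ---------------------------------------------------------------------------
# Runs of homozygosity


def call_roh(
    gm: GenotypeMatrix,
    sample: str,
    min_snps: int = 10,
    min_kb: float = 40.0,
    max_missing: int = 2,
    max_het: int = 0,
) -> list[ROHSegment]:
    """Deterministic run-growing ROH caller.

    Grows maximal runs of consecutive sites containing at most ``max_het``
    heterozygous and ``max_missing`` missing calls; a run is trimmed to end
    at its last homozygous site and accepted iff its span is at least
    ``min_kb`` kb and it contains at least ``min_snps`` sites.
    """
    j = gm.sample_index(sample)
    out: list[ROHSegment] = []
    scafs = gm.sites["scaffold"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    g = gm.geno[:, j]
    for scaf in pd.unique(scafs):
        sel = np.flatnonzero(scafs == scaf)
        p = pos0[sel]
        gg = g[sel]
        i = 0
        n = len(sel)
        while i < n:
            if gg[i] == 1 or gg[i] < 0:
                i += 1
                continue
            # grow from first homozygous anchor
            het = miss = 0
            last_hom = i
            k = i
            while k + 1 < n:
                nxt = gg[k + 1]
                if nxt == 1:
                    if het + 1 > max_het:
                        break
                    het += 1
                elif nxt < 0:
                    if miss + 1 > max_missing:
                        break
                    miss += 1
                else:
                    last_hom = k + 1
                k += 1
            start, end = int(p[i]), int(p[last_hom]) + 1
            n_snps = last_hom - i + 1
            n_miss = int((gg[i : last_hom + 1] < 0).sum())
            if end - start >= min_kb * 1000 and n_snps >= min_snps:
                out.append(ROHSegment(sample, str(scaf), start, end, n_snps, n_miss))
            i = last_hom + 1
    return out


ROH_BINS_KB = (100, 500, 1000)


def bin_roh(segments: list[ROHSegment]) -> dict[str, int]:
    """Counts in the four length bins: <100 kb, [100,500) kb, [500,1000) kb,
    >=1000 kb (left-closed boundaries)."""
    counts = {"<100kb": 0, "100-500kb": 0, "500-1000kb": 0, ">1000kb": 0}
    for s in segments:
        kb = s.length / 1000
        if kb < 100:
            counts["<100kb"] += 1
        elif kb < 500:
            counts["100-500kb"] += 1
        elif kb < 1000:
            counts["500-1000kb"] += 1
        else:
            counts[">1000kb"] += 1
    return counts


def f_roh(segments: list[ROHSegment], genome_length: float) -> float:
    """Genomic inbreeding coefficient: summed ROH length / genome length.

    Overlapping segments for one sample are an error (they would double
    count)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_scaf: dict[tuple, list[ROHSegment]] = {}
    for s in segments:
        by_scaf.setdefault((s.sample, s.scaffold), []).append(s)
    for segs in by_scaf.values():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping ROH segments at {a.scaffold}:{b.start}")
    total = sum(s.length for s in segments)
    return total / genome_length


def flag_lroh(window_stats: pd.DataFrame, pi_threshold: float = 1e-4) -> pd.DataFrame:
    """Flag low-diversity windows (pi strictly below threshold) and merge
    consecutive flagged windows into LROH runs.

    Returns a DataFrame of runs (scaffold, start, end, n_windows, span).
    """
    ws = window_stats.sort_values(["scaffold", "start"]).reset_index(drop=True)
    flagged = ws["pi"].to_numpy() < pi_threshold
    runs = []
    cur = None
    for i in range(len(ws)):
        row = ws.iloc[i]
        contiguous = (
            cur is not None
            and row["scaffold"] == cur["scaffold"]
            and row["start"] == cur["end"]
        )
        if flagged[i]:
            if contiguous:
                cur["end"] = row["end"]
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    runs.append(cur)
                cur = {
                    "scaffold": row["scaffold"],
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "n_windows": 1,
                }
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)
    df = pd.DataFrame(runs, columns=["scaffold", "start", "end", "n_windows"])
    df["span"] = df["end"] - df["start"]
    return df


# ---------------------------------------------------------------------------
# LD decay


def ld_decay(
    gm: GenotypeMatrix,
    max_dist: int = 500_000,
    bin_bp: int = 1000,
    samples=None,
    r2_target: float = 0.3,
):
    """Distance-binned mean r^2 and the decay length where it crosses
    ``r2_target`` from above.

    r^2 is the squared sample correlation of dosage vectors over jointly
    non-missing samples; all intra-scaffold pairs within ``max_dist`` are
    used.  The decay length interpolates linearly between bin midpoints;
    NaN if the curve never exceeds or never drops below the target.

    Returns (DataFrame with bin_mid / mean_r2 / n_pairs, decay_length).
    """
    idx = gm.sample_indices(samples) if samples is not None else np.arange(gm.n_samples)
    g = gm.geno[:, idx].astype(float)
    g[g < 0] = np.nan
    scafs = gm.sites["scaffold"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    n_bins = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for scaf in pd.unique(scafs):
        sel = np.flatnonzero(scafs == scaf)
        if len(sel) < 2:
            continue
        p = pos[sel]
        gs = g[sel]
        for a in range(len(sel) - 1):
            hi = np.searchsorted(p, p[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            x = gs[a]
            ys = gs[a + 1 : hi]
            ok = ~np.isnan(x)[None, :] & ~np.isnan(ys)
            nn = ok.sum(axis=1)
            xm = np.where(ok, x[None, :], 0.0)
            ym = np.where(ok, ys, 0.0)
            sx = xm.sum(axis=1)
            sy = ym.sum(axis=1)
            sxx = (xm * xm).sum(axis=1)
            syy = (ym * ym).sum(axis=1)
            sxy = (xm * ym).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sxy - sx * sy / nn
                vx = sxx - sx * sx / nn
                vy = syy - sy * sy / nn
                r2 = cov * cov / (vx * vy)
            dist = p[a + 1 : hi] - p[a]
            b = np.minimum((dist - 1) // bin_bp, n_bins - 1)
            good = np.isfinite(r2) & (nn >= 2) & (vx > 0) & (vy > 0)
            np.add.at(sums, b[good], r2[good])
            np.add.at(counts, b[good], 1)
    mids = (np.arange(n_bins) + 0.5) * bin_bp
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    df = pd.DataFrame({"bin_mid": mids, "mean_r2": means, "n_pairs": counts})
    decay = _decay_length(mids, means, r2_target)
    return df, decay


def _decay_length(mids, means, target):
    ok = np.isfinite(means)
    x, y = mids[ok], means[ok]
    if len(x) == 0 or np.nanmax(y) <= target or np.nanmin(y) >= target:
        return np.nan
    for i in range(1, len(x)):
        if y[i - 1] > target >= y[i]:
            frac = (y[i - 1] - target) / (y[i - 1] - y[i])
            return float(x[i - 1] + frac * (x[i] - x[i - 1]))
    return np.nan


# ---------------------------------------------------------------------------
# Method-of-moments inbreeding coefficient


def inbreeding_f(gm: GenotypeMatrix, sample: str, group_samples=None) -> float:
    """PLINK-style F = (O_hom - E_hom) / (L - E_hom).

    E_hom per used site is 1 - 2*p*(1-p)*m/(m-1) with p estimated from the
    group (or the whole cohort), including the sample.  Sites where the
    sample is missing or fewer than 2 alleles are called are excluded;
    negative values (heterozygosity excess) are permitted.
    """
    j = gm.sample_index(sample)
    idx = gm.sample_indices(group_samples) if group_samples is not None else None
    u, m = _site_pi(gm, idx)
    called = gm.geno[:, j] >= 0
    use = called & (m >= 2)
    L = int(use.sum())
    if L == 0:
        return np.nan
    e_hom = float((1.0 - u[use]).sum())
    o_hom = int(((gm.geno[:, j] == 0) | (gm.geno[:, j] == 2))[use].sum())
    denom = L - e_hom
    if denom == 0:
        return np.nan
    return (o_hom - e_hom) / denom
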