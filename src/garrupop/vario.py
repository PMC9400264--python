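"""Variant I/O, hard filtering, call-set intersection, LD pruning and window tiling.

The in-memory substrate for every statistic in the package is
:class:`GenotypeMatrix`: a site table (pandas DataFrame) plus a dense
``int8`` genotype array of alt-allele dosages (0/1/2, ``-1`` = missing).
Only biallelic SNVs are kept; multiallelic records and indels are counted
and dropped at read time.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("garrupop")

MISSING = -1

#: GATK-style record-level hard-filter thresholds. A site fails when ANY
#: criterion fires; an absent INFO key means that criterion cannot fire.
DEFAULT_HARD_FILTER = {
    "QD_min": 2.0,
    "FS_max": 20.0,
    "MQ_min": 40.0,
    "SOR_max": 3.0,
    "MQRankSum_min": -2.0,
    "ReadPosRankSum_min": -5.0,
}

INFO_KEYS = ("QD", "FS", "MQ", "SOR", "MQRankSum", "ReadPosRankSum")

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt"] + list(INFO_KEYS)


class VcfParseError(ValueError):
    """Malformed VCF content (carries the offending line number when known)."""


@dataclass
class Window:
    """Half-open genomic interval [start, end) on a scaffold."""

    scaffold: str
    start: int
    end: int
    partial: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty window [{self.start},{self.end})")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNV genotype store.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per site, columns ``scaffold, pos, ref, alt`` plus the six
        INFO keys (NaN when absent).  ``pos`` is 1-based as in VCF.
        Sorted by (scaffold, pos), no duplicate (scaffold, pos).
    samples : list of str
        Unique sample ids, column order of ``geno``.
    geno : numpy.ndarray
        int8 array of shape (n_sites, n_samples); alt dosage 0/1/2 or -1.
    scaffold_lengths : dict
        Scaffold -> length in bp (from the VCF header contig lines, or the
        simulator's design).
    """

    sites: pd.DataFrame
    samples: list[str]
    geno: np.ndarray
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids")
        if self.geno.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def sample_indices(self, samples) -> np.ndarray:
        return np.array([self.sample_index(s) for s in samples], dtype=int)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        """New matrix restricted to the given site mask / integer index."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            geno=self.geno[idx],
            scaffold_lengths=dict(self.scaffold_lengths),
        )

    def subset_samples(self, samples) -> "GenotypeMatrix":
        cols = self.sample_indices(samples)
        return GenotypeMatrix(
            sites=self.sites.copy(),
            samples=list(samples),
            geno=self.geno[:, cols],
            scaffold_lengths=dict(self.scaffold_lengths),
        )

    # -- per-site summaries -------------------------------------------------

    def alt_counts(self, sample_idx=None):
        """(alt allele count, called allele count) per site, over a sample set."""
        g = self.geno if sample_idx is None else self.geno[:, sample_idx]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        m = 2 * called.sum(axis=1)
        return alt, m

    def alt_freq(self, sample_idx=None):
        """Alt-allele frequency per site (NaN where no calls)."""
        alt, m = self.alt_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(m > 0, alt / np.maximum(m, 1), np.nan)


# ---------------------------------------------------------------------------
# VCF I/O


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT genotypes."""
    lines = ["##fileformat=VCFv4.2", "##source=garrupop"]
    for scaf, length in gm.scaffold_lengths.items():
        lines.append(f"##contig=<ID={scaf},length={length}>")
    for key in INFO_KEYS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    sites = gm.sites
    info_vals = {k: sites[k].to_numpy() for k in INFO_KEYS if k in sites}
    scafs = sites["scaffold"].to_numpy()
    poss = sites["pos"].to_numpy()
    refs = sites["ref"].to_numpy()
    alts = sites["alt"].to_numpy()
    for i in range(gm.n_sites):
        info = ";".join(
            f"{k}={info_vals[k][i]:.4g}"
            for k in info_vals
            if not np.isnan(info_vals[k][i])
        ) or "."
        gts = "\t".join(gt_str[g] for g in gm.geno[i])
        lines.append(
            f"{scafs[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\t.\t{info}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path, sample_subset=None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNVs are retained; counts of excluded records
    (multiallelic, indel/other) are logged.  Phased and unphased genotypes
    are treated identically (alt dosage).

    Parameters
    ----------
    sample_subset : sequence of str, optional
        Restrict to these samples (order preserved).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True, samples=list(sample_subset) if sample_subset else None)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    lengths: dict[str, int] = {}
    try:
        lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:
        pass

    rows = []
    genos = []
    n_multi = n_indel = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if not rec.is_snp or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_indel += 1
            continue
        info = [rec.INFO.get(k) for k in INFO_KEYS]
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], *info))
        gt = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        genos.append(gt)
    vcf.close()
    if n_multi or n_indel:
        log.info("read_vcf: excluded %d multiallelic and %d non-SNV records", n_multi, n_indel)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    sites[list(INFO_KEYS)] = sites[list(INFO_KEYS)].astype(float)
    geno = (
        np.vstack(genos)
        if genos
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    gm = GenotypeMatrix(sites=sites, samples=samples, geno=geno, scaffold_lengths=lengths)
    gm.excluded = {"multiallelic": n_multi, "non_snv": n_indel}
    return gm


# ---------------------------------------------------------------------------
# Record-level hard filter


def hard_filter_variants(gm: GenotypeMatrix, thresholds=None):
    """Remove sites failing any GATK-style hard-filter criterion.

    A site is removed iff ANY of QD < QD_min, FS > FS_max, MQ < MQ_min,
    SOR > SOR_max, MQRankSum < MQRankSum_min, ReadPosRankSum <
    ReadPosRankSum_min fires; a missing INFO value never fires.

    Returns ``(filtered_matrix, n_removed)``.
    """
    thr = dict(DEFAULT_HARD_FILTER)
    if thresholds:
        unknown = set(thresholds) - set(thr)
        if unknown:
            raise ValueError(f"unknown hard-filter keys: {sorted(unknown)}")
        thr.update(thresholds)

    s = gm.sites
    def col(k):
        return s[k].to_numpy(dtype=float) if k in s else np.full(len(s), np.nan)

    with np.errstate(invalid="ignore"):
        fail = (
            (col("QD") < thr["QD_min"])
            | (col("FS") > thr["FS_max"])
            | (col("MQ") < thr["MQ_min"])
            | (col("SOR") > thr["SOR_max"])
            | (col("MQRankSum") < thr["MQRankSum_min"])
            | (col("ReadPosRankSum") < thr["ReadPosRankSum_min"])
        )
    fail = np.asarray(fail)  # NaN comparisons are False: absent INFO never fires
    n_removed = int(fail.sum())
    return gm.take_sites(~fail), n_removed


def intersect_variant_sets(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Sites present (same scaffold, pos, ref, alt) in both call sets.

    Genotypes are taken from ``a``.  Records sharing a position but
    disagreeing on ref/alt are reported and dropped.
    """
    key_a = a.sites[["scaffold", "pos", "ref", "alt"]]
    key_b = b.sites[["scaffold", "pos", "ref", "alt"]]
    merged = key_a.reset_index().merge(key_b, on=["scaffold", "pos", "ref", "alt"])
    # positional matches with allele conflict, for the log
    pos_match = key_a.reset_index().merge(
        key_b, on=["scaffold", "pos"], suffixes=("_a", "_b")
    )
    n_conflict = int(
        ((pos_match["ref_a"] != pos_match["ref_b"]) | (pos_match["alt_a"] != pos_match["alt_b"])).sum()
    )
    if n_conflict:
        log.warning("intersect: %d positionally matching records with allele conflicts dropped", n_conflict)
    return a.take_sites(merged["index"].to_numpy())


# ---------------------------------------------------------------------------
# LD pruning


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared correlation of two dosage vectors over jointly called samples."""
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return r * r


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.5, window_snps: int = 50, step: int = 5) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within sliding SNP windows.

    For any within-window pair with r^2 > ``r2_max`` the later site is
    dropped; the surviving set has no within-window pair above the bound.
    Windows never span scaffolds.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    if gm.n_sites < 2:
        return gm

    keep = np.ones(gm.n_sites, dtype=bool)
    scafs = gm.sites["scaffold"].to_numpy()
    for scaf in pd.unique(scafs):
        idx = np.flatnonzero(scafs == scaf)
        for start in range(0, len(idx), step):
            window = idx[start : start + window_snps]
            kept = [i for i in window if keep[i]]
            for a_pos in range(len(kept)):
                i = kept[a_pos]
                if not keep[i]:
                    continue
                for j in kept[a_pos + 1 :]:
                    if not keep[j]:
                        continue
                    r2 = _pairwise_r2(gm.geno[i], gm.geno[j])
                    if np.isfinite(r2) and r2 > r2_max:
                        keep[j] = False
            if start + window_snps >= len(idx):
                break
    return gm.take_sites(keep)


# ---------------------------------------------------------------------------
# Window tiling


def make_windows(scaffold_lengths: dict[str, int], size: int = 40_000) -> list[Window]:
    """Tile each scaffold with non-overlapping windows from coordinate 0.

    The final partial window is kept and flagged ``partial``.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    windows = []
    for scaf, length in scaffold_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for scaffold {scaf}")
        for start in range(0, length, size):
            end = min(start + size, length)
            windows.append(Window(scaf, start, end, partial=(end - start) < size))
    return windows


def assign_windows(gm: GenotypeMatrix, windows: list[Window]) -> np.ndarray:
    """Window index per site (-1 if unassigned); uses pos-1 (0-based)."""
    out = np.full(gm.n_sites, -1, dtype=int)
    scafs = gm.sites["scaffold"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1
    by_scaf: dict[str, list[tuple[int, Window]]] = {}
    for wi, w in enumerate(windows):
        by_scaf.setdefault(w.scaffold, []).append((wi, w))
    for scaf, wlist in by_scaf.items():
        starts = np.array([w.start for _, w in wlist])
        ends = np.array([w.end for _, w in wlist])
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        widx = np.array([wlist[o][0] for o in order])
        mask = scafs == scaf
        if not mask.any():
            continue
        p = pos0[mask]
        j = np.searchsorted(starts, p, side="right") - 1
        valid = (j >= 0) & (p < ends[np.clip(j, 0, None)])
        res = np.where(valid, widx[np.clip(j, 0, None)], -1)
        out[mask] = res
    return out


def windows_to_bed(windows: list[Window], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\n")
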