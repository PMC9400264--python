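"""Pairwise relatedness and gene flow.

Identity-by-state (IBS) counts and DST, method-of-moments
identity-by-descent probabilities and PI_HAT, iterative pruning of related
samples, the 1-DST distance matrix, a neighbor-joining tree, and the
ABBA-BABA (Patterson's D) introgression statistic with a block-jackknife
Z-score.

The IBD moments estimator follows the PLINK scheme: expected IBS-class
counts under IBD state 0/1/2 are computed from the cohort's observed
allele pool with exact without-replacement (hypergeometric) draws — the
small-sample bias correction — then the observed IBS counts are solved
sequentially for (P0, P1, P2), clamped to [0, 1] and renormalized;
PI_HAT = P2 + P1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vario import GenotypeMatrix


@dataclass
class KinshipPair:
    id_a: str
    id_b: str
    ibs0: int
    ibs1: int
    ibs2: int
    dst: float
    p_ibd: tuple[float, float, float]
    pi_hat: float


def ibs_counts(gm: GenotypeMatrix, id_a: str, id_b: str) -> tuple[int, int, int]:
    """(IBS0, IBS1, IBS2) site counts over jointly non-missing sites.

    IBS = 2 - |dosage_a - dosage_b|: opposite homozygotes are IBS0,
    hom/het is IBS1, identical genotypes (incl. het/het) are IBS2.
    """
    ga = gm.geno[:, gm.sample_index(id_a)]
    gb = gm.geno[:, gm.sample_index(id_b)]
    ok = (ga >= 0) & (gb >= 0)
    if not ok.any():
        raise ValueError(f"no jointly called sites for {id_a}/{id_b}")
    ibs = 2 - np.abs(ga[ok].astype(int) - gb[ok].astype(int))
    return (
        int((ibs == 0).sum()),
        int((ibs == 1).sum()),
        int((ibs == 2).sum()),
    )


def dst(counts) -> float:
    """DST = (IBS2 + 0.5*IBS1) / (IBS0 + IBS1 + IBS2)."""
    i0, i1, i2 = counts
    total = i0 + i1 + i2
    if total == 0:
        return np.nan
    return (i2 + 0.5 * i1) / total


def _ibs_expectations(gm: GenotypeMatrix, joint_mask: np.ndarray):
    """Summed expected IBS-class counts under IBD 0/1/2 over usable sites.

    Uses cohort allele counts X (alt), Y (ref), T = X + Y per site; a pair's
    four (IBD0), three (IBD1) or two (IBD2) founding alleles are modelled as
    draws WITHOUT replacement from the observed pool of T alleles, which is
    exactly the finite-sample correction to the p^k frequency moments.
    """
    alt, m = gm.alt_counts()
    X = alt.astype(float)
    T = m.astype(float)
    Y = T - X
    use = joint_mask & (X > 0) & (Y > 0) & (T >= 4)
    X, Y, T = X[use], Y[use], T[use]
    d4 = T * (T - 1) * (T - 2) * (T - 3)
    d3 = T * (T - 1) * (T - 2)
    # IBD = 0: four independent founder alleles
    e0_ibd0 = 2 * X * (X - 1) * Y * (Y - 1) / d4
    e1_ibd0 = (4 * X * (X - 1) * (X - 2) * Y + 4 * X * Y * (Y - 1) * (Y - 2)) / d4
    e2_ibd0 = 1 - e0_ibd0 - e1_ibd0
    # IBD = 1: one shared founder allele + two free
    e1_ibd1 = 2 * X * Y * (X + Y - 2) / d3
    e2_ibd1 = 1 - e1_ibd1
    return {
        "n_sites": int(use.sum()),
        "use": use,
        "E0_0": float(e0_ibd0.sum()),
        "E1_0": float(e1_ibd0.sum()),
        "E2_0": float(e2_ibd0.sum()),
        "E1_1": float(e1_ibd1.sum()),
        "E2_1": float(e2_ibd1.sum()),
    }


def ibd_moments(gm: GenotypeMatrix, id_a: str, id_b: str) -> KinshipPair:
    """Method-of-moments IBD estimate for one pair (PLINK --genome analogue).

    Allele frequencies come from the whole cohort including the pair.
    Monomorphic sites are uninformative and excluded.
    """
    ga = gm.geno[:, gm.sample_index(id_a)]
    gb = gm.geno[:, gm.sample_index(id_b)]
    joint = (ga >= 0) & (gb >= 0)
    exp = _ibs_expectations(gm, joint)
    if exp["n_sites"] == 0:
        raise ValueError("no informative (polymorphic, jointly called) sites")
    use = exp["use"]
    ibs = 2 - np.abs(ga[use].astype(int) - gb[use].astype(int))
    n0, n1, n2 = int((ibs == 0).sum()), int((ibs == 1).sum()), int((ibs == 2).sum())
    n = exp["n_sites"]

    p0 = n0 / exp["E0_0"] if exp["E0_0"] > 0 else 0.0
    p1 = (n1 - p0 * exp["E1_0"]) / exp["E1_1"] if exp["E1_1"] > 0 else 0.0
    p2 = (n2 - p0 * exp["E2_0"] - p1 * exp["E2_1"]) / n
    p = np.clip([p0, p1, p2], 0.0, 1.0)
    s = p.sum()
    if s > 0:
        p = p / s
    pi_hat = float(p[2] + 0.5 * p[1])
    all0, all1, all2 = ibs_counts(gm, id_a, id_b)
    return KinshipPair(
        id_a,
        id_b,
        all0,
        all1,
        all2,
        dst((all0, all1, all2)),
        (float(p[0]), float(p[1]), float(p[2])),
        pi_hat,
    )


def pairwise_kinship(gm: GenotypeMatrix, samples=None) -> pd.DataFrame:
    """IBD/IBS table over all sample pairs."""
    ids = list(samples) if samples is not None else list(gm.samples)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            kp = ibd_moments(gm, ids[i], ids[j])
            rows.append(
                {
                    "id_a": kp.id_a,
                    "id_b": kp.id_b,
                    "ibs0": kp.ibs0,
                    "ibs1": kp.ibs1,
                    "ibs2": kp.ibs2,
                    "dst": kp.dst,
                    "p0": kp.p_ibd[0],
                    "p1": kp.p_ibd[1],
                    "p2": kp.p_ibd[2],
                    "pi_hat": kp.pi_hat,
                }
            )
    return pd.DataFrame(rows)


def prune_related(pairs: pd.DataFrame, quality: dict[str, float], pi_hat_threshold: float = 0.2) -> set[str]:
    """Iteratively drop the lower-quality member of each related pair.

    While any kept pair has PI_HAT above the threshold, the member with the
    lower quality score (e.g. mean depth) is removed; quality ties remove
    the lexicographically larger id.  Returns the kept sample set.
    """
    kept = set(pairs["id_a"]) | set(pairs["id_b"]) | set(quality)
    while True:
        live = pairs[
            pairs["id_a"].isin(kept)
            & pairs["id_b"].isin(kept)
            & (pairs["pi_hat"] > pi_hat_threshold)
        ]
        if live.empty:
            return kept
        row = live.sort_values("pi_hat", ascending=False).iloc[0]
        a, b = row["id_a"], row["id_b"]
        qa, qb = quality.get(a, 0.0), quality.get(b, 0.0)
        if qa < qb:
            kept.discard(a)
        elif qb < qa:
            kept.discard(b)
        else:
            kept.discard(max(a, b))


def ibs_distance_matrix(gm: GenotypeMatrix, samples=None):
    """Symmetric 1 - DST distance matrix; returns (matrix, ids)."""
    ids = list(samples) if samples is not None else list(gm.samples)
    if len(ids) < 2:
        raise ValueError("need >=2 samples")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - dst(ibs_counts(gm, ids[i], ids[j]))
    return d, ids


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dist: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Q-matrix ties break on the smallest (i, j) index pair; negative branch
    lengths are clamped to 0 (a warning is logged).  The final three nodes
    are resolved with the closed-form star solution.
    """
    import logging

    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 taxa")

    def clamp(x):
        if x < 0:
            logging.getLogger("garrupop").warning("NJ: negative branch %.3g clamped to 0", x)
            return 0.0
        return x

    nodes = [str(l) for l in labels]
    active = list(range(n))
    dm = d.copy()
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dm[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * dm[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dm[i, j] - li
        li, lj = clamp(li), clamp(lj)
        new_label = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dm = np.pad(dm, ((0, 1), (0, 1)))
        k = dm.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            dm[k, m] = dm[m, k] = 0.5 * (dm[i, m] + dm[j, m] - dm[i, j])
        nodes.append(new_label)
        active = [m for m in active if m not in (i, j)] + [k]
    i, j, k = active
    li = clamp(0.5 * (dm[i, j] + dm[i, k] - dm[j, k]))
    lj = clamp(0.5 * (dm[i, j] + dm[j, k] - dm[i, k]))
    lk = clamp(0.5 * (dm[i, k] + dm[j, k] - dm[i, j]))
    return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"


# ---------------------------------------------------------------------------
# ABBA-BABA


@dataclass
class DStatResult:
    n_abba: float
    n_baba: float
    d: float
    z: float
    n_blocks: int


def patterson_d(
    gm: GenotypeMatrix,
    p1_samples,
    p2_samples,
    p3_samples,
    outgroup_samples,
    block_snps: int = 5000,
) -> DStatResult:
    """Frequency-weighted Patterson's D for (P1, P2; P3, Outgroup).

    ABBA = sum (1-p1) p2 p3 (1-p4); BABA = sum p1 (1-p2) p3 (1-p4);
    D = (ABBA - BABA) / (ABBA + BABA).  D > 0 means P2 and P3 share more
    derived alleles than P1 and P3 do (gene flow P3 <-> P2 for this
    ordering).  Z is a delete-one block jackknife over consecutive blocks
    of ``block_snps`` sites.
    """
    groups = [p1_samples, p2_samples, p3_samples, outgroup_samples]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every population needs >= 1 sample")
    freqs = [gm.alt_freq(gm.sample_indices(g)) for g in groups]
    ok = np.all([np.isfinite(f) for f in freqs], axis=0)
    f1, f2, f3, f4 = (f[ok] for f in freqs)
    abba = (1 - f1) * f2 * f3 * (1 - f4)
    baba = f1 * (1 - f2) * f3 * (1 - f4)
    tot_abba, tot_baba = float(abba.sum()), float(baba.sum())
    denom = tot_abba + tot_baba
    if denom == 0:
        raise ValueError("ABBA + BABA = 0: D undefined")
    d = (tot_abba - tot_baba) / denom

    n = len(abba)
    n_blocks = max(1, int(np.ceil(n / block_snps)))
    d_del = []
    for b in range(n_blocks):
        sl = slice(b * block_snps, min((b + 1) * block_snps, n))
        a = tot_abba - abba[sl].sum()
        bb = tot_baba - baba[sl].sum()
        if a + bb > 0:
            d_del.append((a - bb) / (a + bb))
    d_del = np.array(d_del)
    z = np.nan
    if len(d_del) > 1:
        se = np.sqrt((len(d_del) - 1) / len(d_del) * ((d_del - d_del.mean()) ** 2).sum())
        if se > 0:
            z = d / se
    return DStatResult(tot_abba, tot_baba, d, z, n_blocks)
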