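"""Hierarchical AMOVA, fixation indices, and pairwise F_ST with FDR control.

Variance is partitioned among groups (regions), among populations within
groups, and within populations, following the standard nested sums-of-squares
decomposition of squared inter-individual distances.  The default distance is
allele identity (0/1 by haplotype identity), giving conventional F-statistics;
site-difference distances give the Phi-statistic analogue.  Permutation
p-values use the three standard schemes, and pairwise F_ST matrices carry
Benjamini-Yekutieli adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .seqio import Alignment, PopulationMap

__all__ = [
    "distance_matrix",
    "amova",
    "pairwise_fst",
    "benjamini_yekutieli",
    "group_mean_fst",
    "AmovaResult",
    "PairwiseFst",
]


def distance_matrix(aln: Alignment, mode: str = "allele_identity") -> np.ndarray:
    """Square distance matrix over samples.

    ``allele_identity``: 0 if two samples carry the same haplotype (exact
    string match), else 1.  ``site_differences``: Hamming distance over sites
    unambiguous in both members of the pair.
    """
    if mode == "allele_identity":
        seqs = aln.seqs
        n = len(seqs)
        codes = {}
        lab = np.array([codes.setdefault(s, len(codes)) for s in seqs])
        return (lab[:, None] != lab[None, :]).astype(float)
    if mode == "site_differences":
        from .seqio import MISSING

        mat = aln.matrix()
        ok = mat != MISSING
        n = mat.shape[0]
        D = np.zeros((n, n))
        for i in range(n):
            valid = ok[i] & ok[i + 1:]
            D[i, i + 1:] = ((mat[i] != mat[i + 1:]) & valid).sum(axis=1)
        return D + D.T
    raise ValueError(f"unknown distance mode {mode!r}")


@dataclass
class AmovaResult:
    df: dict[str, int]
    ss: dict[str, float]
    sigma: dict[str, float]          # variance components a (AG), b (AP/WG), c (WP)
    percent: dict[str, float]
    f_ct: float
    f_sc: float
    f_st: float
    p_values: dict[str, float] = field(default_factory=dict)
    negative_components: bool = False

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("Among groups", self.df["among_groups"], self.ss["among_groups"],
             self.sigma["a"], self.percent["a"]),
            ("Among populations within groups", self.df["among_pops"],
             self.ss["among_pops"], self.sigma["b"], self.percent["b"]),
            ("Within populations", self.df["within_pops"], self.ss["within_pops"],
             self.sigma["c"], self.percent["c"]),
        ]
        return pd.DataFrame(
            rows, columns=["source", "df", "sum_of_squares",
                           "variance_component", "percent_variation"]
        )


def _amova_stats(D2: np.ndarray, pops: np.ndarray, groups: np.ndarray):
    """Nested sums of squares -> (df, SS, variance components, F-statistics).

    ``pops``/``groups`` are integer labels per sample; groups nest pops.
    """
    N = D2.shape[0]
    pop_ids = np.unique(pops)
    grp_ids = np.unique(groups)
    P, G = pop_ids.size, grp_ids.size

    total = D2[np.triu_indices(N, 1)].sum() / N
    ss_wp = 0.0
    for p in pop_ids:
        idx = np.nonzero(pops == p)[0]
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_wp += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_wg = 0.0
    for g in grp_ids:
        idx = np.nonzero(groups == g)[0]
        sub = D2[np.ix_(idx, idx)]
        ss_wg += sub[np.triu_indices(idx.size, 1)].sum() / idx.size

    ss_ag = total - ss_wg
    ss_ap = ss_wg - ss_wp
    df_ag, df_ap, df_wp = G - 1, P - G, N - P

    # sample-size coefficients for unbalanced designs
    n_p = np.array([(pops == p).sum() for p in pop_ids], dtype=float)
    grp_of_pop = np.array([groups[pops == p][0] for p in pop_ids])
    N_g = np.array([(groups == g).sum() for g in grp_ids], dtype=float)
    sum_np2_over_Ng = sum(
        (n_p[grp_of_pop == g] ** 2).sum() / N_g[k]
        for k, g in enumerate(grp_ids)
    )
    n1 = (N - sum_np2_over_Ng) / df_ap if df_ap > 0 else np.nan
    n2 = (sum_np2_over_Ng - (n_p**2).sum() / N) / df_ag if df_ag > 0 else np.nan
    n3 = (N - (N_g**2).sum() / N) / df_ag if df_ag > 0 else np.nan

    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
    ms_ag = ss_ag / df_ag if df_ag > 0 else np.nan

    sig_c = ms_wp
    sig_b = (ms_ap - sig_c) / n1 if df_ap > 0 else 0.0
    sig_a = (ms_ag - sig_c - n2 * sig_b) / n3 if df_ag > 0 else np.nan
    sig_t = sig_a + sig_b + sig_c

    with np.errstate(divide="ignore", invalid="ignore"):
        f_ct = sig_a / sig_t
        f_sc = sig_b / (sig_b + sig_c)
        f_st = (sig_a + sig_b) / sig_t
    return (
        {"among_groups": df_ag, "among_pops": df_ap, "within_pops": df_wp},
        {"among_groups": ss_ag, "among_pops": ss_ap, "within_pops": ss_wp},
        {"a": sig_a, "b": sig_b, "c": sig_c},
        (float(f_ct), float(f_sc), float(f_st)),
    )


def amova(
    dist: np.ndarray,
    pm: PopulationMap,
    sample_ids: list[str],
    n_perm: int = 1023,
    rng_seed: int | None = None,
    squared: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA over samples grouped by population and region.

    ``dist`` is the sample distance matrix ordered as ``sample_ids``;
    distances are squared internally unless ``squared`` is set.  P-values use
    the three standard permutation schemes: all samples among populations
    (F_ST); samples among populations within their group (F_SC); whole
    populations among groups (F_CT).
    """
    pops_s = [pm.sample_to_pop[s] for s in sample_ids]
    grp_s = [pm.pop_to_region[p] for p in pops_s]
    grp_names = sorted(set(grp_s))
    if len(grp_names) < 2:
        raise ValueError("AMOVA requires at least 2 groups (F_CT undefined)")
    pop_names = sorted(set(pops_s))
    if len(pop_names) < 2:
        raise ValueError("AMOVA requires at least 2 populations")
    pops = np.array([pop_names.index(p) for p in pops_s])
    groups = np.array([grp_names.index(g) for g in grp_s])
    D2 = np.asarray(dist, dtype=float)
    if not squared:
        D2 = D2**2

    df, ss, sigma, (f_ct, f_sc, f_st) = _amova_stats(D2, pops, groups)
    negative = any(v < 0 for v in sigma.values() if np.isfinite(v))
    if negative:
        warnings.warn("negative variance component(s); retained but flagged")
    tot = sigma["a"] + sigma["b"] + sigma["c"]
    percent = {k: 100.0 * sigma[k] / tot if tot != 0 else np.nan for k in "abc"}

    p_values: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(rng_seed)
        grp_of_pop = np.array([groups[pops == k][0] for k in range(len(pop_names))])
        hits = {"f_st": 0, "f_sc": 0, "f_ct": 0}
        for _ in range(n_perm):
            # F_ST: samples among populations among groups
            perm = rng.permutation(len(sample_ids))
            st = _amova_stats(D2[np.ix_(perm, perm)], pops, groups)[3][2]
            if st >= f_st:
                hits["f_st"] += 1
            # F_SC: samples among populations within groups
            perm2 = np.arange(len(sample_ids))
            for g in range(len(grp_names)):
                idx = np.nonzero(groups == g)[0]
                perm2[idx] = idx[rng.permutation(idx.size)]
            sc = _amova_stats(D2[np.ix_(perm2, perm2)], pops, groups)[3][1]
            if sc >= f_sc:
                hits["f_sc"] += 1
            # F_CT: whole populations among groups
            g_perm = grp_of_pop[rng.permutation(len(pop_names))]
            ct = _amova_stats(D2, pops, g_perm[pops])[3][0]
            if ct >= f_ct:
                hits["f_ct"] += 1
        for k, h in hits.items():
            p_values[k] = (h + 1) / (n_perm + 1)

    return AmovaResult(df, ss, sigma, percent, f_ct, f_sc, f_st, p_values,
                       negative_components=negative)


def _two_pop_fst(D2: np.ndarray, labels: np.ndarray) -> float:
    """Two-population AMOVA F_ST from a squared distance matrix."""
    N = D2.shape[0]
    n0 = int((labels == 0).sum())
    n1 = N - n0
    total = D2[np.triu_indices(N, 1)].sum() / N
    ss_wp = 0.0
    for v in (0, 1):
        idx = np.nonzero(labels == v)[0]
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_wp += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_ap = total - ss_wp
    ms_wp = ss_wp / (N - 2)
    ms_ap = ss_ap / 1.0
    nc = (N - (n0**2 + n1**2) / N)  # / (P - 1) with P = 2
    sig_a = (ms_ap - ms_wp) / nc
    denom = sig_a + ms_wp
    if denom == 0:
        return np.nan
    return float(sig_a / denom)


@dataclass
class PairwiseFst:
    populations: list[str]
    fst: pd.DataFrame
    p_raw: pd.DataFrame
    p_adjusted: pd.DataFrame


def pairwise_fst(
    dist: np.ndarray,
    pm: PopulationMap,
    sample_ids: list[str],
    n_perm: int = 1023,
    rng_seed: int | None = None,
    squared: bool = False,
) -> PairwiseFst:
    """Population-pairwise F_ST with permutation p-values and B-Y adjustment.

    Each pair's p-value shuffles samples between just those two populations.
    Pairs where either population has n < 2 are skipped with a warning.
    """
    D2 = np.asarray(dist, dtype=float)
    if not squared:
        D2 = D2**2
    pops_s = np.array([pm.sample_to_pop[s] for s in sample_ids])
    pop_names = [p for p in pm.populations if (pops_s == p).sum() > 0]
    sizes = {p: int((pops_s == p).sum()) for p in pop_names}
    rng = np.random.default_rng(rng_seed)

    K = len(pop_names)
    fst = np.full((K, K), np.nan)
    praw = np.full((K, K), np.nan)
    pairs = []
    for i in range(K):
        for j in range(i + 1, K):
            a, b = pop_names[i], pop_names[j]
            if sizes[a] < 2 or sizes[b] < 2:
                warnings.warn(f"skipping pair ({a}, {b}): population with n < 2")
                continue
            idx = np.nonzero((pops_s == a) | (pops_s == b))[0]
            sub = D2[np.ix_(idx, idx)]
            labels = (pops_s[idx] == b).astype(int)
            obs = _two_pop_fst(sub, labels)
            fst[i, j] = fst[j, i] = obs
            if n_perm > 0 and np.isfinite(obs):
                hits = 0
                for _ in range(n_perm):
                    perm = _two_pop_fst(sub, labels[rng.permutation(labels.size)])
                    if np.isfinite(perm) and perm >= obs:
                        hits += 1
                p = (hits + 1) / (n_perm + 1)
                praw[i, j] = praw[j, i] = p
                pairs.append((i, j))

    padj = np.full((K, K), np.nan)
    if pairs:
        raw = [praw[i, j] for i, j in pairs]
        adj = benjamini_yekutieli(raw)
        for (i, j), v in zip(pairs, adj):
            padj[i, j] = padj[j, i] = v
    mk = lambda M: pd.DataFrame(M, index=pop_names, columns=pop_names)
    return PairwiseFst(pop_names, mk(fst), mk(praw), mk(padj))


def benjamini_yekutieli(pvals) -> np.ndarray:
    """Benjamini-Yekutieli FDR adjustment (valid under arbitrary dependence)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return false_discovery_control(p, method="by")


def group_mean_fst(pf: PairwiseFst, pm: PopulationMap) -> pd.DataFrame:
    """Arithmetic mean of pairwise F_ST over population pairs spanning regions."""
    regions = sorted({pm.pop_to_region[p] for p in pf.populations})
    out = pd.DataFrame(np.nan, index=regions, columns=regions)
    for ri in regions:
        for rj in regions:
            vals = []
            for a in pf.populations:
                for b in pf.populations:
                    if a >= b:
                        continue
                    pa, pb = pm.pop_to_region[a], pm.pop_to_region[b]
                    if {pa, pb} == {ri, rj} or (ri == rj and pa == pb == ri):
                        v = pf.fst.loc[a, b]
                        if np.isfinite(v):
                            vals.append(v)
            if vals:
                out.loc[ri, rj] = float(np.mean(vals))
    return out
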