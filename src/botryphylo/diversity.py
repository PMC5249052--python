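"""Per-population polymorphism and neutrality statistics.

Implements the classic single-locus summaries for an aligned haploid sample:
nucleotide diversity (pi), Watterson's theta, haplotype diversity, Tajima's D
(with significance by neutral-coalescent simulation), Fu's Fs via the Ewens
sampling formula, and Ramos-Onsins & Rozas' R2.  Ambiguous bases and gaps are
excluded pairwise ("all sites" behaviour with pairwise deletion); statistics
are reported as missing for populations with fewer than four sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .seqio import MISSING, Alignment, HaplotypeTable, PopulationMap, collapse_haplotypes

__all__ = [
    "nucleotide_diversity",
    "watterson_theta",
    "haplotype_diversity",
    "tajimas_d",
    "fu_fs",
    "ewens_log_pmf",
    "r2_statistic",
    "segregating_sites",
    "mean_pairwise_differences",
    "diversity_summary",
]


# ---------------------------------------------------------------------------
# pairwise machinery (operates on the uint8 site matrix)

def _unique_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, counts = np.unique(mat, axis=0, return_counts=True)
    return uniq, counts


def _pair_stats(mat: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Return (mean per-site difference, mean raw difference count,
    per-pair raw counts, pair weights) over all unordered sample pairs,
    with pairwise deletion of ambiguous sites.

    Identical rows are collapsed first so cost scales with haplotype count.
    """
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    uniq, counts = _unique_rows(mat)
    m = uniq.shape[0]
    ok = uniq != MISSING
    pair_diffs = []
    pair_props = []
    pair_w = []
    for i in range(m):
        for j in range(i, m):
            if i == j:
                w = counts[i] * (counts[i] - 1) / 2
                if w == 0:
                    continue
                d = 0.0
                p = 0.0
            else:
                w = counts[i] * counts[j]
                valid = ok[i] & ok[j]
                nv = int(valid.sum())
                d = float(np.sum((uniq[i] != uniq[j]) & valid))
                p = d / nv if nv > 0 else 0.0
            pair_diffs.append(d)
            pair_props.append(p)
            pair_w.append(w)
    w = np.asarray(pair_w, dtype=float)
    diffs = np.asarray(pair_diffs, dtype=float)
    props = np.asarray(pair_props, dtype=float)
    tot = w.sum()
    return float((props * w).sum() / tot), float((diffs * w).sum() / tot), diffs, w


def nucleotide_diversity(aln: Alignment) -> float:
    """Average pairwise proportion of differing sites (per-site pi)."""
    return _pair_stats(aln.matrix())[0]


def mean_pairwise_differences(aln: Alignment) -> float:
    """Mean raw count of pairwise differences (k-bar)."""
    return _pair_stats(aln.matrix())[1]


def segregating_sites(aln_or_mat) -> int:
    mat = aln_or_mat.matrix() if isinstance(aln_or_mat, Alignment) else aln_or_mat
    S = 0
    for col in mat.T:
        vals = col[col != MISSING]
        if vals.size and np.unique(vals).size > 1:
            S += 1
    return S


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def watterson_theta(aln: Alignment) -> float:
    """S / (a1 * L): Watterson's estimator of 2*Ne*mu per site."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    S = segregating_sites(aln)
    return S / (_harmonic(aln.n) * aln.length)


def haplotype_diversity(ht: HaplotypeTable, population: str | None = None) -> float:
    """(n/(n-1)) * (1 - sum p_i^2) over haplotype frequencies."""
    if population is None:
        counts = np.array([ht.total_count(h) for h in ht.sequences], dtype=float)
    else:
        counts = np.array(
            list(ht.population_counts(population).values()), dtype=float
        )
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 sequences")
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


# ---------------------------------------------------------------------------
# Tajima's D

def _tajima_constants(n: int) -> dict[str, float]:
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _tajimas_d_from(n: int, S: int, kbar: float) -> float:
    c = _tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (kbar - S / c["a1"]) / math.sqrt(var)


def _simulate_d_null(n: int, theta_locus: float, n_sims: int, rng) -> np.ndarray:
    """Tajima's D under the standard neutral coalescent (infinite sites),
    conditioned on sample size with per-locus theta."""
    out = np.empty(n_sims)
    npair = n * (n - 1) / 2.0
    for rep in range(n_sims):
        active = list(range(n))
        ndesc = {i: 1 for i in range(n)}
        S = 0
        ksum = 0.0
        nxt = n
        k = n
        while k > 1:
            rate = k * (k - 1) / 2.0
            t = rng.exponential(1.0 / rate)
            # mutations on each active lineage during this interval
            nmut = rng.poisson(theta_locus / 2.0 * t, size=k)
            for lin, mcount in zip(active, nmut):
                if mcount:
                    c = ndesc[lin]
                    S += mcount
                    ksum += mcount * c * (n - c)
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            ndesc[nxt] = ndesc[a] + ndesc[b]
            active = [x for x in active if x not in (a, b)] + [nxt]
            nxt += 1
            k -= 1
        if S == 0:
            out[rep] = 0.0
        else:
            out[rep] = _tajimas_d_from(n, S, ksum / npair)
    return out


def tajimas_d(
    aln: Alignment,
    simulate_p: bool = False,
    n_sims: int = 1000,
    seed: int | None = None,
) -> tuple[float, float | None]:
    """Tajima's D with optional two-sided significance by coalescent simulation.

    The null distribution is simulated conditioned on n with theta set to the
    Watterson estimate from the data.  Returns (D, p) with p None unless
    ``simulate_p``.  D is undefined (ValueError) for S = 0 or n < 4.
    """
    if aln.n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    S = segregating_sites(aln)
    if S == 0:
        raise ValueError("Tajima's D undefined for S = 0")
    kbar = mean_pairwise_differences(aln)
    D = _tajimas_d_from(aln.n, S, kbar)
    if not simulate_p:
        return D, None
    rng = np.random.default_rng(seed)
    theta_locus = S / _harmonic(aln.n)
    null = _simulate_d_null(aln.n, theta_locus, n_sims, rng)
    p = float(np.mean(np.abs(null) >= abs(D)))
    return D, p


# ---------------------------------------------------------------------------
# Fu's Fs

@lru_cache(maxsize=256)
def _log_stirling_first(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    cur = np.full(n + 1, -np.inf)
    cur[0] = 0.0
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1:m + 1] = np.logaddexp(
            math.log(m - 1) + cur[1:m + 1] if m > 1 else -np.inf, cur[0:m]
        )
        cur = new
    return tuple(cur)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = np.array(_log_stirling_first(n))[1:]
    k = np.arange(1, n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return ls + k * math.log(theta) - log_rising


def fu_fs(aln: Alignment) -> float:
    """Fu's Fs: ln(S'/(1-S')) with S' = Pr(K >= k_obs | theta = k-bar).

    Returns +/-inf (flagged extreme) at the numerical boundaries, including
    the monomorphic case.
    """
    kbar = mean_pairwise_differences(aln)
    n = aln.n
    k_obs = len({s for s in aln.seqs})
    if kbar <= 0:
        return -math.inf if k_obs > 1 else math.inf
    logp = ewens_log_pmf(n, kbar)
    sprime = float(np.exp(logsumexp(logp[k_obs - 1:])))
    if sprime >= 1.0:
        return math.inf
    if sprime <= 0.0:
        return -math.inf
    return math.log(sprime / (1.0 - sprime))


# ---------------------------------------------------------------------------
# Ramos-Onsins & Rozas R2

def _singletons_per_sequence(mat: np.ndarray) -> np.ndarray:
    """U_i: number of singleton sites whose unique carrier is sequence i."""
    n = mat.shape[0]
    U = np.zeros(n)
    for col in mat.T:
        vals = col[col != MISSING]
        if vals.size == 0:
            continue
        alleles, counts = np.unique(vals, return_counts=True)
        if alleles.size < 2:
            continue
        for a, c in zip(alleles, counts):
            if c == 1:
                U[np.nonzero(col == a)[0][0]] += 1
    return U


def r2_statistic(aln: Alignment) -> float:
    """R2 = sqrt(mean_i (U_i - kbar/2)^2) / S."""
    mat = aln.matrix()
    S = segregating_sites(mat)
    if S == 0:
        raise ValueError("R2 undefined for S = 0")
    kbar = _pair_stats(mat)[1]
    U = _singletons_per_sequence(mat)
    return float(math.sqrt(np.mean((U - kbar / 2.0) ** 2)) / S)


# ---------------------------------------------------------------------------
# per-population table

@dataclass
class DiversitySummary:
    table: pd.DataFrame


def diversity_summary(
    aln: Alignment,
    pm: PopulationMap,
    min_n: int = 4,
    d_significance: bool = False,
    n_sims: int = 1000,
    seed: int | None = None,
) -> DiversitySummary:
    """Per-population n, h, Hd, S, pi, theta_w, D (+flag), Fs, R2.

    Populations with n < ``min_n`` (the "> 3 sequences" rule) are listed with
    statistics reported as missing.
    """
    pm.check_covers(aln)
    rows = []
    rng = np.random.default_rng(seed)
    for pop in pm.populations:
        ids = [s for s in aln.ids if pm.sample_to_pop.get(s) == pop]
        n = len(ids)
        row: dict[str, object] = {"population": pop, "region": pm.pop_to_region[pop],
                                  "n": n}
        if n < min_n:
            rows.append(row)
            continue
        sub = aln.subset(ids)
        ht = collapse_haplotypes(sub)
        row["h"] = ht.n_haplotypes
        row["Hd"] = haplotype_diversity(ht)
        S = segregating_sites(sub)
        row["S"] = S
        row["pi"] = nucleotide_diversity(sub)
        row["theta_w"] = watterson_theta(sub)
        if S > 0:
            sub_seed = int(rng.integers(2**31)) if d_significance else None
            D, p = tajimas_d(sub, simulate_p=d_significance, n_sims=n_sims,
                             seed=sub_seed)
            row["D"] = D
            if d_significance:
                row["D_p"] = p
                row["D_significant"] = p is not None and p < 0.05
            row["R2"] = r2_statistic(sub)
        row["Fs"] = fu_fs(sub)
        rows.append(row)
    cols = ["population", "region", "n", "h", "Hd", "S", "pi", "theta_w",
            "D", "D_p", "D_significant", "Fs", "R2"]
    df = pd.DataFrame(rows)
    df = df.reindex(columns=[c for c in cols if c in df.columns or c in
                             ("population", "region", "n")])
    return DiversitySummary(df)
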