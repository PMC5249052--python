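"""ABC model choice and parameter estimation for demographic scenarios.

The workflow mirrors the standard reference-table approach for one-locus
sequence data: simulate many datasets per candidate scenario from the joint
prior, reduce each to a fixed vector of summary statistics, then

* ``pre_evaluate`` — prior-predictive check of the observed statistics
  (per-statistic quantiles plus a two-component PCA overlay);
* ``posterior_probabilities`` — scenario posterior probabilities by linear
  discriminant projection of the statistics followed by a multinomial
  logistic regression over the retained nearest simulations, with bootstrap
  confidence intervals (a rejection-sampling estimate is also reported);
* ``estimate_parameters`` — local-linear (ridge-regularised) regression
  adjustment of retained parameter draws;
* ``model_check`` — posterior-predictive tail probabilities per statistic;
* ``scenario_tournament`` — the two-round protocol in which the best
  scenario(s) from each candidate ancestral region advance by the
  CI-overlap rule to a pooled final, escalating to a head-to-head round
  when the finalists' intervals overlap, with the final comparison repeated
  under an alternate N_e prior maximum.

Undefined statistics (e.g. Tajima's D when S = 0) are imputed as 0 with a
paired indicator column so the vector length is fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, Ridge

from . import diversity
from .coalsim import (
    ParamDraw,
    PriorSpec,
    Scenario,
    SimDataset,
    sample_priors,
    simulate_dataset,
)
from .seqio import MISSING, Alignment, PopulationMap

__all__ = [
    "SummaryStatVector",
    "ReferenceTable",
    "ModelChoiceResult",
    "ParamEstimate",
    "summary_stats",
    "build_reference_table",
    "pre_evaluate",
    "posterior_probabilities",
    "estimate_parameters",
    "model_check",
    "select_by_ci_overlap",
    "scenario_tournament",
    "TournamentConfig",
]


# ---------------------------------------------------------------------------
# summary statistics

@dataclass
class SummaryStatVector:
    names: list[str]
    values: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def _group_matrices(ds: SimDataset | tuple[Alignment, PopulationMap],
                    scheme: str = "region"):
    if isinstance(ds, SimDataset):
        aln, pm = ds.alignment, ds.popmap
    else:
        aln, pm = ds
    if scheme == "region":
        key = {s: pm.region_of_sample(s) for s in aln.ids}
    elif scheme == "population":
        key = {s: pm.sample_to_pop[s] for s in aln.ids}
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    groups = sorted(set(key.values()))
    mat = aln.matrix()
    out = {}
    for g in groups:
        idx = [k for k, s in enumerate(aln.ids) if key[s] == g]
        if not idx:
            raise ValueError(f"empty group {g!r}")
        out[g] = mat[idx]
    return out


def _seg_mask(uniq: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Segregating-column mask for the unique rows selected by ``present``."""
    sub = uniq[present].astype(np.int16)
    ok = sub != MISSING
    lo = np.where(ok, sub, np.int16(512)).min(axis=0)
    hi = np.where(ok, sub, np.int16(-1)).max(axis=0)
    return (hi > lo) & (lo < 512)


def summary_stats(
    ds: SimDataset | tuple[Alignment, PopulationMap], scheme: str = "region"
) -> SummaryStatVector:
    """Fixed-order one-locus summary statistics per group and group pair.

    Per group: haplotype count, segregating sites, private segregating
    sites, mean and variance of pairwise differences, Tajima's D (0 with
    indicator when undefined).  Per group pair: mean between-group pairwise
    differences and a pairwise F_ST from within/between diversity.
    """
    mats = _group_matrices(ds, scheme)
    groups = list(mats)

    # collapse all samples to unique rows once; per-group multiplicities
    mat = np.vstack([mats[g] for g in groups])
    gsizes = [mats[g].shape[0] for g in groups]
    uniq, inv = np.unique(mat, axis=0, return_inverse=True)
    U = uniq.shape[0]
    C = np.zeros((len(groups), U))
    start = 0
    for gi, sz in enumerate(gsizes):
        np.add.at(C[gi], inv[start:start + sz], 1.0)
        start += sz

    # pairwise raw difference counts among unique rows (pairwise deletion)
    ok = uniq != MISSING
    D = np.zeros((U, U))
    for i in range(U):
        valid = ok[i] & ok[i + 1:]
        D[i, i + 1:] = ((uniq[i] != uniq[i + 1:]) & valid).sum(axis=1)
    D = D + D.T

    seg_masks = {g: _seg_mask(uniq, C[gi] > 0) for gi, g in enumerate(groups)}
    within: dict[str, tuple[float, float]] = {}
    names: list[str] = []
    vals: list[float] = []
    for gi, g in enumerate(groups):
        c = C[gi]
        n = int(c.sum())
        hap = int((c > 0).sum())
        S = int(seg_masks[g].sum())
        others = np.zeros(uniq.shape[1], dtype=bool)
        for h in groups:
            if h != g:
                others |= seg_masks[h]
        private = int((seg_masks[g] & ~others).sum())
        # weighted mean/var of pairwise differences within the group
        W = np.outer(c, c)
        np.fill_diagonal(W, c * (c - 1))
        tot = W.sum() / 2.0
        if tot > 0:
            kbar = float((W * D).sum() / 2.0 / tot)
            kvar = float((W * D**2).sum() / 2.0 / tot - kbar**2)
        else:
            kbar = kvar = 0.0
        within[g] = (kbar, kvar)
        if n >= 4 and S >= 1:
            Dt = diversity._tajimas_d_from(n, S, kbar)
            d_ok = 1.0
        else:
            Dt, d_ok = 0.0, 0.0
        names += [f"{g}:h", f"{g}:S", f"{g}:Sp", f"{g}:kbar", f"{g}:kvar",
                  f"{g}:D", f"{g}:D_def"]
        vals += [hap, S, private, kbar, kvar, Dt, d_ok]

    for i, g in enumerate(groups):
        for j in range(i + 1, len(groups)):
            h = groups[j]
            wts = np.outer(C[i], C[j])
            kb = float((wts * D).sum() / wts.sum())
            kw = 0.5 * (within[g][0] + within[h][0])
            if kb > 0:
                fst = max(0.0, (kb - kw) / kb)
                okf = 1.0
            else:
                fst, okf = 0.0, 0.0
            names += [f"{g}|{h}:kbar", f"{g}|{h}:fst", f"{g}|{h}:fst_def"]
            vals += [kb, fst, okf]
    return SummaryStatVector(names, np.asarray(vals, dtype=float))


# ---------------------------------------------------------------------------
# reference tables

@dataclass
class ReferenceTable:
    scenario_ids: np.ndarray          # (n,) row scenario labels
    params: pd.DataFrame              # (n, p) parameter draws
    stats: np.ndarray                 # (n, d) summary statistics
    stat_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def restrict(self, sid: str) -> "ReferenceTable":
        mask = self.scenario_ids == sid
        return ReferenceTable(
            self.scenario_ids[mask], self.params.loc[mask].reset_index(drop=True),
            self.stats[mask], self.stat_names, dict(self.meta),
        )


def build_reference_table(
    scenarios: dict[str, Scenario],
    priors: dict[str, PriorSpec] | PriorSpec,
    sample_config: dict[str, dict[str, int]],
    n_per_scenario: int,
    seed: int,
    L: int = 524,
    scheme: str = "region",
    max_failure_rate: float = 0.01,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` prior draws per scenario into a table."""
    rng = np.random.default_rng(seed)
    sids, rows_p, rows_s = [], [], []
    stat_names: list[str] | None = None
    failures = 0
    for sid, sc in scenarios.items():
        sc.validate()
        ps = priors[sid] if isinstance(priors, dict) else priors
        done = 0
        while done < n_per_scenario:
            draw = sample_priors(ps, rng, sid)
            try:
                ds = simulate_dataset(sc, draw, sample_config,
                                      seed=int(rng.integers(1, 2**31)), L=L)
                vec = summary_stats(ds, scheme)
            except Exception:
                failures += 1
                if failures > max(10, max_failure_rate * n_per_scenario * len(scenarios)):
                    raise RuntimeError(
                        "simulation failure rate above threshold; aborting"
                    )
                continue
            if stat_names is None:
                stat_names = vec.names
            sids.append(sid)
            rows_p.append(draw.values)
            rows_s.append(vec.values)
            done += 1
    return ReferenceTable(
        np.array(sids), pd.DataFrame(rows_p), np.vstack(rows_s), stat_names,
        meta={"seed": seed, "n_per_scenario": n_per_scenario,
              "sample_config": sample_config, "failures": failures},
    )


# ---------------------------------------------------------------------------
# pre-evaluation

def pre_evaluate(
    rt: ReferenceTable, observed: SummaryStatVector, seed: int | None = None
) -> dict:
    """Prior-predictive location of the observed statistics per scenario.

    Reports, per scenario and statistic, the quantile of the observed value
    among the simulations, flagging quantiles < 0.01 or > 0.99, plus the
    first two principal-component coordinates of simulated and observed
    statistics (PCA on standardised, non-constant columns).
    """
    if rt.n_rows == 0:
        raise ValueError("empty reference table")
    obs = observed.values
    report: dict = {"per_scenario": {}, "flagged": {}}
    for sid in dict.fromkeys(rt.scenario_ids.tolist()):
        sub = rt.restrict(sid).stats
        q = np.array([
            (np.sum(sub[:, j] <= obs[j]) / sub.shape[0]) for j in range(len(obs))
        ])
        flags = [rt.stat_names[j] for j in range(len(obs))
                 if q[j] < 0.01 or q[j] > 0.99]
        report["per_scenario"][sid] = pd.Series(q, index=rt.stat_names)
        report["flagged"][sid] = flags

    X = rt.stats
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn("constant statistic column(s) excluded from PCA")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    obs_s = (obs[keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=min(2, Xs.shape[1]), random_state=seed)
    coords = pca.fit_transform(Xs)
    report["pca_simulated"] = coords
    report["pca_observed"] = pca.transform(obs_s[None, :])[0]
    report["pca_scenarios"] = rt.scenario_ids
    return report


# ---------------------------------------------------------------------------
# model choice

@dataclass
class ModelChoiceResult:
    probabilities: pd.Series            # logistic/LDA posterior per scenario
    ci: pd.DataFrame                    # columns lo, hi
    rejection: pd.Series                # retained-count estimate
    method: str
    n_retained: int


def _standardise(X: np.ndarray, obs: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    return (X[:, keep] - mean[keep]) / sd[keep], (obs[keep] - mean[keep]) / sd[keep]


def _fit_logistic(Z, labels, classes):
    clf = LogisticRegression(max_iter=500, C=1e4)
    clf.fit(Z, labels)
    return clf


def posterior_probabilities(
    rt: ReferenceTable,
    observed: SummaryStatVector,
    retain_frac: float = 0.01,
    n_boot: int = 500,
    seed: int | None = None,
) -> ModelChoiceResult:
    """Scenario posterior probabilities at the observed statistics.

    Statistics are standardised and projected onto linear discriminant axes
    fitted to the scenario labels; the ``retain_frac`` simulations nearest
    the observed point (Euclidean, LDA space) feed a multinomial logistic
    regression evaluated at the observed point.  95% CIs come from
    bootstrap resampling of the retained set.  A rejection estimate (label
    frequencies among retained rows) is reported alongside.
    """
    scenarios = sorted(dict.fromkeys(rt.scenario_ids.tolist()))
    if len(scenarios) < 2:
        raise ValueError("model choice needs at least 2 scenarios")
    n_keep = max(50, int(math.ceil(retain_frac * rt.n_rows)))
    if n_keep > rt.n_rows:
        n_keep = rt.n_rows

    Xs, obs_s = _standardise(rt.stats, observed.values)
    method = "lda_logistic"
    try:
        lda = LinearDiscriminantAnalysis(
            n_components=min(len(scenarios) - 1, Xs.shape[1])
        )
        Z = lda.fit_transform(Xs, rt.scenario_ids)
        z_obs = lda.transform(obs_s[None, :])[0]
    except Exception:
        warnings.warn("singular LDA; falling back to standardised statistics")
        Z, z_obs = Xs, obs_s
        method = "std_logistic"

    dist = np.linalg.norm(Z - z_obs, axis=1)
    keep_idx = np.argsort(dist)[:n_keep]
    Zk = Z[keep_idx]
    lab = rt.scenario_ids[keep_idx]

    rej = pd.Series(
        [np.mean(lab == s) for s in scenarios], index=scenarios, dtype=float
    )

    present = sorted(set(lab.tolist()))
    if len(present) < 2:
        # degenerate: rejection answer, absent scenarios floored at 0
        warnings.warn("scenario(s) absent from the retained set")
        probs = rej.copy()
        ci = pd.DataFrame({"lo": probs, "hi": probs})
        return ModelChoiceResult(probs, ci, rej, "rejection", n_keep)

    clf = _fit_logistic(Zk, lab, present)
    p = clf.predict_proba(z_obs[None, :])[0]
    probs = pd.Series(0.0, index=scenarios)
    for cls, v in zip(clf.classes_, p):
        probs[cls] = v
    missing = [s for s in scenarios if s not in present]
    if missing:
        warnings.warn(f"scenarios absent from retained set floored at 0: {missing}")

    rng = np.random.default_rng(seed)
    boot = np.zeros((max(n_boot, 0), len(scenarios)))
    for b in range(n_boot):
        idx = rng.integers(0, n_keep, n_keep)
        lb = lab[idx]
        if len(set(lb.tolist())) < 2:
            boot[b] = [1.0 if s == lb[0] else 0.0 for s in scenarios]
            continue
        cb = _fit_logistic(Zk[idx], lb, present)
        pb = cb.predict_proba(z_obs[None, :])[0]
        row = pd.Series(0.0, index=scenarios)
        for cls, v in zip(cb.classes_, pb):
            row[cls] = v
        boot[b] = row.values
    if n_boot > 0:
        lo = np.quantile(boot, 0.025, axis=0)
        hi = np.quantile(boot, 0.975, axis=0)
        lo = np.minimum(lo, probs.values)
        hi = np.maximum(hi, probs.values)
    else:
        lo = hi = probs.values
    ci = pd.DataFrame({"lo": lo, "hi": hi}, index=scenarios)
    return ModelChoiceResult(probs, ci, rej, method, n_keep)


# ---------------------------------------------------------------------------
# parameter estimation

@dataclass
class ParamEstimate:
    table: pd.DataFrame                # index: parameter; median + quantiles
    adjusted_draws: pd.DataFrame
    n_retained: int


def estimate_parameters(
    rt: ReferenceTable,
    observed: SummaryStatVector,
    retain_frac: float = 0.01,
    ridge_alpha: float = 1e-6,
    adjust: bool = True,
) -> ParamEstimate:
    """Local-linear regression-adjusted posterior for one scenario's rows.

    With ``adjust=False`` the retained draws are used untouched (so at
    retain_frac=1 the posterior reduces to the prior).
    """
    sids = set(rt.scenario_ids.tolist())
    if len(sids) != 1:
        raise ValueError("restrict the table to a single scenario first")
    n_keep = max(50, int(math.ceil(retain_frac * rt.n_rows)))
    n_keep = min(n_keep, rt.n_rows)

    Xs, obs_s = _standardise(rt.stats, observed.values)
    dist = np.linalg.norm(Xs - obs_s, axis=1)
    keep_idx = np.argsort(dist)[:n_keep]
    Xk = Xs[keep_idx] - obs_s           # residuals at observed point
    theta = rt.params.iloc[keep_idx].reset_index(drop=True)

    adjusted = {}
    for col in theta.columns:
        y = theta[col].to_numpy(dtype=float)
        if not adjust or np.ptp(y) == 0:
            adjusted[col] = y
            continue
        reg = Ridge(alpha=ridge_alpha)
        reg.fit(Xk, y)
        adjusted[col] = y - Xk @ reg.coef_
    adj = pd.DataFrame(adjusted)
    qs = adj.quantile([0.025, 0.5, 0.975]).T
    qs.columns = ["q2.5", "median", "q97.5"]
    return ParamEstimate(qs, adj, n_keep)


def parameter_validation(
    scenario: Scenario,
    priors: PriorSpec,
    sample_config: dict[str, dict[str, int]],
    rt: ReferenceTable,
    params: list[str],
    n_pseudo: int = 40,
    retain_frac: float = 0.05,
    seed: int = 0,
    L: int = 524,
    scheme: str = "region",
) -> pd.DataFrame:
    """Bias, RMSE and 95%-interval coverage over pseudo-observed datasets."""
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n_pseudo):
        draw = sample_priors(priors, rng, scenario.sid)
        ds = simulate_dataset(scenario, draw, sample_config,
                              seed=int(rng.integers(1, 2**31)), L=L)
        obs = summary_stats(ds, scheme)
        est = estimate_parameters(rt, obs, retain_frac)
        for p in params:
            truth = draw.values[p]
            row = est.table.loc[p]
            recs.append({
                "parameter": p, "truth": truth, "median": row["median"],
                "covered": bool(row["q2.5"] <= truth <= row["q97.5"]),
            })
    df = pd.DataFrame(recs)
    out = df.groupby("parameter").apply(
        lambda g: pd.Series({
            "bias": (g["median"] - g["truth"]).mean(),
            "rmse": math.sqrt(((g["median"] - g["truth"]) ** 2).mean()),
            "coverage": g["covered"].mean(),
        }),
        include_groups=False,
    )
    return out


# ---------------------------------------------------------------------------
# model checking

def model_check(
    scenario: Scenario,
    param_posterior: pd.DataFrame,
    observed: SummaryStatVector,
    sample_config: dict[str, dict[str, int]],
    n_ppc: int = 500,
    seed: int = 0,
    L: int = 524,
    scheme: str = "region",
) -> dict:
    """Posterior-predictive check: per-statistic tail probability of the
    observed value among datasets simulated from posterior draws."""
    if n_ppc < 100:
        warnings.warn("n_ppc < 100 gives unstable tail probabilities")
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_ppc):
        row = param_posterior.iloc[int(rng.integers(len(param_posterior)))]
        draw = ParamDraw(scenario.sid, row.to_dict())
        ds = simulate_dataset(scenario, draw, sample_config,
                              seed=int(rng.integers(1, 2**31)), L=L)
        sims.append(summary_stats(ds, scheme).values)
    S = np.vstack(sims)
    obs = observed.values
    q = np.array([np.mean(S[:, j] <= obs[j]) for j in range(S.shape[1])])
    flagged = [observed.names[j] for j in range(len(q))
               if q[j] < 0.01 or q[j] > 0.99]
    sd = S.std(axis=0)
    keep = sd > 0
    Xs = (S[:, keep] - S[:, keep].mean(axis=0)) / sd[keep]
    obs_s = (obs[keep] - S[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=min(2, Xs.shape[1]), random_state=seed)
    coords = pca.fit_transform(Xs)
    return {
        "tail_prob": pd.Series(q, index=observed.names),
        "flagged": flagged,
        "pca_simulated": coords,
        "pca_observed": pca.transform(obs_s[None, :])[0],
    }


# ---------------------------------------------------------------------------
# the scenario tournament

def select_by_ci_overlap(
    probs: dict[str, float], cis: dict[str, tuple[float, float]]
) -> tuple[list[str], bool]:
    """Apply the CI-overlap selection rule to (probability, 95% CI) entries.

    The top-probability scenario is chosen together with every scenario whose
    CI overlaps the top's, provided no chosen scenario's CI overlaps an
    unchosen one's.  Returns (selected ids, clean) where ``clean`` is False
    when no non-overlapping selection exists (the selection then still lists
    the top-overlap set, flagged for escalation).
    """
    order = sorted(probs, key=lambda s: -probs[s])
    top = order[0]

    def overlaps(a, b):
        (alo, ahi), (blo, bhi) = cis[a], cis[b]
        return alo <= bhi and blo <= ahi

    selected = [s for s in order if s == top or overlaps(s, top)]
    unselected = [s for s in order if s not in selected]
    clean = all(
        not overlaps(s, u) for s in selected for u in unselected
    )
    return selected, clean


@dataclass
class TournamentConfig:
    sample_config: dict[str, dict[str, int]]
    n_per_scenario: int = 10_000
    retain_frac: float = 0.01
    n_boot: int = 500
    seed: int = 0
    L: int = 524
    scheme: str = "region"
    ne_max: float = 2e5
    ne_max_alternate: float = 6e5
    mu_bounds: tuple[float, float] = (1e-8, 1e-6)
    fixed: dict[str, float] | None = None


def _round(scenarios: dict[str, Scenario], observed, cfg: TournamentConfig,
           ne_max: float, seed: int) -> ModelChoiceResult:
    from .coalsim import default_priors

    priors = {
        sid: default_priors(sc, ne_max=ne_max, mu_bounds=cfg.mu_bounds,
                            fixed=cfg.fixed)
        for sid, sc in scenarios.items()
    }
    rt = build_reference_table(
        scenarios, priors, cfg.sample_config, cfg.n_per_scenario, seed,
        L=cfg.L, scheme=cfg.scheme,
    )
    return posterior_probabilities(
        rt, observed, cfg.retain_frac, cfg.n_boot, seed=seed + 1,
    )


def scenario_tournament(
    ancestral_sets: dict[str, dict[str, Scenario]],
    observed: SummaryStatVector,
    cfg: TournamentConfig,
) -> dict:
    """Two-round scenario choice with CI-overlap escalation.

    Round 1 ranks scenarios within each ancestral set and advances the
    CI-overlap selection.  Round 2 pools the selected scenarios; if the
    finalists' CIs overlap a third head-to-head round runs among them.  The
    final comparison is repeated under the alternate N_e prior maximum.
    Returns an audit dict with per-round results, the winner, and flags.
    """
    audit: dict = {"round1": {}, "flags": []}
    seed = cfg.seed
    pooled: dict[str, Scenario] = {}
    for label, scen_set in ancestral_sets.items():
        if not scen_set:
            raise ValueError(f"ancestral set {label!r} is empty")
        if len(scen_set) == 1:
            sid = next(iter(scen_set))
            audit["round1"][label] = {"selected": [sid], "clean": True,
                                      "result": None}
            pooled[sid] = scen_set[sid]
            continue
        seed += 1
        res = _round(scen_set, observed, cfg, cfg.ne_max, seed)
        sel, clean = select_by_ci_overlap(
            res.probabilities.to_dict(),
            {s: (res.ci.loc[s, "lo"], res.ci.loc[s, "hi"]) for s in res.ci.index},
        )
        if not clean:
            audit["flags"].append(f"round1[{label}]: overlap with unselected")
        audit["round1"][label] = {"selected": sel, "clean": clean, "result": res}
        for sid in sel:
            pooled[sid] = scen_set[sid]

    def final_round(scens: dict[str, Scenario], ne_max: float, seed: int):
        if len(scens) == 1:
            sid = next(iter(scens))
            return None, [sid], True
        res = _round(scens, observed, cfg, ne_max, seed)
        sel, clean = select_by_ci_overlap(
            res.probabilities.to_dict(),
            {s: (res.ci.loc[s, "lo"], res.ci.loc[s, "hi"]) for s in res.ci.index},
        )
        return res, sel, clean

    res2, sel2, clean2 = final_round(pooled, cfg.ne_max, seed + 100)
    audit["round2"] = {"selected": sel2, "clean": clean2, "result": res2}

    winner_set = sel2
    if len(sel2) > 1:
        head = {sid: pooled[sid] for sid in sel2}
        res3, sel3, clean3 = final_round(head, cfg.ne_max, seed + 200)
        audit["round3"] = {"selected": sel3, "clean": clean3, "result": res3}
        winner_set = sel3
        if not clean3 or len(sel3) > 1:
            audit["flags"].append("head-to-head round could not separate finalists")

    res_alt, sel_alt, clean_alt = final_round(
        {sid: pooled[sid] for sid in (sel2 if len(sel2) > 1 else pooled)},
        cfg.ne_max_alternate, seed + 300,
    )
    audit["alternate_ne_max"] = {"selected": sel_alt, "clean": clean_alt,
                                 "result": res_alt}
    audit["winner"] = winner_set[0]
    audit["winner_set"] = winner_set
    audit["winner_alternate"] = sel_alt[0]
    return audit
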