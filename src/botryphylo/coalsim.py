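"""Coalescent simulation of mtCOI datasets under demographic scenarios.

A Scenario lists haploid populations (sampled plus unsampled "ghost"
lineages) and a backward-in-time event schedule of merges
(daughter -> parent at time t) and admixtures (each lineage in the target
moves to source A with probability ra, else to source B).  Effective sizes
are in gene copies of a haploid maternal locus, so the expected pairwise
coalescence time within a population of size N_e is N_e generations.
Parameters (N_e's, event times t2..t4, admixture rate, mutation rate, HKY
kappa, invariant proportion) are drawn from uniform priors subject to
time-order constraints (t4 > t3, t4 > t2, t3 >= t2) by rejection.

Genealogies come from msprime (continuous-time approximation); sequences
evolve down the genealogy under HKY with a fraction I of sites held
invariant and the variable sites accelerated to rate mu/(1-I) so the mean
per-site rate is mu.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit

from .seqio import Alignment, PopulationMap, matrix_to_seqs

__all__ = [
    "Population",
    "MergeEvent",
    "AdmixtureEvent",
    "Scenario",
    "PriorSpec",
    "ParamDraw",
    "SimDataset",
    "sample_priors",
    "simulate_genealogy",
    "simulate_sequences",
    "simulate_dataset",
    "builtin_scenarios",
    "default_priors",
]

_OPS = {">": operator.gt, ">=": operator.ge, "<": operator.lt, "<=": operator.le}


@dataclass(frozen=True)
class Population:
    name: str
    ne: str              # parameter name for the population's N_e
    sampled: bool = True


@dataclass(frozen=True)
class MergeEvent:
    daughter: str
    parent: str
    time: str            # parameter name (or numeric literal as str)


@dataclass(frozen=True)
class AdmixtureEvent:
    target: str
    source_a: str
    source_b: str
    rate: str            # parameter name for ra
    time: str


@dataclass
class Scenario:
    sid: str
    populations: list[Population]
    events: list[MergeEvent | AdmixtureEvent]
    description: str = ""

    @property
    def sampled_populations(self) -> list[str]:
        return [p.name for p in self.populations if p.sampled]

    def parameter_names(self) -> set[str]:
        names = {p.ne for p in self.populations}
        for ev in self.events:
            names.add(ev.time)
            if isinstance(ev, AdmixtureEvent):
                names.add(ev.rate)
        return names

    def validate(self, draw: "ParamDraw | None" = None) -> None:
        """Check every sampled population has a path to a common ancestor."""
        pops = {p.name for p in self.populations}
        for ev in self.events:
            names = (
                (ev.daughter, ev.parent) if isinstance(ev, MergeEvent)
                else (ev.target, ev.source_a, ev.source_b)
            )
            for n in names:
                if n not in pops:
                    raise ValueError(f"{self.sid}: event references unknown {n!r}")
        # simulate lineage flow with events in schedule order
        alive = set(pops)
        for ev in self.events:
            if isinstance(ev, MergeEvent):
                if ev.daughter not in alive:
                    raise ValueError(
                        f"{self.sid}: merge daughter {ev.daughter!r} already absorbed"
                    )
                alive.discard(ev.daughter)
            else:
                if ev.target not in alive:
                    raise ValueError(
                        f"{self.sid}: admixture target {ev.target!r} already absorbed"
                    )
                alive.discard(ev.target)
        if len(alive) != 1:
            raise ValueError(
                f"{self.sid}: lineages stranded; {sorted(alive)} never merge"
            )
        if draw is not None:
            times = [draw.values[ev.time] for ev in self.events]
            if any(t < 0 for t in times):
                raise ValueError(f"{self.sid}: negative event time")
            if times != sorted(times):
                raise ValueError(f"{self.sid}: events out of time order for draw")


@dataclass
class PriorSpec:
    """Uniform bounds per parameter plus order constraints like (t4, '>', t3)."""

    bounds: dict[str, tuple[float, float]]
    constraints: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r}: min must be < max")
        for a, op, b in self.constraints:
            if op not in _OPS:
                raise ValueError(f"unknown constraint operator {op!r}")

    def satisfies(self, values: dict[str, float]) -> bool:
        return all(
            _OPS[op](values[a], values[b])
            for a, op, b in self.constraints
            if a in values and b in values
        )


@dataclass
class ParamDraw:
    scenario_id: str
    values: dict[str, float]


@dataclass
class SimDataset:
    alignment: Alignment
    popmap: PopulationMap
    draw: ParamDraw


def sample_priors(
    ps: PriorSpec, rng: np.random.Generator, scenario_id: str = "",
    max_tries: int = 100_000,
) -> ParamDraw:
    """Rejection-sample the joint uniform prior until all constraints hold."""
    names = list(ps.bounds)
    lo = np.array([ps.bounds[n][0] for n in names])
    hi = np.array([ps.bounds[n][1] for n in names])
    for tries in range(1, max_tries + 1):
        vals = dict(zip(names, lo + (hi - lo) * rng.random(len(names))))
        if ps.satisfies(vals):
            if tries > 10_000:
                raise RuntimeError(
                    "prior acceptance rate below 1e-4; revise the bounds"
                )
            return ParamDraw(scenario_id, vals)
    raise RuntimeError("prior acceptance rate below 1e-4; revise the bounds")


def _event_time(ev, draw: ParamDraw) -> float:
    try:
        return float(ev.time)
    except ValueError:
        return float(draw.values[ev.time])


def _to_demography(sc: Scenario, draw: ParamDraw) -> msprime.Demography:
    dem = msprime.Demography()
    for p in sc.populations:
        dem.add_population(name=p.name, initial_size=draw.values[p.ne])
    events = sorted(sc.events, key=lambda ev: _event_time(ev, draw))
    for ev in events:
        # events exactly at the sampling time are nudged forward one tick
        t = max(_event_time(ev, draw), 1e-9)
        if isinstance(ev, MergeEvent):
            dem.add_mass_migration(time=t, source=ev.daughter, dest=ev.parent,
                                   proportion=1.0)
        else:
            ra = float(draw.values[ev.rate])
            dem.add_mass_migration(time=t, source=ev.target, dest=ev.source_a,
                                   proportion=ra)
            dem.add_mass_migration(time=t, source=ev.target, dest=ev.source_b,
                                   proportion=1.0)
    dem.sort_events()
    return dem


def simulate_genealogy(
    sc: Scenario,
    draw: ParamDraw,
    sample_sizes: dict[str, int],
    seed: int | None = None,
    L: int = 524,
) -> tskit.TreeSequence:
    """Backward-in-time coalescent genealogy for the configured samples.

    ``sample_sizes`` maps sampled population name -> number of gene copies at
    time 0.  Returns a single-tree tskit TreeSequence over a genome of L sites
    (mtCOI is non-recombining).
    """
    sc.validate()
    unknown = set(sample_sizes) - set(sc.sampled_populations)
    if unknown:
        raise ValueError(f"samples requested from unsampled/unknown pops {unknown}")
    dem = _to_demography(sc, draw)
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n, population=pop, ploidy=1)
            for pop, n in sample_sizes.items() if n > 0
        ],
        demography=dem,
        ploidy=1,
        sequence_length=L,
        recombination_rate=0.0,
        random_seed=None if seed is None else (seed % (2**31)) + 1,
    )
    return ts


def simulate_sequences(
    genealogy: tskit.TreeSequence,
    mu: float,
    kappa: float,
    invariant: float,
    L: int | None = None,
    seed: int | None = None,
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> list[str]:
    """HKY+I sequences for every sample in the genealogy (list of strings).

    A Bernoulli(I) mask flags sites as invariant (rate 0); the remaining
    sites mutate at rate mu/(1-I).  Root states at unmutated sites are drawn
    from the stationary frequencies.
    """
    if mu < 0 or kappa <= 0:
        raise ValueError("require mu >= 0 and kappa > 0")
    if not 0 <= invariant < 1:
        raise ValueError("invariant proportion must be in [0, 1)")
    L = int(L if L is not None else genealogy.sequence_length)
    rng = np.random.default_rng(seed)
    n = genealogy.num_samples

    root_codes = rng.choice(4, size=L, p=np.asarray(freqs) / np.sum(freqs))
    mat = np.tile(root_codes, (n, 1)).astype(np.uint8)
    if mu > 0:
        inv_mask = rng.random(L) < invariant
        rates = np.where(inv_mask, 0.0, mu / (1.0 - invariant))
        # collapse equal-rate runs into a RateMap
        pos = [0]
        rate_list = []
        cur = rates[0]
        for i in range(1, L):
            if rates[i] != cur:
                pos.append(i)
                rate_list.append(cur)
                cur = rates[i]
        pos.append(L)
        rate_list.append(cur)
        rate_map = msprime.RateMap(position=pos, rate=rate_list)
        # some kappa values trip msprime's exact row-sum check through float
        # round-off; nudge kappa by one ulp-scale step until the matrix builds
        model = None
        k = float(kappa)
        for _ in range(50):
            try:
                model = msprime.HKY(kappa=k, equilibrium_frequencies=list(freqs))
                break
            except Exception:
                k = np.nextafter(k, np.inf if k < kappa * (1 + 1e-9) else -np.inf)
                k += kappa * 1e-12
        if model is None:
            raise ValueError(f"could not build HKY model for kappa={kappa}")
        mts = msprime.sim_mutations(
            genealogy, rate=rate_map, model=model,
            random_seed=int(rng.integers(1, 2**31)),
        )
        alleles = {a: k for k, a in enumerate("ACGT")}
        for var in mts.variants():
            site = int(var.site.position)
            codes = np.array([alleles[a] for a in var.alleles if a is not None],
                             dtype=np.uint8)
            mat[:, site] = codes[var.genotypes]
    return matrix_to_seqs(mat)


def simulate_dataset(
    sc: Scenario,
    draw: ParamDraw,
    sample_config: dict[str, dict[str, int]],
    seed: int | None = None,
    L: int = 524,
    prefix: str = "s",
) -> SimDataset:
    """Simulate an Alignment + PopulationMap for a population sampling design.

    ``sample_config`` maps region (a sampled scenario population) to
    {population name: n samples}.
    """
    rng = np.random.default_rng(seed)
    region_sizes = {
        reg: sum(cfg.values()) for reg, cfg in sample_config.items()
    }
    ts = simulate_genealogy(sc, draw, region_sizes,
                            seed=int(rng.integers(1, 2**31)), L=L)
    seqs = simulate_sequences(
        ts,
        mu=draw.values.get("mu", 0.0),
        kappa=draw.values.get("kappa", 2.0),
        invariant=draw.values.get("I", 0.0),
        L=L,
        seed=int(rng.integers(1, 2**31)),
    )
    # msprime orders samples by SampleSet order == insertion order here
    ids: list[str] = []
    sample_to_pop: dict[str, str] = {}
    pop_to_region: dict[str, str] = {}
    k = 0
    for reg, cfg in sample_config.items():
        if region_sizes[reg] == 0:
            continue
        for pop, npop in cfg.items():
            pop_to_region[pop] = reg
            for _ in range(npop):
                sid = f"{prefix}{k}"
                ids.append(sid)
                sample_to_pop[sid] = pop
                k += 1
    aln = Alignment(ids, seqs[: len(ids)])
    return SimDataset(aln, PopulationMap(sample_to_pop, pop_to_region), draw)


# ---------------------------------------------------------------------------
# priors and scenario library

NE_MAX_DEFAULT = 2e5
NE_MAX_ALTERNATE = 6e5


def default_priors(
    scenario: Scenario,
    ne_max: float = NE_MAX_DEFAULT,
    mu_bounds: tuple[float, float] = (1e-8, 1e-6),
    fixed: dict[str, float] | None = None,
) -> PriorSpec:
    """Uniform priors for every parameter a scenario references.

    N_e parameters: [10, ne_max]; times: [10, 1e5] generations;
    admixture rates: [0.001, 0.999]; mu per site per generation; HKY kappa
    [0.05, 20]; invariant proportion [0, 0.9].  Time parameters named t2..t4
    get the order constraints t4 > t3, t4 > t2, t3 >= t2.  ``fixed`` pins
    parameters to a point (degenerate narrow prior).
    """
    bounds: dict[str, tuple[float, float]] = {}
    for name in sorted(scenario.parameter_names()):
        if name.startswith("N"):
            bounds[name] = (10.0, ne_max)
        elif name.startswith("t"):
            bounds[name] = (10.0, 1e5)
        elif name.startswith("ra"):
            bounds[name] = (0.001, 0.999)
    bounds["mu"] = mu_bounds
    bounds["kappa"] = (0.05, 20.0)
    bounds["I"] = (0.0, 0.9)
    constraints = []
    tnames = {n for n in bounds if n in ("t2", "t3", "t4")}
    if {"t3", "t4"} <= tnames:
        constraints.append(("t4", ">", "t3"))
    if {"t2", "t4"} <= tnames:
        constraints.append(("t4", ">", "t2"))
    if {"t2", "t3"} <= tnames:
        constraints.append(("t3", ">=", "t2"))
    if fixed:
        for name, v in fixed.items():
            eps = abs(v) * 1e-9 + 1e-12
            bounds[name] = (v, v + eps)
    return PriorSpec(bounds, constraints)


def builtin_scenarios(clade: str) -> dict[str, Scenario]:
    """Machine-readable encodings of the named dispersal scenarios.

    Clade A regions: Mediterranean (Med), northeastern Atlantic (NEA),
    northwestern Atlantic (NWA), Pacific (Pac).  Clade E regions: English
    Channel France (ECF), English Channel England (ECE), Bay of Biscay (BB),
    Mediterranean (Med).
    """
    if clade == "A":
        regions = ["Med", "NEA", "NWA", "Pac"]

        def pops(ghost: bool = False):
            ps = [Population(r, f"N_{r}") for r in regions]
            if ghost:
                ps.append(Population("ghost", "N_ghost", sampled=False))
            return ps

        s21 = Scenario(
            "s21", pops(ghost=True),
            [
                MergeEvent("Med", "NEA", "t2"),
                MergeEvent("NEA", "ghost", "t3"),
                MergeEvent("NWA", "ghost", "t3"),
                MergeEvent("ghost", "Pac", "t4"),
            ],
            "Pacific ancestral; an unsampled lineage diverges from the "
            "original Pacific lineage and gives rise to the two Atlantic "
            "lineages; the Mediterranean arises from the NE Atlantic.",
        )
        s26 = Scenario(
            "s26", pops(),
            [
                MergeEvent("NWA", "Med", "t2"),
                MergeEvent("NEA", "Med", "t3"),
                MergeEvent("Med", "Pac", "t4"),
            ],
            "Pacific ancestral; the Mediterranean lineage descends from the "
            "ancestral Pacific lineage early and gives rise to both Atlantic "
            "lineages.",
        )
        s48 = Scenario(
            "s48", pops(),
            [
                MergeEvent("Med", "NEA", "t2"),
                MergeEvent("NEA", "NWA", "t3"),
                MergeEvent("Pac", "NWA", "t4"),
            ],
            "NW Atlantic ancestral placeholder topology.",
        )
        s14 = Scenario(
            "s14", pops(),
            [
                MergeEvent("Med", "NEA", "t2"),
                MergeEvent("NWA", "NEA", "t3"),
                MergeEvent("Pac", "NEA", "t4"),
            ],
            "NE Atlantic ancestral alternate.",
        )
        s2 = Scenario(
            "s2", pops(),
            [
                MergeEvent("NEA", "Med", "t2"),
                MergeEvent("NWA", "Med", "t3"),
                MergeEvent("Pac", "Med", "t4"),
            ],
            "Mediterranean ancestral alternate.",
        )
        out = {s.sid: s for s in (s21, s26, s48, s14, s2)}
    elif clade == "E":
        regions = ["ECF", "ECE", "BB", "Med"]

        def pops(ghost: bool = False):
            ps = [Population(r, f"N_{r}") for r in regions]
            if ghost:
                ps.append(Population("ghost", "N_ghost", sampled=False))
            return ps

        s19 = Scenario(
            "s19", pops(ghost=True),
            [
                MergeEvent("Med", "ECE", "t2"),
                MergeEvent("BB", "ECE", "t2"),
                MergeEvent("ECE", "ghost", "t3"),
                MergeEvent("ghost", "ECF", "t4"),
            ],
            "English Channel France ancestral; an unsampled lineage diverges "
            "from the French lineage, gives rise to the English populations, "
            "which in turn give rise to the Mediterranean and Bay of Biscay.",
        )
        s15 = Scenario(
            "s15", pops(ghost=True),
            [
                MergeEvent("Med", "ECF", "t2"),
                MergeEvent("BB", "ECF", "t2"),
                MergeEvent("ECF", "ghost", "t3"),
                MergeEvent("ghost", "ECE", "t4"),
            ],
            "English Channel England ancestral mirror of s19.",
        )
        s7 = Scenario(
            "s7", pops(),
            [
                MergeEvent("BB", "ECE", "t2"),
                MergeEvent("ECE", "ECF", "t3"),
                MergeEvent("ECF", "Med", "t4"),
            ],
            "Mediterranean ancestral chain alternate.",
        )
        s8 = Scenario(
            "s8", pops(),
            [
                MergeEvent("BB", "ECF", "t2"),
                MergeEvent("ECF", "ECE", "t3"),
                MergeEvent("ECE", "Med", "t4"),
            ],
            "Mediterranean ancestral chain alternate (swapped Channel order).",
        )
        out = {s.sid: s for s in (s19, s15, s7, s8)}
    else:
        raise ValueError(f"unknown clade {clade!r}; expected 'A' or 'E'")
    for s in out.values():
        s.validate()
    return out
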