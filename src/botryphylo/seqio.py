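"""Alignment and population-map IO, haplotype collapsing, population filters.

The data unit throughout the package is an equal-length DNA alignment (for
mtCOI, 524 bp once trimmed) together with a two-level grouping of samples:
sample -> population -> geographic region.  Sequences collapse to haplotypes
by exact identity; populations can be filtered by the sample-size rule
(> 3 sequences) or by Tajima's-D significance flags before downstream
analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")

# Base codes: A/C/G/T -> 0..3, anything ambiguous (N, gaps, IUPAC codes) -> MISSING.
MISSING = 255
_CODE_LUT = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i
_CHAR_LUT = np.array([ord(c) for c in "ACGT"] + [ord("N")] * 252, dtype=np.uint8)


class AlignmentError(ValueError):
    """Raised when an alignment violates its invariants."""


@dataclass
class Alignment:
    """Equal-length DNA sequences with unique sample identifiers."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        if len(self.ids) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        self.seqs = [s.upper() for s in self.seqs]
        L = len(self.seqs[0])
        if L < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - VALID_CHARS
            if bad:
                raise AlignmentError(f"sequence {sid!r} has invalid characters {bad}")
        self._matrix: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        """(n, L) uint8 matrix; A,C,G,T -> 0..3, ambiguous/gap -> 255."""
        if self._matrix is None:
            raw = np.frombuffer(
                "".join(self.seqs).encode("ascii"), dtype=np.uint8
            ).reshape(self.n, self.length)
            self._matrix = _CODE_LUT[raw]
        return self._matrix

    def subset(self, ids: list[str]) -> "Alignment":
        index = {sid: k for k, sid in enumerate(self.ids)}
        missing = [sid for sid in ids if sid not in index]
        if missing:
            raise AlignmentError(f"ids not in alignment: {missing}")
        return Alignment(list(ids), [self.seqs[index[sid]] for sid in ids])


def matrix_to_seqs(mat: np.ndarray) -> list[str]:
    """Inverse of :meth:`Alignment.matrix` (missing codes render as N)."""
    chars = _CHAR_LUT[np.minimum(mat, 4)]
    return [row.tobytes().decode("ascii") for row in chars]


def read_alignment(path, expected_length: int | None = None) -> Alignment:
    """Read a FASTA alignment, validating lengths and id uniqueness."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    if expected_length is not None:
        for sid, s in zip(ids, seqs):
            if len(s) != expected_length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(s)}, expected {expected_length}"
                )
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


class PopulationMapError(ValueError):
    pass


@dataclass
class PopulationMap:
    """sample -> population and population -> region assignments."""

    sample_to_pop: dict[str, str]
    pop_to_region: dict[str, str]

    def __post_init__(self) -> None:
        for pop in set(self.sample_to_pop.values()):
            if pop not in self.pop_to_region:
                raise PopulationMapError(f"population {pop!r} has no region")

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_pop)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_to_pop.values():
            seen.setdefault(pop, None)
        for pop in self.pop_to_region:
            seen.setdefault(pop, None)
        return list(seen)

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for reg in self.pop_to_region.values():
            seen.setdefault(reg, None)
        return list(seen)

    def samples_in(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def region_of_sample(self, sample: str) -> str:
        return self.pop_to_region[self.sample_to_pop[sample]]

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {p: 0 for p in self.populations}
        for pop in self.sample_to_pop.values():
            sizes[pop] += 1
        return sizes

    def restrict_to(self, pops: set[str]) -> "PopulationMap":
        return PopulationMap(
            {s: p for s, p in self.sample_to_pop.items() if p in pops},
            {p: r for p, r in self.pop_to_region.items() if p in pops},
        )

    def check_covers(self, aln: Alignment) -> None:
        unmapped = [sid for sid in aln.ids if sid not in self.sample_to_pop]
        if unmapped:
            raise PopulationMapError(f"alignment ids without population: {unmapped}")


def read_popmap(path) -> PopulationMap:
    """3-column TSV ``sample<TAB>population<TAB>region`` with one header line."""
    sample_to_pop: dict[str, str] = {}
    pop_to_region: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise PopulationMapError(f"empty popmap file {path}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PopulationMapError(
                    f"{path}:{lineno}: expected 3 tab-separated fields"
                )
            sample, pop, region = parts
            if sample in sample_to_pop:
                raise PopulationMapError(f"{path}:{lineno}: duplicate sample {sample!r}")
            if pop in pop_to_region and pop_to_region[pop] != region:
                raise PopulationMapError(
                    f"{path}:{lineno}: population {pop!r} assigned to two regions"
                )
            sample_to_pop[sample] = pop
            pop_to_region[pop] = region
    return PopulationMap(sample_to_pop, pop_to_region)


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tregion\n")
        for sample, pop in pm.sample_to_pop.items():
            fh.write(f"{sample}\t{pop}\t{pm.pop_to_region[pop]}\n")


@dataclass
class HaplotypeTable:
    """Distinct haplotype sequences with per-(haplotype, population) counts.

    ``counts`` maps haplotype id -> {population -> count}.  When built without
    a population map every sample sits in the pseudo-population ``"all"``.
    """

    sequences: dict[str, str]
    counts: dict[str, dict[str, int]]
    members: dict[str, list[str]] = field(default_factory=dict)

    def total_count(self, hap: str) -> int:
        return sum(self.counts[hap].values())

    @property
    def n_samples(self) -> int:
        return sum(self.total_count(h) for h in self.sequences)

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def population_counts(self, pop: str) -> dict[str, int]:
        return {h: c[pop] for h, c in self.counts.items() if c.get(pop, 0) > 0}


def _matches_at_unambiguous(a: str, b: str) -> bool:
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT" and x != y:
            return False
    return True


def collapse_haplotypes(
    aln: Alignment,
    pm: PopulationMap | None = None,
    ambiguous_policy: str = "merge",
    prefix: str = "H",
) -> HaplotypeTable:
    """Group identical sequences into haplotypes.

    Haplotype identity is exact string match.  Under the default
    ``ambiguous_policy="merge"``, a sequence class containing N/- is kept as
    its own haplotype only if it differs from every other class at an
    unambiguous site; otherwise it merges into the matching class (the most
    frequent match, ties broken by first occurrence).  ``"distinct"`` keeps
    every distinct string separate.
    """
    if ambiguous_policy not in ("merge", "distinct"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    if pm is not None:
        pm.check_covers(aln)

    by_seq: dict[str, list[str]] = {}
    for sid, s in zip(aln.ids, aln.seqs):
        by_seq.setdefault(s, []).append(sid)

    order = sorted(by_seq, key=lambda s: (-len(by_seq[s]), aln.seqs.index(s)))
    if ambiguous_policy == "merge":
        kept: list[str] = [s for s in order if not (set(s) - set("ACGT"))]
        for s in [t for t in order if set(t) - set("ACGT")]:
            matches = [t for t in kept if _matches_at_unambiguous(s, t)]
            if matches:
                by_seq[matches[0]].extend(by_seq.pop(s))
            else:
                kept.append(s)
        order = [s for s in order if s in by_seq]

    sequences: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    members: dict[str, list[str]] = {}
    for k, s in enumerate(order, start=1):
        hid = f"{prefix}{k}"
        sequences[hid] = s
        members[hid] = sorted(by_seq[s])
        tab: dict[str, int] = {}
        for sid in by_seq[s]:
            pop = pm.sample_to_pop[sid] if pm is not None else "all"
            tab[pop] = tab.get(pop, 0) + 1
        counts[hid] = tab
    return HaplotypeTable(sequences, counts, members)


def filter_populations(
    pm: PopulationMap,
    stats: dict[str, object] | None = None,
    rule: str = "min_n",
    min_n: int = 4,
) -> PopulationMap:
    """Restrict a population map by a filtering rule.

    ``rule="min_n"``: keep populations with at least ``min_n`` samples
    (default 4, i.e. the "> 3 sequences" inclusion rule).  ``stats`` may
    supply a precomputed {population: n} mapping; otherwise sizes come from
    the map itself.

    ``rule="exclude_nonzero_D"``: ``stats`` maps population -> bool flag,
    True meaning Tajima's D deviates significantly from zero; flagged
    populations are removed.
    """
    if rule == "min_n":
        sizes = stats if stats is not None else pm.population_sizes()
        keep = {p for p in pm.populations if int(sizes.get(p, 0)) >= min_n}
        dropped = [p for p in pm.populations if p not in keep]
    elif rule == "exclude_nonzero_D":
        if stats is None:
            raise ValueError("exclude_nonzero_D requires significance flags")
        keep = {p for p in pm.populations if not stats.get(p, False)}
        dropped = [p for p in pm.populations if p not in keep]
    else:
        raise ValueError(f"unknown filtering rule {rule!r}")
    if dropped:
        logger.info("filter_populations(%s): excluded %s", rule, dropped)
    if not keep:
        warnings.warn("no populations pass the filter; returning empty map")
    return pm.restrict_to(keep)
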