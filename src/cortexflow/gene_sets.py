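"""Gene-set algebra: core-set intersection, overlap fractions, enrichment.

Implements the three-way intersection that defines the core
hormone-responsive gene set (induced in the cortex, reduced in the
receptor-null cortex, developmentally varying along the wild-type cortex
trajectory), plus generic overlap and hypergeometric enrichment against
user-supplied collections (e.g. ChIP target lists). GMT-style files are the
on-disk format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import scipy.stats

__all__ = ["GeneSet", "CoreSetResult", "intersect_core", "overlap_fraction",
           "hypergeom_enrichment", "read_gmt", "write_gmt"]


@dataclass
class GeneSet:
    name: str
    gene_ids: set
    description: str = ""

    def __post_init__(self):
        self.gene_ids = set(self.gene_ids)

    def __len__(self):
        return len(self.gene_ids)


@dataclass
class CoreSetResult:
    """Pairwise and triple intersections of the three defining sets."""

    a: GeneSet
    b: GeneSet
    c: GeneSet
    ab: set = field(init=False)
    bc: set = field(init=False)
    ac: set = field(init=False)
    core: GeneSet = field(init=False)

    def __post_init__(self):
        self.ab = self.a.gene_ids & self.b.gene_ids
        self.bc = self.b.gene_ids & self.c.gene_ids
        self.ac = self.a.gene_ids & self.c.gene_ids
        self.core = GeneSet("core", self.ab & self.c.gene_ids,
                            f"triple intersection of {self.a.name}, "
                            f"{self.b.name}, {self.c.name}")

    def sizes(self) -> dict:
        return {"A": len(self.a), "B": len(self.b), "C": len(self.c),
                "A∩B": len(self.ab), "B∩C": len(self.bc), "A∩C": len(self.ac),
                "core": len(self.core)}


def intersect_core(A: GeneSet, B: GeneSet, C: GeneSet) -> CoreSetResult:
    """Three-way intersection; order-invariant and deterministic."""
    return CoreSetResult(A, B, C)


def overlap_fraction(query: GeneSet, reference: GeneSet) -> float:
    """|query ∩ reference| / |query| — e.g. fraction of core genes that are
    direct targets in a ChIP list."""
    if len(query) == 0:
        raise ValueError("query set is empty")
    return len(query.gene_ids & reference.gene_ids) / len(query)


def hypergeom_enrichment(query: GeneSet, reference: GeneSet,
                         universe: GeneSet) -> tuple:
    """Upper-tail hypergeometric enrichment of query in reference.

    Returns ``(p, fold_enrichment, overlap_size)`` where p is the probability
    of at least the observed overlap under random draws of |query| genes from
    the universe, and fold = (overlap/|query|) / (|reference|/|universe|).
    No multiple-testing correction is applied here; callers apply BH over
    collections.
    """
    for s, name in ((query, "query"), (reference, "reference")):
        extra = s.gene_ids - universe.gene_ids
        if extra:
            raise ValueError(
                f"{name} set not contained in universe; offending ids: "
                f"{sorted(extra)[:10]}")
    k = len(query.gene_ids & reference.gene_ids)
    M, nref, N = len(universe), len(reference), len(query)
    p = float(scipy.stats.hypergeom.sf(k - 1, M, nref, N))
    fold = (k / N) / (nref / M) if N and nref else float("nan")
    return p, fold, k


def read_gmt(path: str) -> list:
    """Read GMT: one set per line — name, description, then gene ids."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            sets.append(GeneSet(parts[0], set(g for g in parts[2:] if g),
                                parts[1]))
    return sets


def write_gmt(sets, path: str) -> str:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description] + sorted(s.gene_ids)))
            fh.write("\n")
    return path
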