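"""Haplogroup definitions, motif-based classification and frequency surveys.

A haplogroup is a clade of mtDNA lineages sharing the derived mutations (its
*motif*) on the branch from its parent clade.  The shipped definition table
covers the N1a1b/I and W clade system; a profile is assigned to the clade
whose cumulative motif (union of branch motifs from the root, with back
mutations cancelling earlier events at the same position) it matches best.
Population surveys tabulate per-clade carrier frequencies from HVS-I
haplotype lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import (
    HVS1_RANGE,
    MtVariant,
    VarClass,
    VariantProfile,
    parse_tokens,
)

__all__ = [
    "HaplogroupDef",
    "HaplogroupTree",
    "ClassificationResult",
    "PopulationSurvey",
    "load_definitions",
    "default_definitions",
    "cumulative_motif",
    "classify",
    "survey_frequencies",
    "read_survey_tsv",
]

logger = logging.getLogger(__name__)

ROOT_SENTINELS = frozenset({"-", "", "root", "rCRS", "RSRS"})


@dataclass(frozen=True)
class HaplogroupDef:
    """A named clade: its parent and the branch motif from that parent."""

    name: str
    parent: str
    motif: frozenset[MtVariant]
    status: str = "printed"


class HaplogroupTree:
    """A rooted tree of haplogroup definitions.

    The root is the reference haplotype itself (sentinel name, empty motif);
    every other clade names an existing parent and the parent relation is
    acyclic.
    """

    def __init__(self, defs: Iterable[HaplogroupDef], root: str = "rCRS"):
        self.root = root
        self._defs: dict[str, HaplogroupDef] = {
            root: HaplogroupDef(root, "-", frozenset(), "root")
        }
        for d in defs:
            if d.name in self._defs:
                raise ValueError(f"duplicate haplogroup definition {d.name!r}")
            self._defs[d.name] = d
        for d in self._defs.values():
            if d.name == root:
                continue
            parent = root if d.parent in ROOT_SENTINELS else d.parent
            if parent not in self._defs:
                raise ValueError(f"clade {d.name!r} names unknown parent {d.parent!r}")
        # cycle check via root-path walk
        for name in self._defs:
            self.path(name)
        self._cumulative: dict[str, frozenset[MtVariant]] = {}

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __iter__(self):
        return iter(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    def definition(self, name: str) -> HaplogroupDef:
        try:
            return self._defs[name]
        except KeyError:
            raise KeyError(f"unknown haplogroup {name!r}") from None

    def parent(self, name: str) -> str | None:
        d = self.definition(name)
        if name == self.root:
            return None
        return self.root if d.parent in ROOT_SENTINELS else d.parent

    def path(self, name: str) -> list[str]:
        """Clade names from the root down to ``name`` (inclusive)."""
        chain = [name]
        seen = {name}
        while (p := self.parent(chain[-1])) is not None:
            if p in seen:
                raise ValueError(f"cycle in haplogroup definitions at {p!r}")
            chain.append(p)
            seen.add(p)
        return chain[::-1]

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def cumulative_motif(self, name: str) -> frozenset[MtVariant]:
        """Union of branch motifs root->clade with back-mutation cancellation.

        A back mutation at position p removes the earlier event at p and is
        itself dropped; an uncancelled back mutation (no earlier event on the
        path) is kept, since it still marks a difference from the root state.
        """
        if name not in self._cumulative:
            state: dict[tuple[int, int | None], MtVariant] = {}
            for clade in self.path(name):
                for v in sorted(self.definition(clade).motif):
                    if v.var_class is VarClass.BACK_MUTATION and v.site in state:
                        del state[v.site]
                    else:
                        state[v.site] = v
            self._cumulative[name] = frozenset(state.values())
        return self._cumulative[name]


def cumulative_motif(tree: HaplogroupTree, clade: str) -> frozenset[MtVariant]:
    """Functional alias for :meth:`HaplogroupTree.cumulative_motif`."""
    return tree.cumulative_motif(clade)


def load_definitions(path, root: str = "rCRS") -> HaplogroupTree:
    """Read a tab-separated definition table (name, parent, [status,] motif)."""
    defs = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None and fields[0] == "name":
                header = fields
                continue
            if len(fields) == 3:
                name, parent, motif = fields
                status = "printed"
            else:
                name, parent, status, motif = fields[:4]
            defs.append(HaplogroupDef(name, parent, parse_tokens(motif), status))
    return HaplogroupTree(defs, root=root)


_DEFAULT_TREE: HaplogroupTree | None = None


def default_definitions() -> HaplogroupTree:
    """The shipped N1a1b/I + W definition tree."""
    global _DEFAULT_TREE
    if _DEFAULT_TREE is None:
        with resources.as_file(
            resources.files("mitophylo.data").joinpath("haplogroup_defs.tsv")
        ) as p:
            _DEFAULT_TREE = load_definitions(p)
    return _DEFAULT_TREE


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    best_clade: str
    matched: int
    missing: int
    private: int
    score: int


def _visible(motif: Iterable[MtVariant], profile: VariantProfile) -> frozenset[MtVariant]:
    return frozenset(v for v in motif if profile.covers(v.position))


def classify(
    profile: VariantProfile, tree: HaplogroupTree | None = None
) -> ClassificationResult:
    """Assign a profile to the best-matching haplogroup.

    Each clade is scored as matched − missing over the part of its cumulative
    motif falling in the profile's observed region (HVS-I, or explicit
    covered ranges); sample variants outside every motif are private and not
    penalised.  Among top-scoring clades, a clade is dropped when its parent
    scores equally well (descending without added evidence is not an
    assignment), then the deepest remaining clade wins, then the
    lexicographically smallest name.
    """
    tree = tree or default_definitions()
    if len(tree) <= 1:
        raise ValueError("empty haplogroup definition tree")
    observed = frozenset(v for v in profile.variants if profile.covers(v.position))
    scores: dict[str, tuple[int, int]] = {}
    for name in tree:
        motif = _visible(tree.cumulative_motif(name), profile)
        matched = len(motif & observed)
        scores[name] = (matched, len(motif) - matched)
    best = max(m - x for m, x in scores.values())
    top = {n for n, (m, x) in scores.items() if m - x == best}
    # prune zero-evidence descents: drop clades whose parent ties them
    pruned = {
        n for n in top
        if (p := tree.parent(n)) is None or p not in top
    }
    winner = max(pruned, key=lambda n: (tree.depth(n), [-ord(c) for c in n]))
    matched, missing = scores[winner]
    path_union: set[MtVariant] = set()
    for clade in tree.path(winner):
        path_union |= _visible(tree.definition(clade).motif, profile)
    private = len(observed - path_union)
    return ClassificationResult(
        profile.sample_id, winner, matched, missing, private, matched - missing
    )


# ---------------------------------------------------------------------------
# Frequency surveys


@dataclass(frozen=True)
class PopulationSurvey:
    """One population's HVS-I haplotype sample for a frequency survey."""

    population: str
    latitude: float
    longitude: float
    n: int
    haplotypes: tuple[VariantProfile, ...]

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90 or not -180 <= self.longitude <= 180:
            raise ValueError(f"{self.population}: coordinates out of range")
        if self.n < len(self.haplotypes):
            raise ValueError(
                f"{self.population}: n={self.n} below listed haplotype count"
            )


def _hvs1_motif(tree: HaplogroupTree, clade: str) -> frozenset[MtVariant]:
    lo, hi = HVS1_RANGE
    return frozenset(
        v for v in tree.cumulative_motif(clade) if lo <= v.position <= hi
    )


def hvs1_assessable(tree: HaplogroupTree, clade: str) -> bool:
    """Whether a clade is distinguishable from its parent in HVS-I data.

    A clade whose HVS-I-restricted cumulative motif is empty or identical to
    its parent's (e.g. one defined solely by a coding-region transition)
    cannot be surveyed from control-region databases.
    """
    motif = _hvs1_motif(tree, clade)
    parent = tree.parent(clade)
    if not motif:
        return False
    return parent is None or motif != _hvs1_motif(tree, parent)


def survey_frequencies(
    surveys: Sequence[PopulationSurvey],
    tree: HaplogroupTree | None = None,
    clades: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-population carrier frequencies (%) of each clade's HVS-I motif.

    A haplotype is a carrier of a clade when it contains the clade's full
    HVS-I-restricted cumulative motif.  Clades not assessable from HVS-I
    data get NaN columns; populations with n=0 are skipped with a warning.
    Row order follows the input.
    """
    tree = tree or default_definitions()
    assessable = {c: hvs1_assessable(tree, c) for c in clades}
    for c, ok in assessable.items():
        if not ok:
            logger.warning(
                "clade %s is not assessable from HVS-I data "
                "(no control-region motif beyond its parent)", c
            )
    rows = []
    for s in surveys:
        if s.n == 0:
            logger.warning("population %s skipped: n=0", s.population)
            continue
        row: dict[str, object] = {
            "population": s.population,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "n": s.n,
        }
        for c in clades:
            if not assessable[c]:
                row[c] = float("nan")
                continue
            motif = _hvs1_motif(tree, c)
            carriers = sum(1 for h in s.haplotypes if motif <= h.variants)
            row[c] = 100.0 * carriers / s.n
        rows.append(row)
    return pd.DataFrame(rows)


def read_survey_tsv(path) -> list[PopulationSurvey]:
    """Read surveys: ``population<TAB>lat<TAB>lon<TAB>n`` header lines, each
    followed by one indented/continuation line per carried haplotype is not
    required — the flat format is one row per haplotype:
    ``population<TAB>lat<TAB>lon<TAB>n<TAB>tokens`` (tokens empty for
    populations listed without haplotypes)."""
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pop, lat, lon, n, *rest = line.split("\t")
            g = groups.setdefault(
                pop, {"lat": float(lat), "lon": float(lon), "n": int(n), "haps": []}
            )
            toks = rest[0].strip() if rest else ""
            if toks:
                g["haps"].append(
                    VariantProfile.from_tokens(
                        f"{pop}_{len(g['haps']) + 1}", toks, region="HVS-I"
                    )
                )
    return [
        PopulationSurvey(p, g["lat"], g["lon"], g["n"], tuple(g["haps"]))
        for p, g in groups.items()
    ]
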