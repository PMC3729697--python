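"""Coalescent simulation of mtDNA clades with known truth.

Generates rooted genealogies (Kingman coalescent via msprime, or a fixed
user tree), places Poisson mutations on branches at a whole-molecule rate
consistent with the corrected clock (about one substitution every 2.5-3 ky
on recent lineages), concentrates recurrent hits at designated hotspot
positions, and emits aligned FASTA, variant profiles and truth records, so
that every upstream stage — nomenclature, classification, tree building and
dating — can be exercised against planted answers.

The root haplotype is the reference itself, so a tip's profile is exactly
the set of surviving mutations on its root path.  A repeat hit at an
already-mutated position on a lineage becomes a reversion (``@``) with
probability 1/2, otherwise a transversion to a third base.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .variants import (
    MT_LENGTH,
    HVS1_RANGE,
    MtVariant,
    TRANSITIONS,
    VarClass,
    VariantProfile,
)

__all__ = [
    "SimConfig",
    "GenealogyNode",
    "SimTruth",
    "SimResult",
    "default_hotspot_rates",
    "synthetic_reference",
    "simulate_clade",
    "make_survey",
]

#: Years per substitution on recent lineages (local slope of the corrected
#: clock near the origin); the default mutation rate is its reciprocal.
RECENT_YEARS_PER_SUB = 2600.0


def default_hotspot_rates() -> dict[int, float]:
    """Shipped hotspot positions with their rate multipliers."""
    text = resources.files("mitophylo.data").joinpath("hotspots.tsv").read_text()
    out = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("position"):
            continue
        pos, _, mult = line.split("\t")
        out[int(pos)] = float(mult)
    return out


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated clade.

    Exactly one of ``tmrca_years`` (genealogy rescaled to a fixed root age)
    or ``coalescent_ne_years`` (free-floating Kingman with the given scale)
    must be set unless a fixed genealogy is supplied.
    """

    n_tips: int
    seed: int
    tmrca_years: float | None = None
    coalescent_ne_years: float | None = None
    rate_per_year: float = 1.0 / RECENT_YEARS_PER_SUB
    hotspots: Mapping[int, float] | None = None
    transversion_fraction: float = 0.05
    use_hotspots: bool = True

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")
        if self.rate_per_year < 0 or not 0 <= self.transversion_fraction <= 1:
            raise ValueError("rates must be non-negative")
        if self.tmrca_years is not None and self.coalescent_ne_years is not None:
            raise ValueError(
                "set either tmrca_years or coalescent_ne_years, not both"
            )


class GenealogyNode:
    """A node of the true genealogy; ``duration`` is the branch length in
    years to the parent."""

    __slots__ = ("name", "duration", "children", "time")

    def __init__(self, name: str | None = None, duration: float = 0.0):
        self.name = name
        self.duration = duration
        self.children: list[GenealogyNode] = []
        self.time = 0.0  # age in years (0 at tips), filled by _set_times

    def add(self, child: "GenealogyNode") -> "GenealogyNode":
        self.children.append(child)
        return child

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self) -> str:
        if self.children:
            inner = ",".join(c.newick() for c in self.children)
            return f"({inner}){self.name or ''}:{self.duration:.1f}"
        return f"{self.name}:{self.duration:.1f}"


def _set_times(root: GenealogyNode) -> None:
    # age of a node = max tip distance below (genealogies here are clock-like)
    def depth(n: GenealogyNode) -> float:
        if not n.children:
            n.time = 0.0
            return 0.0
        n.time = max(depth(c) + c.duration for c in n.children)
        return n.time

    depth(root)


@dataclass
class SimTruth:
    """Planted truth: the genealogy (with node times), per-edge mutation
    tokens and the true TMRCA in years."""

    genealogy: GenealogyNode
    tmrca_years: float
    edge_mutations: dict[str, list[str]]  # node path-id -> tokens
    tip_tokens: dict[str, list[str]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "tmrca_years": self.tmrca_years,
                "newick": self.genealogy.newick() + ";",
                "edge_mutations": self.edge_mutations,
                "tip_profiles": self.tip_tokens,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SimResult:
    truth: SimTruth
    profiles: list[VariantProfile]
    sequences: dict[str, str]

    def truth_phylogeny(self):
        """The planted genealogy with its planted mutations, as a
        :class:`~mitophylo.tree.CladePhylogeny` (topology fixed to truth)."""
        from .tree import CladePhylogeny, PhyloNode
        from .variants import parse_variant

        def convert(g: GenealogyNode, path: str) -> PhyloNode:
            node = PhyloNode(g.name if not g.children else None)
            node.edge_mutations = [
                parse_variant(t) for t in self.truth.edge_mutations[path]
            ]
            for i, c in enumerate(g.children):
                node.add_child(convert(c, f"{path}.{i}"))
            return node

        return CladePhylogeny(convert(self.truth.genealogy, "r"))

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "samples.fasta", "w") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        from .variants import write_profiles_tsv

        write_profiles_tsv(self.profiles, out / "profiles.tsv")
        with open(out / "truth.json", "w") as fh:
            fh.write(self.truth.to_json() + "\n")


_REF_CACHE: str | None = None


def synthetic_reference(length: int = MT_LENGTH) -> str:
    """A fixed synthetic 16,569-nt reference (seeded once, mtDNA-like base
    composition); stands in for a real reference so the pipeline needs no
    external downloads."""
    global _REF_CACHE
    if _REF_CACHE is None or len(_REF_CACHE) != length:
        rng = np.random.default_rng(16569)
        bases = np.array(list("ACGT"))
        _REF_CACHE = "".join(
            rng.choice(bases, size=length, p=[0.31, 0.31, 0.13, 0.25])
        )
    return _REF_CACHE


def _coalescent_genealogy(cfg: SimConfig, rng: np.random.Generator) -> GenealogyNode:
    import msprime

    ne = cfg.coalescent_ne_years if cfg.coalescent_ne_years is not None else 1.0
    ts = msprime.sim_ancestry(
        samples=cfg.n_tips,
        ploidy=1,
        population_size=ne,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    t = ts.first()
    scale = 1.0
    if cfg.tmrca_years is not None:
        root_time = max(t.time(r) for r in t.roots)
        scale = cfg.tmrca_years / root_time

    def convert(u: int) -> GenealogyNode:
        parent_time = t.time(t.parent(u)) if t.parent(u) != -1 else t.time(u)
        node = GenealogyNode(
            name=f"t{u}" if t.is_leaf(u) else None,
            duration=(parent_time - t.time(u)) * scale,
        )
        for c in t.children(u):
            node.add(convert(c))
        return node

    root = convert(t.root)
    _set_times(root)
    return root


def _site_distribution(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    weights = np.ones(MT_LENGTH)
    if cfg.use_hotspots:
        hot = cfg.hotspots if cfg.hotspots is not None else default_hotspot_rates()
        for pos, mult in hot.items():
            weights[pos - 1] = mult
    return np.arange(1, MT_LENGTH + 1), weights / weights.sum()


def simulate_clade(
    cfg: SimConfig, genealogy: GenealogyNode | None = None
) -> SimResult:
    """Simulate one clade: genealogy, Poisson mutations, emitted data.

    Deterministic given ``cfg.seed`` (and the fixed genealogy, if given).
    """
    rng = np.random.default_rng(cfg.seed)
    if genealogy is None:
        if cfg.tmrca_years is None and cfg.coalescent_ne_years is None:
            raise ValueError(
                "need tmrca_years or coalescent_ne_years (or a fixed genealogy)"
            )
        genealogy = _coalescent_genealogy(cfg, rng)
    else:
        _set_times(genealogy)
    positions, probs = _site_distribution(cfg)
    ref = synthetic_reference()
    tvs = {b: sorted(set("ACGT") - {b, TRANSITIONS[b]}) for b in "ACGT"}

    edge_mutations: dict[str, list[str]] = {}
    tip_tokens: dict[str, list[str]] = {}
    profiles: list[VariantProfile] = []
    sequences: dict[str, str] = {}
    counter = [0]

    def descend(node: GenealogyNode, state: dict[int, MtVariant], path: str) -> None:
        n_mut = rng.poisson(cfg.rate_per_year * node.duration)
        events: list[str] = []
        for _ in range(n_mut):
            pos = int(rng.choice(positions, p=probs))
            ref_base = ref[pos - 1]
            if pos in state:
                if rng.random() < 0.5:
                    events.append(MtVariant(pos, VarClass.BACK_MUTATION).render())
                    del state[pos]
                else:
                    base = tvs[ref_base][int(rng.integers(0, 2))]
                    v = MtVariant(pos, VarClass.TRANSVERSION, base)
                    events.append(v.render())
                    state[pos] = v
            elif rng.random() < cfg.transversion_fraction:
                base = tvs[ref_base][int(rng.integers(0, 2))]
                v = MtVariant(pos, VarClass.TRANSVERSION, base)
                events.append(v.render())
                state[pos] = v
            else:
                v = MtVariant(pos, VarClass.TRANSITION)
                events.append(v.render())
                state[pos] = v
        edge_mutations[path] = events
        if not node.children:
            sid = node.name or f"tip{counter[0]}"
            counter[0] += 1
            variants = frozenset(state.values())
            tip_tokens[sid] = [v.render() for v in sorted(variants)]
            profiles.append(VariantProfile(sid, variants))
            seq = list(ref)
            for v in variants:
                seq[v.position - 1] = (
                    v.derived_base
                    if v.derived_base is not None
                    else TRANSITIONS[ref[v.position - 1]]
                )
            sequences[sid] = "".join(seq)
            return
        for i, child in enumerate(node.children):
            descend(child, dict(state), f"{path}.{i}")

    descend(genealogy, {}, "r")
    truth = SimTruth(genealogy, genealogy.time, edge_mutations, tip_tokens)
    return SimResult(truth, profiles, sequences)


# ---------------------------------------------------------------------------
# Survey fixtures


def make_survey(
    n_populations: int,
    clade_carriers: Mapping[str, int | Sequence[int]],
    n: int = 100,
    seed: int = 0,
    defs=None,
    n_background: int = 5,
):
    """Construct HVS-I survey fixtures with exact planted frequencies.

    Each population holds, per requested clade, the stated number of
    haplotypes carrying that clade's HVS-I cumulative motif, plus background
    haplotypes built from non-motif control-region transitions; recovered
    frequencies equal carriers/n exactly.
    """
    from .haplogroups import PopulationSurvey, default_definitions

    defs = defs or default_definitions()
    rng = np.random.default_rng(seed)
    lo, hi = HVS1_RANGE
    motif_positions: set[int] = set()
    motifs: dict[str, frozenset[MtVariant]] = {}
    for clade in clade_carriers:
        m = frozenset(
            v for v in defs.cumulative_motif(clade) if lo <= v.position <= hi
        )
        motifs[clade] = m
    for name in defs:
        for v in defs.cumulative_motif(name):
            if lo <= v.position <= hi:
                motif_positions.add(v.position)
    free = sorted(set(range(lo, hi + 1)) - motif_positions)

    surveys = []
    for p in range(n_populations):
        pops_n = n if isinstance(n, int) else n[p]
        haps = []
        for clade, carriers in clade_carriers.items():
            c = carriers if isinstance(carriers, int) else carriers[p]
            if c > pops_n:
                raise ValueError(
                    f"population {p}: {c} {clade} carriers exceed n={pops_n}"
                )
            for i in range(c):
                haps.append(
                    VariantProfile(
                        f"pop{p}_{clade}_{i}", motifs[clade], region="HVS-I"
                    )
                )
        for b in range(n_background):
            k = int(rng.integers(1, 4))
            pos = rng.choice(free, size=k, replace=False)
            variants = frozenset(MtVariant(int(q)) for q in pos)
            haps.append(
                VariantProfile(f"pop{p}_bg{b}", variants, region="HVS-I")
            )
        surveys.append(
            PopulationSurvey(
                population=f"pop{p}",
                latitude=float(rng.uniform(-60, 70)),
                longitude=float(rng.uniform(-170, 170)),
                n=pops_n,
                haplotypes=tuple(haps),
            )
        )
    return surveys
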