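"""mtDNA variant nomenclature: parsing, profiles, masks and distances.

Human mitochondrial variation is conventionally written as positional tokens
relative to a reference sequence (rCRS coordinates, 1..16569): ``16292`` is a
transition at 16292, ``8616T`` a transversion whose derived base is T,
``195@`` a back mutation (reversion toward the ancestral state), ``16189d`` a
deletion and ``309.1C`` an insertion after position 309.  This module parses
and renders those tokens, derives variant profiles from aligned sequences,
applies the hotspot exclusion mask used for dating, and computes
symmetric-difference distances between profiles.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "MT_LENGTH",
    "HVS1_RANGE",
    "VarClass",
    "MtVariant",
    "VariantProfile",
    "SiteMask",
    "DEFAULT_MASK",
    "VariantParseError",
    "parse_variant",
    "parse_tokens",
    "profile_from_sequence",
    "apply_mask",
    "profile_distance",
    "read_fasta_profiles",
    "read_profiles_tsv",
    "write_profiles_tsv",
    "rsrs_rcrs_differences",
    "convert_reference",
]

#: Length of the human mitochondrial genome in rCRS numbering.
MT_LENGTH = 16569

#: First hypervariable segment of the control region (inclusive bounds).
HVS1_RANGE = (16024, 16365)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
#: Transition partner of each base.
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


class VarClass(str, enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INSERTION = "insertion"
    DELETION = "deletion"
    BACK_MUTATION = "back_mutation"


class VariantParseError(ValueError):
    """Raised when a nomenclature token cannot be parsed."""


_TOKEN_RE = re.compile(
    r"""^(?P<pos>\d+)
        (?:\.(?P<ins>\d+))?
        (?P<base>[ACGT])?
        (?P<del>d)?
        (?P<back>@)?$""",
    re.VERBOSE,
)


@dataclass(frozen=True, order=True)
class MtVariant:
    """A single mutation event in mtDNA positional nomenclature."""

    position: int
    var_class: VarClass = VarClass.TRANSITION
    derived_base: str | None = None
    insert_index: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise VariantParseError(
                f"position {self.position} outside 1..{MT_LENGTH}"
            )
        if self.var_class is VarClass.TRANSVERSION and self.derived_base is None:
            raise VariantParseError(
                f"transversion at {self.position} requires a derived base"
            )
        if self.var_class is VarClass.INSERTION and (
            self.insert_index is None or self.derived_base is None
        ):
            raise VariantParseError(
                f"insertion at {self.position} requires '.N' index and base"
            )

    @property
    def is_substitution(self) -> bool:
        return self.var_class in (
            VarClass.TRANSITION,
            VarClass.TRANSVERSION,
            VarClass.BACK_MUTATION,
        )

    @property
    def site(self) -> tuple[int, int | None]:
        """Identity of the mutated site: (position, insert_index)."""
        return (self.position, self.insert_index)

    def render(self) -> str:
        """Canonical token; ``parse_variant(v.render()) == v``."""
        s = str(self.position)
        if self.var_class is VarClass.INSERTION:
            return f"{s}.{self.insert_index}{self.derived_base}"
        if self.var_class is VarClass.DELETION:
            return s + "d"
        if self.derived_base is not None:
            s += self.derived_base
        if self.var_class is VarClass.BACK_MUTATION:
            s += "@"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_variant(token: str) -> MtVariant:
    """Parse one nomenclature token into an :class:`MtVariant`.

    A bare number is a transition, a base suffix marks a transversion (the
    derived base), ``d`` a deletion, ``.N<base>`` an insertion and a trailing
    ``@`` a back mutation.
    """
    tok = token.strip()
    if not tok:
        raise VariantParseError("empty variant token")
    m = _TOKEN_RE.match(tok)
    if m is None:
        raise VariantParseError(f"malformed variant token {token!r}")
    pos = int(m.group("pos"))
    if not 1 <= pos <= MT_LENGTH:
        raise VariantParseError(
            f"variant token {token!r}: position {pos} outside 1..{MT_LENGTH}"
        )
    ins = m.group("ins")
    base = m.group("base")
    is_del = m.group("del") is not None
    is_back = m.group("back") is not None
    if is_del and (ins or base):
        raise VariantParseError(f"malformed variant token {token!r}")
    if ins is not None:
        if base is None or is_back:
            raise VariantParseError(
                f"insertion token {token!r} needs a base and cannot be '@'"
            )
        return MtVariant(pos, VarClass.INSERTION, base, int(ins))
    if is_del:
        return MtVariant(pos, VarClass.DELETION)
    if is_back:
        return MtVariant(pos, VarClass.BACK_MUTATION, base)
    if base is not None:
        return MtVariant(pos, VarClass.TRANSVERSION, base)
    return MtVariant(pos, VarClass.TRANSITION)


def parse_tokens(tokens: str | Iterable[str]) -> frozenset[MtVariant]:
    """Parse whitespace- or dash-separated motif strings or token iterables."""
    if isinstance(tokens, str):
        tokens = re.split(r"[\s,-]+", tokens.strip())
    return frozenset(parse_variant(t) for t in tokens if t)


@dataclass(frozen=True)
class SiteMask:
    """Variant identities excluded from distance and dating computations.

    A mask entry with a derived base (``16182C``) matches only that state; a
    bare-position entry (``16519``) matches any variant at the position.
    """

    excluded: frozenset[MtVariant] = frozenset()

    @classmethod
    def from_tokens(cls, tokens: str | Iterable[str]) -> "SiteMask":
        return cls(parse_tokens(tokens))

    def matches(self, v: MtVariant) -> bool:
        for e in self.excluded:
            if e.position != v.position:
                continue
            if e.derived_base is None or e.derived_base == v.derived_base:
                return True
        return False


#: Hotspot sites excluded from all distance and dating computations:
#: the length-variant-prone 16182C/16183C states and the 16519 hotspot.
DEFAULT_MASK = SiteMask.from_tokens("16182C 16183C 16519")


def _check_region(variants: Iterable[MtVariant], region: str) -> None:
    if region == "HVS-I":
        lo, hi = HVS1_RANGE
        for v in variants:
            if not lo <= v.position <= hi:
                raise ValueError(
                    f"variant {v.render()} outside HVS-I ({lo}-{hi}) "
                    "in an HVS-I profile"
                )


@dataclass(frozen=True)
class VariantProfile:
    """A sample's variants relative to a named reference.

    ``region`` is ``full_genome`` or ``HVS-I``; ``covered`` optionally narrows
    the observed span further (e.g. an ancient sample typed for 15995-16429
    plus 34-287), as a tuple of inclusive (start, end) ranges used when
    scoring motif evidence.
    """

    sample_id: str
    variants: frozenset[MtVariant]
    reference: str = "rCRS"
    region: str = "full_genome"
    covered: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.reference not in ("rCRS", "RSRS"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.region not in ("full_genome", "HVS-I"):
            raise ValueError(f"unknown region {self.region!r}")
        seen: dict[tuple[int, int | None], MtVariant] = {}
        for v in self.variants:
            if v.site in seen:
                raise ValueError(
                    f"profile {self.sample_id}: duplicate variants at site "
                    f"{v.site}: {seen[v.site].render()} / {v.render()}"
                )
            seen[v.site] = v
        _check_region(self.variants, self.region)

    @classmethod
    def from_tokens(
        cls,
        sample_id: str,
        tokens: str | Iterable[str],
        reference: str = "rCRS",
        region: str = "full_genome",
        covered: tuple[tuple[int, int], ...] | None = None,
    ) -> "VariantProfile":
        return cls(sample_id, parse_tokens(tokens), reference, region, covered)

    @property
    def covered_ranges(self) -> tuple[tuple[int, int], ...]:
        if self.covered is not None:
            return self.covered
        if self.region == "HVS-I":
            return (HVS1_RANGE,)
        return ((1, MT_LENGTH),)

    def covers(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.covered_ranges)

    def tokens(self) -> list[str]:
        return [v.render() for v in sorted(self.variants)]

    def substitutions(self) -> frozenset[MtVariant]:
        return frozenset(v for v in self.variants if v.is_substitution)


def apply_mask(profile: VariantProfile, mask: SiteMask = DEFAULT_MASK) -> VariantProfile:
    """Return a copy of ``profile`` with masked variants removed."""
    kept = frozenset(v for v in profile.variants if not mask.matches(v))
    return replace(profile, variants=kept)


def profile_distance(
    a: VariantProfile, b: VariantProfile, mask: SiteMask = DEFAULT_MASK
) -> int:
    """Symmetric-difference count between two masked profiles."""
    if a.reference != b.reference:
        raise ValueError(
            f"profiles use different references: {a.reference} vs {b.reference}"
        )
    va = frozenset(v for v in a.variants if not mask.matches(v))
    vb = frozenset(v for v in b.variants if not mask.matches(v))
    return len(va ^ vb)


# ---------------------------------------------------------------------------
# Sequence comparison

_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")


def profile_from_sequence(
    seq: str,
    ref: str,
    sample_id: str = "sample",
    ref_name: str = "rCRS",
    gap_chars: str = "-",
) -> VariantProfile:
    """Call a variant profile from an aligned sequence/reference pair.

    Both strings must have the same alignment length; positions are reported
    in reference (rCRS-style) coordinates.  Substitutions are classed as
    transition or transversion from the reference base; a gap in the sample
    is a deletion, a gap in the reference an insertion (left-aligned ``.N``
    numbering).  Ambiguity codes are rejected rather than silently dropped,
    because profiles are consensus calls.
    """
    if len(seq) != len(ref):
        raise ValueError(
            f"alignment length mismatch: sample {len(seq)} vs reference {len(ref)}"
        )
    seq = seq.upper()
    ref = ref.upper()
    variants: list[MtVariant] = []
    pos = 0  # last reference coordinate seen
    insert_index = 0
    for col, (s, r) in enumerate(zip(seq, ref), start=1):
        if r in gap_chars and s in gap_chars:
            continue
        for c in (s, r):
            if c not in gap_chars and c not in "ACGT":
                if c in _IUPAC_AMBIGUOUS:
                    raise ValueError(
                        f"ambiguity code {c!r} at alignment column {col}; "
                        "profiles require consensus calls"
                    )
                raise ValueError(f"non-IUPAC character {c!r} at alignment column {col}")
        if r in gap_chars:
            insert_index += 1
            variants.append(
                MtVariant(max(pos, 1), VarClass.INSERTION, s, insert_index)
            )
            continue
        pos += 1
        insert_index = 0
        if s in gap_chars:
            variants.append(MtVariant(pos, VarClass.DELETION))
        elif s != r:
            if TRANSITIONS[r] == s:
                variants.append(MtVariant(pos, VarClass.TRANSITION))
            else:
                variants.append(MtVariant(pos, VarClass.TRANSVERSION, s))
    return VariantProfile(sample_id, frozenset(variants), reference=ref_name)


def read_fasta_profiles(
    samples_path, ref_path, ref_name: str = "rCRS"
) -> list[VariantProfile]:
    """Call profiles for every record of an aligned multi-FASTA against a
    single-record reference FASTA."""
    from Bio import SeqIO

    refs = list(SeqIO.parse(str(ref_path), "fasta"))
    if len(refs) != 1:
        raise ValueError(f"reference FASTA must hold one record, found {len(refs)}")
    ref = str(refs[0].seq)
    return [
        profile_from_sequence(str(rec.seq), ref, sample_id=rec.id, ref_name=ref_name)
        for rec in SeqIO.parse(str(samples_path), "fasta")
    ]


# ---------------------------------------------------------------------------
# Plain-text profile lists: one sample per line, "sample_id<TAB>tokens"


def read_profiles_tsv(path, reference: str = "rCRS", region: str = "full_genome"):
    profiles = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, _, toks = line.partition("\t")
            profiles.append(
                VariantProfile.from_tokens(sid, toks, reference=reference, region=region)
            )
    return profiles


def write_profiles_tsv(profiles: Sequence[VariantProfile], path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(f"{p.sample_id}\t{' '.join(p.tokens())}\n")


# ---------------------------------------------------------------------------
# rCRS / RSRS reference translation

_RSRS_DIFFS: frozenset[MtVariant] | None = None


def rsrs_rcrs_differences() -> frozenset[MtVariant]:
    """Variant set separating the rCRS from the RSRS ancestral root, as
    tokens in rCRS coordinates (shipped translation table)."""
    global _RSRS_DIFFS
    if _RSRS_DIFFS is None:
        text = (
            resources.files("mitophylo.data").joinpath("rsrs_rcrs_diff.tsv").read_text()
        )
        toks = [
            line.split("\t")[0]
            for line in text.splitlines()
            if line and not line.startswith("#")
        ]
        _RSRS_DIFFS = parse_tokens(toks)
    return _RSRS_DIFFS


def convert_reference(profile: VariantProfile, to: str) -> VariantProfile:
    """Re-express a profile against the other root reference.

    Switching reference toggles membership of every translation-table site:
    a difference from rCRS that is ancestral in RSRS disappears, and vice
    versa.  Coordinates stay in rCRS numbering throughout.  Back mutations,
    indels and transversions at translation sites are left untouched (they
    remain informative under either root).
    """
    if to not in ("rCRS", "RSRS"):
        raise ValueError(f"unknown reference {to!r}")
    if profile.reference == to:
        return profile
    diffs = {v for v in rsrs_rcrs_differences() if v.var_class is VarClass.TRANSITION}
    plain = {v for v in profile.variants if v.var_class is VarClass.TRANSITION}
    other = profile.variants - plain
    toggled = (plain - diffs) | (diffs - plain)
    return replace(profile, variants=frozenset(toggled) | other, reference=to)
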