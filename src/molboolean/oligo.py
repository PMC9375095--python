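"""Sequence-level model of the dual-tag rolling-circle assay DNA logic.

The assay encodes protein detection events in a preformed DNA circle: antibody
probes carry "arm" oligonucleotides complementary to the circle; a hybridized
arm creates a double-stranded substrate in which a nicking endonuclease cuts
the circle strand; a probe-specific "tag" oligonucleotide is then ligated into
the nick. A sealed circle is amplified by rolling-circle amplification (RCA)
into a concatemer whose tag content records which probes engaged. Padlock
probes are the single-reporter control: a linear oligo whose two termini
hybridize adjacently on an arm and are ligated into a circle that can only
ever carry one tag.

All coordinates are 0-based, half-open. Circle positions are modulo the circle
length with the first base of circle part 1 as origin; nicks are inter-base
positions (a nick at position ``p`` severs the backbone between bases ``p-1``
and ``p``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "End5Mod",
    "OligoRole",
    "Oligo",
    "HybridizationMatch",
    "Circle",
    "Concatemer",
    "NICKASE_MOTIF",
    "NICK_OFFSET",
    "reverse_complement",
    "assemble_circle",
    "find_complement_match",
    "hybridization_footprint",
    "find_nick_sites",
    "nick_circle",
    "incorporate_tags",
    "amplify",
    "circularize_padlock",
    "exonuclease_digest",
    "cognate_tag_of_arm",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Nt.BsmAI-style nickase modeled as pure motif logic: the recognition motif
#: read on the circle strand, with the cut placed ``NICK_OFFSET`` nucleotides
#: 3' of the motif (so the nick lands on the circle, never on the arm).
NICKASE_MOTIF = "GTCTC"
NICK_OFFSET = 1


class End5Mod(str, Enum):
    PHOSPHATE = "phosphate"
    ALDEHYDE = "aldehyde"
    OYO_LINK = "oyo_link"
    FLUOROPHORE = "fluorophore"
    NONE = "none"


class OligoRole(str, Enum):
    CIRCLE_PART = "circle_part"
    ARM = "arm"
    TAG = "tag"
    DETECTION = "detection"
    PADLOCK = "padlock"


#: 5' modifications admissible per role: ligatable species carry a phosphate
#: (or none, in which case ligation operations reject them), arms need a
#: conjugation handle for the antibody.
_ALLOWED_MODS = {
    OligoRole.CIRCLE_PART: {End5Mod.PHOSPHATE, End5Mod.NONE},
    OligoRole.TAG: {End5Mod.PHOSPHATE, End5Mod.NONE},
    OligoRole.PADLOCK: {End5Mod.PHOSPHATE, End5Mod.NONE},
    OligoRole.ARM: {End5Mod.ALDEHYDE, End5Mod.OYO_LINK},
    OligoRole.DETECTION: set(End5Mod),
}


def _validate_dna(seq: str) -> None:
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(f"non-ACGT character {base!r} at position {i}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA string (involution)."""
    _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Oligo:
    """A named DNA oligonucleotide with 5' end modification and assay role.

    ``tail3`` records a non-DNA 3' tail (e.g. the 2'-OMe-U tail of detection
    oligos); hybridization always uses the DNA-equivalent body ``sequence``.
    Fluorophore names and backbone chemistry are metadata only.
    """

    name: str
    sequence: str
    end5_mod: End5Mod = End5Mod.NONE
    role: OligoRole = OligoRole.DETECTION
    tail3: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"oligo {self.name!r} has an empty sequence")
        _validate_dna(self.sequence)
        if self.end5_mod not in _ALLOWED_MODS[self.role]:
            raise ValueError(
                f"oligo {self.name!r}: 5' modification {self.end5_mod.value!r} "
                f"is not admissible for role {self.role.value!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _as_seq(x: "Oligo | str") -> str:
    return x.sequence if isinstance(x, Oligo) else x


@dataclass(frozen=True)
class HybridizationMatch:
    """An exact antiparallel duplex between a query and a target.

    ``query[query_start:query_end]`` equals the reverse complement of
    ``target[target_start:target_end]``; the query's 5'-most matched base
    pairs with the target's 3'-most matched base.
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int

    @property
    def length(self) -> int:
        return self.query_end - self.query_start

    def __bool__(self) -> bool:
        return self.length > 0


_NO_MATCH = HybridizationMatch(0, 0, 0, 0)


def find_complement_match(
    query: "Oligo | str",
    target: "Oligo | str",
    anchor: str = "anywhere",
) -> HybridizationMatch:
    """Longest exact reverse-complement match of ``query`` against ``target``.

    ``anchor`` restricts where the match may sit on the query: ``"terminal5"``
    requires it to include the query's first (5') base, ``"terminal3"`` its
    last (3') base, ``"anywhere"`` imposes no constraint. A zero-length match
    is a valid result, returned when no duplex of length >= 1 exists.
    """
    q, t = _as_seq(query), _as_seq(target)
    if anchor not in ("terminal5", "terminal3", "anywhere"):
        raise ValueError(f"unknown anchor {anchor!r}")
    n = len(q)
    if anchor == "terminal5":
        starts: Sequence[int] = (0,)
    elif anchor == "terminal3":
        starts = range(n)
    else:
        starts = range(n)
    best = _NO_MATCH
    for i in starts:
        max_len = n - i
        if anchor == "terminal3":
            sub_lengths: Iterable[int] = (n - i,)  # must reach the last base
        else:
            sub_lengths = range(max_len, best.length, -1)
        for length in sub_lengths:
            if length <= best.length:
                break
            j = t.find(reverse_complement(q[i : i + length]))
            if j >= 0:
                best = HybridizationMatch(i, i + length, j, j + length)
                break
    return best


@dataclass(frozen=True)
class Circle:
    """A circular single-stranded DNA molecule with nick bookkeeping.

    ``nicks`` maps each open inter-base position to the name of the arm whose
    hybridization templated it (empty string when no arm is responsible).
    ``sealed`` is true iff there are no open nicks; only sealed circles are
    amplifiable and survive exonuclease digestion.
    """

    sequence: str
    nicks: Mapping[int, str] = field(default_factory=dict)
    tags_incorporated: frozenset[str] = frozenset()
    junction: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        _validate_dna(self.sequence)
        for pos in self.nicks:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"nick position {pos} outside circle")

    @property
    def sealed(self) -> bool:
        return not self.nicks

    @property
    def nick_positions(self) -> frozenset[int]:
        return frozenset(self.nicks)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Concatemer:
    """A rolling-circle product: tandem repeats of one circle complement."""

    unit: str
    n_repeats: int

    @property
    def sequence(self) -> str:
        return self.unit * self.n_repeats

    def count(self, subseq: str) -> int:
        """Non-overlapping occurrences of ``subseq`` in the concatemer."""
        return self.sequence.count(subseq)


def assemble_circle(part1: Oligo, part2: Oligo) -> Circle:
    """Ligate two 5'-phosphorylated circle parts into a sealed circle.

    Mirrors the T4-ligase circle assembly; the junction order part1 -> part2
    is recorded. The ligation template is taken as given (the parts' ends are
    trusted, not re-verified against a splint).
    """
    for part in (part1, part2):
        if part.role is not OligoRole.CIRCLE_PART:
            raise ValueError(f"{part.name!r} is not a circle part")
        if part.end5_mod is not End5Mod.PHOSPHATE:
            raise ValueError(f"{part.name!r} lacks a 5'-phosphate: not ligatable")
    return Circle(sequence=part1.sequence + part2.sequence, junction=(part1.name, part2.name))


def exonuclease_digest(species: Iterable[object]) -> list[object]:
    """Simulated exonuclease clean-up: sealed circles survive, linear DNA
    (plain oligos) and open circles are removed."""
    return [s for s in species if isinstance(s, Circle) and s.sealed]


def hybridization_footprint(
    arm: "Oligo | str", circle: Circle, min_match: int = 10
) -> list[tuple[int, int]]:
    """Duplex footprint of an arm on the circle, as merged circle intervals.

    An arm binds the circle in one or more exact complementary stretches
    (the design interleaves circle-binding segments with the tag-complement
    loop), so the footprint is the union of all maximal exact
    reverse-complement matches of length >= ``min_match``, computed on the
    doubled circle sequence to honour origin wrap-around. Intervals are
    half-open ``(start, end)`` with ``end`` possibly exceeding the circle
    length for wrapping segments.
    """
    a = _as_seq(arm)
    n = len(circle.sequence)
    dbl = circle.sequence + circle.sequence
    hits: set[tuple[int, int]] = set()
    for i in range(len(a)):
        for length in range(len(a) - i, min_match - 1, -1):
            sub = reverse_complement(a[i : i + length])
            start = 0
            found = False
            while True:
                j = dbl.find(sub, start)
                if j < 0 or j >= n:
                    break
                found = True
                hits.add((j, j + length))
                start = j + 1
            if found:
                break
    # merge overlapping / contained intervals
    merged: list[tuple[int, int]] = []
    for s, e in sorted(hits):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def find_nick_sites(
    circle: Circle,
    bound_arms: Iterable[Oligo],
    motif: str = NICKASE_MOTIF,
    offset: int = NICK_OFFSET,
    min_match: int = 10,
) -> dict[int, str]:
    """Nick positions created by the nickase, keyed to the generating arm.

    A nick is emitted only where an arm's duplex footprint contains the
    recognition motif read on the circle strand; the cut is placed ``offset``
    nucleotides 3' of the motif, also on the circle strand (the arm is never
    cut). With no bound arms there is no double-stranded substrate and no
    nick. An arm with no footprint contributes no nick (with a warning).
    """
    n = len(circle.sequence)
    dbl = circle.sequence + circle.sequence
    sites: dict[int, str] = {}
    for arm in bound_arms:
        footprint = hybridization_footprint(arm, circle, min_match=min_match)
        if not footprint:
            warnings.warn(
                f"arm {arm.name!r} has no hybridization footprint on the circle",
                stacklevel=2,
            )
            continue
        for s, e in footprint:
            pos = s
            while True:
                k = dbl.find(motif, pos, e)
                if k < 0 or k + len(motif) > e:
                    break
                sites[(k + len(motif) + offset) % n] = arm.name
                pos = k + 1
    return sites


def nick_circle(circle: Circle, bound_arms: Iterable[Oligo], **kwargs) -> Circle:
    """Apply the nickase to a circle with the given hybridized arms."""
    sites = find_nick_sites(circle, bound_arms, **kwargs)
    nicks = dict(circle.nicks)
    nicks.update(sites)
    return replace(circle, nicks=nicks)


def cognate_tag_of_arm(arm: Oligo, tags: Iterable[Oligo]) -> Oligo | None:
    """The tag whose reverse complement is carried in the arm's loop region."""
    for tag in tags:
        if reverse_complement(tag.sequence) in arm.sequence:
            return tag
    return None


def incorporate_tags(
    circle: Circle, bound_arms: Iterable[Oligo], offered_tags: Iterable[Oligo]
) -> Circle:
    """Ligate cognate tags into the nicked circle and seal where possible.

    Each nick was templated by one arm; only that arm's cognate tag (the tag
    whose reverse complement sits in the arm's loop-and-hairpin region) can be
    held in place for ligation. For every nick whose cognate tag is offered,
    the tag sequence is inserted at the nick and the nick sealed. A circle
    left with any open nick is non-amplifiable. The displaced-strand fate of
    the invasion is not modeled beyond this content bookkeeping.
    """
    if circle.sealed:
        raise ValueError("circle has no nick: nothing to incorporate")
    offered = list(offered_tags)
    for tag in offered:
        if tag.end5_mod is not End5Mod.PHOSPHATE:
            raise ValueError(f"tag {tag.name!r} lacks a 5'-phosphate: not ligatable")
    arm_by_name = {arm.name: arm for arm in bound_arms}
    insertions: list[tuple[int, str, str]] = []  # (position, tag seq, tag name)
    remaining: dict[int, str] = {}
    for pos, arm_name in circle.nicks.items():
        arm = arm_by_name.get(arm_name)
        tag = cognate_tag_of_arm(arm, offered) if arm is not None else None
        if tag is None:
            remaining[pos] = arm_name
        else:
            insertions.append((pos, tag.sequence, tag.name))
    seq = circle.sequence
    shifted_remaining = dict(remaining)
    for pos, tag_seq, _ in sorted(insertions, reverse=True):
        seq = seq[:pos] + tag_seq + seq[pos:]
        shifted_remaining = {
            (p + len(tag_seq) if p >= pos else p): a
            for p, a in shifted_remaining.items()
        }
    return replace(
        circle,
        sequence=seq,
        nicks=shifted_remaining,
        tags_incorporated=circle.tags_incorporated
        | frozenset(name for _, _, name in insertions),
    )


def amplify(circle: Circle, n_repeats: int) -> Concatemer:
    """Rolling-circle amplification of a sealed circle.

    The product is ``n_repeats`` tandem copies of the reverse complement of
    the circle read once around from the origin. An open (nicked) circle is
    not amplifiable.
    """
    if not circle.sealed:
        raise ValueError("circle is nicked: not amplifiable")
    if n_repeats < 0:
        raise ValueError("n_repeats must be >= 0")
    return Concatemer(unit=reverse_complement(circle.sequence), n_repeats=n_repeats)


def circularize_padlock(
    padlock: Oligo, arm: "Oligo | str", min_footprint: int = 10
) -> Circle | None:
    """Arm-templated circularization of a padlock probe.

    The padlock's 5'- and 3'-terminal segments hybridize to the arm; ligation
    requires both terminal footprints to be stable duplexes (length >=
    ``min_footprint``) and the arm bases pairing the two terminal padlock
    bases to be immediately adjacent (no gap, no overlap). Returns the sealed
    circle of the padlock's own length, or ``None`` when the ends cannot be
    juxtaposed.
    """
    if padlock.role is not OligoRole.PADLOCK:
        raise ValueError(f"{padlock.name!r} is not a padlock probe")
    if padlock.end5_mod is not End5Mod.PHOSPHATE:
        raise ValueError(f"{padlock.name!r} lacks a 5'-phosphate: not ligatable")
    m5 = find_complement_match(padlock, arm, anchor="terminal5")
    m3 = find_complement_match(padlock, arm, anchor="terminal3")
    if m5.length < min_footprint or m3.length < min_footprint:
        return None
    # Antiparallel pairing: the padlock 5'-terminal base pairs with the arm
    # base at m5.target_end - 1; the 3'-terminal base with the arm base at
    # m3.target_start. Ligatable iff those arm positions are adjacent.
    if m3.target_start != m5.target_end:
        return None
    return Circle(sequence=padlock.sequence, junction=(padlock.name, padlock.name))
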