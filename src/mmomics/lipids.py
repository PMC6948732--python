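"""Lipid shorthand nomenclature parsing and lipid-set construction.

Lipid features come with names in the common shorthand used by MS-DIAL /
LipidBlast and Skyline exports, e.g.::

    PC 34:4                       sum composition: class, carbons:double bonds
    Cer[NS](d18:1/16:0)           per-chain, 'd' marks the sphingoid base
    Cer[NS] 34:1; Cer[NS](d18:1/16:0); [M+H]+     annotated feature name
    Plasmenyl-PE 40:6             vinyl-ether (plasmalogen) -> PE-P
    PC(O-38:6) / PC(P-38:5)       unresolved alkyl-/vinyl-ether alternatives

The parser is strict: a name that does not fit any grammar raises
:class:`LipidNameError` carrying the offending token — never a silent
guess. For enrichment, every parsed species feeds three sets: its class,
its total chain length, and its total unsaturation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["LipidSpecies", "LipidNameError", "FeatureSet",
           "parse_lipid_name", "build_lipid_sets"]


class LipidNameError(ValueError):
    """Raised for a lipid name that fits no supported grammar."""

    def __init__(self, name: str, token: str, why: str = ""):
        self.name = name
        self.token = token
        msg = f"cannot parse lipid name {name!r}: offending token {token!r}"
        if why:
            msg += f" ({why})"
        super().__init__(msg)


@dataclass(frozen=True)
class Chain:
    carbons: int
    double_bonds: int
    sphingoid: bool = False


@dataclass
class LipidSpecies:
    """A parsed lipid identity at sum-composition (and optionally chain) level."""

    raw_name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    chains: list[Chain] | None = None
    ambiguous_alternatives: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_carbons <= 0:
            raise ValueError(f"{self.raw_name!r}: total carbons must be > 0")
        if self.total_double_bonds < 0:
            raise ValueError(f"{self.raw_name!r}: double bonds must be >= 0")
        if self.chains:
            c = sum(ch.carbons for ch in self.chains)
            db = sum(ch.double_bonds for ch in self.chains)
            if (c, db) != (self.total_carbons, self.total_double_bonds):
                raise ValueError(
                    f"{self.raw_name!r}: chain sums {c}:{db} != totals "
                    f"{self.total_carbons}:{self.total_double_bonds}")


_ADDUCT = re.compile(r"^\[M[+-][A-Za-z0-9+-]*\][+-]?$")
_CLASS = re.compile(r"^([A-Za-z][A-Za-z0-9]*(?:-[OP])?)")
_SUBCLASS = re.compile(r"^\[([A-Za-z0-9]+)\]")
_TOTALS = re.compile(r"^(\d+):(\d+)$")
_ETHER = re.compile(r"^\(([OP])-(\d+):(\d+)\)$")
_CHAIN = re.compile(r"^([dt]?)(\d+):(\d+)$")

_LINKAGE_PREFIX = {"plasmenyl": "P", "plasmanyl": "O"}


def _parse_segment(segment: str, full_name: str) -> LipidSpecies:
    """Parse one name segment (no semicolons, no alternatives)."""
    s = segment.strip()
    linkage = None
    low = s.lower()
    for prefix, suffix in _LINKAGE_PREFIX.items():
        if low.startswith(prefix + "-"):
            linkage = suffix
            s = s[len(prefix) + 1:]
            break
    m = _CLASS.match(s)
    if not m:
        raise LipidNameError(full_name, segment, "no class token")
    cls = m.group(1)
    rest = s[m.end():]
    msub = _SUBCLASS.match(rest)
    if msub:
        rest = rest[msub.end():]
    rest = rest.strip()

    mt = _TOTALS.match(rest)
    if mt:
        carbons, db = int(mt.group(1)), int(mt.group(2))
        if linkage:
            cls = f"{cls}-{linkage}"
        return LipidSpecies(full_name, cls, carbons, db)

    me = _ETHER.match(rest)
    if me:
        if linkage:
            raise LipidNameError(full_name, segment,
                                 "linkage prefix combined with O-/P- notation")
        cls = f"{cls}-{me.group(1)}"
        return LipidSpecies(full_name, cls, int(me.group(2)), int(me.group(3)))

    if rest.startswith("(") and rest.endswith(")"):
        chains = []
        for part in rest[1:-1].split("/"):
            mc = _CHAIN.match(part.strip())
            if not mc:
                raise LipidNameError(full_name, part.strip(), "bad chain token")
            chains.append(Chain(int(mc.group(2)), int(mc.group(3)),
                                sphingoid=bool(mc.group(1))))
        carbons = sum(c.carbons for c in chains)
        db = sum(c.double_bonds for c in chains)
        if linkage:
            cls = f"{cls}-{linkage}"
        return LipidSpecies(full_name, cls, carbons, db, chains=chains)

    raise LipidNameError(full_name, rest or segment, "no composition found")


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a lipid shorthand name into a :class:`LipidSpecies`.

    Handles sum-composition names, per-chain names, ``Plasmenyl-``/
    ``Plasmanyl-`` prefixes (mapped to the ``-P``/``-O`` class suffix),
    semicolon-joined annotation variants with adduct suffixes stripped, and
    ``A / B`` unresolved ether alternatives (the O- form, listed first, is
    primary; others go to ``ambiguous_alternatives``).
    """
    if not name or not name.strip():
        raise LipidNameError(name, name, "empty name")

    segments = [seg.strip() for seg in name.split(";") if seg.strip()]
    segments = [seg for seg in segments if not _ADDUCT.match(seg)]
    if not segments:
        raise LipidNameError(name, name, "only adduct tokens present")

    # Unresolved alternatives: "PC(O-38:6) / PC(P-38:5)"
    if " / " in segments[0]:
        parts = [p.strip() for p in segments[0].split(" / ")]
        parsed = [_parse_segment(p, name) for p in parts]
        primary = parsed[0]
        primary.ambiguous_alternatives = [
            (sp.lipid_class, sp.total_carbons, sp.total_double_bonds)
            for sp in parsed[1:]]
        return primary

    parsed = [_parse_segment(seg, name) for seg in segments]
    primary = parsed[0]
    # later variants may refine with chain-level information
    for sp in parsed[1:]:
        if (sp.total_carbons, sp.total_double_bonds) != (
                primary.total_carbons, primary.total_double_bonds):
            raise LipidNameError(name, sp.raw_name,
                                 "inconsistent totals across variants")
        if sp.chains and primary.chains is None:
            primary.chains = sp.chains
    return primary


@dataclass
class FeatureSet:
    """A named set of feature ids (lipid set or pathway gene set)."""

    set_id: str
    kind: str                    # class | chain_length | unsaturation | pathway
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"set {self.set_id!r} has duplicate members")


def build_lipid_sets(species: list[LipidSpecies]) -> list[FeatureSet]:
    """One set per observed class, per total chain length, per unsaturation.

    Every species appears in exactly three sets (one of each kind);
    ambiguous species contribute through their primary identity only.
    """
    by_class: dict[str, list[str]] = {}
    by_length: dict[int, list[str]] = {}
    by_unsat: dict[int, list[str]] = {}
    for sp in species:
        by_class.setdefault(sp.lipid_class, []).append(sp.raw_name)
        by_length.setdefault(sp.total_carbons, []).append(sp.raw_name)
        by_unsat.setdefault(sp.total_double_bonds, []).append(sp.raw_name)
    sets = [FeatureSet(f"class:{c}", "class", mem) for c, mem in sorted(by_class.items())]
    sets += [FeatureSet(f"length:{n}", "chain_length", mem)
             for n, mem in sorted(by_length.items())]
    sets += [FeatureSet(f"unsat:{n}", "unsaturation", mem)
             for n, mem in sorted(by_unsat.items())]
    return sets
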