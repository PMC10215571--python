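"""MedDRA preferred terms and named ADR query sets.

Reactions in spontaneous-report databases are coded at the MedDRA
preferred-term (PT) level.  Public portals print PT labels with
inconsistent capitalisation ("Drug resistance" vs "drug resistance"),
so PT identity here is case-insensitive and whitespace-normalised.
No MedDRA hierarchy is modelled: PTs are flat strings, and a query set
(:class:`AdrCategory`) is simply a named set of PTs, optionally with
spelling aliases that map onto a canonical member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


def normalize_pt(label: str) -> str:
    """Normalise a PT label for comparison: trim, collapse internal
    whitespace, lowercase.

    Raises ``ValueError`` on labels that are empty after trimming.
    """
    key = " ".join(str(label).split()).lower()
    if not key:
        raise ValueError("preferred term label is empty after trimming")
    return key


@dataclass(frozen=True)
class PreferredTerm:
    """A MedDRA preferred term.

    Equality and hashing use the normalised form, so
    ``PreferredTerm("Drug Ineffective") == PreferredTerm("drug ineffective")``.
    The original label is preserved for display and serialisation.
    """

    label: str

    def __post_init__(self) -> None:
        # raises on empty labels
        normalize_pt(self.label)

    @property
    def key(self) -> str:
        return normalize_pt(self.label)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, PreferredTerm):
            return self.key == other.key
        if isinstance(other, str):
            return self.key == normalize_pt(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.key)

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class AdrCategory:
    """A named set of preferred terms defining one ADR category.

    ``aliases`` maps alternative spellings (normalised) to the canonical
    member label they stand for; a report using either spelling counts
    toward the same member.
    """

    name: str
    members: frozenset[PreferredTerm]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"category {self.name!r} has no members")
        keys = [m.key for m in self.members]
        if len(keys) != len(set(keys)):
            raise ValueError(f"category {self.name!r} has duplicate members")
        for alias, target in self.aliases.items():
            if normalize_pt(target) not in set(keys):
                raise ValueError(
                    f"alias {alias!r} maps to {target!r}, not a member of {self.name!r}"
                )

    @classmethod
    def from_labels(
        cls,
        name: str,
        labels: Iterable[str],
        aliases: Mapping[str, str] | None = None,
    ) -> "AdrCategory":
        members = frozenset(PreferredTerm(lbl) for lbl in labels)
        norm_aliases = {
            normalize_pt(a): t for a, t in (aliases or {}).items()
        }
        return cls(name=name, members=members, aliases=norm_aliases)

    @property
    def member_keys(self) -> frozenset[str]:
        """Normalised keys that count as membership (members + aliases)."""
        return frozenset(m.key for m in self.members) | frozenset(self.aliases)

    def canonical_label(self, label: str) -> str | None:
        """Return the canonical member label matching ``label``, or None."""
        key = normalize_pt(label)
        if key in self.aliases:
            key = normalize_pt(self.aliases[key])
        for m in self.members:
            if m.key == key:
                return m.label
        return None

    def __contains__(self, label: object) -> bool:
        try:
            key = normalize_pt(str(label))
        except ValueError:
            return False
        return key in self.member_keys


# The two query sets used for antimicrobial-resistance surveillance in
# EudraVigilance-style analyses: three PTs flag suspected drug resistance
# (DR) and nine flag drug ineffectiveness (DI).
DR_TERMS = (
    "drug resistance",
    "multiple-drug resistance",
    "pathogen resistance",
)

DI_TERMS = (
    "therapeutic product effect decreased",
    "therapeutic product effect incomplete",
    "decreased activity",
    "drug ineffective for unapproved indication",
    "therapeutic product ineffective",
    "therapeutic response decreased",
    "treatment failure",
    "therapy non-responder",
    "drug ineffective",
)

# "multi-drug resistance" appears in the wild as an alternative spelling
# of the same PT.
_DR_ALIASES = {"multi-drug resistance": "multiple-drug resistance"}


def builtin_categories() -> list[AdrCategory]:
    """The built-in DR (3 PTs) and DI (9 PTs) ADR categories."""
    dr = AdrCategory.from_labels("DR", DR_TERMS, aliases=_DR_ALIASES)
    di = AdrCategory.from_labels("DI", DI_TERMS)
    return [dr, di]
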