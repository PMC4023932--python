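"""Morph taxonomy registry for *Papilio dardanus*.

Female *P. dardanus* come in many discrete mimetic wing-pattern forms
("morphs", conventionally written f. *name*), classically organised into
groups of similar-looking forms; subspecies are geographic populations
defined chiefly by male pattern, each harbouring a characteristic subset of
female morphs.  The registry holds three look-ups:

* ``morph_to_group`` — morph name → morph group.  The grouping follows the
  classical similarity classes (the hippocoon, cenea, trophonius,
  planemoides, niobe, natalica, dionysos, poultoni, trimeni and lamborni
  groups, plus the male-like non-mimetic forms), with f. *leighi* placed in
  the *planemoides* group on the evidence of breeding work, and the rare
  Ethiopian tailed variants filed with their tail-less counterparts
  (ruspinae→trophonius, weinholti→poultoni, niavoides→hippocoon group,
  vaccaroi→cenea).
* ``subspecies_to_morphs`` — subspecies → recorded female morphs (the
  mainland/island subspecies recognised by all authors; *byatti* is known
  only from male-like material and carries an empty list).
* ``imperfect_morphs`` — the forms counted as "imperfect" mimics: mixed or
  inaccurate patterns concentrated where the Eastern and Western lineages
  meet, plus the label ``intermediate`` used for specimens that cannot be
  assigned to a single group.

All keys are stored normalised (lower case, "f." prefix stripped); every
accessor normalises its argument the same way.  The default tables are
plain data and can be overridden wholesale for other taxonomies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["MorphRegistry", "default_registry", "normalise_morph", "is_imperfect"]

_F_PREFIX = re.compile(r"^f\.?\s+", flags=re.IGNORECASE)


def normalise_morph(name: str) -> str:
    """Canonical form of a morph/subspecies label.

    Lower-cases, strips the conventional "f." prefix, asterisks and stray
    punctuation, and collapses internal whitespace: ``"f. Trimeni "`` →
    ``"trimeni"``.
    """
    s = name.strip().strip("*").strip()
    s = _F_PREFIX.sub("", s)
    s = s.strip(" .,;:").lower()
    s = re.sub(r"\s+", " ", s)
    return s


# Morph groups: the classical similarity classes of the female forms.
_GROUPS: dict[str, list[str]] = {
    "male-like": ["antinorii", "meriones", "humbloti", "flavicornis", "atavica", "ochracea"],
    "hippocoon": ["hippocoon", "hippocoonides", "meseres", "niavoides"],
    "cenea": ["cenea", "salaami", "vaccaroi", "proto-cenea"],
    "trophonius": ["trophonius", "ruspinae", "dorrippoides"],
    "planemoides": ["planemoides", "leighi"],
    "niobe": ["niobe", "niobioides"],
    "natalica": ["natalica"],
    "dionysos": ["dionysos", "dionysoides"],
    "poultoni": ["poultoni", "weinholti", "swynnertoni", "carpenteri"],
    "trimeni": ["trimeni"],
    "lamborni": ["lamborni", "mixtoides"],
    "intermediate": ["intermediate"],
}

# Subspecies → female morphs recorded in that subspecies ("byatti" is known
# only from male-like females, hence the empty list).
_SUBSPECIES_MORPHS: dict[str, list[str]] = {
    "dardanus": ["hippocoon", "dionysos", "planemoides", "trophonius", "cenea",
                 "niobe", "lamborni", "niobioides", "natalica", "mixtoides"],
    "tibullus": ["cenea", "trophonius", "hippocoonides", "salaami", "natalica",
                 "trimeni", "poultoni", "lamborni", "mixtoides"],
    "cenea": ["cenea", "leighi", "trophonius", "hippocoonides", "salaami", "natalica"],
    "ochraceana": ["ochracea"],
    "flavicornis": ["flavicornis", "atavica"],
    "antinorii": ["antinorii", "niavoides", "ruspinae", "weinholti", "vaccaroi"],
    "meriones": ["meriones"],
    "humbloti": ["humbloti"],
    "meseres": ["hippocoonides", "cenea", "meseres", "lamborni", "planemoides",
                "salaami", "trimeni", "mixtoides"],
    "polytrophus": ["hippocoonides", "cenea", "meseres", "poultoni", "lamborni",
                    "planemoides", "trimeni", "swynnertoni", "carpenteri", "mixtoides"],
    "byatti": [],
}

_SUBSPECIES_CLADE: dict[str, str] = {
    "dardanus": "Western",
    "ochraceana": "Western",
    "tibullus": "Eastern",
    "cenea": "Eastern",
    "flavicornis": "Eastern",
    "antinorii": "Eastern",
    "meseres": "Eastern",
    "polytrophus": "Eastern",
    "byatti": "Eastern",
    "meriones": "IndianOcean",
    "humbloti": "IndianOcean",
}

# Imperfect mimics: mixed/inaccurate female patterns, plus "intermediate"
# specimens showing attributes of more than one morph group.
_IMPERFECT: frozenset[str] = frozenset(
    {
        "trimeni",
        "dorrippoides",
        "dionysoides",
        "proto-cenea",
        "mixtoides",
        "swynnertoni",
        "carpenteri",
        "lamborni",
        "intermediate",
    }
)


@dataclass(frozen=True)
class MorphRegistry:
    morph_to_group: dict[str, str]
    subspecies_to_morphs: dict[str, list[str]]
    subspecies_to_clade: dict[str, str]
    imperfect_morphs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for ssp, morphs in self.subspecies_to_morphs.items():
            for m in morphs:
                if m not in self.morph_to_group:
                    raise ValueError(
                        f"morph {m!r} of subspecies {ssp!r} has no morph group"
                    )

    def group_of(self, morph: str) -> str:
        """Morph group for a morph label, or '' if unknown."""
        return self.morph_to_group.get(normalise_morph(morph), "")

    def is_imperfect(self, morph: str) -> bool:
        """True iff the (normalised) morph counts as an imperfect mimic."""
        return normalise_morph(morph) in self.imperfect_morphs

    def morphs_for_subspecies(self, subspecies: str) -> list[str]:
        key = normalise_morph(subspecies)
        if key not in self.subspecies_to_morphs:
            raise KeyError(
                f"unknown subspecies {subspecies!r}; valid: "
                f"{sorted(self.subspecies_to_morphs)}"
            )
        return list(self.subspecies_to_morphs[key])

    def clade_of(self, subspecies: str) -> str:
        return self.subspecies_to_clade.get(normalise_morph(subspecies), "unassigned")


def default_registry() -> MorphRegistry:
    """The built-in *P. dardanus* registry."""
    morph_to_group = {
        normalise_morph(m): g for g, morphs in _GROUPS.items() for m in morphs
    }
    return MorphRegistry(
        morph_to_group=morph_to_group,
        subspecies_to_morphs={k: list(v) for k, v in _SUBSPECIES_MORPHS.items()},
        subspecies_to_clade=dict(_SUBSPECIES_CLADE),
        imperfect_morphs=_IMPERFECT,
    )


def is_imperfect(morph: str, registry: MorphRegistry | None = None) -> bool:
    """Module-level convenience wrapper around :meth:`MorphRegistry.is_imperfect`."""
    return (registry or default_registry()).is_imperfect(morph)
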