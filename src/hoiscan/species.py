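"""Species and treatment vocabulary for the protist microcosm design.

The experimental system is a five-species ciliate food web: two focal
competitors (*Colpidium*, *Dexiostoma*), two alternative third competitors
(*Paramecium*, *Spirostomum*) and one top predator (*Spathidium*).
Communities are labelled by the one-letter codes of the species they
contain, e.g. ``CDS`` = Colpidium + Dexiostoma + Spirostomum and
``CDSPd`` the same community with the predator added.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Species(str, enum.Enum):
    """One-letter species codes of the five-species food web."""

    C = "C"
    D = "D"
    P = "P"
    S = "S"
    Pd = "Pd"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @property
    def is_predator(self) -> bool:
        return self is Species.Pd

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_DISPLAY_NAMES = {
    Species.C: "Colpidium",
    Species.D: "Dexiostoma",
    Species.P: "Paramecium",
    Species.S: "Spirostomum",
    Species.Pd: "Spathidium",
}

#: Canonical ordering used everywhere a deterministic species order is
#: needed (design-matrix columns, CSV row order): focal pair first, then
#: the third competitor, predator last.
SPECIES_ORDER = [Species.C, Species.D, Species.P, Species.S, Species.Pd]

#: The two focal competitors whose mutual interaction is under study.
FOCAL_PAIR = (Species.C, Species.D)


def species_sort_key(sp: Species) -> int:
    return SPECIES_ORDER.index(sp)


def parse_community_code(code: str) -> frozenset[Species]:
    """Parse a concatenation of species codes ('CDPPd' -> {C, D, P, Pd})."""
    members: set[Species] = set()
    i = 0
    while i < len(code):
        if code[i : i + 2] == "Pd":
            token, i = "Pd", i + 2
        else:
            token, i = code[i], i + 1
        try:
            sp = Species(token)
        except ValueError:
            raise ValueError(f"community code {code!r}: unknown species token {token!r}")
        if sp in members:
            raise ValueError(f"community code {code!r}: species {token!r} repeated")
        members.add(sp)
    if not members:
        raise ValueError("empty community code")
    return frozenset(members)


@dataclass(frozen=True)
class Treatment:
    """A community composition, identified by its concatenated species codes.

    The six experimental treatments (CD, CDP, CDS and their predator
    counterparts) are canonical, but any concatenation of known species
    codes is accepted so reduced communities (e.g. monocultures in
    simulation tests) can be represented.
    """

    code: str

    def __post_init__(self) -> None:
        parse_community_code(self.code)  # raises on malformed codes

    @property
    def species_set(self) -> frozenset[Species]:
        return parse_community_code(self.code)

    @property
    def is_design_treatment(self) -> bool:
        return self.code in TREATMENT_SPECIES

    @property
    def species(self) -> list[Species]:
        """Members in canonical order."""
        return sorted(self.species_set, key=species_sort_key)

    @property
    def predator_present(self) -> bool:
        return Species.Pd in self.species_set

    @property
    def consumers(self) -> list[Species]:
        """Non-predator members in canonical order."""
        return [sp for sp in self.species if not sp.is_predator]

    @property
    def competition_code(self) -> str:
        """The predator-free community underlying this treatment."""
        return "".join(sp.value for sp in self.consumers)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


TREATMENT_SPECIES: dict[str, frozenset[Species]] = {
    "CD": frozenset({Species.C, Species.D}),
    "CDP": frozenset({Species.C, Species.D, Species.P}),
    "CDS": frozenset({Species.C, Species.D, Species.S}),
    "CDPd": frozenset({Species.C, Species.D, Species.Pd}),
    "CDPPd": frozenset({Species.C, Species.D, Species.P, Species.Pd}),
    "CDSPd": frozenset({Species.C, Species.D, Species.S, Species.Pd}),
}

#: All six treatment codes in canonical order: predator-free first.
TREATMENT_ORDER = ["CD", "CDP", "CDS", "CDPd", "CDPPd", "CDSPd"]

ALL_TREATMENTS = [Treatment(code) for code in TREATMENT_ORDER]
COMPETITION_TREATMENTS = [t for t in ALL_TREATMENTS if not t.predator_present]
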