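"""White-matter tract registry.

The analyses in this package operate over a fixed inventory of 50 named
white-matter bundles: 21 bilateral left/right pairs, seven corpus-callosum
segments and the middle cerebellar peduncle.  The inventory matches the
bundle nomenclature of neural-network tractography segmentation tools
(arcuate fascicle, superior longitudinal fascicle I-III, thalamo- and
striato-cortical projections, ...), which produce one binary mask per
bundle per subject.

A :class:`TractRegistry` carries laterality metadata (hemisphere, fibre
family, contralateral homologue) so reports can summarise left/right
asymmetry, and acts as the schema against which metric tables are
validated.  Custom registries can be loaded from JSON for non-default
segmentations.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "Hemisphere",
    "Family",
    "TractDescriptor",
    "TractRegistry",
    "default_tract_registry",
    "load_registry",
    "normalize_tract_name",
    "UnknownTractError",
]


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    COMMISSURAL = "commissural"


class Family(str, Enum):
    ASSOCIATION = "association"
    COMMISSURAL = "commissural"
    PROJECTION = "projection"
    CEREBELLAR = "cerebellar"


class UnknownTractError(KeyError):
    """Raised when a tract name does not resolve in the registry."""


# Unicode hyphen variants that appear in typeset bundle names.
_HYPHENS = re.compile("[‐‑‒–—]")
_WS = re.compile(r"\s+")


def normalize_tract_name(name: str) -> str:
    """Canonicalise a bundle name for lookup.

    Collapses whitespace, maps typographic hyphens to ASCII, lowercases,
    and expands the abbreviated corpus-callosum segment ("post. midbody").
    """
    s = _HYPHENS.sub("-", str(name)).strip()
    s = _WS.sub(" ", s).lower()
    s = s.replace("post. midbody", "posterior midbody")
    return s


@dataclass(frozen=True)
class TractDescriptor:
    """One named bundle with laterality metadata.

    ``homologue`` is the contralateral partner for left/right tracts and
    ``None`` for commissural structures.
    """

    name: str
    hemisphere: Hemisphere
    family: Family
    homologue: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.hemisphere is Hemisphere.COMMISSURAL) != (self.homologue is None):
            raise ValueError(
                f"tract {self.name!r}: commissural tracts must have no homologue "
                "and lateralised tracts must have one"
            )


class TractRegistry:
    """Ordered, name-indexed collection of :class:`TractDescriptor`."""

    def __init__(self, descriptors: Iterable[TractDescriptor]):
        self._tracts: list[TractDescriptor] = list(descriptors)
        self._index: dict[str, TractDescriptor] = {}
        for d in self._tracts:
            key = normalize_tract_name(d.name)
            if key in self._index:
                raise ValueError(f"duplicate tract name {d.name!r}")
            self._index[key] = d
        self._check_homologues()

    def _check_homologues(self) -> None:
        for d in self._tracts:
            if d.homologue is None:
                continue
            try:
                partner = self.lookup(d.homologue)
            except UnknownTractError:
                raise ValueError(
                    f"tract {d.name!r}: homologue {d.homologue!r} not in registry"
                ) from None
            opposite = (
                Hemisphere.RIGHT if d.hemisphere is Hemisphere.LEFT else Hemisphere.LEFT
            )
            if partner.hemisphere is not opposite or partner.homologue != d.name:
                raise ValueError(
                    f"homologue map not an involution at {d.name!r} / {partner.name!r}"
                )

    def __len__(self) -> int:
        return len(self._tracts)

    def __iter__(self) -> Iterator[TractDescriptor]:
        return iter(self._tracts)

    def __contains__(self, name: str) -> bool:
        return normalize_tract_name(name) in self._index

    @property
    def names(self) -> list[str]:
        return [d.name for d in self._tracts]

    def lookup(self, name: str) -> TractDescriptor:
        try:
            return self._index[normalize_tract_name(name)]
        except KeyError:
            raise UnknownTractError(name) from None

    def resolve(self, name: str) -> str:
        """Canonical registry spelling of ``name``."""
        return self.lookup(name).name

    def by_hemisphere(self, hemisphere: Hemisphere) -> list[TractDescriptor]:
        return [d for d in self._tracts if d.hemisphere is hemisphere]

    # -- serialisation --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": d.name,
                "hemisphere": d.hemisphere.value,
                "family": d.family.value,
                "homologue": d.homologue,
            }
            for d in self._tracts
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TractRegistry":
        payload = json.loads(Path(path).read_text())
        return cls(
            TractDescriptor(
                name=e["name"],
                hemisphere=Hemisphere(e["hemisphere"]),
                family=Family(e["family"]),
                homologue=e.get("homologue"),
            )
            for e in payload
        )


# 21 bilateral families; each yields "<name> left" and "<name> right".
_BILATERAL: list[tuple[str, Family]] = [
    ("Anterior thalamic radiation", Family.PROJECTION),
    ("Arcuate fascicle", Family.ASSOCIATION),
    ("Cingulum", Family.ASSOCIATION),
    ("Corticospinal tract", Family.PROJECTION),
    ("Fronto-pontine tract", Family.PROJECTION),
    ("Inferior cerebellar peduncle", Family.CEREBELLAR),
    ("Inferior longitudinal fascicle", Family.ASSOCIATION),
    ("Inferior occipito-frontal fascicle", Family.ASSOCIATION),
    ("Optic radiation", Family.PROJECTION),
    ("Parieto-occipital pontine", Family.PROJECTION),
    ("Striato-fronto-orbital", Family.PROJECTION),
    ("Striato-premotor", Family.PROJECTION),
    ("Superior cerebellar peduncle", Family.CEREBELLAR),
    ("Superior longitudinal fascicle I", Family.ASSOCIATION),
    ("Superior longitudinal fascicle II", Family.ASSOCIATION),
    ("Superior longitudinal fascicle III", Family.ASSOCIATION),
    ("Superior thalamic radiation", Family.PROJECTION),
    ("Thalamo-occipital", Family.PROJECTION),
    ("Thalamo-parietal", Family.PROJECTION),
    ("Thalamo-premotor", Family.PROJECTION),
    ("Uncinate fascicle", Family.ASSOCIATION),
]

_CC_SEGMENTS = [
    "rostrum",
    "genu",
    "rostral body",
    "anterior midbody",
    "posterior midbody",
    "isthmus",
    "splenium",
]


def default_tract_registry() -> TractRegistry:
    """The default 50-bundle registry.

    21 bilateral pairs (42 tracts), the seven corpus-callosum segments and
    the middle cerebellar peduncle.  Commissural structures carry no
    homologue; every lateralised tract's homologue map is an involution.
    """
    descriptors: list[TractDescriptor] = []
    for base, family in _BILATERAL:
        descriptors.append(
            TractDescriptor(f"{base} left", Hemisphere.LEFT, family, f"{base} right")
        )
        descriptors.append(
            TractDescriptor(f"{base} right", Hemisphere.RIGHT, family, f"{base} left")
        )
    for seg in _CC_SEGMENTS:
        descriptors.append(
            TractDescriptor(
                f"Corpus callosum: {seg}", Hemisphere.COMMISSURAL, Family.COMMISSURAL
            )
        )
    descriptors.append(
        TractDescriptor(
            "Middle cerebellar peduncle", Hemisphere.COMMISSURAL, Family.CEREBELLAR
        )
    )
    return TractRegistry(descriptors)


def load_registry(spec: str | Path | None) -> TractRegistry:
    """Load a registry: ``None`` or ``"default"`` gives the built-in one."""
    if spec is None or spec == "default":
        return default_tract_registry()
    return TractRegistry.from_json(spec)
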