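"""Anatomical vocabulary for traumatic axonal injury (TAI) lesion annotations.

A lesion observation is a :class:`LesionSite`: a brain region, an optional
subregion, a laterality, and the MRI sequence family on which the lesion was
seen.  A patient's full set of observations is a :class:`LesionMap`.  TAI is
recorded as present/absent only -- no volumes, no signal intensities.

Sequence families
-----------------
``dwi``
    Diffusion-weighted imaging; acute non-hemorrhagic TAI show restricted
    diffusion.
``flair``
    T2-weighted fluid-attenuated inversion recovery; non-hemorrhagic TAI
    appear hyperintense.
``susceptibility``
    The susceptibility-sensitive family: SWI, with T2*-weighted gradient
    echo as its historical equivalent.  Hemorrhagic TAI appear hypointense.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

REGIONS: tuple[str, ...] = (
    "basal_ganglia",
    "corpus_callosum",
    "internal_capsule_plic",
    "midbrain",
    "pons",
    "subcortical",
    "thalamus",
)

#: Subregions recognised per region.  ``unspecified`` means the annotation
#: does not localise the lesion further within the region.
SUBREGIONS: Mapping[str, tuple[str, ...]] = {
    "basal_ganglia": ("unspecified",),
    "corpus_callosum": ("trunk", "splenium", "genu_rostrum"),
    "internal_capsule_plic": ("unspecified",),
    "midbrain": ("tegmentum", "tectum", "cerebral_peduncles", "unspecified"),
    "pons": ("ventral", "dorsal", "unspecified"),
    "subcortical": ("unspecified",),
    "thalamus": ("unspecified",),
}

SEQUENCES: tuple[str, ...] = ("dwi", "flair", "susceptibility")
LATERALITIES: tuple[str, ...] = ("unilateral", "bilateral", "not_applicable")

#: Supratentorial regions (everything above the tentorium); the complement
#: within our vocabulary is the brainstem.
SUPRATENTORIAL: frozenset[str] = frozenset(
    {"basal_ganglia", "corpus_callosum", "internal_capsule_plic", "subcortical", "thalamus"}
)
BRAINSTEM: frozenset[str] = frozenset({"midbrain", "pons"})

#: Hemispheric regions in the sense of the Adams and Abu Hamdeh grade-I
#: rules: lobar/subcortical white matter plus the deep grey structures.
HEMISPHERIC: frozenset[str] = frozenset(
    {"subcortical", "basal_ganglia", "internal_capsule_plic", "thalamus"}
)


@dataclass(frozen=True, order=True)
class LesionSite:
    """One binary TAI observation: (region, subregion, laterality, sequence).

    The corpus callosum is a midline structure, so its laterality is always
    ``not_applicable``; every other region is annotated unilateral or
    bilateral.
    """

    region: str
    subregion: str
    laterality: str
    sequence: str

    def __post_init__(self) -> None:
        if self.region not in SUBREGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.subregion not in SUBREGIONS[self.region]:
            raise ValueError(
                f"subregion {self.subregion!r} not valid for region {self.region!r}"
            )
        if self.sequence not in SEQUENCES:
            raise ValueError(f"unknown sequence family {self.sequence!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.region == "corpus_callosum":
            if self.laterality != "not_applicable":
                raise ValueError("corpus callosum sites are midline: laterality must be not_applicable")
        elif self.laterality == "not_applicable":
            raise ValueError(f"laterality required for region {self.region!r}")

    @property
    def column(self) -> str:
        """Canonical flat-file column name for this site."""
        return f"{self.region}_{self.subregion}_{self.laterality}_{self.sequence}"


def _build_catalog() -> tuple[LesionSite, ...]:
    sites = []
    for region in REGIONS:
        for subregion in SUBREGIONS[region]:
            lats = ("not_applicable",) if region == "corpus_callosum" else ("unilateral", "bilateral")
            for lat in lats:
                for seq in SEQUENCES:
                    sites.append(LesionSite(region, subregion, lat, seq))
    return tuple(sites)


#: Every valid LesionSite, in canonical order (75 sites).
SITE_CATALOG: tuple[LesionSite, ...] = _build_catalog()
SITE_COLUMNS: tuple[str, ...] = tuple(s.column for s in SITE_CATALOG)
COLUMN_TO_SITE: Mapping[str, LesionSite] = {s.column: s for s in SITE_CATALOG}


class LesionMap:
    """An immutable set of :class:`LesionSite` observations for one patient."""

    __slots__ = ("sites",)

    def __init__(self, sites: Iterable[LesionSite] = ()) -> None:
        sites = frozenset(sites)
        for s in sites:
            if not isinstance(s, LesionSite):
                raise TypeError(f"expected LesionSite, got {type(s).__name__}")
        object.__setattr__(self, "sites", sites)

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("LesionMap is immutable")

    def __iter__(self) -> Iterator[LesionSite]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, site: LesionSite) -> bool:
        return site in self.sites

    def __eq__(self, other) -> bool:
        return isinstance(other, LesionMap) and self.sites == other.sites

    def __hash__(self) -> int:
        return hash(self.sites)

    def __le__(self, other: "LesionMap") -> bool:
        return self.sites <= other.sites

    def __or__(self, other: "LesionMap") -> "LesionMap":
        return LesionMap(self.sites | other.sites)

    def __repr__(self) -> str:
        cols = ", ".join(sorted(s.column for s in self.sites))
        return f"LesionMap({{{cols}}})"

    def match(
        self,
        region: str | None = None,
        subregion: str | None = None,
        laterality: str | None = None,
        sequence: str | None = None,
    ) -> frozenset[LesionSite]:
        """Sites matching every given criterion (``None`` = any)."""
        return frozenset(
            s
            for s in self.sites
            if (region is None or s.region == region)
            and (subregion is None or s.subregion == subregion)
            and (laterality is None or s.laterality == laterality)
            and (sequence is None or s.sequence == sequence)
        )

    def match_regions(self, regions: Iterable[str], **kwargs) -> frozenset[LesionSite]:
        out: frozenset[LesionSite] = frozenset()
        for r in regions:
            out |= self.match(region=r, **kwargs)
        return out

    def to_columns(self) -> dict[str, int]:
        """0/1 indicator per catalog column (flat-file representation)."""
        present = {s.column for s in self.sites}
        return {c: int(c in present) for c in SITE_COLUMNS}

    @classmethod
    def from_columns(cls, row: Mapping[str, object]) -> "LesionMap":
        sites = []
        for col, site in COLUMN_TO_SITE.items():
            v = row.get(col, 0)
            try:
                flag = int(v)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"lesion column {col!r} must be 0/1, got {v!r}") from exc
            if flag not in (0, 1):
                raise ValueError(f"lesion column {col!r} must be 0/1, got {v!r}")
            if flag:
                sites.append(site)
        return cls(sites)


EMPTY_MAP = LesionMap()


# ---------------------------------------------------------------------------
# Lesion types: the row set of the severity table.  Each entry maps a
# human-readable label to match criteria over LesionSite fields.  The types
# deliberately overlap for the midbrain and pons (a tegmental lesion is also
# counted in the unilateral/bilateral rows), mirroring how severity is
# conventionally tabulated per anatomical compartment.
# ---------------------------------------------------------------------------

LESION_TYPES: tuple[tuple[str, dict], ...] = (
    ("basal_ganglia_unilateral", dict(region="basal_ganglia", laterality="unilateral")),
    ("basal_ganglia_bilateral", dict(region="basal_ganglia", laterality="bilateral")),
    ("corpus_callosum_trunk", dict(region="corpus_callosum", subregion="trunk")),
    ("corpus_callosum_splenium", dict(region="corpus_callosum", subregion="splenium")),
    ("corpus_callosum_genu_rostrum", dict(region="corpus_callosum", subregion="genu_rostrum")),
    ("internal_capsule_plic_unilateral", dict(region="internal_capsule_plic", laterality="unilateral")),
    ("internal_capsule_plic_bilateral", dict(region="internal_capsule_plic", laterality="bilateral")),
    ("midbrain_unilateral", dict(region="midbrain", laterality="unilateral")),
    ("midbrain_tegmentum", dict(region="midbrain", subregion="tegmentum")),
    ("midbrain_tectum", dict(region="midbrain", subregion="tectum")),
    ("midbrain_cerebral_peduncles", dict(region="midbrain", subregion="cerebral_peduncles")),
    ("midbrain_bilateral", dict(region="midbrain", laterality="bilateral")),
    ("pons_ventral", dict(region="pons", subregion="ventral")),
    ("pons_unilateral", dict(region="pons", laterality="unilateral")),
    ("pons_dorsal", dict(region="pons", subregion="dorsal")),
    ("pons_bilateral", dict(region="pons", laterality="bilateral")),
    ("subcortical_unilateral", dict(region="subcortical", laterality="unilateral")),
    ("subcortical_bilateral", dict(region="subcortical", laterality="bilateral")),
    ("thalamus_unilateral", dict(region="thalamus", laterality="unilateral")),
    ("thalamus_bilateral", dict(region="thalamus", laterality="bilateral")),
)

LESION_TYPE_NAMES: tuple[str, ...] = tuple(name for name, _ in LESION_TYPES)


def has_lesion_type(lesions: LesionMap, type_name: str, sequence: str | None = None) -> bool:
    """Whether the map contains a lesion of the named type.

    ``sequence`` restricts the check to one sequence family; ``None`` accepts
    any family.
    """
    for name, crit in LESION_TYPES:
        if name == type_name:
            return bool(lesions.match(sequence=sequence, **crit))
    raise KeyError(f"unknown lesion type {type_name!r}")
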