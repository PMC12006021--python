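"""Lineage-level aggregation of off-target hits.

Covers the three standard rollups: species overlap between biomes
(three-set Venn), per-target phylum composition, and the pathogenic /
non-pathogenic / NA partition against a curated pathogen catalog.

Two counting units coexist deliberately: species-level tables
deduplicate to unique species, while phylum composition counts hit
proteins.  GTDB and NCBI phylum synonyms (e.g. Firmicutes/Bacillota)
are NOT merged by default; an optional synonym map is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import BIOMES, PathogenCatalog, normalize_species
from .screen import OffTargetHit

__all__ = [
    "SpeciesSetSummary",
    "species_overlap",
    "phylum_composition",
    "classify_pathogenicity",
    "VENN_REGIONS",
    "PHYLUM_SYNONYMS",
]

VENN_REGIONS = (
    "gut_only",
    "oral_only",
    "vaginal_only",
    "gut_oral",
    "gut_vaginal",
    "oral_vaginal",
    "all_three",
)

# GTDB <-> NCBI phylum renames seen in MAG catalogues; off by default.
PHYLUM_SYNONYMS: Mapping[str, str] = {
    "Bacillota": "Firmicutes",
    "Firmicutes_A": "Firmicutes",
    "Actinomycetota": "Actinobacteriota",
    "Pseudomonadota": "Proteobacteria",
    "Bacteroidetes": "Bacteroidota",
}


@dataclass(frozen=True)
class SpeciesSetSummary:
    """Per-biome species sets with the 7 exclusive Venn region counts."""

    species_by_biome: dict[str, frozenset[str]]
    venn: dict[str, int]
    na_counts: dict[str, int]  # hits without a species rank, per biome

    def __post_init__(self) -> None:
        union = frozenset().union(*self.species_by_biome.values())
        if sum(self.venn.values()) != len(union):
            raise AssertionError("Venn regions do not sum to the union size")


def species_overlap(hits: Iterable[OffTargetHit]) -> SpeciesSetSummary:
    """Deduplicated species per biome and all 7 exclusive Venn regions.

    Species are normalized before comparison; hits from MAGs without an
    s__ rank are excluded from the overlap but tallied in
    ``na_counts`` (unique MAGs per biome).
    """
    sets: dict[str, set[str]] = {b: set() for b in BIOMES}
    na_mags: dict[str, set[str]] = {b: set() for b in BIOMES}
    for h in hits:
        if h.species:
            sets[h.biome].add(normalize_species(h.species))
        else:
            na_mags[h.biome].add(h.mag_id or h.protein_id)
    g, o, v = sets["gut"], sets["oral"], sets["vaginal"]
    venn = {
        "gut_only": len(g - o - v),
        "oral_only": len(o - g - v),
        "vaginal_only": len(v - g - o),
        "gut_oral": len((g & o) - v),
        "gut_vaginal": len((g & v) - o),
        "oral_vaginal": len((o & v) - g),
        "all_three": len(g & o & v),
    }
    return SpeciesSetSummary(
        species_by_biome={b: frozenset(sets[b]) for b in BIOMES},
        venn=venn,
        na_counts={b: len(na_mags[b]) for b in BIOMES},
    )


def phylum_composition(
    hits: Iterable[OffTargetHit],
    merge_synonyms: bool = False,
) -> pd.DataFrame:
    """Hit-protein counts per target per phylum, with per-target totals.

    Missing phyla land in an "NA" bucket.  Returns a tidy table with
    columns target_id, phylum, count plus one "total" row per target.
    """
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        phylum = h.phylum or "NA"
        if merge_synonyms:
            phylum = PHYLUM_SYNONYMS.get(phylum, phylum)
        counts[(h.target_id, phylum)] = counts.get((h.target_id, phylum), 0) + 1
    rows = [
        {"target_id": t, "phylum": p, "count": c}
        for (t, p), c in sorted(counts.items())
    ]
    totals: dict[str, int] = {}
    for (t, _), c in counts.items():
        totals[t] = totals.get(t, 0) + c
    rows.extend(
        {"target_id": t, "phylum": "total", "count": c}
        for t, c in sorted(totals.items())
    )
    return pd.DataFrame(rows, columns=["target_id", "phylum", "count"])


def classify_pathogenicity(
    hits: Iterable[OffTargetHit], catalog: PathogenCatalog
) -> pd.DataFrame:
    """Unique-species pathogenic / non-pathogenic / NA counts.

    Each species lands in exactly one class: in the catalog ->
    pathogenic, absent -> non-pathogenic, no species rank -> NA (counted
    as unique MAGs).  Counts are per (target_class, biome).
    """
    path: dict[tuple[str, str], set[str]] = {}
    nonpath: dict[tuple[str, str], set[str]] = {}
    na: dict[tuple[str, str], set[str]] = {}
    keys: set[tuple[str, str]] = set()
    for h in hits:
        key = (h.target_class, h.biome)
        keys.add(key)
        if h.species is None:
            na.setdefault(key, set()).add(h.mag_id or h.protein_id)
        elif h.species in catalog:
            path.setdefault(key, set()).add(normalize_species(h.species))
        else:
            nonpath.setdefault(key, set()).add(normalize_species(h.species))
    rows = []
    for key in sorted(keys):
        rows.append(
            {
                "target_class": key[0],
                "biome": key[1],
                "pathogenic": len(path.get(key, set())),
                "non_pathogenic": len(nonpath.get(key, set())),
                "na": len(na.get(key, set())),
            }
        )
    return pd.DataFrame(
        rows, columns=["target_class", "biome", "pathogenic", "non_pathogenic", "na"]
    )
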