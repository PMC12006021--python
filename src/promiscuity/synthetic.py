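"""Synthetic pipeline inputs with planted, exactly recoverable structure.

Every generated dataset ships with a :class:`SyntheticTruth` recording
what was planted (homolog identities, species Venn structure, symptom
prevalences, pocket edits) so each downstream stage can be tested
against a known answer.  Generation is fully deterministic under the
seed: the same seed reproduces byte-identical files.

Background metaproteome sequences are drawn i.i.d. from the
Robinson-Robinson amino-acid background frequencies (the null model
underlying BLOSUM62), so they carry no similarity to the targets above
chance.  Planted homologs are substitution-only by default, which makes
the planted global identity exact up to rounding; an indel mode exists
for stress-testing the aligner, with the truth recording the realized
rather than nominal identity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    AtomRecord,
    BIOMES,
    ComplexStructure,
    MetaproteomeEntry,
    PathogenCatalog,
    SideEffectTable,
    TargetRecord,
)

__all__ = [
    "SyntheticTruth",
    "SymptomSpec",
    "PocketSpec",
    "mutate_to_identity",
    "random_sequence",
    "generate_targets",
    "generate_metaproteome",
    "generate_pathogen_catalog",
    "generate_side_effects",
    "generate_complex",
    "complex_from_contacts",
    "apply_edit_script",
    "DEFAULT_VENN_SPEC",
    "DEFAULT_SYMPTOM_SPECS",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Robinson & Robinson amino-acid background frequencies (the standard
# protein null model), ordered to match RESIDUES.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}
BACKGROUND_FREQS = np.array([_RR[c] for c in RESIDUES])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

PHYLA = ("Firmicutes", "Proteobacteria", "Bacteroidota", "Actinobacteriota", "Fusobacteriota")

# Region sizes for the three-set species Venn planted by default.
DEFAULT_VENN_SPEC: dict[str, int] = {
    "gut_only": 4,
    "oral_only": 3,
    "vaginal_only": 2,
    "gut_oral": 3,
    "gut_vaginal": 1,
    "oral_vaginal": 1,
    "all_three": 5,
}

_REGION_BIOMES = {
    "gut_only": ("gut",),
    "oral_only": ("oral",),
    "vaginal_only": ("vaginal",),
    "gut_oral": ("gut", "oral"),
    "gut_vaginal": ("gut", "vaginal"),
    "oral_vaginal": ("oral", "vaginal"),
    "all_three": ("gut", "oral", "vaginal"),
}


@dataclass(frozen=True)
class SymptomSpec:
    """Planted Bernoulli prevalence of one symptom in the two drug groups."""

    symptom: str
    system_organ_class: str
    p_affecting: float
    p_non_affecting: float

    def __post_init__(self) -> None:
        for p in (self.p_affecting, self.p_non_affecting):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")


DEFAULT_SYMPTOM_SPECS: tuple[SymptomSpec, ...] = (
    SymptomSpec("opportunistic infection", "Infections and infestations", 0.6, 0.2),
    SymptomSpec("septic shock", "Infections and infestations", 0.35, 0.15),
    SymptomSpec("anaemia", "Blood and lymphatic system disorders", 0.5, 0.25),
    SymptomSpec("lymphopenia", "Blood and lymphatic system disorders", 0.4, 0.2),
    SymptomSpec("hypersensitivity", "Immune system disorders", 0.3, 0.15),
    SymptomSpec("headache", "Nervous system disorders", 0.5, 0.5),
    SymptomSpec("nausea", "Gastrointestinal disorders", 0.6, 0.6),
    SymptomSpec("palpitations", "Cardiac disorders", 0.15, 0.35),
    SymptomSpec("insomnia", "Psychiatric disorders", 0.2, 0.35),
    SymptomSpec("wound complication", "Injury, poisoning and procedural complications", 0.3, 0.0),
    SymptomSpec("apathy", "Psychiatric disorders", 0.0, 0.3),
)


@dataclass
class SyntheticTruth:
    """Everything that was planted, serializable alongside the dataset."""

    seed: int
    planted_homologs: list[dict] = field(default_factory=list)
    identical_plants: list[dict] = field(default_factory=list)
    species_by_biome: dict[str, list[str]] = field(default_factory=dict)
    venn_spec: dict[str, int] = field(default_factory=dict)
    pathogenic_species: list[str] = field(default_factory=list)
    planted_symptoms: list[dict] = field(default_factory=list)
    affecting_drugs: list[str] = field(default_factory=list)
    non_affecting_drugs: list[str] = field(default_factory=list)
    pocket_edit: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        merged = dataclasses.asdict(self)
        for key, val in dataclasses.asdict(other).items():
            if key == "seed":
                continue
            if isinstance(val, list):
                merged[key] = merged[key] + val
            elif isinstance(val, dict) and val:
                merged[key] = {**merged[key], **val}
        return SyntheticTruth(**merged)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Draw an i.i.d. sequence from the Robinson-Robinson background."""
    idx = rng.choice(len(RESIDUES), size=length, p=BACKGROUND_FREQS)
    return "".join(RESIDUES[i] for i in idx)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


_SCHEME_CACHE: list = []


def _default_scheme():
    if not _SCHEME_CACHE:
        from .align import ScoringScheme

        _SCHEME_CACHE.append(ScoringScheme())
    return _SCHEME_CACHE[0]


def mutate_to_identity(
    sequence: str,
    target_identity: float,
    seed: int | np.random.Generator,
    max_attempts: int = 1000,
) -> str:
    """Substitution-only mutant whose realized global identity is exact.

    Exactly ``round((1 - t/100) * L)`` positions are substituted, each to
    a uniformly drawn *different* residue, so the gapless identity to the
    original is t up to the rounding granularity 100/L.  Because an
    optimal affine-gap alignment of a heavily mutated pair can trade gap
    cost for extra matches and drift off the planted value, draws are
    (deterministically, under the seed) resampled until the gapless
    alignment is score-optimal, which pins the measured identity to the
    planted one.  Raises if no realization is found in ``max_attempts``
    (only plausible far below 20% identity).
    """
    if not 0.0 < target_identity <= 100.0:
        raise ValueError("target_identity must be in (0, 100]")
    L = len(sequence)
    if L < 20:
        raise ValueError("sequence must be at least 20 residues")
    rng = _as_rng(seed)
    n_sub = int(round((1.0 - target_identity / 100.0) * L))
    if n_sub == 0:
        return sequence
    from . import _kernels

    scheme = _default_scheme()
    base_idx = scheme.encode(sequence)
    for _ in range(max_attempts):
        positions = rng.choice(L, size=n_sub, replace=False)
        seq = list(sequence)
        for pos in sorted(positions):
            choices = [r for r in RESIDUES if r != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        mutant = "".join(seq)
        mut_idx = scheme.encode(mutant)
        gapless = int(scheme.matrix[base_idx, mut_idx].sum())
        optimal = int(
            _kernels.global_score(base_idx, mut_idx, scheme.matrix,
                                  scheme.gap_open, scheme.gap_extend)
        )
        if optimal == gapless:
            return mutant
    raise RuntimeError(
        f"could not realize a {target_identity}% plant with a gapless "
        f"optimal alignment in {max_attempts} attempts"
    )


def mutate_with_indels(
    sequence: str, target_identity: float, n_indels: int, seed: int | np.random.Generator
) -> str:
    """Indel-mode mutant for stress-testing the aligner.

    Applies the substitution plant first, then ``n_indels`` single-residue
    deletions at random interior positions; the realized identity must be
    measured, not assumed.
    """
    rng = _as_rng(seed)
    seq = list(mutate_to_identity(sequence, target_identity, rng))
    for _ in range(n_indels):
        pos = int(rng.integers(1, len(seq) - 1))
        del seq[pos]
    return "".join(seq)


# ---------------------------------------------------------------------------
# targets
# ---------------------------------------------------------------------------

_FUNCTIONS = (
    "dihydrofolate reductase",
    "DNA-directed RNA polymerase subunit beta",
    "peptidyl-prolyl cis-trans isomerase",
    "acetylcholinesterase",
    "carbonic anhydrase 2",
    "sodium/glucose cotransporter 2",
    "DNA gyrase subunit A",
    "beta-lactamase",
    "penicillin-binding protein 2",
    "30S ribosomal protein S9",
)

_PATHOGEN_ORGANISMS = (
    "Escherichia coli",
    "Mycobacterium tuberculosis",
    "Clostridioides difficile",
    "Staphylococcus aureus",
    "Klebsiella pneumoniae",
)


def generate_targets(
    n_targets: int = 20, length: int = 200, seed: int | np.random.Generator = 0
) -> list[TargetRecord]:
    """Synthetic reviewed drug targets, half human and half pathogen."""
    rng = _as_rng(seed)
    targets = []
    n_human = n_targets // 2
    for i in range(n_targets):
        is_human = i < n_human
        cls = "human" if is_human else "pathogen"
        tid = f"{'HT' if is_human else 'PT'}{i + 1:03d}"
        organism = (
            "Homo sapiens" if is_human
            else _PATHOGEN_ORGANISMS[(i - n_human) % len(_PATHOGEN_ORGANISMS)]
        )
        targets.append(
            TargetRecord(
                target_id=tid,
                sequence=random_sequence(length, rng),
                target_organism=organism,
                target_class=cls,
                function_label=_FUNCTIONS[i % len(_FUNCTIONS)],
                drug_ids=(),
            )
        )
    return targets


def link_drugs(
    targets: Sequence[TargetRecord],
    affecting_target_ids: Sequence[str],
    n_drugs_per_group: int = 100,
) -> tuple[list[TargetRecord], list[str], list[str]]:
    """Attach drug links so group membership follows the planted hits.

    Affecting drugs are spread round-robin over the targets expected to
    have hits, non-affecting drugs over the rest.  Returns the relinked
    targets plus the two drug-id lists.
    """
    affecting = [t for t in targets if t.target_id in set(affecting_target_ids)]
    non_affecting = [t for t in targets if t.target_id not in set(affecting_target_ids)]
    if not affecting or not non_affecting:
        raise ValueError("need at least one target in each group")
    drug_map: dict[str, list[str]] = {t.target_id: [] for t in targets}
    aff_drugs = [f"DA{i:04d}" for i in range(n_drugs_per_group)]
    non_drugs = [f"DN{i:04d}" for i in range(n_drugs_per_group)]
    for i, drug in enumerate(aff_drugs):
        drug_map[affecting[i % len(affecting)].target_id].append(drug)
    for i, drug in enumerate(non_drugs):
        drug_map[non_affecting[i % len(non_affecting)].target_id].append(drug)
    relinked = [replace(t, drug_ids=tuple(drug_map[t.target_id])) for t in targets]
    return relinked, aff_drugs, non_drugs


# ---------------------------------------------------------------------------
# metaproteome
# ---------------------------------------------------------------------------


def _species_pool(venn_spec: dict[str, int]) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Fabricate species names per Venn region and collect per-biome lists."""
    unknown = set(venn_spec) - set(_REGION_BIOMES)
    if unknown:
        raise ValueError(f"unknown Venn regions {sorted(unknown)}")
    if any(v < 0 for v in venn_spec.values()):
        raise ValueError("negative Venn region count")
    region_species: dict[str, list[str]] = {}
    by_biome: dict[str, list[str]] = {b: [] for b in BIOMES}
    for region in _REGION_BIOMES:
        count = venn_spec.get(region, 0)
        names = [f"Synthetica {region.replace('_', '')}{i + 1}" for i in range(count)]
        region_species[region] = names
        for biome in _REGION_BIOMES[region]:
            by_biome[biome].extend(names)
    return region_species, by_biome


def generate_metaproteome(
    targets: Sequence[TargetRecord],
    n_per_biome: int = 200,
    venn_spec: dict[str, int] | None = None,
    identity_ladder: Sequence[float] = (20.0, 35.0, 50.0, 65.0, 80.0, 95.0),
    plant_identity_choices: Sequence[float] = (35.0, 50.0, 65.0, 80.0, 95.0),
    hypothetical_fraction: float = 0.3,
    n_identical_per_biome: int = 2,
    na_plants_per_biome: int = 1,
    planted_target_fraction: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> tuple[list[MetaproteomeEntry], SyntheticTruth]:
    """Generate per-biome catalogues with planted homologs and lineages.

    One homolog is planted per planted species (so the species Venn is
    exactly realized by the screening hits), an identity ladder is
    planted in the gut on the first target, ``n_identical_per_biome``
    exact copies of pathogen targets are planted per biome, and
    ``na_plants_per_biome`` homologs sit on MAGs whose lineage stops at
    the genus (no species rank).  The remainder are background draws.
    """
    rng = _as_rng(seed)
    venn_spec = dict(venn_spec if venn_spec is not None else DEFAULT_VENN_SPEC)
    _, by_biome = _species_pool(venn_spec)
    truth = SyntheticTruth(seed=-1, venn_spec=venn_spec,
                           species_by_biome={b: list(v) for b, v in by_biome.items()})
    pathogen_targets = [t for t in targets if t.target_class == "pathogen"]
    # homologs are planted only on a leading fraction of the targets so
    # that a non-affecting target group always remains for the clinical
    # comparison
    planted_targets = list(targets[: max(1, round(planted_target_fraction * len(targets)))])
    entries: list[MetaproteomeEntry] = []
    for biome in BIOMES:
        prefix = biome.upper()
        species_list = by_biome[biome]
        counter = 0

        def next_ids() -> tuple[str, str]:
            nonlocal counter
            counter += 1
            return f"{prefix}_P{counter:05d}", f"{prefix}_MAG{counter:04d}"

        def lineage_for(species: str | None, phylum: str) -> str:
            base = (
                f"d__Bacteria;p__{phylum};c__Synthclassia;o__Synthales;"
                f"f__Synthaceae;g__Synthetica"
            )
            return base + (f";s__{species}" if species else "")

        # one plant per planted species
        for si, species in enumerate(species_list):
            target = planted_targets[si % len(planted_targets)]
            identity = float(rng.choice(list(plant_identity_choices)))
            pid_, mag = next_ids()
            seq = mutate_to_identity(target.sequence, identity, rng)
            hypothetical = bool(rng.random() < hypothetical_fraction)
            entries.append(
                MetaproteomeEntry(
                    protein_id=pid_, sequence=seq, mag_id=mag, biome=biome,
                    lineage=lineage_for(species, PHYLA[si % len(PHYLA)]),
                    function_annotation=(
                        "hypothetical protein" if hypothetical else target.function_label
                    ),
                )
            )
            truth.planted_homologs.append(
                {
                    "target_id": target.target_id, "protein_id": pid_, "biome": biome,
                    "planted_identity": identity, "species": species,
                    "function_copied": not hypothetical,
                }
            )
        # identity ladder on the first target, species drawn from this biome
        for identity in identity_ladder:
            pid_, mag = next_ids()
            seq = mutate_to_identity(targets[0].sequence, identity, rng)
            species = species_list[0] if species_list else None
            entries.append(
                MetaproteomeEntry(
                    protein_id=pid_, sequence=seq, mag_id=mag, biome=biome,
                    lineage=lineage_for(species, PHYLA[0]),
                    function_annotation=targets[0].function_label,
                )
            )
            truth.planted_homologs.append(
                {
                    "target_id": targets[0].target_id, "protein_id": pid_,
                    "biome": biome, "planted_identity": float(identity),
                    "species": species, "function_copied": True, "ladder": True,
                }
            )
        # exact copies of pathogen targets (identical-match truth)
        for k in range(n_identical_per_biome):
            target = pathogen_targets[k % len(pathogen_targets)]
            pid_, mag = next_ids()
            species = species_list[0] if species_list else None
            entries.append(
                MetaproteomeEntry(
                    protein_id=pid_, sequence=target.sequence, mag_id=mag, biome=biome,
                    lineage=lineage_for(species, PHYLA[1]),
                    function_annotation=target.function_label,
                )
            )
            truth.identical_plants.append(
                {"target_id": target.target_id, "protein_id": pid_, "biome": biome}
            )
        # homologs on MAGs without a species rank
        for k in range(na_plants_per_biome):
            target = planted_targets[(k + 1) % len(planted_targets)]
            pid_, mag = next_ids()
            seq = mutate_to_identity(target.sequence, 60.0, rng)
            entries.append(
                MetaproteomeEntry(
                    protein_id=pid_, sequence=seq, mag_id=mag, biome=biome,
                    lineage=lineage_for(None, PHYLA[2]),
                    function_annotation=target.function_label,
                )
            )
            truth.planted_homologs.append(
                {
                    "target_id": target.target_id, "protein_id": pid_, "biome": biome,
                    "planted_identity": 60.0, "species": None, "function_copied": True,
                }
            )
        # background
        while counter < n_per_biome:
            pid_, mag = next_ids()
            length = int(rng.integers(150, 251))
            species = f"Backgroundia {biome}{counter}"
            entries.append(
                MetaproteomeEntry(
                    protein_id=pid_, sequence=random_sequence(length, rng),
                    mag_id=mag, biome=biome,
                    lineage=lineage_for(species, PHYLA[counter % len(PHYLA)]),
                    function_annotation="hypothetical protein",
                )
            )
    return entries, truth


def generate_pathogen_catalog(
    truth: SyntheticTruth,
    pathogenic_fraction: float = 0.4,
    n_extra: int = 50,
    seed: int | np.random.Generator = 0,
) -> tuple[PathogenCatalog, SyntheticTruth]:
    """Mark a seeded fraction of planted species pathogenic, plus decoys."""
    rng = _as_rng(seed)
    all_species = sorted({s for v in truth.species_by_biome.values() for s in v})
    n_path = int(round(pathogenic_fraction * len(all_species)))
    chosen = sorted(rng.choice(all_species, size=n_path, replace=False).tolist())
    extras = [f"Decoya pathogen{i}" for i in range(n_extra)]
    catalog = PathogenCatalog.from_names(list(chosen) + extras)
    truth = dataclasses.replace(truth, pathogenic_species=list(chosen))
    return catalog, truth


# ---------------------------------------------------------------------------
# side effects
# ---------------------------------------------------------------------------


def generate_side_effects(
    affecting_drugs: Sequence[str],
    non_affecting_drugs: Sequence[str],
    symptom_specs: Sequence[SymptomSpec] = DEFAULT_SYMPTOM_SPECS,
    seed: int | np.random.Generator = 0,
) -> tuple[SideEffectTable, SyntheticTruth]:
    """Draw each drug-symptom row independently Bernoulli(p_group)."""
    rng = _as_rng(seed)
    rows: list[tuple[str, str, str]] = []
    for spec in symptom_specs:
        for drug in affecting_drugs:
            if rng.random() < spec.p_affecting:
                rows.append((drug, spec.symptom, spec.system_organ_class))
        for drug in non_affecting_drugs:
            if rng.random() < spec.p_non_affecting:
                rows.append((drug, spec.symptom, spec.system_organ_class))
    truth = SyntheticTruth(
        seed=-1,
        planted_symptoms=[dataclasses.asdict(s) for s in symptom_specs],
        affecting_drugs=list(affecting_drugs),
        non_affecting_drugs=list(non_affecting_drugs),
    )
    return SideEffectTable(tuple(rows)), truth


# ---------------------------------------------------------------------------
# complexes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PocketSpec:
    """Geometry plan: which residues sit within the pocket cutoff."""

    n_residues: int = 40
    pocket_indices: tuple[int, ...] = (18, 19, 20, 21, 22)  # 1-based residue numbers
    pocket_cutoff: float = 5.0
    contact_cutoff: float = 10.5
    ligand_elements: tuple[str, ...] = ("C", "C", "N", "O")

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        bad = [i for i in self.pocket_indices if not 1 <= i <= self.n_residues]
        if bad:
            raise ValueError(f"pocket indices out of range: {bad}")
        if not 0 < self.pocket_cutoff <= self.contact_cutoff:
            raise ValueError("need 0 < pocket_cutoff <= contact_cutoff")
        if not self.ligand_elements:
            raise ValueError("ligand needs at least one atom")


# backbone + one sidechain atom per residue; CB element C, carbonyl O
_RES_ATOMS = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"))
_RES_NAMES = ("ALA", "GLY", "SER", "THR", "VAL", "LEU", "ILE", "PHE", "TYR", "TRP",
              "ASP", "GLU", "ASN", "GLN", "LYS", "ARG", "HIS", "MET", "CYS", "PRO")


def generate_complex(
    pocket_spec: PocketSpec | None = None, seed: int | np.random.Generator = 0
) -> tuple[ComplexStructure, SyntheticTruth]:
    """Toy posed complex realizing a planted pocket membership.

    The ligand sits near the origin; pocket residues are placed on a
    ~4 angstrom shell around it (inside ``pocket_cutoff``), all other
    residues far outside ``contact_cutoff`` so they contribute neither
    pocket membership nor contacts.
    """
    spec = pocket_spec or PocketSpec()
    rng = _as_rng(seed)
    atoms: list[AtomRecord] = []
    for k, elem in enumerate(spec.ligand_elements):
        atoms.append(
            AtomRecord(element=elem, x=1.4 * k, y=0.0, z=0.0, res_name="LIG",
                       res_num=1, chain_id="L", atom_name=f"L{k + 1}", is_ligand=True)
        )
    lig_center = np.array([1.4 * (len(spec.ligand_elements) - 1) / 2.0, 0.0, 0.0])
    pocket = set(spec.pocket_indices)
    far_radius = spec.contact_cutoff + 25.0
    for resnum in range(1, spec.n_residues + 1):
        res_name = _RES_NAMES[int(rng.integers(len(_RES_NAMES)))]
        if resnum in pocket:
            theta = 2.0 * np.pi * (resnum / max(len(pocket), 1))
            center = lig_center + 4.0 * np.array([np.cos(theta), np.sin(theta), 0.4])
        else:
            theta = 2.0 * np.pi * (resnum / spec.n_residues)
            center = lig_center + far_radius * np.array(
                [np.cos(theta), np.sin(theta), 1.0 + 0.2 * resnum]
            )
        for k, (name, elem) in enumerate(_RES_ATOMS):
            offset = 0.8 * np.array([np.cos(1.3 * k), np.sin(1.3 * k), 0.3 * k])
            pos = center + offset
            atoms.append(
                AtomRecord(element=elem, x=float(pos[0]), y=float(pos[1]),
                           z=float(pos[2]), res_name=res_name, res_num=resnum,
                           chain_id="A", atom_name=name, is_ligand=False)
            )
    complex_ = ComplexStructure(atoms=tuple(atoms), ligand_name="LIG")
    truth = SyntheticTruth(
        seed=-1,
        pocket_edit={
            "pocket_indices": sorted(pocket),
            "pocket_cutoff": spec.pocket_cutoff,
            "contact_cutoff": spec.contact_cutoff,
        },
    )
    return complex_, truth


def complex_from_contacts(
    contact_counts: dict[str, int], cutoff: float = 10.5
) -> ComplexStructure:
    """Build a complex whose contact profile is exactly ``contact_counts``.

    Each requested class gets its own spatial station, separated by far
    more than the cutoff, holding one ligand atom and the requested
    number of protein atoms at ~3 angstroms.  X-class atoms are realized
    as S (protein) / P (ligand).
    """
    element_for = {"C": "C", "N": "N", "O": "O", "X": "S"}
    ligand_for = {"C": "C", "N": "N", "O": "O", "X": "P"}
    atoms: list[AtomRecord] = []
    spacing = 4.0 * cutoff + 10.0
    station = 0
    for cls, count in sorted(contact_counts.items()):
        if count < 0:
            raise ValueError("negative contact count")
        if count == 0:
            continue
        lig_elem = ligand_for[cls[0]]
        prot_elem = element_for[cls[1]]
        x0 = spacing * station
        station += 1
        atoms.append(
            AtomRecord(element=lig_elem, x=x0, y=0.0, z=0.0, res_name="LIG",
                       res_num=1, chain_id="L", atom_name=f"L{station}", is_ligand=True)
        )
        for k in range(count):
            theta = 2.0 * np.pi * k / max(count, 1)
            atoms.append(
                AtomRecord(
                    element=prot_elem, x=x0 + 3.0 * np.cos(theta),
                    y=3.0 * np.sin(theta), z=0.5, res_name="ALA",
                    res_num=station * 100 + k, chain_id="A",
                    atom_name=prot_elem, is_ligand=False,
                )
            )
    if not any(a.is_ligand for a in atoms):
        # degenerate all-zero request: isolated ligand far from one protein atom
        atoms = [
            AtomRecord("C", 0.0, 0.0, 0.0, "LIG", 1, "L", "L1", True),
            AtomRecord("C", 10.0 * cutoff, 0.0, 0.0, "ALA", 1, "A", "CA", False),
        ]
    return ComplexStructure(atoms=tuple(atoms), ligand_name="LIG")


def write_default_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_targets: int = 20,
    target_length: int = 200,
    n_per_biome: int = 200,
    n_drugs_per_group: int = 100,
    similarity_threshold: float = 30.0,
) -> SyntheticTruth:
    """Write the full default synthetic input bundle plus truth.json.

    Emits exactly the formats the readers consume: targets.fasta +
    targets.tsv, metaproteome.fasta + metaproteome.tsv, pathogens.csv,
    side_effects.tsv, complex.pdb + complex_comparison.fasta, and a
    run_config.yaml wiring them together.  Regeneration from the same
    seed is byte-identical.
    """
    import csv as _csv

    from .io_formats import write_complex, write_fasta, write_metaproteome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    targets = generate_targets(n_targets, target_length, rng)
    entries, truth = generate_metaproteome(targets, n_per_biome=n_per_biome, seed=rng)
    truth.seed = seed
    catalog, truth = generate_pathogen_catalog(truth, seed=rng)

    hit_targets = sorted(
        {h["target_id"] for h in truth.planted_homologs
         if h["planted_identity"] > similarity_threshold}
        | {h["target_id"] for h in truth.identical_plants}
    )
    targets, aff_drugs, non_drugs = link_drugs(targets, hit_targets, n_drugs_per_group)
    side_effects, se_truth = generate_side_effects(aff_drugs, non_drugs, seed=rng)
    truth = truth.merge(se_truth)

    # posed complex with a planted pocket edit script: 2 substitutions
    # plus 1 single-residue insertion inside the pocket
    pocket_spec = PocketSpec()
    complex_, cx_truth = generate_complex(pocket_spec, seed=rng)
    from .structure import chain_sequence

    ref_seq, _ = chain_sequence(complex_)
    subs_pos = [pocket_spec.pocket_indices[0] + 1, pocket_spec.pocket_indices[-1]]
    subs = {}
    for pos in subs_pos:
        current = ref_seq[pos - 1]
        subs[pos] = "W" if current != "W" else "F"
    ins_pos = pocket_spec.pocket_indices[len(pocket_spec.pocket_indices) // 2]
    ins_res = "P" if ref_seq[ins_pos - 1] != "P" and ref_seq[ins_pos] != "P" else "G"
    comparison = apply_edit_script(ref_seq, substitutions=subs,
                                   insertions={ins_pos: ins_res})
    cx_truth.pocket_edit.update(
        {
            "substitutions": {str(k): v for k, v in subs.items()},
            "insertion_after": ins_pos,
            "inserted_residue": ins_res,
            "comparison_id": "pocket_homolog",
        }
    )
    truth = truth.merge(cx_truth)

    # --- write everything -------------------------------------------------
    write_fasta([(t.target_id, t.sequence) for t in targets], outdir / "targets.fasta")
    with open(outdir / "targets.tsv", "w", newline="") as fh:
        w = _csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target_id", "target_organism", "target_class", "function", "drug_ids"])
        for t in targets:
            w.writerow([t.target_id, t.target_organism, t.target_class,
                        t.function_label, ";".join(t.drug_ids)])
    write_metaproteome(entries, outdir / "metaproteome.fasta", outdir / "metaproteome.tsv")
    with open(outdir / "pathogens.csv", "w", newline="") as fh:
        w = _csv.writer(fh, lineterminator="\n")
        w.writerow(["species"])
        for name in truth.pathogenic_species:
            w.writerow([name])
        for i in range(50):
            w.writerow([f"Decoya pathogen{i}"])
    with open(outdir / "side_effects.tsv", "w", newline="") as fh:
        w = _csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["drug_id", "symptom", "system_organ_class"])
        for row in side_effects.rows:
            w.writerow(list(row))
    write_complex(complex_, outdir / "complex.pdb")
    write_fasta([("pocket_homolog", comparison)], outdir / "complex_comparison.fasta")
    truth.to_json(outdir / "truth.json")

    config_text = (
        "targets_fasta: targets.fasta\n"
        "targets_table: targets.tsv\n"
        "metaproteome_fasta: metaproteome.fasta\n"
        "metaproteome_table: metaproteome.tsv\n"
        "pathogen_catalog: pathogens.csv\n"
        "side_effects: side_effects.tsv\n"
        "complexes:\n"
        "  - pdb: complex.pdb\n"
        "    ligand: LIG\n"
        "    comparison_fasta: complex_comparison.fasta\n"
        f"similarity_threshold: {similarity_threshold}\n"
        "function_threshold: 50.0\n"
        "evalue_cutoff: 1.0e-06\n"
        "identity_mode: global\n"
        "contact_cutoff: 10.5\n"
        "pocket_cutoff: 5.0\n"
        "min_change: 10.0\n"
        f"seed: {seed}\n"
        "output_dir: results\n"
    )
    (outdir / "run_config.yaml").write_text(config_text)
    return truth


def apply_edit_script(
    sequence: str,
    substitutions: dict[int, str] | None = None,
    insertions: dict[int, str] | None = None,
    deletions: Iterable[int] = (),
) -> str:
    """Apply a planted edit script (1-based positions on the input).

    ``substitutions`` maps position -> new residue; ``insertions`` maps
    position -> residue inserted *after* that position; ``deletions``
    removes positions.  Used to construct homologs whose pocket-level
    differences are known exactly.
    """
    substitutions = substitutions or {}
    insertions = insertions or {}
    deletions = set(deletions)
    out: list[str] = []
    for i, ch in enumerate(sequence, start=1):
        if i in deletions:
            continue
        if i in substitutions:
            if substitutions[i] == ch:
                raise ValueError(f"substitution at {i} does not change the residue")
            out.append(substitutions[i])
        else:
            out.append(ch)
        if i in insertions:
            out.append(insertions[i])
    return "".join(out)
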