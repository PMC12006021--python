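"""Readers and writers for every external format the pipeline touches.

Sequence data travel as FASTA, tabular annotations as TSV with a header
line, the pathogen catalog as a single-column CSV, and posed
protein-ligand complexes as PDB.  All parsing is strict: malformed
records raise :class:`FormatError` naming the offending record instead
of being silently dropped.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi

__all__ = [
    "FormatError",
    "TargetRecord",
    "MetaproteomeEntry",
    "PathogenCatalog",
    "SideEffectTable",
    "AtomRecord",
    "ComplexStructure",
    "read_fasta",
    "write_fasta",
    "read_targets",
    "read_annotation_table",
    "write_metaproteome",
    "read_pathogen_catalog",
    "read_side_effects",
    "read_drug_target_links",
    "read_complex",
    "write_complex",
    "parse_lineage",
    "normalize_species",
    "LINEAGE_RANKS",
    "BIOMES",
]

# 20 standard residues plus X for unknown/nonstandard.
STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_TO_X = set("UOBZJ*")  # selenocysteine etc. -> X with a warning
BIOMES = ("gut", "oral", "vaginal")
LINEAGE_RANKS = ("d", "p", "c", "o", "f", "g", "s")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetRecord:
    """A reviewed drug-target protein with its organism and drug links."""

    target_id: str
    sequence: str
    target_organism: str
    target_class: str  # "human" | "pathogen"
    function_label: str
    drug_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"target {self.target_id}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES - {"X"}
        if bad:
            raise FormatError(
                f"target {self.target_id}: invalid residues {sorted(bad)}"
            )
        if self.target_class not in ("human", "pathogen"):
            raise FormatError(
                f"target {self.target_id}: target_class must be 'human' or "
                f"'pathogen', got {self.target_class!r}"
            )


@dataclass(frozen=True)
class MetaproteomeEntry:
    """One predicted protein from a MAG catalogue, with lineage/function."""

    protein_id: str
    sequence: str
    mag_id: str
    biome: str
    lineage: str
    function_annotation: str = ""

    def __post_init__(self) -> None:
        if self.biome not in BIOMES:
            raise FormatError(
                f"protein {self.protein_id}: unknown biome {self.biome!r} "
                f"(expected one of {BIOMES})"
            )

    @property
    def ranks(self) -> dict[str, str]:
        return parse_lineage(self.lineage)

    @property
    def species(self) -> str | None:
        """Binomial species name from the s__ rank, or None when absent."""
        return self.ranks.get("s") or None

    @property
    def phylum(self) -> str | None:
        return self.ranks.get("p") or None


@dataclass(frozen=True)
class PathogenCatalog:
    """Curated list of bacterial species recorded as infection-capable."""

    species_names: frozenset[str]

    def __contains__(self, species: str) -> bool:
        return normalize_species(species) in self.species_names

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "PathogenCatalog":
        return cls(frozenset(normalize_species(n) for n in names if n.strip()))


@dataclass(frozen=True)
class SideEffectTable:
    """Drug -> MedDRA preferred-term rows with system-organ-class labels."""

    rows: tuple[tuple[str, str, str], ...]  # (drug_id, symptom, soc)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for drug_id, symptom, soc in self.rows:
            if not soc:
                raise FormatError(
                    f"side-effect row ({drug_id}, {symptom}): empty "
                    "system_organ_class"
                )
            key = (drug_id, symptom)
            if key in seen:
                raise FormatError(
                    f"duplicate side-effect row for drug {drug_id!r}, "
                    f"symptom {symptom!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def drugs(self) -> set[str]:
        return {r[0] for r in self.rows}


@dataclass(frozen=True)
class AtomRecord:
    element: str
    x: float
    y: float
    z: float
    res_name: str
    res_num: int
    chain_id: str
    atom_name: str
    is_ligand: bool


@dataclass(frozen=True)
class ComplexStructure:
    """A posed protein-ligand complex (waters already removed)."""

    atoms: tuple[AtomRecord, ...]
    ligand_name: str

    def __post_init__(self) -> None:
        if not any(not a.is_ligand for a in self.atoms):
            raise FormatError("complex has no protein atoms")
        if not any(a.is_ligand for a in self.atoms):
            raise FormatError(
                f"complex has no ligand atoms named {self.ligand_name!r}"
            )
        for a in self.atoms:
            if not a.element:
                raise FormatError("atom with empty element symbol")
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise FormatError("non-finite atom coordinate")

    @property
    def protein_atoms(self) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if not a.is_ligand)

    @property
    def ligand_atoms(self) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if a.is_ligand)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _clean_sequence(raw: str, rec_id: str, offset: int) -> str:
    out = []
    for i, ch in enumerate(raw):
        c = ch.upper()
        if c in STANDARD_RESIDUES or c == "X":
            out.append(c)
        elif c in AMBIGUOUS_TO_X:
            warnings.warn(
                f"record {rec_id}: nonstandard residue {ch!r} at position "
                f"{offset + i + 1} mapped to X",
                stacklevel=3,
            )
            out.append("X")
        else:
            raise FormatError(
                f"record {rec_id}: non-amino-acid character {ch!r} at "
                f"sequence position {offset + i + 1}"
            )
    return "".join(out)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into ``[(id, sequence), ...]`` in file order.

    Ids are the first whitespace-delimited header token; sequences are
    upper-cased.  Empty files, duplicate ids and non-amino-acid
    characters raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    rec_id: str | None = None
    parts: list[str] = []
    length = 0

    def flush() -> None:
        nonlocal rec_id, parts, length
        if rec_id is None:
            return
        seq = "".join(parts)
        if not seq:
            raise FormatError(f"record {rec_id}: empty sequence")
        records.append((rec_id, seq))
        rec_id, parts, length = None, [], 0

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                rec_id = line[1:].split()[0] if line[1:].split() else ""
                if not rec_id:
                    raise FormatError("FASTA header with empty id")
                if rec_id in seen:
                    raise FormatError(f"duplicate FASTA id {rec_id!r}")
                seen.add(rec_id)
            else:
                if rec_id is None:
                    raise FormatError("sequence data before first FASTA header")
                parts.append(_clean_sequence(line.strip(), rec_id, length))
                length += len(line.strip())
    flush()
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# lineage / species helpers
# ---------------------------------------------------------------------------


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a GTDB-style rank-prefixed lineage into ``{rank: name}``.

    Accepts up to the 7 ranks d,p,c,o,f,g,s separated by ";"; absent
    ranks may be omitted entirely or present with an empty name.  An
    unknown rank prefix or a malformed field raises
    :class:`FormatError`.
    """
    ranks: dict[str, str] = {}
    if not lineage.strip():
        return ranks
    for fld in lineage.split(";"):
        fld = fld.strip()
        if not fld:
            continue
        if len(fld) < 3 or fld[1:3] != "__":
            raise FormatError(f"malformed lineage field {fld!r}")
        rank, name = fld[0], fld[3:].strip()
        if rank not in LINEAGE_RANKS:
            raise FormatError(f"unknown lineage rank prefix {rank!r}__")
        if rank in ranks:
            raise FormatError(f"duplicate lineage rank {rank!r}__")
        if name:
            ranks[rank] = name
    return ranks


def normalize_species(name: str) -> str:
    """Normalize a species string for catalog matching.

    Lower-case, collapse internal whitespace, and keep only the binomial
    (first two tokens), stripping strain suffixes.
    """
    tokens = name.strip().lower().split()
    return " ".join(tokens[:2])


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty table")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        return [dict(row) for row in reader]


def read_targets(fasta_path: str | Path, table_path: str | Path) -> list[TargetRecord]:
    """Join a target FASTA with its metadata sidecar TSV.

    The sidecar must carry columns target_id, target_organism,
    target_class, function and drug_ids (semicolon-separated).
    """
    seqs = dict(read_fasta(fasta_path))
    rows = _read_tsv(
        table_path,
        ["target_id", "target_organism", "target_class", "function", "drug_ids"],
    )
    targets = []
    for row in rows:
        tid = row["target_id"]
        if tid not in seqs:
            raise FormatError(f"target {tid!r} in table but absent from FASTA")
        drug_ids = tuple(d for d in row["drug_ids"].split(";") if d)
        targets.append(
            TargetRecord(
                target_id=tid,
                sequence=seqs[tid],
                target_organism=row["target_organism"],
                target_class=row["target_class"],
                function_label=row["function"],
                drug_ids=drug_ids,
            )
        )
    return targets


def read_annotation_table(
    table_path: str | Path, fasta_path: str | Path
) -> list[MetaproteomeEntry]:
    """Join a per-catalogue annotation TSV with its companion FASTA.

    Rows whose lineage fails to parse are collected and reported in a
    single error rather than silently dropped; proteins present in the
    TSV but missing from the FASTA are an error listing the ids.
    """
    seqs = dict(read_fasta(fasta_path))
    rows = _read_tsv(table_path, ["protein_id", "mag_id", "biome", "lineage", "function"])
    missing = [r["protein_id"] for r in rows if r["protein_id"] not in seqs]
    if missing:
        raise FormatError(
            f"{len(missing)} proteins in annotation table absent from FASTA: "
            f"{missing[:10]}"
        )
    entries: list[MetaproteomeEntry] = []
    rejects: list[str] = []
    seen: set[tuple[str, str]] = set()
    for row in rows:
        pid = row["protein_id"]
        key = (row["biome"], pid)
        if key in seen:
            raise FormatError(f"duplicate protein_id {pid!r} within biome {row['biome']!r}")
        seen.add(key)
        try:
            parse_lineage(row["lineage"])
            entries.append(
                MetaproteomeEntry(
                    protein_id=pid,
                    sequence=seqs[pid],
                    mag_id=row["mag_id"],
                    biome=row["biome"],
                    lineage=row["lineage"],
                    function_annotation=row["function"],
                )
            )
        except FormatError as exc:
            if "biome" in str(exc):
                raise
            rejects.append(f"{pid}: {exc}")
    if rejects:
        raise FormatError(
            f"{len(rejects)} annotation rows with unparseable lineage: "
            + "; ".join(rejects[:10])
        )
    return entries


def write_metaproteome(
    entries: Iterable[MetaproteomeEntry],
    fasta_path: str | Path,
    table_path: str | Path,
) -> None:
    entries = list(entries)
    write_fasta([(e.protein_id, e.sequence) for e in entries], fasta_path)
    with open(table_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "mag_id", "biome", "lineage", "function"])
        for e in entries:
            w.writerow([e.protein_id, e.mag_id, e.biome, e.lineage, e.function_annotation])


def read_pathogen_catalog(path: str | Path) -> PathogenCatalog:
    """Read a one-column CSV of species names (optional 'species' header)."""
    path = Path(path)
    names: list[str] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or not row[0].strip():
                continue
            if i == 0 and row[0].strip().lower() in ("species", "species_name"):
                continue
            names.append(row[0])
    if not names:
        raise FormatError(f"{path}: empty pathogen catalog")
    return PathogenCatalog.from_names(names)


def read_side_effects(path: str | Path) -> SideEffectTable:
    rows = _read_tsv(path, ["drug_id", "symptom", "system_organ_class"])
    return SideEffectTable(
        tuple((r["drug_id"], r["symptom"], r["system_organ_class"]) for r in rows)
    )


def read_drug_target_links(path: str | Path) -> list[tuple[str, str]]:
    rows = _read_tsv(path, ["drug_id", "target_id"])
    return [(r["drug_id"], r["target_id"]) for r in rows]


# ---------------------------------------------------------------------------
# PDB complexes
# ---------------------------------------------------------------------------

# PDB v3 convention: atom name columns 13-16; the element is encoded in
# the first characters once digits/whitespace are stripped.  Used only
# when the element columns (77-78) are blank.
_TWO_LETTER_ELEMENTS = {
    "BR", "CL", "FE", "MG", "MN", "ZN", "CA", "NA", "CU", "NI", "CO", "SE", "SI",
}


def _infer_element(atom_name: str, res_name: str) -> str:
    name = atom_name.strip()
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        return ""
    # In standard residues, names like "CA"/"CB" are carbons; the
    # two-character metal reading applies to HET species (ions) where the
    # name fills columns 13-14.
    if len(atom_name) >= 2 and not atom_name.startswith(" "):
        two = stripped[:2]
        if two in _TWO_LETTER_ELEMENTS:
            return two.capitalize()
    return stripped[0]


def write_complex(complex_: ComplexStructure, path: str | Path) -> None:
    """Write a complex as fixed-column PDB (ATOM for protein, HETATM for ligand)."""
    with open(path, "w") as fh:
        for serial, a in enumerate(complex_.atoms, start=1):
            record = "HETATM" if a.is_ligand else "ATOM"
            name = a.atom_name
            if len(name) < 4 and len(a.element) == 1:
                name = f" {name:<3}"
            else:
                name = f"{name:<4}"
            fh.write(
                f"{record:<6}{serial:>5} {name}{'':1}{a.res_name:>3} "
                f"{a.chain_id:1}{a.res_num:>4}{'':1}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element.upper():>2}\n"
            )
        fh.write("END\n")


def read_complex(path: str | Path, ligand_name: str) -> ComplexStructure:
    """Read a posed complex from PDB: ATOM -> protein, HETATM(ligand_name) -> ligand.

    Waters (HOH/WAT/DOD) are dropped.  The element is taken from the PDB
    element columns when present, else inferred from the atom name.
    Hydrogens are kept in the record list; contact analysis filters them.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.remove_waters()
    atoms: list[AtomRecord] = []
    ligand_name = ligand_name.strip().upper()
    model = st[0]
    for chain in model:
        for residue in chain:
            is_het = residue.het_flag == "H"
            resname = residue.name.strip().upper()
            if is_het and resname in ("HOH", "WAT", "DOD"):
                continue
            is_ligand = is_het and resname == ligand_name
            if is_het and not is_ligand:
                continue  # other heteroatoms (ions, cofactors) ignored
            for atom in residue:
                element = atom.element.name if not atom.element.is_metal else atom.element.name
                if element in ("", "X"):
                    element = _infer_element(atom.name, residue.name)
                atoms.append(
                    AtomRecord(
                        element=element,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        res_name=residue.name,
                        res_num=residue.seqid.num,
                        chain_id=chain.name,
                        atom_name=atom.name,
                        is_ligand=is_ligand,
                    )
                )
    if not any(a.is_ligand for a in atoms):
        raise FormatError(f"{path}: no HETATM records with ligand name {ligand_name!r}")
    if not any(not a.is_ligand for a in atoms):
        raise FormatError(f"{path}: no protein ATOM records")
    return ComplexStructure(atoms=tuple(atoms), ligand_name=ligand_name)
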