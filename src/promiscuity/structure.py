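"""Structural comparison of posed protein-ligand complexes.

Three pieces: (1) classification of protein-ligand heavy-atom contacts
within a distance cutoff into the 10 unordered element-pair classes
over {C, N, O, X}; (2) a purely linear contact-count -> binding free
energy model (kcal/mol); (3) projection of the reference complex's
binding-pocket residues through a global alignment onto a homologous
sequence, classifying each as identical / substituted / gapped and
counting insertions inside the pocket.

Homology modelling and docking are consumed, not performed: the module
takes already-posed complexes as PDB input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from Bio.SeqUtils import seq1

from .align import GAP, ScoringScheme, global_align
from .io_formats import ComplexStructure

__all__ = [
    "CONTACT_CLASSES",
    "ContactProfile",
    "AffinityModel",
    "PocketComparison",
    "contact_profile",
    "predict_affinity",
    "pocket_residues",
    "chain_sequence",
    "compare_pockets",
]

# The 10 unordered element-pair classes, in the conventional column order.
CONTACT_CLASSES = ("CC", "CO", "CN", "CX", "OO", "OX", "NO", "NN", "NX", "XX")

_ELEMENT_CLASS = {"C": "C", "N": "N", "O": "O"}


def _pair_class(e1: str, e2: str) -> str:
    a = _ELEMENT_CLASS.get(e1.capitalize(), "X")
    b = _ELEMENT_CLASS.get(e2.capitalize(), "X")
    key = a + b
    return key if key in CONTACT_CLASSES else b + a


@dataclass(frozen=True)
class ContactProfile:
    """Counts of protein/ligand heavy-atom pairs per element-pair class."""

    counts: dict[str, int]
    cutoff_used: float

    def __post_init__(self) -> None:
        missing = set(CONTACT_CLASSES) - set(self.counts)
        if missing:
            raise ValueError(f"profile missing classes {sorted(missing)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative contact count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CONTACT_CLASSES], dtype=float)


@dataclass(frozen=True)
class AffinityModel:
    """Linear contact-count -> binding free energy model (kcal/mol).

    The shipped default ("contacts_default") is a synthetic set of
    package-default weights — small negative contributions per contact,
    polar pairs weighted more than apolar — intended as a user-replaceable
    placeholder; fitted coefficients can be loaded from a key-value text
    file with :meth:`from_file`.
    """

    intercept: float
    coefficients: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(CONTACT_CLASSES) - set(self.coefficients)
        if missing:
            raise ValueError(f"model missing coefficients {sorted(missing)}")

    @classmethod
    def default(cls) -> "AffinityModel":
        coeff = {
            "CC": -0.020, "CO": -0.030, "CN": -0.030, "CX": -0.015,
            "OO": -0.040, "OX": -0.020, "NO": -0.045, "NN": -0.040,
            "NX": -0.020, "XX": -0.010,
        }
        return cls(intercept=0.0, coefficients=coeff, name="contacts_default")

    @classmethod
    def from_file(cls, path: str | Path) -> "AffinityModel":
        """Read ``key value`` lines: 'intercept' plus the 10 class names."""
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split()
            values[key] = float(val)
        intercept = values.pop("intercept", 0.0)
        return cls(intercept=intercept, coefficients=values, name=Path(path).stem)


@dataclass(frozen=True)
class PocketComparison:
    """Pocket residues of a reference complex mapped onto a homolog."""

    residues: tuple[tuple[str, int, str], ...]  # (chain, resnum, resname)
    statuses: tuple[str, ...]  # identical | substituted | deleted
    aligned_residues: tuple[str, ...]  # one-letter code or "-" per pocket residue
    n_insertions: int  # comparison residues inserted inside the pocket span
    percent_identity: float

    @property
    def n_identical(self) -> int:
        return sum(1 for s in self.statuses if s == "identical")

    @property
    def n_substituted(self) -> int:
        return sum(1 for s in self.statuses if s == "substituted")

    @property
    def n_deleted(self) -> int:
        return sum(1 for s in self.statuses if s == "deleted")


def _heavy(atoms):
    return [a for a in atoms if a.element.capitalize() != "H"]


def contact_profile(complex_: ComplexStructure, cutoff: float = 10.5) -> ContactProfile:
    """Count protein/ligand heavy-atom pairs within ``cutoff`` angstroms.

    Every (protein heavy atom, ligand heavy atom) pair with Euclidean
    distance <= cutoff contributes one count to its unordered
    element-pair class (C, N, O kept; everything else X).
    """
    prot = _heavy(complex_.protein_atoms)
    lig = _heavy(complex_.ligand_atoms)
    if not lig:
        raise ValueError("complex has no ligand heavy atoms")
    if not prot:
        raise ValueError("complex has no protein heavy atoms")
    counts = {c: 0 for c in CONTACT_CLASSES}
    p_xyz = np.array([[a.x, a.y, a.z] for a in prot])
    l_xyz = np.array([[a.x, a.y, a.z] for a in lig])
    dist = cdist(p_xyz, l_xyz)
    for pi, li in zip(*np.nonzero(dist <= cutoff)):
        counts[_pair_class(prot[pi].element, lig[li].element)] += 1
    return ContactProfile(counts=counts, cutoff_used=cutoff)


def predict_affinity(profile: ContactProfile, model: AffinityModel | None = None) -> float:
    """Evaluate the linear model: intercept + sum(coeff_class * count_class)."""
    model = model or AffinityModel.default()
    return model.intercept + sum(
        model.coefficients[c] * profile.counts[c] for c in CONTACT_CLASSES
    )


def pocket_residues(
    complex_: ComplexStructure, pocket_cutoff: float = 5.0
) -> list[tuple[str, int, str]]:
    """Residues with >=1 heavy atom within ``pocket_cutoff`` of the ligand.

    Returned in sequence order (chain, then residue number).
    """
    lig = _heavy(complex_.ligand_atoms)
    if not lig:
        return []
    l_xyz = np.array([[a.x, a.y, a.z] for a in lig])
    found: set[tuple[str, int, str]] = set()
    prot = _heavy(complex_.protein_atoms)
    if prot:
        p_xyz = np.array([[a.x, a.y, a.z] for a in prot])
        close = (cdist(p_xyz, l_xyz) <= pocket_cutoff).any(axis=1)
        for a, is_close in zip(prot, close):
            if is_close:
                found.add((a.chain_id, a.res_num, a.res_name))
    return sorted(found, key=lambda r: (r[0], r[1]))


def chain_sequence(complex_: ComplexStructure, chain_id: str | None = None) -> tuple[str, list[tuple[str, int, str]]]:
    """One-letter sequence of the (first) protein chain, with residue keys."""
    residues: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int]] = set()
    for a in complex_.protein_atoms:
        if chain_id is not None and a.chain_id != chain_id:
            continue
        key = (a.chain_id, a.res_num)
        if key not in seen:
            seen.add(key)
            residues.append((a.chain_id, a.res_num, a.res_name))
    if chain_id is None and residues:
        first_chain = residues[0][0]
        residues = [r for r in residues if r[0] == first_chain]
    residues.sort(key=lambda r: r[1])
    seq = "".join(_one_letter(r[2]) for r in residues)
    return seq, residues


def _one_letter(res_name: str) -> str:
    code = seq1(res_name.capitalize())
    return code if code != "" and code in "ACDEFGHIKLMNPQRSTVWYX" else "X"


def compare_pockets(
    reference: ComplexStructure,
    comparison_sequence: str,
    scheme: ScoringScheme | None = None,
    pocket_cutoff: float = 5.0,
    chain_id: str | None = None,
) -> PocketComparison:
    """Project the reference pocket through a global alignment.

    The reference chain sequence is extracted from the structure and
    globally aligned to ``comparison_sequence``; each pocket residue is
    classified identical / substituted / deleted (aligned to a gap), and
    comparison-sequence residues inserted strictly between pocket
    alignment columns are counted as pocket insertions.  An overall
    alignment identity below 15% aborts with an error since the
    projection is then unreliable.
    """
    scheme = scheme or ScoringScheme()
    ref_seq, ref_residues = chain_sequence(reference, chain_id)
    if not ref_seq:
        raise ValueError("could not extract a reference chain sequence")
    aln = global_align(ref_seq, comparison_sequence, scheme)
    if aln.percent_identity < 15.0:
        raise ValueError(
            f"pocket projection unreliable: alignment identity "
            f"{aln.percent_identity:.1f}% < 15%"
        )
    use_chain = ref_residues[0][0]
    pocket = [r for r in pocket_residues(reference, pocket_cutoff) if r[0] == use_chain]
    # map reference residue index -> alignment column
    ref_col: dict[int, int] = {}
    ri = 0
    for col, c in enumerate(aln.aligned_query):
        if c != GAP:
            ref_col[ri] = col
            ri += 1
    index_of = {(r[0], r[1]): i for i, r in enumerate(ref_residues)}
    statuses: list[str] = []
    aligned: list[str] = []
    cols: list[int] = []
    for r in pocket:
        idx = index_of[(r[0], r[1])]
        col = ref_col[idx]
        cols.append(col)
        other = aln.aligned_subject[col]
        aligned.append(other)
        if other == GAP:
            statuses.append("deleted")
        elif other == aln.aligned_query[col] and other != "X":
            statuses.append("identical")
        else:
            statuses.append("substituted")
    n_ins = 0
    if cols:
        lo, hi = min(cols), max(cols)
        n_ins = sum(
            1
            for col in range(lo + 1, hi)
            if aln.aligned_query[col] == GAP and aln.aligned_subject[col] != GAP
        )
    return PocketComparison(
        residues=tuple(pocket),
        statuses=tuple(statuses),
        aligned_residues=tuple(aligned),
        n_insertions=n_ins,
        percent_identity=aln.percent_identity,
    )
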