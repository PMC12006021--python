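"""Side-effect prevalence comparison between microbiome-affecting and
non-affecting drug targets.

A target is *microbiome-affecting* when it has at least one off-target
hit at the configured identity threshold; a drug is affecting when ANY
of its linked targets is.  Symptoms observed on the linked drugs are
partitioned into unique-to-group and shared sets, and for shared
symptoms the *normalized prevalence* — the fraction of drugs in a group
reporting the symptom — is compared between groups as a percent change.
Symptoms whose absolute percent change exceeds a minimum (default 10%,
strict) survive the screen; no multiple-testing correction is applied
because this is a descriptive screen, but a seeded permutation null is
available for calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SideEffectTable, TargetRecord
from .screen import OffTargetHit

__all__ = [
    "TargetGroupAssignment",
    "SymptomPrevalence",
    "assign_groups",
    "symptom_partition",
    "prevalence_change",
    "all_shared_prevalences",
    "soc_rollup",
    "permutation_null",
]

AFFECTING = "affecting"
NON_AFFECTING = "non_affecting"


@dataclass(frozen=True)
class TargetGroupAssignment:
    """Partition of targets (and, via links, drugs) into the two groups."""

    target_group: dict[str, str]
    drug_group: dict[str, str]
    unlinked_targets: tuple[str, ...] = ()

    def drugs_in(self, group: str) -> set[str]:
        return {d for d, g in self.drug_group.items() if g == group}


@dataclass(frozen=True)
class SymptomPrevalence:
    """Per-symptom normalized prevalence in the two groups."""

    symptom: str
    system_organ_class: str
    n_affecting: int
    n_non_affecting: int
    p_affecting: float
    p_non_affecting: float
    percent_change: float
    membership: str  # unique_affecting | unique_non_affecting | shared


def assign_groups(
    targets: Sequence[TargetRecord], hits: Iterable[OffTargetHit]
) -> TargetGroupAssignment:
    """Assign every target, and every linked drug, to a similarity group.

    Targets with >=1 hit are affecting.  A drug linked to at least one
    affecting target is counted in the affecting group only (ANY rule).
    Targets without any drug link trigger a warning and are excluded
    from the drug-level analysis.
    """
    hit_targets = {h.target_id for h in hits}
    target_group = {
        t.target_id: (AFFECTING if t.target_id in hit_targets else NON_AFFECTING)
        for t in targets
    }
    unlinked = tuple(t.target_id for t in targets if not t.drug_ids)
    if unlinked:
        warnings.warn(
            f"{len(unlinked)} targets without drug links excluded from "
            f"drug-level analysis: {unlinked[:5]}",
            stacklevel=2,
        )
    drug_group: dict[str, str] = {}
    for t in targets:
        for drug in t.drug_ids:
            if target_group[t.target_id] == AFFECTING:
                drug_group[drug] = AFFECTING
            else:
                drug_group.setdefault(drug, NON_AFFECTING)
    return TargetGroupAssignment(
        target_group=target_group, drug_group=drug_group, unlinked_targets=unlinked
    )


def _symptom_counts(
    assignment: TargetGroupAssignment, side_effects: SideEffectTable
) -> tuple[dict[str, tuple[set[str], set[str]]], dict[str, str]]:
    """Per symptom: (affecting drug set, non-affecting drug set) and SOC."""
    by_symptom: dict[str, tuple[set[str], set[str]]] = {}
    soc: dict[str, str] = {}
    for drug_id, symptom, soc_label in side_effects.rows:
        group = assignment.drug_group.get(drug_id)
        if group is None:
            continue  # drug not linked to any known target
        aff, non = by_symptom.setdefault(symptom, (set(), set()))
        (aff if group == AFFECTING else non).add(drug_id)
        soc.setdefault(symptom, soc_label)
    return by_symptom, soc


def symptom_partition(
    assignment: TargetGroupAssignment, side_effects: SideEffectTable
) -> tuple[set[str], set[str], set[str]]:
    """Split observed symptoms into (unique_affecting, unique_non_affecting, shared).

    Only side-effect rows for drugs present in the assignment count;
    symptoms observed on no linked drug are dropped.
    """
    if len(side_effects) == 0:
        raise ValueError("side-effect table is empty")
    by_symptom, _ = _symptom_counts(assignment, side_effects)
    unique_aff, unique_non, shared = set(), set(), set()
    for symptom, (aff, non) in by_symptom.items():
        if aff and non:
            shared.add(symptom)
        elif aff:
            unique_aff.add(symptom)
        elif non:
            unique_non.add(symptom)
    return unique_aff, unique_non, shared


def _prevalences(
    assignment: TargetGroupAssignment, side_effects: SideEffectTable
) -> list[SymptomPrevalence]:
    by_symptom, soc = _symptom_counts(assignment, side_effects)
    n_aff_drugs = len(assignment.drugs_in(AFFECTING))
    n_non_drugs = len(assignment.drugs_in(NON_AFFECTING))
    if n_aff_drugs == 0 or n_non_drugs == 0:
        raise ValueError("both drug groups must be non-empty")
    out = []
    for symptom in sorted(by_symptom):
        aff, non = by_symptom[symptom]
        if not aff and not non:
            continue
        p_a = len(aff) / n_aff_drugs
        p_n = len(non) / n_non_drugs
        if aff and non:
            membership = "shared"
            # integer arithmetic with one final division keeps exact
            # boundary cases (e.g. +10.0%) exactly representable
            numer = 100 * (len(aff) * n_non_drugs - len(non) * n_aff_drugs)
            pc = numer / (len(non) * n_aff_drugs)
        elif aff:
            membership = "unique_affecting"
            pc = float("inf")
        else:
            membership = "unique_non_affecting"
            pc = float("-inf")
        out.append(
            SymptomPrevalence(
                symptom=symptom,
                system_organ_class=soc[symptom],
                n_affecting=len(aff),
                n_non_affecting=len(non),
                p_affecting=p_a,
                p_non_affecting=p_n,
                percent_change=pc,
                membership=membership,
            )
        )
    return out


def prevalence_change(
    assignment: TargetGroupAssignment,
    side_effects: SideEffectTable,
    min_change: float = 10.0,
) -> list[SymptomPrevalence]:
    """Shared symptoms whose |percent change| strictly exceeds ``min_change``.

    percent_change = 100*(p_affecting - p_non_affecting)/p_non_affecting
    with p_g the fraction of the group's drugs reporting the symptom.
    Output is sorted by |percent_change| descending (symptom name as
    tiebreak).
    """
    shared = [p for p in _prevalences(assignment, side_effects) if p.membership == "shared"]
    kept = [p for p in shared if abs(p.percent_change) > min_change]
    kept.sort(key=lambda p: (-abs(p.percent_change), p.symptom))
    return kept


def all_shared_prevalences(
    assignment: TargetGroupAssignment, side_effects: SideEffectTable
) -> list[SymptomPrevalence]:
    """Every shared symptom's prevalence pair, unfiltered (for denominators)."""
    return [p for p in _prevalences(assignment, side_effects) if p.membership == "shared"]


def soc_rollup(
    prevalences: Sequence[SymptomPrevalence],
    shared: Sequence[SymptomPrevalence] | None = None,
):
    """Per system-organ-class counts of enriched symptoms in each direction.

    ``prevalences`` is the filtered output of :func:`prevalence_change`;
    ``shared`` (optionally) supplies the unfiltered shared-symptom list
    used for the per-SOC denominators, else denominators come from the
    filtered list itself.
    """
    import pandas as pd

    denom_src = shared if shared is not None else prevalences
    socs = sorted({p.system_organ_class for p in denom_src} | {p.system_organ_class for p in prevalences})
    rows = []
    for soc in socs:
        up = sum(1 for p in prevalences if p.system_organ_class == soc and p.percent_change > 0)
        down = sum(1 for p in prevalences if p.system_organ_class == soc and p.percent_change < 0)
        n_shared = sum(1 for p in denom_src if p.system_organ_class == soc)
        rows.append(
            {
                "system_organ_class": soc,
                "affecting_enriched": up,
                "non_affecting_enriched": down,
                "n_shared": n_shared,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["system_organ_class", "affecting_enriched", "non_affecting_enriched", "n_shared"],
    )


def permutation_null(
    assignment: TargetGroupAssignment,
    side_effects: SideEffectTable,
    symptom: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for one symptom's percent change.

    Drug group labels are shuffled ``n_permutations`` times (seeded);
    the p-value is the fraction of permutations with |percent change|
    at least the observed one.
    """
    observed = {p.symptom: p for p in all_shared_prevalences(assignment, side_effects)}
    if symptom not in observed:
        raise ValueError(f"symptom {symptom!r} is not shared between groups")
    obs = abs(observed[symptom].percent_change)
    drugs = sorted(assignment.drug_group)
    labels = np.array([assignment.drug_group[d] == AFFECTING for d in drugs])
    reporting = {
        d for d, s, _ in side_effects.rows if s == symptom and d in assignment.drug_group
    }
    rep = np.array([d in reporting for d in drugs])
    rng = np.random.default_rng(seed)
    n_aff = labels.sum()
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        a = rep[perm].sum() / n_aff
        n = rep[~perm].sum() / (len(drugs) - n_aff)
        if n == 0:
            pc = float("inf") if a > 0 else 0.0
        else:
            pc = abs(100.0 * (a - n) / n)
        if pc >= obs:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
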