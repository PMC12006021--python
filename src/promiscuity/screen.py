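"""Off-target screening of drug targets against metaproteome catalogues.

The screen is two-stage, mirroring a BLAST-then-global-identity reading:
a fast local alignment provides the E-value filter for candidate
discovery, and the reported identity is then recomputed with a full
global alignment on the surviving pairs (``identity_mode="global"``,
the default) or taken from the local alignment (``"local"``, the BLAST
``pident`` convention).

All qualifying pairs are emitted, not best-hit-only: downstream species
summaries deduplicate where needed, while per-protein counting feeds
the gene-level tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .align import AlignmentResult, ScoringScheme, evalue, global_align, local_align
from .io_formats import MetaproteomeEntry, TargetRecord

__all__ = [
    "OffTargetHit",
    "screen_targets",
    "identical_matches",
    "function_concordance",
    "summarize_screen",
    "hits_to_frame",
]


@dataclass(frozen=True)
class OffTargetHit:
    """A drug-target -> metaproteome-protein call above the identity threshold."""

    target_id: str
    protein_id: str
    biome: str
    percent_identity: float
    e_value: float
    species: str | None
    phylum: str | None
    function_annotation: str
    is_identical: bool
    # enrichment fields used by downstream aggregation
    target_class: str = ""
    target_function: str = ""
    mag_id: str = ""


def screen_targets(
    targets: Sequence[TargetRecord],
    metaproteome: Sequence[MetaproteomeEntry],
    scheme: ScoringScheme | None = None,
    similarity_threshold: float = 30.0,
    evalue_cutoff: float = 1e-6,
    identity_mode: str = "global",
) -> list[OffTargetHit]:
    """Map every target against every metaproteome entry and call hits.

    A hit is emitted iff the local E-value is <= ``evalue_cutoff`` AND
    the percent identity is strictly greater than
    ``similarity_threshold`` ("above" is strict).  Output is ordered by
    (target_id, biome, protein_id).
    """
    if not targets or not metaproteome:
        raise ValueError("targets and metaproteome must be non-empty")
    if not 0.0 < similarity_threshold <= 100.0:
        raise ValueError("similarity_threshold must be in (0, 100]")
    if identity_mode not in ("global", "local"):
        raise ValueError("identity_mode must be 'global' or 'local'")
    scheme = scheme or ScoringScheme()
    mat = scheme.matrix
    encoded = [(e, scheme.encode(e.sequence)) for e in metaproteome]
    hits: list[OffTargetHit] = []
    for target in targets:
        qi = scheme.encode(target.sequence)
        m = len(qi)
        for entry, si in encoded:
            score = int(
                _kernels.local_score(qi, si, mat, scheme.gap_open, scheme.gap_extend)
            )
            e = evalue(score, m, len(si), scheme)
            if e > evalue_cutoff:
                continue
            if identity_mode == "global":
                aln = global_align(target.sequence, entry.sequence, scheme)
            else:
                aln = local_align(target.sequence, entry.sequence, scheme)
            if aln.percent_identity <= similarity_threshold:
                continue
            is_identical = (
                aln.percent_identity == 100.0
                and aln.n_columns == len(target.sequence) == len(entry.sequence)
            )
            hits.append(
                OffTargetHit(
                    target_id=target.target_id,
                    protein_id=entry.protein_id,
                    biome=entry.biome,
                    percent_identity=aln.percent_identity,
                    e_value=e,
                    species=entry.species,
                    phylum=entry.phylum,
                    function_annotation=entry.function_annotation,
                    is_identical=is_identical,
                    target_class=target.target_class,
                    target_function=target.function_label,
                    mag_id=entry.mag_id,
                )
            )
    hits.sort(key=lambda h: (h.target_id, h.biome, h.protein_id))
    return hits


def identical_matches(hits: Iterable[OffTargetHit]) -> pd.DataFrame:
    """Unique metaproteome proteins identical to a target, per class and biome.

    A protein identical to several targets of the same class is counted
    once.  Returns a table with columns target_class, biome,
    n_identical_proteins.
    """
    rows: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        if h.is_identical:
            rows.setdefault((h.target_class, h.biome), set()).add(h.protein_id)
    out = pd.DataFrame(
        [
            {"target_class": tc, "biome": b, "n_identical_proteins": len(pids)}
            for (tc, b), pids in sorted(rows.items())
        ],
        columns=["target_class", "biome", "n_identical_proteins"],
    )
    return out


def function_concordance(
    hits: Iterable[OffTargetHit], function_threshold: float = 50.0
) -> pd.DataFrame:
    """Aggregate (target function, metaproteome annotation) pairs above threshold.

    Only hits with percent identity strictly above ``function_threshold``
    contribute.  Pairs whose annotation strings match exactly are
    flagged "identical function", everything else "other" (including
    mappings onto "hypothetical protein", which are retained).
    """
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        if h.percent_identity > function_threshold:
            key = (h.target_function, h.function_annotation)
            counts[key] = counts.get(key, 0) + 1
    out = pd.DataFrame(
        [
            {
                "target_function": tf,
                "function_annotation": fa,
                "count": c,
                "relationship": "identical function" if tf == fa else "other",
            }
            for (tf, fa), c in sorted(counts.items())
        ],
        columns=["target_function", "function_annotation", "count", "relationship"],
    )
    return out


def summarize_screen(hits: Iterable[OffTargetHit]) -> pd.DataFrame:
    """Per (target_class, biome) hit count, mean identity and identical count."""
    df = hits_to_frame(hits)
    if df.empty:
        return pd.DataFrame(
            columns=["target_class", "biome", "n_hits", "mean_identity", "n_identical"]
        )
    g = df.groupby(["target_class", "biome"], sort=True)
    out = g.agg(
        n_hits=("protein_id", "size"),
        mean_identity=("percent_identity", "mean"),
        n_identical=("is_identical", "sum"),
    ).reset_index()
    out["n_identical"] = out["n_identical"].astype(int)
    return out


def hits_to_frame(hits: Iterable[OffTargetHit]) -> pd.DataFrame:
    cols = [
        "target_id", "protein_id", "biome", "percent_identity", "e_value",
        "species", "phylum", "function_annotation", "is_identical",
        "target_class", "target_function", "mag_id",
    ]
    return pd.DataFrame([h.__dict__ for h in hits], columns=cols)
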