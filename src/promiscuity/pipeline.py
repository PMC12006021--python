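"""End-to-end orchestration: screen -> taxa -> clinical (-> structure).

A :class:`RunConfig` collects every input path and threshold; the run
writes one TSV per stage output plus a JSON manifest recording the
config hash, input checksums and per-stage row counts.  Outputs are
fully deterministic: rerunning with identical inputs and config yields
byte-identical files, and every table carries the config hash in a
header comment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import ScoringScheme
from .clinical import (
    all_shared_prevalences,
    assign_groups,
    prevalence_change,
    soc_rollup,
    symptom_partition,
)
from .io_formats import (
    read_annotation_table,
    read_complex,
    read_drug_target_links,
    read_fasta,
    read_pathogen_catalog,
    read_side_effects,
    read_targets,
)
from .screen import (
    function_concordance,
    hits_to_frame,
    identical_matches,
    screen_targets,
    summarize_screen,
)
from .structure import (
    AffinityModel,
    CONTACT_CLASSES,
    compare_pockets,
    contact_profile,
    pocket_residues,
    predict_affinity,
)
from .taxa import classify_pathogenicity, phylum_composition, species_overlap

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("promiscuity")


@dataclass
class RunConfig:
    """All inputs, thresholds and the output directory for one run."""

    targets_fasta: str
    targets_table: str
    metaproteome_fasta: str
    metaproteome_table: str
    output_dir: str
    side_effects: str | None = None
    drug_links: str | None = None
    pathogen_catalog: str | None = None
    complexes: list[dict] = field(default_factory=list)
    affinity_model: str | None = None
    similarity_threshold: float = 30.0
    function_threshold: float = 50.0
    evalue_cutoff: float = 1e-6
    identity_mode: str = "global"
    contact_cutoff: float = 10.5
    pocket_cutoff: float = 5.0
    min_change: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.similarity_threshold <= 100:
            raise ValueError("similarity_threshold outside (0, 100]")
        if not 0 < self.function_threshold <= 100:
            raise ValueError("function_threshold outside (0, 100]")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.identity_mode not in ("global", "local"):
            raise ValueError("identity_mode must be 'global' or 'local'")
        if self.contact_cutoff <= 0 or self.pocket_cutoff <= 0:
            raise ValueError("distance cutoffs must be positive")
        if self.min_change < 0:
            raise ValueError("min_change must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        cfg = cls(**raw)
        # resolve relative paths against the config file location
        base = path.parent
        for attr in ("targets_fasta", "targets_table", "metaproteome_fasta",
                     "metaproteome_table", "side_effects", "drug_links",
                     "pathogen_catalog", "affinity_model", "output_dir"):
            val = getattr(cfg, attr)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        for cplx in cfg.complexes:
            for key in ("pdb", "comparison_fasta"):
                if key in cplx and not Path(cplx[key]).is_absolute():
                    cplx[key] = str(base / cplx[key])
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where its results land
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> int:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run manifest dict.

    Stage order: screen -> taxa -> clinical -> structure.  A missing
    optional input (pathogen catalog, side effects, complexes) skips its
    stage with a logged warning; any stage error aborts with the stage
    name attached.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    scheme = ScoringScheme()
    counts: dict[str, int] = {}
    checksums: dict[str, str] = {}

    stage = "load"
    try:
        targets = read_targets(config.targets_fasta, config.targets_table)
        if config.drug_links:
            links = read_drug_target_links(config.drug_links)
            by_target: dict[str, list[str]] = {}
            for drug, tid in links:
                by_target.setdefault(tid, []).append(drug)
            targets = [
                dataclasses.replace(t, drug_ids=tuple(by_target.get(t.target_id, ())))
                for t in targets
            ]
        metaproteome = read_annotation_table(
            config.metaproteome_table, config.metaproteome_fasta
        )
        for attr in ("targets_fasta", "targets_table", "metaproteome_fasta",
                     "metaproteome_table", "side_effects", "drug_links",
                     "pathogen_catalog"):
            val = getattr(config, attr)
            if val:
                checksums[attr] = _sha256(val)

        stage = "screen"
        hits = screen_targets(
            targets, metaproteome, scheme,
            similarity_threshold=config.similarity_threshold,
            evalue_cutoff=config.evalue_cutoff,
            identity_mode=config.identity_mode,
        )
        counts["hits"] = _write_table(hits_to_frame(hits), outdir / "hits.tsv", chash)
        counts["screen_summary"] = _write_table(
            summarize_screen(hits), outdir / "screen_summary.tsv", chash
        )
        counts["identical_matches"] = _write_table(
            identical_matches(hits), outdir / "identical_matches.tsv", chash
        )
        counts["function_concordance"] = _write_table(
            function_concordance(hits, config.function_threshold),
            outdir / "function_concordance.tsv", chash,
        )

        stage = "taxa"
        summary = species_overlap(hits)
        venn_rows = [{"region": r, "count": summary.venn[r]} for r in summary.venn]
        venn_rows += [
            {"region": f"{b}_total", "count": len(summary.species_by_biome[b])}
            for b in sorted(summary.species_by_biome)
        ]
        venn_rows += [
            {"region": f"{b}_na", "count": summary.na_counts[b]}
            for b in sorted(summary.na_counts)
        ]
        counts["venn"] = _write_table(
            pd.DataFrame(venn_rows, columns=["region", "count"]),
            outdir / "venn.tsv", chash,
        )
        counts["phylum_composition"] = _write_table(
            phylum_composition(hits), outdir / "phylum_composition.tsv", chash
        )
        if config.pathogen_catalog:
            catalog = read_pathogen_catalog(config.pathogen_catalog)
            counts["pathogenicity"] = _write_table(
                classify_pathogenicity(hits, catalog), outdir / "pathogenicity.tsv", chash
            )
        else:
            logger.warning("no pathogen catalog configured; pathogenicity stage skipped")

        stage = "clinical"
        if config.side_effects:
            side_effects = read_side_effects(config.side_effects)
            assignment = assign_groups(targets, hits)
            ua, un, sh = symptom_partition(assignment, side_effects)
            part = pd.DataFrame(
                sorted(
                    [{"symptom": s, "membership": "unique_affecting"} for s in ua]
                    + [{"symptom": s, "membership": "unique_non_affecting"} for s in un]
                    + [{"symptom": s, "membership": "shared"} for s in sh],
                    key=lambda r: (r["membership"], r["symptom"]),
                ),
                columns=["symptom", "membership"],
            )
            counts["symptom_partition"] = _write_table(
                part, outdir / "symptom_partition.tsv", chash
            )
            changed = prevalence_change(assignment, side_effects, config.min_change)
            counts["prevalence_change"] = _write_table(
                pd.DataFrame(
                    [dataclasses.asdict(p) for p in changed],
                    columns=["symptom", "system_organ_class", "n_affecting",
                             "n_non_affecting", "p_affecting", "p_non_affecting",
                             "percent_change", "membership"],
                ),
                outdir / "prevalence_change.tsv", chash,
            )
            shared_all = all_shared_prevalences(assignment, side_effects)
            counts["soc_rollup"] = _write_table(
                soc_rollup(changed, shared_all), outdir / "soc_rollup.tsv", chash
            )
        else:
            logger.warning("no side-effect table configured; clinical stage skipped")

        stage = "structure"
        if config.complexes:
            model = (
                AffinityModel.from_file(config.affinity_model)
                if config.affinity_model
                else AffinityModel.default()
            )
            contact_rows, affinity_rows, pocket_rows = [], [], []
            for cplx_cfg in config.complexes:
                name = Path(cplx_cfg["pdb"]).stem
                checksums[f"complex:{name}"] = _sha256(cplx_cfg["pdb"])
                cplx = read_complex(cplx_cfg["pdb"], cplx_cfg["ligand"])
                profile = contact_profile(cplx, config.contact_cutoff)
                contact_rows.append(
                    {"complex": name, **{c: profile.counts[c] for c in CONTACT_CLASSES}}
                )
                affinity_rows.append(
                    {
                        "complex": name,
                        "delta_g_kcal_mol": predict_affinity(profile, model),
                        "total_contacts": profile.total,
                        "model": model.name,
                    }
                )
                if cplx_cfg.get("comparison_fasta"):
                    for comp_id, comp_seq in read_fasta(cplx_cfg["comparison_fasta"]):
                        pc = compare_pockets(
                            cplx, comp_seq, scheme, config.pocket_cutoff
                        )
                        for (chain, resnum, resname), status, other in zip(
                            pc.residues, pc.statuses, pc.aligned_residues
                        ):
                            pocket_rows.append(
                                {
                                    "complex": name, "comparison_id": comp_id,
                                    "chain": chain, "res_num": resnum,
                                    "res_name": resname, "status": status,
                                    "aligned_residue": other,
                                    "n_insertions_in_pocket": pc.n_insertions,
                                }
                            )
            counts["contacts"] = _write_table(
                pd.DataFrame(contact_rows, columns=["complex", *CONTACT_CLASSES]),
                outdir / "contacts.tsv", chash,
            )
            counts["affinity"] = _write_table(
                pd.DataFrame(
                    affinity_rows,
                    columns=["complex", "delta_g_kcal_mol", "total_contacts", "model"],
                ),
                outdir / "affinity.tsv", chash,
            )
            counts["pocket_comparison"] = _write_table(
                pd.DataFrame(
                    pocket_rows,
                    columns=["complex", "comparison_id", "chain", "res_num",
                             "res_name", "status", "aligned_residue",
                             "n_insertions_in_pocket"],
                ),
                outdir / "pocket_comparison.tsv", chash,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "input_checksums": checksums,
        "version": __version__,
        "stage_row_counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
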