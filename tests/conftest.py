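"""Shared fixtures: a scoring scheme, small record factories, and the
session-scoped default synthetic dataset with one pipeline run over it."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from promiscuity.align import ScoringScheme
from promiscuity.io_formats import MetaproteomeEntry, TargetRecord
from promiscuity.screen import OffTargetHit


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture
def make_target():
    def _make(target_id="T1", sequence="MKVLIT" * 5, target_class="human",
              function="dihydrofolate reductase", drug_ids=(), organism=None):
        return TargetRecord(
            target_id=target_id,
            sequence=sequence,
            target_organism=organism or ("Homo sapiens" if target_class == "human"
                                         else "Escherichia coli"),
            target_class=target_class,
            function_label=function,
            drug_ids=tuple(drug_ids),
        )

    return _make


@pytest.fixture
def make_entry():
    def _make(protein_id="P1", sequence="MKVLIT" * 5, biome="gut", mag_id="MAG1",
              species="Lactobacillus crispatus", phylum="Firmicutes",
              function="dihydrofolate reductase"):
        parts = ["d__Bacteria"]
        if phylum:
            parts.append(f"p__{phylum}")
        parts += ["c__Bacilli", "o__Lactobacillales", "f__Lactobacillaceae",
                  "g__Lactobacillus"]
        if species:
            parts.append(f"s__{species}")
        return MetaproteomeEntry(
            protein_id=protein_id, sequence=sequence, mag_id=mag_id,
            biome=biome, lineage=";".join(parts), function_annotation=function,
        )

    return _make


@pytest.fixture
def make_hit():
    def _make(target_id="T1", protein_id="P1", biome="gut", pid=55.0,
              species="Lactobacillus crispatus", phylum="Firmicutes",
              function="dihydrofolate reductase", identical=False,
              target_class="human", target_function="dihydrofolate reductase",
              mag_id="MAG1", e_value=1e-30):
        return OffTargetHit(
            target_id=target_id, protein_id=protein_id, biome=biome,
            percent_identity=pid, e_value=e_value, species=species,
            phylum=phylum, function_annotation=function, is_identical=identical,
            target_class=target_class, target_function=target_function,
            mag_id=mag_id,
        )

    return _make


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic bundle (written once per session)."""
    from promiscuity.synthetic import SyntheticTruth, write_default_dataset

    outdir = tmp_path_factory.mktemp("dataset")
    truth = write_default_dataset(outdir, seed=7)
    return outdir, truth


@pytest.fixture(scope="session")
def pipeline_run(default_dataset, tmp_path_factory):
    """One full pipeline execution over the default synthetic bundle."""
    from promiscuity.pipeline import RunConfig, run_pipeline

    outdir, truth = default_dataset
    results = tmp_path_factory.mktemp("results")
    config = RunConfig.from_yaml(outdir / "run_config.yaml")
    config.output_dir = str(results)
    manifest = run_pipeline(config)
    return results, manifest, truth
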