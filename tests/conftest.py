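import pytest

from glutenprofiler.evidence import (
    DigestIndex,
    InferenceConfig,
    assign_uniqueness,
    collapse_modification_variants,
    filter_evidence,
    infer_proteins,
    reliable_peptides,
)
from glutenprofiler.seqdb import ProteinRecord
from glutenprofiler.simulate import default_scenario, make_hmw_like_pair


def record(accession, sequence, description="", organism="Triticum aestivum"):
    return ProteinRecord(
        accession=accession,
        description=description,
        organism=organism,
        sequence=sequence,
    )


@pytest.fixture(scope="session")
def hmw_pair():
    """Deterministic synthetic HMW glutenin allelic pair (Dx2/Dx5 style)."""
    return make_hmw_like_pair(seed=2016)


@pytest.fixture(scope="session")
def scenario():
    """Default closed-loop benchmark: 20 true proteins, detection 0.9."""
    return default_scenario(seed=11)


@pytest.fixture(scope="session")
def scenario_pipeline(scenario):
    """The scenario run through the full inference pipeline."""
    database, rows, truth, spec = scenario
    config = InferenceConfig()
    index = DigestIndex(database, spec.rule, config.max_missed)
    retained, rejected = filter_evidence(rows, config, index)
    entities = collapse_modification_variants(retained, config.uniqueness_mode)
    reliable_peptides(entities, config)
    assign_uniqueness(entities, index)
    identifications, counts = infer_proteins(entities, config, index)
    return {
        "database": database,
        "rows": rows,
        "truth": truth,
        "spec": spec,
        "config": config,
        "index": index,
        "retained": retained,
        "rejected": rejected,
        "entities": entities,
        "identifications": identifications,
        "counts": counts,
    }
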