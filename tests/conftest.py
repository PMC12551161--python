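import pytest

from recessivescan.reporting import PipelineInputs
from recessivescan.synthetic import GeneratorConfig, generate_dataset


def pipeline_inputs(ds) -> PipelineInputs:
    return PipelineInputs(
        cohort_vcf=ds.cohort_vcf,
        cohort_sheet=ds.cohort_sheet,
        gene_model=ds.gene_model,
        reference=ds.reference,
        panel_vcf=ds.panel_vcf,
        panel_sheet=ds.panel_sheet,
        liftover_map=ds.liftover_map,
    )


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One full default-configuration synthetic study, shared across tests."""
    outdir = tmp_path_factory.mktemp("dataset_seed1")
    return generate_dataset(GeneratorConfig(seed=1), str(outdir))


@pytest.fixture(scope="session")
def default_tx(default_dataset):
    import recessivescan.io as rio

    return rio.read_gene_model(default_dataset.gene_model, default_dataset.reference)
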