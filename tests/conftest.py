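import pathlib

import pytest

from stprep.demultiplex import BarcodeAllowList
from stprep.features import count_molecules, load_annotation
from stprep.simulate import (
    SimulationConfig,
    generate_transcriptome,
    simulate_reads,
    write_gff3,
)


@pytest.fixture(scope="session")
def toy_transcriptome():
    return generate_transcriptome(n_genes=30, seed=11)


@pytest.fixture(scope="session")
def clean_sample(tmp_path_factory, toy_transcriptome):
    """Simulated sample with no injected errors and no PCR duplication."""
    out = tmp_path_factory.mktemp("clean")
    cfg = SimulationConfig(
        n_tissue_locations=20,
        n_empty_locations=10,
        n_genes=30,
        mean_molecules_per_location=50,
        pcr_duplication_rate=0.0,
        barcode_error_rate=0.0,
        umi_error_rate=0.0,
        seed=7,
    )
    sample = simulate_reads(cfg, transcriptome=toy_transcriptome, out_dir=out)
    gff = write_gff3(toy_transcriptome, out / "annotation.gff3")
    return sample, gff, cfg


@pytest.fixture(scope="session")
def clean_count_result(clean_sample, toy_transcriptome):
    sample, gff, _ = clean_sample
    annotation = load_annotation(gff)
    allow = BarcodeAllowList(frozenset(sample.truth.layout.table["barcode"]))
    return count_molecules(sample.sam_path, annotation, mode="genome", allow=allow)
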