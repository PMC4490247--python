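import numpy as np
import pytest

from cassmicro.community import OtuTable, SampleInfo
from cassmicro.synthetic import SyntheticConfig


@pytest.fixture
def toy_table() -> OtuTable:
    """Six samples, five OTUs, with guild-bearing taxonomy and metadata."""
    counts = np.array(
        [
            [40, 10, 5, 0, 0],
            [35, 15, 4, 1, 0],
            [5, 5, 30, 20, 0],
            [4, 6, 28, 22, 0],
            [0, 0, 5, 10, 40],
            [0, 1, 6, 8, 42],
        ]
    )
    sample_ids = ["A1_0-2", "A1_2-4", "A2_0-2", "A2_2-4", "A3_0-2", "A3_2-4"]
    taxonomy = {
        "Otu01": "Bacteria(100);Proteobacteria(99);Gammaproteobacteria(97);"
        "Alteromonadales(95);Shewanellaceae(92);Shewanella(90);",
        "Otu02": "Bacteria(100);Proteobacteria(99);Deltaproteobacteria(98);"
        "Desulfobacterales(96);Desulfobacteraceae(93);Desulfobacter(91);",
        "Otu03": "Bacteria(100);Firmicutes(95);Clostridia(90);Clostridiales(88);"
        "Ruminococcaceae(80);unclassified(60);",
        "Otu04": "Bacteria(100);Chloroflexi(97);Anaerolineae(95);",
        "Otu05": "Bacteria(100);Proteobacteria(98);Deltaproteobacteria(95);"
        "Desulfuromonadales(90);Geobacteraceae(88);Geobacter(85);",
    }
    metadata = {
        sid: SampleInfo(
            site=sid.split("_")[0],
            depth_top_cm=float(sid.split("_")[1].split("-")[0]),
            depth_bottom_cm=float(sid.split("_")[1].split("-")[1]),
        )
        for sid in sample_ids
    }
    return OtuTable(
        sample_ids=sample_ids,
        otu_ids=["Otu01", "Otu02", "Otu03", "Otu04", "Otu05"],
        counts=counts,
        taxonomy=taxonomy,
        metadata=metadata,
    )


@pytest.fixture
def small_synth_cfg() -> SyntheticConfig:
    """A reduced synthetic design that keeps pipeline tests fast."""
    return SyntheticConfig(seed=11, reads_mean=1200.0, reads_dispersion=20.0)
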