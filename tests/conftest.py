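import pytest

from phosprop.design import (
    DesignConfig, PhosphositeAnnotation, ProteinRecord, build_design,
)
from phosprop.ngs import SampleRow, SampleSheet


@pytest.fixture(scope="session")
def config():
    return DesignConfig()


@pytest.fixture(scope="session")
def toy_design(config):
    """Four peptides: two single-site class I, one 2-site class I, one class-none."""
    proteome = [
        ProteinRecord("P1", "GGGGGGGGGGGKRSFTESNV"),   # site T at p-4
        ProteinRecord("P2", "GGGGGGGGGGGRPHTNETSL"),   # class I, site T at p-2
        ProteinRecord("P3", "GGGGGGGGGGGKKSGNTTSL"),   # class I, sites at p-3, p-1
        ProteinRecord("P4", "GGGGGGGGGGGNNNNQSNRG"),   # no PDZbm, site at p-3
    ]
    sites = [
        PhosphositeAnnotation("P1", 16, "T"),
        PhosphositeAnnotation("P2", 18, "T"),
        PhosphositeAnnotation("P3", 17, "T"),
        PhosphositeAnnotation("P3", 19, "S"),
        PhosphositeAnnotation("P4", 17, "S"),
    ]
    return build_design(proteome, sites, config)


@pytest.fixture(scope="session")
def mixed_fixture(tmp_path_factory):
    """The 'mixed' scenario at moderate depth, run once per session."""
    from phosprop.simulate import end_to_end_fixture

    out = tmp_path_factory.mktemp("mixed")
    return end_to_end_fixture("mixed", seed=11, out_dir=out, depth=20_000,
                              replicates=3)


@pytest.fixture
def samplesheet():
    return SampleSheet([
        SampleRow("s1", "AAAAAAAA", "CCCCCC", "PDZ1", 1, "selection"),
        SampleRow("s2", "CCCCCCCC", "GGGGGG", "PDZ1", 2, "selection"),
        SampleRow("s3", "GGGGGGGG", "TTTTTT", "PDZ1", 3, "selection"),
    ])
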