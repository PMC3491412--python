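import pytest
from hypothesis import HealthCheck, settings

from lineage_methylome.annotation import (GenomeAnnotation, apply_detection_filter,
                                          flag_qualifying_probes, map_probes_to_genes)
from lineage_methylome.caller import HypermethylationCaller
from lineage_methylome.synthetic import SynthConfig, generate_dataset

settings.register_profile(
    "deterministic", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 3 types, 40 tumors + 8 normals per type,
    2,000 genes, planted methylation frequency 0.35."""
    return generate_dataset(SynthConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def annotated(default_bundle):
    """Probe-gene map with qualifying flags plus the detection-filtered betas."""
    b = default_bundle
    ann = GenomeAnnotation(tss=b.tss, cgi=b.cgi, probes=b.probes[["chrom", "pos"]])
    pmap = flag_qualifying_probes(map_probes_to_genes(ann), ann)
    beta = apply_detection_filter(b.beta, b.detection_p)
    return pmap, beta


@pytest.fixture(scope="session")
def fitted_caller(default_bundle, annotated):
    pmap, beta = annotated
    return HypermethylationCaller().fit(
        beta, samples=default_bundle.samples, probe_map=pmap)
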