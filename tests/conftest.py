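import numpy as np
import pandas as pd
import pytest

from nodulomics.somatic_filter import FilterConfig, call_somatic_multi_sample
from nodulomics.synthdata import SimConfig, simulate_patient


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A 3-patient cohort with a 3-mutation trunk, small expression panel."""
    return SimConfig(n_patients=3, trunk_mutations=3, n_genes=160, seed=11)


@pytest.fixture(scope="session")
def small_patient(small_config):
    return simulate_patient(small_config, 0)


@pytest.fixture(scope="session")
def small_calls(small_patient):
    return call_somatic_multi_sample(
        small_patient.observations,
        small_patient.annotations,
        FilterConfig(),
        blood_sample=small_patient.blood_sample,
    )


def toy_calls(keys, sample="S"):
    """Call-set DataFrame from (chrom,pos,ref,alt) tuples."""
    return pd.DataFrame(
        [{"chrom": c, "pos": p, "ref": r, "alt": a, "sample": sample, "vaf": 0.4}
         for c, p, r, a in keys],
        columns=["chrom", "pos", "ref", "alt", "sample", "vaf"],
    )
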