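import numpy as np
import pandas as pd
import pytest

from clonemix import (
    AssayKind,
    MarkerDef,
    MeasurementTable,
    SampleMeta,
    SimulationConfig,
    simulate_two_subclone_panel,
)

#: Genes whose integer genotypes are identifiable from the panel (they carry
#: a CN assay); AF-only genes are genotyped under a diploid assumption and
#: are not expected to match the simulator truth.
CN_RESOLVABLE = {
    "LRP1B": ((1, 4), (0, 2)),
    "ERBB4": ((1, 3), (0, 1)),
    "EPHA3": ((0, 4), (0, 2)),
    "EPHA5": ((0, 4), (0, 2)),
    "PTPRD": ((0, 3), (0, 2)),
    "AR": ((0, 2), (0, 4)),
    "EXOC4": ((0, 2), (0, 2)),
    "AKR1B1": ((0, 2), (0, 2)),
}


def make_table(values: dict[str, list[float]], kinds: dict[str, str] | None = None):
    """Small MeasurementTable from a column dict; marker kind from suffix."""
    markers = []
    for mid in values:
        kind = (kinds or {}).get(mid) or ("AF" if mid.endswith("_AF") else "CN")
        markers.append(MarkerDef(mid, mid.rsplit("_", 1)[0], AssayKind(kind)))
    n = len(next(iter(values.values())))
    samples = [SampleMeta(sample_id=f"s{i + 1}") for i in range(n)]
    df = pd.DataFrame(values, index=pd.Index([s.sample_id for s in samples], name="sample_id"))
    return MeasurementTable(markers=markers, samples=samples, values=df)


@pytest.fixture(scope="session")
def noise_free_panel():
    cfg = SimulationConfig(sigma_af=0.0, sigma_cn=0.0, seed=1)
    return simulate_two_subclone_panel(cfg)


@pytest.fixture(scope="session")
def default_panel_seed1():
    return simulate_two_subclone_panel(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
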