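import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import immunoprofiler as ip

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def tiny_panel() -> ip.PanelDefinition:
    """3 endogenous + 2 HK + 3 positive + 1 negative probes."""
    rows = [
        ("GENE1", "Endogenous", "NM_000001.1", 0.0),
        ("GENE2", "Endogenous", "NM_000002.1", 0.0),
        ("GENE3", "Endogenous", "NM_000003.1", 0.0),
        ("HK1", "Housekeeping", "NM_000004.1", 0.0),
        ("HK2", "Housekeeping", "NM_000005.1", 0.0),
        ("POS_A", "Positive", "POS_A", 128.0),
        ("POS_B", "Positive", "POS_B", 32.0),
        ("POS_C", "Positive", "POS_C", 8.0),
        ("NEG_A", "Negative", "NEG_A", 0.0),
    ]
    return ip.PanelDefinition(table=pd.DataFrame(
        rows, columns=["probe", "code_class", "accession", "expected_conc_fM"]))


def make_sample(panel: ip.PanelDefinition, sample_id: str,
                counts: dict[str, int] | None = None, fill: int = 50) -> ip.RawSample:
    all_counts = {p: fill for p in panel.probes}
    if counts:
        all_counts.update(counts)
    return ip.RawSample(sample_id=sample_id, counts=all_counts,
                        lane_attributes={"ID": "1"})


@pytest.fixture(scope="session")
def panel():
    return tiny_panel()


def cohort_expression(config):
    """Run a synthetic cohort through QC, normalization, and log2; return
    (expr restricted to endogenous genes, truth, panel)."""
    samples, panel, truth = ip.simulate.simulate_counts(config)
    cm = ip.assemble_counts(samples, panel)
    _, passed = ip.qc_filter(cm, panel)
    norm = ip.normalize(passed, panel)
    expr = ip.log2_transform(norm)
    expr.data = expr.data.loc[panel.endogenous_probes]
    return expr, truth, panel


@pytest.fixture(scope="session")
def braf_cohort():
    """Three planted immune clusters, n=60, pushed through the full
    preprocessing chain once per session."""
    cfg = ip.simulate.braf_cluster_config(seed=11)
    return cohort_expression(cfg)
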