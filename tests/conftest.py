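import numpy as np
import pandas as pd
import pytest

import zygopeak as z


@pytest.fixture
def panel():
    return z.DEFAULT_PANEL


@pytest.fixture
def small_peak_tsv(tmp_path):
    """One fully amplified sample over the default four-marker panel."""
    text = (
        "Sample\tMarker\tSize\tHeight\tArea\n"
        "S1\t35S_S\t176.0\t820.0\t5300.0\n"
        "S1\tOCS_S\t138.0\t790.0\t5100.0\n"
        "S1\tNPTII-3\t212.0\t760.0\t4900.0\n"
        "S1\tGhUBC1\t156.0\t400.0\t2600.0\n"
    )
    path = tmp_path / "peaks.tsv"
    path.write_text(text)
    return path


def run_calls_on_population(table, truth, config=None):
    """Presence -> normalization -> zygosity calls for one simulated population."""
    config = config or z.CallConfig(method="both")
    height = z.build_trait_matrix(table, "height")
    area = z.build_trait_matrix(table, "area")
    presence = z.call_presence(height, z.DEFAULT_PANEL)
    grouping = truth.set_index("sample_id")["population_id"]
    norm_h = z.normalize_traits(height, z.DEFAULT_PANEL, grouping, "height")
    norm_a = z.normalize_traits(area, z.DEFAULT_PANEL, grouping, "area")
    calls = z.call_zygosity({"height": norm_h, "area": norm_a}, presence, config)
    merged = calls.calls.merge(truth[["sample_id", "genotype"]], on="sample_id")
    return calls, merged


@pytest.fixture
def simulated_calls():
    """A 240-plant 1:2:1 population run through the full calling pipeline."""
    table, truth = z.simulate_population(240, (1, 2, 1), seed=11)
    return run_calls_on_population(table, truth)
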