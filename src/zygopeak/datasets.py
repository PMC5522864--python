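"""Bundled example datasets.

Two tables transcribe published per-population summaries of a cotton
backcross programme in which nine BC1S1 populations (240 plants each,
derived from a transgenic RNAi event crossed to nine cultivars) were
genotyped for transgene zygosity by log-phase PCR:

* ``bc1s1_segregation_counts.tsv`` — transgenic / null / missing plant
  counts per population;
* ``bc1s1_cluster_means.tsv`` — K-means cluster sizes, mean normalized OCS
  peak heights and areas per zygosity class, and the CCC per population.

``bc1s2_families_synthetic.tsv`` is a SYNTHETIC reconstruction of the
selfed-progeny confirmation experiment: family-level progeny counts are not
published, so plausible per-family counts were constructed to be consistent
with the published class-level summaries (20 homozygous-predicted families
of which 19 breed true, 456 progeny; 21 hemizygous-predicted families all
segregating 1:2:1, 488 progeny).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_bc1s1_segregation", "load_bc1s1_cluster_means",
    "load_bc1s2_families", "expand_to_samples",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("zygopeak.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_bc1s1_segregation() -> pd.DataFrame:
    """Per-population transgenic / null / missing counts (nine BC1S1 populations)."""
    return _read("bc1s1_segregation_counts.tsv")


def load_bc1s1_cluster_means() -> pd.DataFrame:
    """Per-population zygosity-cluster sizes, mean normalized OCS traits and CCC."""
    return _read("bc1s1_cluster_means.tsv").set_index("population")


def load_bc1s2_families() -> pd.DataFrame:
    """Synthetic family-level selfed-progeny counts (see module docstring)."""
    return _read("bc1s2_families_synthetic.tsv")


def expand_to_samples(seg: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Expand per-population counts into per-sample presence calls and a sheet.

    Inverse of the aggregation performed by
    :func:`zygopeak.segregation.summarize_populations`: synthesises one
    sample id per plant so count tables can be pushed through the same
    summary code path as real per-sample data.
    """
    presence_rows: dict[str, str] = {}
    sheet_rows = []
    for row in seg.itertuples(index=False):
        i = 0
        for status, n in (("transgenic", row.n_transgenic),
                          ("null", row.n_null), ("missing", row.n_missing)):
            for _ in range(int(n)):
                i += 1
                sid = f"{row.population}-{i:03d}"
                presence_rows[sid] = status
                sheet_rows.append({"sample_id": sid,
                                   "population_id": row.population,
                                   "generation": "BC1S1",
                                   "family_id": "", "parent_prediction": ""})
    presence = pd.Series(presence_rows, name="presence")
    presence.index.name = "sample_id"
    return presence, pd.DataFrame(sheet_rows)
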