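"""Synthetic log-phase PCR peak-table generator with ground truth.

Amplification follows a discrete logistic recursion per marker:

    P_0 = copies * A0,    P_{i+1} = P_i + e * P_i * (1 - P_i / K)

so product grows geometrically by (1 + e) per cycle while far below the
reaction capacity K and plateaus as it approaches K.  In the unsaturated
("log-phase") regime the final product stays proportional to starting
template, which is what makes a 10-cycle program discriminate one transgene
copy (hemizygous) from two (homozygous) at a product ratio of 0.5; by 20-40
cycles both genotypes sit on the plateau and the ratio approaches 1.

Peak height and area are lognormal-noise readouts of the product quantity,
scaled to the RFU ranges typical of capillary electrophoresis.  Noise has
two components: a per-sample amplification factor shared by every marker of
a sample (template amount and quality; removed by reference-gene
normalization) and independent per-peak measurement noise.  With the default
per-peak CV of 8.5% the normalized trait value T = (X/Y)*Z carries noise
from two peaks and its within-genotype CV comes out near 12%.  A
peak is reported only when its noise-free height clears the detection
threshold (five-cycle programs fall below it) and the marker did not suffer
a random amplification failure.  The reference gene is always present at two
copies; transgene markers carry 0, 1 or 2 copies according to genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peak_io import DEFAULT_PANEL, MarkerPanel, PeakTable

__all__ = ["AmpParams", "amplify", "simulate_sample", "simulate_population",
           "simulate_family", "GENOTYPE_COPIES"]

GENOTYPE_COPIES = {"homozygous": 2, "hemizygous": 1, "null": 0}

#: Typical amplicon sizes (bp) used for simulated panels.
_DEFAULT_SIZES = {"35S_S": 176.0, "OCS_S": 138.0, "NPTII-3": 212.0, "GhUBC1": 156.0}

#: Per-marker amplification failure rates: the NPTII target amplifies less
#: consistently than the promoter/terminator targets.
DEFAULT_FAILURE_RATES: Mapping[str, float] = {
    "35S_S": 0.01, "OCS_S": 0.01, "NPTII-3": 0.04, "GhUBC1": 0.01,
}


@dataclass(frozen=True)
class AmpParams:
    """Amplification-kinetics and measurement-noise parameters.

    Defaults emulate an abbreviated 10-cycle log-phase program calibrated so
    noise-free normalized heights land near 800 (homozygous) and 400
    (hemizygous) RFU, normalized within-genotype CV near 12%, and a 50 RFU
    detection threshold that five-cycle products do not reach.
    """

    efficiency: float = 0.9          # per-cycle gain e in (0, 1]
    initial_template: float = 1.0    # A0, product units per template copy
    capacity: float = 1e5            # saturation ceiling K
    cycles: int = 10                 # post-touchdown cycle count n
    detection_threshold: float = 50.0  # minimum height (RFU) for a reported peak
    height_scale: float = 0.65       # RFU per product unit
    area_scale: float = 4.2          # area units per product unit
    noise_cv: float = 0.085          # CV of per-peak multiplicative lognormal noise
    sample_cv: float = 0.15          # CV of the shared per-sample amplification factor
    marker_failure_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAILURE_RATES))
    dilution: float = 1.0            # scales every peak of a sample

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValidationError("efficiency must be in (0, 1]")
        for name in ("initial_template", "capacity", "height_scale",
                     "area_scale", "dilution"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.cycles < 0 or self.noise_cv < 0 or self.sample_cv < 0:
            raise ValidationError("cycles, noise_cv and sample_cv must be non-negative")
        for m, r in dict(self.marker_failure_rates).items():
            if not 0 <= r < 1:
                raise ValidationError(f"failure rate for {m!r} must be in [0, 1)")

    def noiseless(self) -> "AmpParams":
        """Copy with noise, failures and detection threshold switched off."""
        return replace(self, noise_cv=0.0, sample_cv=0.0,
                       marker_failure_rates={}, detection_threshold=0.0)


def amplify(copies: int, params: AmpParams) -> float:
    """Noise-free product quantity after the configured number of cycles.

    Iterates the logistic recursion; zero template yields zero product.
    ``capacity=inf`` gives the exact geometric law copies*A0*(1+e)^n.
    """
    if copies < 0:
        raise ValidationError("copies must be non-negative")
    if copies == 0:
        return 0.0
    p = copies * params.initial_template
    if np.isinf(params.capacity):
        return float(p * (1.0 + params.efficiency) ** params.cycles)
    for _ in range(params.cycles):
        p = p + params.efficiency * p * (1.0 - p / params.capacity)
    return float(p)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    # mean-one lognormal so noise does not bias the expected trait value
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_sample(sample_id: str, genotype: str, panel: MarkerPanel,
                    params: AmpParams, rng: np.random.Generator) -> list[dict]:
    """Peak records for one sample; markers below detection or failed are omitted."""
    if genotype not in GENOTYPE_COPIES:
        raise ValidationError(f"unknown genotype {genotype!r}")
    records = []
    markers = panel.all_markers
    sample_factor = _lognormal_factor(rng, params.sample_cv, 1)[0]
    eps_h = _lognormal_factor(rng, params.noise_cv, len(markers))
    eps_a = _lognormal_factor(rng, params.noise_cv, len(markers))
    fail_draw = rng.random(len(markers))
    for j, marker in enumerate(markers):
        copies = 2 if marker == panel.reference_marker else GENOTYPE_COPIES[genotype]
        product = amplify(copies, params) * params.dilution * sample_factor
        height = params.height_scale * product * eps_h[j]
        area = params.area_scale * product * eps_a[j]
        fail_rate = dict(params.marker_failure_rates).get(marker, 0.0)
        if fail_draw[j] < fail_rate:
            continue
        if params.height_scale * product < params.detection_threshold or product <= 0:
            continue
        size = dict(panel.expected_size_bp).get(marker, _DEFAULT_SIZES.get(marker, 150.0))
        records.append({"sample_id": sample_id, "marker": marker,
                        "size_bp": float(size), "height": float(height),
                        "area": float(area)})
    return records


def _assemble(records: list[dict], truth_rows: list[dict],
              panel: MarkerPanel) -> tuple[PeakTable, pd.DataFrame]:
    table = PeakTable(
        records=pd.DataFrame(records, columns=["sample_id", "marker", "size_bp",
                                               "height", "area"]),
        panel=panel)
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "genotype",
                                              "population_id", "family_id"])
    return table, truth


def simulate_population(
    n: int,
    genotype_ratio: Sequence[float] = (1.0, 2.0, 1.0),
    panel: MarkerPanel = DEFAULT_PANEL,
    params: AmpParams = AmpParams(),
    seed: int = 0,
    population_id: str = "pop1",
) -> tuple[PeakTable, pd.DataFrame]:
    """Simulate a segregating population with ground-truth genotypes.

    Genotypes (homozygous : hemizygous : null) are drawn multinomially from
    ``genotype_ratio``.  Identical seeds reproduce byte-identical tables.
    Returns the peak table and a truth DataFrame (sample_id, genotype,
    population_id, family_id).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    ratio = np.asarray(genotype_ratio, dtype=float)
    if ratio.size != 3 or (ratio < 0).any() or ratio.sum() <= 0:
        raise ValidationError("genotype_ratio must be 3 non-negative numbers")
    rng = np.random.default_rng(seed)
    genos = rng.choice(["homozygous", "hemizygous", "null"], size=n,
                       p=ratio / ratio.sum())
    width = len(str(n))
    records, truth_rows = [], []
    for i, g in enumerate(genos, start=1):
        sid = f"{population_id}-{i:0{width}d}"
        records.extend(simulate_sample(sid, g, panel, params, rng))
        truth_rows.append({"sample_id": sid, "genotype": g,
                           "population_id": population_id, "family_id": ""})
    return _assemble(records, truth_rows, panel)


def simulate_family(
    parent_genotype: str,
    size: int,
    panel: MarkerPanel = DEFAULT_PANEL,
    params: AmpParams = AmpParams(),
    seed: int = 0,
    family_id: str = "fam1",
    population_id: str = "selfed",
) -> tuple[PeakTable, pd.DataFrame]:
    """Simulate selfed progeny of one parent.

    A homozygous parent breeds true; a hemizygous parent throws 1:2:1
    homozygous : hemizygous : null progeny.
    """
    if parent_genotype not in ("homozygous", "hemizygous"):
        raise ValidationError("parent_genotype must be homozygous or hemizygous")
    if size < 1:
        raise ValidationError("size must be >= 1")
    rng = np.random.default_rng(seed)
    if parent_genotype == "homozygous":
        genos = np.repeat("homozygous", size)
    else:
        genos = rng.choice(["homozygous", "hemizygous", "null"], size=size,
                           p=[0.25, 0.5, 0.25])
    width = len(str(size))
    records, truth_rows = [], []
    for i, g in enumerate(genos, start=1):
        sid = f"{family_id}-{i:0{width}d}"
        records.extend(simulate_sample(sid, str(g), panel, params, rng))
        truth_rows.append({"sample_id": sid, "genotype": str(g),
                           "population_id": population_id, "family_id": family_id})
    return _assemble(records, truth_rows, panel)
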