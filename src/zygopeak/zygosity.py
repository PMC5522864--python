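"""Transgene presence and zygosity calling.

A sample is *transgenic* when every transgene marker and the reference gene
amplified, *null* when only the reference amplified, and *missing* otherwise
(reference failure or partial transgene amplification).

Within each population the transgenic samples are split into homozygous (AA,
two transgene copies) and hemizygous (AB, one copy) classes.  Under log-phase
PCR the homozygous class yields roughly twice the normalized product of the
hemizygous class, so the population distribution of normalized trait values
is a mixture of two modes.  Two split methods are implemented:

* the bimodal "pit": the valley of minimum kernel-density between the two
  highest density modes is the natural split point;
* one-dimensional K-means with k = 2, solved exactly by exhaustive search
  over the n-1 contiguous splits of the sorted values (the 1-D optimum is
  always a contiguous partition).  Cluster support is evaluated with Sarle's
  Cubic Clustering Criterion (CCC >= 2 indicates well-supported clusters)
  and the Tukey-Kramer HSD test between the two cluster means.

Populations whose distribution does not support a split (no pit, or CCC
below threshold) are flagged and their transgenic samples are left
'unresolved' rather than being forced into AA/AB classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import DegenerateInputError, StateError, ValidationError
from .normalization import NormalizedTraitTable
from .peak_io import MarkerPanel

__all__ = [
    "CallConfig", "BimodalSplit", "KMeansResult", "HSDResult",
    "PopulationClusterStats", "ZygosityCallSet", "Concordance",
    "call_presence", "find_pit", "split_by_pit", "kmeans_1d",
    "lloyd_kmeans_1d", "compute_ccc", "tukey_kramer", "call_zygosity",
    "concordance",
]

HOMOZYGOUS = "AA"
HEMIZYGOUS = "AB"


@dataclass(frozen=True)
class CallConfig:
    """Configuration for zygosity calling.

    marker/trait select which normalized values drive the split (OCS
    terminator peak height by default — the marker/trait combination that
    gives the cleanest bimodal separation).  method is 'kmeans', 'pit' or
    'both' ('both' uses K-means for the final call and records both).
    """

    marker: str = "OCS_S"
    trait: str = "height"
    method: str = "kmeans"
    min_samples: int = 20
    kde_grid: int = 512
    bandwidth_rule: str = "silverman"
    min_prominence_frac: float = 0.05
    alpha: float = 0.05
    ccc_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.method not in ("pit", "kmeans", "both"):
            raise ValidationError(f"unknown method {self.method!r}")


def call_presence(matrix: pd.DataFrame, panel: MarkerPanel) -> pd.Series:
    """Classify each sample as transgenic / null / missing.

    ``matrix`` is a trait matrix (NaN = marker absent).  Transgenic requires
    every transgene marker plus the reference; null requires the reference
    only; anything else — reference failure or partial transgene
    amplification — is missing.
    """
    present = matrix.notna()
    ref = present[panel.reference_marker]
    tg = present[list(panel.transgene_markers)]
    status = pd.Series("missing", index=matrix.index, name="presence")
    status[ref & tg.all(axis=1)] = "transgenic"
    status[ref & ~tg.any(axis=1)] = "null"
    return status


# ---------------------------------------------------------------------------
# bimodal pit split

@dataclass
class BimodalSplit:
    """Kernel-density description of a (possibly) bimodal distribution."""

    mode_locations: tuple[float, float] | None
    mode_densities: tuple[float, float] | None
    pit_location: float | None
    pit_density: float | None
    bandwidth: float
    is_bimodal: bool
    grid: np.ndarray = field(repr=False, default=None)
    density: np.ndarray = field(repr=False, default=None)


def _silverman_bandwidth(values: np.ndarray) -> float:
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * values.size ** (-1 / 5)


def find_pit(values: Iterable[float], min_samples: int = 20,
             grid_size: int = 512, min_prominence_frac: float = 0.05) -> BimodalSplit:
    """Locate the density valley ("pit") between the two modes, if any.

    A Gaussian KDE with Silverman's bandwidth 0.9*min(sd, IQR/1.34)*n^(-1/5)
    is evaluated on a fixed grid over [min, max].  If at least two local
    maxima (with prominence >= min_prominence_frac of the density maximum)
    exist, the two of highest density are the modes and the pit is the grid
    point of minimum density strictly between them.
    """
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size < min_samples:
        raise ValidationError(
            f"find_pit needs >= {min_samples} finite values, got {arr.size}")
    if arr.std(ddof=1) == 0:
        raise DegenerateInputError("zero variance: no density structure to split")

    h = _silverman_bandwidth(arr)
    grid = np.linspace(arr.min(), arr.max(), grid_size)
    kde = stats.gaussian_kde(arr, bw_method=h / arr.std(ddof=1))
    dens = kde(grid)

    # pad with -inf so modes sitting on the grid boundary (e.g. tight
    # clusters at the data extremes) register as local maxima
    padded = np.concatenate([[-np.inf], dens, [-np.inf]])
    peaks, _ = signal.find_peaks(padded, prominence=min_prominence_frac * dens.max())
    peaks = peaks - 1
    if len(peaks) < 2:
        return BimodalSplit(None, None, None, None, h, False, grid, dens)

    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = sorted(top2)
    between = slice(lo + 1, hi)
    pit_idx = lo + 1 + int(np.argmin(dens[between]))
    m1, m2 = sorted((grid[lo], grid[hi]))
    d1, d2 = (dens[lo], dens[hi]) if grid[lo] == m1 else (dens[hi], dens[lo])
    return BimodalSplit(
        mode_locations=(float(m1), float(m2)),
        mode_densities=(float(d1), float(d2)),
        pit_location=float(grid[pit_idx]),
        pit_density=float(dens[pit_idx]),
        bandwidth=h, is_bimodal=True, grid=grid, density=dens,
    )


def split_by_pit(values: Iterable[float], split: BimodalSplit) -> np.ndarray:
    """Assign AA (above the pit) / AB (at or below the pit) labels.

    Values exactly at the pit go to the hemizygous class — the larger
    expected class in a 1:2:1 population, minimising expected misassignment.
    """
    if not split.is_bimodal:
        raise StateError("split_by_pit requires a bimodal split")
    arr = np.asarray(list(values), dtype=float)
    return np.where(arr > split.pit_location, HOMOZYGOUS, HEMIZYGOUS)


# ---------------------------------------------------------------------------
# 1-D K-means (k = 2)

@dataclass
class KMeansResult:
    """Two-cluster 1-D K-means outcome, oriented so AA has the larger centroid."""

    assignments: np.ndarray  # AA / AB per input value
    centroids: tuple[float, float]  # (AB centroid, AA centroid)
    n_per_cluster: tuple[int, int]  # (n_AB, n_AA)
    within_ss: float
    total_ss: float
    r_squared: float
    ccc: float | None = None


def _partition_result(values: np.ndarray, right_mask: np.ndarray) -> KMeansResult:
    left, right = values[~right_mask], values[right_mask]
    m_left, m_right = left.mean(), right.mean()
    wss = float(((left - m_left) ** 2).sum() + ((right - m_right) ** 2).sum())
    tss = float(((values - values.mean()) ** 2).sum())
    labels = np.where(right_mask, HOMOZYGOUS, HEMIZYGOUS)
    return KMeansResult(
        assignments=labels,
        centroids=(float(m_left), float(m_right)),
        n_per_cluster=(int(left.size), int(right.size)),
        within_ss=wss, total_ss=tss,
        r_squared=1.0 - wss / tss,
    )


def kmeans_1d(values: Iterable[float], k: int = 2) -> KMeansResult:
    """Globally optimal two-cluster split by exhaustive threshold search.

    In one dimension the optimal k-means partition is contiguous in sorted
    order, so scanning the n-1 split points with prefix sums finds the exact
    minimum within-cluster sum of squares.
    """
    if k != 2:
        raise ValidationError("only k = 2 is supported")
    arr = np.sort(np.asarray(list(values), dtype=float))
    n = arr.size
    if n < 2 or arr[0] == arr[-1]:
        raise DegenerateInputError("k-means needs >= 2 distinct values")

    csum = np.cumsum(arr)
    csq = np.cumsum(arr ** 2)
    i = np.arange(1, n)  # left cluster = arr[:i]
    left_ss = csq[i - 1] - csum[i - 1] ** 2 / i
    right_sum = csum[-1] - csum[i - 1]
    right_ss = (csq[-1] - csq[i - 1]) - right_sum ** 2 / (n - i)
    wss = left_ss + right_ss
    split = int(i[np.argmin(wss)])

    order = np.argsort(np.asarray(list(values), dtype=float), kind="mergesort")
    right_mask = np.zeros(n, dtype=bool)
    right_mask[order[split:]] = True
    return _partition_result(np.asarray(list(values), dtype=float), right_mask)


def lloyd_kmeans_1d(values: Iterable[float], max_iter: int = 200) -> KMeansResult:
    """Lloyd iteration with deterministic centroids at the 10th/90th percentiles.

    Provided as the classical iterative route; its fixed point coincides with
    the exhaustive optimum on well-separated data and is checked against it
    in the test suite.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2 or np.ptp(arr) == 0:
        raise DegenerateInputError("k-means needs >= 2 distinct values")
    c = np.percentile(arr, [10, 90]).astype(float)
    if c[0] == c[1]:
        c = np.array([arr.min(), arr.max()], dtype=float)
    for _ in range(max_iter):
        right = np.abs(arr - c[1]) < np.abs(arr - c[0])  # ties -> lower cluster
        if right.all() or (~right).all():
            # one cluster emptied; reseed at extremes
            right = arr > np.median(arr)
        new = np.array([arr[~right].mean(), arr[right].mean()])
        if np.allclose(new, c):
            break
        c = new
    return _partition_result(arr, right)


# ---------------------------------------------------------------------------
# Cubic Clustering Criterion (Sarle), specialised to 1-D, q = 2

def expected_r_squared(n: int, q: int = 2) -> float:
    """E(R^2) under the uniform null for q clusters of n points in 1-D.

    Specialisation of Sarle's general formula: with one dimension the
    hypercube edge scaling gives u = q, so
    E(R^2) = 1 - [((n-q)^2 / n) (1 + 4/n)] / [(n + q) q^2].
    As n grows this approaches 1 - 1/q^2 (0.75 for q = 2), the R^2 of an
    equal split of a uniform distribution.
    """
    u = float(q)
    return 1.0 - ((n - q) ** 2 / n) * (1.0 + 4.0 / n) / ((n + u) * u * u)


def compute_ccc(result: KMeansResult, n: int | None = None, p: int = 1) -> float:
    """Sarle's Cubic Clustering Criterion for a two-cluster 1-D solution.

    CCC = ln[(1 - E(R^2)) / (1 - R^2)] * sqrt(n p / 2) / (0.001 + E(R^2))^1.2.
    Zero when R^2 equals its uniform-null expectation, positive when the
    observed clustering is tighter, negative when looser.  Values >= 2 are
    taken as evidence of well-supported clusters.
    """
    if p != 1:
        raise ValidationError("only p = 1 (univariate) is supported")
    if n is None:
        n = int(result.assignments.size)
    if n < 4:
        raise ValidationError("CCC needs n >= 4")
    r2 = result.r_squared
    e_r2 = expected_r_squared(n, q=2)
    if r2 >= 1.0:
        warnings.warn("R^2 = 1: clusters are exact point masses; CCC is infinite")
        return float("inf")
    return float(np.log((1.0 - e_r2) / (1.0 - r2))
                 * np.sqrt(n * p / 2.0) / (0.001 + e_r2) ** 1.2)


# ---------------------------------------------------------------------------
# Tukey-Kramer HSD for the two K-means groups

@dataclass
class HSDResult:
    group_means: tuple[float, float]
    q_statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float = 0.05


def tukey_kramer(group_a: Iterable[float], group_b: Iterable[float],
                 alpha: float = 0.05) -> HSDResult:
    """Tukey-Kramer honestly-significant-difference test for two groups.

    q = |mean_a - mean_b| / sqrt((MSW/2)(1/n_a + 1/n_b)) with MSW the pooled
    within-group mean square and df = n_a + n_b - 2.  With only two groups
    the studentized range reduces to q = t * sqrt(2), so the p-value comes
    from the two-sided t distribution.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    df = a.size + b.size - 2
    msw = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if msw == 0:
        raise DegenerateInputError("zero pooled within-group variance")
    se = np.sqrt((msw / 2.0) * (1.0 / a.size + 1.0 / b.size))
    q = abs(a.mean() - b.mean()) / se
    p = 2.0 * stats.t.sf(q / np.sqrt(2.0), df)
    return HSDResult(
        group_means=(float(a.mean()), float(b.mean())),
        q_statistic=float(q), df=int(df), p_value=float(min(p, 1.0)),
        significant=bool(p < alpha), alpha=alpha,
    )


# ---------------------------------------------------------------------------
# population-level calling

@dataclass
class PopulationClusterStats:
    """Per-population diagnostics for the configured marker/trait."""

    population_id: str
    n_transgenic: int
    split: BimodalSplit | None = None
    kmeans: KMeansResult | None = None
    ccc: float | None = None
    hsd: HSDResult | None = None
    flags: tuple[str, ...] = ()


@dataclass
class ZygosityCallSet:
    """Per-sample calls plus per-population clustering diagnostics.

    ``calls`` columns: sample_id, population_id, presence, pit_call,
    kmeans_call, final_call, normalized_height, normalized_area, concordant.
    final_call is homozygous/hemizygous for resolved transgenic samples,
    null/missing from presence, or 'unresolved' when the population's
    distribution did not support a split under the configured method.
    """

    calls: pd.DataFrame
    population_stats: dict[str, PopulationClusterStats]
    config: CallConfig

    def __len__(self) -> int:
        return len(self.calls)

    def counts(self, population_id: str | None = None) -> tuple[int, int, int]:
        """(n_homozygous, n_hemizygous, n_null) for segregation testing."""
        df = self.calls
        if population_id is not None:
            df = df[df["population_id"] == population_id]
        fc = df["final_call"]
        return (int((fc == "homozygous").sum()),
                int((fc == "hemizygous").sum()),
                int((fc == "null").sum()))


@dataclass
class Concordance:
    n_agree: int
    n_disagree: int
    fraction_agree: float


_LABEL_TO_CALL = {HOMOZYGOUS: "homozygous", HEMIZYGOUS: "hemizygous"}


def call_zygosity(
    normalized: NormalizedTraitTable | Mapping[str, NormalizedTraitTable],
    presence: pd.Series,
    config: CallConfig = CallConfig(),
) -> ZygosityCallSet:
    """Split transgenic samples into zygosity classes, population by population.

    ``normalized`` is the NormalizedTraitTable for the calling trait, or a
    mapping {trait name: table} (extra traits are carried through to the
    output columns).  ``presence`` is the Series from :func:`call_presence`.
    Pit and K-means splits run on each population's transgenic samples; the
    final call comes from the configured method, gated on split support
    (pit: bimodality; K-means: CCC >= threshold).
    """
    tables = dict(normalized) if isinstance(normalized, Mapping) else {
        normalized.trait: normalized}
    if config.trait not in tables:
        raise ValidationError(f"no normalized table for trait {config.trait!r}")
    main = tables[config.trait]
    t_main = main.values_for(config.marker)
    groups = main.groups()

    aux: dict[str, pd.Series] = {}
    for name in ("height", "area"):
        if name in tables:
            aux[name] = tables[name].values_for(config.marker)

    calls = pd.DataFrame({
        "sample_id": t_main.index,
        "population_id": groups.reindex(t_main.index).values,
        "presence": presence.reindex(t_main.index).values,
    })
    calls["pit_call"] = pd.Series(np.nan, index=calls.index, dtype=object)
    calls["kmeans_call"] = pd.Series(np.nan, index=calls.index, dtype=object)
    calls["final_call"] = calls["presence"].map(
        {"null": "null", "missing": "missing"}).fillna("unresolved")
    calls["normalized_height"] = aux.get(
        "height", pd.Series(dtype=float)).reindex(t_main.index).values
    calls["normalized_area"] = aux.get(
        "area", pd.Series(dtype=float)).reindex(t_main.index).values
    calls = calls.set_index("sample_id", drop=False)

    stats_by_pop: dict[str, PopulationClusterStats] = {}
    n_called_pops = 0
    for pop, pop_calls in calls.groupby("population_id", sort=True):
        tg = pop_calls.index[pop_calls["presence"] == "transgenic"]
        vals = t_main.reindex(tg).dropna()
        pstat = PopulationClusterStats(population_id=str(pop),
                                       n_transgenic=int(vals.size))
        flags: list[str] = []
        if vals.size < config.min_samples:
            flags.append("too_few_transgenic")
            pstat.flags = tuple(flags)
            stats_by_pop[str(pop)] = pstat
            continue
        n_called_pops += 1

        # pit split
        try:
            split = find_pit(vals, min_samples=config.min_samples,
                             grid_size=config.kde_grid,
                             min_prominence_frac=config.min_prominence_frac)
        except DegenerateInputError:
            split = None
            flags.append("degenerate_distribution")
        pstat.split = split
        if split is not None and split.is_bimodal:
            labels = split_by_pit(vals, split)
            calls.loc[vals.index, "pit_call"] = labels
        else:
            flags.append("not_bimodal")

        # K-means split
        try:
            km = kmeans_1d(vals)
            km = replace(km, ccc=compute_ccc(km, n=vals.size))
            pstat.kmeans = km
            pstat.ccc = km.ccc
            calls.loc[vals.index, "kmeans_call"] = km.assignments
            ab = vals.values[km.assignments == HEMIZYGOUS]
            aa = vals.values[km.assignments == HOMOZYGOUS]
            if ab.size >= 2 and aa.size >= 2:
                try:
                    pstat.hsd = tukey_kramer(ab, aa, alpha=config.alpha)
                except DegenerateInputError:
                    pass
            if km.ccc < config.ccc_threshold:
                flags.append("ccc_below_threshold")
        except DegenerateInputError:
            flags.append("kmeans_degenerate")

        # final call from the configured method, gated on split support
        method = "kmeans" if config.method == "both" else config.method
        if method == "pit" and split is not None and split.is_bimodal:
            final_labels = calls.loc[vals.index, "pit_call"]
        elif (method == "kmeans" and pstat.kmeans is not None
              and pstat.ccc is not None and pstat.ccc >= config.ccc_threshold):
            final_labels = calls.loc[vals.index, "kmeans_call"]
        else:
            final_labels = None
            flags.append("unresolved_population")
        if final_labels is not None:
            calls.loc[vals.index, "final_call"] = final_labels.map(_LABEL_TO_CALL)
        pstat.flags = tuple(flags)
        stats_by_pop[str(pop)] = pstat

    if n_called_pops == 0:
        raise ValidationError(
            f"no population has >= {config.min_samples} transgenic samples")

    both = calls["pit_call"].notna() & calls["kmeans_call"].notna()
    calls["concordant"] = pd.Series(np.nan, index=calls.index, dtype=object)
    calls.loc[both, "concordant"] = (
        calls.loc[both, "pit_call"] == calls.loc[both, "kmeans_call"])
    return ZygosityCallSet(calls=calls.reset_index(drop=True),
                           population_stats=stats_by_pop, config=config)


def concordance(calls: ZygosityCallSet) -> Concordance:
    """Agreement between the pit and K-means splits over samples with both calls."""
    df = calls.calls
    both = df["pit_call"].notna() & df["kmeans_call"].notna()
    n_both = int(both.sum())
    n_disagree = int((df.loc[both, "pit_call"] != df.loc[both, "kmeans_call"]).sum())
    frac = 1.0 - n_disagree / n_both if n_both else float("nan")
    return Concordance(n_agree=n_both - n_disagree, n_disagree=n_disagree,
                       fraction_agree=frac)
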