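"""Mendelian segregation tests and selfed-family zygosity confirmation.

A single-locus transgene in a selfed hemizygous background segregates 3:1
transgenic:null, or 1:2:1 homozygous:hemizygous:null when zygosity is
resolved.  Goodness of fit is tested with both the Pearson chi-square and
the likelihood-ratio G statistic; a ratio "fits" only when both tests accept
(conservative conjunction — no combination rule is standard here).

Parental zygosity predictions are confirmed from selfed-progeny families: a
predicted homozygote must breed true (no nulls, no detectable hemizygous
class), a predicted hemizygote must throw a 1:2:1 progeny ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError, ValidationError
from .zygosity import CallConfig, ZygosityCallSet, find_pit

__all__ = [
    "SegregationTest", "FamilyConfirmation", "chisq_gof", "classify_family",
    "confirm_families", "confirmation_summary", "summarize_populations",
    "cluster_means_table", "with_average_row",
]

RATIO_3_1 = (3.0, 1.0)
RATIO_1_2_1 = (1.0, 2.0, 1.0)


@dataclass
class SegregationTest:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    expected: tuple[float, ...]
    pearson_chi2: float
    g_statistic: float
    df: int
    p_pearson: float
    p_g: float
    alpha: float
    fits: bool


def chisq_gof(observed: Sequence[int], ratio: Sequence[float],
              alpha: float = 0.05) -> SegregationTest:
    """Pearson chi-square and likelihood-ratio G goodness-of-fit tests.

    Expected counts are total * ratio_i / sum(ratio); df = classes - 1; no
    continuity correction.  Zero observed cells contribute 0 to G
    (0*ln(0) = 0).
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.size != rat.size or obs.size < 2:
        raise ValidationError("observed and ratio must have equal length >= 2")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValidationError("observed must be non-negative integer counts")
    if (rat <= 0).any():
        raise ValidationError("ratio entries must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValidationError("total count must be positive")
    expected = total * rat / rat.sum()

    chi2, p_pearson = stats.chisquare(obs, expected)
    g, p_g = stats.power_divergence(obs, expected, lambda_="log-likelihood")
    return SegregationTest(
        observed=tuple(int(o) for o in obs),
        expected_ratio=tuple(float(r) for r in rat),
        expected=tuple(float(e) for e in expected),
        pearson_chi2=float(chi2), g_statistic=float(g),
        df=obs.size - 1, p_pearson=float(p_pearson), p_g=float(p_g),
        alpha=alpha, fits=bool(min(p_pearson, p_g) >= alpha),
    )


@dataclass
class FamilyConfirmation:
    family_id: str
    parent_prediction: str  # homozygous | hemizygous
    progeny_counts: tuple[int, int, int]  # (n_homozygous, n_hemizygous, n_null)
    confirmed: bool
    test: SegregationTest | None = None


def classify_family(progeny_counts: Sequence[int], prediction: str,
                    alpha: float = 0.05, family_id: str = "",
                    values: Iterable[float] | None = None,
                    min_progeny: int = 8,
                    config: CallConfig = CallConfig()) -> FamilyConfirmation:
    """Confirm or reject a parental zygosity prediction from selfed progeny.

    ``progeny_counts`` is (n_homozygous, n_hemizygous, n_null).  A homozygous
    prediction is confirmed iff no nulls occur and no hemizygous class is
    detected (by the counts, and — when the family's normalized trait
    ``values`` are supplied — by the absence of a bimodal split).  A
    hemizygous prediction is confirmed iff the counts fit 1:2:1.
    """
    if prediction not in ("homozygous", "hemizygous"):
        raise ValidationError(f"unknown prediction {prediction!r}")
    counts = tuple(int(c) for c in progeny_counts)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise ValidationError("progeny_counts must be 3 non-negative integers")
    if sum(counts) < min_progeny:
        raise ValidationError(
            f"family {family_id or '?'}: needs >= {min_progeny} scored progeny")

    if prediction == "homozygous":
        hem_detected = counts[1] > 0
        if values is not None:
            arr = [v for v in values if np.isfinite(v)]
            if len(arr) >= config.min_samples:
                hem_detected = find_pit(
                    arr, min_samples=config.min_samples,
                    grid_size=config.kde_grid,
                    min_prominence_frac=config.min_prominence_frac).is_bimodal
        confirmed = counts[2] == 0 and not hem_detected
        test = None
    else:
        test = chisq_gof(counts, RATIO_1_2_1, alpha=alpha)
        confirmed = test.fits
    return FamilyConfirmation(family_id=family_id, parent_prediction=prediction,
                              progeny_counts=counts, confirmed=confirmed,
                              test=test)


def confirm_families(calls: ZygosityCallSet, sheet: pd.DataFrame,
                     alpha: float = 0.05, min_progeny: int = 8,
                     ) -> list[FamilyConfirmation]:
    """Run :func:`classify_family` for every selfed family in the sample sheet.

    Families are sheet rows with generation BC1S2, grouped by family_id;
    the parent prediction is taken from the sheet.  Progeny counts come from
    the call set's final calls; the family's normalized calling-trait values
    feed the bimodality check for homozygous predictions.
    """
    df = calls.calls.set_index("sample_id")
    fam_sheet = sheet[sheet["generation"] == "BC1S2"]
    out: list[FamilyConfirmation] = []
    trait_col = ("normalized_height" if calls.config.trait == "height"
                 else "normalized_area")
    for fam, rows in fam_sheet.groupby("family_id", sort=True):
        preds = set(rows["parent_prediction"]) - {""}
        if len(preds) != 1:
            raise ValidationError(
                f"family {fam!r} needs exactly one parent prediction, got {preds}")
        ids = [s for s in rows["sample_id"] if s in df.index]
        sub = df.loc[ids]
        # transgenic progeny left 'unresolved' form a single cluster (the
        # family's split was unsupported); as one class they count as
        # homozygous and the bimodality check below arbitrates
        n_single = int(((sub["final_call"] == "unresolved")
                        & (sub["presence"] == "transgenic")).sum())
        counts = (int((sub["final_call"] == "homozygous").sum()) + n_single,
                  int((sub["final_call"] == "hemizygous").sum()),
                  int((sub["final_call"] == "null").sum()))
        tg_vals = sub.loc[sub["presence"] == "transgenic", trait_col]
        out.append(classify_family(
            counts, preds.pop(), alpha=alpha, family_id=str(fam),
            values=tg_vals.values, min_progeny=min_progeny,
            config=calls.config))
    return out


def confirmation_summary(families: Sequence[FamilyConfirmation]) -> pd.DataFrame:
    """Per-prediction confirmation rates and mean progeny class counts.

    One row per prediction class with n_families, n_confirmed,
    percent_confirmed and the mean number of homozygous / hemizygous / null
    progeny per family.
    """
    if not families:
        raise ValidationError("need at least one family")
    rows = pd.DataFrame({
        "prediction": [f.parent_prediction for f in families],
        "confirmed": [f.confirmed for f in families],
        "n_homozygous": [f.progeny_counts[0] for f in families],
        "n_hemizygous": [f.progeny_counts[1] for f in families],
        "n_null": [f.progeny_counts[2] for f in families],
    })
    out = rows.groupby("prediction").agg(
        n_families=("confirmed", "size"),
        n_confirmed=("confirmed", "sum"),
        mean_homozygous=("n_homozygous", "mean"),
        mean_hemizygous=("n_hemizygous", "mean"),
        mean_null=("n_null", "mean"),
    )
    out["percent_confirmed"] = 100.0 * out["n_confirmed"] / out["n_families"]
    return out


def summarize_populations(presence: pd.Series, calls: ZygosityCallSet | None,
                          sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-population presence and zygosity counts, with an exact Total row.

    Every sample with a presence call must appear in the sample sheet.
    Columns: n_transgenic, n_null, n_missing, n_total, n_homozygous,
    n_hemizygous, plus ccc when a call set is given.
    """
    pops = sheet.set_index("sample_id")["population_id"]
    absent = [s for s in presence.index if s not in pops.index]
    if absent:
        raise IntegrityError(
            f"sample(s) missing from sample sheet: {', '.join(sorted(absent)[:5])}")
    df = pd.DataFrame({"presence": presence,
                       "population_id": pops.reindex(presence.index)})
    tab = df.groupby("population_id")["presence"].value_counts().unstack(fill_value=0)
    for col in ("transgenic", "null", "missing"):
        if col not in tab.columns:
            tab[col] = 0
    out = pd.DataFrame({
        "n_transgenic": tab["transgenic"],
        "n_null": tab["null"],
        "n_missing": tab["missing"],
    })
    out["n_total"] = out.sum(axis=1)

    out["n_homozygous"] = 0
    out["n_hemizygous"] = 0
    if calls is not None:
        for pop in out.index:
            n_hom, n_hem, _ = calls.counts(str(pop))
            out.loc[pop, ["n_homozygous", "n_hemizygous"]] = (n_hom, n_hem)
        out["ccc"] = [
            calls.population_stats[str(p)].ccc
            if str(p) in calls.population_stats else np.nan
            for p in out.index]

    total = out.sum(axis=0)
    if "ccc" in out.columns:
        total["ccc"] = np.nan
    out.loc["Total"] = total
    count_cols = ["n_transgenic", "n_null", "n_missing", "n_total",
                  "n_homozygous", "n_hemizygous"]
    out[count_cols] = out[count_cols].astype(int)
    out.index.name = "population_id"
    return out


def cluster_means_table(calls: ZygosityCallSet) -> pd.DataFrame:
    """Per-population cluster sizes and mean normalized traits per zygosity class.

    Columns: n_homozygous, homozygous_height, homozygous_area, n_hemizygous,
    hemizygous_height, hemizygous_area, ccc.  Means are over samples given
    the respective final call.
    """
    df = calls.calls
    rows = {}
    for pop, sub in df.groupby("population_id", sort=True):
        hom = sub[sub["final_call"] == "homozygous"]
        hem = sub[sub["final_call"] == "hemizygous"]
        pstat = calls.population_stats.get(str(pop))
        rows[str(pop)] = {
            "n_homozygous": len(hom),
            "homozygous_height": hom["normalized_height"].mean(),
            "homozygous_area": hom["normalized_area"].mean(),
            "n_hemizygous": len(hem),
            "hemizygous_height": hem["normalized_height"].mean(),
            "hemizygous_area": hem["normalized_area"].mean(),
            "ccc": pstat.ccc if pstat else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "population_id"
    return out


def with_average_row(table: pd.DataFrame, label: str = "Average") -> pd.DataFrame:
    """Append the unweighted column mean across populations as a final row."""
    out = table.copy()
    out.loc[label] = table.mean(axis=0, numeric_only=True)
    return out
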