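"""Trait normalization against the single-copy reference gene.

Each transgene-marker trait value X (peak height or area) is rescaled by the
same sample's reference-gene value Y and the normalization group's median
reference value Z:

    T = (X / Y) * Z

Dividing by Y removes per-sample amplification and loading effects (template
quality, injection variation, dilution); multiplying by the group median Z
restores the values to the original trait scale.  The median, not the mean,
is used because trait distributions in segregating populations are not
normal.  One Z is computed per normalization group (by default, per
population) and per trait.

Samples without a detected reference product cannot be normalized; their T
values are left unset and the sample is flagged for the "missing" class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peak_io import MarkerPanel

__all__ = ["NormalizedTraitTable", "population_median", "normalize_traits"]


def population_median(values: Iterable[float]) -> float:
    """Median of positive trait values.

    Middle order statistic for odd counts; mean of the two middle order
    statistics for even counts (the usual convention).
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValidationError("population_median needs at least one finite value")
    return float(np.median(arr))


@dataclass
class NormalizedTraitTable:
    """Long-format table of normalized trait values.

    ``data`` columns: sample_id, group_id, marker, X (raw transgene value),
    Y (raw reference value), Z (group median reference value), T
    (normalized value, NaN when X or Y is absent).  ``missing_reference``
    lists samples with no detected reference product.
    """

    data: pd.DataFrame
    trait: str
    group_medians: pd.Series  # Z per group_id
    missing_reference: tuple[str, ...]

    def values_for(self, marker: str, finite_only: bool = False) -> pd.Series:
        """T values for one marker, indexed by sample id."""
        sub = self.data[self.data["marker"] == marker]
        s = sub.set_index("sample_id")["T"]
        return s.dropna() if finite_only else s

    def groups(self) -> pd.Series:
        """group_id per sample id."""
        return self.data.drop_duplicates("sample_id").set_index("sample_id")["group_id"]


def normalize_traits(
    matrix: pd.DataFrame,
    panel: MarkerPanel,
    grouping: Mapping[str, str] | pd.Series,
    trait: str = "height",
) -> NormalizedTraitTable:
    """Apply T = (X/Y)*Z to every (sample, transgene marker) cell of ``matrix``.

    ``matrix`` is a trait matrix from :func:`zygopeak.peak_io.build_trait_matrix`
    (samples x panel markers, NaN = absent).  ``grouping`` maps every sample to
    its normalization group; Z is the median of the group's finite reference
    values.  A group with no finite reference value raises ValidationError.
    """
    grouping = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    missing_group = [s for s in matrix.index if s not in grouping.index]
    if missing_group:
        raise ValidationError(
            f"grouping does not cover sample(s): {', '.join(sorted(missing_group)[:5])}")
    groups = grouping.reindex(matrix.index)

    y = matrix[panel.reference_marker]
    medians = {}
    for gid, idx in matrix.groupby(groups).groups.items():
        ref = y.loc[idx]
        ref = ref[np.isfinite(ref)]
        if ref.empty:
            raise ValidationError(f"group {gid!r} has no finite reference values")
        medians[gid] = population_median(ref)
    z = groups.map(medians)

    rows = []
    for marker in panel.transgene_markers:
        x = matrix[marker]
        t = (x / y) * z
        rows.append(pd.DataFrame({
            "sample_id": matrix.index,
            "group_id": groups.values,
            "marker": marker,
            "X": x.values,
            "Y": y.values,
            "Z": z.values,
            "T": t.values,
        }))
    data = pd.concat(rows, ignore_index=True)
    missing_ref = tuple(sorted(matrix.index[~np.isfinite(y)]))
    return NormalizedTraitTable(
        data=data, trait=trait,
        group_medians=pd.Series(medians, name="Z"),
        missing_reference=missing_ref,
    )
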