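"""Normalization and grouping of abundance tables.

``normalize`` implements peak-area / band-intensity normalization: each value is
divided by the total of its sample column, yielding per-sample compositional
profiles. ``aggregate`` rolls features up to a chemical category or a taxonomic
level using an annotation table; when the grouping is a partition of all
features the per-sample totals are conserved exactly.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .tabular_io import AbundanceTable, FeatureAnnotation, annotation_index

_LEVELS = ("category", "phylum", "genus", "species")


def normalize(raw: AbundanceTable) -> AbundanceTable:
    """Divide each value by its sample-column total (compositional closure).

    Idempotent on tables that are already relative. Raises if a sample has an
    all-zero column, naming the sample.
    """
    sums = raw.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(
            f"sample column {zero.index[0]!r} has zero total; cannot normalize"
        )
    rel = raw.data.div(sums, axis=1)
    return AbundanceTable(rel, mode="relative")


def aggregate(
    table: AbundanceTable,
    annotations: Iterable[FeatureAnnotation],
    level: str,
) -> AbundanceTable:
    """Sum feature values per sample within groups at the requested level.

    ``level`` is one of ``category`` (volatiles), ``phylum``/``genus``/``species``
    (microbes). Every feature in the table must be annotated at that level.
    """
    if level not in _LEVELS:
        raise ConfigurationError(f"unknown aggregation level {level!r}")
    index = annotation_index(annotations)
    groups: dict[str, str] = {}
    missing = []
    for fid in table.feature_ids:
        ann = index.get(fid)
        label = getattr(ann, level, None) if ann is not None else None
        if not label:
            missing.append(fid)
        else:
            groups[fid] = label
    if missing:
        raise ValidationError(
            f"features lack a {level!r} annotation: {missing}"
        )
    grouped = table.data.groupby(pd.Series(groups), sort=True).sum()
    grouped.index.name = level
    # Summing within a partition conserves the column totals, so a relative
    # table stays relative.
    return AbundanceTable(grouped, mode=table.mode)


def count_detected(table: AbundanceTable, detection_epsilon: float = 0.0) -> pd.Series:
    """Number of features detected (value > detection_epsilon) per sample."""
    if detection_epsilon < 0:
        raise ConfigurationError("detection_epsilon must be nonnegative")
    counts = (table.data > detection_epsilon).sum(axis=0)
    counts.name = "n_detected"
    return counts


def shared_features(table: AbundanceTable, detection_epsilon: float = 0.0) -> set[str]:
    """Ids of features detected in every sample of the table."""
    if detection_epsilon < 0:
        raise ConfigurationError("detection_epsilon must be nonnegative")
    mask = (table.data > detection_epsilon).all(axis=1)
    return set(table.data.index[mask])
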