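"""Shannon-Wiener diversity and Pielou evenness from relative abundances.

For a sample with relative abundances ``p_1..p_S`` (positive entries only):

    H = -sum_i p_i * ln(p_i)          (nats; 0*ln 0 := 0)
    E = H / ln(S)                     (Pielou's J; undefined for S = 1)
    S = number of detected features   (p_i > 0)

The natural logarithm is the default and is what makes printed (H, E) pairs
consistent with integer band counts via exp(H/E) ~ S; the base is configurable.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tabular_io import AbundanceTable

_SUM_TOL = 1e-6


def shannon(p, base: float = math.e) -> float:
    """Shannon-Wiener index of a relative-abundance vector.

    ``p`` must be nonnegative and sum to 1 (validated, not renormalized).
    """
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise ValidationError("relative abundances must be nonnegative")
    total = arr.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise ValidationError(f"relative abundances sum to {total:.6g}, expected 1")
    pos = arr[arr > 0]
    h = float(-(pos * np.log(pos)).sum())
    if base != math.e:
        h /= math.log(base)
    return max(h, 0.0)


def evenness(h: float, s: int, base: float = math.e) -> float:
    """Pielou evenness E = H / log(S); NaN (with a warning) when S = 1."""
    if s <= 0:
        raise ValidationError("richness S must be >= 1")
    if h < 0:
        raise ValidationError("Shannon index must be nonnegative")
    if s == 1:
        warnings.warn("evenness is undefined for a single detected feature (S=1)")
        return float("nan")
    return h / (math.log(s) / (math.log(base) if base != math.e else 1.0))


def richness(p, detection_epsilon: float = 0.0) -> int:
    """Count of features with relative abundance above the detection threshold."""
    arr = np.asarray(p, dtype=float)
    return int((arr > detection_epsilon).sum())


def diversity_table(
    table: AbundanceTable, base: float = math.e, detection_epsilon: float = 0.0
) -> pd.DataFrame:
    """Per-sample H, E and S for a relative abundance table.

    Returns a DataFrame indexed by sample id with columns ``H``, ``E``, ``S``.
    """
    if table.mode != "relative":
        raise ValidationError("diversity requires a relative-mode table")
    rows = {}
    for sample in table.sample_ids:
        p = table.data[sample].to_numpy()
        s = richness(p, detection_epsilon)
        if s == 0:
            raise ValidationError(f"sample {sample!r} has no detected features")
        h = shannon(p, base=base)
        if s == 1:
            e = float("nan")
            warnings.warn(
                f"sample {sample!r}: evenness undefined for a single detected feature"
            )
        else:
            e = evenness(h, s, base=base)
        rows[sample] = {"H": h, "E": e, "S": s}
    out = pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]
    out.index.name = "sample"
    return out
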