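"""Plant survey processing: point-centred-quarter densities, relative
abundances, and trait table preparation.

Survey input is a delimited table with columns ``site``, ``species``,
``method`` (``pcq`` or ``cover``), distance columns ``d1..d4`` in metres
(blank = species absent in that corner) and ``cover`` (fraction of plot).
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateScalingError, EmptyCommunityError, ValidationError

__all__ = [
    "pcq_density",
    "relative_abundance",
    "community_matrix",
    "aggregate_trait",
    "scale_trait",
    "read_survey",
    "read_traits",
]

MAX_CORNER_DISTANCE = 3.5  # metres
ZERO_DISTANCE_SUBSTITUTE = 0.01  # one centimetre, applied to the corner average
N_CORNERS = 4


def pcq_density(distances: Iterable[float | None], n_corners: int = N_CORNERS) -> float:
    """Density score from per-corner nearest-individual distances.

    ``distances`` holds one entry per corner; ``None``/NaN marks absence.
    The score is (1 / d̄²) × f, with d̄ the mean distance over corners where
    the species was found (a zero average is substituted by 0.01 m) and f
    the fraction of corners occupied. Absent everywhere → 0.
    """
    present = []
    for d in distances:
        if d is None or (isinstance(d, float) and math.isnan(d)):
            continue
        d = float(d)
        if d < 0 or d > MAX_CORNER_DISTANCE:
            raise ValidationError(
                f"corner distance {d} m outside [0, {MAX_CORNER_DISTANCE}]"
            )
        present.append(d)
    if not present:
        return 0.0
    dbar = float(np.mean(present))
    if dbar == 0.0:
        dbar = ZERO_DISTANCE_SUBSTITUTE
    f = len(present) / n_corners
    return f / dbar**2


def relative_abundance(densities: pd.Series) -> pd.Series:
    """Scale a vector of per-species density/cover scores to sum to one."""
    densities = densities.astype(float)
    if (densities < 0).any():
        raise ValidationError("negative density")
    total = densities.sum()
    if total <= 0:
        raise EmptyCommunityError("no species with positive density at this site")
    return densities / total


def community_matrix(survey: pd.DataFrame) -> pd.DataFrame:
    """Build the sites × species relative-abundance matrix from survey records.

    Each row of the output sums to one. PCQ sites are scored with
    :func:`pcq_density`; cover sites use the recorded cover fraction.
    Repeated (site, species) records are summed before normalization.
    """
    required = {"site", "species", "method"}
    if not required.issubset(survey.columns):
        raise ValidationError(f"survey table missing columns {required - set(survey.columns)}")

    dist_cols = [c for c in ("d1", "d2", "d3", "d4") if c in survey.columns]
    scores: dict[tuple[str, str], float] = {}
    for _, row in survey.iterrows():
        method = str(row["method"]).lower()
        if method == "pcq":
            score = pcq_density([row.get(c) for c in dist_cols])
        elif method == "cover":
            cover = float(row["cover"])
            if not 0 <= cover <= 1:
                raise ValidationError(f"cover {cover} outside [0, 1]")
            score = cover
        else:
            raise ValidationError(f"unknown survey method '{method}'")
        key = (row["site"], row["species"])
        scores[key] = scores.get(key, 0.0) + score

    wide = (
        pd.Series(scores)
        .rename_axis(["site", "species"])
        .unstack(fill_value=0.0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return wide.apply(relative_abundance, axis=1)


def aggregate_trait(values: Iterable[float]) -> float:
    """Median of the available measurements for one species; NaN when empty."""
    vals = [float(v) for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(np.median(vals))


def scale_trait(values: pd.Series | np.ndarray) -> np.ndarray:
    """Min–max scale trait values to [0, 1] over the whole species pool.

    NaNs pass through. A constant trait raises
    :class:`DegenerateScalingError` (every pairwise distance would be zero).
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise DegenerateScalingError("need at least two finite trait values")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise DegenerateScalingError("constant trait cannot be min-max scaled")
    out = (x - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def read_survey(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def read_traits(path, sep: str = "\t") -> pd.DataFrame:
    """Read a species trait table; repeated species rows collapse to medians."""
    df = pd.read_csv(path, sep=sep)
    if "species" not in df.columns:
        raise ValidationError("trait table needs a 'species' column")
    trait_cols = [c for c in df.columns if c != "species"]
    return df.groupby("species", sort=True)[trait_cols].agg(aggregate_trait).reset_index()
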