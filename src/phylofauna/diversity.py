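"""Community diversity metrics with null-model standardization.

Implements abundance-weighted and unweighted mean pairwise distance (MPD)
and mean nearest taxon distance (MNTD) on a patristic distance matrix,
standardized effect sizes against a species-reshuffling null, Rao's
quadratic entropy on a single [0,1]-scaled trait, and community-weighted
trait means.

Conventions
-----------
* Weighted MPD averages over pairs of individuals of *distinct* species:
  sum_{i != j} p_i p_j d_ij / sum_{i != j} p_i p_j.
* Rao's Q is the unnormalized double sum sum_{i,j} p_i p_j d_ij (the i = j
  terms vanish on a zero-diagonal matrix); with all interspecific
  distances equal to one it reduces to Simpson's 1 - sum p_i^2.
* Metrics are NaN (never zero) when fewer than two species are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phylo import DistanceMatrix

__all__ = [
    "mpd",
    "mntd",
    "ses",
    "run_null",
    "rao",
    "quadratic_entropy",
    "cwm",
    "NullModelSpec",
    "community_diversity",
]


@dataclass(frozen=True)
class NullModelSpec:
    """Species-reshuffling null: permute species identities on the distance
    matrix across the whole observed pool, keeping abundance vectors fixed."""

    replicates: int = 999
    seed: int = 0
    scheme: str = "taxa-shuffle"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.scheme != "taxa-shuffle":
            raise ValidationError(f"unknown null scheme '{self.scheme}'")


def _present(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("negative abundance")
    return np.flatnonzero(p > 0)


def mpd(p, d, weighted: bool = True) -> float:
    """Mean pairwise distance among species present (p > 0).

    Unweighted: plain mean of d_ij over unordered distinct pairs.
    Weighted: sum_{i != j} p_i p_j d_ij / sum_{i != j} p_i p_j.
    NaN when fewer than two species are present.
    """
    d = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    idx = _present(p)
    if idx.size < 2:
        return float("nan")
    sub = d[np.ix_(idx, idx)]
    if weighted:
        q = p[idx]
        w = np.outer(q, q)
        np.fill_diagonal(w, 0.0)
        return float((w * sub).sum() / w.sum())
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def mntd(p, d, weighted: bool = True) -> float:
    """Mean distance from each present species to its nearest present neighbour.

    Weighted variant weights each species' nearest-neighbour distance by its
    relative abundance (renormalized over present species).
    """
    d = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    idx = _present(p)
    if idx.size < 2:
        return float("nan")
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    ntd = sub.min(axis=1)
    if weighted:
        q = p[idx] / p[idx].sum()
        return float(q @ ntd)
    return float(ntd.mean())


def ses(observed, null_draws) -> np.ndarray | float:
    """Standardized effect size: (observed − null mean) / null SD (ddof=1).

    ``null_draws`` has replicates along axis 0. A zero null SD yields NaN
    with a warning naming the affected positions.
    """
    obs = np.asarray(observed, dtype=float)
    draws = np.asarray(null_draws, dtype=float)
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (obs - mean) / sd
    bad = np.asarray(sd == 0)
    if bad.any():
        warnings.warn(
            f"null SD is zero for {int(bad.sum())} site(s); SES undefined there",
            UserWarning,
            stacklevel=2,
        )
        out = np.where(bad, np.nan, out)
    if np.isscalar(observed) or obs.ndim == 0:
        return float(out)
    return out


def run_null(
    metric: str,
    abundances: np.ndarray | pd.DataFrame,
    d,
    spec: NullModelSpec,
    weighted: bool = True,
) -> np.ndarray:
    """Null distribution of a metric under species-identity reshuffling.

    Each replicate applies one random permutation of the species pool to the
    distance matrix and recomputes the metric for every site with unchanged
    abundance vectors. Returns an array of shape (replicates, n_sites).
    Deterministic for a given ``spec.seed``.
    """
    if metric not in ("mpd", "mntd"):
        raise ValidationError(f"unknown metric '{metric}'")
    M = np.asarray(
        abundances.values if isinstance(abundances, pd.DataFrame) else abundances,
        dtype=float,
    )
    if M.ndim == 1:
        M = M[None, :]
    D = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    pool = D.shape[0]
    if pool < 2:
        raise ValidationError("species pool must hold at least 2 species")
    if M.shape[1] != pool:
        raise ValidationError("abundance matrix and distance matrix disagree on pool size")

    rng = np.random.default_rng(spec.seed)
    n_sites = M.shape[0]
    out = np.empty((spec.replicates, n_sites))

    if metric == "mpd":
        # Vectorized over sites: with zero diagonal, weighted MPD per site is
        # (m' D m) / (1 - sum m^2); unweighted uses the presence indicator.
        richness = (M > 0).sum(axis=1)
        ok = richness >= 2
        if weighted:
            W = np.where(M > 0, M, 0.0)
            rowsum = W.sum(axis=1, keepdims=True)
            W = np.divide(W, rowsum, out=np.zeros_like(W), where=rowsum > 0)
            denom = 1.0 - (W**2).sum(axis=1)
        else:
            W = (M > 0).astype(float)
            denom = richness * (richness - 1.0)
        for r in range(spec.replicates):
            perm = rng.permutation(pool)
            Dp = D[np.ix_(perm, perm)]
            num = ((W @ Dp) * W).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = num / denom
            out[r] = np.where(ok, vals, np.nan)
    else:
        for r in range(spec.replicates):
            perm = rng.permutation(pool)
            Dp = D[np.ix_(perm, perm)]
            for s in range(n_sites):
                out[r, s] = mntd(M[s], Dp, weighted=weighted)
    return out


def quadratic_entropy(p, d) -> float:
    """Unnormalized Rao quadratic form sum_{i,j} p_i p_j d_ij.

    With every interspecific distance equal to one this is Simpson's
    1 - sum p_i^2. ``p`` must sum to one.
    """
    p = np.asarray(p, dtype=float)
    d = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    return float(p @ d @ p)


def rao(p, trait_scaled) -> tuple[float, int]:
    """Rao's quadratic entropy for one [0,1]-scaled trait.

    d_ij = |x'_i − x'_j|; species with a missing trait are dropped and the
    abundances renormalized. Returns (value, number of dropped present
    species). NaN value when fewer than two trait-bearing species remain.
    """
    p = np.asarray(p, dtype=float)
    x = np.asarray(trait_scaled, dtype=float)
    present = p > 0
    keep = present & np.isfinite(x)
    dropped = int(present.sum() - keep.sum())
    if keep.sum() < 2:
        return (0.0 if keep.sum() == 1 else float("nan")), dropped
    q = p[keep] / p[keep].sum()
    xx = x[keep]
    d = np.abs(xx[:, None] - xx[None, :])
    return quadratic_entropy(q, d), dropped


def cwm(p, trait_values) -> float:
    """Community-weighted mean trait value (raw trait units).

    Missing-trait species are dropped with abundance renormalization;
    NaN when no present species carries the trait.
    """
    p = np.asarray(p, dtype=float)
    x = np.asarray(trait_values, dtype=float)
    keep = (p > 0) & np.isfinite(x)
    if not keep.any():
        return float("nan")
    q = p[keep] / p[keep].sum()
    return float(q @ x[keep])


def community_diversity(
    community: pd.DataFrame,
    dmat: DistanceMatrix,
    traits_raw: pd.DataFrame | None = None,
    null: NullModelSpec | None = None,
    weighted: bool = True,
    metrics: tuple[str, ...] = ("mpd", "mntd"),
) -> pd.DataFrame:
    """Per-site diversity table: observed MPD/MNTD, their SES, and per-trait
    Rao's Q (on min–max scaled values) and CWM (raw units).

    ``community`` is sites × species (rows sum to 1); ``traits_raw`` is
    indexed by species with one column per trait. Species order is aligned
    to the community matrix columns.
    """
    from .vegetation import scale_trait

    species = list(community.columns)
    d = dmat.submatrix(species)
    M = community.to_numpy(dtype=float)
    null = null or NullModelSpec()

    rows = pd.DataFrame(index=community.index)
    fns = {"mpd": mpd, "mntd": mntd}
    for name in metrics:
        rows[f"{name}_obs"] = [fns[name](m, d, weighted=weighted) for m in M]
        draws = run_null(name, M, d, null, weighted=weighted)
        rows[f"ses_{name}"] = ses(rows[f"{name}_obs"].to_numpy(), draws)

    if traits_raw is not None:
        traits = traits_raw.reindex(species)
        for trait in traits.columns:
            raw = traits[trait].to_numpy(dtype=float)
            scaled = scale_trait(raw)
            rows[f"rao_{trait}"] = [rao(m, scaled)[0] for m in M]
            rows[f"cwm_{trait}"] = [cwm(m, raw) for m in M]
    return rows
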