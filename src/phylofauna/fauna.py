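"""Soil-fauna summaries: group abundances, log transform, Simpson
diversity, and the nematode Structure Index.

The canonical fauna table is long-format delimited text with columns
``site``, ``taxon``, ``major_group`` (earthworm | springtail | mite |
nematode), ``subgroup`` (closed vocabulary per major group; for nematodes
a guild code such as ``Ba2`` or ``Ca4`` combining feeding group and c-p
class) and ``count``.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError, VocabularyError

__all__ = [
    "VOCABULARIES",
    "GuildWeights",
    "DEFAULT_GUILD_WEIGHTS",
    "group_abundance",
    "log_abundance",
    "simpson",
    "structure_index",
    "summarize_fauna",
]

# Closed annotation vocabularies per major group.
VOCABULARIES: dict[str, frozenset[str]] = {
    "earthworm": frozenset({"epigeic", "anecic", "endogeic"}),
    "springtail": frozenset({"epigeic", "hemiedaphic", "euedaphic"}),
    "mite": frozenset({"actinedid", "gamasid", "other"}),
}

_GUILD_RE = re.compile(r"^(Ba|Fu|Pl|Ca|Om)([1-5])$")

# Feeding-group prefixes used to split nematodes by trophic exposure.
NEMATODE_PHYTOPHAGE_PREFIX = "Pl"
NEMATODE_CARNIVORE_PREFIX = "Ca"


def parse_guild(label: str) -> tuple[str, int]:
    """Split a nematode guild code into (feeding prefix, c-p class)."""
    m = _GUILD_RE.match(str(label))
    if not m:
        raise VocabularyError(
            f"'{label}' is not a valid nematode guild code (e.g. Ba2, Fu2, Ca4)"
        )
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class GuildWeights:
    """Weighting scheme for the Structure Index.

    Structure guilds are those with c-p class 3–5; the basal component is
    built from Ba2 and Fu2. Defaults follow the standard soil food-web
    weighting; alternative tables can be injected.
    """

    structure: Mapping[int, float] = field(
        default_factory=lambda: {3: 1.8, 4: 3.2, 5: 5.0}
    )
    basal_guilds: frozenset[str] = frozenset({"Ba2", "Fu2"})
    basal_weight: float = 0.8

    def __post_init__(self):
        if self.basal_weight <= 0 or any(w <= 0 for w in self.structure.values()):
            raise ValidationError("guild weights must be positive")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "GuildWeights":
        """Build from a two-column (guild, weight) table; guilds named by
        c-p class ('cp3'..'cp5') or basal code (Ba2/Fu2)."""
        structure = {}
        basal_guilds = set()
        basal_weight = 0.8
        for _, row in df.iterrows():
            g, w = str(row["guild"]), float(row["weight"])
            if g.startswith("cp"):
                structure[int(g[2:])] = w
            else:
                basal_guilds.add(g)
                basal_weight = w
        return cls(structure, frozenset(basal_guilds), basal_weight)


DEFAULT_GUILD_WEIGHTS = GuildWeights()


def group_abundance(
    table: pd.DataFrame, major_group: str, grouping: str = "subgroup"
) -> pd.DataFrame:
    """Sum counts within site × annotation group for one major fauna group.

    Every vocabulary group appears in the output, zero-filled when absent.
    Unknown annotation values raise :class:`VocabularyError`.
    """
    sub = table[table["major_group"] == major_group]
    if major_group in VOCABULARIES:
        vocab = VOCABULARIES[major_group]
        bad = set(sub[grouping].astype(str)) - vocab
        if bad:
            raise VocabularyError(
                f"unknown {major_group} {grouping} value(s): {sorted(bad)}"
            )
        columns = sorted(vocab)
    else:  # nematodes: validate guild codes instead
        for g in sub[grouping].unique():
            parse_guild(g)
        columns = sorted(sub[grouping].unique())
    _check_counts(sub["count"])
    out = (
        sub.pivot_table(
            index="site", columns=grouping, values="count", aggfunc="sum", fill_value=0
        )
        .reindex(columns=columns, fill_value=0)
        .rename_axis(columns=None)
    )
    return out


def _check_counts(counts) -> None:
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValidationError("negative count")


def log_abundance(count):
    """log10(count + 1); maps 0 to 0 and accepts scalars or arrays."""
    c = np.asarray(count, dtype=float)
    if (c < 0).any():
        raise ValidationError("negative count")
    out = np.log10(c + 1.0)
    return float(out) if np.isscalar(count) else out


def simpson(abundances) -> float:
    """Simpson diversity 1 − Σ p_i² (0 = no diversity). Accepts counts or
    proportions; NaN for an empty community."""
    a = np.asarray(abundances, dtype=float)
    _check_counts(a)
    total = a.sum()
    if total <= 0:
        return float("nan")
    p = a / total
    return float(1.0 - (p**2).sum())


def structure_index(
    guild_counts: Mapping[str, float], weights: GuildWeights = DEFAULT_GUILD_WEIGHTS
) -> float:
    """Nematode Structure Index, 100·s/(s+b).

    s sums weighted counts over structure guilds (c-p 3–5), b over the
    basal guilds (Ba2, Fu2). Guilds in neither set (e.g. plant feeders,
    c-p 1 colonisers) do not enter. NaN when s + b = 0.
    """
    s = b = 0.0
    for guild, n in guild_counts.items():
        if n < 0:
            raise ValidationError("negative count")
        prefix, cp = parse_guild(guild)
        if guild in weights.basal_guilds:
            b += weights.basal_weight * n
        elif cp in weights.structure and prefix != NEMATODE_PHYTOPHAGE_PREFIX:
            s += weights.structure[cp] * n
    if s + b == 0:
        return float("nan")
    return 100.0 * s / (s + b)


def summarize_fauna(
    table: pd.DataFrame, weights: GuildWeights = DEFAULT_GUILD_WEIGHTS
) -> pd.DataFrame:
    """Per-site wide summary used as the response table for the models.

    Columns: total abundance per major group; abundance per exposure
    subgroup (epigeic/endogeic earthworms, hemiedaphic/euedaphic
    springtails, actinedid/gamasid mites, phytophagous/carnivorous
    nematodes); Simpson diversity of earthworms, springtails and
    nematodes (taxon level); nematode Structure Index.
    """
    sites = sorted(table["site"].unique())
    out = pd.DataFrame(index=pd.Index(sites, name="site"))
    _check_counts(table["count"])

    for group in ("earthworm", "springtail", "mite", "nematode"):
        sub = table[table["major_group"] == group]
        out[f"abund_{group}"] = sub.groupby("site")["count"].sum().reindex(sites, fill_value=0)

    for group, wanted in (
        ("earthworm", ("epigeic", "endogeic")),
        ("springtail", ("hemiedaphic", "euedaphic")),
        ("mite", ("actinedid", "gamasid")),
    ):
        ga = group_abundance(table, group)
        for sg in wanted:
            out[f"abund_{group}_{sg}"] = ga[sg].reindex(sites, fill_value=0) if sg in ga else 0

    nem = group_abundance(table, "nematode")
    phyto = [g for g in nem.columns if g.startswith(NEMATODE_PHYTOPHAGE_PREFIX)]
    carn = [g for g in nem.columns if g.startswith(NEMATODE_CARNIVORE_PREFIX)]
    out["abund_nematode_phytophage"] = nem[phyto].sum(axis=1).reindex(sites, fill_value=0)
    out["abund_nematode_carnivore"] = nem[carn].sum(axis=1).reindex(sites, fill_value=0)

    for group in ("earthworm", "springtail", "nematode"):
        sub = table[table["major_group"] == group]
        by_taxon = sub.pivot_table(
            index="site", columns="taxon", values="count", aggfunc="sum", fill_value=0
        )
        out[f"simpson_{group}"] = by_taxon.apply(simpson, axis=1).reindex(sites)

    out["structure_index"] = nem.apply(
        lambda row: structure_index(row.to_dict(), weights), axis=1
    ).reindex(sites)
    return out
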