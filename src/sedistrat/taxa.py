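"""Knowledge-group and guild classification of OTUs, and group summaries.

Sediment 16S communities mix lineages with cultivated, functionally
characterised representatives ("well-characterized") and candidate taxa
known almost solely from environmental sequences ("poorly-known"). A
:class:`TaxonDictionary` encodes that split — together with functional
guilds such as acetoclastic/hydrogenotrophic methanogens and aerobic or
anaerobic methanotrophs — as rank-scoped lineage-prefix rules. A versioned
default dictionary ships with the package and can be replaced by any user
YAML of the same shape.

The module also provides guild abundance summaries and the
acetoclastic:hydrogenotrophic methane pathway ratio, both the observed
per-layer value and the stoichiometric expectation for complete anaerobic
degradation of carbohydrate (2:1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .layers import LayerSeries

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

KNOWLEDGE_LABELS = frozenset(
    {"well_characterized", "poorly_known", "unclassified_domain"}
)

DEFAULT_GUILDS = (
    "methanogen_acetoclastic",
    "methanogen_hydrogenotrophic",
    "methanogen_other",
    "methanotroph_aerobic",
    "methanotroph_anaerobic",
    "protein_degrader",
)


class DictionaryError(ValueError):
    """Raised for malformed or internally conflicting rule sets."""


@dataclass(frozen=True)
class Rule:
    pattern: str
    rank: str
    labels: frozenset

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise DictionaryError(
                f"rule {self.pattern!r}: unknown rank {self.rank!r} (use one of {RANKS})"
            )
        if not self.labels:
            raise DictionaryError(f"rule {self.pattern!r}: empty label set")

    @property
    def rank_index(self) -> int:
        return RANKS.index(self.rank)

    @property
    def knowledge_labels(self) -> frozenset:
        return self.labels & KNOWLEDGE_LABELS


@dataclass
class TaxonDictionary:
    """Lineage-pattern -> label-set rules with load-time conflict checks."""

    rules: list[Rule]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], Rule] = {}
        for rule in self.rules:
            key = (rule.pattern, rule.rank)
            if key in seen:
                raise DictionaryError(
                    f"conflicting rules for pattern {rule.pattern!r} at rank {rule.rank!r}"
                )
            seen[key] = rule

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "TaxonDictionary":
        rules = [
            Rule(
                pattern=str(r["pattern"]),
                rank=str(r["rank"]),
                labels=frozenset(r["labels"]),
            )
            for r in doc["rules"]
        ]
        return cls(rules=rules, version=str(doc.get("version", "unversioned")))

    @classmethod
    def from_yaml(cls, path) -> "TaxonDictionary":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "TaxonDictionary":
        text = resources.files("sedistrat.data").joinpath("taxon_groups.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))


def _lineage_tokens(lineage: str) -> list[str]:
    return [t.strip() for t in str(lineage).split(";")]


def classify_lineage(lineage: str, dictionary: TaxonDictionary) -> frozenset:
    """Label set for one lineage.

    The knowledge group comes from the deepest-rank matching rule that
    carries a knowledge label; guild labels accumulate from every matching
    rule. Lineages matching no knowledge rule are ``unclassified_domain``.
    """
    tokens = _lineage_tokens(lineage)
    knowledge: tuple[int, frozenset] | None = None
    guilds: set = set()
    for rule in dictionary.rules:
        i = rule.rank_index
        if i >= len(tokens) or not tokens[i].startswith(rule.pattern):
            continue
        guilds |= set(rule.labels - KNOWLEDGE_LABELS)
        kl = rule.knowledge_labels
        if kl:
            if knowledge is None or i > knowledge[0]:
                knowledge = (i, kl)
            elif i == knowledge[0] and kl != knowledge[1]:
                raise DictionaryError(
                    f"lineage {lineage!r}: rules at rank {RANKS[i]!r} assign "
                    f"conflicting knowledge groups {sorted(knowledge[1])} vs {sorted(kl)}"
                )
    labels = set(guilds)
    labels |= set(knowledge[1]) if knowledge else {"unclassified_domain"}
    return frozenset(labels)


def classify(table_or_lineages, dictionary: TaxonDictionary | None = None) -> pd.Series:
    """Per-OTU label sets for an :class:`~sedistrat.io.OtuTable`,
    :class:`~sedistrat.io.RelAbundTable` or a plain lineage Series."""
    if dictionary is None:
        dictionary = TaxonDictionary.default()
    lineages = getattr(table_or_lineages, "lineages", table_or_lineages)
    return pd.Series(
        {otu: classify_lineage(lin, dictionary) for otu, lin in lineages.items()},
        dtype=object,
    ).reindex(lineages.index)


def _as_frame(series) -> pd.DataFrame:
    return series.values if isinstance(series, LayerSeries) else series


@dataclass
class GroupProfile:
    """Group x layer matrix of summed relative abundances with provenance."""

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def group_abundance(
    series,
    labels: pd.Series,
    groups: Iterable[str] = ("well_characterized", "poorly_known", "unclassified_domain"),
    fold_unclassified: bool = False,
    provenance: dict | None = None,
) -> GroupProfile:
    """Sum relative abundances per knowledge group and layer.

    With ``fold_unclassified=True`` the domain-unclassified OTUs are folded
    into the poorly-known sum (they are taxa without even a confident
    domain-internal placement), and only two partition rows are returned.
    """
    frame = _as_frame(series)
    labels = labels.reindex(frame.index)
    if labels.isna().any():
        missing = list(frame.index[labels.isna()])[:5]
        raise ValueError(f"OTUs without labels, e.g. {missing}")
    groups = list(groups)
    layer_missing = frame.isna().all(axis=0)
    out = pd.DataFrame(0.0, index=groups, columns=frame.columns)
    for group in groups:
        mask = labels.map(lambda ls: group in ls).to_numpy(dtype=bool)
        out.loc[group] = frame.loc[mask].sum(axis=0)
    out.loc[:, layer_missing] = np.nan
    if fold_unclassified:
        folded = pd.DataFrame(
            {
                "well_characterized": out.loc["well_characterized"],
                "poorly_known": out.loc["poorly_known"]
                + out.loc["unclassified_domain"],
            }
        ).T
        out = folded
    return GroupProfile(values=out, provenance=dict(provenance or {}))


def pathway_ratio(
    series,
    labels: pd.Series,
    acetoclastic_label: str = "methanogen_acetoclastic",
    hydrogenotrophic_label: str = "methanogen_hydrogenotrophic",
) -> pd.Series:
    """Per-layer acetoclastic:hydrogenotrophic methanogen abundance ratio.

    Layers where the hydrogenotrophic sum is zero yield NaN (undefined),
    never infinity.
    """
    frame = _as_frame(series)
    labels = labels.reindex(frame.index)
    layer_missing = frame.isna().all(axis=0)
    aceto = frame.loc[labels.map(lambda ls: acetoclastic_label in ls).to_numpy(dtype=bool)].sum(axis=0)
    hydro = frame.loc[labels.map(lambda ls: hydrogenotrophic_label in ls).to_numpy(dtype=bool)].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = aceto / hydro
    return ratio.where((hydro > 0) & ~layer_missing, np.nan)


def theoretical_pathway_ratio(
    ch4_acetoclastic: int | Fraction = Fraction(2),
    ch4_hydrogenotrophic: int | Fraction = Fraction(1),
) -> float:
    """Stoichiometric acetoclastic:hydrogenotrophic methane ratio.

    The default encodes complete methanogenic degradation of hexose:
    hexose -> 2 acetate + 2 CO2 + 4 H2; the 2 acetate cleave to 2 CH4
    (acetoclastic) while 4 H2 + CO2 reduce to 1 CH4 (hydrogenotrophic),
    i.e. a 2:1 split. Exact rational arithmetic is used.
    """
    aceto = Fraction(ch4_acetoclastic)
    hydro = Fraction(ch4_hydrogenotrophic)
    if hydro <= 0:
        raise ValueError("hydrogenotrophic CH4 term must be positive")
    if aceto < 0:
        raise ValueError("acetoclastic CH4 term must be non-negative")
    return float(aceto / hydro)


@dataclass
class GuildSummary:
    """Per-layer guild relative abundances plus each guild's maximum layer value."""

    per_layer: pd.DataFrame
    max_across_layers: pd.Series


def guild_summary(
    series,
    labels: pd.Series,
    guilds: Iterable[str] = DEFAULT_GUILDS,
) -> GuildSummary:
    """Per-layer summed relative abundance of each guild and its "up to" maximum."""
    frame = _as_frame(series)
    labels = labels.reindex(frame.index)
    guilds = list(guilds)
    layer_missing = frame.isna().all(axis=0)
    per_layer = pd.DataFrame(0.0, index=guilds, columns=frame.columns)
    for guild in guilds:
        mask = labels.map(lambda ls: guild in ls).to_numpy(dtype=bool)
        per_layer.loc[guild] = frame.loc[mask].sum(axis=0)
    per_layer.loc[:, layer_missing] = np.nan
    max_across = per_layer.max(axis=1, skipna=True).fillna(0.0)
    return GuildSummary(per_layer=per_layer, max_across_layers=max_across)
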