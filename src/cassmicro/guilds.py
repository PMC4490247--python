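"""Functional-guild assignment from 16S taxonomy and guild co-abundance.

OTUs are mapped to guilds of iron-reducing (IRB) and sulfate-reducing (SRB)
bacteria by lexical matching of a taxonomic rank (genus, order or class)
against curated name lists; guild read counts per sample are then related
by ordinary least squares to test whether the guilds co-vary down-core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import RANKS, OtuTable
from .errors import ConfigurationError, InvalidInputError, UndefinedFitError

#: Genera with experimentally demonstrated dissimilatory iron-reducing
#: ability, used as the lexical definition of the IRB guild.
IRB_GENERA: tuple[str, ...] = (
    "Paraferrimonas",
    "Aciditerrimonas",
    "Desulfuromonas",
    "Bacillus",
    "Pelobacter",
    "Desulfuromusa",
    "Desulfitobacterium",
    "Thiobacillus",
    "Geobacter",
    "Desulfosporosinus",
    "Ferroplasma",
    "Geothrix",
    "Shewanella",
    "Ferribacterium",
    "Ferrimonas",
)

#: Orders of classical sulfate/sulfur-reducing deltaproteobacteria; the
#: default (order-level) SRB definition.
SRB_ORDERS: tuple[str, ...] = (
    "Desulfobacterales",
    "Desulfovibrionales",
    "Desulfuromonadales",
    "Syntrophobacterales",
)

#: Default confidence cutoff (%) below which a rank name is not trusted.
DEFAULT_MIN_CONFIDENCE = 50.0


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomy from domain to genus with optional confidences (%)."""

    names: tuple[str, ...]
    confidences: tuple[float | None, ...]

    def at(self, rank: str) -> tuple[str, float | None]:
        i = RANKS.index(rank)
        return self.names[i], self.confidences[i]


def parse_lineage(raw: str) -> Lineage:
    """Parse a semicolon-delimited lineage with optional "(NN)" confidences.

    Ranks are assigned positionally domain -> genus; missing trailing ranks
    are filled with "unclassified" (no confidence).  Extra tokens beyond
    genus (e.g. species) are ignored.
    """
    if not raw or not raw.strip():
        raise InvalidInputError("empty lineage string")
    tokens = [t.strip() for t in raw.strip().split(";") if t.strip()]
    names: list[str] = []
    confs: list[float | None] = []
    for tok in tokens[: len(RANKS)]:
        conf: float | None = None
        if tok.endswith(")") and "(" in tok:
            name, _, conf_part = tok.rpartition("(")
            conf_str = conf_part[:-1]
            try:
                conf = float(conf_str)
                tok = name
            except ValueError:
                pass  # parenthetical that is not a confidence; keep token whole
        names.append(tok)
        confs.append(conf)
    while len(names) < len(RANKS):
        names.append("unclassified")
        confs.append(None)
    return Lineage(names=tuple(names), confidences=tuple(confs))


@dataclass(frozen=True)
class GuildDefinition:
    """A named guild matched lexically at one taxonomic rank.

    Matching is exact and case-insensitive; an OTU whose lineage carries the
    rank name at or above the confidence cutoff contributes all its reads.
    """

    guild_name: str
    rank: str
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ConfigurationError(f"unknown taxonomic rank {self.rank!r}")
        if not self.names:
            raise ConfigurationError(f"guild {self.guild_name!r}: empty name list")

    def matches(self, lineage: Lineage, min_confidence: float) -> bool:
        name, conf = lineage.at(self.rank)
        if conf is not None and conf < min_confidence:
            return False
        return name.lower() in {n.lower() for n in self.names}


def default_guilds(srb_mode: str = "order") -> list[GuildDefinition]:
    """The shipped IRB (genus-level) and SRB definitions.

    ``srb_mode='order'`` uses the four sulfate/sulfur-reducer orders;
    ``srb_mode='class'`` falls back to all of class Deltaproteobacteria.
    """
    if srb_mode == "order":
        srb = GuildDefinition("SRB", "order", SRB_ORDERS)
    elif srb_mode == "class":
        srb = GuildDefinition("SRB", "class", ("Deltaproteobacteria",))
    else:
        raise ConfigurationError(f"unknown SRB mode {srb_mode!r}")
    return [GuildDefinition("IRB", "genus", IRB_GENERA), srb]


def assign_guilds(
    table: OtuTable,
    definitions: list[GuildDefinition],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> pd.DataFrame:
    """Guild read counts per sample (the guild table).

    Returns a DataFrame indexed by sample with one column per guild plus
    ``unassigned`` (reads of OTUs matching no guild) and ``total``.  An OTU
    matching several guilds is counted in each of them, so guild columns may
    overlap when definitions do.
    """
    lineages = {otu: parse_lineage(raw) for otu, raw in table.taxonomy.items()}
    guild_otus: dict[str, np.ndarray] = {}
    matched_any = np.zeros(len(table.otu_ids), dtype=bool)
    for d in definitions:
        mask = np.zeros(len(table.otu_ids), dtype=bool)
        for j, otu in enumerate(table.otu_ids):
            lin = lineages.get(otu)
            if lin is not None and d.matches(lin, min_confidence):
                mask[j] = True
        guild_otus[d.guild_name] = mask
        matched_any |= mask

    out = pd.DataFrame(index=pd.Index(table.sample_ids, name="sample"))
    for name, mask in guild_otus.items():
        out[name] = table.counts[:, mask].sum(axis=1)
    out["unassigned"] = table.counts[:, ~matched_any].sum(axis=1)
    out["total"] = table.counts.sum(axis=1)
    return out


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def guild_regression(x, y) -> RegressionResult:
    """OLS fit of one guild's per-sample reads on another's.

    r^2 is the squared Pearson correlation; the p-value is the two-sided
    test of zero slope via t with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need >= 3 paired samples")
    if np.ptp(x) == 0:
        raise UndefinedFitError("zero variance in x: slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )
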