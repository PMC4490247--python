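"""Readers and writers for the tab-separated dialects used around 16S studies.

Covers the mothur "shared" (label / Group / numOtus / OtuNNNN...) and
"constaxonomy" (OTU / Size / Taxonomy) formats, a depth-resolved
geochemistry CSV, YAML reaction/kinetics configuration, and the tidy TSV
outputs of the pipeline.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import DistanceMatrix, OtuTable, SampleInfo
from .energetics import (
    ActivityModel,
    DriveResult,
    KineticParams,
    Reaction,
)
from .errors import ConfigurationError, InvalidInputError
from .guilds import GuildDefinition

_SAMPLE_ID_RE = re.compile(r"^(?P<site>.+)_(?P<top>\d+(?:\.\d+)?)-(?P<bot>\d+(?:\.\d+)?)$")


def parse_sample_id(sample_id: str) -> SampleInfo | None:
    """Site and depth interval from ids of the form ``A1_4-6`` (cm)."""
    m = _SAMPLE_ID_RE.match(sample_id)
    if not m:
        return None
    return SampleInfo(
        site=m.group("site"),
        depth_top_cm=float(m.group("top")),
        depth_bottom_cm=float(m.group("bot")),
    )


# ---------------------------------------------------------------------------
# mothur shared / constaxonomy

def read_shared(path: str | Path) -> pd.DataFrame:
    """Counts DataFrame (samples x OTUs) from a mothur shared file."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "Group", "numOtus"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"{path}: not a mothur shared file (missing {required - set(df.columns)})")
    counts = df.drop(columns=["label", "numOtus"]).set_index("Group")
    counts.index = counts.index.astype(str)
    return counts.astype(np.int64)


def write_shared(table: OtuTable, path: str | Path, label: str = "0.03") -> None:
    df = table.to_frame()
    out = pd.DataFrame({"label": label, "Group": df.index, "numOtus": len(table.otu_ids)})
    out = pd.concat([out.reset_index(drop=True), df.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_constaxonomy(path: str | Path) -> dict[str, str]:
    """OTU -> lineage string from a mothur cons.taxonomy file."""
    df = pd.read_csv(path, sep="\t")
    if not {"OTU", "Taxonomy"}.issubset(df.columns):
        raise InvalidInputError(f"{path}: not a constaxonomy file")
    return dict(zip(df["OTU"].astype(str), df["Taxonomy"].astype(str)))


def write_constaxonomy(table: OtuTable, path: str | Path) -> None:
    sizes = dict(zip(table.otu_ids, table.counts.sum(axis=0)))
    rows = [
        {"OTU": otu, "Size": int(sizes[otu]), "Taxonomy": table.taxonomy.get(otu, "")}
        for otu in table.otu_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_otu_table(
    shared_path: str | Path,
    taxonomy_path: str | Path | None = None,
) -> OtuTable:
    """Assemble an :class:`OtuTable` from shared (+ optional taxonomy) files.

    Sample metadata (site, depth interval) is parsed from ids of the form
    ``SITE_top-bottom``; other ids simply carry no metadata.
    """
    counts = read_shared(shared_path)
    taxonomy = read_constaxonomy(taxonomy_path) if taxonomy_path else {}
    taxonomy = {otu: lin for otu, lin in taxonomy.items() if otu in counts.columns}
    metadata = {}
    for sid in counts.index:
        info = parse_sample_id(sid)
        if info is not None:
            metadata[sid] = info
    return OtuTable(
        sample_ids=list(counts.index),
        otu_ids=list(counts.columns),
        counts=counts.to_numpy(),
        taxonomy=taxonomy,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# geochemistry

def read_geochem(path: str | Path) -> pd.DataFrame:
    """Geochemistry CSV with site, depth interval, pH, Eh and *_mM columns."""
    df = pd.read_csv(path)
    required = {"site", "depth_top_cm", "depth_bottom_cm"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing geochemistry columns {sorted(missing)}")
    return df


def write_geochem(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def profile_from_geochem(df: pd.DataFrame, site: str | None = None) -> list[tuple[str, "EnvironmentState"]]:
    """Ordered (depth label, EnvironmentState) pairs for one site.

    ``<species>_mM`` columns become molar concentrations; ``gamma_<species>``
    columns, if present, become per-row activity coefficients.  A
    ``temperature_K`` column overrides the 298 K default.
    """
    from .energetics import EnvironmentState

    if site is not None:
        df = df[df["site"] == site]
        if df.empty:
            raise InvalidInputError(f"no geochemistry rows for site {site!r}")
    df = df.sort_values(["site", "depth_top_cm"])
    species_cols = [c for c in df.columns if c.endswith("_mM")]
    gamma_cols = [c for c in df.columns if c.startswith("gamma_")]
    profile = []
    for _, row in df.iterrows():
        conc = {
            c[: -len("_mM")]: float(row[c]) / 1000.0
            for c in species_cols
            if pd.notna(row[c])
        }
        gammas = {
            c[len("gamma_"):]: float(row[c]) for c in gamma_cols if pd.notna(row[c])
        }
        env = EnvironmentState(
            concentrations=conc,
            temperature=float(row["temperature_K"]) if "temperature_K" in df.columns else 298.0,
            activity_coefficients=gammas or None,
            ionic_strength=float(row["ionic_strength_M"]) if "ionic_strength_M" in df.columns and pd.notna(row.get("ionic_strength_M")) else None,
        )
        label = f"{row['site']} {row['depth_top_cm']:g}-{row['depth_bottom_cm']:g} cm"
        profile.append((label, env))
    return profile


# ---------------------------------------------------------------------------
# configuration

def load_reaction_config(path: str | Path) -> tuple[Reaction, KineticParams, ActivityModel]:
    """Reaction, kinetics and activity model from a YAML config.

    Keys: ``reaction.stoichiometry``, ``reaction.delta_G0_kJ``,
    ``reaction.chi``, ``reaction.delta_GC_kJ``; ``kinetics.K_<species>_M``
    and optional ``kinetics.rate_scale``; ``activity.mode`` (davies|fixed)
    with optional ``activity.gammas`` and ``activity.davies_A``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        r = cfg["reaction"]
        reaction = Reaction(
            name=r.get("name", "configured_reaction"),
            stoichiometry={str(k): float(v) for k, v in r["stoichiometry"].items()},
            delta_G0=float(r["delta_G0_kJ"]),
            chi=float(r["chi"]),
            delta_GC=float(r["delta_GC_kJ"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing reaction key {exc}") from None
    kin = cfg.get("kinetics", {})
    half_sat = {
        key[len("K_"): -len("_M")]: float(val)
        for key, val in kin.items()
        if key.startswith("K_") and key.endswith("_M")
    }
    rate_scale = float(kin.get("rate_scale", 1.0))
    if half_sat:
        params = KineticParams(half_saturation=half_sat, rate_scale=rate_scale)
    else:
        params = KineticParams(rate_scale=rate_scale)
    act = cfg.get("activity", {})
    model_kwargs = {"mode": act.get("mode", "fixed")}
    if "gammas" in act:
        model_kwargs["fixed_gammas"] = {str(k): float(v) for k, v in act["gammas"].items()}
    if "davies_A" in act:
        model_kwargs["davies_A"] = float(act["davies_A"])
    return reaction, params, ActivityModel(**model_kwargs)


def load_guild_definitions(path: str | Path) -> list[GuildDefinition]:
    """Guild definitions from YAML: a list of {guild_name, rank, names}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ConfigurationError(f"{path}: expected a YAML list of guild definitions")
    defs = []
    for e in entries:
        try:
            defs.append(
                GuildDefinition(
                    guild_name=str(e["guild_name"]),
                    rank=str(e["rank"]),
                    names=tuple(str(n) for n in e["names"]),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: guild entry missing key {exc}") from None
    return defs


# ---------------------------------------------------------------------------
# outputs

def write_drive_tsv(results: dict[str, list[DriveResult]], path: str | Path) -> None:
    """Tidy TSV of drive-profile rows: one per site x depth x reaction."""
    rows = []
    for (site, reaction_name), drive in results.items():
        for r in drive:
            rows.append(
                {
                    "site": site,
                    "reaction": reaction_name,
                    "depth": r.depth_label,
                    "delta_GA_kJ": r.delta_GA,
                    "F_T": r.F_T,
                    "F_T_clamped": r.F_T_clamped,
                    "F_K": r.F_K,
                    "relative_rate": r.relative_rate,
                    "flags": ",".join(r.flags),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP-like distance matrix: count line, then label + row."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.data):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().strip())
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(labels=labels, data=np.array(rows))
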