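"""End-to-end orchestration: simulate or load data, run every analysis stage.

``run_all`` takes a :class:`RunConfig` (real input paths or a synthetic
configuration), runs alpha diversity with rarefaction CIs, beta-diversity
zoning (Jaccard + UPGMA, Yue-Clayton + PCoA), across-site ANOVA, guild
assignment and per-zone co-abundance regressions, and the thermodynamic-
kinetic drive profiles, writing tidy TSVs plus a manifest.  All randomness
flows from the single configured seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
from scipy import stats

from . import __version__, community, energetics, guilds, io, synthetic
from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 1498


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input mode: either ``synthetic`` is set, or at least one of
    the real-input paths (shared/taxonomy/geochem) is given.  Community
    analyses need shared (+ taxonomy for guilds); drive profiles need
    geochemistry; missing inputs skip their stage with a logged notice.
    """

    seed: int
    outdir: str | Path = "results/run"
    synthetic: synthetic.SyntheticConfig | None = None
    shared_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    geochem_path: str | Path | None = None
    reaction_config: str | Path | None = None
    guild_file: str | Path | None = None
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    ci_iterations: int = 1000
    k_zones: int = 3
    srb_mode: str = "order"

    def __post_init__(self) -> None:
        real = any((self.shared_path, self.taxonomy_path, self.geochem_path))
        if self.synthetic is not None and real:
            raise ConfigurationError("give either synthetic config or real input paths, not both")
        if self.synthetic is None and not real:
            raise ConfigurationError("no inputs: set synthetic or at least one input path")

    def config_hash(self) -> str:
        def encode(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: encode(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, dict):
                return {str(k): encode(x) for k, x in sorted(v.items())}
            if isinstance(v, (list, tuple)):
                return [encode(x) for x in v]
            return v

        fields = encode(self)
        fields.pop("outdir", None)  # hash the analysis, not the destination
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _zone_number(label: str) -> int:
    return int(label.split()[-1])


def report_zones(
    diversity: pd.DataFrame,
    zones: dict[str, str],
    geochem: pd.DataFrame | None = None,
    guild_table: pd.DataFrame | None = None,
    metadata: dict[str, community.SampleInfo] | None = None,
) -> pd.DataFrame:
    """Per-zone summary: n, mean +/- 95% CI of each alpha index, pH/Eh ranges, guild fractions.

    Zones that lost all their samples (e.g. to rarefaction drops) still get
    a row with n=0 and blank statistics.
    """
    indices = ["goods_coverage", "chao1", "shannon", "inv_simpson", "evenness"]
    zone_labels = sorted(set(zones.values()), key=_zone_number)
    rows = []
    div = diversity.set_index("sample") if "sample" in diversity.columns else diversity
    for zone in zone_labels:
        members = sorted(s for s, z in zones.items() if z == zone)
        present = [s for s in members if s in div.index]
        row: dict = {"zone": zone, "n": len(present)}
        for idx in indices:
            if present:
                vals = div.loc[present, idx].astype(float).dropna()
                row[f"{idx}_mean"] = vals.mean() if len(vals) else np.nan
                if len(vals) > 1:
                    lo, hi = stats.t.interval(0.95, len(vals) - 1, loc=vals.mean(), scale=stats.sem(vals))
                    row[f"{idx}_ci_low"], row[f"{idx}_ci_high"] = lo, hi
                else:
                    row[f"{idx}_ci_low"] = row[f"{idx}_ci_high"] = np.nan
            else:
                row[f"{idx}_mean"] = row[f"{idx}_ci_low"] = row[f"{idx}_ci_high"] = np.nan
        if geochem is not None and metadata is not None and present:
            keys = {
                (metadata[s].site, metadata[s].depth_top_cm)
                for s in present
                if s in metadata
            }
            sel = geochem[
                [
                    (r["site"], r["depth_top_cm"]) in keys
                    for _, r in geochem.iterrows()
                ]
            ]
            if not sel.empty:
                row["pH_min"], row["pH_max"] = sel["pH"].min(), sel["pH"].max()
                row["Eh_mV_min"], row["Eh_mV_max"] = sel["Eh_mV"].min(), sel["Eh_mV"].max()
        if guild_table is not None and present:
            gt = guild_table.loc[[s for s in present if s in guild_table.index]]
            if not gt.empty:
                for g in gt.columns:
                    if g in ("total", "unassigned"):
                        continue
                    row[f"{g}_fraction"] = float((gt[g] / gt["total"]).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kwargs)


def run_all(cfg: RunConfig) -> dict:
    """Run every applicable stage and write the outputs atomically.

    Returns the manifest (also written as ``manifest.json``): config hash,
    seed, package version, the artifact list, and sample accounting.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tmpdir = outdir / f".tmp-{os.getpid()}"
    if tmpdir.exists():
        shutil.rmtree(tmpdir)
    tmpdir.mkdir()
    artifacts: list[str] = []
    notes: list[str] = []

    try:
        # ------------------------------------------------ inputs
        table = None
        geochem = None
        if cfg.synthetic is not None:
            table, truth = synthetic.gen_otu_table(cfg.synthetic)
            geochem = synthetic.gen_geochem_profile(cfg.synthetic)
            with open(tmpdir / "ground_truth.json", "w") as fh:
                json.dump(truth, fh, indent=1, sort_keys=True)
            artifacts.append("ground_truth.json")
        else:
            if cfg.shared_path:
                table = io.load_otu_table(cfg.shared_path, cfg.taxonomy_path)
            if cfg.geochem_path:
                geochem = io.read_geochem(cfg.geochem_path)

        n_input = table.n_samples if table is not None else 0
        rarefied = None
        zones: dict[str, str] = {}
        div_frame = None
        guild_frame = None

        # ------------------------------------------------ community stages
        if table is not None:
            records = community.alpha_with_ci(
                table, cfg.rarefaction_depth, n_iter=cfg.ci_iterations, seed=cfg.seed
            )
            div_frame = community.diversity_frame(records)
            _write(div_frame, tmpdir / "diversity.tsv")
            artifacts.append("diversity.tsv")

            rarefied = community.rarefy(table, cfg.rarefaction_depth, seed=cfg.seed)
            dropped = sorted(set(table.sample_ids) - set(rarefied.sample_ids))
            for sid in dropped:
                notes.append(f"dropped {sid}: fewer than {cfg.rarefaction_depth} reads")

            if rarefied.n_samples >= 2:
                jac = community.distance_matrix(rarefied, "jaccard")
                io.write_distance_tsv(jac, tmpdir / "jaccard.dist.tsv")
                yc = community.distance_matrix(rarefied, "yue_clayton")
                io.write_distance_tsv(yc, tmpdir / "yueclayton.dist.tsv")
                artifacts += ["jaccard.dist.tsv", "yueclayton.dist.tsv"]

                tree = community.upgma(jac)
                (tmpdir / "upgma.nwk").write_text(tree.to_newick() + "\n")
                artifacts.append("upgma.nwk")

                depths = {
                    s: info.depth_mid_cm for s, info in rarefied.metadata.items()
                }
                k = min(cfg.k_zones, rarefied.n_samples)
                zones = community.zone_cut(tree, k, depths or None)
                zone_df = pd.DataFrame(
                    sorted(zones.items()), columns=["sample", "zone"]
                )
                _write(zone_df, tmpdir / "zones.tsv")
                artifacts.append("zones.tsv")

                ord_res = community.pcoa(yc)
                coords = ord_res.coordinates.reset_index(names="sample")
                _write(coords, tmpdir / "pcoa.tsv")
                eig = pd.DataFrame(
                    {
                        "axis": np.arange(1, len(ord_res.eigenvalues) + 1),
                        "eigenvalue": ord_res.eigenvalues,
                        "proportion_explained": ord_res.proportion_explained,
                    }
                )
                _write(eig, tmpdir / "pcoa_eigenvalues.tsv")
                artifacts += ["pcoa.tsv", "pcoa_eigenvalues.tsv"]

            # across-site ANOVA on the inverse Simpson index
            sites = {}
            for _, row in div_frame.iterrows():
                info = table.metadata.get(row["sample"]) or io.parse_sample_id(row["sample"])
                if info is not None and np.isfinite(row["inv_simpson"]):
                    sites.setdefault(info.site, []).append(float(row["inv_simpson"]))
            if len(sites) >= 2 and all(len(v) for v in sites.values()):
                f, p = community.anova_oneway([sites[s] for s in sorted(sites)])
                anova_df = pd.DataFrame(
                    [
                        {
                            "index": "inv_simpson",
                            "grouping": "site",
                            "F": f,
                            "p": p,
                            "df_between": len(sites) - 1,
                            "df_within": sum(len(v) for v in sites.values()) - len(sites),
                        }
                    ]
                )
                _write(anova_df, tmpdir / "anova.tsv")
                artifacts.append("anova.tsv")

            # guild stages need taxonomy
            if rarefied is not None and rarefied.taxonomy and rarefied.n_samples:
                if cfg.guild_file:
                    defs = io.load_guild_definitions(cfg.guild_file)
                else:
                    defs = guilds.default_guilds(cfg.srb_mode)
                guild_frame = guilds.assign_guilds(rarefied, defs)
                _write(guild_frame.reset_index(), tmpdir / "guilds.tsv")
                artifacts.append("guilds.tsv")

                reg_rows = []
                pair = [d.guild_name for d in defs[:2]]
                if len(pair) == 2 and zones:
                    for zone in sorted(set(zones.values()), key=_zone_number):
                        members = [
                            s for s, z in zones.items() if z == zone and s in guild_frame.index
                        ]
                        if len(members) < 3:
                            notes.append(f"{zone}: {len(members)} samples, regression skipped")
                            continue
                        x = guild_frame.loc[members, pair[0]]
                        y = guild_frame.loc[members, pair[1]]
                        if np.ptp(x.to_numpy()) == 0:
                            notes.append(f"{zone}: zero variance in {pair[0]}, regression skipped")
                            continue
                        fit = guilds.guild_regression(x, y)
                        reg_rows.append(
                            {
                                "zone": zone,
                                "x_guild": pair[0],
                                "y_guild": pair[1],
                                "slope": fit.slope,
                                "intercept": fit.intercept,
                                "r_squared": fit.r_squared,
                                "p_value": fit.p_value,
                                "n": fit.n,
                            }
                        )
                if reg_rows:
                    _write(pd.DataFrame(reg_rows), tmpdir / "guild_regressions.tsv")
                    artifacts.append("guild_regressions.tsv")

            if div_frame is not None and zones:
                summary = report_zones(
                    div_frame, zones, geochem, guild_frame, rarefied.metadata
                )
                _write(summary, tmpdir / "zone_summary.tsv")
                artifacts.append("zone_summary.tsv")
        else:
            notes.append("no OTU inputs: community and guild stages skipped")
            logger.info("no OTU inputs: community and guild stages skipped")

        # ------------------------------------------------ energetics stage
        if geochem is not None:
            if cfg.reaction_config:
                reaction, params, activity_model = io.load_reaction_config(cfg.reaction_config)
            else:
                reaction = energetics.ACETOTROPHIC_SULFATE_REDUCTION
                params = energetics.KineticParams()
                activity_model = energetics.ActivityModel()
            drive = {}
            for site in sorted(geochem["site"].unique()):
                profile = io.profile_from_geochem(geochem, site)
                drive[(site, reaction.name)] = energetics.evaluate_profile(
                    profile, reaction, params, activity_model
                )
            io.write_drive_tsv(drive, tmpdir / "drive.tsv")
            artifacts.append("drive.tsv")
        else:
            notes.append("no geochemistry input: drive stage skipped")
            logger.info("no geochemistry input: drive stage skipped")

        n_used = rarefied.n_samples if rarefied is not None else 0
        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "artifacts": sorted(artifacts),
            "samples_input": n_input,
            "samples_used": n_used,
            "samples_dropped": n_input - n_used,
            "notes": notes,
        }
        with open(tmpdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

        # atomic publish: move everything into place only on full success
        for name in artifacts + ["manifest.json"]:
            os.replace(tmpdir / name, outdir / name)
    finally:
        shutil.rmtree(tmpdir, ignore_errors=True)
    return manifest


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level: str) -> None:
    """CASS microbiome analysis: diversity, zoning, guilds, kinetic drives."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))


@cli.command()
@click.option("--seed", type=int, required=True)
@click.option("--outdir", type=click.Path(), required=True)
def simulate(seed: int, outdir: str) -> None:
    """Write a synthetic dataset (shared, taxonomy, geochem CSV, ground truth)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.SyntheticConfig(seed=seed)
    table, truth = synthetic.gen_otu_table(cfg)
    io.write_shared(table, out / "synthetic.shared")
    io.write_constaxonomy(table, out / "synthetic.cons.taxonomy")
    io.write_geochem(synthetic.gen_geochem_profile(cfg), out / "synthetic_geochem.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    click.echo(f"wrote synthetic dataset to {out}")


def _common_run(cfg: RunConfig) -> None:
    manifest = run_all(cfg)
    click.echo(json.dumps(manifest, indent=1, sort_keys=True))


@cli.command("all")
@click.option("--seed", type=int, required=True)
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--shared", "shared_path", type=click.Path(exists=True), default=None)
@click.option("--taxonomy", "taxonomy_path", type=click.Path(exists=True), default=None)
@click.option("--geochem", "geochem_path", type=click.Path(exists=True), default=None)
@click.option("--synthetic", "use_synthetic", is_flag=True, help="Generate inputs instead of reading them.")
@click.option("--depth", type=int, default=DEFAULT_RAREFACTION_DEPTH, show_default=True)
@click.option("--iterations", type=int, default=1000, show_default=True)
@click.option("--k-zones", type=int, default=3, show_default=True)
@click.option("--reaction-config", type=click.Path(exists=True), default=None)
@click.option("--guild-file", type=click.Path(exists=True), default=None)
def all_cmd(seed, outdir, shared_path, taxonomy_path, geochem_path, use_synthetic,
            depth, iterations, k_zones, reaction_config, guild_file) -> None:
    """Run every stage end to end."""
    cfg = RunConfig(
        seed=seed,
        outdir=outdir,
        synthetic=synthetic.SyntheticConfig(seed=seed) if use_synthetic else None,
        shared_path=shared_path,
        taxonomy_path=taxonomy_path,
        geochem_path=geochem_path,
        reaction_config=reaction_config,
        guild_file=guild_file,
        rarefaction_depth=depth,
        ci_iterations=iterations,
        k_zones=k_zones,
    )
    _common_run(cfg)


@cli.command()
@click.option("--seed", type=int, required=True)
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--shared", "shared_path", type=click.Path(exists=True), required=True)
@click.option("--taxonomy", "taxonomy_path", type=click.Path(exists=True), default=None)
@click.option("--depth", type=int, default=DEFAULT_RAREFACTION_DEPTH, show_default=True)
@click.option("--iterations", type=int, default=1000, show_default=True)
def diversity(seed, outdir, shared_path, taxonomy_path, depth, iterations) -> None:
    """Alpha diversity with rarefaction CIs (plus ANOVA across sites)."""
    cfg = RunConfig(
        seed=seed, outdir=outdir, shared_path=shared_path,
        taxonomy_path=taxonomy_path, rarefaction_depth=depth, ci_iterations=iterations,
    )
    _common_run(cfg)


@cli.command()
@click.option("--seed", type=int, required=True)
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--shared", "shared_path", type=click.Path(exists=True), required=True)
@click.option("--depth", type=int, default=DEFAULT_RAREFACTION_DEPTH, show_default=True)
@click.option("--k-zones", type=int, default=3, show_default=True)
def zones(seed, outdir, shared_path, depth, k_zones) -> None:
    """Beta diversity, UPGMA tree, zone cut, PCoA."""
    cfg = RunConfig(
        seed=seed, outdir=outdir, shared_path=shared_path,
        rarefaction_depth=depth, k_zones=k_zones, ci_iterations=100,
    )
    _common_run(cfg)


@cli.command("guilds")
@click.option("--seed", type=int, required=True)
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--shared", "shared_path", type=click.Path(exists=True), required=True)
@click.option("--taxonomy", "taxonomy_path", type=click.Path(exists=True), required=True)
@click.option("--guild-file", type=click.Path(exists=True), default=None)
@click.option("--depth", type=int, default=DEFAULT_RAREFACTION_DEPTH, show_default=True)
def guilds_cmd(seed, outdir, shared_path, taxonomy_path, guild_file, depth) -> None:
    """Guild assignment and per-zone co-abundance regressions."""
    cfg = RunConfig(
        seed=seed, outdir=outdir, shared_path=shared_path, taxonomy_path=taxonomy_path,
        guild_file=guild_file, rarefaction_depth=depth, ci_iterations=100,
    )
    _common_run(cfg)


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--geochem", "geochem_path", type=click.Path(exists=True), required=True)
@click.option("--reaction-config", type=click.Path(exists=True), default=None)
def drive(seed, outdir, geochem_path, reaction_config) -> None:
    """Thermodynamic-kinetic drive profiles from a geochemistry CSV."""
    cfg = RunConfig(
        seed=seed, outdir=outdir, geochem_path=geochem_path,
        reaction_config=reaction_config,
    )
    _common_run(cfg)
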