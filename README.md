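# cassmicro

Microbiome and bioenergetics analysis for **coastal acid sulfate soils
(CASS)** — salt-marsh and wetland sediments whose iron sulfides generate
sulfuric acid when drained and exposed to air. Tidal re-inundation is a
passive remediation strategy: seawater supplies sulfate and bicarbonate,
and microbial iron and sulfate reduction consume acidity and re-precipitate
iron sulfides. Whether that works hinges on two questions this package
addresses quantitatively:

1. **Are the reducing metabolisms limited by energy or by substrate
   kinetics?** Answered with a thermodynamic–kinetic rate law evaluated
   over geochemical depth profiles.
2. **How are the microbial communities and the iron-/sulfate-reducing
   guilds (IRB/SRB) distributed across sites and depths?** Answered with
   16S OTU-table diversity analysis, dendrogram zoning, ordination, and
   guild co-abundance regression.

It is aimed at geomicrobiologists and biogeochemists working with
depth-resolved 16S surveys (mothur `shared`/`cons.taxonomy` dialects) and
matching pore-water chemistry tables.

## The rate law

The metabolic rate of a terminal electron-accepting process such as
acetotrophic sulfate reduction,

> SO₄²⁻ + CH₃COO⁻ ⇌ HS⁻ + 2 HCO₃⁻,

is modelled as

```
v = k [X] · F_T · F_K

F_T = 1 − exp((ΔG_A + ΔG_C) / (χRT))          thermodynamic factor
F_K = Π_s [s] / (K_s + [s])                    dual-Monod kinetic factor
ΔG_A = ΔG° + RT ln Q,   Q = Π (γ_i [i])^ν_i    in-situ Gibbs energy
```

where `k[X]` lumps the rate constant and biomass, ΔG_C is the energy the
organism conserves per mole of sulfate (45 kJ/mol by default, literature
range 33–47), χ is the average stoichiometric number (6), ΔG° = −47.6
kJ/mol, and the default half-saturation constants are K_acetate = 5.0×10⁻⁶
M and K_sulfate = 9.17×10⁻⁴ M. Both factors lie in [0, 1]; values near 1
mean the metabolism runs far from equilibrium, unthrottled. Activity
coefficients come either from the Davies equation (given an ionic
strength) or from a fixed per-species set defaulting to estuarine
midpoints (γ_SO₄ ≈ 0.161, γ_acetate = γ_HCO₃ ≈ 0.683, γ_HS ≈ 0.641).

## The community analysis

OTU tables are rarefied to a common depth (default 1498 reads), and alpha
diversity (Good's coverage, bias-corrected Chao1, Shannon, unbiased
inverse Simpson, Simpson evenness) is reported with 95% CIs over repeated
rarefactions. Beta diversity uses incidence-based Jaccard distances
clustered by UPGMA into depth zones, and abundance-based Yue–Clayton
distances ordinated by PCoA. One-way ANOVA tests diversity differences
across sites, and OLS regression quantifies IRB–SRB co-abundance within
zones. A synthetic-data module generates zone-structured
Dirichlet-multinomial communities, guild read pairs with a controllable
correlation, and geochemical profiles inside field-observed ranges, so the
whole pipeline is testable without sequence downloads.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
dataset and write tables under `results/`:

```sh
python analysis/01_simulate.py    # 3 sites x 10 depths, 150 OTUs
python analysis/02_diversity.py
python analysis/03_zones.py
python analysis/04_guilds.py
python analysis/05_drive.py
```

Output of `05_drive.py` (seed 42):

```
30 depth points across 3 sites
F_T range 0.858-0.968; F_K range 0.747-0.980
relative rate range 0.641-0.948
thermodynamic drive is high throughout: no energetic limitation
0 rows carry data-quality flags
```

The thermodynamic factor stays above 0.85 everywhere in the profile —
reactants (sulfate 3–45 mM, acetate up to 95 mM) far outweigh products
(sulfide capped at 2 μM, bicarbonate at 1.6 mM), so energy supply does not
throttle sulfate reduction; with substrates well above their
half-saturation constants, neither do the kinetics. `03_zones.py` reports
the UPGMA zone cut recovering the generating three-zone structure
(adjusted Rand 1.0), and `02_diversity.py` an across-site ANOVA on the
inverse Simpson index of F = 17.1, p ≈ 2×10⁻⁵.

The same stages are available as a CLI (`cass simulate|diversity|zones|
guilds|drive|all`) for running on real mothur-format inputs.

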