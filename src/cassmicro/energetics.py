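"""Combined thermodynamic-kinetic rate law for microbial redox metabolisms.

The metabolic rate of a terminal electron-accepting process such as
acetotrophic sulfate reduction is modelled as

    v = k [X] * F_T * F_K

where ``k [X]`` lumps the rate constant and biomass, ``F_T`` is the
thermodynamic limitation factor

    F_T = 1 - exp((dG_A + dG_C) / (chi * R * T))

and ``F_K`` is the dual-Monod kinetic factor, a product of
``[S] / (K_S + [S])`` terms over the rate-limiting substrates
(electron donor and acceptor).  ``dG_A`` is the in-situ Gibbs free
energy of the catabolic reaction, ``dG_C`` the energy conserved by the
organism per mole of limiting substrate, and ``chi`` the average
stoichiometric number.  Both factors lie in [0, 1] for a feasible
metabolism; F_T <= 0 signals that the environment no longer pays the
organism's energetic cost.

Units: concentrations in mol/L, energies in kJ/mol, temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError, InvalidInputError, UndefinedQuotientError

#: Gas constant, J/(K mol).  Energies are reported in kJ/mol.
R_GAS = 8.314

#: Charge numbers used by the Davies activity model for the default species.
SPECIES_CHARGE: dict[str, int] = {
    "sulfate": -2,
    "acetate": -1,
    "sulfide": -1,  # HS- at circumneutral pH
    "bicarbonate": -1,
    "Fe2+": 2,
    "H+": 1,
}

#: Midpoints of the activity-coefficient ranges computed for estuarine pore
#: water at the study site (sulfate 0.1561-0.16508, acetate and bicarbonate
#: 0.6825-0.6842, bisulfide 0.6395-0.6426).
FIXED_GAMMA_MIDPOINTS: dict[str, float] = {
    "sulfate": 0.16059,
    "acetate": 0.68335,
    "sulfide": 0.64105,
    "bicarbonate": 0.68335,
}

#: Detection-limit substitutions for species routinely below detection in
#: sulfidic pore waters: bisulfide capped at its theoretical ceiling of 2 uM,
#: bicarbonate at the highest value measured on site, 1.6 mM.
DEFAULT_DETECTION_LIMITS: dict[str, float] = {
    "sulfide": 2e-6,
    "bicarbonate": 1.6e-3,
}

#: Concentration floor (mol/L) substituted for a zero concentration so the
#: reaction quotient stays defined; flagged, never silent, in profiles.
DEFAULT_CONCENTRATION_FLOOR = 1e-6


@dataclass(frozen=True)
class Reaction:
    """A catabolic reaction with its energetic bookkeeping.

    Stoichiometric coefficients are signed: products positive, reactants
    negative.  ``delta_G0`` is the standard Gibbs energy at the reference
    temperature (kJ/mol), ``chi`` the average stoichiometric number and
    ``delta_GC`` the conserved energy per mole of limiting substrate (kJ/mol).
    """

    name: str
    stoichiometry: dict[str, float]
    delta_G0: float
    chi: float
    delta_GC: float

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise InvalidInputError(f"reaction {self.name!r}: empty stoichiometry")
        for sp, nu in self.stoichiometry.items():
            if nu == 0:
                raise InvalidInputError(f"reaction {self.name!r}: zero coefficient for {sp!r}")
        if not self.chi > 0:
            raise InvalidInputError(f"reaction {self.name!r}: chi must be > 0")
        if self.delta_GC < 0:
            raise InvalidInputError(f"reaction {self.name!r}: delta_GC must be >= 0")


#: Acetotrophic sulfate reduction, SO4(2-) + CH3COO- <-> HS- + 2 HCO3-.
#: dG0 = -47.6 kJ/mol; chi = 6; dG_C = 45 kJ/mol (literature range 33-47).
ACETOTROPHIC_SULFATE_REDUCTION = Reaction(
    name="acetotrophic_sulfate_reduction",
    stoichiometry={"sulfate": -1.0, "acetate": -1.0, "sulfide": 1.0, "bicarbonate": 2.0},
    delta_G0=-47.6,
    chi=6.0,
    delta_GC=45.0,
)

#: Half-saturation constants for the default dual-Monod pair (mol/L).
DEFAULT_HALF_SATURATION: dict[str, float] = {
    "acetate": 5.0e-6,
    "sulfate": 9.17e-4,
}


def iron_reduction(delta_G0: float, chi: float, delta_GC: float) -> Reaction:
    """Heterotrophic ferrihydrite reduction, Fe(OH)3 + 0.25 CH2O + 2 H+ -> Fe2+ + 0.25 CO2 + 2.75 H2O.

    No standard energetic constants are bundled for this reaction: callers
    must supply ``delta_G0`` (kJ/mol), ``chi`` and ``delta_GC`` (kJ/mol)
    appropriate to their mineral phase and organism.  Water and the solid
    Fe(OH)3 phase are taken at unit activity and omitted from the quotient.
    """
    return Reaction(
        name="iron_reduction",
        stoichiometry={"organic_carbon": -0.25, "H+": -2.0, "Fe2+": 1.0, "CO2": 0.25},
        delta_G0=delta_G0,
        chi=chi,
        delta_GC=delta_GC,
    )


@dataclass(frozen=True)
class EnvironmentState:
    """Pore-water chemistry at one depth point.

    ``concentrations`` are molar (mol/L).  Activity coefficients may be
    supplied per species; otherwise they are computed from ``ionic_strength``
    by the configured activity model.
    """

    concentrations: dict[str, float]
    temperature: float = 298.0
    activity_coefficients: dict[str, float] | None = None
    ionic_strength: float | None = None

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be > 0 K")
        for sp, c in self.concentrations.items():
            if c < 0:
                raise InvalidInputError(f"negative concentration for {sp!r}")
        if self.activity_coefficients is not None:
            for sp, g in self.activity_coefficients.items():
                if not (0 < g <= 1.5):
                    raise InvalidInputError(f"activity coefficient for {sp!r} outside (0, 1.5]")
        if self.ionic_strength is not None and self.ionic_strength < 0:
            raise InvalidInputError("ionic strength must be >= 0")


@dataclass(frozen=True)
class KineticParams:
    """Half-saturation constants (mol/L) and the lumped k*[X] rate scale."""

    half_saturation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HALF_SATURATION)
    )
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        for sp, k in self.half_saturation.items():
            if not k > 0:
                raise InvalidInputError(f"half-saturation constant for {sp!r} must be > 0")


@dataclass(frozen=True)
class ActivityModel:
    """How species activities are derived from concentrations.

    ``mode='davies'`` computes gamma from the ionic strength with the Davies
    equation; ``mode='fixed'`` uses the configured per-species coefficients
    (defaulting to the estuarine midpoints above).  Coefficients supplied
    directly on an :class:`EnvironmentState` always win.
    """

    mode: str = "fixed"
    fixed_gammas: dict[str, float] = field(
        default_factory=lambda: dict(FIXED_GAMMA_MIDPOINTS)
    )
    davies_A: float = 0.509

    def __post_init__(self) -> None:
        if self.mode not in ("davies", "fixed"):
            raise ConfigurationError(f"unknown activity mode {self.mode!r}")


@dataclass(frozen=True)
class ThermodynamicFactor:
    """Raw F_T (may be negative near/past equilibrium) and its clamp to [0, 1]."""

    raw: float
    clamped: float


@dataclass(frozen=True)
class DriveResult:
    """Per-depth evaluation of the rate law."""

    depth_label: str
    delta_GA: float
    F_T: float
    F_T_clamped: float
    F_K: float
    relative_rate: float
    flags: tuple[str, ...] = ()


def activity_coefficient(
    charge: int,
    ionic_strength: float,
    temperature: float = 298.0,
    A: float = 0.509,
) -> float:
    """Single-ion activity coefficient from the Davies equation.

    log10(gamma) = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I), with A = 0.509 for
    water at 25 C.  The result is clipped at 1.0 so gamma stays in (0, 1]
    (the raw Davies expression exceeds unity only above I ~ 5.9 mol/L, far
    outside the estuarine range this model is meant for).
    """
    if ionic_strength < 0:
        raise InvalidInputError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return 1.0
    sqrt_i = math.sqrt(ionic_strength)
    log10_gamma = -A * charge * charge * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)
    return min(10.0 ** log10_gamma, 1.0)


def _gamma_for(species: str, env: EnvironmentState, model: ActivityModel) -> float:
    if env.activity_coefficients and species in env.activity_coefficients:
        return env.activity_coefficients[species]
    if model.mode == "fixed":
        return model.fixed_gammas.get(species, 1.0)
    # Davies mode needs an ionic strength and a charge number.
    if env.ionic_strength is None:
        raise ConfigurationError(
            f"Davies activity mode needs an ionic strength to compute gamma for {species!r}"
        )
    charge = SPECIES_CHARGE.get(species)
    if charge is None:
        raise ConfigurationError(f"no charge number known for species {species!r}")
    return activity_coefficient(charge, env.ionic_strength, env.temperature, model.davies_A)


def gibbs_energy(
    reaction: Reaction,
    env: EnvironmentState,
    activity_model: ActivityModel | None = None,
    floor: float | None = None,
) -> float:
    """In-situ Gibbs free energy dG_A = dG0 + RT ln Q, in kJ/mol.

    Q is the activity quotient Prod (gamma_i [i])^nu_i with products over
    reactants.  A species whose activity is zero makes Q undefined and raises
    :class:`UndefinedQuotientError` unless a detection-limit ``floor``
    (mol/L, applied to the concentration) is given.
    """
    if activity_model is None:
        activity_model = ActivityModel()
    rt_kj = R_GAS * env.temperature / 1000.0
    ln_q = 0.0
    for species, nu in reaction.stoichiometry.items():
        try:
            conc = env.concentrations[species]
        except KeyError:
            raise ConfigurationError(
                f"no concentration for species {species!r} in reaction {reaction.name!r}"
            ) from None
        if conc <= 0:
            if floor is None:
                raise UndefinedQuotientError(
                    f"zero activity for {species!r}: reaction quotient undefined "
                    "(configure a detection-limit floor to substitute)"
                )
            conc = floor
        activity = _gamma_for(species, env, activity_model) * conc
        ln_q += nu * math.log(activity)
    return reaction.delta_G0 + rt_kj * ln_q


def thermodynamic_factor(
    delta_GA: float,
    reaction: Reaction,
    temperature: float = 298.0,
) -> ThermodynamicFactor:
    """F_T = 1 - exp((dG_A + dG_C) / (chi R T)); raw and clamped-to-zero values.

    F_T is exactly 0 when dG_A = -dG_C (the environment just covers the
    conserved energy) and approaches 1 as dG_A becomes strongly negative.
    A negative raw value marks an energetically infeasible metabolism.
    """
    chi_rt = reaction.chi * R_GAS * temperature / 1000.0
    raw = 1.0 - math.exp((delta_GA + reaction.delta_GC) / chi_rt)
    return ThermodynamicFactor(raw=raw, clamped=max(raw, 0.0))


def kinetic_factor(
    env: EnvironmentState,
    params: KineticParams,
    substrates: tuple[str, ...] | list[str],
) -> float:
    """Dual (or multi) Monod factor F_K = Prod [S]/(K_S + [S]) over substrates."""
    f_k = 1.0
    for species in substrates:
        try:
            conc = env.concentrations[species]
        except KeyError:
            raise ConfigurationError(f"no concentration for substrate {species!r}") from None
        try:
            k = params.half_saturation[species]
        except KeyError:
            raise ConfigurationError(
                f"no half-saturation constant for substrate {species!r}"
            ) from None
        f_k *= conc / (k + conc)
    return f_k


def relative_rate(
    F_T: float,
    F_K: float,
    params: KineticParams | None = None,
    ignore_thermo: bool = False,
) -> float:
    """Rate relative to k[X]: rate_scale * clamp(F_T) * F_K.

    With ``ignore_thermo`` the thermodynamic factor is dropped (the far-from-
    equilibrium regime where v = k[X] F_K).
    """
    scale = params.rate_scale if params is not None else 1.0
    if ignore_thermo:
        return scale * F_K
    return scale * max(F_T, 0.0) * F_K


def evaluate_profile(
    profile: list[tuple[str, EnvironmentState]],
    reaction: Reaction = ACETOTROPHIC_SULFATE_REDUCTION,
    params: KineticParams | None = None,
    activity_model: ActivityModel | None = None,
    substrates: tuple[str, ...] | None = None,
    detection_limits: dict[str, float] | None = None,
    floor: float = DEFAULT_CONCENTRATION_FLOOR,
) -> list[DriveResult]:
    """Evaluate the rate law at every depth of an ordered geochemical profile.

    The detection-limit policy fills species that are absent from a row
    (bisulfide at its 2 uM ceiling, bicarbonate at 1.6 mM by default) and
    floors zero concentrations at ``floor`` mol/L; each substitution is
    recorded as a flag on the :class:`DriveResult`.
    """
    if not profile:
        raise InvalidInputError("empty profile")
    if params is None:
        params = KineticParams()
    if detection_limits is None:
        detection_limits = dict(DEFAULT_DETECTION_LIMITS)
    if substrates is None:
        substrates = tuple(
            sp
            for sp, nu in reaction.stoichiometry.items()
            if nu < 0 and sp in params.half_saturation
        )

    results: list[DriveResult] = []
    for depth_label, env in profile:
        flags: list[str] = []
        conc = dict(env.concentrations)
        for species in reaction.stoichiometry:
            if species not in conc and species in detection_limits:
                conc[species] = detection_limits[species]
                flags.append(f"{species}-detection-limit")
        for species in reaction.stoichiometry:
            if conc.get(species, 0.0) <= 0:
                conc[species] = floor
                flags.append(f"{species}-below-detection")
        env_filled = replace(env, concentrations=conc)

        d_ga = gibbs_energy(reaction, env_filled, activity_model, floor=floor)
        ft = thermodynamic_factor(d_ga, reaction, env_filled.temperature)
        if ft.raw < 0:
            flags.append("thermodynamically-infeasible")
        f_k = kinetic_factor(env_filled, params, substrates)
        rate = relative_rate(ft.raw, f_k, params)
        results.append(
            DriveResult(
                depth_label=depth_label,
                delta_GA=d_ga,
                F_T=ft.raw,
                F_T_clamped=ft.clamped,
                F_K=f_k,
                relative_rate=rate,
                flags=tuple(flags),
            )
        )
    return results
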