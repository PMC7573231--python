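"""Fasting mass-loss bioenergetic model.

Apportions daily body-mass loss into pelage, water, fat-free mass and
fat, converts the metabolizable components into daily energy expenditure
via fixed energy equivalents, and extrapolates a whole-body skeletal
muscle leak respiratory capacity from a mass-specific flux.

Two energy paths are provided: the kcal path (9 / 1 kcal g^-1, canonical
for the kcal figure) and the kJ path (37.7 / 4.2 kJ g^-1).  They differ
by ~0.3% because 9 kcal g^-1 x 4.184 != 37.7 kJ g^-1; reports use the kJ
path and document the tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import ConfigError, ValidationError

__all__ = [
    "SealRecord",
    "CompositionModel",
    "EnergyEquivalents",
    "EnergyBudget",
    "daily_mass_loss",
    "apportion",
    "energy_expenditure",
    "muscle_mass",
    "flux_to_mlO2",
    "mlO2_to_flux",
    "leak_capacity",
    "field_metabolic_rate",
    "seal_budget",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class SealRecord:
    """One animal's molt record: paired body masses and days ashore."""

    animal_id: str
    mass_pre: float  # kg
    mass_post: float  # kg
    days_ashore: float  # days

    def __post_init__(self) -> None:
        if self.mass_pre <= 0 or self.mass_post <= 0:
            raise ValidationError(f"{self.animal_id}: masses must be > 0")
        if self.days_ashore <= 0:
            raise ValidationError(f"{self.animal_id}: days_ashore must be > 0")
        if self.mass_post > self.mass_pre:
            warnings.warn(
                f"{self.animal_id}: post-molt mass exceeds pre-molt mass",
                UserWarning,
                stacklevel=2,
            )

    @property
    def mean_mass(self) -> float:
        return 0.5 * (self.mass_pre + self.mass_post)


@dataclass(frozen=True)
class CompositionModel:
    """Composition of lost mass, as fractions of the total daily loss.

    Defaults: 14% molted pelage; the remainder 41% fat, 25% water and
    20% metabolizable fat-free mass (fractions of the total, summing to
    1).  The FFM hydration split (5% dry matter, 15% additional water)
    is stored for reference but takes no part in the energy math: the
    1 kcal g^-1 equivalent applies to the whole hydrated FFM component.
    """

    frac_pelage: float = 0.14
    frac_fat: float = 0.41
    frac_water: float = 0.25
    frac_ffm: float = 0.20
    ffm_dry_frac: float = 0.05
    ffm_extra_water_frac: float = 0.15

    def __post_init__(self) -> None:
        fracs = (self.frac_pelage, self.frac_fat, self.frac_water, self.frac_ffm)
        if any(not (0 <= f <= 1) for f in fracs):
            raise ConfigError("composition fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > _FRACTION_TOL:
            raise ConfigError(
                f"composition fractions sum to {sum(fracs)!r}, expected 1"
            )


@dataclass(frozen=True)
class EnergyEquivalents:
    """Energy, oxygen and scaling constants used by the budget model."""

    fat_kcal_per_g: float = 9.0
    ffm_kcal_per_g: float = 1.0
    fat_kj_per_g: float = 37.7
    ffm_kj_per_g: float = 4.2
    kj_per_kcal: float = 4.184
    o2_kj_per_l: float = 19.7
    molar_volume_l_per_mol: float = 22.4  # STP
    muscle_mass_fraction: float = 0.28
    fmr_kj_per_kg_day: float = 106.5

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")


@dataclass
class EnergyBudget:
    """Daily mass-loss apportionment and the resulting energy figures."""

    daily_loss: float  # kg day^-1
    pelage: float
    water: float
    ffm: float
    fat: float
    dee_kcal: float  # kcal day^-1 (kcal-equivalent path)
    dee_mj: float  # MJ day^-1 (kJ-equivalent path)
    dee_mj_kcal_path: float  # MJ day^-1 via kcal x 4.184
    fat_mj: float  # MJ day^-1 from fat oxidation (kJ path)
    fat_fraction: float = math.nan  # share of energy from fat; NaN if dee == 0
    animal_id: str = ""
    extras: dict = field(default_factory=dict)


def daily_mass_loss(rec: SealRecord) -> tuple[float, float]:
    """(kg lost per day ashore, percent of initial mass lost in total)."""
    lost = rec.mass_pre - rec.mass_post
    return lost / rec.days_ashore, 100.0 * lost / rec.mass_pre


def apportion(
    daily_loss: float, comp: CompositionModel | None = None
) -> tuple[float, float, float, float]:
    """Split a daily mass loss into (pelage, water, ffm, fat) kg day^-1."""
    if daily_loss < 0:
        raise ValidationError(f"daily_loss must be >= 0, got {daily_loss}")
    comp = comp or CompositionModel()
    return (
        daily_loss * comp.frac_pelage,
        daily_loss * comp.frac_water,
        daily_loss * comp.frac_ffm,
        daily_loss * comp.frac_fat,
    )


def energy_expenditure(
    fat: float, ffm: float, eq: EnergyEquivalents | None = None
) -> dict[str, float]:
    """Daily energy expenditure from catabolized fat and fat-free mass.

    Returns dee_kcal (kcal path), dee_mj and fat_mj (kJ path),
    dee_mj_kcal_path (kcal x 4.184), and fat_fraction (fat share of the
    kJ-path total; NaN when total energy is zero).
    """
    if fat < 0 or ffm < 0:
        raise ValidationError("fat and ffm must be >= 0")
    eq = eq or EnergyEquivalents()
    grams_fat, grams_ffm = fat * 1000.0, ffm * 1000.0
    dee_kcal = grams_fat * eq.fat_kcal_per_g + grams_ffm * eq.ffm_kcal_per_g
    fat_kj = grams_fat * eq.fat_kj_per_g
    dee_kj = fat_kj + grams_ffm * eq.ffm_kj_per_g
    return {
        "dee_kcal": dee_kcal,
        "dee_mj": dee_kj / 1000.0,
        "dee_mj_kcal_path": dee_kcal * eq.kj_per_kcal / 1000.0,
        "fat_mj": fat_kj / 1000.0,
        "fat_fraction": fat_kj / dee_kj if dee_kj > 0 else math.nan,
    }


def muscle_mass(body_mass: float, eq: EnergyEquivalents | None = None) -> float:
    """Skeletal muscle mass (kg) as a fixed fraction of body mass."""
    if body_mass <= 0:
        raise ValidationError(f"body_mass must be > 0, got {body_mass}")
    eq = eq or EnergyEquivalents()
    return body_mass * eq.muscle_mass_fraction


def flux_to_mlO2(flux: float, eq: EnergyEquivalents | None = None) -> float:
    """Convert pmol O2 s^-1 mg^-1 to ml O2 kg^-1 min^-1.

    pmol mg^-1 s^-1 is numerically umol kg^-1 s^-1; x60 to per minute,
    then x molar volume (ul per umol) gives ul, /1000 -> ml.
    """
    if flux < 0:
        raise ValidationError(f"flux must be >= 0, got {flux}")
    eq = eq or EnergyEquivalents()
    return flux * 60.0 * eq.molar_volume_l_per_mol / 1000.0


def mlO2_to_flux(mlo2: float, eq: EnergyEquivalents | None = None) -> float:
    """Inverse of :func:`flux_to_mlO2`."""
    if mlo2 < 0:
        raise ValidationError(f"value must be >= 0, got {mlo2}")
    eq = eq or EnergyEquivalents()
    return mlo2 / (60.0 * eq.molar_volume_l_per_mol / 1000.0)


def leak_capacity(
    muscle_kg: float, leak_flux: float, eq: EnergyEquivalents | None = None
) -> float:
    """Whole-muscle leak respiratory capacity, MJ day^-1.

    Uses the unrounded ml O2 kg^-1 min^-1 conversion: whole-muscle
    oxygen consumption x 1440 min day^-1 -> L day^-1, then the oxygen
    energy equivalent (kJ per L O2).
    """
    if muscle_kg <= 0 or leak_flux <= 0:
        raise ValidationError("muscle_kg and leak_flux must be > 0")
    eq = eq or EnergyEquivalents()
    ml_per_min = muscle_kg * flux_to_mlO2(leak_flux, eq)
    l_per_day = ml_per_min * 1440.0 / 1000.0
    return l_per_day * eq.o2_kj_per_l / 1000.0


def field_metabolic_rate(
    body_mass: float, eq: EnergyEquivalents | None = None
) -> float:
    """Free-ranging field metabolic rate, MJ day^-1, scaled from body mass."""
    if body_mass <= 0:
        raise ValidationError(f"body_mass must be > 0, got {body_mass}")
    eq = eq or EnergyEquivalents()
    return body_mass * eq.fmr_kj_per_kg_day / 1000.0


def seal_budget(
    rec: SealRecord,
    comp: CompositionModel | None = None,
    eq: EnergyEquivalents | None = None,
) -> EnergyBudget:
    """Full per-animal energy budget from a molt record."""
    loss, pct = daily_mass_loss(rec)
    pelage, water, ffm, fat = apportion(loss, comp)
    e = energy_expenditure(fat, ffm, eq)
    return EnergyBudget(
        daily_loss=loss,
        pelage=pelage,
        water=water,
        ffm=ffm,
        fat=fat,
        dee_kcal=e["dee_kcal"],
        dee_mj=e["dee_mj"],
        dee_mj_kcal_path=e["dee_mj_kcal_path"],
        fat_mj=e["fat_mj"],
        fat_fraction=e["fat_fraction"],
        animal_id=rec.animal_id,
        extras={"percent_loss": pct, "mean_mass": rec.mean_mass},
    )
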