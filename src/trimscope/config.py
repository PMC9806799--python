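"""Simulation configuration for the synthetic cyclic-immunofluorescence generator.

The generator emulates a cell-resealing Trim-Away experiment read out by
multi-round immunofluorescence imaging: streptolysin-O (SLO) permeabilization
with per-cell heterogeneity, antibody delivery, TRIM21-dependent target
degradation, correlated downstream phospho signals, and confocal-like
acquisition artifacts (stage drift between rounds, bleaching carryover,
background and shot/read noise).

All intensities are arbitrary fluorescence units (AU); all lengths are pixels
unless suffixed ``_um``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Literal

__all__ = [
    "SimConfig",
    "PermHill",
    "DegKinetics",
    "PhosphoLink",
    "NoiseConfig",
    "GradientConfig",
    "CCSubpop",
    "PRESET_NAMES",
]

Condition = Literal["targeting", "NC"]


@dataclass(frozen=True)
class PermHill:
    """Hill curve for the SLO-dose → permeabilization-probability relationship.

    p(dose) = dose^h / (dose^h + k_dose^h), modulated per cell by a lognormal
    membrane-cholesterol factor (SLO binding is cholesterol dependent).
    """

    k_dose: float = 0.12  # µg/ml-equivalent half-saturation dose
    h: float = 2.0
    chol_sigma: float = 0.3  # log-sd of the per-cell cholesterol factor


@dataclass(frozen=True)
class DegKinetics:
    """First-order degradation with saturating antibody and TRIM21 dependence.

    X(t) = X0 * [f_res + (1 - f_res) * exp(-k_i t)],
    k_i = k_max * A/(A + K_A) * T/(T + K_T).

    ``resistant_fraction`` (f_res) models a target pool the ligase cannot
    reach (e.g. organelle-bound protein).
    """

    k_max: float = 1.0  # 1/h
    K_A: float = 150.0  # AU, antibody half-saturation
    K_T: float = 300.0  # AU, TRIM21 half-saturation
    resistant_fraction: float = 0.0


@dataclass(frozen=True)
class PhosphoLink:
    """Downstream phospho channel P = beta * X^gamma * exp(eps), eps~N(0, sd)."""

    beta: float = 0.5
    gamma: float = 0.8
    noise_sd: float = 0.25


@dataclass(frozen=True)
class CCSubpop:
    """High-signal subpopulation (e.g. cell-cycle-driven pS6): with probability
    ``pi``, the linked channel is multiplied by ``fold``."""

    pi: float = 0.15
    fold: float = 2.5
    channel: str = "pS6"


@dataclass(frozen=True)
class NoiseConfig:
    background: float = 8.0  # flat background plane, AU
    gradient: float = 3.0  # amplitude of a linear illumination gradient, AU
    read_sd: float = 2.0  # gaussian read noise sd, AU
    shot: bool = True  # Poisson shot noise on (signal + background)

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(background=0.0, gradient=0.0, read_sd=0.0, shot=False)


@dataclass(frozen=True)
class GradientConfig:
    """Radial delivery falloff for the adherent-electroporation spatial mode.

    g(r) = 1 - amplitude * sigmoid(steepness * (r/R - midpoint_frac)), where R
    is the half-diagonal of the field. amplitude = 0 reduces to uniform.
    """

    midpoint_frac: float = 0.3
    steepness: float = 10.0
    amplitude: float = 0.9


def _require(ok: bool, name: str, msg: str) -> None:
    if not ok:
        raise ValueError(f"SimConfig.{name}: {msg}")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated field of cells.

    One config describes one condition (``targeting`` or ``NC``) in one field;
    multi-field experiments reuse the config with per-field seeds.
    """

    n_cells: int = 700
    field_shape: tuple[int, int] = (1024, 1024)
    pixel_um: float = 0.33
    slo_dose: float = 0.2
    perm_hill: PermHill = field(default_factory=PermHill)
    antibody_lognormal: tuple[float, float] = (math.log(300.0), 0.7)
    reseal_fail_prob: float = 0.01
    trim21_lognormal: tuple[float, float] = (math.log(1000.0), 0.5)
    target_lognormal: tuple[float, float] = (math.log(300.0), 0.5)
    deg_kinetics: DegKinetics = field(default_factory=DegKinetics)
    incubation_h: float = 3.0
    condition: Condition = "targeting"
    phospho_link: dict[str, PhosphoLink] = field(default_factory=dict)
    baseline_channels: dict[str, tuple[float, float]] = field(default_factory=dict)
    cc_subpop: CCSubpop = field(default_factory=CCSubpop)
    rounds: tuple[tuple[str, ...], ...] = (("Hoechst", "Ab", "Target"),)
    nuclear_channel: str = "Hoechst"
    ab_channel: str = "Ab"
    target_channel: str = "Target"
    pi_channel: str | None = None
    shift_px_sd: float = 2.0
    bleach_carryover: float = 0.02
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    spatial_mode: Literal["uniform", "center_gradient"] = "uniform"
    gradient: GradientConfig = field(default_factory=GradientConfig)
    # geometry
    nucleus_axes_px: tuple[float, float] = (5.5, 8.5)  # semi-axis range
    cyto_radius_px: float = 12.0
    min_spacing_px: float = 26.0
    margin_px: float = 30.0
    target_nuclear_ratio: float = 0.5
    dna_mean: float = 400.0
    dna_sd: float = 60.0
    died_nucleus_shrink: float = 0.6
    died_pi_intensity: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("slo_dose", "incubation_h", "pixel_um", "shift_px_sd"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, name, f"must be finite and >= 0, got {v}")
        _require(self.n_cells >= 0, "n_cells", "must be >= 0")
        _require(0.0 <= self.reseal_fail_prob <= 1.0, "reseal_fail_prob", "probability in [0,1]")
        _require(0.0 <= self.bleach_carryover < 1.0, "bleach_carryover", "fraction in [0,1)")
        k = self.deg_kinetics
        _require(math.isfinite(k.k_max) and k.k_max >= 0, "deg_kinetics.k_max", "must be >= 0")
        _require(0.0 <= k.resistant_fraction < 1.0, "deg_kinetics.resistant_fraction", "in [0,1)")
        _require(k.K_A > 0 and k.K_T > 0, "deg_kinetics", "K_A and K_T must be > 0")
        for nm, (mu, sd) in (
            ("antibody_lognormal", self.antibody_lognormal),
            ("trim21_lognormal", self.trim21_lognormal),
            ("target_lognormal", self.target_lognormal),
        ):
            _require(math.isfinite(mu), nm, "mu must be finite")
            _require(math.isfinite(sd) and sd >= 0, nm, "sigma must be finite and >= 0")
        _require(self.perm_hill.k_dose > 0, "perm_hill.k_dose", "must be > 0")
        _require(self.perm_hill.h > 0, "perm_hill.h", "must be > 0")
        _require(self.perm_hill.chol_sigma >= 0, "perm_hill.chol_sigma", "must be >= 0")
        _require(0.0 <= self.cc_subpop.pi <= 1.0, "cc_subpop.pi", "probability in [0,1]")
        _require(self.condition in ("targeting", "NC"), "condition", "targeting or NC")
        _require(len(self.rounds) >= 1, "rounds", "at least one round")
        for i, chans in enumerate(self.rounds):
            _require(
                self.nuclear_channel in chans,
                "rounds",
                f"round {i + 1} is missing the nuclear channel {self.nuclear_channel!r}",
            )
        _require(
            0.0 <= self.gradient.amplitude <= 1.0, "gradient.amplitude", "fraction in [0,1]"
        )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @property
    def channels(self) -> tuple[str, ...]:
        """All distinct channel names across rounds, in first-appearance order."""
        seen: dict[str, None] = {}
        for chans in self.rounds:
            for c in chans:
                seen.setdefault(c)
        return tuple(seen)


PRESET_NAMES = (
    "SLO-titration-HEK",
    "IKKa-30min",
    "IKKa-3h",
    "IKKa-HEK-endoT21",
    "IKKa-twostep-TRIM21",
    "IKKa-twostep-noTRIM21",
    "mTOR-12h",
    "reseal-fail",
    "electroporation-well",
)
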