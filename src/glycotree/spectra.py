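"""Post-processing of externally computed harmonic frequencies and energies:
mode-type frequency scaling, IR envelope broadening, Boltzmann population
weights and conformer ranking at 0 K versus 298.15 K."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AnnotationError, EmptySpectrumError, ScaleFactorError

__all__ = [
    "VibrationalMode",
    "ScaleFactorSet",
    "ThermoConfig",
    "SpectrumCurve",
    "STRETCH_SCALE_SET",
    "B3LYP_631G_SCALE_SET",
    "scale_frequencies",
    "broaden_spectrum",
    "boltzmann_weights",
    "rank_conformers",
    "RankingResult",
]

#: gas constant, kJ/(mol K)
GAS_CONSTANT_KJ = 0.008314462618

MODE_TYPES = ("OH-stretch", "NH-stretch", "other")


@dataclass(frozen=True)
class VibrationalMode:
    """One harmonic mode: wavenumber (cm^-1), IR intensity, type and label."""

    wavenumber: float
    intensity: float = 0.0
    mode_type: str = "other"
    label: str = ""

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class ScaleFactorSet:
    """Mapping from mode type to an empirical harmonic scale factor."""

    mapping: tuple[tuple[str, float], ...]
    name: str = ""

    @classmethod
    def from_dict(cls, mapping: dict[str, float], name: str = "") -> "ScaleFactorSet":
        return cls(tuple(sorted(mapping.items())), name)

    def factor(self, mode_type: str) -> float:
        for k, v in self.mapping:
            if k == mode_type:
                return v
        raise ScaleFactorError(f"no scale factor for mode type {mode_type!r} in set {self.name!r}")


#: mode-specific stretch factors (hydroxyl 0.9734, amide N-H 0.9600)
STRETCH_SCALE_SET = ScaleFactorSet.from_dict(
    {"OH-stretch": 0.9734, "NH-stretch": 0.9600, "other": 1.0}, name="stretch"
)
#: single global factor used with the smaller-basis method
B3LYP_631G_SCALE_SET = ScaleFactorSet.from_dict(
    {"OH-stretch": 0.9603, "NH-stretch": 0.9603, "other": 0.9603}, name="b3lyp-631g"
)

SCALE_SETS = {"stretch": STRETCH_SCALE_SET, "b3lyp-631g": B3LYP_631G_SCALE_SET}


@dataclass(frozen=True)
class ThermoConfig:
    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT_KJ

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class SpectrumCurve:
    """A broadened spectrum on a wavenumber grid."""

    grid: np.ndarray
    intensity: np.ndarray

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.grid))


def scale_frequencies(
    modes: list[VibrationalMode], factors: ScaleFactorSet
) -> list[VibrationalMode]:
    """Multiply each wavenumber by its mode type's factor; intensities are
    untouched.  A mode type with no factor in the set is an error."""
    return [replace(m, wavenumber=m.wavenumber * factors.factor(m.mode_type)) for m in modes]


def broaden_spectrum(
    modes: list[VibrationalMode],
    shape: str = "gaussian",
    fwhm: float = 15.0,
    grid: np.ndarray | None = None,
) -> SpectrumCurve:
    """Convolve stick modes with a normalized Gaussian or Lorentzian profile.

    With the default grid (stick range padded by several widths, 0.1 cm^-1
    spacing) the integrated curve area equals the summed stick intensities to
    well within 0.1% for Gaussian lineshapes.
    """
    if not modes:
        raise EmptySpectrumError("no vibrational modes to broaden")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if shape not in ("gaussian", "lorentzian"):
        raise ValueError(f"unknown lineshape {shape!r}")
    x0 = np.array([m.wavenumber for m in modes])
    amp = np.array([m.intensity for m in modes])
    if grid is None:
        pad = 8 * fwhm if shape == "gaussian" else 2000 * fwhm
        grid = np.arange(x0.min() - pad, x0.max() + pad, min(fwhm / 20.0, 0.5))
    grid = np.asarray(grid, dtype=float)
    y = np.zeros_like(grid)
    if shape == "gaussian":
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        for c, a in zip(x0, amp):
            y += a * np.exp(-0.5 * ((grid - c) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    else:
        gamma = fwhm / 2.0
        for c, a in zip(x0, amp):
            y += a * gamma / (np.pi * ((grid - c) ** 2 + gamma**2))
    return SpectrumCurve(grid, y)


def boltzmann_weights(
    free_energies, config: ThermoConfig = ThermoConfig()
) -> np.ndarray:
    """Normalized populations ∝ exp(−ΔG/RT), referenced to the minimum."""
    g = np.asarray(list(free_energies), dtype=float)
    if g.size == 0:
        raise ValueError("empty energy list")
    if not np.all(np.isfinite(g) | (g == np.inf)):
        raise ValueError("energies must be finite (or +inf for absent states)")
    rt = config.gas_constant * config.temperature
    w = np.exp(-(g - np.nanmin(g[np.isfinite(g)])) / rt)
    return w / w.sum()


@dataclass
class RankingResult:
    ordered: list
    key: str
    #: (conformer id, rank under 0 K energies, rank under Gibbs energies) for
    #: every record whose two ranks differ; empty when either annotation is
    #: missing somewhere
    rank_changes: list[tuple[str, int, int]] = field(default_factory=list)


_RANK_KEYS = {"0K": "energy_0k", "gibbs298": "gibbs_298"}


def rank_conformers(records: list, key: str = "0K") -> RankingResult:
    """Stable ascending sort of conformer records by an energy annotation.

    ``records`` may be :class:`~glycotree.tree.ConformerRecord` objects or any
    objects with an ``annotations`` dict and a ``conformer_id``.  When both
    annotations are present on all records the report lists every conformer
    whose 0 K and 298.15 K ranks differ.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"key must be one of {sorted(_RANK_KEYS)}")
    attr = _RANK_KEYS[key]
    for r in records:
        if attr not in r.annotations:
            raise AnnotationError(
                f"conformer {getattr(r, 'conformer_id', r)} lacks annotation {attr!r}"
            )
    ordered = sorted(records, key=lambda r: r.annotations[attr])
    changes: list[tuple[str, int, int]] = []
    if records and all(
        all(a in r.annotations for a in _RANK_KEYS.values()) for r in records
    ):
        by_e0 = sorted(records, key=lambda r: r.annotations["energy_0k"])
        by_g = sorted(records, key=lambda r: r.annotations["gibbs_298"])
        for r in records:
            r0 = by_e0.index(r) + 1
            rg = by_g.index(r) + 1
            if r0 != rg:
                changes.append((getattr(r, "conformer_id", str(r)), r0, rg))
    return RankingResult(ordered, key, changes)
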