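"""Default covariate registry and hypothesis groupings.

Thirty-three ecogeographical variables describe each 5-km cell, grouped into
four competing hypotheses about what limits a rear-edge badger population:
landcover composition (H1), anthropogenic disturbance (H2), topography and
geology (H3) and climate (H4). Means and ranges follow the study-area
summary statistics of the sampled cells; the synthetic generator reproduces
those first two moments, not the real geography.

``Sediment`` is deliberately generated as a near-exact complement of the
other lithology shares so that collinearity screening has a real offender to
find, mirroring the one variable the screening excluded in the field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Collinearity",
    "CovariateSpec",
    "HYPOTHESIS_GROUPS",
    "default_covariate_specs",
]


@dataclass(frozen=True)
class Collinearity:
    """Build a variable as intercept + weights . sources + N(0, noise_sd)."""

    sources: tuple
    weights: tuple
    intercept: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    hypothesis_group: str  # H1_landcover | H2_disturbance | H3_abiotic | H4_climate
    mean: float
    range: tuple  # (min, max)
    spatial_range_cells: float = 3.0
    collinear_with: Collinearity | None = None
    binary: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.range
        if not (lo <= self.mean <= hi):
            raise ValueError(f"{self.name}: mean outside range")
        if self.spatial_range_cells < 0:
            raise ValueError(f"{self.name}: negative spatial range")


def _lc(name, mean, lo, hi, rng=3.0):
    return CovariateSpec(name, "H1_landcover", mean, (lo, hi), rng)


def _di(name, mean, lo, hi, rng=3.0, **kw):
    return CovariateSpec(name, "H2_disturbance", mean, (lo, hi), rng, **kw)


def _ab(name, mean, lo, hi, rng=4.0, **kw):
    return CovariateSpec(name, "H3_abiotic", mean, (lo, hi), rng, **kw)


def _cl(name, mean, lo, hi, rng=8.0):
    return CovariateSpec(name, "H4_climate", mean, (lo, hi), rng)


def default_covariate_specs() -> list[CovariateSpec]:
    """The 33-variable default registry (means and ranges per cell)."""
    return [
        # H1 - landcover composition (% cover; H = Shannon-Wiener index)
        _lc("Deciduous", 10.3, 0, 62.9),
        _lc("Coniferous", 11.3, 0, 68.1),
        _lc("Agroforestry", 4.7, 0, 71.2),
        _lc("Eucalyptus", 6.4, 0, 55.3),
        _lc("Exotic", 0.005, 0, 2.4),
        _lc("Shrublands", 15.6, 0, 75.9),
        _lc("Wetlands", 1.1, 0, 42.4),
        _lc("Herbaceous", 12.7, 0, 78.4),
        _lc("Food", 17.0, 0, 75.0),
        _lc("Artificial", 4.8, 0, 56.3),
        _lc("H", 1.55, 0.70, 2.10),
        # H2 - anthropogenic disturbance
        _di("Highways", 0.08, 0, 0.95),
        _di("Roads", 1.63, 0, 12.29),
        _di("Unpaved_roads", 1.23, 0, 6.96),
        _di("Human_pop", 165.3, 0, 8435.76),
        _di("PA", 21.8, 0, 100),
        _di("Hunting", 0.5, 0, 1, binary=True),
        _di("Cattle", 1.25, 0, 62.20),
        _di("Goat&sheep", 1.83, 0.25, 9.42),
        _di("Pigs", 2.28, 0, 129.40),
        # H3 - topography, lithology and soils
        _ab("Alt_mean", 347.73, 5.84, 1297.59),
        _ab("Alt_range", 286.97, 14.00, 1350.00),
        _ab(
            "Sediment",
            34.0,
            0,
            100,
            collinear_with=Collinearity(
                sources=("Sediment/Metamorph", "Eruptive"),
                weights=(-1.0, -1.0),
                intercept=100.0,
                noise_sd=1.0,
            ),
        ),
        _ab("Sediment/Metamorph", 36.2, 0, 100),
        _ab("Eruptive", 28.6, 0, 100),
        _ab("Podzols", 12.4, 0, 100),
        _ab("Luvisols", 13.7, 0, 100),
        _ab("Lithosols", 13.9, 0, 100),
        _ab("Cambisols", 50.2, 0, 100),
        # H4 - climate
        _cl("Ann_Prec", 907.93, 526.63, 1614.83),
        _cl("Prec_season", 55.43, 41.59, 67.74),
        _cl("Ann_Temp", 14.13, 9.33, 17.00),
        _cl("Temp_season", 42.83, 30.00, 50.77),
    ]


# Hypothesis registry: variable sets competed against each other. H5 (the
# hybrid) is never hand-set; it is assembled from the top-influence variables
# of the fitted H1-H4 models.
HYPOTHESIS_GROUPS: dict[str, list[str]] = {
    "H1": [
        "Deciduous", "Coniferous", "Agroforestry", "Eucalyptus", "Exotic",
        "Shrublands", "Wetlands", "Herbaceous", "Food", "Artificial", "H",
    ],
    "H2": [
        "Highways", "Roads", "Unpaved_roads", "Human_pop", "PA", "Hunting",
        "Cattle", "Goat&sheep", "Pigs",
    ],
    "H3": [
        "Alt_mean", "Alt_range", "Sediment", "Sediment/Metamorph", "Eruptive",
        "Podzols", "Luvisols", "Lithosols", "Cambisols",
    ],
    "H4": ["Ann_Prec", "Prec_season", "Ann_Temp", "Temp_season"],
}
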