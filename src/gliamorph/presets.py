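"""Phenotype presets for the synthetic microglia generator.

A :class:`PhenotypePreset` is a small stochastic morphology model for one
Braak-stage-like microglial phenotype.  Two presets are registered:

``ramified_braak2``
    Homeostatic, highly ramified microglia as seen in low-Braak-stage
    (control-like) dentate gyrus: large surveillance domains
    (2012.12 +/- 453.44 um^2 per cell), many processes, no fragmentation,
    and a parenchymal coverage of 0.24 um^2/um^2.

``dystrophic_braak56``
    Degenerating microglia of fully demented (Braak V-VI-like) tissue:
    shortened, deramified arbors (domain 1119.39 +/- 376.86 um^2),
    fragmented processes (cytorrhexis) decorated with spheroidal
    swellings, and a coverage of only 0.08 um^2/um^2.

The domain means/SDs and coverage targets are the calibration anchors of
the whole package: the generator draws per-cell territories from these
distributions, so downstream measurements can be validated against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, ParameterError

__all__ = ["PhenotypePreset", "make_preset", "available_presets"]


@dataclass(frozen=True)
class PhenotypePreset:
    """Stochastic morphology model for one microglial phenotype.

    Parameters
    ----------
    name
        Registered preset label.
    soma_radius_um
        (mean, sd) of the soma disc radius in micrometres.
    n_primary_branches
        (mean, dispersion) of the number of radial processes; the realized
        count is a rounded normal draw clipped to >= 3 so that every cell
        contributes a well-defined territory polygon.
    domain_area_um2
        (mean, sd) of the per-cell surveillance domain, i.e. the area of
        the polygon over the distal branch tips, in um^2.
    branch_width_um
        Rendered process width in micrometres (processes taper to a single
        pixel at the tip).
    tortuosity
        Unitless >= 0; scales the lateral wobble of process centrelines.
    fragmentation_prob
        Per-branch probability that the process is rendered as two or more
        disconnected segments (cytorrhexis).
    spheroid_rate
        Expected number of spheroidal swellings per 100 um of process.
    target_coverage
        Fraction of region pixels that rendered cells should occupy once
        the cell density has been calibrated (see ``calibrate_density``).
    """

    name: str
    soma_radius_um: tuple[float, float]
    n_primary_branches: tuple[float, float]
    domain_area_um2: tuple[float, float]
    branch_width_um: float
    tortuosity: float
    fragmentation_prob: float
    spheroid_rate: float
    target_coverage: float

    def __post_init__(self) -> None:
        for nm in ("soma_radius_um", "n_primary_branches", "domain_area_um2"):
            mean, sd = getattr(self, nm)
            if mean <= 0 or sd < 0:
                raise ParameterError(f"{nm} must have positive mean and sd >= 0")
        if self.branch_width_um <= 0:
            raise ParameterError("branch_width_um must be > 0")
        if self.tortuosity < 0:
            raise ParameterError("tortuosity must be >= 0")
        if not 0.0 <= self.fragmentation_prob <= 1.0:
            raise ParameterError("fragmentation_prob must lie in [0, 1]")
        if self.spheroid_rate < 0:
            raise ParameterError("spheroid_rate must be >= 0")
        if not 0.0 <= self.target_coverage <= 1.0:
            raise ParameterError("target_coverage must lie in [0, 1]")


_REGISTRY: dict[str, PhenotypePreset] = {
    "ramified_braak2": PhenotypePreset(
        name="ramified_braak2",
        soma_radius_um=(4.5, 0.5),
        n_primary_branches=(10.0, 2.0),
        domain_area_um2=(2012.12, 453.44),
        branch_width_um=2.0,
        tortuosity=0.12,
        fragmentation_prob=0.0,
        spheroid_rate=0.0,
        target_coverage=0.24,
    ),
    "dystrophic_braak56": PhenotypePreset(
        name="dystrophic_braak56",
        soma_radius_um=(4.0, 0.5),
        n_primary_branches=(5.0, 1.2),
        domain_area_um2=(1119.39, 376.86),
        branch_width_um=2.0,
        tortuosity=0.20,
        fragmentation_prob=0.35,
        spheroid_rate=1.5,
        target_coverage=0.08,
    ),
}


def available_presets() -> tuple[str, ...]:
    """Names of the registered phenotype presets."""
    return tuple(_REGISTRY)


def make_preset(name: str) -> PhenotypePreset:
    """Return the registered preset called ``name``.

    Raises
    ------
    ConfigurationError
        If ``name`` is not a registered preset.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
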