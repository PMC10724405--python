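"""Species tables and reduced-unit particle compositions.

Measured particle properties (hydrodynamic diameters in nm, particle
masses in g, bulk mass ratios, molecular weights in kDa) are converted
into the dimensionless units used by the hard-sphere engine: lengths in
multiples of the largest particle's diameter ``sigma`` and masses in
multiples of its mass ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpeciesSpec",
    "SpeciesSet",
    "to_reduced_units",
    "mole_fractions_from_mass",
    "packing_fraction",
    "realize_counts",
    "exclude_species",
    "lens_species",
    "lens_composition",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Physical parameters of one particle species.

    Parameters
    ----------
    name
        Species label (e.g. ``"alpha"``).
    diameter_nm
        Hydrodynamic (DLS) diameter in nanometres; must be positive.
    mass_g
        Single-particle mass in grams; must be positive.
    mass_ratio
        Dimensionless bulk mass-ratio weight (optional, used to derive
        mole fractions).
    molecular_weight_kda
        Molecular weight in kDa (optional, used to derive mole fractions).
    """

    name: str
    diameter_nm: float
    mass_g: float
    mass_ratio: Optional[float] = None
    molecular_weight_kda: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.diameter_nm) or self.diameter_nm <= 0:
            raise ValueError(f"diameter_nm must be positive, got {self.diameter_nm!r}")
        if not np.isfinite(self.mass_g) or self.mass_g <= 0:
            raise ValueError(f"mass_g must be positive, got {self.mass_g!r}")
        if self.mass_ratio is not None and self.mass_ratio < 0:
            raise ValueError(f"mass_ratio must be >= 0, got {self.mass_ratio!r}")
        if self.molecular_weight_kda is not None and self.molecular_weight_kda <= 0:
            raise ValueError(
                f"molecular_weight_kda must be positive, got {self.molecular_weight_kda!r}"
            )


@dataclass(frozen=True)
class SpeciesSet:
    """A reduced-unit particle composition.

    The reference species is the one with the largest physical diameter;
    its reduced diameter and mass are exactly 1.  All reduced values are
    stored at full precision; rounding is display-only.
    """

    species: tuple[SpeciesSpec, ...]
    mole_fraction: np.ndarray
    sigma_nm: float
    m_ref_g: float
    reduced_diameter: np.ndarray
    reduced_mass: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.mole_fraction, dtype=float)
        if abs(float(x.sum()) - 1.0) > 1e-12:
            raise ValueError(f"mole fractions must sum to 1, got {x.sum()!r}")
        if np.any(x < 0):
            raise ValueError("mole fractions must be non-negative")
        d = np.asarray(self.reduced_diameter, dtype=float)
        m = np.asarray(self.reduced_mass, dtype=float)
        if np.any(d <= 0) or np.any(d > 1 + 1e-12):
            raise ValueError("reduced diameters must lie in (0, 1]")
        if np.any(m <= 0) or np.any(m > 1 + 1e-12):
            raise ValueError("reduced masses must lie in (0, 1]")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no species named {name!r}; have {self.names}") from None

    def display_table(self) -> list[dict]:
        """Per-species summary with 2-decimal reduced units (display only)."""
        return [
            {
                "name": s.name,
                "diameter_nm": s.diameter_nm,
                "mass_g": s.mass_g,
                "mole_fraction": float(self.mole_fraction[i]),
                "reduced_diameter": round(float(self.reduced_diameter[i]), 2),
                "reduced_mass": round(float(self.reduced_mass[i]), 2),
            }
            for i, s in enumerate(self.species)
        ]


def to_reduced_units(
    specs: Sequence[SpeciesSpec],
    mole_fractions: Optional[Sequence[float]] = None,
) -> SpeciesSet:
    """Convert physical species parameters to reduced units.

    The species with the largest diameter becomes the reference with
    ``reduced_diameter == reduced_mass == 1``; every other species is
    expressed as a multiple of the reference diameter/mass.

    Parameters
    ----------
    specs
        Ordered species parameters (at least one entry).
    mole_fractions
        Optional explicit per-species mole fractions (summing to 1).  If
        omitted they are derived from ``mass_ratio``/``molecular_weight_kda``
        when every species carries both, or set uniform otherwise.
    """
    if len(specs) == 0:
        raise ValueError("at least one species is required")
    specs = tuple(specs)

    ref = max(specs, key=lambda s: s.diameter_nm)
    sigma_nm = ref.diameter_nm
    m_ref_g = ref.mass_g

    d = np.array([s.diameter_nm / sigma_nm for s in specs], dtype=float)
    m = np.array([s.mass_g / m_ref_g for s in specs], dtype=float)

    if mole_fractions is not None:
        x = np.asarray(mole_fractions, dtype=float)
        if x.shape != (len(specs),):
            raise ValueError("mole_fractions length must match number of species")
        x = x / x.sum()
    elif all(
        s.mass_ratio is not None and s.molecular_weight_kda is not None for s in specs
    ):
        x = mole_fractions_from_mass(
            [s.mass_ratio for s in specs],
            [s.molecular_weight_kda for s in specs],
        )
    else:
        x = np.full(len(specs), 1.0 / len(specs))

    return SpeciesSet(
        species=specs,
        mole_fraction=x,
        sigma_nm=sigma_nm,
        m_ref_g=m_ref_g,
        reduced_diameter=d,
        reduced_mass=m,
    )


def mole_fractions_from_mass(
    mass_ratios: Sequence[float], molecular_weights_kda: Sequence[float]
) -> np.ndarray:
    """Mole fractions from bulk mass ratios and molecular weights.

    ``fraction_i = (ratio_i / MW_i) / sum_j (ratio_j / MW_j)``.  Invariant
    under rescaling all mass ratios by a common factor.
    """
    r = np.asarray(mass_ratios, dtype=float)
    w = np.asarray(molecular_weights_kda, dtype=float)
    if r.shape != w.shape or r.ndim != 1:
        raise ValueError("mass_ratios and molecular_weights_kda must be equal-length 1-D")
    if np.any(r <= 0) or np.any(w <= 0):
        raise ValueError("mass ratios and molecular weights must be positive")
    moles = r / w
    return moles / moles.sum()


def packing_fraction(
    counts: Sequence[int], reduced_diameters: Sequence[float], box_edge: float
) -> float:
    """Volume fraction of spheres with the given per-species counts in a cubic box."""
    if box_edge <= 0:
        raise ValueError(f"box_edge must be positive, got {box_edge!r}")
    n = np.asarray(counts, dtype=float)
    d = np.asarray(reduced_diameters, dtype=float)
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    return float((n * (np.pi / 6.0) * d**3).sum() / box_edge**3)


def realize_counts(fractions: Sequence[float], n_total: int) -> np.ndarray:
    """Integer particle counts from mole fractions via largest-remainder rounding.

    Conserves ``sum(counts) == n_total`` exactly.
    """
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total!r}")
    x = np.asarray(fractions, dtype=float)
    x = x / x.sum()
    ideal = x * n_total
    base = np.floor(ideal).astype(int)
    remainder = ideal - base
    missing = n_total - int(base.sum())
    # ties broken by species order (stable argsort on negated remainder)
    order = np.argsort(-remainder, kind="stable")
    for k in order[:missing]:
        base[k] += 1
    return base


def exclude_species(
    species_set: SpeciesSet, name: str, n_total: int
) -> tuple[SpeciesSet, int]:
    """Remove one species while retaining the same overall particle mass.

    The removed species' mass is redistributed to the remaining species
    proportionally to their mole fractions, which leaves the remaining
    relative ratios unchanged and increases the total particle count.

    Returns the reduced-composition :class:`SpeciesSet` and the new total
    particle count that carries the same total mass as ``n_total``
    particles of the full composition.
    """
    idx = species_set.index_of(name)
    keep = [i for i in range(species_set.n_species) if i != idx]
    if not keep:
        raise ValueError("cannot exclude the only species")

    x = species_set.mole_fraction
    m = species_set.reduced_mass
    mass_kept = float((x[keep] * m[keep]).sum())
    mass_removed = float(x[idx] * m[idx])
    # extra particles per original particle, split proportionally to x_j
    extra = n_total * mass_removed / mass_kept
    n_new = int(round((n_total + extra) * float(x[keep].sum())))

    new_specs = tuple(species_set.species[i] for i in keep)
    new_x = x[keep] / x[keep].sum()
    reduced = to_reduced_units(new_specs, mole_fractions=new_x)
    return reduced, n_new


# ---------------------------------------------------------------------------
# Packaged composition preset: bovine lens crystallins.
# DLS diameters/masses and the lens-average mole-fraction vector are the
# published measurement values; the 35:37:21 mass ratios with MWs
# 680/180/21 kDa give a slightly different mole-fraction vector
# (~0.04:0.16:0.80), so the preset carries the published fractions verbatim
# and the mass-ratio route remains available via mole_fractions_from_mass.
# ---------------------------------------------------------------------------

LENS_MOLE_FRACTIONS = (0.05, 0.20, 0.75)


def lens_species() -> tuple[SpeciesSpec, SpeciesSpec, SpeciesSpec]:
    """The three lens-crystallin species with measured parameters."""
    return (
        SpeciesSpec("alpha", diameter_nm=18.6, mass_g=1.13e-18,
                    mass_ratio=35.0, molecular_weight_kda=680.0),
        SpeciesSpec("beta", diameter_nm=11.7, mass_g=2.99e-19,
                    mass_ratio=37.0, molecular_weight_kda=180.0),
        SpeciesSpec("gamma", diameter_nm=3.56, mass_g=3.49e-20,
                    mass_ratio=21.0, molecular_weight_kda=21.0),
    )


def lens_composition(mole_fractions: Optional[Sequence[float]] = None) -> SpeciesSet:
    """Reduced-unit three-species lens composition.

    Uses the lens-average mole fractions 0.05:0.20:0.75 unless an explicit
    vector is supplied.
    """
    if mole_fractions is None:
        mole_fractions = LENS_MOLE_FRACTIONS
    return to_reduced_units(lens_species(), mole_fractions=mole_fractions)
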