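"""Isotropic linear-elastic material library for dento-alveolar tissues.

All tissues are treated as isotropic, homogeneous and linearly elastic,
which is the standard simplification for static load-capacity studies of
the periodontium (the periodontal ligament is in reality visco-elastic;
see the methods note for what this does and does not capture).

Units are fixed package-wide at mm-N-MPa, so an elastic modulus in MPa
combines directly with geometry in mm to give forces in N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MaterialSpec",
    "MaterialError",
    "TISSUE_LIBRARY",
    "get_material",
    "lame_parameters",
    "from_lame",
    "isotropic_elastic_tensor",
    "material_table",
]


class MaterialError(ValueError):
    """Unknown tissue or invalid elastic constants."""


@dataclass(frozen=True)
class MaterialSpec:
    """Isotropic elastic constants of one tissue.

    Attributes
    ----------
    name : tissue label
    elastic_modulus : Young's modulus E in MPa
    poisson_ratio : Poisson ratio, dimensionless, in [0, 0.5)
    """

    name: str
    elastic_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.elastic_modulus > 0:
            raise MaterialError(
                f"{self.name}: elastic modulus must be positive, "
                f"got {self.elastic_modulus}"
            )
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise MaterialError(
                f"{self.name}: Poisson ratio must lie in [0, 0.5), "
                f"got {self.poisson_ratio} (incompressible limit unsupported)"
            )


# Standard literature values for human dento-alveolar tissues (E in MPa).
# The ~200x stiffness gap between PDL and dentin/bone, and the 10x
# cortical/cancellous contrast, drive the load-transfer behaviour.
TISSUE_LIBRARY: dict[str, MaterialSpec] = {
    spec.name: spec
    for spec in (
        MaterialSpec("enamel", 84_000.0, 0.33),
        MaterialSpec("dentin", 18_600.0, 0.31),
        MaterialSpec("pulp", 2.07, 0.45),
        MaterialSpec("pdl", 68.9, 0.45),
        MaterialSpec("gingiva", 3.0, 0.45),
        MaterialSpec("cortical_bone", 13_700.0, 0.3),
        MaterialSpec("cancellous_bone", 1_370.0, 0.3),
    )
}

# Cementum is not distinguished mechanically in the source table; its
# modulus is close to dentin's and the layer is 50-150 um thin, so it is
# assigned dentin-like constants.  Override via register/YAML if needed.
TISSUE_LIBRARY["cementum"] = MaterialSpec("cementum", 18_600.0, 0.31)

_ALIASES = {"pdl": "pdl", "PDL": "pdl", "cortical": "cortical_bone",
            "cancellous": "cancellous_bone"}


def get_material(tissue: str, library: dict[str, MaterialSpec] | None = None) -> MaterialSpec:
    """Look up a tissue's elastic constants.

    Raises :class:`MaterialError` listing the available labels if the
    tissue is unknown.
    """
    lib = TISSUE_LIBRARY if library is None else library
    key = _ALIASES.get(tissue, tissue.lower())
    try:
        return lib[key]
    except KeyError:
        raise MaterialError(
            f"unknown tissue {tissue!r}; available: {sorted(lib)}"
        ) from None


def lame_parameters(spec: MaterialSpec) -> tuple[float, float]:
    """Return the Lame parameters (lambda, mu) in MPa.

    lambda = E*nu / ((1+nu)(1-2nu)),  mu = E / (2(1+nu)).
    """
    e, nu = spec.elastic_modulus, spec.poisson_ratio
    lam = e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = e / (2.0 * (1.0 + nu))
    return lam, mu


def from_lame(lam: float, mu: float, name: str = "custom") -> MaterialSpec:
    """Inverse of :func:`lame_parameters`: rebuild (E, nu) from (lambda, mu)."""
    e = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return MaterialSpec(name, e, nu)


def isotropic_elastic_tensor(spec: MaterialSpec) -> np.ndarray:
    """6x6 stiffness matrix in engineering (Voigt) notation.

    Strain ordering is [exx, eyy, ezz, gyz, gxz, gxy] with engineering
    shear strains, so the shear block is mu * I.  The matrix is symmetric
    positive-definite for any valid :class:`MaterialSpec`.
    """
    lam, mu = lame_parameters(spec)
    c = np.zeros((6, 6))
    c[:3, :3] = lam
    c[np.diag_indices(3)] += 2.0 * mu
    c[3:, 3:] = mu * np.eye(3)
    return c


def material_table(library: dict[str, MaterialSpec] | None = None) -> pd.DataFrame:
    """Active material table as a DataFrame (exportable to CSV)."""
    lib = TISSUE_LIBRARY if library is None else library
    return pd.DataFrame(
        [(s.name, s.elastic_modulus, s.poisson_ratio) for s in lib.values()],
        columns=["tissue", "elastic_modulus_MPa", "poisson_ratio"],
    )
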