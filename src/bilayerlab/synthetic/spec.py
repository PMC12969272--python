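"""Parameterization of synthetic trajectories: PMF shapes and the full spec.

Every generated quantity is tied to an analytically known ground truth so
that downstream estimators can be validated by parameter recovery:

- lateral lipid tracks        -> known diffusion coefficient
- box / phosphate z series    -> known area per lipid and thickness
- chain C-H orientations      -> known order parameter (exact in expectation)
- solute z tracks             -> known free-energy profile and, through the
                                 inhomogeneous solubility-diffusion integral,
                                 a known permeability coefficient
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from bilayerlab.core.config import GAS_CONSTANT_KCAL

PMF_FORMS = ("flat", "single_gaussian_barrier", "interfacial_wells_plus_barrier", "tabulated")


@dataclass(frozen=True)
class PMFSpec:
    """Bounded, continuous free-energy profile G(z) in kcal/mol.

    ``flat``: G = 0 everywhere.
    ``single_gaussian_barrier``: G = B exp(-z^2 / 2w^2).
    ``interfacial_wells_plus_barrier``: the Gaussian barrier minus two
    symmetric Gaussian wells of depth ``well_depth`` at +-``well_position``.
    ``tabulated``: linear interpolation of (table_z, table_g), clamped to the
    end values outside the table.
    """

    form: str = "flat"
    barrier_height: float = 0.0
    well_depth: float = 0.0
    well_position: float = 0.0
    width: float = 3.0
    table_z: tuple[float, ...] | None = None
    table_g: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.form not in PMF_FORMS:
            raise ValueError(f"unknown PMF form {self.form!r}; options: {PMF_FORMS}")
        if self.width <= 0:
            raise ValueError("PMF width must be positive")
        if self.form == "tabulated":
            if self.table_z is None or self.table_g is None:
                raise ValueError("tabulated PMF requires table_z and table_g")
            if len(self.table_z) != len(self.table_g) or len(self.table_z) < 2:
                raise ValueError("table_z/table_g must be equal-length with >= 2 points")
            if not np.all(np.isfinite(self.table_g)):
                raise ValueError("tabulated PMF must be bounded")

    def value(self, z):
        z = np.asarray(z, dtype=float)
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "single_gaussian_barrier":
            return self.barrier_height * np.exp(-(z ** 2) / (2 * self.width ** 2))
        if self.form == "interfacial_wells_plus_barrier":
            g = self.barrier_height * np.exp(-(z ** 2) / (2 * self.width ** 2))
            for sign in (+1, -1):
                g = g - self.well_depth * np.exp(
                    -((z - sign * self.well_position) ** 2) / (2 * self.width ** 2)
                )
            return g
        return np.interp(z, np.asarray(self.table_z), np.asarray(self.table_g))

    def grad(self, z):
        """dG/dz, analytic for the closed-form shapes."""
        z = np.asarray(z, dtype=float)
        w2 = self.width ** 2
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "single_gaussian_barrier":
            return -(z / w2) * self.barrier_height * np.exp(-(z ** 2) / (2 * w2))
        if self.form == "interfacial_wells_plus_barrier":
            g = -(z / w2) * self.barrier_height * np.exp(-(z ** 2) / (2 * w2))
            for sign in (+1, -1):
                dz = z - sign * self.well_position
                g = g + (dz / w2) * self.well_depth * np.exp(-(dz ** 2) / (2 * w2))
            return g
        # central differences on the table grid
        h = 1e-4
        return (self.value(z + h) - self.value(z - h)) / (2 * h)


@dataclass(frozen=True)
class SyntheticSpec:
    n_lipids_per_leaflet: int = 100
    box0: tuple[float, float, float] = (80.0, 80.0, 100.0)
    apl_target: float = 64.0
    apl_sd: float = 0.0
    thickness_target: float = 39.3
    thickness_sd: float = 0.0
    lipid_D: float = 1.5            # A^2/ns
    chain_S_target: float = 0.14
    n_ch_pairs_per_lipid: int = 2
    n_solutes: int = 0
    solute_D_z: float = 50.0        # A^2/ns
    pmf: PMFSpec = field(default_factory=PMFSpec)
    dt: float = 0.1                 # ns per frame
    substeps: int = 1               # Langevin integration substeps per frame
    n_frames: int = 1000
    temperature: float = 300.0
    seed: int = 0
    lateral_mode: str = "random"
    segregation_gap: float = 15.0   # A, strip separation in segregated mode
    membrane_halfwidth: float | None = None  # default thickness/2 + 5 A

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet <= 0:
            raise ValueError("n_lipids_per_leaflet must be positive")
        if any(b <= 0 for b in self.box0):
            raise ValueError("box lengths must be positive")
        for name in ("apl_target", "thickness_target", "dt", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("apl_sd", "thickness_sd", "lipid_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -0.5 <= self.chain_S_target <= 1.0:
            raise ValueError(
                f"chain_S_target {self.chain_S_target} outside the reachable "
                "range [-0.5, 1]"
            )
        if self.n_solutes and self.solute_D_z <= 0:
            raise ValueError("solute_D_z must be positive when solutes are present")
        if self.n_frames < 1 or self.substeps < 1:
            raise ValueError("n_frames and substeps must be >= 1")
        if self.lateral_mode not in ("random", "segregated"):
            raise ValueError(f"unknown lateral_mode {self.lateral_mode!r}")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature

    @property
    def halfwidth(self) -> float:
        """Membrane half-extent used for bulk definitions and the ISD span."""
        if self.membrane_halfwidth is not None:
            return self.membrane_halfwidth
        return self.thickness_target / 2.0 + 5.0

    def lateral_box(self) -> tuple[float, float]:
        """Mean lateral box lengths implied by the APL target, keeping the
        aspect ratio of ``box0`` (box0 z is the actual box height)."""
        area = self.n_lipids_per_leaflet * self.apl_target
        aspect = self.box0[0] / self.box0[1]
        ly = float(np.sqrt(area / aspect))
        return area / ly, ly

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def isd_permeability(pmf: PMFSpec, d_z: float, rt: float, halfwidth: float) -> float:
    """Inhomogeneous solubility-diffusion permeability over [-halfwidth, halfwidth].

    Pm = [ integral exp(G(z)/RT) / D(z) dz ]^-1, with constant D here.
    Result in A/ns; 1 A/ns = 1e-8 cm / 1e-9 s = 10 cm/s.
    """
    integrand = lambda z: np.exp(pmf.value(z) / rt) / d_z
    integral, _ = quad(integrand, -halfwidth, halfwidth, limit=200)
    return 1.0 / integral


#: unit conversion: 1 A/ns = 10 cm/s
A_PER_NS_TO_CM_PER_S = 10.0
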