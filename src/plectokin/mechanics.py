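"""Closed-form DNA mechanics and nucleoprotein free-energy estimates.

Everything in this module is analytic: supercoiling free energy from the
empirical quadratic relation, harmonic DNA-bending penalties, interface
binding free energies from bound/unbound lifetimes, the Bell model for
force-dependent bond lifetimes, the linear extension-to-linking-number
conversion of the plectonemic regime, and the AFM tip-convolution geometry.

Energies are returned in units of kBT at an explicit temperature; angles are
accepted in degrees at the API boundary and converted to radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "KB_PN_NM_PER_K",
    "MechanicsParameters",
    "PlasmidTopology",
    "EnergyValue",
    "kbt_pn_nm",
    "reference_linking_number",
    "linking_difference",
    "supercoiling_free_energy",
    "bending_free_energy",
    "prebend_corrected_penalty",
    "interface_free_energy",
    "bell_lifetime",
    "extension_to_linking",
    "tip_convolution_fwhm",
]

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K × 1e21 pN·nm/J)
KB_PN_NM_PER_K = 1.380649e-2


def kbt_pn_nm(temperature_K: float) -> float:
    """Thermal energy kBT in pN·nm at the given absolute temperature."""
    if not 250.0 <= temperature_K <= 400.0:
        raise ValueError(f"temperature {temperature_K} K outside [250, 400] K")
    return KB_PN_NM_PER_K * temperature_K


@dataclass(frozen=True)
class MechanicsParameters:
    """Physical constants of the DNA tether and measurement.

    Attributes
    ----------
    helical_repeat_bp : float
        Base pairs per helical turn of relaxed B-DNA (10.5).
    rise_per_bp_nm : float
        Helical rise, nm per base pair (0.34).
    persistence_length_nm : float
        Bending persistence length A under assay buffer conditions (~40 nm).
    temperature_bulk_K : float
        Temperature of the bulk (ensemble) reactions, 310 K.
    temperature_mt_K : float
        Temperature of the magnetic-tweezers measurements (room temperature,
        298 K; not stated by the source experiments, exposed as a parameter).
    extension_per_turn_nm : float
        Slope of the linear extension-vs-linking-difference relation in the
        plectonemic regime at the working force, nm per turn (~45).
    """

    helical_repeat_bp: float = 10.5
    rise_per_bp_nm: float = 0.34
    persistence_length_nm: float = 40.0
    temperature_bulk_K: float = 310.0
    temperature_mt_K: float = 298.0
    extension_per_turn_nm: float = 45.0

    def __post_init__(self) -> None:
        for name in (
            "helical_repeat_bp",
            "rise_per_bp_nm",
            "persistence_length_nm",
            "temperature_bulk_K",
            "temperature_mt_K",
            "extension_per_turn_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("temperature_bulk_K", "temperature_mt_K"):
            t = getattr(self, name)
            if not 250.0 <= t <= 400.0:
                raise ValueError(f"{name}={t} outside plausible range [250, 400] K")


DEFAULT_PARAMS = MechanicsParameters()


@dataclass(frozen=True)
class EnergyValue:
    """An energy expressed in units of kBT at a stated temperature."""

    magnitude_kbt: float
    temperature_K: float = 310.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude_kbt):
            raise ValueError("energy must be finite")

    def __float__(self) -> float:
        return float(self.magnitude_kbt)

    @property
    def pn_nm(self) -> float:
        """The same energy in pN·nm."""
        return self.magnitude_kbt * kbt_pn_nm(self.temperature_K)

    @property
    def kj_per_mol(self) -> float:
        """The same energy in kJ/mol (never applied implicitly)."""
        # R = 8.31446 J/(mol·K)
        return self.magnitude_kbt * 8.31446e-3 * self.temperature_K


@dataclass(frozen=True)
class PlasmidTopology:
    """Topological state of a covalently closed plasmid."""

    n_bp: int
    linking_difference: float
    supercoiling_density: float = field(default=0.0)
    helical_repeat_bp: float = 10.5

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        lk0 = reference_linking_number(self.n_bp, self.helical_repeat_bp)
        expected_sigma = self.linking_difference / lk0
        if abs(self.supercoiling_density - expected_sigma) > 1e-9:
            raise ValueError(
                f"inconsistent topology: sigma={self.supercoiling_density} but "
                f"delta_lk/Lk0 = {expected_sigma}"
            )

    @classmethod
    def from_sigma(
        cls, n_bp: int, sigma: float, helical_repeat_bp: float = 10.5
    ) -> "PlasmidTopology":
        dlk = linking_difference(n_bp, sigma, helical_repeat_bp)
        return cls(n_bp, dlk, sigma, helical_repeat_bp)


def reference_linking_number(n_bp: int, helical_repeat_bp: float = 10.5) -> int:
    """Relaxed linking number Lk0 = round(N / helical repeat).

    Rounding to the nearest integer turn is the convention under which a
    4361 bp plasmid at |sigma| = 0.05 carries a linking difference of exactly
    20.75 turns (415.33 -> 415; 415 x 0.05 = 20.75).
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    return int(round(n_bp / helical_repeat_bp))


def linking_difference(
    n_bp: int, sigma: float, helical_repeat_bp: float = 10.5
) -> float:
    """Linking difference dLk = sigma x Lk0, sign preserved."""
    return sigma * reference_linking_number(n_bp, helical_repeat_bp)


def supercoiling_free_energy(
    n_bp: int, delta_lk: float, temperature_K: float = 310.0
) -> EnergyValue:
    """Supercoiling free energy from the empirical quadratic relation.

    dG_SC = (1100 / N) kBT dLk^2, with N the plasmid length in bp. Even in
    the sign of dLk and inversely proportional to N.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    return EnergyValue(1100.0 / n_bp * delta_lk**2, temperature_K)


def bending_free_energy(
    theta_deg: float,
    l_bp: float,
    persistence_length_nm: float = 40.0,
    rise_per_bp_nm: float = 0.34,
    temperature_K: float = 310.0,
) -> EnergyValue:
    """Harmonic bending penalty dG = A kBT theta^2 / (2 l).

    theta is the total bend angle in degrees; l the contour length over
    which the bend is distributed, in bp (converted at 0.34 nm/bp).
    A 60 degree bend over 14 bp with A = 40 nm costs ~4.6 kBT.
    """
    if l_bp <= 0:
        raise ValueError("l_bp must be > 0")
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError("theta_deg must lie in [0, 180]")
    theta = math.radians(theta_deg)
    l_nm = l_bp * rise_per_bp_nm
    return EnergyValue(persistence_length_nm * theta**2 / (2.0 * l_nm), temperature_K)


def prebend_corrected_penalty(
    theta_deg: float,
    theta_pre_deg: float,
    l_bp: float,
    persistence_length_nm: float = 40.0,
    rise_per_bp_nm: float = 0.34,
    temperature_K: float = 310.0,
) -> EnergyValue:
    """Bending penalty reduced by thermally pre-existing curvature.

    Supercoiled DNA is locally pre-bent (e.g. ~10 degrees over 14 bp at
    |sigma| = 0.05); the residual cost of reaching the bound-state bend is
    dG(theta) - dG(theta_pre). Non-negative whenever theta >= theta_pre.
    """
    if theta_pre_deg > theta_deg:
        raise ValueError("pre-bend angle exceeds target bend angle")
    full = bending_free_energy(
        theta_deg, l_bp, persistence_length_nm, rise_per_bp_nm, temperature_K
    )
    pre = bending_free_energy(
        theta_pre_deg, l_bp, persistence_length_nm, rise_per_bp_nm, temperature_K
    )
    return EnergyValue(full.magnitude_kbt - pre.magnitude_kbt, temperature_K)


def interface_free_energy(
    tau_bound_s: float, tau_unbound_s: float, temperature_K: float = 310.0
) -> EnergyValue:
    """Binding free energy of an interface from its dwell-time ratio.

    dG = kBT ln(tau_bound / tau_unbound). Antisymmetric under exchange of
    the two lifetimes.
    """
    if tau_bound_s <= 0 or tau_unbound_s <= 0:
        raise ValueError("lifetimes must be strictly positive")
    return EnergyValue(math.log(tau_bound_s / tau_unbound_s), temperature_K)


def bell_lifetime(
    tau0: float, delta_x_nm: float, force_pN: float, temperature_K: float = 298.0
) -> float:
    """Bell-model bond lifetime under constant force.

    tau(F) = tau0 exp(-F dx / kBT); monotone decreasing in F for dx > 0.
    The returned lifetime carries the units of tau0.
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be > 0")
    if force_pN < 0:
        raise ValueError("force must be >= 0")
    return tau0 * math.exp(-force_pN * delta_x_nm / kbt_pn_nm(temperature_K))


def extension_to_linking(delta_z_nm: float, c_nm_per_turn: float = 45.0) -> float:
    """Convert an extension change to turns via the plectonemic slope.

    dLk = dz / c, with c the nm released per turn at the working force.
    Linear and sign-preserving.
    """
    if c_nm_per_turn <= 0:
        raise ValueError("slope c must be > 0")
    return delta_z_nm / c_nm_per_turn


def tip_convolution_fwhm(d_nm: float, h_nm: float, alpha_deg: float) -> float:
    """Apparent FWHM of a particle imaged with a conical AFM tip.

    FWHM = D + h tan(alpha) for a particle of true lateral size D and
    height h, imaged with a tip of half-cone angle alpha.
    """
    if d_nm < 0 or h_nm < 0:
        raise ValueError("D and h must be non-negative")
    if not 0.0 <= alpha_deg < 90.0:
        raise ValueError("half-cone angle must lie in [0, 90) degrees")
    return d_nm + h_nm * math.tan(math.radians(alpha_deg))
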