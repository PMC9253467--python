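"""Physical and numerical parameters of one pore-transit scenario."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from ..analytic_flow import mean_velocity_for_Re, pressure_gradient_for_mean_velocity


class ConfigError(ValueError):
    """Invalid physical/numerical configuration."""


@dataclass
class SimulationParams:
    """One (Re, AR) scenario plus geometry, material and numerics settings.

    Physical defaults describe the study system: a 10 um leukocyte
    (membrane thickness 0.4 um, elastic modulus 100 Pa — physiological
    range 50-500 Pa — Poisson ratio 0.25) in plasma of viscosity 8e-4 Pa*s
    and density 1000 kg/m^3, inside a 20 um channel.  ``AR`` is the pore
    width divided by the cell diameter, so AR < 1 means the pore is
    narrower than the cell.  The flow is driven by the pressure drop that
    would sustain the Re-matched mean velocity in the unobstructed channel.
    """

    Re: float
    AR: float
    # --- cell ---
    cell_diameter: float = 10e-6
    membrane_thickness: float = 0.4e-6
    elastic_modulus: float = 100.0
    poisson_ratio: float = 0.25
    # --- fluid ---
    viscosity: float = 8e-4
    density: float = 1000.0
    # --- geometry ---
    channel_width: float = 20e-6
    channel_length: float = 80e-6
    pore_length: float = 5e-6
    lip_radius: float = 1e-6
    pore_entrance: float = 35e-6
    standoff_diameters: float = 1.5  # centroid standoff upstream of pore entrance
    # --- numerics ---
    grid_cells_per_diameter: int = 12
    markers_per_grid_cell: float = 2.0
    cfl: float = 0.25
    membrane_dt_safety: float = 0.4
    dt: float | None = None  # explicit override; otherwise from stability bounds
    max_sim_time: float = 1.0
    output_interval: float = 2e-4
    # --- impaction / stopping ---
    stall_velocity_fraction: float = 1e-3
    stall_duration: float = 0.01
    # --- membrane numerics ---
    area_stiffness: float = 2000.0  # Pa; weak penalty keeping enclosed area
    bending_scale: float = 1.0  # multiplies the plate-theory bending stiffness
    enforce_physiological: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Re <= 0:
            raise ConfigError(f"Re must be positive, got {self.Re}")
        if self.AR <= 0:
            raise ConfigError(f"AR must be positive, got {self.AR}")
        if self.enforce_physiological and not (50.0 <= self.elastic_modulus <= 500.0):
            raise ConfigError(
                f"elastic modulus {self.elastic_modulus} Pa outside the physiological "
                "50-500 Pa window (set enforce_physiological=False to override)"
            )
        if self.pore_width >= self.channel_width and self.pore_length > 0:
            raise ConfigError(
                f"pore width {self.pore_width:.3g} m must be smaller than the "
                f"channel width {self.channel_width:.3g} m"
            )
        if self.cell_diameter >= self.channel_width:
            raise ConfigError("cell does not fit in the channel (overlaps walls)")
        if self.initial_centroid_x - self.cell_diameter / 2 <= 0:
            raise ConfigError("cell standoff places the membrane outside the inlet")
        if self.pore_exit >= self.channel_length:
            raise ConfigError("pore exit lies beyond the channel outlet")

    # -- derived quantities -------------------------------------------------

    @property
    def pore_width(self) -> float:
        """Constriction gap: AR times the cell diameter."""
        return self.AR * self.cell_diameter

    @property
    def pore_exit(self) -> float:
        return self.pore_entrance + self.pore_length

    @property
    def initial_centroid_x(self) -> float:
        return self.pore_entrance - self.standoff_diameters * self.cell_diameter

    @property
    def mean_velocity(self) -> float:
        """Cell-free mean inlet velocity matching Re."""
        return mean_velocity_for_Re(self.Re, self.channel_width, self.density, self.viscosity)

    @property
    def pressure_drop(self) -> float:
        """Driving pressure drop over the full channel length (Pa)."""
        dpdx = pressure_gradient_for_mean_velocity(
            self.mean_velocity, self.channel_width, self.viscosity
        )
        return -dpdx * self.channel_length

    @property
    def grid_spacing(self) -> float:
        return self.cell_diameter / self.grid_cells_per_diameter

    @property
    def stretch_stiffness(self) -> float:
        """Plane-stress membrane stretching stiffness E*h/(1-nu^2), N/m."""
        return self.elastic_modulus * self.membrane_thickness / (1.0 - self.poisson_ratio**2)

    @property
    def bending_stiffness(self) -> float:
        """Plate-theory bending stiffness E*h^3/(12(1-nu^2)), N*m."""
        return (
            self.bending_scale
            * self.elastic_modulus
            * self.membrane_thickness**3
            / (12.0 * (1.0 - self.poisson_ratio**2))
        )

    def to_dict(self) -> dict:
        return asdict(self)
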