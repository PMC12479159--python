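"""Scaled bioenergetic-capacity partition of ATP-linked respiration.

The total ATP-linked respiration of a condition, scaled by the control
(``Resp_ATP / Resp_ATP,control``), is split between the perinuclear and
peripheral regions in proportion to each region's weight: the product of its
linearized membrane potential and its mitochondrial volume,

    BC_peri   = ψL_peri · V_peri · R / (ψL_peri · V_peri + ψL_periph · V_periph),
    BC_periph = ψL_periph · V_periph · R / (ψL_peri · V_peri + ψL_periph · V_periph),

with ``R = Resp_ATP / Resp_ATP,control``.  The two components therefore sum
exactly to the scaled total (``BC_total = R``), and only the *ratio* of the
regional weights matters: scaling both volumes or both potentials by a
common factor leaves the partition unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dynamics import RegionalVolume


@dataclass(frozen=True)
class LinearPotentialMap:
    """Affine map ``psi -> a*psi + b`` linearizing potential into a respiration factor.

    The default is the proportional (identity) map: any purely
    multiplicative constant cancels in the partition, so only a nonzero
    intercept ``b`` changes results.  Configurations that could produce a
    negative factor on valid input (``a < 0`` or ``b < 0``) are rejected
    when constructed.
    """

    a: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(
                f"map (a={self.a}, b={self.b}) can produce negative factors "
                "on nonnegative potentials"
            )

    def __call__(self, normalized_psi: float) -> float:
        if normalized_psi < 0:
            raise ValueError(f"normalized potential must be >= 0, got {normalized_psi}")
        return self.a * normalized_psi + self.b


def linearize_potential(
    normalized_psi: float, mapping: LinearPotentialMap = LinearPotentialMap()
) -> float:
    """Linearized respiration factor for a normalized potential (monotone)."""
    return mapping(normalized_psi)


@dataclass(frozen=True)
class BioenergeticPartition:
    """Scaled regional bioenergetic capacities for one condition."""

    bc_perinuclear: float
    bc_peripheral: float
    psi_lin_perinuclear: float
    psi_lin_peripheral: float
    resp_ratio: float

    @property
    def bc_total(self) -> float:
        return self.bc_perinuclear + self.bc_peripheral

    @property
    def perinuclear_fraction_of_total(self) -> float:
        if self.bc_total <= 0:
            raise ValueError("total bioenergetic capacity is not positive")
        return self.bc_perinuclear / self.bc_total


def partition_bioenergetics(
    psi_perinuclear: float,
    psi_peripheral: float,
    volumes: RegionalVolume,
    resp_atp: float,
    resp_atp_control: float,
    mapping: LinearPotentialMap = LinearPotentialMap(),
) -> BioenergeticPartition:
    """Partition scaled ATP-linked respiration between the two regions.

    Parameters
    ----------
    psi_perinuclear, psi_peripheral
        Normalized regional membrane potentials (>= 0, at least one positive
        after linearization).
    volumes
        Regional mitochondrial volumes (µm³; >= 0, at least one positive).
    resp_atp, resp_atp_control
        ATP-linked respiration of this condition and of the control
        (pmol O₂/min); the control must be positive.
    """
    if resp_atp_control <= 0:
        raise ValueError(f"control ATP-linked respiration must be > 0, "
                         f"got {resp_atp_control}")
    if volumes.v_perinuclear < 0 or volumes.v_peripheral < 0:
        raise ValueError("regional volumes must be >= 0")
    psi_l_peri = linearize_potential(psi_perinuclear, mapping)
    psi_l_periph = linearize_potential(psi_peripheral, mapping)
    w_peri = psi_l_peri * volumes.v_perinuclear
    w_periph = psi_l_periph * volumes.v_peripheral
    denom = w_peri + w_periph
    if denom <= 0:
        raise ValueError(
            "both regional weights (potential x volume) are zero; "
            "the partition is undefined"
        )
    resp_ratio = resp_atp / resp_atp_control
    return BioenergeticPartition(
        bc_perinuclear=w_peri * resp_ratio / denom,
        bc_peripheral=w_periph * resp_ratio / denom,
        psi_lin_perinuclear=psi_l_peri,
        psi_lin_peripheral=psi_l_periph,
        resp_ratio=resp_ratio,
    )


def percent_change_from_control(
    partition: BioenergeticPartition, control: BioenergeticPartition
) -> float:
    """Percent change of the perinuclear component relative to the control."""
    if control.bc_perinuclear <= 0:
        raise ValueError("control perinuclear component must be positive")
    return (
        100.0
        * (partition.bc_perinuclear - control.bc_perinuclear)
        / control.bc_perinuclear
    )
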