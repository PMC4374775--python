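"""Metal-nucleotide speciation for assay design.

Pyruvate-kinase assays are run at set concentrations of the *complexed*
nucleotide (ADP-Mg or ADP-Mn) and of the *free* divalent cation, while what
the experimenter pipettes are totals.  This module does the 1:1 mass-action
bookkeeping in both directions: totals -> species (``speciate``) and target
species -> totals (``totals_for_design``), plus the Henderson-Hasselbalch
fraction of ionized phosphoenolpyruvate.

Only a single 1:1 equilibrium is modelled.  Competing equilibria (ATP,
protonation of the nucleotide, ionic-strength corrections) are out of scope;
the dissociation constants are configuration, not results.

All concentrations are in mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ADP_MG_KD_MM",
    "ADP_MN_KD_MM",
    "BindingSystem",
    "SpeciationResult",
    "speciate",
    "totals_for_design",
    "ionized_pep",
]

#: Literature default for the ADP-Mg dissociation constant (mM).  The value
#: is an assumption (apparent Kd near neutral pH, ~25 degC); pass your own Kd
#: if your buffer conditions differ.
ADP_MG_KD_MM = 0.76

#: Literature default for the ADP-Mn dissociation constant (mM).  Mn2+ binds
#: ADP roughly an order of magnitude tighter than Mg2+.  Also an assumption.
ADP_MN_KD_MM = 0.053


def _require_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class BindingSystem:
    """Totals and dissociation constant of one 1:1 metal-ligand equilibrium.

    Attributes
    ----------
    total_metal, total_ligand : float
        Total (analytical) concentrations in mM.
    kd : float
        Dissociation constant of the complex in mM (must be > 0).
    """

    total_metal: float
    total_ligand: float
    kd: float

    def __post_init__(self) -> None:
        _require_nonneg("total_metal", self.total_metal)
        _require_nonneg("total_ligand", self.total_ligand)
        if not self.kd > 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium species (mM): complex, free metal, free ligand."""

    complex: float
    free_metal: float
    free_ligand: float


def speciate(system: BindingSystem) -> SpeciationResult:
    """Solve the 1:1 binding equilibrium for the given totals.

    The complex concentration ``c`` is the physical root of

        c**2 - (M + L + Kd) * c + M * L = 0

    with M, L the totals.  The root is evaluated in the cancellation-free
    form ``c = 2 M L / (b + sqrt(b**2 - 4 M L))`` with ``b = M + L + Kd``,
    which stays accurate when Kd is orders of magnitude below the totals
    (assay conditions here span ~0.02-30 mM).
    """
    m, ligand, kd = system.total_metal, system.total_ligand, system.kd
    product = m * ligand
    if product == 0.0:
        return SpeciationResult(0.0, m, ligand)
    b = m + ligand + kd
    disc = b * b - 4.0 * product
    # b >= 2*sqrt(ML) + kd > 2*sqrt(ML), so disc > 0 always.
    c = 2.0 * product / (b + math.sqrt(disc))
    return SpeciationResult(c, m - c, ligand - c)


def totals_for_design(
    target_free_metal: float, target_complex: float, kd: float
) -> BindingSystem:
    """Totals that speciate to the requested free metal and complex.

    Inverse of :func:`speciate`: given the free-metal concentration to hold
    constant and the complex concentration wanted, return the
    :class:`BindingSystem` to pipette.  Closed form: the free ligand follows
    from mass action, ``L_free = Kd * c / M_free``, and each total is
    free + complexed.

    Raises
    ------
    ValueError
        If a target is negative, or a nonzero complex is requested at zero
        free metal (mass action then has no finite solution).
    """
    _require_nonneg("target_free_metal", target_free_metal)
    _require_nonneg("target_complex", target_complex)
    if not kd > 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if target_complex == 0.0:
        return BindingSystem(target_free_metal, 0.0, kd)
    if target_free_metal == 0.0:
        raise ValueError(
            "target_free_metal must be > 0 when target_complex > 0"
        )
    free_ligand = kd * target_complex / target_free_metal
    return BindingSystem(
        target_free_metal + target_complex,
        free_ligand + target_complex,
        kd,
    )


def ionized_pep(total_pep: float, ph: float, pk: float = 6.3) -> float:
    """Concentration of the active PEP trianion at the given pH.

    Phosphoenolpyruvate is catalytically competent as PEP(3-); the fraction
    ionized follows Henderson-Hasselbalch with the phosphate pK (default
    6.3): ``total / (1 + 10**(pk - ph))``.
    """
    _require_nonneg("total_pep", total_pep)
    return total_pep / (1.0 + 10.0 ** (pk - ph))
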