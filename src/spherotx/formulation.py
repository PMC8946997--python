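"""Lipoplex (LPX) formulation charge arithmetic.

Lipoplexes form by electrostatic complexation of cationic lipid (e.g. DOTMA)
with mRNA, one negative charge per nucleotide.  Two numbers characterise a
formulation:

* the **overall charge ratio** — moles of cationic lipid charge per mole of
  nucleotide charge in the mix; a value below 1 means RNA is in excess;
* the **free RNA fraction** — when the complex itself binds lipid and RNA at
  a fixed internal stoichiometry (typically 1:1 charge-wise), any RNA charge
  beyond that stoichiometry remains uncomplexed in solution.

With overall ratio ``r = c_lipid / c_rna`` and internal stoichiometry ``s``
(lipid:RNA charges inside the particle), the uncomplexed fraction of the RNA
is ``max(0, 1 - r/s)``.

Report values are conventionally rounded: charge ratios to the nearest 0.05
and free-RNA fractions to the nearest 5 percentage points, matching how such
numbers are quoted in formulation work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


def _round_to(x: float, step: float) -> float:
    """Round half away from zero to the nearest multiple of ``step``."""
    import math

    q = abs(x) / step
    n = math.floor(q + 0.5)
    return math.copysign(n * step, x)


@dataclass(frozen=True)
class FormulationSpec:
    """Charge concentrations of a lipoplex formulation.

    Parameters
    ----------
    lipid_charge_mM:
        Molar concentration of cationic lipid charges (mM).  DOTMA carries
        one positive charge per molecule.
    rna_charge_mM:
        Molar concentration of anionic nucleotide charges (mM), one negative
        charge per nucleotide.
    internal_charge_ratio:
        Lipid:RNA charge stoichiometry inside the assembled particle
        (dimensionless, default 1.0).
    lipid_mg_per_ml, rna_mg_per_ml:
        Optional mass concentrations.  When given together with the
        corresponding per-charge molar mass they must reproduce the charge
        molarities within 10%.
    lipid_da_per_charge, rna_da_per_charge:
        Molar mass per unit charge (g/mol) used to check the mass inputs.
    """

    lipid_charge_mM: float
    rna_charge_mM: float
    internal_charge_ratio: float = 1.0
    lipid_mg_per_ml: Optional[float] = None
    rna_mg_per_ml: Optional[float] = None
    lipid_da_per_charge: Optional[float] = None
    rna_da_per_charge: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.lipid_charge_mM > 0:
            raise ValueError(
                f"lipid_charge_mM must be > 0, got {self.lipid_charge_mM}"
            )
        if not self.rna_charge_mM > 0:
            raise ValueError(f"rna_charge_mM must be > 0, got {self.rna_charge_mM}")
        if not self.internal_charge_ratio > 0:
            raise ValueError(
                f"internal_charge_ratio must be > 0, got {self.internal_charge_ratio}"
            )
        self._check_mass(
            self.lipid_mg_per_ml, self.lipid_da_per_charge, self.lipid_charge_mM, "lipid"
        )
        self._check_mass(
            self.rna_mg_per_ml, self.rna_da_per_charge, self.rna_charge_mM, "rna"
        )

    @staticmethod
    def _check_mass(mg_per_ml, da_per_charge, charge_mM, name) -> None:
        if mg_per_ml is None and da_per_charge is None:
            return
        if mg_per_ml is None or da_per_charge is None:
            raise ValueError(
                f"{name}: mass concentration and per-charge molar mass must be "
                "given together"
            )
        # mg/mL divided by g/mol gives mol/L·10^-3·10^3 = mM directly
        implied_mM = mg_per_ml / da_per_charge * 1000.0
        if abs(implied_mM - charge_mM) > 0.10 * charge_mM:
            raise ValueError(
                f"{name}: mass input implies {implied_mM:.3g} mM charges, "
                f"inconsistent with declared {charge_mM:.3g} mM (>10% off)"
            )


def charge_ratio(spec: FormulationSpec) -> float:
    """Overall cationic/anionic charge ratio of the mixed formulation.

    Mixing-ratio invariant for one-to-one (v/v) mixing of the lipid and RNA
    stocks: the quotient of the two charge molarities.
    """
    return spec.lipid_charge_mM / spec.rna_charge_mM


def charge_ratio_report(spec: FormulationSpec) -> float:
    """Charge ratio rounded to the nearest 0.05 for report output."""
    return _round_to(charge_ratio(spec), 0.05)


def free_rna_fraction(spec: FormulationSpec) -> float:
    """Fraction of RNA left uncomplexed, in [0, 1].

    With the particle binding lipid:RNA charges at ``internal_charge_ratio``,
    the lipid present can complex ``charge_ratio / internal_charge_ratio`` of
    the RNA charge; the remainder is free.  Clamped at 0 when lipid charges
    are in excess.
    """
    return max(0.0, 1.0 - charge_ratio(spec) / spec.internal_charge_ratio)


def free_rna_percent_report(spec: FormulationSpec) -> float:
    """Free RNA expressed in percent, rounded to the nearest 5% for reports."""
    return _round_to(100.0 * free_rna_fraction(spec), 5.0)


def formulation_report(spec: FormulationSpec) -> dict:
    """One-page report: raw and rounded values plus input provenance."""
    return {
        "inputs": {
            "lipid_charge_mM": spec.lipid_charge_mM,
            "rna_charge_mM": spec.rna_charge_mM,
            "internal_charge_ratio": spec.internal_charge_ratio,
            "lipid_mg_per_ml": spec.lipid_mg_per_ml,
            "rna_mg_per_ml": spec.rna_mg_per_ml,
        },
        "charge_ratio": charge_ratio(spec),
        "charge_ratio_rounded": charge_ratio_report(spec),
        "free_rna_fraction": free_rna_fraction(spec),
        "free_rna_percent_rounded": free_rna_percent_report(spec),
    }
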