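"""Sequence-based charge balance for protein-RNA complex coacervation.

Complex coacervation of a polycation (tau) with a polyanion (RNA) is maximal
near overall charge neutrality.  This module computes the net charge of a
protein at a given pH by Henderson-Hasselbalch summation over its ionizable
groups, converts RNA mass concentrations into negative-charge concentrations
(one phosphate charge per nucleotide by default), and locates the composition
in a mixture grid whose protein(+):RNA(-) charge ratio is closest to 1:1.

Charge of a single ionizable group at pH ``p``:

* basic group with pKa ``k``:   +1 / (1 + 10**(p - k))
* acidic group with pKa ``k``:  -1 / (1 + 10**(k - p))

The protein net charge is the sum over side chains plus the two termini.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Average residue masses (Da) for molar-mass bookkeeping; +water per chain.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.01528


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and terminal pKa values with the sign of each group.

    Defaults are a fixed published set (the EMBOSS-style table); every value
    is overridable so alternative tables can be swapped in without touching
    the charge arithmetic.
    """

    positive: Mapping[str, float] = field(
        default_factory=lambda: {"R": 12.5, "K": 10.8, "H": 6.5}
    )
    negative: Mapping[str, float] = field(
        default_factory=lambda: {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
    )
    n_term: float = 8.6
    c_term: float = 3.6

    def __post_init__(self) -> None:
        for name, value in {
            **dict(self.positive), **dict(self.negative),
            "n_term": self.n_term, "c_term": self.c_term,
        }.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa for {name!r} must lie in (0, 14), got {value}")
        dup = set(self.positive) & set(self.negative)
        if dup:
            raise ValueError(f"residues assigned to both signs: {sorted(dup)}")


DEFAULT_PKA = PkaTable()


@dataclass(frozen=True)
class ProteinSpec:
    """A protein construct: the biological sequence plus an optional
    expression tag (e.g. a His6 prefix) kept as a separate field.

    The tag always counts toward the molar mass of the construct (it is part
    of the molecule that is weighed and quantified); whether its residues
    enter the charge sum is decided by the caller of
    :func:`net_protein_charge`.
    """

    name: str
    sequence: str
    tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("protein sequence must be non-empty")
        for label, seq in (("sequence", self.sequence), ("tag", self.tag)):
            for i, aa in enumerate(seq):
                if aa not in CANONICAL_RESIDUES:
                    raise ValueError(
                        f"invalid residue {aa!r} at {label} position {i + 1} "
                        f"of {self.name!r}"
                    )

    @property
    def full_sequence(self) -> str:
        return self.tag + self.sequence

    @property
    def molar_mass(self) -> float:
        """Average molar mass of the construct (tag included), Da."""
        mass = sum(_RESIDUE_MASS[aa] for aa in self.full_sequence) + _WATER_MASS
        if mass <= 0:  # pragma: no cover - unreachable for valid residues
            raise ValueError("molar mass must be positive")
        return mass


@dataclass(frozen=True)
class RNASpec:
    """An RNA species described by its per-nucleotide properties.

    ``nucleotide_mass`` is the mean residue mass in Da per nucleotide (330 by
    default) and ``charges_per_nt`` the number of negative charges carried per
    nucleotide (1 by default, the backbone phosphate).  ``chain_mass`` (Da)
    is optional and only needed for molar-ratio conversions of a polymer of
    defined length, e.g. tRNA at 25 kDa.
    """

    name: str
    nucleotide_mass: float = 330.0
    charges_per_nt: float = 1.0
    chain_mass: float | None = None

    def __post_init__(self) -> None:
        if self.nucleotide_mass <= 0:
            raise ValueError("nucleotide mass must be positive")
        if self.charges_per_nt <= 0:
            raise ValueError("charges per nucleotide must be positive")
        if self.chain_mass is not None and self.chain_mass <= 0:
            raise ValueError("chain mass must be positive")

    @property
    def charges_per_molecule(self) -> float:
        if self.chain_mass is None:
            raise ValueError(f"{self.name!r} has no chain mass defined")
        return self.chain_mass / self.nucleotide_mass * self.charges_per_nt


@dataclass(frozen=True)
class MixtureComposition:
    """A single mixing condition: protein molarity, RNA mass concentration,
    pH, and environment metadata (salt, temperature) that the charge model
    does not use but downstream reporting carries along."""

    protein_uM: float
    rna_ugml: float
    pH: float = 7.0
    nacl_mM: float = 0.0
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if self.protein_uM < 0 or self.rna_ugml < 0:
            raise ValueError("concentrations must be non-negative")
        if not 0.0 < self.pH < 14.0:
            raise ValueError(f"pH must lie in (0, 14), got {self.pH}")


@dataclass(frozen=True)
class ChargeReport:
    """All intermediate quantities of a charge-ratio computation."""

    protein_net_charge: float
    protein_charge_uM: float
    rna_charge_uM: float
    charge_ratio: float
    composition: MixtureComposition


def _group_charge(pka: float, pH: float, sign: int) -> float:
    if sign > 0:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - pH))


def net_protein_charge(
    spec: ProteinSpec,
    pH: float,
    pka: PkaTable = DEFAULT_PKA,
    *,
    include_tag_charge: bool = False,
    masked_positions: Iterable[int] = (),
) -> float:
    """Net charge (elementary charges) of a protein at a given pH.

    Henderson-Hasselbalch summation over ionizable side chains plus both
    termini.  By default only the biological ``sequence`` enters the sum; set
    ``include_tag_charge=True`` to also count ionizable tag residues.
    ``masked_positions`` (1-based indices into ``sequence``) removes residues
    from the sum, e.g. cysteines carrying a spin label and hence no free
    thiol.
    """
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    masked = set(masked_positions)
    charge = _group_charge(pka.n_term, pH, +1) + _group_charge(pka.c_term, pH, -1)
    residues: list[str] = []
    if include_tag_charge:
        residues.extend(spec.tag)
    residues.extend(
        aa for i, aa in enumerate(spec.sequence, start=1) if i not in masked
    )
    for aa in residues:
        if aa in pka.positive:
            charge += _group_charge(pka.positive[aa], pH, +1)
        elif aa in pka.negative:
            charge += _group_charge(pka.negative[aa], pH, -1)
    return charge


def rna_charge_concentration(spec: RNASpec, mass_ugml: float) -> float:
    """Negative-charge concentration (uM) of an RNA at a mass concentration.

    ug/ml divided by Da/nt gives umol nt per ml, i.e. mM of nucleotide; the
    factor 1000 converts to uM.
    """
    if mass_ugml < 0:
        raise ValueError("mass concentration must be non-negative")
    return mass_ugml / spec.nucleotide_mass * spec.charges_per_nt * 1000.0


def charge_ratio(
    mixture: MixtureComposition,
    protein: ProteinSpec,
    rna: RNASpec,
    pka: PkaTable = DEFAULT_PKA,
    **charge_kwargs,
) -> ChargeReport:
    """Protein(+):RNA(-) charge ratio of a mixture with all intermediates."""
    if mixture.rna_ugml == 0:
        raise ValueError(
            "charge ratio undefined: RNA mass concentration is zero"
        )
    z = net_protein_charge(protein, mixture.pH, pka, **charge_kwargs)
    protein_charge = mixture.protein_uM * z
    rna_charge = rna_charge_concentration(rna, mixture.rna_ugml)
    return ChargeReport(
        protein_net_charge=z,
        protein_charge_uM=protein_charge,
        rna_charge_uM=rna_charge,
        charge_ratio=protein_charge / rna_charge,
        composition=mixture,
    )


def mixture_at_mass_ratio(
    protein_uM: float,
    mass_ratio: float,
    protein: ProteinSpec,
    pH: float = 7.0,
    **metadata,
) -> MixtureComposition:
    """Composition with a given protein:RNA mass ratio (e.g. 7 for 7:1).

    The RNA mass concentration follows from the protein mass concentration
    (uM x Da / 1000 = ug/ml) divided by the ratio.
    """
    if mass_ratio <= 0:
        raise ValueError("mass ratio must be positive")
    protein_ugml = protein_uM * protein.molar_mass / 1000.0
    return MixtureComposition(
        protein_uM=protein_uM,
        rna_ugml=protein_ugml / mass_ratio,
        pH=pH,
        **metadata,
    )


def charge_balance_map(
    grid: Sequence[MixtureComposition],
    protein: ProteinSpec,
    rna: RNASpec,
    pka: PkaTable = DEFAULT_PKA,
    **charge_kwargs,
) -> tuple[pd.DataFrame, MixtureComposition]:
    """Charge ratios over a composition grid plus the predicted optimum.

    The optimum is the composition whose |log(charge ratio)| is minimal, i.e.
    closest to 1:1 charge balance; ties are broken toward lower total mass
    concentration.  Zero-RNA grid points are flagged (``valid=False``), not
    fatal.
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    rows = []
    for comp in grid:
        if comp.rna_ugml == 0:
            rows.append(
                dict(
                    protein_uM=comp.protein_uM, rna_ugml=comp.rna_ugml,
                    pH=comp.pH, nacl_mM=comp.nacl_mM,
                    protein_net_charge=np.nan, protein_charge_uM=np.nan,
                    rna_charge_uM=0.0, charge_ratio=np.nan, valid=False,
                )
            )
            continue
        rep = charge_ratio(comp, protein, rna, pka, **charge_kwargs)
        rows.append(
            dict(
                protein_uM=comp.protein_uM, rna_ugml=comp.rna_ugml,
                pH=comp.pH, nacl_mM=comp.nacl_mM,
                protein_net_charge=rep.protein_net_charge,
                protein_charge_uM=rep.protein_charge_uM,
                rna_charge_uM=rep.rna_charge_uM,
                charge_ratio=rep.charge_ratio, valid=True,
            )
        )
    table = pd.DataFrame(rows)

    best: MixtureComposition | None = None
    best_key: tuple[float, float] | None = None
    for comp, row in zip(grid, rows):
        if not row["valid"] or row["charge_ratio"] <= 0:
            continue
        total_mass = comp.protein_uM * protein.molar_mass / 1000.0 + comp.rna_ugml
        key = (abs(math.log(row["charge_ratio"])), total_mass)
        if best_key is None or key < best_key:
            best_key, best = key, comp
    if best is None:
        raise ValueError("no grid point with a defined positive charge ratio")
    return table, best
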