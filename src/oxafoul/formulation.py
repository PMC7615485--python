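"""Bookkeeping for ABA triblock copolymers and copolymer blends.

PMOXA-b-PDMS-b-PMOXA copolymers are named by the degrees of polymerization
of their blocks ("6-65-6" = 6 MOXA units per hydrophilic arm, 65 DMS units
in the hydrophobic middle block).  The hydrophilic weight fraction
f_hydrophilic = M_w(hydrophilic blocks) / M_w(copolymer) x 100 governs
whether a copolymer self-assembles into vesicles (roughly 35 +/- 10 wt%)
or micelles, and blends of a long- and a short-PMOXA copolymer are denoted
by their molar ratios.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

#: Default repeat-unit molar masses, g/mol.
MASS_MOXA = 85.10  # 2-methyl-2-oxazoline repeat unit
MASS_DMS = 74.15  # dimethylsiloxane repeat unit

#: Hydrophilic weight-percent window in which ABA amphiphiles tend to form
#: vesicles rather than micelles (annotation only; never enforced).
VESICLE_F_HYDROPHILIC_WINDOW = (25.0, 45.0)

_NAME_RE = re.compile(r"^(\d+)-(\d+)-(\d+)$")


class CopolymerNameError(ValueError):
    """Raised when a copolymer name does not parse as 'A-B-A'."""


class UnsupportedArchitectureError(ValueError):
    """Raised for asymmetric (A-B-A') names; only symmetric ABA is supported."""


@dataclass(frozen=True)
class Copolymer:
    """Symmetric ABA triblock with hydrophilic A arms and a hydrophobic B block.

    Parameters
    ----------
    name
        Label in the "A-B-A" convention, e.g. ``"6-65-6"``.
    dp_hydrophilic_per_arm
        MOXA units per hydrophilic arm (there are two arms).
    dp_hydrophobic
        DMS units in the middle block.
    mass_hydrophilic_unit, mass_hydrophobic_unit
        Repeat-unit molar masses, g/mol.
    end_group_mass_hydrophilic
        Extra mass (g/mol) counted toward the hydrophilic portion, e.g.
        initiator/terminator groups.  Zero by default.
    """

    name: str
    dp_hydrophilic_per_arm: int
    dp_hydrophobic: int
    mass_hydrophilic_unit: float = MASS_MOXA
    mass_hydrophobic_unit: float = MASS_DMS
    end_group_mass_hydrophilic: float = 0.0

    def __post_init__(self) -> None:
        if self.dp_hydrophilic_per_arm < 1 or self.dp_hydrophobic < 1:
            raise ValueError("degrees of polymerization must be >= 1")
        if self.mass_hydrophilic_unit <= 0 or self.mass_hydrophobic_unit <= 0:
            raise ValueError("repeat-unit masses must be positive")
        if self.end_group_mass_hydrophilic < 0:
            raise ValueError("end-group mass must be non-negative")

    @property
    def mass_hydrophilic(self) -> float:
        """Molar mass of both hydrophilic arms plus end groups, g/mol."""
        return (
            2.0 * self.dp_hydrophilic_per_arm * self.mass_hydrophilic_unit
            + self.end_group_mass_hydrophilic
        )

    @property
    def mass_hydrophobic(self) -> float:
        """Molar mass of the hydrophobic middle block, g/mol."""
        return self.dp_hydrophobic * self.mass_hydrophobic_unit

    @property
    def molar_mass(self) -> float:
        """Total copolymer molar mass, g/mol."""
        return self.mass_hydrophilic + self.mass_hydrophobic


def parse_copolymer_name(
    name: str,
    unit_masses: tuple[float, float] = (MASS_MOXA, MASS_DMS),
    end_group_mass_hydrophilic: float = 0.0,
) -> Copolymer:
    """Parse an "A-B-A" copolymer name into a :class:`Copolymer`.

    ``unit_masses`` is ``(hydrophilic, hydrophobic)`` in g/mol.  Asymmetric
    names (first and last integer differ) are rejected: only symmetric ABA
    architectures are modelled.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise CopolymerNameError(
            f"copolymer name {name!r} does not match the 'A-B-A' integer convention"
        )
    a1, b, a2 = (int(g) for g in m.groups())
    if a1 != a2:
        raise UnsupportedArchitectureError(
            f"asymmetric A blocks in {name!r} ({a1} != {a2}); only symmetric ABA supported"
        )
    return Copolymer(
        name=name.strip(),
        dp_hydrophilic_per_arm=a1,
        dp_hydrophobic=b,
        mass_hydrophilic_unit=unit_masses[0],
        mass_hydrophobic_unit=unit_masses[1],
        end_group_mass_hydrophilic=end_group_mass_hydrophilic,
    )


def hydrophilic_fraction(c: Copolymer) -> float:
    """Hydrophilic weight fraction of the copolymer, percent.

    100 x (2 * dp_A * m_A + m_end) / (2 * dp_A * m_A + dp_B * m_B + m_end).
    """
    return 100.0 * c.mass_hydrophilic / c.molar_mass


@dataclass(frozen=True)
class Blend:
    """Molar blend of copolymers, e.g. 50:50 n(21-65-21):n(6-65-6)."""

    components: tuple[tuple[Copolymer, float], ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("blend must contain at least one component")
        fracs = [x for _, x in self.components]
        if any(x < 0 for x in fracs):
            raise ValueError("mole fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1 (got {sum(fracs)})")


def blend_summary(b: Blend) -> pd.DataFrame:
    """Per-component mole/mass fractions and PMOXA content of a blend.

    Returns a DataFrame with one row per component (columns ``name``,
    ``mole_fraction``, ``mass_fraction``, ``dp_hydrophilic_per_arm``,
    ``f_hydrophilic_pct``).  The mole-fraction-weighted mean PMOXA DP per
    arm — the quantity that sets average brush length on a blended
    membrane — is stored in ``df.attrs["mean_dp_hydrophilic_per_arm"]``.
    """
    total_molar = sum(x * c.molar_mass for c, x in b.components)
    rows = []
    for c, x in b.components:
        rows.append(
            {
                "name": c.name,
                "mole_fraction": x,
                "mass_fraction": x * c.molar_mass / total_molar,
                "dp_hydrophilic_per_arm": c.dp_hydrophilic_per_arm,
                "f_hydrophilic_pct": hydrophilic_fraction(c),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_dp_hydrophilic_per_arm"] = float(
        sum(x * c.dp_hydrophilic_per_arm for c, x in b.components)
    )
    df.attrs["description"] = b.description
    return df
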