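"""Henderson-Hasselbalch protonation arithmetic for titratable sites.

For an acid/base site with a given pKa, the protonated fraction at a given
pH is ``f = 1 / (1 + 10^(pH - pKa))``.  With the textbook imidazole pKa of
~6.5 this puts histidine at 17% protonated at pH 7.2 and 67% at pH 6.2
(integer-percent rounding) -- the arithmetic behind pH-dependent
aggregation behaviour of His-bearing amyloidogenic proteins.  Sites are
treated as independent; site-site titration coupling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TitratableSite",
    "protonated_fraction",
    "percent_protonated",
    "fraction_ratio",
    "assign_his_states",
]


@dataclass(frozen=True)
class TitratableSite:
    """A titratable residue (His, Asp, Glu, C-terminus) with its pKa."""

    residue_number: int
    residue_type: str
    pKa: float

    def __post_init__(self):
        if not 0 < self.pKa < 14:
            raise ValueError("pKa must lie in (0, 14)")


def protonated_fraction(pKa: float, pH: float) -> float:
    """Equilibrium protonated fraction, 1 / (1 + 10^(pH - pKa))."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def percent_protonated(pKa: float, pH: float) -> int:
    """Protonated fraction as a whole percent (half away from zero)."""
    f = 100.0 * protonated_fraction(pKa, pH)
    return int(np.floor(f + 0.5))


def fraction_ratio(pKa: float, pH_low: float, pH_high: float) -> float:
    """Fold increase of the protonated fraction going from pH_high down to
    pH_low (>= 1 since protonation grows as pH drops)."""
    if pH_low > pH_high:
        raise ValueError("pH_low must not exceed pH_high")
    return protonated_fraction(pKa, pH_low) / protonated_fraction(pKa, pH_high)


def assign_his_states(
    structure,
    pH: float,
    pKa_map: dict[int, float],
    seed: int = 0,
) -> dict[int, bool]:
    """Independent Bernoulli protonation flags for every His in *structure*.

    ``pKa_map`` maps His residue numbers to per-site pKa values and must
    cover every histidine.  Reproducible under *seed*.
    """
    his = sorted(
        {
            a.residue_number
            for a in structure.atoms
            if a.residue_name in ("HIS", "HSD", "HSE", "HSP")
        }
    )
    missing = [r for r in his if r not in pKa_map]
    if missing:
        raise KeyError(f"pKa_map missing His residues: {missing}")
    rng = np.random.default_rng(seed)
    return {
        r: bool(rng.random() < protonated_fraction(pKa_map[r], pH)) for r in his
    }
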