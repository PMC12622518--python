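"""Natural isotope abundances and mass-shift distributions of molecular formulas.

Isotopologue intensities measured by GC-MS mix the tracer signal with the
contribution of naturally occurring heavy isotopes (13C, 2H, 18O, 29/30Si, ...).
This module provides the elemental abundance vectors and the convolution
arithmetic needed to predict — and later remove — that contribution.

Abundance values are IUPAC/CIAAW 2021 representative isotopic compositions,
indexed by nominal mass shift relative to the lightest isotope.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Mapping

import numpy as np

# Representative isotopic composition (CIAAW 2021), by nominal mass shift.
# Index i = probability of carrying i extra nominal mass units.
NATURAL_ABUNDANCE: Mapping[str, tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    # 16O, 17O, 18O
    "O": (0.99757, 0.00038, 0.00205),
    # 28Si, 29Si, 30Si
    "Si": (0.92223, 0.04685, 0.03092),
    # 32S, 33S, 34S, (35: none), 36S
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def element_isotope_vector(element: str) -> np.ndarray:
    """Natural isotope abundance of one element, by nominal mass shift.

    Parameters
    ----------
    element : str
        Element symbol; one of H, C, N, O, Si, S.

    Returns
    -------
    ndarray
        Probability vector over mass shifts 0..max; sums to 1.
    """
    try:
        vec = NATURAL_ABUNDANCE[element]
    except KeyError:
        raise ValueError(
            f"no natural-abundance data for element {element!r}; "
            f"known elements: {sorted(NATURAL_ABUNDANCE)}"
        ) from None
    return np.asarray(vec, dtype=float)


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse an elemental composition like ``'C6H8O7'`` into a count map.

    A mapping passed in is validated and returned as a plain dict.
    """
    if isinstance(formula, Mapping):
        counts = {el: int(n) for el, n in formula.items() if int(n) != 0}
        for el, n in counts.items():
            if n < 0:
                raise ValueError(f"negative atom count for {el}: {n}")
        return counts
    counts: Counter[str] = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not match.group(0):
            break
        el, num = match.group(1), match.group(2)
        counts[el] += int(num) if num else 1
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return dict(counts)


def _truncate(dist: np.ndarray, tail: float = 1e-12) -> np.ndarray:
    """Drop the high-mass tail carrying cumulative probability < ``tail``."""
    csum = np.cumsum(dist)
    keep = int(np.searchsorted(csum, csum[-1] - tail)) + 1
    return dist[: max(keep, 1)]


def formula_distribution(
    formula: str | Mapping[str, int], tail: float = 1e-12
) -> np.ndarray:
    """Mass-shift distribution of a molecular formula at natural abundance.

    Convolves the per-atom isotope vectors over every atom in the formula;
    the result is the probability of observing each nominal mass shift of the
    intact molecule. An empty formula yields the convolution identity [1.0].
    """
    counts = parse_formula(formula)
    dist = np.array([1.0])
    for element, n in counts.items():
        atom = element_isotope_vector(element)
        # atom^n by binary exponentiation of the convolution
        power = atom
        k = n
        while k:
            if k & 1:
                dist = np.convolve(dist, power)
            k >>= 1
            if k:
                power = np.convolve(power, power)
            dist = _truncate(dist, tail)
            power = _truncate(power, tail)
    return _truncate(dist, tail)


def binomial_shift_vector(n: int, p_heavy: float) -> np.ndarray:
    """Distribution of mass shift among n positions each heavy with prob p."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= p_heavy <= 1.0:
        raise ValueError("p_heavy must lie in [0, 1]")
    k = np.arange(n + 1)
    from scipy.stats import binom

    return binom.pmf(k, n, p_heavy)


def subtract_atoms(
    formula: str | Mapping[str, int], element: str, n: int
) -> dict[str, int]:
    """Remove ``n`` atoms of ``element`` from a formula (tracer positions)."""
    counts = parse_formula(formula)
    have = counts.get(element, 0)
    if have < n:
        raise ValueError(
            f"formula has only {have} {element} atoms; cannot remove {n}"
        )
    counts[element] = have - n
    if counts[element] == 0:
        del counts[element]
    return counts
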