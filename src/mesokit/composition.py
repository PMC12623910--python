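"""Sample stoichiometry and composition-weighted atomic scattering quantities.

Normalizing a measured diffraction pattern to electron units and converting
it to a structure factor requires, for the sample composition, the mean
coherent atomic form factor ``<f>(Q)``, its mean square ``<f^2>(Q)``, and an
estimate of the incoherent (Compton) contribution.  Coherent form factors use
the standard four-Gaussian Cromer-Mann parameterisation

    f(Q) = sum_j a_j exp(-b_j s^2) + c,     s = Q / (4 pi),

with coefficients for the light elements of organic molecules shipped as a
package data table (``data/elements.csv``).  Throughout the package the
scattering-vector convention is Q = 4 pi sin(theta) / lambda; the variable
``s`` appears only inside this module.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping

import numpy as np

__all__ = [
    "ElementParams",
    "Composition",
    "element_table",
    "parse_formula",
    "molar_mass",
    "form_factor",
    "mean_f",
    "mean_f2",
    "incoherent_intensity",
]


@dataclass(frozen=True)
class ElementParams:
    """Per-element scattering parameters.

    Attributes
    ----------
    symbol : element symbol, e.g. ``"Cl"``.
    Z : atomic number (number of electrons).
    atomic_weight : standard atomic weight in g/mol.
    cm_a, cm_b : the four Cromer-Mann Gaussian amplitudes / exponents.
    cm_c : Cromer-Mann constant term; ``sum(cm_a) + cm_c ~= Z``.
    incoh_k, incoh_p : coefficients of the saturating incoherent-scattering
        model (see :func:`incoherent_intensity`).
    """

    symbol: str
    Z: int
    atomic_weight: float
    cm_a: tuple
    cm_b: tuple
    cm_c: float
    incoh_k: float
    incoh_p: float

    def form_factor(self, q) -> np.ndarray:
        """Coherent form factor f(Q) in electrons; Q in 1/Angstrom."""
        q = np.asarray(q, dtype=float)
        if np.any(q < 0):
            raise ValueError("Q must be non-negative")
        s2 = (q / (4.0 * np.pi)) ** 2
        out = np.full(q.shape, self.cm_c, dtype=float)
        for a, b in zip(self.cm_a, self.cm_b):
            out += a * np.exp(-b * s2)
        return out


_TABLE: Dict[str, ElementParams] = {}


def element_table() -> Mapping[str, ElementParams]:
    """The embedded element table, keyed by symbol (loaded once, cached)."""
    if not _TABLE:
        ref = resources.files("mesokit.data").joinpath("elements.csv")
        with ref.open("r", encoding="utf-8") as fh:
            rows = [r for r in fh if not r.startswith("#")]
        for rec in csv.DictReader(rows):
            _TABLE[rec["symbol"]] = ElementParams(
                symbol=rec["symbol"],
                Z=int(rec["Z"]),
                atomic_weight=float(rec["weight"]),
                cm_a=tuple(float(rec[f"a{i}"]) for i in range(1, 5)),
                cm_b=tuple(float(rec[f"b{i}"]) for i in range(1, 5)),
                cm_c=float(rec["c"]),
                incoh_k=float(rec["incoh_k"]),
                incoh_p=float(rec["incoh_p"]),
            )
    return _TABLE


def _element(symbol: str) -> ElementParams:
    table = element_table()
    try:
        return table[symbol]
    except KeyError:
        raise KeyError(
            f"unknown element symbol {symbol!r}; available: {sorted(table)}"
        ) from None


@dataclass(frozen=True)
class Composition:
    """Atomic composition of a sample, e.g. the drug molecule stoichiometry.

    ``counts`` maps element symbols to positive integer counts per formula
    unit; ``fractions`` are the derived atomic fractions c_i (summing to 1),
    the weights in <f>, <f^2> and the incoherent estimate.
    """

    counts: Mapping[str, int]
    fractions: Mapping[str, float] = field(init=False)

    def __post_init__(self):
        if not self.counts:
            raise ValueError("composition must contain at least one element")
        for sym, n in self.counts.items():
            _element(sym)  # raises on unknown symbol
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"count for {sym} must be a positive integer")
        total = sum(self.counts.values())
        object.__setattr__(
            self,
            "fractions",
            {sym: n / total for sym, n in self.counts.items()},
        )

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    @property
    def n_electrons(self) -> int:
        return sum(n * _element(s).Z for s, n in self.counts.items())


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Composition:
    """Parse a chemical formula string such as ``"C35H38Cl2N8O4"``.

    Each token is an element symbol optionally followed by a positive integer
    count.  Repeated symbols accumulate.  Raises ``ValueError`` for an empty
    string or any token that is not a known element.
    """
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    formula = formula.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"cannot parse formula at {formula[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in element_table():
            raise ValueError(f"unknown element symbol {sym!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise ValueError(f"count for {sym} must be positive in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return Composition(counts=counts)


def molar_mass(comp: Composition) -> float:
    """Molar mass in g/mol from standard atomic weights."""
    return sum(n * _element(s).atomic_weight for s, n in comp.counts.items())


def form_factor(element: str, q) -> np.ndarray:
    """Coherent atomic form factor f(Q) of one element, in electrons."""
    return _element(element).form_factor(q)


def mean_f(comp: Composition, q) -> np.ndarray:
    """Composition-weighted mean form factor <f>(Q) = sum_i c_i f_i(Q)."""
    q = np.asarray(q, dtype=float)
    out = np.zeros(q.shape, dtype=float)
    for sym, c in comp.fractions.items():
        out += c * _element(sym).form_factor(q)
    return out


def mean_f2(comp: Composition, q) -> np.ndarray:
    """Composition-weighted mean squared form factor <f^2>(Q) = sum_i c_i f_i(Q)^2."""
    q = np.asarray(q, dtype=float)
    out = np.zeros(q.shape, dtype=float)
    for sym, c in comp.fractions.items():
        out += c * _element(sym).form_factor(q) ** 2
    return out


def incoherent_intensity(comp: Composition, q) -> np.ndarray:
    """Per-atom incoherent (Compton) intensity estimate, in electron units.

    Uses the smooth two-parameter saturating model per element

        I_inc,i(Q) = (Z_i - f_i(Q)^2 / Z_i) * (1 - exp(-k_i Q^p_i)),

    which vanishes at Q = 0 and approaches the free-electron limit Z_i from
    below at large Q.  This is an analytic stand-in adequate for plumbing the
    reduction: synthetic data are generated and corrected with the same
    model, and a "none" mode exists downstream for already-corrected input.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("Q must be non-negative")
    out = np.zeros(q.shape, dtype=float)
    for sym, c in comp.fractions.items():
        el = _element(sym)
        # the CM parameterisation is only physical for s = Q/4pi <~ 2;
        # clamp f to [0, Z] so the model stays sane at extreme Q
        f = np.clip(el.form_factor(q), 0.0, float(el.Z))
        out += c * (el.Z - f * f / el.Z) * (1.0 - np.exp(-el.incoh_k * q**el.incoh_p))
    return out
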