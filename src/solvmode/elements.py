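"""Element lookup tables: masses, covalent radii, van der Waals radii.

The table is shipped as a plain-text file (``data/elements.tsv``) covering
H through Rn. Covalent radii follow Cordero 2008, van der Waals radii the
Bondi/Mantina consensus, masses the standard atomic weights.
"""

from __future__ import annotations

from importlib import resources


class UnknownElementError(KeyError):
    """Raised when a symbol is not present in the element table."""


def _load_table() -> dict[str, tuple[float, float, float]]:
    table: dict[str, tuple[float, float, float]] = {}
    text = resources.files("solvmode.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, mass, r_cov, r_vdw = line.split("\t")
        table[sym] = (float(mass), float(r_cov), float(r_vdw))
    return table


_TABLE = _load_table()


def _lookup(symbol: str) -> tuple[float, float, float]:
    try:
        return _TABLE[symbol]
    except KeyError:
        raise UnknownElementError(
            f"element symbol {symbol!r} not in the shipped table (H-Rn)"
        ) from None


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight in amu."""
    return _lookup(symbol)[0]


def covalent_radius(symbol: str) -> float:
    """Covalent single-bond radius in Angstrom (Cordero 2008)."""
    return _lookup(symbol)[1]


def vdw_radius(symbol: str) -> float:
    """Van der Waals radius in Angstrom (Bondi/Mantina consensus)."""
    return _lookup(symbol)[2]


def known_elements() -> frozenset[str]:
    return frozenset(_TABLE)
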