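"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by brute force
(multinomial enumeration of isotopologues, exhaustive enumeration of
one-to-one peak matchings) so the fast implementations are checked
against an independent computation path.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from halomet import chem
from halomet.chem import ISOTOPES, ElementCount
from halomet.msnet import MsmsSpectrum


def multinomial_pattern(formula, prune: float = 0.0):
    """Brute-force isotope envelope by enumerating every isotopologue.

    Only feasible for small formulas (<= ~6 atoms). Returns dict
    offset -> (centroid mz, abundance normalised to base peak = 1).
    """
    f = chem._as_formula(formula)
    atoms = []
    for sym, n in f:
        atoms.extend([ISOTOPES[sym]] * n)
    mono = sum(iso[0][0] for iso in atoms)
    acc: dict[int, list[float]] = {}
    for combo in itertools.product(*atoms):
        mass = sum(m for m, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        off = int(round(mass - mono))
        slot = acc.setdefault(off, [0.0, 0.0])
        slot[0] += prob
        slot[1] += prob * mass
    base = max(a for a, _ in acc.values())
    out = {}
    for off, (a, ms) in sorted(acc.items()):
        rel = a / base
        if rel >= prune:
            out[off] = (ms / a, rel)
    return out


def brute_force_modified_cosine(a: MsmsSpectrum, b: MsmsSpectrum,
                                frag_tol: float = 0.02) -> float:
    """Exhaustive maximum over all one-to-one peak matchings."""
    wa = np.sqrt(a.intensities)
    wa /= np.linalg.norm(wa)
    wb = np.sqrt(b.intensities)
    wb /= np.linalg.norm(wb)
    mz_a, mz_b = a.mzs, b.mzs
    la = a.precursor_mz - mz_a
    lb = b.precursor_mz - mz_b
    options = []
    for i in range(len(mz_a)):
        opts = []
        for j in range(len(mz_b)):
            if (abs(mz_a[i] - mz_b[j]) <= frag_tol
                    or abs(la[i] - lb[j]) <= frag_tol):
                opts.append((j, wa[i] * wb[j]))
        options.append(opts)

    def search(i: int, used: frozenset) -> float:
        if i == len(options):
            return 0.0
        best = search(i + 1, used)  # leave peak i unmatched
        for j, w in options[i]:
            if j not in used:
                best = max(best, w + search(i + 1, used | {j}))
        return best

    return search(0, frozenset())


def random_spectrum(rng: np.random.Generator, n_peaks: int,
                    mz_range=(100.0, 800.0)) -> MsmsSpectrum:
    prec = float(rng.uniform(400.0, 900.0))
    mzs = rng.uniform(*mz_range, size=n_peaks)
    ints = rng.uniform(10.0, 1000.0, size=n_peaks)
    return MsmsSpectrum(
        f"rand{rng.integers(1 << 30)}", prec,
        tuple(zip(mzs.tolist(), ints.tolist())),
    )


def random_plausible_formula(
    rng: np.random.Generator,
    mass_range=(300.0, 900.0),
    with_cl: bool | None = None,
) -> ElementCount:
    """Sample a metabolite-like formula (integer RDBE >= 0) in a mass range."""
    while True:
        c = int(rng.integers(12, 49))
        o = int(rng.integers(0, 11))
        n = int(rng.integers(0, 3))
        s = int(rng.integers(0, 2))
        if with_cl is None:
            cl = int(rng.integers(0, 2))
        else:
            cl = int(rng.integers(1, 3)) if with_cl else 0
        h = int(rng.integers(c, 2 * c + 2 + n - cl + 1))
        if (h + n + cl) % 2 != 0:
            h += 1
        f = ElementCount({"C": c, "H": h, "N": n, "O": o, "S": s, "Cl": cl})
        m = chem.monoisotopic_mass(f)
        if not (mass_range[0] <= m <= mass_range[1]):
            continue
        r = chem.rdbe(f)
        if 0 <= r <= 30 and abs(r - round(r)) < 1e-9:
            return f


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
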