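"""Molecular formula arithmetic for small-molecule mass spectrometry.

This module is the chemistry core of the package: formula parsing and
Hill-notation formatting, monoisotopic and adduct ion masses, isotope
envelope simulation by per-element convolution, chlorine detection from
the M+2 isotopologue, and bounded molecular formula decomposition from an
exact mass.

Masses are in daltons (Da); m/z values are in thomson (Th). The element
set is configurable through the shipped constants table
(``data/isotopes.tsv``); deuterium is modelled as a distinct, pure element
``D`` so labelled formulas take part in ordinary formula arithmetic.
"""

from __future__ import annotations


import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "NEUTRON_SPACING",
    "TABLE_VERSION",
    "ElementCount",
    "AdductSpec",
    "ADDUCTS",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_pattern",
    "convolve_patterns",
    "site_pattern",
    "ChlorineCall",
    "chlorine_score",
    "Candidate",
    "decompose_mass",
    "DEFAULT_BOUNDS",
    "rdbe",
]

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = 1.00727646688
#: average m/z spacing between successive nominal isotopologue peaks
NEUTRON_SPACING = 1.0033548378


class FormulaError(ValueError):
    """Raised for malformed formula text or unsupported elements."""


def _load_isotopes() -> tuple[str, dict[str, list[tuple[float, float]]]]:
    text = (resources.files("halomet") / "data" / "isotopes.tsv").read_text()
    version = "unknown"
    table: dict[str, list[tuple[float, float]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"version\s+([\w.\-]+)", line)
            if m:
                version = m.group(1)
            continue
        sym, mass, ab = line.split("\t")
        table.setdefault(sym, []).append((float(mass), float(ab)))
    for sym in table:
        table[sym].sort()
    return version, table


TABLE_VERSION, ISOTOPES = _load_isotopes()

#: monoisotopic (lightest-isotope) mass per element
MONO_MASS: dict[str, float] = {sym: iso[0][0] for sym, iso in ISOTOPES.items()}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementCount:
    """A molecular formula as an element -> count multiset.

    Counts are non-negative integers; an absent element is equivalent to a
    count of zero. Instances are immutable and hashable, and round-trip
    losslessly through :meth:`hill` / :func:`parse_formula`.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in ISOTOPES:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if int(n) != n or n < 0:
                raise FormulaError(f"negative or fractional count for {sym}: {n}")
            if n:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", dict(sorted(clean.items())))

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __iter__(self):
        return iter(self.counts.items())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementCount):
            return self.counts == other.counts
        return NotImplemented

    def __add__(self, other: "ElementCount") -> "ElementCount":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementCount(merged)

    def __sub__(self, other: "ElementCount") -> "ElementCount":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) - n
            if merged[sym] < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {sym}"
                )
        return ElementCount(merged)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Format in Hill notation: C, H (D directly after H), rest alphabetical."""
        parts = []
        order: list[str]
        if "C" in self.counts:
            order = ["C", "H", "D"] + sorted(
                s for s in self.counts if s not in ("C", "H", "D")
            )
        else:
            order = sorted(self.counts)
        for sym in order:
            n = self.counts.get(sym, 0)
            if n:
                parts.append(sym + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementCount({self.hill()!r})"


def parse_formula(text: str) -> ElementCount:
    """Parse formula text such as ``"C28H55O8Cl"`` into an :class:`ElementCount`.

    Element symbols may repeat; multiplicities add. Raises
    :class:`FormulaError` naming the offending token on unknown symbols or
    explicit zero multiplicities.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula text")
    counts: dict[str, int] = {}
    pos = 0
    text = text.strip()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula at {text[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ISOTOPES:
            raise FormulaError(f"unknown element symbol: {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive multiplicity for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementCount(counts)


def _as_formula(formula: "ElementCount | str | Mapping[str, int]") -> ElementCount:
    if isinstance(formula, ElementCount):
        return formula
    if isinstance(formula, str):
        return parse_formula(formula)
    return ElementCount(dict(formula))


def monoisotopic_mass(formula: "ElementCount | str | Mapping[str, int]") -> float:
    """Monoisotopic (lightest-isotope) mass of a neutral formula, in Da."""
    f = _as_formula(formula)
    return sum(n * MONO_MASS[sym] for sym, n in f)


@dataclass(frozen=True)
class AdductSpec:
    """An ionising adduct: name, elemental shift and signed charge.

    The elemental shift is stored as signed counts (``[M-H]-`` removes one
    hydrogen). The ionic m/z includes the electron-count correction for the
    charge sign, so a protonated ion gains 1.007276 Da per charge.
    """

    name: str
    delta: Mapping[str, int]
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")
        object.__setattr__(self, "delta", dict(self.delta))

    @property
    def delta_mass(self) -> float:
        return sum(n * MONO_MASS[sym] for sym, n in self.delta.items())

    def mz(self, neutral_mass: float) -> float:
        ionic = neutral_mass + self.delta_mass - self.charge * ELECTRON_MASS
        return ionic / abs(self.charge)

    def neutral_mass(self, mz: float) -> float:
        """Invert :meth:`mz`: neutral monoisotopic mass implied by an ion m/z."""
        return mz * abs(self.charge) - self.delta_mass + self.charge * ELECTRON_MASS


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}, +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", {"N": 1, "H": 4}, +1),
    "[M+Na]+": AdductSpec("[M+Na]+", {"Na": 1}, +1),
    "[M-H]-": AdductSpec("[M-H]-", {"H": -1}, -1),
}


def get_adduct(adduct: "AdductSpec | str") -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    key = adduct.replace("−", "-").replace(" ", "")
    if key not in ADDUCTS:
        raise KeyError(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        )
    return ADDUCTS[key]


def adduct_mz(
    formula: "ElementCount | str | Mapping[str, int]",
    adduct: "AdductSpec | str" = "[M+H]+",
) -> float:
    """Ionic m/z of a neutral formula under the given adduct (Th).

    Includes the electron-mass correction; rounding is left to the caller
    (printed values in this field are conventionally given to 4 d.p.).
    """
    return get_adduct(adduct).mz(monoisotopic_mass(formula))


# --------------------------------------------------------------------------
# Isotope envelopes


@dataclass(frozen=True)
class IsotopePattern:
    """A centroided isotopologue envelope aggregated by nominal-mass offset.

    ``offsets`` are integer nominal-mass indices relative to the lightest
    isotopologue (M+0); ``peaks`` are the matching ``(mz, abundance)`` pairs
    with the base (most abundant) peak normalised to abundance 1.0.
    """

    offsets: tuple[int, ...]
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.peaks):
            raise ValueError("offsets and peaks must align")

    @property
    def base_offset(self) -> int:
        i = max(range(len(self.peaks)), key=lambda k: self.peaks[k][1])
        return self.offsets[i]

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    def abundance_at(self, offset: int) -> float:
        for o, (_, a) in zip(self.offsets, self.peaks):
            if o == offset:
                return a
        return 0.0

    def mz_at(self, offset: int) -> float | None:
        for o, (mz, _) in zip(self.offsets, self.peaks):
            if o == offset:
                return mz
        return None

    def scaled(self, factor: float) -> "IsotopePattern":
        return IsotopePattern(
            self.offsets, tuple((mz, a * factor) for mz, a in self.peaks)
        )


def _finalize(amp: np.ndarray, mom: np.ndarray, prune: float) -> IsotopePattern:
    """Turn raw (abundance, mass-moment) accumulators into a pattern."""
    mask = amp > 0
    if not mask.any():
        raise ValueError("empty isotope distribution")
    base = amp.max()
    offsets, peaks = [], []
    for k in np.nonzero(mask)[0]:
        rel = amp[k] / base
        if rel < prune:
            continue
        offsets.append(int(k))
        peaks.append((mom[k] / amp[k], rel))
    return IsotopePattern(tuple(offsets), tuple(peaks))


def _raw(pattern: IsotopePattern, size: int) -> tuple[np.ndarray, np.ndarray]:
    amp = np.zeros(size)
    mom = np.zeros(size)
    for o, (mz, a) in zip(pattern.offsets, pattern.peaks):
        if o < size:
            amp[o] = a
            mom[o] = a * mz
    return amp, mom


def _conv(a, am, b, bm, size):
    """Convolve two (abundance, mass-moment) accumulator pairs, truncated."""
    na = int(np.nonzero(a)[0].max()) + 1 if a.any() else 0
    nb = int(np.nonzero(b)[0].max()) + 1 if b.any() else 0
    out_a = np.zeros(size)
    out_m = np.zeros(size)
    for i in range(min(na, size)):
        if a[i] == 0:
            continue
        hi = min(nb, size - i)
        out_a[i : i + hi] += a[i] * b[:hi]
        out_m[i : i + hi] += am[i] * b[:hi] + a[i] * bm[:hi]
    return out_a, out_m


def site_pattern(states: Sequence[tuple[float, float]]) -> IsotopePattern:
    """Isotope pattern of a single site with explicit (mass, probability) states.

    Nominal offsets are assigned relative to the lightest state. Used for
    partially pure isotopic labels (e.g. a deuterated position with 1%
    residual protium).
    """
    states = sorted(states)
    m0 = states[0][0]
    offsets = tuple(int(round(m - m0)) for m, _ in states)
    base = max(p for _, p in states)
    return IsotopePattern(offsets, tuple((m, p / base) for m, p in states))


def _element_accumulators(sym: str, count: int, size: int):
    iso = ISOTOPES[sym]
    m0 = iso[0][0]
    single_a = np.zeros(size)
    single_m = np.zeros(size)
    for mass, ab in iso:
        k = int(round(mass - m0))
        if k < size:
            single_a[k] += ab
            single_m[k] += ab * mass
    # exponentiation by squaring over the convolution monoid
    res_a = np.zeros(size)
    res_a[0] = 1.0
    res_m = np.zeros(size)
    base_a, base_m = single_a, single_m
    n = count
    while n:
        if n & 1:
            res_a, res_m = _conv(res_a, res_m, base_a, base_m, size)
        n >>= 1
        if n:
            base_a, base_m = _conv(base_a, base_m, base_a, base_m, size)
    return res_a, res_m


def isotope_pattern(
    formula: "ElementCount | str | Mapping[str, int]",
    max_offsets: int = 10,
    prune: float = 1e-4,
) -> IsotopePattern:
    """Simulate the centroided isotope envelope of a neutral or ionic formula.

    Per-element isotope distributions are convolved and aggregated by
    integer nominal-mass offset; the centroid m/z of each offset is the
    abundance-weighted mean of the contributing isotopologues. Abundances
    are normalised to the base peak and peaks below ``prune`` (relative to
    base) are dropped. Fine isotope structure within an offset (e.g.
    13C2 vs 37Cl) is deliberately not resolved, matching centroided MS1
    data.

    ``max_offsets`` bounds the envelope length (offsets 0..max_offsets-1).
    """
    f = _as_formula(formula)
    if max_offsets < 1:
        raise ValueError("max_offsets must be >= 1")
    amp = np.zeros(max_offsets)
    amp[0] = 1.0
    mom = np.zeros(max_offsets)
    for sym, n in f:
        ea, em = _element_accumulators(sym, n, max_offsets)
        amp, mom = _conv(amp, mom, ea, em, max_offsets)
    return _finalize(amp, mom, prune)


def convolve_patterns(
    a: IsotopePattern, b: IsotopePattern, max_offsets: int = 10, prune: float = 1e-4
) -> IsotopePattern:
    """Offset-wise convolution of two envelopes (masses add, abundances multiply)."""
    aa, am = _raw(a, max_offsets)
    ba, bm = _raw(b, max_offsets)
    ra, rm = _conv(aa, am, ba, bm, max_offsets)
    return _finalize(ra, rm, prune)


# --------------------------------------------------------------------------
# Chlorine detection


class ChlorineCall(NamedTuple):
    is_chlorinated: bool
    ratio: float
    n_cl: int


#: theoretical M+2/M contribution of one 37Cl (0.2424/0.7576)
CL_M2_RATIO = ISOTOPES["Cl"][1][1] / ISOTOPES["Cl"][0][1]


def chlorine_score(
    observed: IsotopePattern,
    window_1cl: tuple[float, float] = (0.20, 0.50),
    window_2cl: tuple[float, float] = (0.50, 0.85),
    max_m1_ratio: float = 0.6,
) -> ChlorineCall:
    """Classify an MS1 envelope as chlorinated from its M+2 isotopologue.

    ``ratio`` is abundance(M+2)/abundance(M+0). The call is positive when
    the ratio falls in the acceptance window for one chlorine
    (``window_1cl``) or two (``window_2cl``), after requiring an M+1 peak
    consistent with a plausible carbon count (M+1/M+0 <= ``max_m1_ratio``).
    ``n_cl`` is the k in {1, 2} whose theoretical contribution 0.320*k is
    nearest the observed ratio, or 0 for a negative call.
    """
    if not observed.peaks:
        raise ValueError("empty isotope pattern")
    m0 = observed.abundance_at(0)
    if m0 <= 0:
        raise ValueError("pattern has no M+0 peak")
    ratio = observed.abundance_at(2) / m0
    m1_ratio = observed.abundance_at(1) / m0
    in_1 = window_1cl[0] <= ratio <= window_1cl[1]
    in_2 = window_2cl[0] < ratio <= window_2cl[1]
    flagged = (in_1 or in_2) and m1_ratio <= max_m1_ratio
    if not flagged:
        return ChlorineCall(False, ratio, 0)
    n_cl = 1 if abs(ratio - CL_M2_RATIO) <= abs(ratio - 2 * CL_M2_RATIO) else 2
    return ChlorineCall(True, ratio, n_cl)


# --------------------------------------------------------------------------
# Formula decomposition

DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 60),
    "H": (0, 120),
    "N": (0, 5),
    "O": (0, 15),
    "S": (0, 3),
    "Cl": (0, 3),
    "Na": (0, 1),
}

# valence - 2 per element, for ring-plus-double-bond equivalents
_RDBE_TERM = {"C": 1.0, "N": 0.5, "H": -0.5, "D": -0.5, "Cl": -0.5, "Na": -0.5,
              "O": 0.0, "S": 0.0}


def rdbe(formula: "ElementCount | str | Mapping[str, int]") -> float:
    """Ring-plus-double-bond equivalents: C - (H+D+Cl+Na)/2 + N/2 + 1."""
    f = _as_formula(formula)
    return 1.0 + sum(_RDBE_TERM.get(sym, 0.0) * n for sym, n in f)


class Candidate(NamedTuple):
    formula: ElementCount
    adduct: AdductSpec
    ppm_error: float


def _heteroatoms(f: ElementCount) -> int:
    return sum(n for sym, n in f if sym not in ("C", "H"))


def decompose_mass(
    mz: float,
    adducts: Iterable["AdductSpec | str"] = ("[M+H]+",),
    tol_ppm: float = 10.0,
    bounds: Mapping[str, tuple[int, int]] | None = None,
    require: Mapping[str, int] | None = None,
    rdbe_range: tuple[float, float] = (-0.5, 40.0),
    even_electron: bool = True,
) -> list[Candidate]:
    """Enumerate molecular formulas consistent with an observed ion m/z.

    Exhaustive search within per-element count ``bounds`` for each adduct;
    candidates must lie within ``tol_ppm`` of the observed m/z, satisfy the
    ring-plus-double-bond filter, and honour ``require`` (minimum element
    counts, e.g. ``{"Cl": 1}`` when the chlorine flag is set). Results are
    sorted by absolute ppm error, ties broken by fewer heteroatoms.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bounds = dict(bounds if bounds is not None else DEFAULT_BOUNDS)
    if not bounds or all(hi <= 0 and lo <= 0 for lo, hi in bounds.values()):
        raise ValueError("empty element bounds")
    require = dict(require or {})
    for sym, n in require.items():
        lo, hi = bounds.get(sym, (0, 0))
        bounds[sym] = (max(lo, n), hi)

    # H is solved in closed form at the innermost level; other elements are
    # enumerated heaviest-first so mass pruning bites early.
    h_lo, h_hi = bounds.pop("H", (0, 0))
    elems = sorted(bounds, key=lambda s: -MONO_MASS[s])
    maxmass = [0.0] * (len(elems) + 1)
    for i in range(len(elems) - 1, -1, -1):
        sym = elems[i]
        maxmass[i] = maxmass[i + 1] + bounds[sym][1] * MONO_MASS[sym]
    mh = MONO_MASS["H"]

    results: list[Candidate] = []
    for adduct in adducts:
        spec = get_adduct(adduct)
        target = spec.neutral_mass(mz)
        tol_da = tol_ppm * 1e-6 * mz * abs(spec.charge) + 1e-9
        counts: dict[str, int] = {}

        def recurse(i: int, remaining: float) -> None:
            if i == len(elems):
                if remaining < -tol_da:
                    return
                h_guess = int(round(remaining / mh))
                for h in range(max(h_lo, h_guess - 1), min(h_hi, h_guess + 1) + 1):
                    err = remaining - h * mh
                    if abs(err) > tol_da:
                        continue
                    counts["H"] = h
                    try:
                        f = ElementCount(dict(counts))
                    finally:
                        counts.pop("H", None)
                    r = rdbe(f)
                    if not (rdbe_range[0] <= r <= rdbe_range[1]):
                        continue
                    if even_electron and abs(r - round(r)) > 1e-9:
                        continue
                    ppm = (spec.mz(monoisotopic_mass(f)) - mz) / mz * 1e6
                    if abs(ppm) <= tol_ppm:
                        results.append(Candidate(f, spec, ppm))
                return
            sym = elems[i]
            lo, hi = bounds[sym]
            m = MONO_MASS[sym]
            # n*m must leave a residue coverable by lighter elements + H
            hi = min(hi, int((remaining + tol_da) // m))
            for n in range(lo, hi + 1):
                rem = remaining - n * m
                if rem + tol_da < 0:
                    break
                if rem - tol_da > maxmass[i + 1] + h_hi * mh:
                    continue
                if n:
                    counts[sym] = n
                recurse(i + 1, rem)
                counts.pop(sym, None)

        recurse(0, target)

    results.sort(key=lambda c: (abs(c.ppm_error), _heteroatoms(c.formula),
                                c.formula.hill()))
    return results
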