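"""Stable-isotope feeding analysis: isotopologue mixture deconvolution.

After feeding a deuterated precursor, the MS1 envelope of a product is a
mixture of the unlabelled species and labelled species that retained some
number of deuterium atoms. This module simulates the theoretical envelope
of each labelling hypothesis and fits the observed envelope as a
non-negative mixture of theoretical envelopes by least squares on the
nominal-mass-offset axis (abundances normalised to M+0 = 1). Comparing
the residuals of "all labels retained" vs "one label lost" hypotheses is
how displacement of a deuterium by a substituent (e.g. chlorine) is
inferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from . import chem
from .chem import ElementCount, IsotopePattern

__all__ = [
    "D_MASS_SHIFT",
    "LabelSpecies",
    "MixtureFit",
    "HypothesisFit",
    "labeled_species",
    "fit_label_mixture",
    "retention_model_test",
]

#: mass gained per H -> D substitution (Da)
D_MASS_SHIFT = chem.MONO_MASS["D"] - chem.MONO_MASS["H"]


@dataclass(frozen=True)
class LabelSpecies:
    """One labelling state of a compound: formula, envelope, mass offset.

    ``mz_offset`` is the monoisotopic shift from the unlabelled parent in
    Da; ``ref_mass`` is the unlabelled parent's monoisotopic mass, the
    anchor against which envelope peaks are assigned absolute nominal
    offsets during fitting (so M+0 of the unlabelled parent is offset 0).
    """

    name: str
    formula: ElementCount
    pattern: IsotopePattern
    mz_offset: float
    ref_mass: float

    @property
    def nominal_offset(self) -> int:
        return int(round(self.mz_offset / chem.NEUTRON_SPACING))

    def absolute_offsets(self) -> list[int]:
        """Nominal offsets of the envelope peaks relative to unlabelled M+0."""
        return [
            int(round((mz - self.ref_mass) / chem.NEUTRON_SPACING))
            for mz, _ in self.pattern.peaks
        ]


def labeled_species(
    parent: "ElementCount | str",
    n_label: int,
    n_lost: int,
    purity: float = 1.0,
    max_offsets: int = 6,
    name: str | None = None,
) -> LabelSpecies:
    """Build the species retaining ``n_label - n_lost`` deuterium atoms.

    ``parent`` is the unlabelled formula; ``n_label`` deuteriums were fed
    and ``n_lost`` were exchanged back to hydrogen (0 <= n_lost <=
    n_label <= H count). ``purity`` models isotopic enrichment per
    labelled position (1.0 = fully deuterated; e.g. 0.99 for commercial
    labels adds small M-1 satellites). ``max_offsets=6`` keeps the default
    M+0..M+5 window per species, matching what is realistically measured.
    """
    parent = chem._as_formula(parent)
    if not 0 <= n_lost <= n_label:
        raise ValueError("need 0 <= n_lost <= n_label")
    n_d = n_label - n_lost
    if n_d > parent["H"]:
        raise ValueError("more labels than exchangeable hydrogens")
    swap = ElementCount({"H": n_d})
    formula = (parent - swap) + ElementCount({"D": n_d})
    if purity >= 1.0 or n_d == 0:
        pattern = chem.isotope_pattern(formula, max_offsets=max_offsets)
    else:
        base = chem.isotope_pattern(parent - swap, max_offsets=max_offsets, prune=0.0)
        site = chem.site_pattern(
            [(chem.MONO_MASS["H"], 1.0 - purity), (chem.MONO_MASS["D"], purity)]
        )
        pattern = base
        for _ in range(n_d):
            pattern = chem.convolve_patterns(
                pattern, site, max_offsets=max_offsets + n_d, prune=0.0
            )
        # re-prune relative to the final base peak
        pattern = IsotopePattern(
            tuple(
                o for o, (m, a) in zip(pattern.offsets, pattern.peaks) if a >= 1e-4
            ),
            tuple((m, a) for m, a in pattern.peaks if a >= 1e-4),
        )
    return LabelSpecies(
        name=name if name is not None else f"d{n_d}",
        formula=formula,
        pattern=pattern,
        mz_offset=n_d * D_MASS_SHIFT,
        ref_mass=chem.monoisotopic_mass(parent),
    )


@dataclass(frozen=True)
class MixtureFit:
    """Result of a non-negative mixture fit of theoretical envelopes."""

    fractions: dict[str, float]
    residual: float
    covered_offsets: tuple[int, ...]

    def fraction(self, name: str) -> float:
        for key, val in self.fractions.items():
            if key == name or name in key.split("+"):
                return val
        raise KeyError(name)


def _design_matrix(
    species: Sequence[LabelSpecies], offsets: np.ndarray
) -> np.ndarray:
    cols = []
    for sp in species:
        col = np.zeros(len(offsets))
        for o, (_, a) in zip(sp.absolute_offsets(), sp.pattern.peaks):
            idx = np.where(offsets == o)[0]
            if idx.size:
                col[idx[0]] = a
        cols.append(col)
    return np.column_stack(cols)


def fit_label_mixture(
    observed: IsotopePattern,
    species: Sequence[LabelSpecies],
    normalize_offset: int = 0,
) -> MixtureFit:
    """Fit the observed envelope as a non-negative mixture of species envelopes.

    Observed and theoretical abundances are aligned by nominal-mass offset
    (relative to the unlabelled M+0) and the observed envelope is
    normalised to its M+0 peak. Weights are obtained by non-negative least
    squares and renormalised to fractions summing to 1; the residual is
    the sum of squared abundance differences at the fitted weights.
    Species with indistinguishable envelopes are collapsed and reported as
    a summed fraction under a joined name.
    """
    if len(species) < 2:
        raise ValueError("need at least two species to deconvolve")
    obs_off = np.array(observed.offsets)
    obs_ab = observed.abundances.astype(float)
    norm = observed.abundance_at(normalize_offset)
    if norm <= 0:
        norm = obs_ab.max()
    obs_ab = obs_ab / norm

    # fit over the measured window only: offsets present in the observed
    # envelope (theoretical peaks outside it are unmeasured, not zero)
    offsets = np.array(sorted(set(obs_off.tolist())))
    b = np.zeros(len(offsets))
    for o, a in zip(obs_off, obs_ab):
        b[np.where(offsets == o)[0][0]] = a
    A = _design_matrix(species, offsets)

    # collapse rank-degenerate (indistinguishable) species
    groups: list[list[int]] = []
    for k in range(A.shape[1]):
        placed = False
        for grp in groups:
            if np.allclose(A[:, grp[0]], A[:, k], atol=1e-9):
                grp.append(k)
                placed = True
                break
        if not placed:
            groups.append([k])
    if len(groups) < len(species):
        warnings.warn(
            "species with identical envelopes collapsed into a joint fraction",
            RuntimeWarning,
        )
    A_fit = np.column_stack([A[:, grp[0]] for grp in groups])

    coef, _ = nnls(A_fit, b)
    total = coef.sum()
    if total <= 0:
        raise ValueError("observed envelope fits no species (all-zero weights)")
    residual = float(np.sum((A_fit @ coef - b) ** 2))
    fractions = {}
    for grp, c in zip(groups, coef):
        key = "+".join(species[k].name for k in grp)
        fractions[key] = float(c / total)
    return MixtureFit(fractions, residual, tuple(int(o) for o in offsets))


@dataclass(frozen=True)
class HypothesisFit:
    """One label-retention hypothesis and its mixture-fit quality."""

    n_lost: int
    label: str
    residual: float
    labeled_fraction: float
    fit: MixtureFit


def retention_model_test(
    observed: IsotopePattern,
    parent: "ElementCount | str",
    n_label: int,
    max_lost: int | None = None,
    purity: float = 1.0,
    min_labeled_fraction: float = 0.05,
) -> list[HypothesisFit]:
    """Rank label-retention hypotheses (all retained, one lost, ...) by fit.

    For each hypothesised loss count k the observed envelope is fitted as
    unlabelled + (n_label - k)-deuterium species; hypotheses are returned
    sorted by residual ascending. If every hypothesis assigns less than
    ``min_labeled_fraction`` to the labelled species the data carry no
    incorporation signal and the ranking is flagged degenerate by naming
    every hypothesis ``inconclusive``.
    """
    if n_label < 1:
        raise ValueError("n_label must be >= 1")
    parent = chem._as_formula(parent)
    if max_lost is None:
        max_lost = n_label
    unlabeled = labeled_species(parent, 0, 0, name="unlabeled")
    fits = []
    for k in range(0, max_lost + 1):
        sp = labeled_species(parent, n_label, k, purity=purity,
                             name=f"d{n_label - k}")
        with warnings.catch_warnings():
            # the k == n_label hypothesis is the unlabelled species itself;
            # its expected collapse is not worth a user-facing warning here
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_label_mixture(observed, [unlabeled, sp])
        label = ("full retention" if k == 0
                 else "one lost" if k == 1 else f"{k} lost")
        # a fraction only identifies labelling when the labelled species is
        # distinguishable from unlabelled (not collapsed into a joint key)
        labeled_fraction = fit.fractions.get(sp.name, 0.0)
        fits.append(
            HypothesisFit(
                n_lost=k,
                label=label,
                residual=fit.residual,
                labeled_fraction=labeled_fraction,
                fit=fit,
            )
        )
    fits.sort(key=lambda h: (h.residual, h.n_lost))
    if all(h.labeled_fraction < min_labeled_fraction for h in fits):
        fits = [
            HypothesisFit(h.n_lost, "inconclusive", h.residual,
                          h.labeled_fraction, h.fit)
            for h in fits
        ]
    return fits
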