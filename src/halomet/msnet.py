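"""MS/MS spectral preprocessing and modified-cosine molecular networking.

Spectra are filtered the way the networking software configured for this
workflow filters them: peaks within +/-17 Th of the precursor are removed
(the exclusion zone suppresses residual precursor and isotope signals),
and a peak survives only if it ranks among the 6 most intense within the
+/-50 Th window centred on itself.

The modified cosine similarity matches peaks either directly (fragment
match, |mz_a - mz_b| <= tol) or after shifting by the precursor-mass
difference (neutral-loss match); a peak may participate once, as one or
the other. The one-to-one matching that maximises the score is found
exactly via linear assignment, with sqrt-intensity weights normalised to
unit vector norm per spectrum, so the score lies in [0, 1]. Edges require
both a minimum cosine (default 0.60) and a minimum number of matched
fragments or neutral losses (default 4).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MsmsSpectrum",
    "read_mgf",
    "write_mgf",
    "collision_energy",
    "filter_peaks",
    "modified_cosine",
    "build_network",
    "component_report",
    "write_graphml",
]


def collision_energy(precursor_mz: float) -> float:
    """Acquisition collision energy (V) as a function of precursor m/z."""
    return 10.0 + 0.02 * precursor_mz


@dataclass(frozen=True)
class MsmsSpectrum:
    """A centroided MS/MS spectrum tied to one LC-MS feature."""

    spectrum_id: str
    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]  # (mz, intensity), mz ascending
    charge: int = 1
    rt: float = 0.0
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i <= 0 for _, i in pk):
            raise ValueError("peak intensities must be positive")
        object.__setattr__(self, "peaks", pk)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    def with_peaks(self, peaks) -> "MsmsSpectrum":
        return replace(self, peaks=tuple(peaks))


def read_mgf(path: "str | Path") -> list[MsmsSpectrum]:
    """Read spectra from an MGF file (TITLE = feature id, RTINSECONDS honoured)."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", f"scan{len(out) + 1}"))
            pep = params.get("pepmass", (0.0,))
            prec = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            charge = params.get("charge")
            z = int(charge[0]) if charge else 1
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            ce = params.get("collision_energy")
            peaks = tuple(
                zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
            )
            out.append(
                MsmsSpectrum(
                    title,
                    prec,
                    peaks,
                    charge=z,
                    rt=rt,
                    collision_energy=float(ce) if ce is not None else None,
                )
            )
    return out


def write_mgf(spectra: Iterable[MsmsSpectrum], path: "str | Path") -> None:
    """Write spectra as MGF with stable formatting (reproducible output)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={abs(s.charge)}{'+' if s.charge >= 0 else '-'}\n")
            fh.write(f"RTINSECONDS={s.rt * 60.0:.3f}\n")
            if s.collision_energy is not None:
                fh.write(f"COLLISION_ENERGY={s.collision_energy:.4f}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.5f} {inten:.3f}\n")
            fh.write("END IONS\n")


def filter_peaks(
    s: MsmsSpectrum,
    precursor_window: float = 17.0,
    top_k: int = 6,
    local_window: float = 50.0,
) -> MsmsSpectrum:
    """Apply the precursor-exclusion and local top-K peak filters.

    (i) peaks with |mz - precursor_mz| <= ``precursor_window`` are removed;
    (ii) a peak survives only if it is among the ``top_k`` most intense
    within +/-``local_window`` Th of its own m/z. Deterministic (intensity
    ties broken toward lower m/z) and idempotent.
    """
    mzs = s.mzs
    ints = s.intensities
    keep = np.abs(mzs - s.precursor_mz) > precursor_window
    mzs, ints = mzs[keep], ints[keep]
    out = []
    for i in range(len(mzs)):
        in_win = np.abs(mzs - mzs[i]) <= local_window
        better = (ints[in_win] > ints[i]) | (
            (ints[in_win] == ints[i]) & (mzs[in_win] < mzs[i])
        )
        if better.sum() < top_k:
            out.append((mzs[i], ints[i]))
    return s.with_peaks(out)


def _weights(intensities: np.ndarray) -> np.ndarray:
    w = np.sqrt(intensities)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    frag_tol: float = 0.02,
    sqrt_intensity: bool = True,
) -> tuple[float, int]:
    """Modified cosine score and matched-pair count between two spectra.

    Peaks i in a and j in b are matchable when their m/z agree within
    ``frag_tol`` (fragment match) or their neutral losses
    (precursor - mz) agree within ``frag_tol`` (loss match). The score is
    the maximum over one-to-one matchings of the sum of w_i * w_j, with
    per-spectrum unit-norm weights (sqrt-intensity by default), computed
    exactly by linear assignment. ``n_matched`` pools fragment- and
    loss-matched pairs of the selected matching.
    """
    if not a.peaks or not b.peaks:
        return 0.0, 0
    mz_a, mz_b = a.mzs, b.mzs
    wa = _weights(a.intensities) if sqrt_intensity else (
        a.intensities / np.linalg.norm(a.intensities)
    )
    wb = _weights(b.intensities) if sqrt_intensity else (
        b.intensities / np.linalg.norm(b.intensities)
    )
    direct = np.abs(mz_a[:, None] - mz_b[None, :]) <= frag_tol
    loss_a = a.precursor_mz - mz_a
    loss_b = b.precursor_mz - mz_b
    shifted = np.abs(loss_a[:, None] - loss_b[None, :]) <= frag_tol
    matchable = direct | shifted
    if not matchable.any():
        return 0.0, 0
    score_mat = np.where(matchable, wa[:, None] * wb[None, :], 0.0)
    row, col = linear_sum_assignment(score_mat, maximize=True)
    used = matchable[row, col]
    score = float(score_mat[row, col].sum())
    return min(score, 1.0), int(used.sum())


def build_network(
    spectra: Sequence[MsmsSpectrum],
    min_cosine: float = 0.60,
    min_matched: int = 4,
    frag_tol: float = 0.02,
    annotations: pd.DataFrame | None = None,
    prefilter: bool = True,
) -> nx.Graph:
    """Score all spectrum pairs and keep edges meeting both thresholds.

    Nodes are spectrum ids with mz/rt attributes plus any columns of
    ``annotations`` (indexed by spectrum/feature id: fold change,
    direction, p value, chlorine flag, formula, ...). Edges carry
    ``cosine`` and ``n_matched``. Spectra are peak-filtered first unless
    ``prefilter=False``.
    """
    ids = [s.spectrum_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate spectrum ids")
    prepared = [filter_peaks(s) for s in spectra] if prefilter else list(spectra)
    g = nx.Graph()
    for s in prepared:
        attrs = {"mz": float(s.precursor_mz), "rt": float(s.rt)}
        if annotations is not None and s.spectrum_id in annotations.index:
            for k, v in annotations.loc[s.spectrum_id].items():
                if isinstance(v, (np.floating, np.integer)):
                    v = v.item()
                attrs[str(k)] = v if v is not None else ""
        g.add_node(s.spectrum_id, **attrs)
    for i in range(len(prepared)):
        for j in range(i + 1, len(prepared)):
            score, n = modified_cosine(prepared[i], prepared[j], frag_tol)
            if score >= min_cosine and n >= min_matched:
                g.add_edge(
                    prepared[i].spectrum_id,
                    prepared[j].spectrum_id,
                    cosine=round(score, 6),
                    n_matched=n,
                )
    return g


def component_report(net: nx.Graph) -> pd.DataFrame:
    """Per-connected-component summary of an annotated network.

    For each component: member count, how many are depleted-without-halide,
    how many carry the chlorine flag, the strongest depletion fold change,
    and the member m/z list. Components are ranked by their maximum
    depletion fold change (then size), the ordering used for candidate
    families.
    """
    rows = []
    for comp in nx.connected_components(net):
        members = sorted(comp)
        nodes = [net.nodes[m] for m in members]
        n_depleted = sum(
            1 for d in nodes if d.get("direction") == "depleted_without_halide"
        )
        n_chlor = sum(1 for d in nodes if bool(d.get("chlorinated", False)))
        folds = [
            float(d.get("fold_change", 1.0))
            for d in nodes
            if d.get("direction") == "depleted_without_halide"
        ]
        rows.append(
            {
                "n_members": len(members),
                "n_depleted_without_halide": n_depleted,
                "n_chlorinated": n_chlor,
                "max_depletion_fold": max(folds) if folds else 1.0,
                "members": ";".join(members),
                "mz_list": ";".join(
                    f"{float(d.get('mz', 0.0)):.4f}" for d in nodes
                ),
            }
        )
    rows.sort(key=lambda r: (-r["max_depletion_fold"], -r["n_members"], r["members"]))
    df = pd.DataFrame(
        rows,
        columns=[
            "n_members",
            "n_depleted_without_halide",
            "n_chlorinated",
            "max_depletion_fold",
            "members",
            "mz_list",
        ],
    )
    df.index = pd.Index(
        [f"C{k + 1:03d}" for k in range(len(df))], name="component_id"
    )
    return df


def write_graphml(net: nx.Graph, path: "str | Path") -> None:
    """Export the network as GraphML (scalar node/edge attributes only)."""
    g = net.copy()
    for _, data in g.nodes(data=True):
        for k, v in list(data.items()):
            if isinstance(v, (list, tuple)):
                data[k] = ";".join(map(str, v))
            elif isinstance(v, (np.bool_, bool)):
                data[k] = bool(v)
            elif v is None or (isinstance(v, float) and np.isnan(v)):
                data[k] = ""
    nx.write_graphml(g, str(path))
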