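"""Cross-run feature alignment and paired-condition differential statistics.

The comparative half of the halide-depletion workflow: per-run LC-MS
feature lists (m/z, retention time, intensity) from cultures grown with
("replete") and without ("depleted") halide are joined into one feature
table, sub-noise cells are floored to a pseudocount, and each feature gets
a fold change plus a two-tailed Student's t-test P value across the
biological replicates. Co-eluting adduct and in-source-fragment artifacts
are grouped so one parent compound is counted once.

Fold changes are stored as magnitudes >= 1 together with a direction
(``depleted_without_halide`` / ``enriched_without_halide`` / ``unchanged``);
a signed export (negative = depleted without halide) is available for
supplement-style tables.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REPLETE",
    "DEPLETED",
    "FeatureRun",
    "FeatureTable",
    "MzTolerance",
    "DEFAULT_DELTAS",
    "read_runs_csv",
    "write_runs_csv",
    "join_features",
    "gap_fill_floor",
    "differential_stats",
    "signed_fold_change",
    "artifact_group",
]

REPLETE = "replete"
DEPLETED = "depleted"
CONDITIONS = (REPLETE, DEPLETED)


@dataclass
class FeatureRun:
    """One LC-MS run: a condition label plus its centroided feature list."""

    run_id: str
    condition: str
    features: pd.DataFrame  # columns: mz, rt, intensity

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        f = self.features
        missing = {"mz", "rt", "intensity"} - set(f.columns)
        if missing:
            raise ValueError(f"feature list missing columns: {sorted(missing)}")
        if (f["mz"] <= 0).any() or (f["rt"] < 0).any() or (f["intensity"] < 0).any():
            raise ValueError("features require mz > 0, rt >= 0, intensity >= 0")


@dataclass
class FeatureTable:
    """Aligned features x samples intensity matrix with condition design.

    ``features`` carries consensus m/z and retention time per row;
    ``matrix`` is indexed by feature_id with one column per run;
    ``gap_filled`` flags cells set to the pseudocount floor.
    """

    features: pd.DataFrame  # index feature_id; columns: mz, rt
    matrix: pd.DataFrame  # index feature_id; columns: run ids
    design: dict[str, str]  # run id -> condition
    gap_filled: pd.DataFrame | None = None
    noise_floor: float | None = None

    def condition_columns(self, condition: str) -> list[str]:
        return [r for r, c in self.design.items() if c == condition]


class MzTolerance:
    """MZmine-style joint tolerance: max(absolute Th, ppm-proportional)."""

    def __init__(self, abs_th: float = 0.01, ppm: float = 20.0):
        if abs_th <= 0 and ppm <= 0:
            raise ValueError("tolerance must be positive")
        self.abs_th = abs_th
        self.ppm = ppm

    def __call__(self, mz: float) -> float:
        return max(self.abs_th, self.ppm * 1e-6 * mz)

    def __repr__(self) -> str:
        return f"MzTolerance(abs_th={self.abs_th}, ppm={self.ppm})"


def read_runs_csv(path: "str | Path") -> list[FeatureRun]:
    """Read a tall per-run feature CSV (run_id, condition, mz, rt, intensity)."""
    df = pd.read_csv(path)
    required = {"run_id", "condition", "mz", "rt", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    runs = []
    for (run_id, condition), grp in df.groupby(["run_id", "condition"], sort=True):
        runs.append(
            FeatureRun(
                str(run_id),
                str(condition),
                grp[["mz", "rt", "intensity"]].reset_index(drop=True),
            )
        )
    return runs


def write_runs_csv(runs: Iterable[FeatureRun], path: "str | Path") -> None:
    frames = []
    for r in runs:
        f = r.features.copy()
        f.insert(0, "run_id", r.run_id)
        f.insert(1, "condition", r.condition)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def join_features(
    runs: Sequence[FeatureRun],
    mz_tol: "MzTolerance | float" = None,
    rt_tol: float = 0.2,
) -> FeatureTable:
    """Greedy agglomerative join of per-run features into aligned rows.

    All features are pooled and visited by descending intensity; each
    feature either joins the nearest existing row (smallest |delta m/z|,
    within both tolerances, and only if that row has no feature from the
    same run yet) or seeds a new row. The seed's m/z and rt become the row
    consensus, which guarantees every member lies within the joining
    tolerances of the consensus. Unmatched cells are 0 pending gap fill.
    """
    if not runs:
        raise ValueError("need at least one run")
    ids = [r.run_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate run_id in runs")
    if mz_tol is None:
        mz_tol = MzTolerance()
    elif not callable(mz_tol):
        mz_tol = MzTolerance(abs_th=float(mz_tol), ppm=0.0)
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")

    recs = []
    for ri, run in enumerate(runs):
        for mz, rt, inten in run.features[["mz", "rt", "intensity"]].itertuples(
            index=False
        ):
            recs.append((float(mz), float(rt), float(inten), ri))
    # visit by descending intensity; deterministic tie-break on (mz, rt, run)
    recs.sort(key=lambda t: (-t[2], t[0], t[1], t[3]))

    seed_mz: list[float] = []  # kept sorted, parallel with seed_row
    seed_row: list[int] = []
    rows: list[dict] = []  # {"mz","rt","cells": {run_index: intensity}}

    for mz, rt, inten, ri in recs:
        tol = mz_tol(mz)
        lo = bisect.bisect_left(seed_mz, mz - tol)
        hi = bisect.bisect_right(seed_mz, mz + tol)
        best = None
        for k in range(lo, hi):
            row = rows[seed_row[k]]
            if ri in row["cells"]:
                continue
            if abs(row["rt"] - rt) > rt_tol:
                continue
            d = abs(seed_mz[k] - mz)
            if best is None or d < best[0]:
                best = (d, seed_row[k])
        if best is None:
            rows.append({"mz": mz, "rt": rt, "cells": {ri: inten}})
            j = bisect.bisect_left(seed_mz, mz)
            seed_mz.insert(j, mz)
            seed_row.insert(j, len(rows) - 1)
        else:
            rows[best[1]]["cells"][ri] = inten

    order = sorted(range(len(rows)), key=lambda i: (rows[i]["mz"], rows[i]["rt"]))
    feature_ids = [f"F{k + 1:05d}" for k in range(len(order))]
    feat = pd.DataFrame(
        {
            "mz": [rows[i]["mz"] for i in order],
            "rt": [rows[i]["rt"] for i in order],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    mat = np.zeros((len(order), len(runs)))
    for k, i in enumerate(order):
        for ri, inten in rows[i]["cells"].items():
            mat[k, ri] = inten
    matrix = pd.DataFrame(mat, index=feat.index, columns=ids)
    design = {r.run_id: r.condition for r in runs}
    return FeatureTable(feat, matrix, design)


def gap_fill_floor(table: FeatureTable, noise: float = 100.0) -> FeatureTable:
    """Floor every cell below ``noise`` counts to ``noise`` and flag it.

    Mirrors the pseudocount rule used before fold-change and t-test
    computation: gap-filled or sub-noise intensities are treated as the
    noise value. Idempotent.
    """
    if noise <= 0:
        raise ValueError("noise floor must be positive")
    flagged = table.matrix < noise
    matrix = table.matrix.mask(flagged, noise)
    prior = table.gap_filled if table.gap_filled is not None else False
    return FeatureTable(
        table.features.copy(),
        matrix,
        dict(table.design),
        gap_filled=flagged | prior,
        noise_floor=noise,
    )


def differential_stats(table: FeatureTable, welch: bool = False) -> pd.DataFrame:
    """Fold change and two-tailed Student's t-test per feature.

    Fold change is max(m_r/m_d, m_d/m_r) of the arithmetic condition means
    (magnitude >= 1; the direction column records which side is larger).
    The t statistic uses the classical pooled-variance two-sample test on
    raw intensities with df = n_r + n_d - 2 (``welch=True`` switches to
    unequal-variance). Features with zero variance in both groups are
    degenerate: t = 0, p = 1, direction ``unchanged``.
    """
    reps = table.condition_columns(REPLETE)
    deps = table.condition_columns(DEPLETED)
    if len(reps) < 2 or len(deps) < 2:
        raise ValueError("each condition needs >= 2 samples")
    a = table.matrix[reps].to_numpy(float)  # replete (with halide)
    b = table.matrix[deps].to_numpy(float)  # depleted (without halide)
    m_r = a.mean(axis=1)
    m_d = b.mean(axis=1)
    v_r = a.var(axis=1, ddof=1)
    v_d = b.var(axis=1, ddof=1)
    degenerate = (v_r == 0) & (v_d == 0)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # floored features are near-constant; degenerate rows are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    # zero-variance-one-group cells can yield nan from Welch; pooled handles
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(m_r >= m_d, m_r / np.maximum(m_d, 1e-300),
                        m_d / np.maximum(m_r, 1e-300))
    direction = np.where(
        degenerate | (m_r == m_d),
        "unchanged",
        np.where(m_r > m_d, "depleted_without_halide", "enriched_without_halide"),
    )
    fold = np.where(direction == "unchanged", np.where(m_r == m_d, 1.0, fold), fold)
    if welch:
        # Welch-Satterthwaite df, per feature
        n_r, n_d = a.shape[1], b.shape[1]
        num = (v_r / n_r + v_d / n_d) ** 2
        den = (v_r / n_r) ** 2 / (n_r - 1) + (v_d / n_d) ** 2 / (n_d - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dof = np.where(den > 0, num / den, float(n_r + n_d - 2))
    else:
        dof = np.full(len(m_r), float(len(reps) + len(deps) - 2))

    out = pd.DataFrame(
        {
            "mz": table.features["mz"],
            "rt": table.features["rt"],
            "mean_replete": m_r,
            "mean_depleted": m_d,
            "fold_change": fold,
            "direction": direction,
            "t_stat": t,
            "p_value": p,
            "df": dof,
            "degenerate": degenerate,
        },
        index=table.features.index,
    )
    return out


def signed_fold_change(diff: pd.DataFrame) -> pd.Series:
    """Supplement-style signed fold change: negative = depleted without halide."""
    sign = np.where(diff["direction"] == "depleted_without_halide", -1.0, 1.0)
    sign = np.where(diff["direction"] == "unchanged", 1.0, sign)
    return pd.Series(sign * diff["fold_change"], index=diff.index, name="signed_fold")


#: known co-elution mass shifts (Da): [M+H]+ <-> [M+NH4]+, [M+H]+ <-> [M+Na]+,
#: and in-source water loss
DEFAULT_DELTAS: dict[str, float] = {
    "NH4_vs_H": 17.0265491,
    "Na_vs_H": 21.9819425,
    "water_loss": 18.0105646,
}


def artifact_group(
    table: FeatureTable,
    rt_window: float = 0.1,
    deltas: Mapping[str, float] | None = None,
    mz_tol: "MzTolerance | float" = None,
) -> pd.DataFrame:
    """Group co-eluting features whose m/z differences match known shifts.

    Features within ``rt_window`` minutes of each other whose pairwise m/z
    difference matches an entry of ``deltas`` (within the MS1 tolerance)
    are placed in one group by transitive closure. Each group designates a
    parent: the member that best explains the others as its ammonium/sodium
    adducts or water-loss in-source fragments, ties broken by the highest
    total intensity. Returns a frame (feature_id-indexed) with ``group_id``
    and ``is_parent`` columns; singleton features form their own group.
    """
    deltas = dict(deltas if deltas is not None else DEFAULT_DELTAS)
    if mz_tol is None:
        mz_tol = MzTolerance()
    elif not callable(mz_tol):
        mz_tol = MzTolerance(abs_th=float(mz_tol), ppm=0.0)
    feats = table.features
    n = len(feats)
    if n == 0:
        return pd.DataFrame(columns=["group_id", "is_parent"])

    mz = feats["mz"].to_numpy()
    rt = feats["rt"].to_numpy()
    total = table.matrix.sum(axis=1).to_numpy()
    parent_idx = list(range(n))

    def find(i):
        while parent_idx[i] != i:
            parent_idx[i] = parent_idx[parent_idx[i]]
            i = parent_idx[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent_idx[rj] = ri

    order = np.argsort(mz)
    dvals = sorted(deltas.values())
    for ii in range(n):
        i = order[ii]
        for jj in range(ii + 1, n):
            j = order[jj]
            dm = mz[j] - mz[i]
            if dm > dvals[-1] + mz_tol(mz[j]):
                break
            if abs(rt[i] - rt[j]) > rt_window:
                continue
            tol = mz_tol(max(mz[i], mz[j]))
            if any(abs(dm - d) <= tol for d in dvals):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    group_id = np.empty(n, dtype=object)
    is_parent = np.zeros(n, dtype=bool)
    for gnum, root in enumerate(sorted(groups, key=lambda r: mz[r]), start=1):
        members = groups[root]
        gid = f"G{gnum:04d}"
        for i in members:
            group_id[i] = gid
        if len(members) == 1:
            is_parent[members[0]] = True
            continue
        # parent = member explaining most others as +NH4/+Na adduct or -H2O
        # in-source fragment relative to its own [M+H]+
        def explained(i: int) -> int:
            cnt = 0
            for j in members:
                if j == i:
                    continue
                dm = mz[j] - mz[i]
                tol = mz_tol(max(mz[i], mz[j]))
                if (
                    abs(dm - deltas.get("NH4_vs_H", np.inf)) <= tol
                    or abs(dm - deltas.get("Na_vs_H", np.inf)) <= tol
                    or abs(-dm - deltas.get("water_loss", np.inf)) <= tol
                ):
                    cnt += 1
            return cnt

        best = max(members, key=lambda i: (explained(i), total[i]))
        is_parent[best] = True

    return pd.DataFrame(
        {"group_id": group_id, "is_parent": is_parent}, index=feats.index
    )
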