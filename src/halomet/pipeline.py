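"""End-to-end discovery pipeline: join -> floor -> stats -> artifact
grouping -> chlorine scan -> formula assignment -> networking -> report.

The pipeline consumes the three text inputs of a comparative halide
experiment (per-run feature CSV, MS/MS MGF, MS1 envelope CSV), executes
every stage with the configured tolerances, and writes the discovery
outputs: the differential-feature table ("volcano twin"), the annotated
GraphML network, the per-component summary, and a ranked candidate list
ordered by depletion fold-change magnitude (ties by P value). Every
report embeds the full effective configuration and the isotope-constants
table version; re-running with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, diffmet, msnet

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the workflow's stated values."""

    features_csv: str = "features.csv"
    mgf: str | None = "spectra.mgf"
    envelopes_csv: str | None = "envelopes.csv"
    outdir: str = "results"
    # joining
    mz_tol_th: float = 0.01
    mz_tol_ppm: float = 20.0
    rt_tol: float = 0.2
    # statistics
    noise_floor: float = 100.0
    welch: bool = False
    # artifact grouping
    artifact_rt_window: float = 0.1
    # networking
    min_cosine: float = 0.60
    min_matched: int = 4
    frag_tol: float = 0.02
    # chlorine window
    cl_window_1: tuple = (0.20, 0.50)
    cl_window_2: tuple = (0.50, 0.85)
    cl_max_m1: float = 0.6
    # formula assignment
    formula_tol_ppm: float = 10.0
    n_formula_candidates: int = 50
    max_formulas_per_feature: int = 3

    def provenance(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        out["constants_table"] = chem.TABLE_VERSION
        return out


@dataclass
class PipelineResult:
    config: PipelineConfig
    table: diffmet.FeatureTable
    diff: pd.DataFrame
    groups: pd.DataFrame
    network: "object"
    components: pd.DataFrame
    candidates: pd.DataFrame
    stage_log: list
    outputs: dict


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _match_feature(
    feats: pd.DataFrame, mz: float, rt: float, mz_tol, rt_tol: float
) -> str | None:
    tol = mz_tol(mz)
    cand = feats[
        (feats["mz"].sub(mz).abs() <= tol) & (feats["rt"].sub(rt).abs() <= rt_tol)
    ]
    if cand.empty:
        return None
    return (cand["mz"].sub(mz).abs()).idxmin()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full discovery workflow and write all outputs.

    Raises :class:`PipelineError` naming the failing stage on missing or
    unparsable inputs.
    """
    log: list[tuple[str, str]] = []
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mz_tol = diffmet.MzTolerance(config.mz_tol_th, config.mz_tol_ppm)

    # --- join --------------------------------------------------------------
    try:
        runs = diffmet.read_runs_csv(config.features_csv)
    except FileNotFoundError as e:
        raise PipelineError("join", f"feature CSV not found: {e.filename}") from e
    n_in = sum(len(r.features) for r in runs)
    table = diffmet.join_features(runs, mz_tol=mz_tol, rt_tol=config.rt_tol)
    log.append(("join", f"{n_in} run features -> {len(table.features)} rows"))

    # --- gap fill + stats ---------------------------------------------------
    table = diffmet.gap_fill_floor(table, noise=config.noise_floor)
    n_filled = int(table.gap_filled.to_numpy().sum())
    log.append(("gap_fill", f"{n_filled} cells floored to {config.noise_floor:g}"))
    diff = diffmet.differential_stats(table, welch=config.welch)
    n_sig = int((diff["p_value"] < 0.05).sum())
    log.append(("stats", f"{len(diff)} features tested, {n_sig} with p < 0.05"))

    # --- artifact grouping --------------------------------------------------
    groups = diffmet.artifact_group(
        table, rt_window=config.artifact_rt_window, mz_tol=mz_tol
    )
    n_grouped = int((groups.groupby("group_id").size() > 1).sum())
    log.append(("artifact_group", f"{n_grouped} multi-member co-elution groups"))
    diff = diff.join(groups)

    # --- chlorine scan ------------------------------------------------------
    diff["chlorinated"] = False
    diff["m2_ratio"] = np.nan
    diff["n_cl"] = 0
    if config.envelopes_csv:
        try:
            env = pd.read_csv(config.envelopes_csv)
        except FileNotFoundError as e:
            raise PipelineError(
                "clscan", f"envelope CSV not found: {e.filename}"
            ) from e
        n_flag = 0
        for sig_id, grp in env.groupby("signal_id", sort=True):
            pattern = chem.IsotopePattern(
                tuple(int(o) for o in grp["offset"]),
                tuple(zip(grp["mz"], grp["abundance"])),
            )
            try:
                call = chem.chlorine_score(
                    pattern,
                    window_1cl=tuple(config.cl_window_1),
                    window_2cl=tuple(config.cl_window_2),
                    max_m1_ratio=config.cl_max_m1,
                )
            except ValueError:
                continue
            # envelopes carry no rt; match on m/z of the monoisotopic peak
            cand = table.features[
                table.features["mz"].sub(float(grp["mz"].iloc[0])).abs()
                <= mz_tol(float(grp["mz"].iloc[0]))
            ]
            if cand.empty:
                continue
            fid = cand["mz"].sub(float(grp["mz"].iloc[0])).abs().idxmin()
            diff.loc[fid, "chlorinated"] = call.is_chlorinated
            diff.loc[fid, "m2_ratio"] = call.ratio
            diff.loc[fid, "n_cl"] = call.n_cl
            n_flag += int(call.is_chlorinated)
        log.append(("clscan", f"{len(env.groupby('signal_id'))} envelopes, "
                              f"{n_flag} chlorine-flagged features"))

    # --- candidate ranking --------------------------------------------------
    depleted = diff[diff["direction"] == "depleted_without_halide"].copy()
    depleted = depleted.sort_values(
        ["fold_change", "p_value"], ascending=[False, True], kind="mergesort"
    )
    candidates = depleted.head(max(config.n_formula_candidates, 0)).copy()

    # --- formula assignment -------------------------------------------------
    diff["formula"] = ""
    for fid, row in candidates.iterrows():
        require = {"Cl": 1} if bool(diff.loc[fid, "chlorinated"]) else None
        found = chem.decompose_mass(
            float(row["mz"]),
            adducts=("[M+H]+", "[M+NH4]+", "[M+Na]+"),
            tol_ppm=config.formula_tol_ppm,
            require=require,
        )
        best = found[: config.max_formulas_per_feature]
        diff.loc[fid, "formula"] = ";".join(
            f"{c.formula.hill()}{c.adduct.name}({c.ppm_error:+.1f}ppm)"
            for c in best
        )
    log.append(("formulas", f"{len(candidates)} candidate features assigned"))

    # --- networking ---------------------------------------------------------
    network = None
    components = pd.DataFrame()
    if config.mgf:
        if not Path(config.mgf).exists():
            raise PipelineError(
                "network",
                f"MGF not found: {config.mgf}; run the acquisition export or "
                "pass mgf=None to skip networking",
            )
        spectra = msnet.read_mgf(config.mgf)
        # one representative spectrum per joined feature: precursor closest
        # in m/z (tie: highest total ion intensity)
        chosen: dict[str, msnet.MsmsSpectrum] = {}
        chosen_key: dict[str, tuple] = {}
        for s in spectra:
            fid = _match_feature(
                table.features, s.precursor_mz, s.rt, mz_tol, config.rt_tol
            )
            if fid is None:
                continue
            dmz = abs(table.features.loc[fid, "mz"] - s.precursor_mz)
            key = (dmz, -sum(s.intensities))
            if fid not in chosen or key < chosen_key[fid]:
                chosen[fid] = dataclasses.replace(s, spectrum_id=str(fid))
                chosen_key[fid] = key
        ann = diff[
            ["mz", "rt", "fold_change", "direction", "p_value", "chlorinated",
             "formula", "group_id"]
        ]
        network = msnet.build_network(
            list(chosen.values()),
            min_cosine=config.min_cosine,
            min_matched=config.min_matched,
            frag_tol=config.frag_tol,
            annotations=ann,
        )
        components = msnet.component_report(network)
        log.append(
            (
                "network",
                f"{len(spectra)} spectra -> {network.number_of_nodes()} nodes, "
                f"{network.number_of_edges()} edges, "
                f"{len(components)} components",
            )
        )

    # --- outputs ------------------------------------------------------------
    diff_out = diff.copy()
    diff_out["signed_fold"] = diffmet.signed_fold_change(diff)
    outputs = {}
    diff_path = outdir / "diff_stats.csv"
    diff_out.to_csv(diff_path, float_format="%.6g")
    outputs["diff_stats"] = diff_path
    cand_path = outdir / "candidates.csv"
    diff_out.loc[candidates.index].to_csv(cand_path, float_format="%.6g")
    outputs["candidates"] = cand_path
    if network is not None:
        gml = outdir / "network.graphml"
        msnet.write_graphml(network, gml)
        outputs["network"] = gml
        comp_path = outdir / "components.csv"
        components.to_csv(comp_path, float_format="%.6g")
        outputs["components"] = comp_path
    report_path = outdir / "report.txt"
    with open(report_path, "w") as fh:
        fh.write("halomet discovery report\n")
        fh.write("# effective configuration\n")
        for k, v in sorted(config.provenance().items()):
            fh.write(f"{k}\t{v}\n")
        fh.write("# note: t-tests computed on raw (untransformed) intensities\n")
        fh.write("# stage log\n")
        for stage, msg in log:
            fh.write(f"{stage}\t{msg}\n")
        fh.write("# top candidates (fold-change ranked, depleted without halide)\n")
        for fid, row in candidates.head(10).iterrows():
            fh.write(
                f"{fid}\tmz={row['mz']:.4f}\trt={row['rt']:.2f}\t"
                f"fold={row['fold_change']:.1f}\tp={row['p_value']:.3g}\t"
                f"Cl={bool(diff.loc[fid, 'chlorinated'])}\t"
                f"formula={diff.loc[fid, 'formula']}\n"
            )
        if len(components):
            fh.write("# top components\n")
            fh.write(components.head(5).to_csv(sep="\t", float_format="%.4g"))
    outputs["report"] = report_path

    return PipelineResult(
        config=config,
        table=table,
        diff=diff_out,
        groups=groups,
        network=network,
        components=components,
        candidates=diff_out.loc[candidates.index],
        stage_log=log,
        outputs=outputs,
    )
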