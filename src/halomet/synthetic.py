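"""Seeded generator of ground-truth two-condition metabolomics experiments.

Because the workflow is validated against planted ground truth rather
than public raw data, this module simulates the full data structure the
pipeline consumes: per-run feature lists for a replete (with halide) vs
depleted (without halide) design with three biological replicates each,
MS/MS peak lists realised from per-compound fragment templates, MS1
isotope envelopes for chlorine screening, and a plain-text truth manifest
recording every planted parameter.

The default demo experiment mirrors the study structure: one eight-member
chlorinated glycolipid-like family with large planted halide-dependent
fold changes (87.5, 421.1, 607.0, ...), one halide-independent family,
and 200 background features. Replicate intensities are log-normal with CV
0.2 around the condition mean; values below the detection limit are
censored so downstream pseudocount flooring is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from . import chem, labelfit, msnet
from .chem import ElementCount, IsotopePattern

__all__ = [
    "Fragment",
    "TruthCompound",
    "ExperimentManifest",
    "SimulatedExperiment",
    "default_manifest",
    "null_manifest",
    "simulate_experiment",
    "simulate_feeding",
]


@dataclass(frozen=True)
class Fragment:
    """One MS/MS template entry: an absolute fragment m/z or a neutral loss."""

    kind: str  # "mz" (absolute fragment) or "loss" (precursor - value)
    value: float
    intensity: float  # relative, (0, 1]

    def __post_init__(self) -> None:
        if self.kind not in ("mz", "loss"):
            raise ValueError("fragment kind must be 'mz' or 'loss'")
        if self.value <= 0 or self.intensity <= 0:
            raise ValueError("fragment value and intensity must be positive")


@dataclass(frozen=True)
class TruthCompound:
    """A planted compound with known abundance behaviour and fragmentation."""

    compound_id: str
    formula: ElementCount
    rt: float
    base_abundance: float
    halide_fold: float = 1.0  # >= 1; 1 = halide-independent
    family_id: str | None = None
    adducts: tuple[str, ...] = ("[M+H]+",)
    fragments: tuple[Fragment, ...] = ()

    def __post_init__(self) -> None:
        if self.halide_fold < 1:
            raise ValueError("halide_fold must be >= 1")
        if self.base_abundance <= 0 or self.rt < 0:
            raise ValueError("invalid abundance or rt")


@dataclass(frozen=True)
class ExperimentManifest:
    """Complete, seedable description of a simulated experiment."""

    seed: int
    compounds: tuple[TruthCompound, ...]
    n_replicates: int = 3
    replicate_cv: float = 0.2
    noise_floor: float = 100.0
    detection_limit: float = 500.0
    mz_ppm_error: float = 3.0
    rt_jitter: float = 0.02  # per-run sd, minutes
    ms1_noise: float = 0.02  # multiplicative envelope noise
    ms2_mz_jitter: float = 0.005  # Th
    ms2_intensity_jitter: float = 0.10
    emit_artifacts: bool = True
    artifact_rel_abundance: dict = field(
        default_factory=lambda: {"[M+NH4]+": 0.3, "[M+Na]+": 0.15, "-H2O": 0.2}
    )

    def validate(self) -> None:
        errors = []
        if self.n_replicates < 2:
            errors.append("n_replicates must be >= 2")
        if not self.compounds:
            errors.append("no compounds planted")
        ids = [c.compound_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            errors.append("duplicate compound_id")
        families: dict[str, list[TruthCompound]] = {}
        for c in self.compounds:
            if c.family_id:
                families.setdefault(c.family_id, []).append(c)
        for fam, members in families.items():
            if len(members) < 2:
                continue
            shared = None
            for c in members:
                keys = {(f.kind, round(f.value, 4)) for f in c.fragments}
                shared = keys if shared is None else shared & keys
            if shared is not None and len(shared) < 5:
                errors.append(
                    f"family {fam!r} shares only {len(shared)} template "
                    "fragments/losses; >= 5 required for networkability"
                )
        if errors:
            raise ValueError("invalid manifest: " + "; ".join(errors))


@dataclass
class SimulatedExperiment:
    """In-memory result of a simulation plus the files it was written to."""

    manifest: ExperimentManifest
    runs_csv: Path
    mgf: Path
    envelopes_csv: Path
    truth: Path
    signals: pd.DataFrame  # planted signal table (ground truth)


# ---------------------------------------------------------------------------
# default study-like manifests

#: shared MS/MS template of the chlorinated family: sugar-like oxocarbenium
#: fragments plus hexose-like neutral losses, mimicking glycolipid spectra
_FAMILY_SHARED = (
    Fragment("mz", 127.0390, 1.0),
    Fragment("mz", 145.0495, 0.9),
    Fragment("mz", 159.0652, 0.8),
    Fragment("mz", 177.0757, 0.7),
    Fragment("loss", 162.0528, 0.85),
    Fragment("loss", 180.0634, 0.75),
    Fragment("loss", 242.0787, 0.6),
)

_INDEP_SHARED = (
    Fragment("mz", 184.0733, 1.0),
    Fragment("mz", 104.1070, 0.9),
    Fragment("mz", 86.0964, 0.8),
    Fragment("loss", 183.0660, 0.7),
    Fragment("loss", 59.0735, 0.6),
)

#: chlorinated family: the lead glycolipid, a desaturated analogue, and
#: fatty-acid ester homologues, with planted halide-dependent fold changes
_FAMILY_SPECS = [
    ("glc01", "C28H55O8Cl", 9.8, 1.8e6, 87.5, ("[M+H]+",)),
    ("glc02", "C28H53O8Cl", 9.5, 1.2e6, 421.1, ("[M+H]+",)),
    ("glc03", "C46H89O9Cl", 16.4, 9.0e5, 607.0, ("[M+NH4]+",)),
    ("glc04", "C44H85O9Cl", 15.8, 7.0e5, 350.0, ("[M+NH4]+",)),
    ("glc05", "C44H83O9Cl", 15.5, 6.0e5, 240.0, ("[M+NH4]+",)),
    ("glc06", "C46H87O9Cl", 16.1, 5.5e5, 180.0, ("[M+NH4]+",)),
    ("glc07", "C48H93O9Cl", 17.0, 5.0e5, 120.0, ("[M+NH4]+",)),
    ("glc08", "C42H81O9Cl", 15.2, 4.5e5, 95.0, ("[M+NH4]+",)),
]

_INDEP_SPECS = [
    ("bkf01", "C42H83NO8", 14.1, 1.5e6),
    ("bkf02", "C44H87NO8", 14.8, 1.1e6),
    ("bkf03", "C40H79NO8", 13.6, 8.0e5),
    ("bkf04", "C42H81NO8", 13.9, 6.0e5),
]


def _unique_fragments(rng: np.random.Generator, n: int) -> tuple[Fragment, ...]:
    mzs = rng.uniform(250.0, 420.0, size=n)
    ints = rng.uniform(0.15, 0.35, size=n)
    return tuple(Fragment("mz", float(m), float(i)) for m, i in zip(mzs, ints))


def _background_formula(rng: np.random.Generator) -> ElementCount:
    """A plausible CHO(N) metabolite formula with integer RDBE."""
    while True:
        c = int(rng.integers(10, 46))
        o = int(rng.integers(0, 11))
        n = int(rng.integers(0, 3))
        h_max = 2 * c + 2 + n
        h = int(rng.integers(max(c // 2, 4), h_max + 1))
        # hydrogen parity must make RDBE integral
        if (h + n) % 2 != 0:
            h += 1
        if h > h_max or h < 1:
            continue
        f = ElementCount({"C": c, "H": h, "O": o, "N": n})
        m = chem.monoisotopic_mass(f)
        if 150.0 <= m <= 900.0 and 0 <= chem.rdbe(f) <= 25:
            return f


def default_manifest(seed: int = 0, n_background: int = 200) -> ExperimentManifest:
    """The demo experiment: planted chlorinated family + independent family +
    background features with no condition effect."""
    rng = np.random.default_rng(seed)
    compounds: list[TruthCompound] = []
    for cid, formula, rt, base, fold, adducts in _FAMILY_SPECS:
        compounds.append(
            TruthCompound(
                cid,
                chem.parse_formula(formula),
                rt,
                base,
                halide_fold=fold,
                family_id="glc",
                adducts=adducts,
                fragments=_FAMILY_SHARED + _unique_fragments(rng, 3),
            )
        )
    for cid, formula, rt, base in _INDEP_SPECS:
        compounds.append(
            TruthCompound(
                cid,
                chem.parse_formula(formula),
                rt,
                base,
                halide_fold=1.0,
                family_id="indep",
                adducts=("[M+H]+",),
                fragments=_INDEP_SHARED + _unique_fragments(rng, 3),
            )
        )
    for k in range(n_background):
        f = _background_formula(rng)
        compounds.append(
            TruthCompound(
                f"bg{k + 1:03d}",
                f,
                float(rng.uniform(1.0, 22.0)),
                float(rng.uniform(2e3, 5e5)),
                halide_fold=1.0,
                adducts=("[M+H]+",),
            )
        )
    return ExperimentManifest(seed=seed, compounds=tuple(compounds))


def null_manifest(seed: int = 0, n_features: int = 2000) -> ExperimentManifest:
    """A planted-null experiment: every compound halide-independent."""
    rng = np.random.default_rng(seed)
    compounds = [
        TruthCompound(
            f"null{k + 1:04d}",
            _background_formula(rng),
            float(rng.uniform(1.0, 22.0)),
            float(rng.uniform(5e3, 5e5)),
            halide_fold=1.0,
        )
        for k in range(n_features)
    ]
    return ExperimentManifest(seed=seed, compounds=tuple(compounds))


# ---------------------------------------------------------------------------
# simulation


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given CV."""
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_experiment(
    manifest: ExperimentManifest, outdir: "str | Path"
) -> SimulatedExperiment:
    """Realise one experiment: run CSVs, MGF, MS1 envelope CSV, truth file.

    Regenerating with the same manifest is byte-identical. Every planted
    signal (parent ion, co-eluting adduct, in-source fragment) is recorded
    in the returned signal table and the truth file.
    """
    manifest.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(manifest.seed)

    # --- planted ion signals (one per compound x adduct/artifact) ---------
    signal_rows = []
    for comp in manifest.compounds:
        ion_formulas = []
        primary = comp.adducts[0]
        mz0 = chem.adduct_mz(comp.formula, primary)
        ion_formulas.append((f"{comp.compound_id}@{primary}", primary, mz0, 1.0,
                             "parent"))
        if manifest.emit_artifacts and comp.family_id is not None:
            for art, rel in manifest.artifact_rel_abundance.items():
                if art == "-H2O":
                    amz = mz0 - 18.0105646
                    kind = "insource_fragment"
                    name = f"{comp.compound_id}@-H2O"
                elif art == primary:
                    continue
                else:
                    amz = chem.adduct_mz(comp.formula, art)
                    kind = "adduct"
                    name = f"{comp.compound_id}@{art}"
                ion_formulas.append((name, art, amz, rel, kind))
        for name, adduct, mz, rel, kind in ion_formulas:
            ppm = rng.uniform(-manifest.mz_ppm_error, manifest.mz_ppm_error)
            signal_rows.append(
                {
                    "signal_id": name,
                    "compound_id": comp.compound_id,
                    "family_id": comp.family_id or "",
                    "kind": kind,
                    "adduct": adduct,
                    "mz": mz * (1 + ppm * 1e-6),
                    "rt": comp.rt,
                    "rel_abundance": rel,
                    "base_abundance": comp.base_abundance * rel,
                    "halide_fold": comp.halide_fold,
                    "chlorinated": comp.formula["Cl"] > 0,
                    "formula": comp.formula.hill(),
                }
            )
    signals = pd.DataFrame(signal_rows)

    # --- per-run feature lists --------------------------------------------
    run_frames = []
    for condition in ("replete", "depleted"):
        for rep in range(1, manifest.n_replicates + 1):
            run_id = f"{condition}_{rep}"
            factors = _lognormal_factor(
                rng, manifest.replicate_cv, size=len(signals)
            )
            mean = signals["base_abundance"].to_numpy().copy()
            if condition == "depleted":
                mean = mean / signals["halide_fold"].to_numpy()
            intensity = mean * factors
            rt = signals["rt"].to_numpy() + rng.normal(
                0.0, manifest.rt_jitter, size=len(signals)
            )
            keep = intensity >= manifest.detection_limit
            df = pd.DataFrame(
                {
                    "run_id": run_id,
                    "condition": condition,
                    "mz": signals["mz"].to_numpy()[keep],
                    "rt": np.clip(rt[keep], 0.0, None),
                    "intensity": intensity[keep],
                }
            )
            run_frames.append(df)
    runs = pd.concat(run_frames, ignore_index=True)
    runs_csv = outdir / "features.csv"
    runs = runs.round({"mz": 6, "rt": 4, "intensity": 2})
    runs.to_csv(runs_csv, index=False)

    # --- MS/MS spectra for compounds with fragment templates --------------
    spectra = []
    for comp in manifest.compounds:
        if not comp.fragments:
            continue
        primary = comp.adducts[0]
        sig = signals.loc[
            signals["signal_id"] == f"{comp.compound_id}@{primary}"
        ].iloc[0]
        prec = float(sig["mz"])
        peaks = []
        for frag in comp.fragments:
            mz = frag.value if frag.kind == "mz" else prec - frag.value
            mz += rng.normal(0.0, manifest.ms2_mz_jitter)
            inten = comp.base_abundance * frag.intensity * max(
                1.0 + rng.normal(0.0, manifest.ms2_intensity_jitter), 0.05
            )
            if mz > 0:
                peaks.append((mz, inten))
        spectra.append(
            msnet.MsmsSpectrum(
                spectrum_id=sig["signal_id"],
                precursor_mz=prec,
                peaks=tuple(peaks),
                charge=1,
                rt=float(sig["rt"]),
                collision_energy=msnet.collision_energy(prec),
            )
        )
    mgf_path = outdir / "spectra.mgf"
    msnet.write_mgf(spectra, mgf_path)

    # --- MS1 isotope envelopes (for parent signals) ------------------------
    env_rows = []
    for comp in manifest.compounds:
        primary = comp.adducts[0]
        sig_id = f"{comp.compound_id}@{primary}"
        ion = comp.formula + ElementCount(
            {s: n for s, n in chem.get_adduct(primary).delta.items() if n > 0}
        )
        pattern = chem.isotope_pattern(ion, max_offsets=6)
        for off, (mz, ab) in zip(pattern.offsets, pattern.peaks):
            noisy = ab * max(1.0 + rng.normal(0.0, manifest.ms1_noise), 0.0)
            env_rows.append(
                {
                    "signal_id": sig_id,
                    "offset": off,
                    "mz": mz,
                    "abundance": noisy,
                }
            )
    env = pd.DataFrame(env_rows).round({"mz": 6, "abundance": 6})
    env_csv = outdir / "envelopes.csv"
    env.to_csv(env_csv, index=False)

    # --- truth file --------------------------------------------------------
    truth_path = outdir / "truth.txt"
    with open(truth_path, "w") as fh:
        fh.write("# halomet synthetic experiment ground truth\n")
        fh.write(f"seed\t{manifest.seed}\n")
        fh.write(f"n_replicates\t{manifest.n_replicates}\n")
        fh.write(f"replicate_cv\t{manifest.replicate_cv}\n")
        fh.write(f"noise_floor\t{manifest.noise_floor}\n")
        fh.write(f"detection_limit\t{manifest.detection_limit}\n")
        fh.write(f"constants_table\t{chem.TABLE_VERSION}\n")
        fh.write("# signals\n")
        cols = list(signals.columns)
        fh.write("\t".join(cols) + "\n")
        for _, row in signals.iterrows():
            fh.write(
                "\t".join(
                    f"{row[c]:.6f}" if isinstance(row[c], float) else str(row[c])
                    for c in cols
                )
                + "\n"
            )

    return SimulatedExperiment(
        manifest=manifest,
        runs_csv=runs_csv,
        mgf=mgf_path,
        envelopes_csv=env_csv,
        truth=truth_path,
        signals=signals,
    )


def simulate_feeding(
    parent: "ElementCount | str",
    n_label: int,
    n_lost: int,
    incorporation: float,
    seed: int = 0,
    noise: float = 0.02,
    purity: float = 1.0,
    max_offsets: int = 6,
) -> tuple[IsotopePattern, dict]:
    """Simulate a label-feeding MS1 envelope and its ground truth.

    The observed envelope is (1 - incorporation) x unlabelled +
    incorporation x labelled theoretical envelopes, aligned on the nominal
    offset axis of the unlabelled parent, with multiplicative abundance
    noise. Returns the pattern plus a truth dict of all parameters.
    """
    if not 0.0 <= incorporation <= 1.0:
        raise ValueError("incorporation must be in [0, 1]")
    parent = chem._as_formula(parent)
    rng = np.random.default_rng(seed)
    unlabeled = labelfit.labeled_species(parent, 0, 0, name="unlabeled",
                                         max_offsets=max_offsets)
    labeled = labelfit.labeled_species(parent, n_label, n_lost, purity=purity,
                                       max_offsets=max_offsets)
    acc: dict[int, float] = {}
    for sp, frac in ((unlabeled, 1.0 - incorporation), (labeled, incorporation)):
        if frac <= 0:
            continue
        for off, (_, ab) in zip(sp.absolute_offsets(), sp.pattern.peaks):
            acc[off] = acc.get(off, 0.0) + frac * ab
    ref = chem.monoisotopic_mass(parent)
    offsets = sorted(acc)
    peaks = []
    for off in offsets:
        ab = acc[off] * max(1.0 + rng.normal(0.0, noise), 0.0) if noise > 0 else acc[off]
        peaks.append((ref + off * chem.NEUTRON_SPACING, ab))
    pattern = IsotopePattern(tuple(offsets), tuple(peaks))
    truth = {
        "parent": parent.hill(),
        "n_label": n_label,
        "n_lost": n_lost,
        "incorporation": incorporation,
        "seed": seed,
        "noise": noise,
        "purity": purity,
    }
    return pattern, truth
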