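"""Peak filtering, modified cosine, network construction and reporting."""

import numpy as np
import pytest

from halomet import msnet
from halomet.msnet import (
    MsmsSpectrum,
    build_network,
    collision_energy,
    component_report,
    filter_peaks,
    modified_cosine,
    read_mgf,
    write_mgf,
)

from conftest import brute_force_modified_cosine, random_spectrum


def spec(sid, prec, peaks, rt=0.0):
    return MsmsSpectrum(sid, prec, tuple(peaks), rt=rt)


class TestFilterPeaks:
    def test_precursor_exclusion_window(self):
        s = spec("a", 500.0, [(480.0, 10.0), (490.0, 20.0), (300.0, 5.0)])
        out = filter_peaks(s)
        mzs = out.mzs.tolist()
        assert 490.0 not in mzs  # within +/-17 Th of precursor
        assert 480.0 in mzs
        assert 300.0 in mzs

    def test_top6_in_local_window(self):
        # 8 peaks within one 100-Th span, distinct intensities: exactly the
        # 6 most intense survive (brute-force check per peak)
        peaks = [(200.0 + 10 * k, 100.0 + k) for k in range(8)]
        s = spec("a", 800.0, peaks)
        out = filter_peaks(s)
        survivors = {round(m, 1) for m in out.mzs}
        for mz, inten in peaks:
            window = [i for m, i in peaks if abs(m - mz) <= 50.0]
            expected = sum(1 for i in window if i > inten) < 6
            assert (round(mz, 1) in survivors) == expected

    def test_empty_spectrum(self):
        s = spec("a", 500.0, [])
        assert filter_peaks(s).peaks == ()

    def test_idempotent(self, rng):
        s = random_spectrum(rng, 30)
        once = filter_peaks(s)
        assert filter_peaks(once).peaks == once.peaks


class TestModifiedCosine:
    def test_self_similarity_is_one(self, rng):
        s = filter_peaks(random_spectrum(rng, 8))
        score, n = modified_cosine(s, s)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert n == len(s.peaks)

    def test_disjoint_spectra_zero(self):
        a = spec("a", 500.0, [(100.0, 10.0), (200.0, 10.0)])
        b = spec("b", 700.0, [(150.0, 10.0), (250.0, 10.0)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_neutral_loss_match(self):
        # no direct fragment agreement, but identical neutral losses
        a = spec("a", 500.0, [(400.0, 100.0)])
        b = spec("b", 520.0, [(420.0, 100.0)])
        score, n = modified_cosine(a, b)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert n == 1

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            a = random_spectrum(rng, int(rng.integers(2, 9)))
            b = random_spectrum(rng, int(rng.integers(2, 9)))
            score, _ = modified_cosine(a, b)
            assert score == pytest.approx(
                brute_force_modified_cosine(a, b), abs=1e-9
            )

    def test_symmetry_and_intensity_scale_invariance(self, rng):
        a = random_spectrum(rng, 6)
        b = random_spectrum(rng, 6)
        s_ab, n_ab = modified_cosine(a, b)
        s_ba, n_ba = modified_cosine(b, a)
        assert s_ab == pytest.approx(s_ba, abs=1e-12)
        assert n_ab == n_ba
        scaled = a.with_peaks([(m, i * 37.5) for m, i in a.peaks])
        s_scaled, _ = modified_cosine(scaled, b)
        assert s_scaled == pytest.approx(s_ab, abs=1e-12)
        assert 0.0 <= s_ab <= 1.0

    def test_agrees_with_matchms_on_unambiguous_spectra(self, rng):
        # independent cross-check: matchms' modified cosine on spectra whose
        # peak matches are unambiguous (well-separated m/z values)
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        sim = ModifiedCosine(tolerance=0.02)
        for k in range(10):
            base = 100.0 + 97.0 * np.arange(5) + rng.uniform(0, 5, 5)
            ia = rng.uniform(10, 1000, 5)
            ib = rng.uniform(10, 1000, 5)
            a = spec("a", 600.0, list(zip(base.tolist(), ia.tolist())))
            b = spec("b", 600.0, list(zip(base.tolist(), ib.tolist())))
            # matchms scores raw intensity products; our weighting is
            # sqrt(intensity), so hand matchms the square-rooted spectra
            ma = matchms.Spectrum(
                mz=a.mzs, intensities=np.sqrt(a.intensities),
                metadata={"precursor_mz": a.precursor_mz},
            )
            mb = matchms.Spectrum(
                mz=b.mzs, intensities=np.sqrt(b.intensities),
                metadata={"precursor_mz": b.precursor_mz},
            )
            expected = sim.pair(ma, mb)
            score, n = modified_cosine(a, b)
            assert score == pytest.approx(float(expected["score"]), abs=1e-6)
            assert n == int(expected["matches"])


class TestNetwork:
    def _family(self, n=4, shared=5, rng=None):
        rng = rng or np.random.default_rng(0)
        shared_mz = 100.0 + 40.0 * np.arange(shared)
        out = []
        for k in range(n):
            peaks = [(m, 500.0 + 10 * k) for m in shared_mz]
            peaks.append((320.0 + 7 * k, 50.0))
            out.append(spec(f"s{k}", 600.0 + 30 * k, peaks))
        return out

    def test_edge_requires_both_thresholds(self):
        a = spec("a", 500.0, [(100.0, 100.0), (140.0, 90.0), (180.0, 80.0)])
        b = spec("b", 520.0, [(100.0, 100.0), (140.0, 90.0), (180.0, 80.0)])
        net = build_network([a, b], min_cosine=0.60, min_matched=4,
                            prefilter=False)
        assert net.number_of_edges() == 0  # only 3 matched pairs
        net2 = build_network([a, b], min_cosine=0.60, min_matched=3,
                             prefilter=False)
        assert net2.number_of_edges() == 1

    def test_high_cosine_low_matches_no_edge(self):
        a = spec("a", 500.0, [(100.0, 1000.0)])
        b = spec("b", 500.0, [(100.0, 1000.0)])
        net = build_network([a, b], prefilter=False)
        assert net.number_of_edges() == 0  # cosine 1.0 but 1 matched pair

    def test_cosine_just_below_threshold_no_edge(self):
        a = spec("a", 500.0, [(100.0, 100.0), (140.0, 100.0), (180.0, 100.0),
                              (220.0, 100.0), (260.0, 400.0)])
        b = spec("b", 500.0, [(100.0, 100.0), (140.0, 100.0), (180.0, 100.0),
                              (220.0, 100.0), (300.0, 400.0)])
        score, n = modified_cosine(a, b)
        assert n >= 4
        net = build_network([a, b], min_cosine=score + 1e-6, prefilter=False)
        assert net.number_of_edges() == 0

    def test_family_forms_single_component(self):
        members = self._family(n=6, shared=5)
        net = build_network(members, prefilter=False)
        import networkx as nx
        comps = list(nx.connected_components(net))
        assert len(comps) == 1
        assert len(comps[0]) == 6

    def test_duplicate_ids_rejected(self):
        a = spec("x", 500.0, [(100.0, 1.0)])
        with pytest.raises(ValueError, match="duplicate"):
            build_network([a, a])

    def test_irrelevant_spectrum_leaves_edges_unchanged(self):
        members = self._family(n=3, shared=6)
        net1 = build_network(members, prefilter=False)
        loner = spec("loner", 900.0, [(777.0, 10.0)])
        net2 = build_network(members + [loner], prefilter=False)
        for u, v, d in net1.edges(data=True):
            assert net2[u][v]["cosine"] == d["cosine"]


class TestReportAndIO:
    def test_component_report_counts(self):
        import pandas as pd
        members = TestNetwork()._family(n=3, shared=6)
        ann = pd.DataFrame(
            {
                "fold_change": [87.5, 421.1, 1.2],
                "direction": ["depleted_without_halide"] * 2 + ["unchanged"],
                "chlorinated": [True, True, False],
            },
            index=["s0", "s1", "s2"],
        )
        net = build_network(members, annotations=ann, prefilter=False)
        rep = component_report(net)
        assert len(rep) == 1
        row = rep.iloc[0]
        assert row["n_members"] == 3
        assert row["n_depleted_without_halide"] == 2
        assert row["n_chlorinated"] == 2
        assert row["max_depletion_fold"] == pytest.approx(421.1)

    def test_singleton_and_empty_reports(self):
        lone = spec("x", 500.0, [(100.0, 1.0)])
        rep = component_report(build_network([lone]))
        assert len(rep) == 1 and rep.iloc[0]["n_members"] == 1
        assert component_report(build_network([])).empty

    def test_mgf_roundtrip(self, tmp_path, rng):
        spectra = [random_spectrum(rng, 5) for _ in range(3)]
        spectra = [
            MsmsSpectrum(f"feat{k}", s.precursor_mz, s.peaks, rt=1.5 * k,
                         collision_energy=collision_energy(s.precursor_mz))
            for k, s in enumerate(spectra)
        ]
        path = tmp_path / "test.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert [s.spectrum_id for s in back] == ["feat0", "feat1", "feat2"]
        for orig, rb in zip(spectra, back):
            assert rb.precursor_mz == pytest.approx(orig.precursor_mz,
                                                    abs=1e-5)
            assert rb.rt == pytest.approx(orig.rt, abs=1e-4)
            assert len(rb.peaks) == len(orig.peaks)

    def test_collision_energy_formula(self):
        assert collision_energy(555.3658) == pytest.approx(21.107, abs=1e-3)

    def test_graphml_written(self, tmp_path):
        members = TestNetwork()._family(n=3, shared=6)
        net = build_network(members, prefilter=False)
        out = tmp_path / "net.graphml"
        msnet.write_graphml(net, out)
        import networkx as nx
        loaded = nx.read_graphml(out)
        assert loaded.number_of_nodes() == 3
        assert loaded.number_of_edges() == net.number_of_edges()
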