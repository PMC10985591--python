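"""Feature detection: EIC building, peak resolving, de-isotoping,
alignment (with a brute-force oracle) and gap filling."""

import numpy as np
import pytest

from diaflav import featdet
from diaflav.dbio import MSRun, Spectrum
from diaflav.featdet import AlignedRow, AlignedTable, DetectionConfig, Feature

from conftest import make_run

CFG = DetectionConfig()


def feature(sample, mz, rt, height, level=1, sigma=0.02, n=9):
    """Synthetic Feature with a Gaussian trace for alignment/link tests."""
    grid = rt + np.linspace(-2 * sigma, 2 * sigma, n)
    vals = height * np.exp(-0.5 * ((grid - rt) / sigma) ** 2)
    return Feature(sample, level, mz, rt, height, float(np.trapezoid(vals, grid)),
                   grid[0], grid[-1], grid, vals)


class TestDetectMasses:
    def test_noise_threshold(self):
        s = Spectrum(0, 0.0, 1, "negative",
                     np.array([100.0, 200.0]), np.array([100.0, 400.0]))
        mz, inten = featdet.detect_masses(s, 300.0)
        assert mz.tolist() == [200.0]

    def test_all_below_noise(self):
        s = Spectrum(0, 0.0, 1, "negative", np.array([100.0]), np.array([10.0]))
        assert featdet.detect_masses(s, 300.0)[0].size == 0

    def test_zero_noise_is_identity(self):
        s = Spectrum(0, 0.0, 1, "negative",
                     np.array([100.0, 200.0]), np.array([5.0, 7.0]))
        assert featdet.detect_masses(s, 0.0)[0].size == 2


class TestBuildEics:
    def test_gaussian_spike_gives_one_eic(self):
        run = make_run([(285.040, 0.15, 0.02, 1e4, 1)])
        eics = featdet.build_eics(run, 1, CFG)
        assert len(eics) == 1
        assert eics[0].mz == pytest.approx(285.040, abs=CFG.mz_window(285.0))

    def test_four_scan_signal_rejected(self):
        # flat 4-scan pulse above every threshold except the 5-scan rule
        spectra = []
        for i in range(12):
            if 4 <= i < 8:
                mz, inten = np.array([285.04]), np.array([1e4])
            else:
                mz, inten = np.empty(0), np.empty(0)
            spectra.append(Spectrum(i, i * 0.005, 1, "negative", mz, inten))
        run = MSRun("four", spectra)
        assert featdet.build_eics(run, 1, CFG) == []

    def test_coeluting_ions_separated(self):
        run = make_run([
            (285.040, 0.15, 0.02, 1e4, 1),
            (285.090, 0.15, 0.02, 1e4, 1),  # 0.05 Da apart > window
        ])
        eics = featdet.build_eics(run, 1, CFG)
        assert len(eics) == 2

    def test_matches_exhaustive_grouping(self):
        """Oracle: with well-separated targets, an EIC must contain exactly
        the above-noise centroids within the m/z window of its target."""
        targets = [(201.0, 0.1), (355.5, 0.2), (702.2, 0.12)]
        run = make_run([(mz, rt, 0.02, 5e4, 1) for mz, rt in targets],
                       noise=250.0, seed=3)
        eics = featdet.build_eics(run, 1, CFG)
        assert len(eics) == len(targets)
        specs = run.spectra_at_level(1)
        for eic, (tmz, _) in zip(sorted(eics, key=lambda e: e.mz), targets):
            expected = []
            for pos, s in enumerate(specs):
                mask = (np.abs(s.mz - tmz) <= CFG.mz_window(tmz)) & \
                       (s.intensity > CFG.noise_level)
                for j in np.flatnonzero(mask):
                    expected.append((pos, round(float(s.mz[j]), 9)))
            got = sorted(zip(eic.scan_pos.tolist(),
                             np.round(eic.trace_mz, 9).tolist()))
            assert got == sorted(expected)


class TestResolvePeaks:
    def _eic(self, intensities, dt=0.005, mz=300.0):
        n = len(intensities)
        return featdet.EIC(mz, 1, np.arange(n), np.arange(n) * dt,
                           np.full(n, mz), np.asarray(intensities, dtype=float))

    def test_single_gaussian_one_feature(self):
        t = np.arange(40) * 0.005
        vals = 1e4 * np.exp(-0.5 * ((t - 0.1) / 0.02) ** 2)
        feats = featdet.resolve_peaks(self._eic(vals), CFG, "s")
        assert len(feats) == 1
        assert feats[0].rt == pytest.approx(0.1, abs=0.005)
        assert feats[0].height == pytest.approx(1e4, rel=0.01)

    def test_two_gaussians_with_deep_valley(self):
        t = np.arange(80) * 0.005
        vals = (1e4 * np.exp(-0.5 * ((t - 0.1) / 0.02) ** 2)
                + 1e4 * np.exp(-0.5 * ((t - 0.3) / 0.02) ** 2))
        feats = featdet.resolve_peaks(self._eic(vals), CFG, "s")
        assert len(feats) == 2

    def test_low_peak_dropped_at_ms1_height(self):
        t = np.arange(40) * 0.005
        vals = 5e3 * np.exp(-0.5 * ((t - 0.1) / 0.02) ** 2)
        assert featdet.resolve_peaks(self._eic(vals), CFG, "s") == []
        # ... but kept with the MS2 height override
        assert len(featdet.resolve_peaks(self._eic(vals), CFG.for_ms2(), "s")) == 1

    def test_trace_is_contiguous_subrange_and_area_bounded(self):
        t = np.arange(80) * 0.005
        vals = (2e4 * np.exp(-0.5 * ((t - 0.1) / 0.02) ** 2)
                + 1e4 * np.exp(-0.5 * ((t - 0.3) / 0.02) ** 2))
        eic = self._eic(vals)
        feats = featdet.resolve_peaks(eic, CFG, "s")
        total = np.trapezoid(eic.intensity, eic.rt)
        assert sum(f.area for f in feats) <= total + 1e-9
        for f in feats:
            i0 = np.searchsorted(eic.rt, f.rt_start)
            assert np.allclose(eic.intensity[i0:i0 + f.trace_rt.size],
                               f.trace_intensity)


class TestDeisotope:
    def test_satellite_collapsed_to_monoisotopic(self):
        mono = feature("s", 400.0, 1.0, 1e5)
        sat = feature("s", 401.00335, 1.0, 2e4)
        out = featdet.deisotope([sat, mono], CFG)
        assert [f.mz for f in out] == [400.0]

    def test_half_spacing_kept_at_max_charge_1(self):
        a = feature("s", 400.0, 1.0, 1e5)
        b = feature("s", 400.50168, 1.0, 2e4)  # would be z=2 satellite
        assert len(featdet.deisotope([a, b], CFG)) == 2

    def test_singleton_unchanged(self):
        a = feature("s", 400.0, 1.0, 1e5)
        assert featdet.deisotope([a], CFG) == [a]

    def test_never_removes_most_intense(self):
        rng = np.random.default_rng(11)
        feats = [feature("s", float(mz), 1.0, float(h))
                 for mz, h in zip(400 + np.cumsum(rng.uniform(0.3, 1.5, 30)),
                                  rng.uniform(1e4, 1e6, 30))]
        out = featdet.deisotope(feats, CFG)
        assert max(f.height for f in out) == max(f.height for f in feats)


class TestAlign:
    def test_single_sample_identity(self):
        feats = [feature("A", 300.0, 1.0, 1e4), feature("A", 500.0, 2.0, 1e4)]
        table = featdet.align({"A": feats}, CFG)
        assert len(table.rows) == 2
        assert all(len(r.members) == 1 for r in table.rows)

    def test_duplicate_sample_pairs_every_row(self):
        feats = [feature("A", 300.0, 1.0, 1e4), feature("A", 500.0, 2.0, 1e4)]
        dup = [feature("B", f.mz, f.rt, f.height) for f in feats]
        table = featdet.align({"A": feats, "B": dup}, CFG)
        assert len(table.rows) == 2
        assert all(len(r.members) == 2 for r in table.rows)

    def test_beyond_mz_tolerance_splits_rows(self):
        table = featdet.align(
            {"A": [feature("A", 300.00, 1.0, 1e4)],
             "B": [feature("B", 300.02, 1.0, 1e4)]},
            CFG,
        )
        assert len(table.rows) == 2

    def test_matches_bruteforce_assignment(self):
        """Oracle: with features spaced far beyond the tolerances, alignment
        must equal the exhaustive nearest-cluster assignment."""
        rng = np.random.default_rng(5)
        centers = [(float(m), float(t)) for m, t in
                   zip(300 + np.arange(15) * 2.0, 1 + rng.uniform(0, 5, 15))]
        per_sample = {}
        present = {}
        for sid in ("A", "B", "C"):
            feats = []
            for ci, (m, t) in enumerate(centers):
                if rng.uniform() < 0.8:
                    feats.append(feature(
                        sid, m + rng.uniform(-2e-3, 2e-3),
                        t + rng.uniform(-0.01, 0.01), 1e4))
                    present.setdefault(ci, set()).add(sid)
            per_sample[sid] = feats
        table = featdet.align(per_sample, CFG)
        expected = sorted(
            (round(centers[ci][0]), frozenset(s)) for ci, s in present.items()
        )
        got = sorted(
            (round(r.mz), frozenset(r.members)) for r in table.rows
        )
        assert got == expected

    def test_sample_order_permutation_same_partition(self):
        rng = np.random.default_rng(6)
        per_sample = {
            sid: [feature(sid, 300 + 3 * k + float(rng.uniform(-1e-3, 1e-3)),
                          1.0, 1e4) for k in range(8)]
            for sid in ("A", "B")
        }
        t1 = featdet.align(per_sample, CFG)
        t2 = featdet.align(dict(reversed(per_sample.items())), CFG)
        part1 = sorted(frozenset((s, round(f.mz, 6)) for s, f in r.members.items())
                       for r in t1.rows)
        part2 = sorted(frozenset((s, round(f.mz, 6)) for s, f in r.members.items())
                       for r in t2.rows)
        assert part1 == part2


class TestGapFill:
    def _table_with_hole(self, mz, rt):
        row = AlignedRow(mz, rt, {"A": feature("A", mz, rt, 2e4)})
        return AlignedTable(1, ["A", "B"], [row])

    def test_real_peak_filled(self):
        run_b = make_run([(300.0, 0.15, 0.02, 5e3, 1)], sample_id="B")
        table = gap = self._table_with_hole(300.0, 0.15)
        featdet.gap_fill(table, [run_b], CFG)
        assert "B" in table.rows[0].members
        filled = table.rows[0].members["B"]
        assert filled.gap_filled
        assert filled.height == pytest.approx(5e3, rel=0.05)

    def test_three_scan_signal_not_filled(self):
        spectra = []
        for i in range(20):
            if 8 <= i < 11:
                mz, inten = np.array([300.0]), np.array([5e3])
            else:
                mz, inten = np.empty(0), np.empty(0)
            spectra.append(Spectrum(i, i * 0.005, 1, "negative", mz, inten))
        run_b = MSRun("B", spectra)
        table = self._table_with_hole(300.0, 0.0475)
        featdet.gap_fill(table, [run_b], CFG)
        assert "B" not in table.rows[0].members

    def test_no_signal_stays_empty(self):
        run_b = make_run([], sample_id="B")
        table = self._table_with_hole(300.0, 0.15)
        featdet.gap_fill(table, [run_b], CFG)
        assert "B" not in table.rows[0].members


class TestDeterminism:
    def test_identical_input_identical_features(self):
        run = make_run([(285.040, 0.15, 0.02, 1e4, 1)], noise=250.0, seed=9)
        a = featdet.detect_features(run, 1, CFG)
        b = featdet.detect_features(run, 1, CFG)
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            assert fa.mz == fb.mz and fa.rt == fb.rt and fa.height == fb.height
            assert np.array_equal(fa.trace_intensity, fb.trace_intensity)
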