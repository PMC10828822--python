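import numpy as np
import pytest

from tmtd.errors import MetricError
from tmtd.io import Ms1Peak, Ms1Snapshot, PsmRecord
from tmtd.layout import two_proteome_layout
from tmtd.purity import (
    compute_oil,
    compute_pic,
    compute_ppf,
    compute_tiw,
    extract_isolation_window,
)

from .oracles import oracle_ppf


def make_psm(mz=500.0, charge=2, rt=10.0, ms2_scan=5, tic=1e6, reporters=None):
    return PsmRecord(
        raw_file="r1",
        ms2_scan=ms2_scan,
        sequence="PEPTIDEK",
        modifications=[(0, "TMTpro")],
        charge=charge,
        precursor_mz=mz,
        retention_time=rt,
        isolation_width=0.7,
        tic=tic,
        reporter_intensities=reporters or {},
    )


def scan(number, rt, peaks):
    return Ms1Snapshot(number, rt, [Ms1Peak(*p) for p in sorted(peaks)])


class TestExtraction:
    def test_retention_time_weights(self):
        # preceding scan 2 s before, following 3 s after -> weights 0.6 / 0.4
        psm = make_psm(rt=10.0)
        scans = [
            scan(4, 10.0 - 2 / 60, [(500.0, 100.0, 1.0)]),
            scan(6, 10.0 + 3 / 60, [(500.0, 100.0, 1.0)]),
        ]
        ex = extract_isolation_window(psm, scans)
        weights = {s.side: s.weight for s in ex.scans}
        assert weights[-1] == pytest.approx(0.6)
        assert weights[+1] == pytest.approx(0.4)

    def test_empty_following_window_skipped(self):
        psm = make_psm()
        scans = [
            scan(4, 9.99, [(500.0, 100.0, 1.0)]),
            scan(6, 10.01, [(900.0, 50.0, 1.0)]),  # nothing near 500
        ]
        ex = extract_isolation_window(psm, scans)
        assert [s.side for s in ex.scans] == [-1]
        assert ex.scans[0].weight == 1.0

    def test_second_last_scan_substitutes(self):
        psm = make_psm()
        scans = [
            scan(2, 9.95, [(500.0, 80.0, 1.0)]),  # second-last has the precursor
            scan(4, 9.99, [(500.3, 40.0, 1.0)]),  # preceding window lacks it
            scan(6, 10.01, [(500.0, 60.0, 1.0)]),
        ]
        ex = extract_isolation_window(psm, scans)
        preceding = next(s for s in ex.scans if s.side == -1)
        assert preceding.scan_number == 2
        assert not preceding.precursor_imputed

    def test_precursor_absent_everywhere_imputes_and_skips_following(self):
        psm = make_psm()
        scans = [
            scan(4, 9.99, [(500.3, 40.0, 1.0), (500.2, 400.0, 1.0)]),
            scan(6, 10.01, [(500.25, 70.0, 1.0)]),
        ]
        ex = extract_isolation_window(psm, scans)
        assert [s.side for s in ex.scans] == [-1]
        preceding = ex.scans[0]
        assert preceding.precursor_imputed
        imputed = [p for p in preceding.peaks if p.mz == psm.precursor_mz]
        # imputed at the scan's minimum observed intensity
        assert imputed[0].weighted_intensity == pytest.approx(40.0)

    def test_no_preceding_scan_flags_unquantifiable(self):
        psm = make_psm(ms2_scan=1)
        with pytest.raises(MetricError, match="unquantifiable"):
            extract_isolation_window(psm, [scan(6, 10.01, [(500.0, 1.0, 1.0)])])

    def test_isotope_peaks_flagged_with_charge_scaled_spacing(self):
        # at 0.7 Th width only isotopes of charge >= 3 fall inside the window
        psm = make_psm(charge=3)
        spacing = 1.00335484 / 3
        scans = [
            scan(
                4,
                9.99,
                [
                    (500.0, 100.0, 1.0),
                    (500.0 + spacing, 30.0, 1.0),
                    (500.0 - spacing, 10.0, 1.0),
                    (500.2, 60.0, 1.0),  # contaminant
                ],
            )
        ]
        ex = extract_isolation_window(psm, scans)
        flags = {round(p.mz, 4): p.is_precursor for p in ex.scans[0].peaks}
        assert flags[500.0] and flags[round(500.0 + spacing, 4)]
        assert flags[round(500.0 - spacing, 4)]
        assert not flags[500.2]


class TestPpfTiw:
    def test_pure_window_gives_one(self):
        psm = make_psm()
        scans = [scan(4, 9.99, [(500.0, 100.0, 1.0)])]
        ex = extract_isolation_window(psm, scans)
        assert compute_ppf(ex) == 1.0

    def test_equidistant_scans_by_hand(self):
        # preceding (precursor 60, other 40), following (precursor 80, other 20)
        psm = make_psm(rt=10.0)
        scans = [
            scan(4, 10.0 - 1 / 60, [(500.0, 60.0, 1.0), (500.2, 40.0, 1.0)]),
            scan(6, 10.0 + 1 / 60, [(500.0, 80.0, 1.0), (500.2, 20.0, 1.0)]),
        ]
        ex = extract_isolation_window(psm, scans)
        assert compute_ppf(ex) == pytest.approx(0.7)
        assert compute_tiw(ex) == pytest.approx(100.0)

    def test_single_scan_tiw_is_plain_sum(self):
        psm = make_psm()
        ex = extract_isolation_window(
            psm, [scan(4, 9.99, [(500.0, 10.0, 1.0), (500.2, 30.0, 1.0)])]
        )
        assert compute_tiw(ex) == pytest.approx(40.0)

    def test_imputed_precursor_among_large_contaminants_gives_small_ppf(self):
        psm = make_psm()
        scans = [scan(4, 9.99, [(500.2, 1000.0, 1.0), (500.3, 999.0, 1.0)])]
        ex = extract_isolation_window(psm, scans)
        assert compute_ppf(ex) < 0.4

    def test_tiw_decomposition_identity(self, small_sim):
        # TIW*PPF + TIW*(1-PPF) == TIW exactly
        from tmtd.pipeline import compute_purity_metrics

        psms = small_sim.psms[:50]
        compute_purity_metrics(psms, small_sim.snapshots)
        for p in psms:
            tiw, ppf = p.metrics.tiw, p.metrics.ppf
            assert tiw * ppf + tiw * (1 - ppf) == pytest.approx(tiw, rel=1e-12)

    def test_matches_brute_force_oracle_on_random_windows(self, rng):
        for _ in range(500):
            psm = make_psm(rt=10.0, charge=int(rng.integers(1, 5)))
            entries = []
            scans = []
            numbers = [4, 6]
            sides = [-1, +1]
            n_scans = int(rng.integers(1, 3))
            for i in range(n_scans):
                d = float(rng.uniform(0.005, 0.05))
                rt = 10.0 + sides[i] * d
                k = int(rng.integers(1, 6))
                peaks = []
                raw = []
                has_precursor = i == 0  # keep branch logic out of the oracle's way
                if has_precursor:
                    inten = float(rng.uniform(10, 1000))
                    peaks.append((500.0, inten, 1.0))
                    raw.append((inten, True))
                for _ in range(k):
                    inten = float(rng.uniform(1, 1000))
                    mz = 500.0 + float(rng.uniform(0.05, 0.3))
                    peaks.append((mz, inten, 1.0))
                    raw.append((inten, False))
                scans.append(scan(numbers[i], rt, peaks))
                entries.append((d, raw))
            ex = extract_isolation_window(psm, scans)
            expected_ppf, expected_tiw = oracle_ppf(
                [(s.d, [(p.weighted_intensity / s.weight, p.is_precursor) for p in s.peaks]) for s in ex.scans]
            )
            got = compute_ppf(ex)
            assert got == pytest.approx(expected_ppf, abs=1e-12)
            assert compute_tiw(ex) == pytest.approx(expected_tiw, abs=1e-9)


class TestPic:
    def test_tic_minus_reporters(self):
        psm = make_psm(tic=1000.0, reporters={"126C": 100.0, "127N": 50.0})
        assert compute_pic(psm) == pytest.approx(850.0)

    def test_no_reporters_gives_tic(self):
        psm = make_psm(tic=1000.0)
        assert compute_pic(psm) == 1000.0

    def test_pathological_reporter_sum_clamps_to_zero(self):
        psm = make_psm(tic=100.0, reporters={"126C": 150.0})
        with pytest.warns(UserWarning, match="clamped"):
            assert compute_pic(psm) == 0.0


class TestOil:
    def test_quarter_by_hand(self, layout):
        values = {c: 2.0 for c in layout.interference_only_channels}
        values.update({c: 8.0 for c in layout.quant_channels})
        assert compute_oil(values, layout) == pytest.approx(0.25)

    def test_capped_at_one(self, layout):
        values = {c: 9.0 for c in layout.interference_only_channels}
        values.update({c: 3.0 for c in layout.quant_channels})
        assert compute_oil(values, layout) == 1.0

    def test_zero_interference(self, layout):
        values = {c: 0.0 for c in layout.interference_only_channels}
        values.update({c: 5.0 for c in layout.quant_channels})
        assert compute_oil(values, layout) == 0.0

    def test_scale_invariance(self, layout, rng):
        values = {c: float(rng.uniform(1, 100)) for c in layout.peptide_channels}
        a = compute_oil(values, layout)
        b = compute_oil({c: 17.3 * v for c, v in values.items()}, layout)
        assert a == pytest.approx(b, rel=1e-12)

    def test_all_denominator_missing_gives_none(self, layout):
        values = {c: 2.0 for c in layout.interference_only_channels}
        assert compute_oil(values, layout) is None
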