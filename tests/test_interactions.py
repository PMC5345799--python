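"""Distance-resolved interaction statistics and hotspot detection."""

import numpy as np
import pytest

from dedomains import (
    ContactMatrix,
    DomainMap,
    Genome,
    Interval,
    SimulationConfig,
    detect_dd_hotspots,
    distance_fraction_profile,
    domain_distance_profile,
    normalize_coverage_product,
)
from dedomains.simulate import simulate_contact_matrix

from conftest import make_regular_map


def _matrix_from_upper(entries, n, res=5_000):
    v = np.zeros((n, n))
    for i, j, val in entries:
        v[i, j] = val
        v[j, i] = val
    return ContactMatrix("c", n * res, res, v)


class TestDistanceFractionProfile:
    def test_all_mass_short_range(self):
        n = 40
        mat = _matrix_from_upper([(20, 22, 8.0)], n)
        prof = distance_fraction_profile(mat, end_exclusion=0, high_percentile=100)
        row = prof.iloc[20]
        assert row.short == pytest.approx(1.0) and row.long == pytest.approx(0.0)

    def test_equal_split_ratio_one(self):
        n = 60
        mat = _matrix_from_upper([(20, 22, 5.0), (20, 40, 5.0)], n)
        prof = distance_fraction_profile(mat, end_exclusion=0, high_percentile=100)
        row = prof.iloc[20]
        assert row.short == pytest.approx(0.5)
        assert row.long == pytest.approx(0.5)
        assert row.ratio == pytest.approx(1.0)

    def test_sub_5kb_mass_in_total_but_not_short(self):
        n = 40
        mat = _matrix_from_upper([(20, 20, 5.0), (20, 22, 5.0)], n)
        prof = distance_fraction_profile(mat, end_exclusion=0, high_percentile=100)
        assert prof.iloc[20].short == pytest.approx(0.5)

    def test_end_exclusion_and_zero_anchors_masked(self):
        n = 500
        mat = _matrix_from_upper([(250, 252, 4.0)], n)
        prof = distance_fraction_profile(mat)  # 1 Mb ends at 5 kb = 200 bins
        assert not prof.iloc[10].kept
        assert not prof.iloc[300].kept  # zero interactions
        assert prof.iloc[250].kept

    def test_matches_brute_force_with_exclusions(self, rng):
        n = 50
        res = 5_000
        v = rng.poisson(2, (n, n)).astype(float)
        v = np.triu(v) + np.triu(v, 1).T
        mat = ContactMatrix("c", n * res, res, v)
        max_d, end_excl, pct = 100_000, 25_000, 90.0
        prof = distance_fraction_profile(
            mat, max_distance=max_d, end_exclusion=end_excl, high_percentile=pct
        )
        end_bins = end_excl // res
        totals = np.empty(n)
        for i in range(n):
            totals[i] = sum(
                v[i, j] for j in range(n) if abs(i - j) * res <= max_d
            )
        pool = [
            totals[i]
            for i in range(end_bins, n - end_bins)
            if totals[i] > 0
        ]
        thr = np.percentile(pool, pct)
        for i in range(n):
            kept = (
                end_bins <= i < n - end_bins and totals[i] > 0 and totals[i] <= thr
            )
            assert prof.iloc[i].kept == kept
            if not kept:
                continue
            short = sum(
                v[i, j] for j in range(n)
                if 5_000 <= abs(i - j) * res <= 50_000 and abs(i - j) * res <= max_d
            )
            long = sum(
                v[i, j] for j in range(n)
                if 50_000 < abs(i - j) * res <= 100_000
            )
            assert prof.iloc[i].short == pytest.approx(short / totals[i])
            assert prof.iloc[i].long == pytest.approx(long / totals[i])

    def test_mass_conservation_per_anchor(self, rng):
        n = 600
        v = rng.poisson(1, (n, n)).astype(float)
        v = np.triu(v) + np.triu(v, 1).T
        mat = ContactMatrix("c", n * 5_000, 5_000, v)
        prof = distance_fraction_profile(mat)
        kept = prof[prof.kept]
        # short + long <= 1; the residual is mass below 5 kb or above 500 kb
        assert ((kept.short + kept.long) <= 1 + 1e-9).all()


class TestDomainDistanceProfile:
    def _constructed(self):
        """Uniform elevated E blocks over a power-law background."""
        n, res, dom_w = 300, 10_000, 300_000
        ivs, pos, lab = [], 0, "D"
        while pos < n * res:
            ivs.append(Interval("c", pos, pos + dom_w, lab))
            pos += dom_w
            lab = "E" if lab == "D" else "D"
        dmap = DomainMap(ivs)
        dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        v = 5.0 / (1.0 + dist)
        labels = np.array(dmap.label_at("c", np.arange(n) * res + res // 2))
        dom_idx = (np.arange(n) * res) // dom_w
        same_e = (
            (dom_idx[:, None] == dom_idx[None, :])
            & (labels == "E")[:, None] & (labels == "E")[None, :]
        )
        v[same_e] = 2.0
        return ContactMatrix("c", n * res, res, v), dmap

    def test_e_flat_d_decays_with_planted_power_law(self):
        mat, dmap = self._constructed()
        table, p = domain_distance_profile(mat, dmap)
        emed = table[table.label == "E"].set_index("distance")["median"]
        dmed = table[table.label == "D"].set_index("distance")["median"]
        assert emed.std() < 1e-12
        assert (np.diff(dmed.to_numpy()) < 0).all()
        for d in dmed.index:
            assert dmed[d] == pytest.approx(5.0 / (1.0 + d / 10_000))
        mid = [c for c in dmed.index.intersection(emed.index) if c >= 30_000]
        assert all(dmed[c] < emed[c] for c in mid)
        assert p < 0.01

    def test_identical_label_distributions_null_p(self):
        # same decay under both labels: rank-sum p is large
        n, res = 200, 10_000
        dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        v = 4.0 / (1.0 + dist)
        ivs = []
        lab, pos = "D", 0
        while pos < n * res:
            ivs.append(Interval("c", pos, pos + 100_000, lab))
            pos += 100_000
            lab = "E" if lab == "D" else "D"
        mat = ContactMatrix("c", n * res, res, v)
        _, p = domain_distance_profile(mat, DomainMap(ivs))
        assert p > 0.5

    def test_medians_match_brute_force_collection(self, rng):
        n, res = 60, 10_000
        v = rng.poisson(3, (n, n)).astype(float)
        v = np.triu(v) + np.triu(v, 1).T
        mat = ContactMatrix("c", n * res, res, v)
        dmap = DomainMap(
            [
                Interval("c", 0, 200_000, "D"),
                Interval("c", 200_000, 450_000, "E"),
                Interval("c", 450_000, 600_000, "D"),
            ]
        )
        table, _ = domain_distance_profile(mat, dmap, min_length=40_000)
        for label in ("D", "E"):
            doms = [iv for iv in dmap.domains(label) if len(iv) > 40_000]
            by_dist = {}
            for dom in doms:
                b0, b1 = dom.start // res, dom.end // res
                for i in range(b0, b1):
                    for j in range(i + 1, b1):
                        by_dist.setdefault(j - i, []).append(v[i, j])
            for d, vals in by_dist.items():
                row = table[(table.label == label) & (table.distance == d * res)]
                assert row.iloc[0]["median"] == pytest.approx(np.median(vals))

    def test_missing_label_rejected(self):
        mat, dmap = self._constructed()
        only_d = DomainMap([iv for iv in dmap if iv.label == "D"])
        with pytest.raises(ValueError):
            domain_distance_profile(mat, only_d)


@pytest.fixture(scope="module")
def planted_run():
    length = 27_000_000
    g = Genome.from_dict({"chrA": length})
    dmap = make_regular_map(length)
    cfg = SimulationConfig(genome=g, seed=21, hotspot_prob=0.35)
    mat, planted = simulate_contact_matrix(cfg, dmap, "chrA", with_truth=True)
    norm = normalize_coverage_product(mat)
    calls = detect_dd_hotspots(norm, dmap)
    return calls, planted


class TestHotspots:
    def test_planted_corners_mostly_detected(self, planted_run):
        calls, planted = planted_run
        el = calls[calls.eligible]
        is_planted = np.array([planted[(r.e_start, r.e_end)] for _, r in el.iterrows()])
        detected = el.is_hotspot.to_numpy()
        assert detected[is_planted].mean() >= 0.85

    def test_detected_fraction_tracks_planted_rate(self, planted_run):
        calls, planted = planted_run
        el = calls[calls.eligible]
        planted_frac = np.mean(
            [planted[(r.e_start, r.e_end)] for _, r in el.iterrows()]
        )
        assert abs(el.is_hotspot.mean() - planted_frac) <= 0.05

    def test_homogeneous_matrix_no_hotspots(self):
        n = 200
        v = np.full((n, n), 3.0)
        mat = ContactMatrix("chrA", n * 10_000, 10_000, v)
        dmap = make_regular_map(n * 10_000)
        calls = detect_dd_hotspots(mat, dmap)
        el = calls[calls.eligible]
        assert len(el) > 0 and not el.is_hotspot.any()

    def test_two_fold_corner_against_flat_background(self):
        # single eligible E domain with a 2x corner on an otherwise flat map
        n = 100
        v = np.full((n, n), 2.0)
        dmap = DomainMap(
            [
                Interval("chrA", 0, 300_000, "D"),
                Interval("chrA", 300_000, 400_000, "E"),
                Interval("chrA", 400_000, 700_000, "D"),
                Interval("chrA", 700_000, 800_000, "E"),
                Interval("chrA", 800_000, 1_000_000, "D"),
            ]
        )
        # corner of first E: rows 20-30 x cols 40-50
        v[20:30, 40:50] *= 2.0
        v[40:50, 20:30] = v[20:30, 40:50].T
        mat = ContactMatrix("chrA", n * 10_000, 10_000, v)
        calls = detect_dd_hotspots(mat, dmap)
        el = calls[calls.eligible].set_index("e_start")
        assert bool(el.loc[300_000].is_hotspot)
        assert not bool(el.loc[700_000].is_hotspot)
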