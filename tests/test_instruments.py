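"""Instrument strength statistics, LD clumping and the selection cascade."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrmediate import (
    ConfounderTable,
    LdTable,
    clump,
    f_statistic,
    select_instruments,
    variance_explained,
)
from mrmediate.simulate import CausalScenario, simulate_triplet_gwas
from tests.conftest import random_records

import pandas as pd


class TestStrengthFormulas:
    def test_zero_effect_gives_zero(self):
        assert variance_explained(0.0, 0.1, 1000) == 0.0
        assert f_statistic(0.0, 0.1, 1000) == 0.0

    def test_hand_evaluated_values(self):
        # z = beta/se = 5, n = 10000: r² = z²/(z²+n), F = (n−2)·z²/n
        assert variance_explained(0.1, 0.02, 10_000) == pytest.approx(0.00249377, abs=1e-8)
        assert f_statistic(0.1, 0.02, 10_000) == pytest.approx(24.995, abs=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.0, 1000)
        with pytest.raises(ValueError):
            f_statistic(0.1, -0.1, 1000)
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.1, 2)

    def test_r2_strictly_decreases_with_se(self):
        ses = np.linspace(0.01, 0.5, 60)
        r2 = variance_explained(0.1, ses, 5000)
        assert np.all(np.diff(r2) < 0)

    @given(st.floats(-2, 2), st.floats(0.001, 1), st.integers(3, 10**6))
    def test_brute_force_formula_agreement(self, beta, se, n):
        """The implemented statistics equal a literal evaluation of
        2β²/(2β²+2Nse²) and (N−2)R²/(1−R²) to 1e-12 relative error."""
        r2_ref = 2 * beta**2 / (2 * beta**2 + 2 * n * se**2)
        f_ref = (n - 2) * r2_ref / (1 - r2_ref)
        assert variance_explained(beta, se, n) == pytest.approx(r2_ref, rel=1e-12, abs=1e-300)
        assert f_statistic(beta, se, n) == pytest.approx(f_ref, rel=1e-12, abs=1e-300)

    def test_f_threshold_boundary_in_z_squared(self):
        # F >= 10 iff z² >= 10·n/(n−2)
        n = 10_000
        z2_boundary = 10 * n / (n - 2)
        se = 0.01
        beta_hi = se * np.sqrt(z2_boundary * 1.0001)
        beta_lo = se * np.sqrt(z2_boundary * 0.9999)
        assert f_statistic(beta_hi, se, n) >= 10
        assert f_statistic(beta_lo, se, n) < 10


def _ld(pairs):
    t = LdTable()
    for a, b, r2 in pairs:
        t.set_r2(a, b, r2)
    return t


def _cand(snp_id, pval, pos, chrom="1"):
    from mrmediate import SnpAssociation

    return SnpAssociation(snp_id, chrom, pos, "A", "G", 0.3, 0.1, 0.01, pval, 10_000)


def _greedy_oracle(cands, ld, r2_max, window_bp):
    """Independent re-statement of the greedy rule, set-based."""
    remaining = list(cands)
    kept = []
    while remaining:
        best = min(remaining, key=lambda r: (r.pval, r.chrom, r.pos))
        kept.append(best)
        remaining = [
            r for r in remaining
            if r is not best
            and not (r.chrom == best.chrom and abs(r.pos - best.pos) <= window_bp
                     and ld.r2(best.snp_id, r.snp_id) > r2_max)
        ]
    return sorted(k.snp_id for k in kept)


class TestClump:
    def test_three_snp_example(self):
        a, b, c = _cand("A", 1e-8, 1000), _cand("B", 1e-7, 5000), _cand("C", 1e-6, 2_000_000)
        ld = _ld([("A", "B", 0.5), ("A", "C", 0.0005)])
        kept = clump([a, b, c], ld, r2_max=0.001, window_kb=10_000)
        assert [k.snp_id for k in kept] == ["A", "C"]

    def test_single_snp_kept(self):
        assert len(clump([_cand("A", 0.5, 1)], LdTable())) == 1

    def test_unlinked_snps_all_kept(self, rng):
        cands = [_cand(f"s{i}", float(rng.random()), 1000 + i) for i in range(20)]
        assert len(clump(cands, LdTable())) == 20

    def test_empty_input(self):
        assert clump([], LdTable()) == []

    def test_matches_independent_greedy_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 15))
            cands = [_cand(f"s{i}", float(rng.random()), int(rng.integers(1, 3_000_000)),
                           chrom=str(rng.integers(1, 3))) for i in range(n)]
            ld = LdTable()
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        ld.set_r2(f"s{i}", f"s{j}", float(rng.random()))
            kept = clump(cands, ld, r2_max=0.1, window_kb=1_000)
            assert sorted(k.snp_id for k in kept) == _greedy_oracle(cands, ld, 0.1, 1_000_000)

    def test_no_retained_pair_exceeds_threshold(self, rng):
        """Maximality: retained SNPs are mutually independent within the window."""
        cands = [_cand(f"s{i}", float(rng.random()), int(rng.integers(1, 500_000))) for i in range(25)]
        ld = LdTable()
        for i in range(25):
            for j in range(i + 1, 25):
                ld.set_r2(f"s{i}", f"s{j}", float(rng.random()))
        kept = clump(cands, ld, r2_max=0.3, window_kb=1_000)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if abs(a.pos - b.pos) <= 1_000_000:
                    assert ld.r2(a.snp_id, b.snp_id) <= 0.3


class TestSelectInstruments:
    def test_all_above_threshold_gives_empty_set(self, rng):
        stats = random_records(rng, n=10)  # uniform p-values, none < 5e-8
        instruments, report = select_instruments(stats, LdTable(), p_threshold=5e-8)
        assert instruments == []
        assert (report["fate"] == "removed_pvalue").all()

    def test_recovers_true_instruments_among_nulls(self):
        trip = simulate_triplet_gwas(CausalScenario(n_snps_exposure=5, n_null_snps=50, seed=7))
        truth = set(trip.truth["instruments"])
        instruments, report = select_instruments(trip.exposure, trip.ld, p_threshold=5e-8)
        assert {r.snp_id for r in instruments} == truth
        assert len(report) == 55

    def test_confounder_step_removes_annotated_snp(self):
        trip = simulate_triplet_gwas(CausalScenario(n_snps_exposure=4, seed=3))
        victim = trip.truth["instruments"][0]
        conf = ConfounderTable(pd.DataFrame({"snp": [victim], "trait": ["smoking"], "pval": [1e-12]}))
        instruments, report = select_instruments(trip.exposure, trip.ld, conf,
                                                 p_threshold=5e-8, confounder_traits=["smoking"])
        assert victim not in {r.snp_id for r in instruments}
        assert report.set_index("snp_id").loc[victim, "fate"] == "removed_confounder"
        # a confounder trait not in the declared list is ignored
        instruments2, _ = select_instruments(trip.exposure, trip.ld, conf,
                                             p_threshold=5e-8, confounder_traits=["height"])
        assert victim in {r.snp_id for r in instruments2}

    def test_weak_f_filter(self):
        # p just under a lenient threshold but F < 10: z² ≈ 9
        weak = _cand("w", 0.002, 1000)
        weak = type(weak)(**{**weak.__dict__, "beta": 0.03, "se": 0.01, "n": 10_000})
        instruments, report = select_instruments([weak], LdTable(), p_threshold=0.01, f_min=10)
        assert instruments == []
        assert report["fate"].tolist() == ["removed_weak_f"]

    def test_report_partitions_input(self, rng):
        trip = simulate_triplet_gwas(CausalScenario(n_snps_exposure=8, n_null_snps=30, seed=11))
        instruments, report = select_instruments(trip.exposure, trip.ld, p_threshold=1e-5)
        assert len(report) == 38
        assert (report["fate"] == "kept").sum() == len(instruments)

    def test_deterministic(self):
        trip = simulate_triplet_gwas(CausalScenario(n_snps_exposure=6, n_null_snps=20, seed=5))
        r1 = select_instruments(trip.exposure, trip.ld, p_threshold=1e-5)
        r2 = select_instruments(trip.exposure, trip.ld, p_threshold=1e-5)
        assert [x.snp_id for x in r1[0]] == [x.snp_id for x in r2[0]]
        assert r1[1].equals(r2[1])


def test_ld_table_round_trip(tmp_path):
    t = _ld([("a", "b", 0.5), ("b", "c", 0.01)])
    f = tmp_path / "ld.tsv"
    t.to_tsv(f)
    back = LdTable.from_tsv(f)
    assert back.r2("a", "b") == 0.5 and back.r2("c", "b") == 0.01
    assert back.r2("a", "a") == 1.0 and back.r2("a", "zzz") == 0.0
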