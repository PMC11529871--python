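"""Trace of K^2: exact routes, Hutchinson estimation, jackknife consistency,
aggregation and the .trace file format."""

import numpy as np
import pytest

from sumrhe.genotype_io import standardize
from sumrhe.phenosim import simulate_genotypes
from sumrhe.trace import (
    TraceCompatibilityError,
    TraceFormatError,
    aggregate_trace_runs,
    exact_trace_K2,
    exact_trace_K2_grm_route,
    jackknife_plan,
    make_trace_summary,
    make_trace_summary_runs,
    read_trace,
    snp_digest,
    stochastic_trace_K2,
    write_trace,
)


class TestExactTrace:
    def test_single_snp_rank_one(self):
        std = standardize(simulate_genotypes(40, 1, seed=1))
        # K = xx' with x'x = N, so tr(K^2) = (x'x)^2 = N^2
        assert exact_trace_K2(std) == pytest.approx(40.0**2, rel=1e-12)

    def test_brute_force_full_matrix(self, rng):
        std = standardize(simulate_genotypes(6, 4, seed=2))
        k = std.matrix @ std.matrix.T / std.m
        assert exact_trace_K2(std) == pytest.approx(float((k * k).sum()), rel=1e-12)

    def test_gram_and_grm_routes_agree(self, mid_std):
        a = exact_trace_K2(mid_std)
        b = exact_trace_K2_grm_route(mid_std)
        assert a == pytest.approx(b, rel=1e-6)

    def test_independent_snp_limit(self):
        # unlinked SNPs: tr(K^2) ~ N + N^2/M
        n, m = 2000, 1000
        std = standardize(simulate_genotypes(n, m, seed=3))
        assert exact_trace_K2(std) == pytest.approx(n + n * n / m, rel=0.05)


class TestStochasticTrace:
    def test_seeded_determinism(self, mid_std):
        assert stochastic_trace_K2(mid_std, 20, seed=5) == stochastic_trace_K2(
            mid_std, 20, seed=5
        )

    def test_unbiased_over_seeds(self):
        std = standardize(simulate_genotypes(100, 200, seed=4))
        exact = exact_trace_K2(std)
        ests = np.array([stochastic_trace_K2(std, 20, seed=s) for s in range(50)])
        se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - exact) < 3 * se

    def test_concentrates_at_large_b(self):
        std = standardize(simulate_genotypes(200, 100, seed=5))
        assert stochastic_trace_K2(std, 2000, seed=6) == pytest.approx(
            exact_trace_K2(std), rel=0.02
        )

    def test_rademacher_probes_also_unbiased(self):
        std = standardize(simulate_genotypes(80, 60, seed=6))
        exact = exact_trace_K2(std)
        ests = np.array(
            [stochastic_trace_K2(std, 20, seed=s, rademacher=True) for s in range(40)]
        )
        se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - exact) < 3 * se


class TestJackknifePlan:
    def test_contiguous_remainder_to_last(self):
        slices = jackknife_plan(103, 10)
        assert len(slices) == 10
        assert [s.stop - s.start for s in slices] == [10] * 9 + [13]
        assert slices[0].start == 0 and slices[-1].stop == 103

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            jackknife_plan(10, 1)
        with pytest.raises(ValueError):
            jackknife_plan(10, 11)


class TestTraceSummary:
    def test_exact_jackknife_equals_physical_subset(self, mid_std):
        ts = make_trace_summary(mid_std, n_blocks=8, exact=True)
        for k in (0, 3, 7):
            sl = ts.block_slices()[k]
            keep = [
                mid_std.snp_ids[j]
                for j in range(mid_std.m)
                if not (sl.start <= j < sl.stop)
            ]
            sub = mid_std.subset_snps(keep)
            rho_sub = (exact_trace_K2(sub) / sub.n - 1.0) / sub.n
            assert ts.blocks[k].rho_jack == pytest.approx(rho_sub, rel=1e-8)

    def test_stochastic_jackknife_equals_physical_subset_same_probes(self, mid_std):
        probes = np.random.default_rng(8).standard_normal((mid_std.n, 30))
        ts = make_trace_summary(mid_std, b=30, n_blocks=5, probes=probes)
        sl = ts.block_slices()[2]
        keep = [
            mid_std.snp_ids[j] for j in range(mid_std.m) if not (sl.start <= j < sl.stop)
        ]
        sub = mid_std.subset_snps(keep)
        tr_sub = stochastic_trace_K2(sub, 30, probes=probes)
        rho_sub = (tr_sub / sub.n - 1.0) / sub.n
        assert ts.blocks[2].rho_jack == pytest.approx(rho_sub, rel=1e-8)

    def test_duplicated_halves_symmetric_blocks(self):
        std = standardize(simulate_genotypes(50, 10, seed=9))
        dup = np.hstack([std.matrix, std.matrix])
        from sumrhe.genotype_io import StandardizedGenotypes

        geno = StandardizedGenotypes(
            matrix=dup,
            snp_ids=[f"a{j}" for j in range(10)] + [f"b{j}" for j in range(10)],
            freqs=np.tile(std.freqs, 2),
            obs_counts=np.tile(std.obs_counts, 2),
        )
        ts = make_trace_summary(geno, b=40, n_blocks=2, seed=10)
        assert ts.blocks[0].rho_jack == pytest.approx(ts.blocks[1].rho_jack, rel=1e-10)

    def test_rho_transfers_between_disjoint_reference_samples(self):
        # rho is a population LD functional: disjoint samples agree within MC error
        panel = simulate_genotypes(1600, 800, seed=11)
        from sumrhe.genotype_io import GenotypePanel

        half1 = GenotypePanel(panel.samples[:800], panel.snps, panel.calls[:800])
        half2 = GenotypePanel(panel.samples[800:], panel.snps, panel.calls[800:])
        r1 = make_trace_summary(standardize(half1), n_blocks=10, exact=True).rho
        r2 = make_trace_summary(standardize(half2), n_blocks=10, exact=True).rho
        # for unlinked SNPs rho ~ (N+1)/(N M) ~ 1/M; sampling noise is O(1/(M sqrt(N)))
        assert r1 == pytest.approx(r2, rel=0.1)
        assert r1 == pytest.approx(1.0 / 800, rel=0.1)


class TestAggregation:
    def test_pooling_matches_single_large_run_in_expectation(self):
        std = standardize(simulate_genotypes(100, 80, seed=12))
        pooled, single = [], []
        for s in range(30):
            runs = [
                make_trace_summary(std, b=100, n_blocks=4, seed=[s, i]) for i in range(5)
            ]
            pooled.append(aggregate_trace_runs(runs).rho)
            single.append(make_trace_summary(std, b=500, n_blocks=4, seed=[s, 99]).rho)
        pooled, single = np.asarray(pooled), np.asarray(single)
        se = np.sqrt(pooled.var(ddof=1) / 30 + single.var(ddof=1) / 30)
        assert abs(pooled.mean() - single.mean()) < 3 * se

    def test_aggregate_with_itself_identical_rho_doubled_b(self):
        std = standardize(simulate_genotypes(60, 40, seed=13))
        ts = make_trace_summary(std, b=50, n_blocks=4, seed=14)
        agg = aggregate_trace_runs([ts, ts])
        assert agg.rho == pytest.approx(ts.rho, rel=1e-15)
        assert agg.b_total == 100
        for a, b in zip(agg.blocks, ts.blocks):
            assert a.rho_jack == pytest.approx(b.rho_jack, rel=1e-15)

    def test_weighted_mean_arithmetic(self):
        std = standardize(simulate_genotypes(30, 20, seed=15))
        t1 = make_trace_summary(std, b=100, n_blocks=2, seed=1)
        t2 = make_trace_summary(std, b=100, n_blocks=2, seed=2)
        agg = aggregate_trace_runs([t1, t2])
        assert agg.rho == pytest.approx((t1.rho + t2.rho) / 2)
        assert agg.b_total == 200

    def test_25_runs_at_b100_near_exact(self):
        std = standardize(simulate_genotypes(500, 400, seed=16))
        agg = make_trace_summary_runs(std, b=100, runs=25, n_blocks=10, seed=17)
        exact_rho = (exact_trace_K2(std) / std.n - 1.0) / std.n
        assert agg.rho == pytest.approx(exact_rho, rel=0.01)
        assert agg.b_total == 2500

    def test_mismatched_runs_rejected(self):
        a = standardize(simulate_genotypes(30, 20, seed=18))
        b = standardize(simulate_genotypes(30, 22, seed=19))
        with pytest.raises(TraceCompatibilityError):
            aggregate_trace_runs(
                [
                    make_trace_summary(a, b=10, n_blocks=2, seed=0),
                    make_trace_summary(b, b=10, n_blocks=2, seed=0),
                ]
            )


class TestTraceFile:
    def test_roundtrip_field_identical(self, tmp_path, mid_std):
        ts = make_trace_summary(mid_std, b=30, n_blocks=7, seed=20)
        write_trace(ts, tmp_path / "x.trace")
        back = read_trace(tmp_path / "x.trace")
        assert (back.n_ref, back.m, back.b_total, back.digest) == (
            ts.n_ref,
            ts.m,
            ts.b_total,
            ts.digest,
        )
        assert back.rho == ts.rho  # bit-exact via 17 significant digits
        assert back.blocks == ts.blocks

    def test_removed_block_line_caught(self, tmp_path, mid_std):
        ts = make_trace_summary(mid_std, b=10, n_blocks=5, seed=21)
        write_trace(ts, tmp_path / "x.trace")
        lines = (tmp_path / "x.trace").read_text().splitlines()
        (tmp_path / "x.trace").write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(TraceFormatError, match="block"):
            read_trace(tmp_path / "x.trace")

    def test_digest_checked_against_snp_list(self, tmp_path, mid_std):
        ts = make_trace_summary(mid_std, b=10, n_blocks=5, seed=22)
        write_trace(ts, tmp_path / "x.trace")
        wrong = ["zz"] * mid_std.m
        with pytest.raises(TraceFormatError, match="digest"):
            read_trace(tmp_path / "x.trace", snp_ids=wrong, strict=True)
        with pytest.warns(UserWarning, match="digest"):
            read_trace(tmp_path / "x.trace", snp_ids=wrong, strict=False)
        ok = read_trace(tmp_path / "x.trace", snp_ids=mid_std.snp_ids)
        assert ok.snp_ids == mid_std.snp_ids

    def test_version_mismatch_rejected(self, tmp_path, mid_std):
        ts = make_trace_summary(mid_std, b=10, n_blocks=5, seed=23)
        write_trace(ts, tmp_path / "x.trace")
        text = (tmp_path / "x.trace").read_text().replace("#VERSION 1", "#VERSION 99")
        (tmp_path / "x.trace").write_text(text)
        with pytest.raises(TraceFormatError, match="version"):
            read_trace(tmp_path / "x.trace")

    def test_digest_is_order_sensitive(self):
        assert snp_digest(["a", "b"]) != snp_digest(["b", "a"])
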