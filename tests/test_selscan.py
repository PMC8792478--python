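import itertools

import numpy as np
import pandas as pd
import pytest

from budworm import selscan
from budworm.selscan import ScanSettings, bayescan_scan, union_outliers, wc_fst

from conftest import make_matrix

TINY = ScanSettings(n_pilot=4, pilot_len=200, burn_in=1000, n_out=400, thin=5)


def wc_theta_oracle(geno1, geno2):
    """Scalar transcription of the two-level variance components for a
    single biallelic locus and two samples of diploid genotypes."""
    r = 2
    samples = [geno1, geno2]
    n = [len(g) for g in samples]
    p = [sum(g) / (2 * len(g)) for g in samples]
    h = [sum(1 for x in g if x == 1) / len(g) for g in samples]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x**2 for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(n[i] * p[i] for i in range(r)) / (r * nbar)
    s2 = sum(n[i] * (p[i] - pbar) ** 2 for i in range(r)) / ((r - 1) * nbar)
    hbar = sum(n[i] * h[i] for i in range(r)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def _run(self, geno1, geno2):
        calls = np.array([list(geno1) + list(geno2)]).T.reshape(-1, 1)
        gm = make_matrix(calls)
        labels = pd.Series(
            ["g1"] * len(geno1) + ["g2"] * len(geno2), index=gm.individuals
        )
        return wc_fst(gm, labels)

    def test_fixed_difference_theta_one(self):
        out = self._run([2] * 10, [0] * 10)
        assert out.per_locus["theta"].iloc[0] == pytest.approx(1.0)

    def test_identical_groups_theta_near_zero(self):
        out = self._run([0, 1, 1, 2, 0, 1, 1, 2], [0, 1, 1, 2, 0, 1, 1, 2])
        assert out.per_locus["theta"].iloc[0] == pytest.approx(0.0, abs=0.1)

    def test_exhaustive_small_tables_match_oracle(self):
        """All 2+2-individual genotype tables agree with the scalar
        transcription of the variance-component formulas."""
        for g1 in itertools.product([0, 1, 2], repeat=2):
            for g2 in itertools.product([0, 1, 2], repeat=2):
                pbar = (sum(g1) + sum(g2)) / 8
                out = self._run(list(g1), list(g2))
                a, b, c = wc_theta_oracle(list(g1), list(g2))
                row = out.per_locus.iloc[0]
                if pbar in (0.0, 1.0):
                    assert not row["defined"]
                    continue
                assert row["a"] == pytest.approx(a, abs=1e-12)
                assert row["b"] == pytest.approx(b, abs=1e-12)
                assert row["c"] == pytest.approx(c, abs=1e-12)
                if (a + b + c) != 0:
                    assert row["theta"] == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_random_small_tables_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            n1, n2 = rng.integers(2, 4, size=2)
            g1 = rng.integers(0, 3, size=n1).tolist()
            g2 = rng.integers(0, 3, size=n2).tolist()
            pbar = (sum(g1) + sum(g2)) / (2 * (n1 + n2))
            if pbar in (0.0, 1.0):
                continue
            a, b, c = wc_theta_oracle(g1, g2)
            row = self._run(g1, g2).per_locus.iloc[0]
            assert row["a"] == pytest.approx(a, abs=1e-12)
            assert row["theta"] == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_genome_wide_is_ratio_of_sums(self, study, study_truth_labels):
        lab = study_truth_labels[study_truth_labels.isin(["P1", "P2"])]
        out = wc_fst(study.genotypes, lab)
        d = out.per_locus[out.per_locus["defined"]]
        expect = d["a"].sum() / (d["a"] + d["b"] + d["c"]).sum()
        assert out.overall == pytest.approx(expect)

    def test_group_with_no_calls_undefined(self):
        calls = np.array([[0], [1], [-1], [-1]], dtype=np.int8)
        gm = make_matrix(calls)
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=gm.individuals)
        out = wc_fst(gm, labels)
        assert not out.per_locus["defined"].iloc[0]
        assert np.isnan(out.overall)

    def test_single_group_rejected(self):
        gm = make_matrix([[0], [1]])
        with pytest.raises(ValueError):
            wc_fst(gm, pd.Series(["g1", "g1"], index=gm.individuals))


def _counts_from_freqs(p1, p2, n_alleles, rng):
    alt = np.column_stack(
        [rng.binomial(n_alleles, p1), rng.binomial(n_alleles, p2)]
    )
    return alt, np.full_like(alt, n_alleles)


class TestBayescanScan:
    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bayescan_scan(np.array([[1, 2]]), np.array([[10, 10]]), TINY)
        with pytest.raises(ValueError):
            bayescan_scan(np.array([[1], [2]]), np.array([[10], [10]]), TINY)

    def test_qvalues_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.8, 40)
        alt, tot = _counts_from_freqs(p, p, 60, rng)
        scan = bayescan_scan(alt, tot, TINY, seed=1)
        t = scan.table.sort_values("posterior_prob", ascending=False)
        assert (np.diff(t["qvalue"].to_numpy()) >= -1e-12).all()
        assert t["qvalue"].between(0, 1).all()

    def test_divergence_ladder_monotone_inclusion(self):
        """Posterior inclusion rises towards 1 as a locus approaches
        fixation for alternate alleles."""
        rng = np.random.default_rng(2)
        p = rng.uniform(0.3, 0.7, 40)
        gaps = [0.0, 0.3, 0.6, 0.98]
        p1 = np.concatenate([p, [0.5 + g / 2 for g in gaps]])
        p2 = np.concatenate([p, [0.5 - g / 2 for g in gaps]])
        alt, tot = _counts_from_freqs(p1, p2, 120, rng)
        pips = []
        for seed in range(3):
            scan = bayescan_scan(alt, tot, TINY, seed=seed)
            pips.append(scan.table["posterior_prob"].to_numpy()[-4:])
        mean_pip = np.mean(pips, axis=0)
        assert mean_pip[-1] > 0.95
        assert (np.diff(mean_pip) >= -0.1).all()

    def test_group_permutation_invariance(self):
        """Swapping group columns leaves locus-effect inferences unchanged
        in distribution: the planted outlier is flagged either way and the
        neutral background stays quiet."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0.3, 0.7, 30)
        p1 = np.concatenate([p, [0.99]])
        p2 = np.concatenate([p, [0.01]])
        alt, tot = _counts_from_freqs(p1, p2, 120, rng)
        a = bayescan_scan(alt, tot, TINY, seed=5)
        b = bayescan_scan(alt[:, ::-1], tot[:, ::-1], TINY, seed=5)
        for scan in (a, b):
            assert scan.table["posterior_prob"].iloc[-1] > 0.9
            assert scan.table["posterior_prob"].iloc[:-1].max() < 0.7
        assert a.outliers() == b.outliers()

    def test_settings_echoed(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.3, 0.7, 20)
        alt, tot = _counts_from_freqs(p, p, 40, rng)
        scan = bayescan_scan(alt, tot, TINY, seed=0)
        assert scan.settings == TINY
        assert scan.seed == 0
        assert set(scan.acceptance) == {"p", "alpha", "rj", "beta"}


class TestUnionOutliers:
    def _scan_with(self, loci, total=5):
        table = pd.DataFrame(
            {
                "fst": 0.1,
                "alpha": 0.0,
                "posterior_prob": [1.0 if i in loci else 0.0 for i in range(total)],
                "qvalue": [0.0 if i in loci else 1.0 for i in range(total)],
                "decision": [i in loci for i in range(total)],
            }
        )
        return selscan.OutlierScan(
            table=table, settings=TINY, seed=0, groups=["a", "b"]
        )

    def test_union_merges_runs(self):
        out = union_outliers([self._scan_with({0, 1}), self._scan_with({1, 2})])
        assert out["locus"].tolist() == [0, 1, 2]
        assert out.set_index("locus").loc[1, "n_runs"] == 2

    def test_identical_runs_same_set(self):
        out = union_outliers([self._scan_with({3}), self._scan_with({3})])
        assert out["locus"].tolist() == [3]

    def test_empty_runs_empty_set(self):
        out = union_outliers([self._scan_with(set()), self._scan_with(set())])
        assert out.empty
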