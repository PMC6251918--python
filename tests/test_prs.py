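import numpy as np
import pandas as pd
import pytest

from comorbigen import prs
from comorbigen.datatypes import GenotypeDataset, PhenotypeTable, SummaryStatsTable, ValidationError

from .conftest import binomial_genotypes
from .oracles import (
    greedy_select_oracle,
    nagelkerke_oracle,
    newton_logistic,
    pairwise_r2_oracle,
)


def _target(alleles):
    """Target dataset with one variant per (ea, nea) pair given."""
    m = len(alleles)
    variants = pd.DataFrame(
        {"id": [f"v{j}" for j in range(m)], "chrom": "1",
         "pos": (1 + np.arange(m)) * 1000,
         "ea": [a for a, _ in alleles], "nea": [b for _, b in alleles],
         "eaf": 0.3, "info": np.nan}
    )
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.3, size=(10, m)).astype(np.float32)
    return GenotypeDataset([f"S{i}" for i in range(10)], variants, d)


class TestMatchAlleles:
    def test_eight_allele_configurations(self):
        target = _target([("A", "G")] * 7)
        base = pd.DataFrame(
            {
                "id": [f"v{j}" for j in range(7)],
                "ea":  ["A", "G", "T", "C", "A", "A", "C"],
                "nea": ["G", "A", "C", "T", "T", "C", "G"],
                "weight": [0.3] * 7,
                "p": [0.01] * 7,
            }
        )
        # v0 exact; v1 swapped; v2 flip(T,C)->(A,G); v3 flip(C,T)->(G,A) swap;
        # v4 palindromic A/T; v5 mismatch; v6 palindromic C/G
        matched, report = prs.match_alleles(base, target)
        assert report == {"kept": 1, "swapped": 1, "flipped": 1,
                          "flipped_swapped": 1, "ambiguous": 2, "mismatch": 1,
                          "absent": 0}
        w = matched.set_index("id")["weight"]
        assert w["v0"] == pytest.approx(0.3)
        assert w["v1"] == pytest.approx(-0.3)
        assert w["v2"] == pytest.approx(0.3)
        assert w["v3"] == pytest.approx(-0.3)
        # matched output is in target orientation
        assert (matched["ea"] == "A").all() and (matched["nea"] == "G").all()

    def test_absent_variant_counted(self):
        target = _target([("A", "G")])
        base = pd.DataFrame({"id": ["nope"], "ea": ["A"], "nea": ["G"],
                             "weight": [0.1], "p": [0.5]})
        matched, report = prs.match_alleles(base, target)
        assert len(matched) == 0 and report["absent"] == 1


class TestClump:
    def _ld_fixture(self):
        """A(p=1e-8) and B(p=1e-4) in LD; C(p=1e-3) independent."""
        rng = np.random.default_rng(30)
        n = 400
        a = rng.binomial(2, 0.4, n).astype(float)
        flip = rng.random(n) < 0.1
        b = np.where(flip, rng.binomial(2, 0.4, n), a).astype(float)  # r2 >> 0.1
        c = rng.binomial(2, 0.4, n).astype(float)
        variants = pd.DataFrame(
            {"id": ["A", "B", "C"], "chrom": "1",
             "pos": [100_000, 150_000, 160_000],
             "ea": "A", "nea": "G", "eaf": 0.4, "info": np.nan}
        )
        ds = GenotypeDataset([f"S{i}" for i in range(n)], variants,
                             np.column_stack([a, b, c]).astype(np.float32))
        ss = SummaryStatsTable(pd.DataFrame(
            {"id": ["A", "B", "C"], "chrom": "1", "pos": [100_000, 150_000, 160_000],
             "ea": "A", "nea": "G", "eaf": 0.4,
             "beta": [0.3, 0.25, 0.2], "se": [0.05, 0.06, 0.06],
             "p": [1e-8, 1e-4, 1e-3], "n": 1e4}
        ))
        return ss, ds

    def test_hand_traced_greedy_result(self):
        ss, ds = self._ld_fixture()
        out = prs.clump(ss, ds)
        assert list(out["id"]) == ["A", "C"]

    def test_zero_ld_keeps_everything(self):
        rng = np.random.default_rng(31)
        ds = binomial_genotypes(rng, 300, rng.uniform(0.2, 0.5, 8))
        ss = SummaryStatsTable(pd.DataFrame(
            {"id": ds.variants["id"], "chrom": "1", "pos": ds.variants["pos"],
             "ea": "A", "nea": "G", "eaf": 0.3, "beta": 0.1, "se": 0.05,
             "p": rng.uniform(0.001, 0.9, 8), "n": 1e4}
        ))
        out = prs.clump(ss, ds)
        assert len(out) == 8

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            n, m = 80, 50
            base = rng.binomial(2, 0.35, size=(n, m)).astype(float)
            # create LD by copying random columns with noise
            for j in range(0, m, 3):
                src = rng.integers(0, m)
                mask = rng.random(n) < 0.25
                base[:, j] = np.where(mask, base[:, j], base[:, src])
            pos = np.sort(rng.integers(1, 2_000_000, m))
            variants = pd.DataFrame(
                {"id": [f"v{j}" for j in range(m)], "chrom": "1", "pos": pos,
                 "ea": "A", "nea": "G", "eaf": 0.35, "info": np.nan}
            )
            ds = GenotypeDataset([f"S{i}" for i in range(n)], variants,
                                 base.astype(np.float32))
            pvals = rng.uniform(1e-6, 1, m)
            ss = SummaryStatsTable(pd.DataFrame(
                {"id": variants["id"], "chrom": "1", "pos": pos, "ea": "A",
                 "nea": "G", "eaf": 0.35, "beta": 0.1, "se": 0.05,
                 "p": pvals, "n": 1e4}
            ))
            out = prs.clump(ss, ds, r2_max=0.1, window_kb=250)
            r2 = pairwise_r2_oracle(base)
            expect = greedy_select_oracle(
                pvals, variants["id"].to_numpy(), variants["chrom"].to_numpy(),
                pos.astype(float), r2, 0.1, 250_000.0,
            )
            assert sorted(out["id"]) == sorted(expect)

    def test_no_overlap_raises(self):
        ss, ds = self._ld_fixture()
        other = SummaryStatsTable(ss.table.assign(id=["X", "Y", "Z"]))
        with pytest.raises(ValidationError, match="overlap"):
            prs.clump(other, ds)


class TestScoreSamples:
    def test_hand_arithmetic(self):
        variants = pd.DataFrame(
            {"id": ["v0", "v1"], "chrom": "1", "pos": [1000, 2000],
             "ea": "A", "nea": "G", "eaf": [0.25, 0.5], "info": np.nan}
        )
        ds = GenotypeDataset(["s"], variants,
                             np.array([[1.0, 2.0]], dtype=np.float32))
        weights = pd.DataFrame({"id": ["v0", "v1"], "ea": "A", "nea": "G",
                                "weight": [0.2, -0.1], "p": np.nan})
        score = prs.score_samples(weights, ds)
        assert score["s"] == pytest.approx((1 * 0.2 + 2 * (-0.1)) / 2)

    def test_zero_dosages_and_zero_weights(self):
        variants = pd.DataFrame(
            {"id": ["v0", "v1"], "chrom": "1", "pos": [1000, 2000],
             "ea": "A", "nea": "G", "eaf": 0.3, "info": np.nan}
        )
        ds0 = GenotypeDataset(["s"], variants, np.zeros((1, 2), dtype=np.float32))
        w = pd.DataFrame({"id": ["v0", "v1"], "ea": "A", "nea": "G",
                          "weight": [0.5, 0.3], "p": np.nan})
        assert prs.score_samples(w, ds0)["s"] == 0.0
        rng = np.random.default_rng(0)
        ds = GenotypeDataset(["s"], variants,
                             rng.binomial(2, 0.4, (1, 2)).astype(np.float32))
        w0 = w.assign(weight=[0.0, 0.0])
        assert prs.score_samples(w0, ds)["s"] == 0.0

    def test_missing_dosage_uses_expected_count(self):
        variants = pd.DataFrame(
            {"id": ["v0"], "chrom": "1", "pos": [1000], "ea": "A", "nea": "G",
             "eaf": 0.3, "info": np.nan}
        )
        d = np.array([[np.nan], [2.0], [0.0], [1.0]], dtype=np.float32)
        ds = GenotypeDataset(list("abcd"), variants, d)
        w = pd.DataFrame({"id": ["v0"], "ea": "A", "nea": "G",
                          "weight": [1.0], "p": np.nan})
        score = prs.score_samples(w, ds)
        assert score["a"] == pytest.approx(2 * (3.0 / 6.0))  # 2 * in-sample EAF

    def test_empty_set_raises(self):
        ds = _target([("A", "G")])
        with pytest.raises(ValidationError, match="empty"):
            prs.score_samples(pd.DataFrame(columns=["id", "ea", "nea", "weight"]), ds)


class TestNagelkerke:
    FIX_Y = pd.Series([1, 0, 1, 1, 0, 0, 1, 0, 1, 0],
                      index=[f"S{i}" for i in range(10)], dtype=float)
    FIX_SCORE = pd.Series([0.8, -0.2, 0.5, 1.1, 0.0, 0.7, -0.3, 0.1, 0.9, -0.4],
                          index=[f"S{i}" for i in range(10)])

    def test_matches_hand_applied_formula(self):
        res = prs.nagelkerke_r2(self.FIX_Y, self.FIX_SCORE)
        y = self.FIX_Y.to_numpy()
        x_full = np.column_stack([np.ones(10), self.FIX_SCORE.to_numpy()])
        _, _, ll_full = newton_logistic(y, x_full)
        _, _, ll_null = newton_logistic(y, np.ones((10, 1)))
        assert res.r2_full == pytest.approx(
            nagelkerke_oracle(ll_full, ll_null, 10), abs=1e-8
        )
        assert res.r2_null == pytest.approx(
            nagelkerke_oracle(ll_null, ll_null, 10), abs=1e-8
        )
        # the displayed difference identity, at machine precision
        assert res.r2_final == res.r2_full - res.r2_null

    def test_constant_score_gives_zero_final(self):
        res = prs.nagelkerke_r2(self.FIX_Y, self.FIX_SCORE * 0 + 1.0)
        assert res.r2_final == 0.0
        assert np.isnan(res.p_assoc)

    def test_affine_rescaling_invariance(self):
        a = prs.nagelkerke_r2(self.FIX_Y, self.FIX_SCORE)
        b = prs.nagelkerke_r2(self.FIX_Y, 5.0 * self.FIX_SCORE + 3.0)
        assert a.r2_final == pytest.approx(b.r2_final, abs=1e-10)
        assert a.p_assoc == pytest.approx(b.p_assoc, abs=1e-10)

    def test_informative_score_detected(self):
        rng = np.random.default_rng(33)
        n = 2000
        liab = rng.normal(size=n)
        y = pd.Series((liab + 0.5 * rng.normal(size=n) > 0.8).astype(float),
                      index=[f"S{i}" for i in range(n)])
        score = pd.Series(liab, index=y.index)
        res = prs.nagelkerke_r2(y, score)
        assert res.r2_final > 0.1 and res.p_assoc < 1e-6


class TestSweepAndDownsample:
    @pytest.fixture(scope="class")
    def study_bits(self, small_study):
        return small_study

    def test_threshold_nesting_and_vacuous_threshold(self, study_bits):
        sweep = prs.threshold_sweep(
            study_bits.sumstats2, study_bits.genotypes, study_bits.phenotypes,
            "T2D", "CONTROL",
        )
        n = sweep["n_variants"].to_numpy()
        assert (np.diff(n) >= 0).all()
        clumped = prs.clump(study_bits.sumstats2, study_bits.genotypes)
        matched, _ = prs.match_alleles(clumped, study_bits.genotypes)
        assert n[-1] == len(matched)  # P_t = 1 includes every clumped variant
        empty = sweep[sweep["n_variants"] == 0]
        assert np.isnan(empty["r2_final"]).all()

    def test_downsample_degenerate_identity(self, study_bits):
        clumped = prs.clump(study_bits.sumstats2, study_bits.genotypes)
        weights = clumped.head(15)
        full = prs.prs_analysis(weights, study_bits.genotypes,
                                study_bits.phenotypes, "T2D", "SCZ")
        n_t2d = len(study_bits.phenotypes.group("T2D"))
        n_scz = len(study_bits.phenotypes.group("SCZ"))
        assert n_t2d == n_scz  # degenerate resampling needs equal groups
        down = prs.downsample_analysis(
            weights, study_bits.genotypes, study_bits.phenotypes,
            "T2D", "SCZ", n_per_group=n_t2d, reps=1, seed=5,
        )
        assert down["mean_r2_final"] == pytest.approx(full.r2_final, abs=1e-10)
        assert down["mean_p"] == pytest.approx(full.p_assoc, abs=1e-10)

    def test_permissive_thresholds_gain_power_when_per_variant_power_is_low(self):
        # with weak base-study power, few causals reach genome-wide
        # significance and the permissive-threshold score explains more
        from .conftest import tiny_spec
        from comorbigen.synthetic_data import simulate_study

        spec = tiny_spec(sumstats_scale=0.2, n_trait1=100, n_trait2=100,
                         n_comorbid=60, n_control=150, n_variants=600,
                         n_blocks=12, m1=60, m2=60, m12=30, effect_sd=0.05)
        st = simulate_study(spec)
        sweep = prs.threshold_sweep(
            st.sumstats2, st.genotypes, st.phenotypes, "T2D", "CONTROL",
            thresholds=(5e-8, 0.05),
        ).set_index("p_t")
        assert sweep.loc[0.05, "r2_final"] > sweep.loc[5e-8, "r2_final"]

    def test_downsample_deterministic_and_near_full_sample(self, study_bits):
        clumped = prs.clump(study_bits.sumstats2, study_bits.genotypes)
        weights = clumped.head(15)
        kw = dict(n_per_group=20, reps=40, seed=11)
        a = prs.downsample_analysis(weights, study_bits.genotypes,
                                    study_bits.phenotypes, "T2D", "CONTROL", **kw)
        b = prs.downsample_analysis(weights, study_bits.genotypes,
                                    study_bits.phenotypes, "T2D", "CONTROL", **kw)
        assert a == b
        too_small = dict(kw, n_per_group=10_000)
        with pytest.raises(ValidationError, match="n_per_group"):
            prs.downsample_analysis(weights, study_bits.genotypes,
                                    study_bits.phenotypes, "T2D", "CONTROL",
                                    **too_small)


class TestFlipInvariance:
    def test_scores_shift_by_constant_and_r2_identical(self, small_study):
        ds = small_study.genotypes
        clumped = prs.clump(small_study.sumstats2, ds)
        weights = clumped.head(20)
        flipped = GenotypeDataset(
            ds.samples,
            ds.variants.rename(columns={"ea": "nea", "nea": "ea"})[
                ["id", "chrom", "pos", "ea", "nea", "eaf", "info"]
            ].assign(eaf=1 - ds.variants["eaf"]),
            2.0 - ds.dosages,
        )
        m1, _ = prs.match_alleles(weights, ds)
        m2, _ = prs.match_alleles(weights, flipped)
        s1 = prs.score_samples(m1, ds)
        s2 = prs.score_samples(m2, flipped)
        shift = s1 - s2
        assert shift.std() == pytest.approx(0.0, abs=1e-6)
        a = prs.prs_analysis(weights, ds, small_study.phenotypes,
                             "T2D", "CONTROL")
        b = prs.prs_analysis(weights, flipped, small_study.phenotypes,
                             "T2D", "CONTROL")
        assert a.r2_final == pytest.approx(b.r2_final, abs=1e-10)
        assert a.p_assoc == pytest.approx(b.p_assoc, abs=1e-10)
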