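import numpy as np
import pandas as pd
import pytest

from comorbigen import qc
from comorbigen.datatypes import GenotypeDataset, ValidationError

from .conftest import binomial_genotypes
from .oracles import hwe_exact_p_oracle


class TestHweExact:
    def test_monomorphic_p_is_one(self):
        assert qc.hwe_exact_p(20, 0, 0) == 1.0
        assert qc.hwe_exact_p(0, 0, 20) == 1.0

    def test_modal_het_count_gives_one(self):
        # 50 hets with 50/50 allele split is the modal outcome
        assert qc.hwe_exact_p(25, 50, 25) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts", [(3, 4, 3), (10, 2, 8), (0, 10, 0), (7, 1, 1), (1, 1, 7)]
    )
    def test_matches_exact_rational_enumeration(self, counts):
        assert qc.hwe_exact_p(*counts) == pytest.approx(
            hwe_exact_p_oracle(*counts), rel=1e-12
        )

    def test_invalid_counts_raise(self):
        with pytest.raises(ValidationError):
            qc.hwe_exact_p(-1, 0, 3)
        with pytest.raises(ValidationError):
            qc.hwe_exact_p(0, 0, 0)


class TestPihat:
    def test_identical_samples_are_fully_related(self):
        rng = np.random.default_rng(0)
        ds = binomial_genotypes(rng, 40, rng.uniform(0.1, 0.5, 500))
        dup = GenotypeDataset(
            ds.samples + ["dup"], ds.variants.copy(),
            np.vstack([ds.dosages, ds.dosages[0]]),
        )
        est = qc.pihat(dup, ("S0", "dup"))
        assert est.pihat == pytest.approx(1.0, abs=0.02)

    def test_unrelated_pair_near_zero(self):
        rng = np.random.default_rng(1)
        ds = binomial_genotypes(rng, 60, rng.uniform(0.1, 0.5, 5000))
        est = qc.pihat(ds, ("S0", "S1"))
        assert abs(est.pihat) <= 0.05

    def test_parent_offspring_near_half(self):
        rng = np.random.default_rng(2)
        m = 5000
        maf = rng.uniform(0.1, 0.5, m)
        background = rng.binomial(2, maf[None, :], size=(60, m)).astype(float)
        father = rng.binomial(2, maf)
        mother = rng.binomial(2, maf)

        def transmit(g):
            return np.where(g == 0, 0, np.where(g == 2, 1, rng.integers(0, 2, m)))

        child = transmit(father) + transmit(mother)
        dos = np.vstack([background, father, mother, child]).astype(np.float32)
        samples = [f"S{i}" for i in range(60)] + ["father", "mother", "child"]
        base = binomial_genotypes(rng, 1, maf)  # reuse variant frame layout
        ds = GenotypeDataset(samples, base.variants.copy(), dos)
        assert qc.pihat(ds, ("father", "child")).pihat == pytest.approx(0.5, abs=0.05)
        assert qc.pihat(ds, ("mother", "child")).pihat == pytest.approx(0.5, abs=0.05)
        assert abs(qc.pihat(ds, ("father", "mother")).pihat) <= 0.05

    def test_symmetric_and_variant_order_invariant(self):
        rng = np.random.default_rng(3)
        ds = binomial_genotypes(rng, 30, rng.uniform(0.1, 0.5, 600))
        a = qc.pihat(ds, ("S3", "S7")).pihat
        b = qc.pihat(ds, ("S7", "S3")).pihat
        perm = rng.permutation(ds.n_variants)
        shuffled = GenotypeDataset(
            ds.samples, ds.variants.iloc[perm].reset_index(drop=True),
            ds.dosages[:, perm],
        )
        c = qc.pihat(shuffled, ("S3", "S7")).pihat
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-9)

    def test_too_few_joint_variants_raise(self):
        rng = np.random.default_rng(4)
        ds = binomial_genotypes(rng, 10, rng.uniform(0.2, 0.5, 50))
        with pytest.raises(ValidationError, match="jointly observed"):
            qc.pihat(ds, ("S0", "S1"))


class TestSampleQc:
    def test_low_call_rate_sample_removed(self):
        rng = np.random.default_rng(5)
        ds = binomial_genotypes(rng, 30, rng.uniform(0.2, 0.5, 400))
        d = ds.dosages.copy()
        d[0, : int(400 * 0.15)] = np.nan  # 85% call rate
        bad = GenotypeDataset(ds.samples, ds.variants.copy(), d)
        report = qc.sample_qc(bad)
        assert report.sample_reasons().get("S0") == "low_call_rate"
        assert len(report.removed_samples) == 1

    def test_duplicate_pair_loses_exactly_one(self):
        rng = np.random.default_rng(6)
        ds = binomial_genotypes(rng, 40, rng.uniform(0.2, 0.5, 600))
        d = np.vstack([ds.dosages, ds.dosages[5]])
        dup = GenotypeDataset(ds.samples + ["zdup"], ds.variants.copy(), d)
        report = qc.sample_qc(dup)
        related = [s for s, r in report.removed_samples if r == "related"]
        assert related == ["zdup"]  # tie on call rate: later id dropped

    def test_planted_het_outlier_removed(self):
        rng = np.random.default_rng(7)
        ds = binomial_genotypes(rng, 100, rng.uniform(0.2, 0.5, 2000))
        d = ds.dosages.copy()
        d[3, :] = 1.0  # heterozygous everywhere: far beyond +3 SD
        planted = GenotypeDataset(ds.samples, ds.variants.copy(), d)
        report = qc.sample_qc(planted)
        assert report.sample_reasons().get("S3") == "het_outlier"
        others = [s for s, r in report.removed_samples if s != "S3"]
        assert others == []

    def test_idempotent_on_survivors(self):
        rng = np.random.default_rng(8)
        ds = binomial_genotypes(rng, 60, rng.uniform(0.2, 0.5, 800))
        d = ds.dosages.copy()
        d[0, :700] = np.nan
        d[1] = d[2]  # related pair
        noisy = GenotypeDataset(ds.samples, ds.variants.copy(), d)
        first = qc.sample_qc(noisy)
        survivors = noisy.subset(samples=first.kept_samples)
        second = qc.sample_qc(survivors)
        assert second.removed_samples == []

    def test_all_removed_raises(self):
        variants = pd.DataFrame(
            {"id": [f"v{i}" for i in range(200)], "chrom": "1",
             "pos": np.arange(1, 201), "ea": "A", "nea": "G",
             "eaf": 0.3, "info": np.nan}
        )
        d = np.full((2, 200), np.nan, dtype=np.float32)
        ds = GenotypeDataset(["a", "b"], variants, d)
        with pytest.raises(ValidationError):
            qc.sample_qc(ds)


class TestVariantQc:
    def _with_column(self, base, col_values, **meta):
        ds = base
        d = ds.dosages.copy()
        d[:, 0] = col_values
        v = ds.variants.copy()
        for k, val in meta.items():
            v.loc[0, k] = val
        return GenotypeDataset(ds.samples, v, d)

    def test_reason_codes(self):
        rng = np.random.default_rng(9)
        ds = binomial_genotypes(rng, 100, np.full(5, 0.4))
        v = ds.variants.copy()
        d = ds.dosages.copy()
        d[:3, 0] = np.nan          # 97% call rate
        d[:, 1] = 0.0              # monomorphic
        v.loc[2, "info"] = 0.3     # below 0.4
        # column 3: gross heterozygote deficit -> HWE failure
        d[:, 3] = np.r_[np.zeros(50), np.full(50, 2.0)].astype(np.float32)
        ds2 = GenotypeDataset(ds.samples, v, d)
        report = qc.variant_qc(ds2)
        reasons = report.variant_reasons()
        assert reasons["v0"] == ("low_call_rate",)
        assert reasons["v1"] == ("low_maf",)
        assert reasons["v2"] == ("low_info",)
        assert "hwe_fail" in reasons["v3"]
        assert "v4" in report.kept_variants

    def test_hwe_boundary_from_enumeration(self):
        # find genotype counts whose exact p sits just below the threshold
        counts = None
        for het in range(0, 30):
            p = hwe_exact_p_oracle(40, het, 40)
            if p < 1e-4:
                counts = (40, het, 40, p)
        n_aa, het, n_bb, p = counts
        assert p < 1e-4
        col = np.r_[np.zeros(n_aa), np.ones(het), np.full(n_bb, 2.0)]
        rng = np.random.default_rng(10)
        ds = binomial_genotypes(rng, len(col), np.full(3, 0.5))
        d = ds.dosages.copy()
        d[:, 0] = col
        ds2 = GenotypeDataset(ds.samples, ds.variants.copy(), d)
        report = qc.variant_qc(ds2)
        assert "hwe_fail" in report.variant_reasons()["v0"]

    def test_idempotent_on_survivors(self, small_study):
        sub = small_study.genotypes.subset(
            samples=small_study.genotypes.samples[:150]
        )
        first = qc.variant_qc(sub)
        keep = sub.variants["id"].isin(first.kept_variants).to_numpy()
        survivors = sub.subset(variant_mask=keep)
        second = qc.variant_qc(survivors)
        assert second.removed_variants == []


class TestMds:
    def test_exact_euclidean_configuration_recovered(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = qc.classical_mds(d, k=2)
        back = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(back, d, atol=1e-10)

    def test_top_component_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(20, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = qc.classical_mds(d, k=3)
        # MDS coordinate variance equals the eigenvalue / n, in order
        variances = coords.var(axis=0)
        assert variances[0] >= variances[1] >= variances[2]
        centred = pts - pts.mean(0)
        top_pc = np.linalg.svd(centred)[0][:, 0] * np.linalg.svd(centred)[1][0]
        r = abs(np.corrcoef(coords[:, 0], top_pc)[0, 1])
        assert r > 1 - 1e-9

    def test_two_clusters_separate_on_first_component(self):
        rng = np.random.default_rng(12)
        m = 400
        maf_a = rng.uniform(0.05, 0.5, m)
        shift = np.where(maf_a < 0.3, 0.35, -0.25)
        maf_b = np.clip(maf_a + shift, 0.02, 0.98)
        a = binomial_genotypes(rng, 40, maf_a, prefix="A")
        b_dos = rng.binomial(2, maf_b[None, :], size=(40, m)).astype(np.float32)
        merged = GenotypeDataset(
            a.samples + [f"B{i}" for i in range(40)],
            a.variants.copy(),
            np.vstack([a.dosages, b_dos]),
        )
        comps = qc.mds_components(merged, k=2)
        label = np.r_[np.zeros(40), np.ones(40)]
        r = np.corrcoef(comps["C1"], label)[0, 1]
        assert abs(r) > 0.9

    def test_identical_samples_have_zero_distance(self):
        rng = np.random.default_rng(13)
        ds = binomial_genotypes(rng, 10, rng.uniform(0.2, 0.5, 300))
        d = np.vstack([ds.dosages, ds.dosages[0]])
        dup = GenotypeDataset(ds.samples + ["dup"], ds.variants.copy(), d)
        dist = qc.ibs_distance_matrix(dup)
        assert dist[0, -1] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_distances_raise(self):
        variants = pd.DataFrame(
            {"id": ["v0", "v1"], "chrom": "1", "pos": [1, 2], "ea": "A",
             "nea": "G", "eaf": 0.5, "info": np.nan}
        )
        d = np.ones((4, 2), dtype=np.float32)
        ds = GenotypeDataset(list("abcd"), variants, d)
        with pytest.raises(ValidationError, match="degenerate"):
            qc.mds_components(ds, k=2)

    def test_k_too_large_raises(self):
        rng = np.random.default_rng(14)
        ds = binomial_genotypes(rng, 5, rng.uniform(0.2, 0.5, 100))
        with pytest.raises(ValidationError):
            qc.mds_components(ds, k=5)


class TestMdsOutliers:
    def test_homogeneous_sample_rarely_flags(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            ds = binomial_genotypes(rng, 25, rng.uniform(0.1, 0.5, 300))
            comps = qc.mds_components(ds, k=2)
            hits += int(len(qc.mds_outlier_filter(comps, sd=3.0)) > 0)
        assert hits <= 2  # zero outliers in >= 18/20 homogeneous panels

    def test_planted_divergent_sample_flagged(self):
        rng = np.random.default_rng(15)
        m = 400
        maf = rng.uniform(0.05, 0.45, m)
        ds = binomial_genotypes(rng, 60, maf)
        alien = rng.binomial(2, np.clip(1.0 - maf, 0.02, 0.98)).astype(np.float32)
        merged = GenotypeDataset(
            ds.samples + ["alien"], ds.variants.copy(),
            np.vstack([ds.dosages, alien]),
        )
        comps = qc.mds_components(merged, k=2)
        flagged = dict(qc.mds_outlier_filter(comps, sd=3.0))
        assert "alien" in flagged

    def test_infinite_sd_flags_nothing(self):
        rng = np.random.default_rng(16)
        ds = binomial_genotypes(rng, 30, rng.uniform(0.2, 0.5, 200))
        comps = qc.mds_components(ds, k=2)
        assert qc.mds_outlier_filter(comps, sd=np.inf) == []
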