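"""Permutation enrichment z-scores and region-level PCA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stemmeth as sm
from stemmeth.comparative_stats import cell_seed
from stemmeth.io_formats import DMRSet

from conftest import make_sample


@pytest.fixture(scope="module")
def template(planted):
    _, truth = planted
    return truth


class TestRegionMethylationDifference:
    def test_identical_samples_zero(self, sample_pair, template):
        a, _ = sample_pair
        stat, n = sm.region_methylation_difference(template, a, a, "CHG", min_cov=4)
        assert stat == 0.0 and n > 0

    def test_recovers_planted_shift(self, sample_pair, template):
        a, b = sample_pair
        stat, n = sm.region_methylation_difference(template, a, b, "CHG", min_cov=4)
        assert stat == pytest.approx(0.4, abs=0.08)

    def test_matches_naive_per_cytosine_loop(self, sample_pair, template):
        a, b = sample_pair
        stat, n = sm.region_methylation_difference(template, a, b, "CHG", min_cov=4)
        # independent slow oracle
        merged = a.records.merge(
            b.records, on=["chrom", "pos", "strand"], suffixes=("_a", "_b")
        )
        merged = merged[merged["context_a"] == "CHG"]
        cov_a = merged["n_meth_a"] + merged["n_unmeth_a"]
        cov_b = merged["n_meth_b"] + merged["n_unmeth_b"]
        merged = merged[(cov_a >= 4) & (cov_b >= 4)]
        diffs = []
        for row in merged.itertuples(index=False):
            for r in template.regions.itertuples(index=False):
                if row.chrom == r.chrom and r.start < row.pos <= r.end:
                    diffs.append(
                        row.n_meth_b / (row.n_meth_b + row.n_unmeth_b)
                        - row.n_meth_a / (row.n_meth_a + row.n_unmeth_a)
                    )
                    break
        assert n == len(diffs)
        assert stat == pytest.approx(np.mean(diffs), abs=1e-12)

    def test_no_qualifying_cytosines_flagged(self, sample_pair):
        a, b = sample_pair
        far = DMRSet(
            regions=pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [100]})
        )
        stat, n = sm.region_methylation_difference(far, a, b, "CHG")
        assert np.isnan(stat) and n == 0


class TestSampleMatchedRegions:
    def test_lengths_and_count_match_template(self, genome, template):
        sets = sm.sample_matched_regions(genome, template, n_perm=5, seed=1)
        tlen = sorted(template.regions["end"] - template.regions["start"])
        for s in sets:
            assert len(s) == len(template)
            assert sorted(s.regions["end"] - s.regions["start"]) == tlen

    def test_deterministic_under_seed(self, genome, template):
        s1 = sm.sample_matched_regions(genome, template, 3, seed=9)
        s2 = sm.sample_matched_regions(genome, template, 3, seed=9)
        for x, y in zip(s1, s2):
            pd.testing.assert_frame_equal(x.regions, y.regions)

    def test_control_contig_excluded(self, genome, template):
        sets = sm.sample_matched_regions(genome, template, 20, seed=2)
        for s in sets:
            assert (s.regions["chrom"] != genome.control_contig).all()

    def test_placement_matches_genomic_te_fraction(self, genome, template):
        """Uniform placement: expected TE-bp overlap equals the genomic
        TE-bp fraction."""
        te_bp = sum(f.length for f in genome.features if f.kind == "TE")
        genome_bp = sum(genome.chrom_lengths[c] for c in genome.nuclear_chroms)
        expected = te_bp / genome_bp
        sets = sm.sample_matched_regions(genome, template, 300, seed=3)
        te_iv = {}
        for f in genome.features:
            if f.kind == "TE":
                te_iv.setdefault(f.chrom, []).append((f.start, f.end))
        overlap = total = 0
        for s in sets:
            for r in s.regions.itertuples(index=False):
                total += r.end - r.start
                for lo, hi in te_iv.get(r.chrom, ()):
                    overlap += max(0, min(hi, r.end) - max(lo, r.start))
        frac = overlap / total
        # binomial-ish spread over region draws
        assert frac == pytest.approx(expected, abs=0.03)

    def test_oversized_region_rejected(self, genome):
        big = DMRSet(
            regions=pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [10_000_000]}
            )
        )
        with pytest.raises(ValueError, match="longer than every chromosome"):
            sm.sample_matched_regions(genome, big, 2, seed=1)


class TestPermutationZscore:
    def test_planted_enrichment_strong_positive(self, genome, sample_pair, template):
        a, b = sample_pair
        res = sm.permutation_zscore(template, a, b, "CHG", genome, n_perm=200, seed=4)
        assert res.z >= 3
        assert res.observed_stat > 0
        assert res.n_perm_used == 200

    def test_swap_antisymmetry_exact(self, genome, sample_pair, template):
        a, b = sample_pair
        r1 = sm.permutation_zscore(template, a, b, "CHG", genome, n_perm=100, seed=5)
        r2 = sm.permutation_zscore(template, b, a, "CHG", genome, n_perm=100, seed=5)
        assert r1.observed_stat == -r2.observed_stat
        assert r1.z == pytest.approx(-r2.z, abs=1e-9)

    def test_invariant_to_region_order(self, genome, sample_pair, template):
        a, b = sample_pair
        shuffled = DMRSet(
            regions=template.regions.sample(frac=1, random_state=0).reset_index(drop=True),
            set_id=template.set_id,
        )
        r1 = sm.permutation_zscore(template, a, b, "CHG", genome, n_perm=50, seed=6)
        r2 = sm.permutation_zscore(shuffled, a, b, "CHG", genome, n_perm=50, seed=6)
        assert r1.z == pytest.approx(r2.z, abs=1e-12)

    def test_untouched_context_modest_z(self, genome, sample_pair, template):
        """Regions planted in CHG only: the CHH contrast shows no signal."""
        a, b = sample_pair
        res = sm.permutation_zscore(template, a, b, "CHH", genome, n_perm=200, seed=7)
        assert abs(res.z) <= 3


class TestEnrichmentMatrix:
    def test_cell_matches_standalone_call(self, genome, sample_pair, template):
        a, b = sample_pair
        sets = {"planted": template}
        mat = sm.enrichment_matrix(
            sets, [("D7", a, b)], ["CHG"], genome, n_perm=60, seed=8
        )
        standalone = sm.permutation_zscore(
            template, a, b, "CHG", genome, n_perm=60,
            seed=cell_seed(8, "planted", "D7", "CHG"),
        )
        assert mat.loc["planted", ("D7", "CHG")] == pytest.approx(standalone.z, abs=1e-12)

    def test_identical_pair_gives_near_zero_or_nan(self, genome, sample_pair, template):
        a, _ = sample_pair
        mat = sm.enrichment_matrix(
            {"planted": template}, [("self", a, a)], ["CHG"], genome, n_perm=30, seed=9
        )
        v = mat.loc["planted", ("self", "CHG")]
        # all per-cytosine diffs are exactly 0, so sd = 0 -> NaN by contract
        assert np.isnan(v)

    def test_failures_propagate_as_nan(self, genome, sample_pair):
        a, b = sample_pair
        bad = DMRSet(
            regions=pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [50]}),
            set_id="bad",
        )
        mat = sm.enrichment_matrix(
            {"bad": bad}, [("D7", a, b)], ["CHG"], genome, n_perm=10, seed=10
        )
        assert np.isnan(mat.loc["bad", ("D7", "CHG")])


class TestRegionFeatureMatrix:
    def test_identical_samples_equal_columns(self, sample_pair, template):
        a, _ = sample_pair
        a2 = sm.MethylomeSample(
            sample_id="copy", stage=a.stage, fraction=a.fraction,
            records=a.records.copy(), genome_id=a.genome_id,
        )
        mat = sm.assemble_region_feature_matrix([a, a2], template, "CHG", min_cov=4)
        assert np.allclose(mat["nonstem"], mat["copy"], equal_nan=True)

    def test_undercovered_region_dropped_everywhere(self, sample_pair, template):
        a, b = sample_pair
        # remove all records of one region from sample b
        r = template.regions.iloc[0]
        keep = ~(
            (b.records["chrom"] == r["chrom"])
            & (b.records["pos"] > r["start"])
            & (b.records["pos"] <= r["end"])
        )
        b2 = sm.MethylomeSample(
            sample_id="gappy", stage=b.stage, fraction=b.fraction,
            records=b.records[keep].reset_index(drop=True),
        )
        mat = sm.assemble_region_feature_matrix([a, b2], template, "CHG", min_cov=4)
        assert f"{r['chrom']}:{r['start']}-{r['end']}" not in mat.index

    def test_entries_match_weighted_level_oracle(self, sample_pair, template):
        a, b = sample_pair
        mat = sm.assemble_region_feature_matrix([a, b], template, "CHG", min_cov=4)
        for region in mat.index[:3]:
            chrom, span = region.split(":")
            start, end = map(int, span.split("-"))
            sub = a.records[
                (a.records["chrom"] == chrom)
                & (a.records["pos"] > start)
                & (a.records["pos"] <= end)
            ]
            expected = sm.weighted_level(sub, "CHG").level
            assert mat.loc[region, "nonstem"] == pytest.approx(expected, abs=1e-12)

    def test_too_few_regions_raises(self, sample_pair):
        a, b = sample_pair
        rs = DMRSet(regions=pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [99]}))
        with pytest.raises(ValueError, match=">= 3"):
            sm.assemble_region_feature_matrix([a, b], rs, "CHG")


class TestPCA:
    def _toy(self):
        rng = np.random.default_rng(12)
        return pd.DataFrame(
            rng.random((5, 4)), index=[f"r{i}" for i in range(5)],
            columns=["s1", "s2", "s3", "s4"],
        )

    def test_duplicate_samples_coincide(self):
        m = self._toy()
        m["s4"] = m["s1"]
        res = sm.pca(m)
        d = np.linalg.norm(res.coordinates.loc["s1"] - res.coordinates.loc["s4"])
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_two_samples_rank_one(self):
        m = self._toy()[["s1", "s2"]]
        res = sm.pca(m)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        m = self._toy()
        res = sm.pca(m)
        x = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        cov = x.T @ x
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for k in range(3):
            expected = v[:, k] * np.sqrt(w[k])
            got = res.coordinates.iloc[:, k].to_numpy()
            assert np.allclose(got, expected, atol=1e-8) or np.allclose(
                got, -expected, atol=1e-8
            )

    def test_full_rank_isometry(self):
        m = self._toy()
        res = sm.pca(m)
        x = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        for i in range(4):
            for j in range(i + 1, 4):
                d_orig = np.linalg.norm(x[:, i] - x[:, j])
                d_pc = np.linalg.norm(
                    res.coordinates.iloc[i] - res.coordinates.iloc[j]
                )
                assert d_pc == pytest.approx(d_orig, abs=1e-8)

    def test_constant_matrix_degenerates_to_zero(self):
        m = pd.DataFrame(np.full((4, 3), 0.5), columns=["a", "b", "c"])
        res = sm.pca(m)
        assert np.all(res.explained_variance_ratio == 0)
        assert np.all(res.coordinates.to_numpy() == 0)


class TestConvergenceDistance:
    def test_reference_to_itself_zero_and_sorted(self):
        coords = pd.DataFrame(
            {"PC1": [0.0, 1.0, 3.0], "PC2": [0.0, 1.0, 0.0]},
            index=["ref", "q1", "q2"],
        )
        res = sm.PCAResult(coords, np.array([0.8, 0.2]), n_features=10)
        d = sm.convergence_distance(res, "ref", ["ref", "q1", "q2"])
        assert d["ref"] == 0.0
        assert list(d.index) == ["ref", "q1", "q2"]
        assert d["q1"] == pytest.approx(np.sqrt(2))

    def test_invariant_to_axis_sign_flip(self):
        coords = pd.DataFrame(
            {"PC1": [0.0, 1.0, 3.0], "PC2": [0.5, 1.0, -1.0]},
            index=["ref", "q1", "q2"],
        )
        flipped = coords.copy()
        flipped["PC1"] *= -1
        r1 = sm.PCAResult(coords, np.array([0.8, 0.2]), 10)
        r2 = sm.PCAResult(flipped, np.array([0.8, 0.2]), 10)
        d1 = sm.convergence_distance(r1, "ref", ["q1", "q2"])
        d2 = sm.convergence_distance(r2, "ref", ["q1", "q2"])
        pd.testing.assert_series_equal(d1, d2)

    def test_unknown_sample_rejected(self):
        coords = pd.DataFrame({"PC1": [0.0]}, index=["ref"])
        res = sm.PCAResult(coords, np.array([1.0]), 5)
        with pytest.raises(KeyError):
            sm.convergence_distance(res, "ref", ["nope"])

    def test_planted_monotone_convergence(self, genome, base_methylome):
        """Samples interpolated toward a reference methylome move
        monotonically closer in PC space."""
        ref_meth, truth = sm.plant_dmrs(
            base_methylome, 10, (400, 800), 0.5, "CHH", seed=31, label="ref"
        )
        fracs = {"far": 0.0, "mid": 0.5, "near": 0.9}
        samples = []
        for name, w in fracs.items():
            interp = base_methylome.copy(label=name)
            for chrom in interp.per_chrom:
                pa = base_methylome.per_chrom[chrom]["p"].to_numpy()
                pb = ref_meth.per_chrom[chrom]["p"].to_numpy()
                interp.per_chrom[chrom]["p"] = (1 - w) * pa + w * pb
            samples.append(
                sm.sample_counts(interp, 40.0, 0.0, seed=32, sample_id=name, fraction="stem")
            )
        samples.append(
            sm.sample_counts(ref_meth, 40.0, 0.0, seed=33, sample_id="ref", fraction="seedling")
        )
        mat = sm.assemble_region_feature_matrix(samples, truth, "CHH", min_cov=4)
        res = sm.pca(mat)
        d = sm.convergence_distance(res, "ref", ["far", "mid", "near"])
        assert d["near"] < d["mid"] < d["far"]
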