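"""Kinship, SNP/gene-level association, pooling and MAF clines."""

import warnings

import numpy as np
import pandas as pd
import pytest

from rootclines.errors import ConfigError, DataError
from rootclines.assoc import (
    cluster_maf_profile,
    compute_kinship,
    gene_level_test,
    make_design,
    pool_candidates,
    snp_association,
)
from rootclines.io_formats import GenotypeMatrix, SnpGeneMap


def two_deme_panel(rng, n_per=60, m=400, fst=0.2):
    """Balding-Nichols two-deme panel (planted structure)."""
    a = (1 - fst) / fst
    p_anc = rng.uniform(0.1, 0.9, m)
    freqs = rng.beta(p_anc[:, None] * a, (1 - p_anc)[:, None] * a, size=(m, 2))
    deme = np.repeat([0, 1], n_per)
    dosage = rng.binomial(2, freqs[:, deme]).T.astype(float)
    keep = np.minimum(dosage.mean(0) / 2, 1 - dosage.mean(0) / 2) > 0.01
    dosage = dosage[:, keep]
    m = dosage.shape[1]
    gm = GenotypeMatrix(
        accessions=[f"a{i:03d}" for i in range(2 * n_per)],
        snp_ids=np.array([f"S1_{1000 * (j + 1)}" for j in range(m)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1) * 1000,
        dosage=dosage)
    return gm, deme


class TestKinship:
    def test_grm_trace_near_n(self, rng):
        gm, _ = two_deme_panel(rng)
        kin = compute_kinship(gm)
        assert np.trace(kin.grm) / gm.n_accessions == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(kin.eigenvalues) <= 1e-9)

    def test_leading_eigenvector_separates_demes(self, rng):
        gm, deme = two_deme_panel(rng)
        kin = compute_kinship(gm)
        r = np.corrcoef(kin.eigenvectors[:, 0], deme)[0, 1]
        assert abs(r) > 0.9

    def test_identical_genotypes_warn(self):
        dosage = np.tile([1.0, 0.0, 2.0, 1.0], (10, 1))
        gm = GenotypeMatrix(accessions=[f"a{i}" for i in range(10)],
                            snp_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
                            chrom=np.array(["1"] * 4, dtype=object),
                            pos=np.array([100, 200, 300, 400]),
                            dosage=dosage)
        with pytest.raises(DataError):
            compute_kinship(gm)


class TestSnpAssociation:
    def test_planted_effect_detected(self, rng):
        ps = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            gm, deme = two_deme_panel(r, n_per=200, m=50)
            g = gm.dosage[:, 7]
            gz = (g - g.mean()) / g.std()
            y = np.sqrt(0.05) * gz + np.sqrt(0.95) * r.normal(size=len(g))
            kin = compute_kinship(gm)
            stats_df = snp_association(make_design(y, kin), gm)
            ps.append(stats_df["p"].iloc[7])
        assert np.median(ps) < 1e-3

    def test_type_one_calibration_on_permuted_response(self, rng):
        gm, _ = two_deme_panel(rng, n_per=100, m=2000, fst=0.1)
        kin = compute_kinship(gm)
        y = rng.normal(size=gm.n_accessions)
        stats_df = snp_association(make_design(y, kin), gm)
        frac = (stats_df["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_treatment_coding_validated(self, rng):
        gm, _ = two_deme_panel(rng, n_per=20, m=30)
        y = rng.normal(size=40)
        with pytest.raises(ConfigError, match="-1/\\+1"):
            make_design(y, treatment=np.zeros(40))

    def test_interaction_terms_reported(self, rng):
        gm, _ = two_deme_panel(rng, n_per=100, m=40)
        n = gm.n_accessions
        t = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        j = int(np.argmax(gm.dosage.var(axis=0)))  # a common SNP
        g = gm.dosage[:, j]
        y = 1.0 * g * t + rng.normal(size=n)
        design = make_design(y, treatment=t)
        out = snp_association(design, gm)
        assert {"p", "p_gxe"} <= set(out.columns)
        assert out["p_gxe"].iloc[j] < 1e-6
        assert (out["p_gxe"].drop(index=j) > 1e-6).mean() > 0.9

    def test_collinear_snp_flagged(self, rng):
        gm, _ = two_deme_panel(rng, n_per=20, m=10)
        gm.dosage[:, 0] = 1.0  # constant after centering
        y = rng.normal(size=40)
        out = snp_association(make_design(y), gm)
        assert out["flagged"].iloc[0]
        assert out["p"].iloc[0] == 1.0


class TestGeneTest:
    def _map(self, gm, groups):
        pairs = pd.DataFrame(
            [(s, g) for g, snps in groups.items() for s in snps],
            columns=["snp_id", "gene_id"])
        return SnpGeneMap(pairs=pairs, empty_genes=[])

    def test_single_snp_gene_equals_snp_wald(self, rng):
        gm, _ = two_deme_panel(rng, n_per=60, m=30)
        kin = compute_kinship(gm)
        y = rng.normal(size=gm.n_accessions)
        design = make_design(y, kin)
        snp_stats = snp_association(design, gm).set_index("snp_id")
        groups = {f"g{j}": [gm.snp_ids[j]] for j in range(10)}
        gt = gene_level_test(gm, design, self._map(gm, groups)).set_index("gene_id")
        for j in range(10):
            s = gm.snp_ids[j]
            assert gt.loc[f"g{j}", "p"] == pytest.approx(
                snp_stats.loc[s, "p"], rel=1e-10, abs=1e-300)
            assert gt.loc[f"g{j}", "F"] == pytest.approx(
                snp_stats.loc[s, "t"] ** 2, rel=1e-9)

    def test_perfect_ld_collapses_to_one_pc(self, rng):
        gm, _ = two_deme_panel(rng, n_per=40, m=20)
        gm.dosage[:, 1] = gm.dosage[:, 0]
        kin = compute_kinship(gm)
        y = rng.normal(size=gm.n_accessions)
        design = make_design(y, kin)
        one = gene_level_test(gm, design,
                              self._map(gm, {"gA": [gm.snp_ids[0]]}))
        two = gene_level_test(gm, design,
                              self._map(gm, {"gB": [gm.snp_ids[0], gm.snp_ids[1]]}))
        assert two["n_pcs"].iloc[0] == 1
        assert two["p"].iloc[0] == pytest.approx(one["p"].iloc[0], rel=1e-9)

    def test_rank_zero_block_flagged(self, rng):
        gm, _ = two_deme_panel(rng, n_per=30, m=10)
        gm.dosage[:, 2] = 1.0
        y = rng.normal(size=60)
        design = make_design(y)
        out = gene_level_test(gm, design, self._map(gm, {"gz": [gm.snp_ids[2]]}))
        assert out["flagged"].iloc[0] and out["p"].iloc[0] == 1.0


class TestPooling:
    def _table(self, genes, ps, analysis, trait):
        return pd.DataFrame({"gene_id": genes, "p": ps,
                             "analysis": analysis, "trait": trait})

    def test_identical_tables_full_overlap(self, rng):
        genes = [f"g{i:03d}" for i in range(150)]
        ps = rng.uniform(size=150)
        t1 = self._table(genes, ps, "prediction", "t")
        t2 = self._table(genes, ps, "environment", "e")
        sets, overlap = pool_candidates([t1, t2], k=100)
        assert overlap.counts.loc["prediction", "environment"] == 100
        assert overlap.row_percent.loc["prediction", "environment"] == 100.0

    def test_disjoint_rankings_no_overlap(self):
        genes = [f"g{i:03d}" for i in range(40)]
        p1 = np.concatenate([np.linspace(1e-6, 1e-3, 20), np.linspace(0.5, 1, 20)])
        p2 = p1[::-1].copy()
        t1 = self._table(genes, p1, "prediction", "t")
        t2 = self._table(genes, p2, "environment", "e")
        sets, overlap = pool_candidates([t1, t2], k=20)
        assert overlap.counts.loc["prediction", "environment"] == 0

    def test_restricted_to_shared_universe_and_ties_by_gene_id(self):
        t1 = self._table(["gB", "gA", "gC"], [0.5, 0.5, 0.5], "prediction", "t")
        t2 = self._table(["gA", "gB"], [0.1, 0.9], "environment", "e")
        sets, _ = pool_candidates([t1, t2], k=1)
        # universe = {gA, gB}; tie in t1 broken by gene id
        assert sets["prediction"].pooled == ["gA"]


class TestMafProfile:
    def test_planted_cline_recovered(self):
        # strong logistic cline over a weakly structured panel
        from rootclines.synthetic import SimConfig, simulate_study
        cfg = SimConfig(n_train=10, n_target=300, n_snps=400, n_genes=40,
                        n_causal_genes=4, fst=0.05, adaptive_shift=0.45,
                        trait_env_r2=0.4, trait_snp_h2=0.1, seed=2)
        s = simulate_study(cfg)
        gm = s.target_genotypes
        elev = s.truth.elevation.loc[gm.accessions]
        labels = pd.Series(pd.qcut(elev, 7, labels=False) + 1, index=gm.accessions)
        proj = pd.DataFrame({"NMV": s.truth.true_traits.set_index("accession")
                            .loc[gm.accessions, "NMV"]})
        prof = cluster_maf_profile(gm, labels, elev, proj, s.truth.causal_snps)
        rs = prof.correlations.query("reference == 'elevation'")["r"].abs()
        assert (rs > 0.8).all()

    def test_non_clinal_snp_small_correlation(self, small_study, rng):
        s = small_study
        gm = s.target_genotypes
        elev = s.truth.elevation.loc[gm.accessions]
        labels = pd.Series(rng.integers(1, 8, gm.n_accessions), index=gm.accessions)
        proj = pd.DataFrame({"NMV": np.ones(gm.n_accessions)}, index=gm.accessions)
        causal = set(s.truth.causal_snps)
        neutral = [x for x in gm.snp_ids if x not in causal][:10]
        prof = cluster_maf_profile(gm, labels, elev, proj, neutral)
        rs = prof.correlations.query("reference == 'elevation'")["r"].abs()
        assert rs.median() < 0.6

    def test_single_cluster_error(self, small_study):
        s = small_study
        gm = s.target_genotypes
        elev = s.truth.elevation.loc[gm.accessions]
        labels = pd.Series(1, index=gm.accessions)
        proj = pd.DataFrame({"NMV": np.ones(gm.n_accessions)}, index=gm.accessions)
        with pytest.raises(DataError):
            cluster_maf_profile(gm, labels, elev, proj, [gm.snp_ids[0]])

    def test_allele_flip_negates_correlation(self, small_study):
        s = small_study
        gm = s.target_genotypes
        elev = s.truth.elevation.loc[gm.accessions]
        labels = pd.Series(pd.qcut(elev, 5, labels=False) + 1, index=gm.accessions)
        proj = pd.DataFrame({"NMV": np.ones(gm.n_accessions)}, index=gm.accessions)
        snp = s.truth.causal_snps[0]
        prof1 = cluster_maf_profile(gm, labels, elev, proj, [snp])
        flipped = GenotypeMatrix(
            accessions=list(gm.accessions), snp_ids=gm.snp_ids.copy(),
            chrom=gm.chrom.copy(), pos=gm.pos.copy(), dosage=2.0 - gm.dosage)
        prof2 = cluster_maf_profile(flipped, labels, elev, proj, [snp])
        r1 = prof1.correlations.query("reference == 'elevation'")["r"].iloc[0]
        r2 = prof2.correlations.query("reference == 'elevation'")["r"].iloc[0]
        # complementing dosages relabels REF/ALT; the panel-wide minor
        # allele is redefined to the same physical allele, so the profile
        # is invariant
        assert r1 == pytest.approx(r2, abs=1e-9)
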