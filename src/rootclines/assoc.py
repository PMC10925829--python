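"""SNP- and gene-level association of projected traits, observed traits
(with treatment interaction) and environmental descriptors, plus candidate
pooling, overlap matrices, and cluster-level minor-allele-frequency clines.

Population structure is handled with fixed-effect covariates: the leading
eigenvectors of the genetic relationship matrix (GRM), computed from
column-centered, column-scaled dosages.  Gene-level tests follow the
multiple-regression aggregation idea: the gene's SNP block is residualized
on the covariates, reduced to principal components capturing a fixed share
of its variance (LD pruning), and tested jointly against the covariate-only
model with an F test.  For a single-SNP gene this reduces exactly to the
squared-t Wald test of that SNP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .io_formats import GenotypeMatrix, SnpGeneMap

logger = logging.getLogger(__name__)

DEFAULT_N_EIGENVECTORS = 5
DEFAULT_VAR_KEEP = 0.999
DEFAULT_TOP_K = 100
ANALYSIS_LABELS = ("prediction", "environment", "G", "GxE")


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class Kinship:
    grm: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # (n, n_eigen)
    accessions: list[str]


def compute_kinship(genos: GenotypeMatrix, n_eigen: int = DEFAULT_N_EIGENVECTORS) -> Kinship:
    """GRM = Z Z' / m with Z the centered, scaled dosage matrix.

    Monomorphic SNPs are excluded from the scaling.  Returns the leading
    ``n_eigen`` eigenvectors; fewer (with a warning) when the spectrum has
    fewer positive eigenvalues.
    """
    if genos.n_accessions < 2 or genos.n_snps < 2:
        raise DataError("kinship needs at least 2 accessions and 2 SNPs")
    G = genos.dosage
    mean = G.mean(axis=0)
    sd = G.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise DataError("all SNPs are monomorphic")
    Z = (G[:, poly] - mean[poly]) / sd[poly]
    grm = Z @ Z.T / poly.sum()
    vals, vecs = np.linalg.eigh(grm)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int((vals > 1e-10).sum())
    if n_pos < n_eigen:
        warnings.warn(f"only {n_pos} positive GRM eigenvalues; returning those",
                      stacklevel=2)
        n_eigen = max(n_pos, 1)
    return Kinship(grm=grm, eigenvalues=vals[:n_eigen],
                   eigenvectors=vecs[:, :n_eigen], accessions=list(genos.accessions))


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass
class GwasDesign:
    """Response + structure covariates (+ optional -1/+1 treatment vector)."""

    response: np.ndarray
    covariates: np.ndarray                  # (n, c) including intercept
    treatment: np.ndarray | None = None     # -1/+1 per observation
    analysis: str = "prediction"
    trait: str = "trait"

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float)
        if not np.isfinite(self.response).all():
            raise DataError("response contains non-finite values")
        self.covariates = np.asarray(self.covariates, dtype=float)
        if np.linalg.matrix_rank(self.covariates) < self.covariates.shape[1]:
            raise ConfigError("covariate matrix is rank deficient")
        if self.treatment is not None:
            self.treatment = np.asarray(self.treatment, dtype=float)
            if not set(np.unique(self.treatment)) <= {-1.0, 1.0}:
                raise ConfigError("treatment vector must be coded -1/+1")
        if self.analysis not in ANALYSIS_LABELS:
            raise ConfigError(f"analysis must be one of {ANALYSIS_LABELS}")


def make_design(response, kinship: Kinship | None = None, treatment=None,
                analysis: str = "prediction", trait: str = "trait") -> GwasDesign:
    """Assemble intercept + GRM eigenvector covariates around a response."""
    y = np.asarray(response, dtype=float)
    cov = [np.ones((len(y), 1))]
    if kinship is not None:
        cov.append(kinship.eigenvectors)
    C = np.hstack(cov)
    return GwasDesign(response=y, covariates=C, treatment=treatment,
                      analysis=analysis, trait=trait)


def _residualize(C: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Project out the covariate column space."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


# ---------------------------------------------------------------------------
# SNP-level association
# ---------------------------------------------------------------------------

def snp_association(design: GwasDesign, genos: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP least squares with Wald t tests.

    Without a treatment vector: response ~ covariates + dosage, two-sided t
    test of the dosage term.  With one: response ~ covariates + treatment +
    dosage + dosage x treatment, separate tests of the main (G) and
    interaction (GxE) terms.  SNPs collinear with the covariates get p = 1
    and a flag.
    """
    y = design.response
    n = len(y)
    C = design.covariates
    if design.treatment is not None:
        C = np.hstack([C, design.treatment[:, None]])
    c = C.shape[1]
    if n <= c + 2:
        raise DataError("too few observations for the design")
    G = genos.dosage
    if G.shape[0] != n:
        raise DataError("genotype rows do not match the response length")
    y_res = _residualize(C, y[:, None]).ravel()
    G_res = _residualize(C, G)
    out = {"snp_id": genos.snp_ids, "chrom": genos.chrom, "pos": genos.pos}

    if design.treatment is None:
        gg = np.einsum("ij,ij->j", G_res, G_res)
        flagged = gg <= 1e-12 * n
        gg_safe = np.where(flagged, 1.0, gg)
        beta = (G_res.T @ y_res) / gg_safe
        df = n - c - 1
        rss = np.maximum(y_res @ y_res - beta ** 2 * gg_safe, 0.0)
        se = np.sqrt(rss / df / gg_safe)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[flagged] = 1.0
        out.update({"beta": beta, "t": t, "p": p, "flagged": flagged})
        return pd.DataFrame(out)

    # main + interaction: two SNP-specific regressors after residualization
    T = design.treatment
    GT = G * T[:, None]
    GT_res = _residualize(C, GT)
    a11 = np.einsum("ij,ij->j", G_res, G_res)
    a22 = np.einsum("ij,ij->j", GT_res, GT_res)
    a12 = np.einsum("ij,ij->j", G_res, GT_res)
    det = a11 * a22 - a12 ** 2
    flagged = (a11 <= 1e-12 * n) | (det <= 1e-14 * np.maximum(a11 * a22, 1e-30))
    det_safe = np.where(flagged, 1.0, det)
    b1 = G_res.T @ y_res
    b2 = GT_res.T @ y_res
    beta_g = (a22 * b1 - a12 * b2) / det_safe
    beta_gt = (a11 * b2 - a12 * b1) / det_safe
    df = n - c - 2
    rss = np.maximum(y_res @ y_res - (beta_g * b1 + beta_gt * b2), 0.0)
    s2 = rss / df
    var_g = s2 * a22 / det_safe
    var_gt = s2 * a11 / det_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        t_g = np.where(var_g > 0, beta_g / np.sqrt(var_g), 0.0)
        t_gt = np.where(var_gt > 0, beta_gt / np.sqrt(var_gt), 0.0)
    p_g = 2.0 * stats.t.sf(np.abs(t_g), df)
    p_gt = 2.0 * stats.t.sf(np.abs(t_gt), df)
    p_g[flagged] = 1.0
    p_gt[flagged] = 1.0
    out.update({"beta": beta_g, "t": t_g, "p": p_g,
                "beta_gxe": beta_gt, "t_gxe": t_gt, "p_gxe": p_gt,
                "flagged": flagged})
    return pd.DataFrame(out)


def interaction_requested_without_treatment(design: GwasDesign) -> None:
    if design.treatment is None:
        raise ConfigError("interaction test requested but the design has no "
                          "treatment vector")


# ---------------------------------------------------------------------------
# Gene-level association
# ---------------------------------------------------------------------------

def gene_level_test(genos: GenotypeMatrix, design: GwasDesign, snp_map: SnpGeneMap,
                    var_keep: float = DEFAULT_VAR_KEEP,
                    term: str = "G") -> pd.DataFrame:
    """Joint PC-regression F test per gene.

    Per gene: residualize the response and the gene's SNP dosage block on
    the covariates, retain principal components of the residualized block
    up to cumulative variance ``var_keep`` (capped at n - c - 2), and F-test
    the joint regression against the covariate-only model.  ``term``
    selects the tested dosage block: ``G`` (dosages) or ``GxE``
    (dosage x treatment, treatment designs only).
    """
    if snp_map.pairs.empty:
        raise DataError("empty SNP-to-gene map")
    y = design.response
    n = len(y)
    C = design.covariates
    if design.treatment is not None:
        C = np.hstack([C, design.treatment[:, None]])
    c = C.shape[1]
    if term == "GxE":
        interaction_requested_without_treatment(design)
        M = genos.dosage * design.treatment[:, None]
    elif term == "G":
        M = genos.dosage
    else:
        raise ConfigError(f"unknown test term {term!r}")
    y_res = _residualize(C, y[:, None]).ravel()
    M_res = _residualize(C, M)
    rss0 = float(y_res @ y_res)
    snp_idx = {s: j for j, s in enumerate(genos.snp_ids)}
    rows = []
    for gene, snps in snp_map.gene_groups().items():
        cols = [snp_idx[s] for s in snps if s in snp_idx]
        if not cols:
            continue
        block = M_res[:, cols]
        U, s, _ = np.linalg.svd(block, full_matrices=False)
        # relative tolerance plus an absolute floor: dosages are O(1), so a
        # residualized column with norm ~1e-9*sqrt(n) is numerically zero
        tol = max(max(block.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0),
                  1e-9 * np.sqrt(n))
        rank = int((s > tol).sum())
        if rank == 0:
            rows.append({"gene_id": gene, "n_snps": len(cols), "n_pcs": 0,
                         "F": 0.0, "p": 1.0, "flagged": True})
            continue
        var = s[:rank] ** 2
        frac = np.cumsum(var) / var.sum()
        q = int(np.searchsorted(frac, var_keep - 1e-12) + 1)
        q = min(q, rank, n - c - 2)
        Uq = U[:, :q]
        coef = Uq.T @ y_res
        explained = float(coef @ coef)
        df2 = n - c - q
        resid = max(rss0 - explained, 0.0)
        if resid <= 0 or df2 <= 0:
            F, p = np.inf, 0.0
        else:
            F = (explained / q) / (resid / df2)
            p = float(stats.f.sf(F, q, df2))
        rows.append({"gene_id": gene, "n_snps": len(cols), "n_pcs": q,
                     "F": float(F), "p": max(p, np.finfo(float).tiny),
                     "flagged": False})
    table = pd.DataFrame(rows)
    table["analysis"] = design.analysis
    table["trait"] = design.trait
    return table


# ---------------------------------------------------------------------------
# Candidate pooling and overlap
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    analysis: str
    per_trait: dict[str, list[str]]
    pooled: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.pooled:
            self.pooled = sorted(set().union(*self.per_trait.values())) \
                if self.per_trait else []


@dataclass
class OverlapMatrix:
    counts: pd.DataFrame
    row_percent: pd.DataFrame


def pool_candidates(tables: list[pd.DataFrame], k: int = DEFAULT_TOP_K
                    ) -> tuple[dict[str, CandidateSet], OverlapMatrix]:
    """Top-k genes per (analysis, trait), pooled per analysis, with the
    pairwise overlap matrix.

    Tables are first restricted to the shared gene universe so analyses on
    different marker sets are comparable.  Ties at the p-value cut resolve
    by ascending gene id.
    """
    if not tables:
        raise DataError("no gene association tables to pool")
    universe = set(tables[0]["gene_id"])
    for t in tables[1:]:
        universe &= set(t["gene_id"])
    if not universe:
        raise DataError("gene association tables share no genes")
    per_analysis: dict[str, dict[str, list[str]]] = {}
    for t in tables:
        sub = t[t["gene_id"].isin(universe)]
        analysis = str(sub["analysis"].iloc[0])
        trait = str(sub["trait"].iloc[0])
        kk = min(k, len(sub))
        if kk < k:
            logger.warning("top-%d requested but only %d genes tested (%s/%s)",
                           k, len(sub), analysis, trait)
        top = sub.sort_values(["p", "gene_id"]).head(kk)["gene_id"].tolist()
        per_analysis.setdefault(analysis, {})[trait] = top
    sets = {a: CandidateSet(analysis=a, per_trait=d) for a, d in per_analysis.items()}
    names = sorted(sets)
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    pct = pd.DataFrame(0.0, index=names, columns=names)
    for a in names:
        sa = set(sets[a].pooled)
        for b in names:
            sb = set(sets[b].pooled)
            counts.loc[a, b] = len(sa & sb)
            pct.loc[a, b] = 100.0 * len(sa & sb) / len(sa) if sa else 0.0
    return sets, OverlapMatrix(counts=counts, row_percent=pct)


# ---------------------------------------------------------------------------
# Cluster MAF profiles
# ---------------------------------------------------------------------------

@dataclass
class ClusterMafProfile:
    profile: pd.DataFrame        # one row per cluster: elevation, traits, MAF per SNP
    correlations: pd.DataFrame   # per SNP x reference: r, p


def cluster_maf_profile(genos: GenotypeMatrix, labels: pd.Series,
                        elevation: pd.Series, projections: pd.DataFrame,
                        candidate_snps: list[str]) -> ClusterMafProfile:
    """Per-cluster mean elevation, mean projected traits and candidate-SNP
    minor allele frequency, with Pearson correlations of MAF against
    elevation and each trait across clusters.

    The minor allele is the panel-wide minor allele frozen at genotype
    load; per-cluster frequencies may exceed 0.5.  Clusters of size < 2 are
    excluded with a warning.
    """
    snp_idx = {s: j for j, s in enumerate(genos.snp_ids)}
    missing = [s for s in candidate_snps if s not in snp_idx]
    if missing:
        raise DataError(f"candidate SNPs absent from the panel: {missing[:5]}")
    acc_idx = {a: i for i, a in enumerate(genos.accessions)}
    rows = []
    for cl in sorted(labels.unique()):
        members = [a for a in labels.index[labels == cl] if a in acc_idx]
        if len(members) < 2:
            warnings.warn(f"cluster {cl} has fewer than 2 genotyped members; excluded",
                          stacklevel=2)
            continue
        ridx = [acc_idx[a] for a in members]
        maf = genos.minor_allele_freq(ridx)
        row = {"cluster": cl, "n": len(members),
               "mean_elevation": float(elevation.loc[members].mean())}
        for t in projections.columns:
            row[f"mean_{t}"] = float(projections.loc[members, t].mean())
        for s in candidate_snps:
            row[f"maf_{s}"] = float(maf[snp_idx[s]])
        rows.append(row)
    profile = pd.DataFrame(rows)
    if len(profile) < 2:
        raise DataError("fewer than 2 usable clusters; correlations undefined")
    refs = ["mean_elevation"] + [f"mean_{t}" for t in projections.columns]
    crows = []
    for s in candidate_snps:
        for ref in refs:
            x, yv = profile[f"maf_{s}"], profile[ref]
            if x.std() == 0 or yv.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, yv)
            crows.append({"snp_id": s, "reference": ref.replace("mean_", ""),
                          "r": float(r), "p": float(p)})
    return ClusterMafProfile(profile=profile, correlations=pd.DataFrame(crows))
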