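"""Synthetic study generator with recorded ground truth.

Emulates the structure of a projection-based GEA study of root anatomy:
a landscape of georeferenced accessions with clinal environmental
descriptors, a population-structured genotyped panel carrying planted
clinal/causal SNPs, environment-driven anatomical traits with noise, and a
greenhouse-style replicated observation table.  Every generated signal is
recorded in a :class:`GroundTruth` object so downstream stages have a
parameter-recovery target.

Randomness: all streams derive from ``SimConfig.seed`` through fixed named
sub-streams (``default_rng([seed, k])`` with k = 1 landscape, 2 annotation,
3 genotypes, 4 traits, 5 greenhouse), so regenerating any component with the
same config is byte-identical regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .io_formats import (
    GeneAnnotation,
    GenotypeMatrix,
    write_dosage_csv,
    write_table,
    write_vcf,
)

# Plausible trait scales: (mean, sd, low, high, integer).  Units follow the
# conventional root-anatomy codes: areas mm^2, diameters mm, counts integer,
# percentages 0-100.  These are emulated magnitudes, not calibrated fits to
# any measured panel.
TRAIT_SCALES = {
    "RXSA": (1.10, 0.25, 0.40, 2.50, False),      # root cross-section area, mm^2
    "TSA.RXSA": (0.18, 0.030, 0.08, 0.35, False),  # stele:root area ratio
    "CCFN": (10.0, 1.5, 6, 16, True),              # cortical cell file number
    "CCS": (4.0e-4, 1.0e-4, 1.0e-4, 9.0e-4, False),  # cortical cell size, mm^2
    "AA": (0.080, 0.050, 0.0, 0.45, False),        # aerenchyma area, mm^2
    "NMV": (9.0, 2.0, 1, 24, True),                # metaxylem vessel count
    "MD": (0.065, 0.012, 0.025, 0.110, False),     # metaxylem diameter, mm
}
PRIMARY_TRAITS = list(TRAIT_SCALES)
DERIVED_TRAITS = ["TSA", "TCA", "X.A", "MA", "MVA"]
# epidermis / endodermis thickness used when deriving the cortical annulus (mm)
_T_EPI = 0.02
_T_ENDO = 0.02


@dataclass
class SimConfig:
    """Study-scale configuration; defaults define the packaged desk-scale study."""

    n_train: int = 60
    n_target: int = 400
    n_descriptors: int = 40
    n_informative: int = 5
    n_snps: int = 2000
    n_genes: int = 200
    n_causal_genes: int = 5
    fst: float = 0.1
    trait_env_r2: float = 0.6
    trait_snp_h2: float = 0.1
    seed: int = 0
    missing_rate: float = 0.0
    n_chromosomes: int = 10
    adaptive_shift: float = 0.25
    cline_on: str = "elevation"  # or a trait code: cline follows that trait's
    #                              environmental component (selection on the trait)
    greenhouse_variances: dict = field(
        default_factory=lambda: {"accession": 1.0, "node": 0.3, "tray": 0.2, "residual": 0.5}
    )

    def __post_init__(self):
        counts = dict(n_train=self.n_train, n_target=self.n_target,
                      n_descriptors=self.n_descriptors, n_snps=self.n_snps,
                      n_genes=self.n_genes, n_chromosomes=self.n_chromosomes)
        for name, v in counts.items():
            if int(v) <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.n_informative < 0 or self.n_informative > self.n_descriptors:
            raise ConfigError("n_informative must be in [0, n_descriptors]")
        if self.n_causal_genes < 0 or self.n_causal_genes > self.n_genes:
            raise ConfigError("n_causal_genes must be in [0, n_genes]")
        if not (0.0 < self.fst < 1.0):
            raise ConfigError("fst must be in (0, 1)")
        for name in ("trait_env_r2", "trait_snp_h2"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must be in [0, 1)")
        if self.trait_env_r2 + self.trait_snp_h2 >= 1.0:
            raise ConfigError("trait_env_r2 + trait_snp_h2 must be < 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.cline_on != "elevation":
            if self.cline_on not in TRAIT_SCALES:
                raise ConfigError(f"cline_on must be 'elevation' or a trait code, "
                                  f"got {self.cline_on!r}")
            if self.trait_snp_h2 > 0:
                raise ConfigError("cline_on a trait requires trait_snp_h2 = 0 "
                                  "(traits must be generable before genotypes)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Everything planted into a synthetic study, for parameter recovery."""

    informative_descriptors: list[str] = field(default_factory=list)
    causal_genes: list[str] = field(default_factory=list)
    causal_snps: list[str] = field(default_factory=list)
    snp_effects: dict = field(default_factory=dict)       # trait -> {snp_id: beta}
    env_function: dict = field(default_factory=dict)      # trait -> coefficient record
    elevation: pd.Series = None                           # per-accession metres
    demes: pd.Series = None                               # per-accession 0/1/2
    greenhouse_variances: dict = field(default_factory=dict)
    env_component_values: pd.DataFrame = None             # realized f per accession/trait
    true_traits: pd.DataFrame = None                      # traits for every accession

    def env_component(self, descriptors: pd.DataFrame, trait: str) -> np.ndarray:
        """Evaluate the recorded trait-generating environmental function."""
        rec = self.env_function[trait]
        if not rec["descriptors"]:
            return np.zeros(len(descriptors))
        z = {}
        for name in rec["descriptors"]:
            z[name] = (descriptors[name].to_numpy(float) - rec["means"][name]) / rec["sds"][name]
        f = np.zeros(len(descriptors))
        for name, b in rec["linear"].items():
            f += b * z[name]
        if rec["interaction"]:
            a, b_name = rec["interaction"]["pair"]
            f += rec["interaction"]["coef"] * z[a] * z[b_name]
        if rec["saturating"]:
            f += rec["saturating"]["coef"] * np.tanh(z[rec["saturating"]["descriptor"]])
        return f

    def to_json(self, path) -> None:
        doc = {
            "informative_descriptors": self.informative_descriptors,
            "causal_genes": self.causal_genes,
            "causal_snps": self.causal_snps,
            "snp_effects": self.snp_effects,
            "env_function": self.env_function,
            "greenhouse_variances": self.greenhouse_variances,
            "elevation": {k: float(v) for k, v in self.elevation.items()}
            if self.elevation is not None else {},
            "demes": {k: int(v) for k, v in self.demes.items()}
            if self.demes is not None else {},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Landscape and environmental descriptors
# ---------------------------------------------------------------------------

def _elevation_surface(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Sum of two smooth sinusoidal ridges over the sampling rectangle."""
    u = (lon + 105.0) / 10.0
    v = (lat - 14.0) / 7.0
    elev = 1500.0 + 900.0 * np.sin(2.2 * np.pi * u + 0.3) + 700.0 * np.sin(1.7 * np.pi * v + 1.1)
    return np.clip(elev, 0.0, None)


def generate_landscape(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Georeferenced accessions with clinal and noise environmental descriptors.

    Coordinates are uniform on a rectangle; elevation is a smooth surface of
    the coordinates; ``n_informative`` descriptors are monotone functions of
    elevation plus noise (pairwise correlated through the shared driver);
    the rest are independent noise.  Three conventional descriptors
    (annual precipitation, mean temperature, soil pH) are always present for
    the PC-environment screen; the first two track elevation, pH does not.
    """
    rng = config.rng(1)
    n = config.n_train + config.n_target
    acc = [f"ACC{i:05d}" for i in range(n)]
    panel = ["train"] * config.n_train + ["target"] * config.n_target
    lon = rng.uniform(-105.0, -95.0, n)
    lat = rng.uniform(14.0, 21.0, n)
    elev = _elevation_surface(lon, lat)
    ez = (elev - elev.mean()) / elev.std()

    df = pd.DataFrame({
        "accession": acc, "panel": panel,
        "longitude": lon, "latitude": lat, "elevation": elev,
    })
    # conventional named descriptors for the correlation screen
    df["annual_precipitation"] = np.clip(
        1400.0 - 0.35 * elev + rng.normal(0, 120.0, n), 50.0, None)
    df["mean_temperature"] = 26.0 - 0.0055 * elev + rng.normal(0, 1.2, n)
    df["soil_ph"] = np.clip(rng.normal(6.3, 0.6, n), 4.0, 8.5)

    names = [f"env_{j + 1:03d}" for j in range(config.n_descriptors)]
    informative = sorted(
        rng.choice(names, size=config.n_informative, replace=False).tolist()
    )
    shapes = [
        lambda z: z,
        np.tanh,
        lambda z: np.arcsinh(1.5 * z),
        lambda z: 2.0 * expit(1.5 * z) - 1.0,
        lambda z: z + 0.15 * z ** 3,
    ]
    for j, name in enumerate(names):
        scale = rng.uniform(0.5, 3.0)
        offset = rng.uniform(-2.0, 10.0)
        if name in informative:
            sign = rng.choice([-1.0, 1.0])
            shape = shapes[j % len(shapes)]
            raw = sign * shape(ez) + 0.55 * rng.normal(size=n)
        else:
            raw = rng.normal(size=n)
        df[name] = offset + scale * raw
    if config.missing_rate > 0:
        mask = rng.random((n, len(names))) < config.missing_rate
        block = df[names].to_numpy()
        block[mask] = np.nan
        df[names] = block

    truth = GroundTruth(informative_descriptors=informative)
    truth.elevation = pd.Series(elev, index=acc, name="elevation")
    return df, truth


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimConfig, truth: GroundTruth) -> GeneAnnotation:
    """Non-overlapping gene models spread over ``n_chromosomes`` contigs.

    Picks ``n_causal_genes`` causal genes (recorded in the ground truth);
    causal SNPs are later planted inside their bodies.
    """
    rng = config.rng(2)
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    ids, chroms, starts, ends = [], [], [], []
    g = 0
    for c in range(1, config.n_chromosomes + 1):
        pos = 15000
        for _ in range(per_chrom[c - 1]):
            g += 1
            length = int(rng.integers(2000, 5000))
            start = pos + int(rng.integers(0, 8000))
            ids.append(f"gene{g:04d}")
            chroms.append(str(c))
            starts.append(start)
            ends.append(start + length - 1)
            pos = start + length + 12000  # spacing > 2 x window, genes do not share SNPs
    ann = GeneAnnotation(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                         np.array(starts), np.array(ends))
    truth.causal_genes = sorted(
        rng.choice(ids, size=config.n_causal_genes, replace=False).tolist()
    ) if config.n_causal_genes else []
    return ann


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def generate_genotypes(config: SimConfig, truth: GroundTruth,
                       annotation: GeneAnnotation | None = None) -> GenotypeMatrix:
    """Balding-Nichols-style structured genotypes with planted clinal SNPs.

    Accessions are split into three demes by elevation tercile; each SNP has
    an ancestral frequency and Beta-distributed deme frequencies with
    differentiation ``fst``.  Causal SNPs (one per causal gene) receive an
    additional logistic frequency shift along elevation, making them clinal
    over and above the deme structure.  All returned SNPs have MAF > 1%.
    """
    if truth.elevation is None:
        raise ConfigError("generate_landscape must run before generate_genotypes")
    if annotation is None:
        annotation = generate_annotation(config, truth)
    rng = config.rng(3)
    acc = list(truth.elevation.index)
    elev = truth.elevation.to_numpy(float)
    q1, q2 = np.quantile(elev, [1 / 3, 2 / 3])
    deme = np.where(elev <= q1, 0, np.where(elev <= q2, 1, 2))
    truth.demes = pd.Series(deme, index=acc, name="deme")
    if config.cline_on == "elevation":
        cline = elev
    else:
        if truth.env_component_values is None:
            raise ConfigError("cline_on a trait requires traits generated first")
        cline = truth.env_component_values[config.cline_on].to_numpy(float)
    ez = (cline - cline.mean()) / cline.std()
    n = len(acc)

    # positions: causal SNPs inside causal gene bodies, the rest uniform
    gene_idx = {gid: i for i, gid in enumerate(annotation.gene_ids)}
    causal_pos = []
    for gid in truth.causal_genes:
        i = gene_idx[gid]
        p = int(rng.integers(annotation.start[i], annotation.end[i] + 1))
        causal_pos.append((str(annotation.chrom[i]), p))
    chrom_span = {str(c): int(annotation.end[annotation.chrom == c].max()) + 20000
                  for c in set(annotation.chrom)}
    chrom_names = sorted(chrom_span, key=lambda c: int(c))
    n_rest = config.n_snps - len(causal_pos)
    if n_rest < 0:
        raise ConfigError("more causal genes than SNPs requested")
    counts = np.full(len(chrom_names), n_rest // len(chrom_names))
    counts[: n_rest % len(chrom_names)] += 1
    sites: list[tuple[str, int]] = list(causal_pos)
    for c, k in zip(chrom_names, counts):
        pos = np.unique(rng.integers(1, chrom_span[c], size=k))
        while len(pos) < k:  # top up collisions
            pos = np.unique(np.concatenate([pos, rng.integers(1, chrom_span[c], size=k - len(pos))]))
        sites.extend((c, int(p)) for p in pos[:k])
    sites = sorted(set(sites), key=lambda s: (int(s[0]), s[1]))
    m = len(sites)
    snp_ids = np.array([f"S{c}_{p}" for c, p in sites], dtype=object)
    causal_ids = {f"S{c}_{p}" for c, p in causal_pos}
    is_causal = np.array([s in causal_ids for s in snp_ids])
    truth.causal_snps = sorted(causal_ids)

    chrom_arr = np.array([c for c, _ in sites], dtype=object)
    pos_arr = np.array([p for _, p in sites], dtype=np.int64)

    F = config.fst
    a_scale = (1.0 - F) / F
    dosage = np.empty((n, m))
    cline_sign = rng.choice([-1.0, 1.0], size=m)
    todo = np.arange(m)
    for _round in range(30):
        k = len(todo)
        lo, hi = (0.3, 0.7) if _round == 0 else (0.2, 0.8)
        p_anc = rng.uniform(0.1, 0.9, size=k)
        p_anc[is_causal[todo]] = rng.uniform(lo, hi, size=int(is_causal[todo].sum()))
        deme_freq = rng.beta(np.outer(p_anc, [1, 1, 1]) * a_scale,
                             np.outer(1 - p_anc, [1, 1, 1]) * a_scale)
        p_ind = deme_freq[np.arange(k)[:, None], deme[None, :]]  # (k, n)
        shift = config.adaptive_shift * (2.0 * expit(1.5 * ez) - 1.0)
        p_ind = np.where(is_causal[todo][:, None],
                         np.clip(p_ind + cline_sign[todo][:, None] * shift[None, :], 0.02, 0.98),
                         p_ind)
        dosage[:, todo] = rng.binomial(2, p_ind).T
        f_alt = dosage[:, todo].mean(axis=0) / 2.0
        maf = np.minimum(f_alt, 1 - f_alt)
        todo = todo[maf <= 0.01]
        if len(todo) == 0:
            break
    if len(todo):  # drop stubborn near-monomorphic sites
        keep = np.ones(m, dtype=bool)
        keep[todo] = False
        snp_ids, chrom_arr, pos_arr, dosage = (
            snp_ids[keep], chrom_arr[keep], pos_arr[keep], dosage[:, keep])
        truth.causal_snps = [s for s in truth.causal_snps if s in set(snp_ids)]
    return GenotypeMatrix(acc, snp_ids, chrom_arr, pos_arr, dosage)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def _derive_secondary(df: pd.DataFrame) -> pd.DataFrame:
    """Fill TSA, TCA, X.A, MA, MVA from the primary traits, keeping the
    combination geometrically buildable (vessels must fit on the placement
    circle inside the stele)."""
    df = df.copy()
    df["TSA"] = df["TSA.RXSA"] * df["RXSA"]
    r_out = np.sqrt(df["RXSA"] / np.pi)
    r_s = np.sqrt(df["TSA"] / np.pi)
    df["TCA"] = np.pi * ((r_out - _T_EPI) ** 2 - (r_s + _T_ENDO) ** 2)
    df["AA"] = np.minimum(df["AA"], 0.5 * df["TCA"])
    df["X.A"] = np.clip(100.0 * df["AA"] / df["TCA"], 0.0, 100.0)
    df["MD"] = np.minimum(df["MD"], 0.6 * r_s)
    ratio = np.clip(df["MD"] / (1.2 * r_s), 1e-6, 0.95)
    nmv_cap = np.floor(np.pi / np.arcsin(ratio)).astype(int)
    df["NMV"] = np.clip(df["NMV"].astype(int), 1, np.maximum(nmv_cap, 1))
    df["MA"] = np.pi * df["MD"] ** 2 / 4.0
    df["MVA"] = df["NMV"] * df["MA"]
    return df


def generate_traits(config: SimConfig, descriptors: pd.DataFrame,
                    genotypes: GenotypeMatrix, truth: GroundTruth) -> pd.DataFrame:
    """Environment- and SNP-driven anatomical traits on plausible scales.

    Each primary trait is a nonlinear function of the informative descriptors
    (linear terms, one pairwise interaction, one saturating tanh term) plus a
    sum of causal-SNP effects and Gaussian noise, with variance fractions
    matched to ``trait_env_r2`` / ``trait_snp_h2`` before mapping onto the
    trait's documented scale.  Coefficients land in the ground truth.
    """
    r2e, h2 = config.trait_env_r2, config.trait_snp_h2
    if r2e > 0 and config.n_informative == 0:
        raise ConfigError("trait_env_r2 > 0 requires n_informative > 0")
    if h2 > 0 and not truth.causal_snps:
        raise ConfigError("trait_snp_h2 > 0 requires planted causal SNPs")
    rng = config.rng(4)
    acc = descriptors["accession"].tolist()
    if genotypes is None:
        if h2 > 0:
            raise ConfigError("genotypes are required when trait_snp_h2 > 0")
        snp_index = {}
    else:
        if acc != list(genotypes.accessions):
            raise ConfigError("descriptors and genotypes must share accession ids in order")
        snp_index = {s: j for j, s in enumerate(genotypes.snp_ids)}
    n = len(acc)
    inf = truth.informative_descriptors

    out = pd.DataFrame({"accession": acc})
    env_values = {}
    for trait, (mean, sd, lo, hi, integer) in TRAIT_SCALES.items():
        rec = {"descriptors": list(inf), "means": {}, "sds": {}, "linear": {},
               "interaction": None, "saturating": None}
        for name in inf:
            col = descriptors[name].to_numpy(float)
            rec["means"][name] = float(np.mean(col))
            rec["sds"][name] = float(np.std(col))
            rec["linear"][name] = float(rng.choice([-1, 1]) * rng.uniform(0.6, 1.4))
        if len(inf) >= 2:
            rec["interaction"] = {"pair": [inf[0], inf[1]],
                                  "coef": float(rng.choice([-1, 1]) * rng.uniform(0.4, 0.9))}
        if len(inf) >= 1:
            sat = inf[2] if len(inf) >= 3 else inf[0]
            rec["saturating"] = {"descriptor": sat,
                                 "coef": float(rng.choice([-1, 1]) * rng.uniform(0.5, 1.0))}
        truth.env_function[trait] = rec
        f = truth.env_component(descriptors, trait)
        env_values[trait] = f

        g = np.zeros(n)
        effects = {}
        if h2 > 0:
            for s in truth.causal_snps:
                beta = float(rng.normal())
                effects[s] = beta
                d = genotypes.dosage[:, snp_index[s]]
                dsd = d.std()
                if dsd > 0:
                    g += beta * (d - d.mean()) / dsd
        truth.snp_effects[trait] = effects

        latent = np.sqrt(max(1.0 - r2e - h2, 0.0)) * rng.normal(size=n)
        if r2e > 0:
            fs = f.std()
            if fs <= 0:
                raise ConfigError(f"environmental component of {trait} has zero variance")
            latent = latent + np.sqrt(r2e) * (f - f.mean()) / fs
        if h2 > 0 and g.std() > 0:
            latent = latent + np.sqrt(h2) * (g - g.mean()) / g.std()
        vals = mean + sd * latent
        vals = np.clip(vals, lo, hi)
        if integer:
            vals = np.maximum(np.round(vals), 1)
        out[trait] = vals

    out = _derive_secondary(out)
    truth.env_component_values = pd.DataFrame(env_values, index=acc)
    truth.true_traits = out.copy()
    return out


# ---------------------------------------------------------------------------
# Greenhouse replicates
# ---------------------------------------------------------------------------

def generate_greenhouse(config: SimConfig, accessions: list[str],
                        n_reps: int = 10, n_nodes: int = 2,
                        plants_per_tray: int = 8,
                        mu: float = 10.0) -> pd.DataFrame:
    """Replicated per-plant records: value = mu + accession + node + tray + e.

    One row per (plant, node); plants are placed on trays in randomized
    order so tray is not confounded with accession.  The variance components
    come from ``config.greenhouse_variances`` and are recorded there for
    recovery studies.
    """
    rng = config.rng(5)
    v = config.greenhouse_variances
    acc_eff = {a: rng.normal(0, np.sqrt(v["accession"])) for a in accessions}
    node_eff = {f"node{k + 1}": rng.normal(0, np.sqrt(v["node"])) for k in range(n_nodes)}
    n_plants = len(accessions) * n_reps
    n_trays = int(np.ceil(n_plants / plants_per_tray))
    tray_eff = {f"tray{t + 1}": rng.normal(0, np.sqrt(v["tray"])) for t in range(n_trays)}
    slots = rng.permutation(n_plants)  # randomized tray layout
    rows = []
    plant = 0
    for a in accessions:
        for r in range(n_reps):
            tray = f"tray{slots[plant] // plants_per_tray + 1}"
            for nd in node_eff:
                value = (mu + acc_eff[a] + node_eff[nd] + tray_eff[tray]
                         + rng.normal(0, np.sqrt(v["residual"])))
                rows.append({"plant": f"plant{plant + 1:04d}", "accession": a,
                             "node": nd, "tray": tray, "value": value})
            plant += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-study bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SimConfig
    descriptors: pd.DataFrame       # all accessions, with panel column
    annotation: GeneAnnotation
    genotypes: GenotypeMatrix       # all accessions
    traits: pd.DataFrame            # train panel only (the "phenotyped" panel)
    greenhouse: pd.DataFrame
    truth: GroundTruth

    @property
    def train_descriptors(self) -> pd.DataFrame:
        return self.descriptors[self.descriptors["panel"] == "train"].reset_index(drop=True)

    @property
    def target_descriptors(self) -> pd.DataFrame:
        return self.descriptors[self.descriptors["panel"] == "target"].reset_index(drop=True)

    @property
    def target_genotypes(self) -> GenotypeMatrix:
        return self.genotypes.subset_accessions(
            self.target_descriptors["accession"].tolist())


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate the complete study: landscape, annotation, genotypes, traits,
    greenhouse replicates, and ground truth.

    With the default ``cline_on='elevation'`` the adaptive SNP cline follows
    elevation and traits may carry causal-SNP effects.  With ``cline_on`` a
    trait code, traits are generated first (environment-only) and the
    adaptive cline follows that trait's environmental component — selection
    acting on the trait optimum.
    """
    descriptors, truth = generate_landscape(config)
    annotation = generate_annotation(config, truth)
    if config.cline_on == "elevation":
        genotypes = generate_genotypes(config, truth, annotation)
        traits_all = generate_traits(config, descriptors, genotypes, truth)
    else:
        traits_all = generate_traits(config, descriptors, None, truth)
        genotypes = generate_genotypes(config, truth, annotation)
    train_ids = descriptors.loc[descriptors["panel"] == "train", "accession"]
    traits = traits_all[traits_all["accession"].isin(train_ids)].reset_index(drop=True)
    gh_acc = train_ids.tolist()[: min(8, len(train_ids))]
    greenhouse = generate_greenhouse(config, gh_acc)
    truth.greenhouse_variances = dict(config.greenhouse_variances)
    return SyntheticStudy(config, descriptors, annotation, genotypes,
                          traits, greenhouse, truth)


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write the study to disk as headered CSV / VCF v4.2 / GFF3 / JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": out / "sim_config.json",
        "descriptors_train": out / "descriptors_train.csv",
        "descriptors_target": out / "descriptors_target.csv",
        "traits": out / "traits_train.csv",
        "genotypes_vcf": out / "genotypes_target.vcf",
        "genotypes_csv": out / "dosage_target.csv",
        "annotation": out / "genes.gff3",
        "greenhouse": out / "greenhouse.csv",
        "ground_truth": out / "ground_truth.json",
    }
    with open(paths["config"], "w") as fh:
        json.dump(asdict(study.config), fh, indent=1, sort_keys=True)
    write_table(study.train_descriptors, paths["descriptors_train"])
    write_table(study.target_descriptors, paths["descriptors_target"])
    write_table(study.traits, paths["traits"])
    tg = study.target_genotypes
    write_vcf(tg, paths["genotypes_vcf"])
    write_dosage_csv(tg, paths["genotypes_csv"])
    study.annotation.to_gff3(paths["annotation"])
    write_table(study.greenhouse, paths["greenhouse"])
    study.truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
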