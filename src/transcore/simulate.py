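"""Synthetic genotypes, eQTL architecture and expression-GWAS summary statistics.

The generator emulates the statistical structure the trans-score analysis
assumes: genotypes arranged in unlinked LD blocks; gene expression controlled
by one strong cis block plus many weak, unlinked trans blocks (with trans
variants carrying ~70% of expression heritability); disease liability that is
logistic in the genetic expression values of a sparse set of core genes; and
an "HLA" region that both directly raises liability and acts as a trans-eQTL
hotspot for every gene, reproducing the confounding that motivates excluding
it from genome-wide trans-scores.  "Bystander" genes share the pleiotropic
trans blocks with core genes but carry no liability coefficient, and a small
set of HLA-driven genes receive trans effects only from the HLA region plus
disease-irrelevant null blocks.

Summary statistics are emitted in an eQTLGen-style flat table; records far
from the target gene (the trans range) are restricted to a randomly chosen
"tested" SNP subset, emulating a meta-analysis that tested only
trait-associated SNPs for trans-association.

All randomness flows from ``SimulationConfig.seed`` through fixed
``numpy.random.SeedSequence`` spawn streams, so identical configurations give
bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ConfigurationError, SimulationConfig

logger = logging.getLogger("transcore")

# distance beyond which an expression GWAS only reports tested SNPs
TRANS_WINDOW_BP = 5_000_000

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G")]

# spawn-stream indices, fixed so each cohort has its own reproducible stream
_S_LAYOUT, _S_ARCH, _S_REF, _S_GWAS, _S_STUDY, _S_TESTED = range(6)


class SimulationError(RuntimeError):
    """Raised when the liability model yields a degenerate study."""


def _stream(config: SimulationConfig, index: int) -> np.random.Generator:
    child = np.random.SeedSequence(config.seed).spawn(6)[index]
    return np.random.default_rng(child)


@dataclass
class GenotypeMatrix:
    """Dosage matrix with variant and sample metadata.

    ``dosages`` is individuals x variants with entries in [0, 2]; ``variants``
    carries id/chrom/pos/alleles/block/maf; ``samples`` carries ids and, for a
    case-control study, status and covariates.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages,
                            index=self.samples["sample_id"].to_numpy(),
                            columns=self.variants["variant_id"].to_numpy())


@dataclass
class TrueArchitecture:
    """The generating truth: variant layout, eQTL effects and liability model."""

    config: SimulationConfig
    variants: pd.DataFrame
    genes: pd.DataFrame          # target_id, chrom, site_start, site_end, role, liability_coef
    effects: pd.DataFrame        # target_id, variant_index, variant_id, effect, kind
    hla_direct: pd.DataFrame     # variant_index, variant_id, coef
    block_roles: dict[int, str] = field(default_factory=dict)

    @property
    def core_genes(self) -> list[str]:
        return list(self.genes.loc[self.genes["role"] == "core", "target_id"])

    def gene_annotation(self) -> pd.DataFrame:
        return self.genes[["target_id", "chrom", "site_start", "site_end"]].copy()

    def genetic_expression(self, dosages: np.ndarray,
                           centered: bool = True) -> pd.DataFrame:
        """Per-individual genetic expression value of every gene.

        With ``centered`` the allele-frequency expectation 2p is removed per
        variant, so values are mean-zero in the population.
        """
        maf = self.variants["maf"].to_numpy()
        out = {}
        for target_id, grp in self.effects.groupby("target_id", sort=False):
            idx = grp["variant_index"].to_numpy()
            d = dosages[:, idx]
            if centered:
                d = d - 2.0 * maf[idx]
            out[target_id] = d @ grp["effect"].to_numpy()
        return pd.DataFrame(out).reindex(columns=self.genes["target_id"])

    def hla_direct_liability(self, dosages: np.ndarray) -> np.ndarray:
        if self.hla_direct.empty:
            return np.zeros(dosages.shape[0])
        idx = self.hla_direct["variant_index"].to_numpy()
        maf = self.variants["maf"].to_numpy()[idx]
        centered = dosages[:, idx] - 2.0 * maf
        return centered @ self.hla_direct["coef"].to_numpy()

    def liability(self, dosages: np.ndarray,
                  rng: np.random.Generator | None = None) -> np.ndarray:
        """Log-odds of disease for each individual (noise added if rng given)."""
        cfg = self.config
        expr = self.genetic_expression(dosages, centered=True)
        coef = self.genes.set_index("target_id")["liability_coef"]
        lin = cfg.baseline_log_odds + expr.to_numpy() @ coef.to_numpy()
        lin = lin + self.hla_direct_liability(dosages)
        if rng is not None and cfg.liability_noise_sd > 0:
            lin = lin + rng.normal(0.0, cfg.liability_noise_sd, size=len(lin))
        return lin


# ---------------------------------------------------------------------------
# variant layout and LD-block genotypes

def _latent_correlation(maf: float, rho_target: float) -> float:
    """Latent Gaussian correlation giving the target allele (phi) correlation.

    Haplotype alleles are Bernoulli(maf) obtained by thresholding equicorrelated
    latent normals; thresholding attenuates correlation, so the latent value is
    calibrated with the bivariate normal CDF to make the realized dosage
    correlation match ``rho_target``.
    """
    if rho_target <= 0.0:
        return 0.0
    t = stats.norm.ppf(maf)
    denom = maf * (1.0 - maf)

    def phi_corr(a: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t, t], mean=[0.0, 0.0], cov=[[1.0, a], [a, 1.0]])
        return (p11 - maf * maf) / denom - rho_target

    return float(optimize.brentq(phi_corr, 0.0, 0.999999, xtol=1e-10))


def variant_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic variant table: blocks placed on named chromosomes.

    HLA blocks sit inside chr6:25-34 Mb; each gene's cis block sits at 100 Mb
    on its own chromosome with the transcription site just downstream; cis-x
    blocks sit 2.5 Mb beyond the first gene sites; pleiotropic and null trans
    blocks are laid out round-robin on chromosomes 1-22 from 140 Mb upward, so
    all three distance classes (cis, cis-x, trans) occur.
    """
    rng = _stream(config, _S_LAYOUT)
    roles = _block_roles(config)
    rows = []
    for block_id in range(config.n_blocks):
        role, payload = roles[block_id]
        chrom, base = _block_position(config, block_id, role, payload)
        maf = rng.uniform(*config.maf_range)
        for j in range(config.snps_per_block):
            ea, oa = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            rows.append({
                "variant_id": f"snp_b{block_id:03d}_{j}",
                "chrom": chrom,
                "pos": base + j * config.snp_spacing_bp,
                "effect_allele": ea,
                "other_allele": oa,
                "block_id": block_id,
                "maf": maf,
            })
    return pd.DataFrame(rows)


def _block_roles(config: SimulationConfig) -> dict[int, tuple[str, int]]:
    """Assign each block a role: hla, cis:<gene>, cisx:<gene>, null or pool."""
    hla = set(config.hla_block_ids)
    free = [b for b in range(config.n_blocks) if b not in hla]
    n_cisx = 2 if (config.n_genes >= 2 and
                   len(free) >= config.n_genes + 4) else 0
    needed = config.n_genes + n_cisx
    if len(free) < needed + 1:
        raise ConfigurationError(
            f"n_blocks={config.n_blocks} too small for {config.n_genes} genes")
    roles: dict[int, tuple[str, int]] = {b: ("hla", i)
                                         for i, b in enumerate(sorted(hla))}
    it = iter(free)
    for g in range(config.n_genes):
        roles[next(it)] = ("cis", g)
    for g in range(n_cisx):
        roles[next(it)] = ("cisx", g)
    rest = list(it)
    n_null = 0
    if config.n_hla_driven_genes > 0:
        n_null = min(config.trans_eqtls_per_gene, len(rest) // 2)
    for i, b in enumerate(rest):
        roles[b] = ("null", i) if i < n_null else ("pool", i - n_null)
    return roles


def _block_position(config: SimulationConfig, block_id: int, role: str,
                    payload: int) -> tuple[str, int]:
    if role == "hla":
        n_hla = len(config.hla_block_ids)
        span = 34_000_000 - 25_000_000
        return "6", 25_000_000 + (payload + 1) * span // (n_hla + 1)
    if role == "cis":
        chrom = str(payload % 22 + 1)
        return chrom, 100_000_000 + (payload // 22) * 30_000_000
    if role == "cisx":
        chrom = str(payload % 22 + 1)
        return chrom, 102_500_000
    # pool / null trans blocks: round-robin beyond 140 Mb
    chrom = str(payload % 22 + 1)
    tier = payload // 22
    offset = 10_000_000 if role == "null" else 0
    return chrom, 140_000_000 + tier * 20_000_000 + offset


def _draw_block_genotypes(rng: np.random.Generator, n: int, n_snps: int,
                          maf: float, latent_a: float) -> np.ndarray:
    """Dosages for one LD block: two thresholded equicorrelated haplotypes."""
    t = stats.norm.ppf(maf)
    shared = rng.standard_normal((n, 2, 1))
    noise = rng.standard_normal((n, 2, n_snps))
    z = np.sqrt(latent_a) * shared + np.sqrt(1.0 - latent_a) * noise
    return (z < t).sum(axis=1).astype(float)


def _draw_genotypes(config: SimulationConfig, variants: pd.DataFrame,
                    rng: np.random.Generator, n: int) -> np.ndarray:
    dosages = np.empty((n, len(variants)))
    calib: dict[float, float] = {}
    for block_id, grp in variants.groupby("block_id", sort=True):
        maf = float(grp["maf"].iloc[0])
        key = round(maf, 9)
        if key not in calib:
            calib[key] = _latent_correlation(maf, config.block_correlation)
        cols = grp.index.to_numpy()
        dosages[:, cols] = _draw_block_genotypes(
            rng, n, len(cols), maf, calib[key])
    return dosages


def _samples_frame(prefix: str, n: int) -> pd.DataFrame:
    return pd.DataFrame({"sample_id": [f"{prefix}{i:06d}" for i in range(n)]})


def simulate_reference_panel(config: SimulationConfig) -> GenotypeMatrix:
    """LD reference panel: block-diagonal correlation, no phenotypes."""
    variants = variant_layout(config)
    rng = _stream(config, _S_REF)
    dosages = _draw_genotypes(config, variants, rng, config.n_reference)
    return GenotypeMatrix(dosages, variants,
                          _samples_frame("ref", config.n_reference))


def simulate_gwas_cohort(config: SimulationConfig) -> GenotypeMatrix:
    """Expression-GWAS cohort, disjoint from both panel and study."""
    variants = variant_layout(config)
    rng = _stream(config, _S_GWAS)
    dosages = _draw_genotypes(config, variants, rng, config.n_gwas)
    return GenotypeMatrix(dosages, variants,
                          _samples_frame("gwa", config.n_gwas))


# ---------------------------------------------------------------------------
# eQTL / disease architecture

def generate_architecture(config: SimulationConfig) -> TrueArchitecture:
    """Draw the true eQTL effects, core-gene set and liability model.

    Core and bystander genes draw ``trans_eqtls_per_gene`` unlinked trans
    blocks from a shared pleiotropic pool (so bystanders receive trans effects
    from the same blocks as core genes); every gene also receives a coherent
    trans effect from each HLA block.  The cis effect size of each gene is set
    so that the trans share of its generating genetic variance equals
    ``trans_heritability_fraction`` exactly, unless ``cis_effect_sd``
    overrides it.
    """
    rng = _stream(config, _S_ARCH)
    variants = variant_layout(config)
    roles = _block_roles(config)
    maf = variants["maf"].to_numpy()
    # causal SNP of each block = its first variant
    causal_of_block = (variants.reset_index()
                       .groupby("block_id", sort=True)["index"].first())

    pool_blocks = [b for b, (r, _) in roles.items() if r == "pool"]
    null_blocks = [b for b, (r, _) in roles.items() if r == "null"]
    hla_blocks = [b for b, (r, _) in roles.items() if r == "hla"]
    cis_block_of_gene = {p: b for b, (r, p) in roles.items() if r == "cis"}
    cisx_block_of_gene = {p: b for b, (r, p) in roles.items() if r == "cisx"}

    n_core = config.n_core_genes
    n_hla_driven = config.n_hla_driven_genes
    gene_rows, effect_rows = [], []
    for g in range(config.n_genes):
        target_id = f"GENE{g:03d}"
        if g < n_core:
            role = "core"
        elif g >= config.n_genes - n_hla_driven:
            role = "hla_driven"
        else:
            role = "bystander"
        k = config.trans_eqtls_per_gene
        if role == "hla_driven":
            chosen = list(rng.choice(null_blocks, size=min(k, len(null_blocks)),
                                     replace=False)) if null_blocks else []
        else:
            chosen = list(rng.choice(pool_blocks, size=min(k, len(pool_blocks)),
                                     replace=False))
        trans_var = 0.0
        for b in chosen:
            v = int(causal_of_block[b])
            beta = config.trans_effect_sd * rng.choice([-1.0, 1.0])
            trans_var += beta ** 2 * 2 * maf[v] * (1 - maf[v])
            effect_rows.append((target_id, v, beta, "trans"))
        for b in hla_blocks:
            # HLA hotspot: coherent-sign trans effect on every gene
            v = int(causal_of_block[b])
            beta = config.trans_effect_sd
            trans_var += beta ** 2 * 2 * maf[v] * (1 - maf[v])
            effect_rows.append((target_id, v, beta, "hla"))
        cisx_var = 0.0
        if g in cisx_block_of_gene:
            v = int(causal_of_block[cisx_block_of_gene[g]])
            beta = config.trans_effect_sd * rng.choice([-1.0, 1.0])
            cisx_var = beta ** 2 * 2 * maf[v] * (1 - maf[v])
            effect_rows.append((target_id, v, beta, "cisx"))
        v = int(causal_of_block[cis_block_of_gene[g]])
        vg = 2 * maf[v] * (1 - maf[v])
        if config.cis_effect_sd is not None:
            cis_beta = config.cis_effect_sd
        else:
            f = config.trans_heritability_fraction
            target_cis_var = (trans_var * (1 - f) / f if f > 0
                              else 4 * trans_var)
            cis_beta = np.sqrt(max(target_cis_var - cisx_var, 0.0) / vg)
        effect_rows.append((target_id, v, rng.choice([-1.0, 1.0]) * cis_beta,
                            "cis"))
        site_chrom, block_base = _block_position(config, cis_block_of_gene[g],
                                                 "cis", g)
        block_end = block_base + (config.snps_per_block - 1) * config.snp_spacing_bp
        coef = 0.0
        if role == "core":
            coef = config.liability_effect_sd * rng.choice([-1.0, 1.0])
        gene_rows.append({
            "target_id": target_id, "chrom": site_chrom,
            "site_start": block_end + 10_000, "site_end": block_end + 30_000,
            "role": role, "liability_coef": coef,
        })

    effects = pd.DataFrame(effect_rows,
                           columns=["target_id", "variant_index", "effect",
                                    "kind"])
    effects["variant_id"] = variants["variant_id"].to_numpy()[
        effects["variant_index"]]
    hla_direct = pd.DataFrame({
        "variant_index": [int(causal_of_block[b]) for b in hla_blocks],
        "coef": [config.hla_liability_effect] * len(hla_blocks),
    })
    hla_direct["variant_id"] = variants["variant_id"].to_numpy()[
        hla_direct["variant_index"]] if len(hla_direct) else []
    return TrueArchitecture(config=config, variants=variants,
                            genes=pd.DataFrame(gene_rows), effects=effects,
                            hla_direct=hla_direct,
                            block_roles={b: r for b, (r, _) in roles.items()})


# ---------------------------------------------------------------------------
# case-control study

def simulate_study(config: SimulationConfig,
                   architecture: TrueArchitecture,
                   max_batches: int = 400) -> GenotypeMatrix:
    """Case-control study ascertained from the liability model.

    Individuals are drawn from the population and assigned by a Bernoulli
    draw on their liability until both the case and the control quota are
    filled; exactly ``n_cases`` cases precede ``n_controls`` controls in the
    output.  Covariates: the first three genotypic principal components, sex,
    age, and the true HLA-region liability contribution as an HLA risk
    covariate.
    """
    variants = architecture.variants
    rng = _stream(config, _S_STUDY)
    batch = max(2048, config.n_cases + config.n_controls)
    cases, controls = [], []
    for _ in range(max_batches):
        d = _draw_genotypes(config, variants, rng, batch)
        lin = architecture.liability(d, rng)
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-lin))
        need_ca = config.n_cases - sum(len(x) for x in cases)
        need_co = config.n_controls - sum(len(x) for x in controls)
        if need_ca > 0:
            cases.append(d[is_case][:need_ca])
        if need_co > 0:
            controls.append(d[~is_case][:need_co])
        if (sum(len(x) for x in cases) >= config.n_cases
                and sum(len(x) for x in controls) >= config.n_controls):
            break
    else:
        got_ca = sum(len(x) for x in cases)
        got_co = sum(len(x) for x in controls)
        raise SimulationError(
            f"could not fill quotas after {max_batches} batches "
            f"(cases {got_ca}/{config.n_cases}, "
            f"controls {got_co}/{config.n_controls}); "
            "liability model may be degenerate")

    dosages = np.vstack(cases + controls)
    n = len(dosages)
    samples = _samples_frame("ind", n)
    samples["status"] = np.r_[np.ones(config.n_cases, dtype=int),
                              np.zeros(config.n_controls, dtype=int)]
    samples["sex"] = rng.integers(0, 2, size=n)
    samples["age"] = np.round(rng.normal(50.0, 12.0, size=n), 1)
    std = dosages.std(axis=0)
    std[std == 0] = 1.0
    x = (dosages - dosages.mean(axis=0)) / std
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    for i in range(3):
        samples[f"pc{i + 1}"] = u[:, i] * s[i]
    samples["hla_risk"] = architecture.hla_direct_liability(dosages)
    return GenotypeMatrix(dosages, variants.copy(), samples)


# ---------------------------------------------------------------------------
# expression-GWAS summary statistics

def compute_summary_stats(panel_for_gwas: GenotypeMatrix,
                          architecture: TrueArchitecture,
                          config: SimulationConfig) -> pd.DataFrame:
    """Marginal single-SNP regression of simulated expression on dosage.

    For each gene, expression is its genetic value plus environmental noise
    scaled so total heritability equals ``expression_heritability``.  Trans
    records (further than 5 Mb from the transcription site, or on another
    chromosome) are emitted only for the tested SNP subset; records within
    the cis window are always emitted.  Monomorphic variants are skipped.
    """
    variants = architecture.variants
    dosages = panel_for_gwas.dosages
    n = dosages.shape[0]
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(6)[_S_TESTED])
    tested = noise_rng.random(len(variants)) < config.tested_snp_fraction
    hla = variants["block_id"].isin(config.hla_block_ids).to_numpy()
    tested |= hla  # trait-associated SNPs are always in the tested set

    var_g = dosages.var(axis=0, ddof=1)
    poly = var_g > 0
    if not poly.all():
        logger.info("summary stats: skipping %d monomorphic variants",
                    (~poly).sum())
    centered = dosages - dosages.mean(axis=0)

    expr = architecture.genetic_expression(dosages, centered=False)
    maf = variants["maf"].to_numpy()
    frames = []
    for _, gene in architecture.genes.iterrows():
        target = gene["target_id"]
        eff = architecture.effects[architecture.effects["target_id"] == target]
        gen_var = float(np.sum(
            eff["effect"].to_numpy() ** 2
            * 2 * maf[eff["variant_index"]] * (1 - maf[eff["variant_index"]])))
        h2 = config.expression_heritability
        env_sd = np.sqrt(gen_var * (1 - h2) / h2) if gen_var > 0 else 1.0
        y = expr[target].to_numpy() + noise_rng.normal(0, env_sd, size=n)
        yc = y - y.mean()
        var_y = yc @ yc / (n - 1)
        beta = np.full(len(variants), np.nan)
        beta[poly] = (centered[:, poly].T @ yc) / ((n - 1) * var_g[poly])
        resid_var = np.maximum(var_y / var_g - beta ** 2, 0.0)
        se = np.sqrt(resid_var / (n - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta / se
        pval = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        pval = np.clip(pval, np.nextafter(0, 1), 1.0)

        same_chrom = (variants["chrom"] == gene["chrom"]).to_numpy()
        dist = np.where(
            variants["pos"] < gene["site_start"],
            gene["site_start"] - variants["pos"],
            np.maximum(variants["pos"] - gene["site_end"], 0))
        in_cis_window = same_chrom & (dist <= TRANS_WINDOW_BP)
        emit = poly & (in_cis_window | tested)
        frames.append(pd.DataFrame({
            "variant_id": variants.loc[emit, "variant_id"].to_numpy(),
            "chrom": variants.loc[emit, "chrom"].to_numpy(),
            "pos": variants.loc[emit, "pos"].to_numpy(),
            "effect_allele": variants.loc[emit, "effect_allele"].to_numpy(),
            "other_allele": variants.loc[emit, "other_allele"].to_numpy(),
            "beta": beta[emit],
            "se": se[emit],
            "pvalue": pval[emit],
            "target_id": target,
            "n": n,
        }))
    return pd.concat(frames, ignore_index=True)
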