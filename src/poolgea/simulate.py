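"""Synthetic pool-seq and ecological data with known ground truth.

The generator emulates the study design this package analyses: K natural
plant populations (default 21) pool-sequenced at moderate depth, whose
allele frequencies covary through a shared demographic history captured by
a K x K covariance matrix Omega of scaled allele frequencies.  A minority
of SNPs respond linearly to an environmental covariate; visitation counts
of pollinator functional categories are over-dispersed (negative binomial).

Everything downstream (filters, Omega estimation, X^T^X, Bayes factors,
local score, enrichment, gene mapping) can therefore be tested against a
recorded truth table instead of unavailable field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AlleleFreqMatrix, PoolCounts, pop_labels

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "build_omega",
    "simulate_frequencies",
    "simulate_environment",
    "spike_environment",
    "simulate_pool_reads",
    "simulate_visitation",
    "write_synthetic_inputs",
]

#: frequency clamp bounds: keep cells away from degenerate Bernoulli draws
FREQ_LO = 0.005
FREQ_HI = 0.995

#: default 12 pollinator functional categories (wasps dropped for scarcity)
POLLINATOR_CATEGORIES = (
    "bumblebees",
    "long_tongue_bees",
    "large_bees",
    "small_bees",
    "honeybees",
    "large_wasps",
    "small_flies",
    "large_flies",
    "hoverflies",
    "small_beetles",
    "large_beetles",
    "butterflies",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    ``omega_spec`` is one of ``identity``, ``block`` or ``spatial-decay``.
    The spatial-decay default places populations on a unit-spaced 1-D
    transect with correlation structure nugget*I + (1-nugget)*exp(-d/range),
    a strongly structured setting mirroring real regional population systems
    where the leading genomic axis dominates.  ``omega_scale`` multiplies the
    whole matrix: it is the drift variance of scaled allele frequencies since
    the common ancestral population (an F_ST-like quantity, typically 0.05 to
    0.3 at regional scale); at 1.0 the frequency clamp would truncate most
    SNPs and destroy the linear geometry the model assumes.
    """

    n_pops: int = 21
    n_snps: int = 10_000
    n_scaffolds: int = 10
    omega_spec: str = "spatial-decay"
    omega_scale: float = 0.15
    omega_nugget: float = 0.1
    omega_range: float = 8.0
    omega_block_size: int = 3
    omega_block_rho: float = 0.5
    pi_range: tuple[float, float] = (0.05, 0.95)
    depth_mean: float = 60.0
    n_adaptive: int = 0
    beta: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pi_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"pi_range must be within (0,1), got {self.pi_range}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.omega_scale <= 0:
            raise ValueError("omega_scale must be positive")
        if self.n_adaptive > self.n_snps:
            raise ValueError("n_adaptive cannot exceed n_snps")
        if self.n_pops < 2:
            raise ValueError("need at least two populations")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pi_range" in raw:
            raw["pi_range"] = tuple(raw["pi_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthTable:
    """Ground truth recorded by the generator."""

    adaptive_snp_ids: list[int] = field(default_factory=list)
    beta_per_snp: dict[int, float] = field(default_factory=dict)
    true_omega: np.ndarray | None = None
    true_pi: np.ndarray | None = None
    spiked_variable: str | None = None


def build_omega(config: SimulationConfig) -> np.ndarray:
    """Construct the true among-population covariance Omega."""
    k = config.n_pops
    if config.omega_spec == "identity":
        omega = np.eye(k)
    elif config.omega_spec == "block":
        bs = config.omega_block_size
        rho = config.omega_block_rho
        omega = np.eye(k)
        for start in range(0, k, bs):
            stop = min(start + bs, k)
            omega[start:stop, start:stop] = rho
        np.fill_diagonal(omega, 1.0)
    elif config.omega_spec == "spatial-decay":
        pos = np.arange(k, dtype=float)
        d = np.abs(pos[:, None] - pos[None, :])
        nug = config.omega_nugget
        omega = nug * np.eye(k) + (1.0 - nug) * np.exp(-d / config.omega_range)
    else:
        raise ValueError(f"unknown omega_spec: {config.omega_spec!r}")
    omega = config.omega_scale * omega
    # explicit failure on non-positive-definite specifications
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guard
        raise ValueError("omega_spec produced a non-positive-definite matrix") from exc
    return omega


def _snp_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign SNPs to scaffolds in contiguous runs with increasing positions."""
    n, s = config.n_snps, config.n_scaffolds
    per = np.full(s, n // s)
    per[: n % s] += 1
    scaffolds = np.repeat([f"scaffold_{i + 1}" for i in range(s)], per)
    positions = np.empty(n, dtype=np.int64)
    start = 0
    for count in per:
        # mean inter-SNP spacing ~120 bp, strictly increasing
        gaps = rng.integers(1, 240, size=count)
        positions[start : start + count] = 100 + np.cumsum(gaps)
        start += count
    return pd.DataFrame({"scaffold": scaffolds, "pos": positions})


def simulate_frequencies(config: SimulationConfig) -> tuple[AlleleFreqMatrix, TruthTable]:
    """Draw population allele frequencies with covariance Omega.

    Per SNP j: ancestral frequency pi_j ~ U(pi_range); deviations
    y_j ~ N(0, Omega); p_ij = clamp(pi_j + sqrt(pi_j(1-pi_j)) y_ij).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    omega = build_omega(config)
    lo, hi = config.pi_range
    pi = rng.uniform(lo, hi, size=config.n_snps)
    chol = np.linalg.cholesky(omega)
    y = rng.standard_normal((config.n_snps, config.n_pops)) @ chol.T
    scale = np.sqrt(pi * (1.0 - pi))[:, None]
    p = np.clip(pi[:, None] + scale * y, FREQ_LO, FREQ_HI)
    snps = _snp_table(config, rng)
    freqs = AlleleFreqMatrix(
        freq=p,
        mask=np.zeros_like(p, dtype=bool),
        pi=p.mean(axis=1),
        snps=snps,
        pop_labels=pop_labels(config.n_pops),
    )
    truth = TruthTable(true_omega=omega, true_pi=pi)
    return freqs, truth


def simulate_environment(
    n_pops: int,
    n_noise_vars: int = 3,
    seed: int = 0,
    gradient_noise: float = 0.3,
) -> pd.DataFrame:
    """Environmental covariates: a latitude-like gradient plus noise variables.

    The gradient variable tracks the transect used by the spatial-decay
    Omega (hence is partly confounded with population structure); the noise
    variables are population-specific, emulating ecological measurements
    that vary independently of the demographic history.
    """
    rng = np.random.default_rng(seed)
    labels = pop_labels(n_pops)
    grad = np.linspace(-1.0, 1.0, n_pops) + gradient_noise * rng.standard_normal(n_pops)
    data = {"latitude_gradient": grad}
    for v in range(n_noise_vars):
        data[f"env_noise_{v + 1}"] = rng.standard_normal(n_pops)
    return pd.DataFrame(data, index=pd.Index(labels, name="population"))


def spike_environment(
    freqs: AlleleFreqMatrix,
    env: np.ndarray | pd.Series,
    config: SimulationConfig,
    truth: TruthTable | None = None,
    block_size: int = 1,
) -> tuple[AlleleFreqMatrix, TruthTable]:
    """Make ``n_adaptive`` SNPs respond linearly to an environmental covariate.

    p_ij <- clamp(p_ij + beta * standardized(env_i)).  With ``block_size``
    > 1 the adaptive SNPs are placed in runs of adjacent SNPs (all inside
    one scaffold), emulating the positional autocorrelation of real hits
    that the local score exploits.
    """
    env = np.asarray(env, dtype=float)
    if env.shape[0] != freqs.n_pops:
        raise ValueError("env must have one value per population")
    if config.n_adaptive > freqs.n_snps:
        raise ValueError("n_adaptive exceeds number of SNPs")
    truth = truth or TruthTable()
    rng = np.random.default_rng(config.seed + 1)
    e = (env - env.mean()) / env.std()

    chosen: list[int] = []
    if config.n_adaptive:
        if block_size <= 1:
            chosen = sorted(
                rng.choice(freqs.n_snps, size=config.n_adaptive, replace=False).tolist()
            )
        else:
            n_blocks, rem = divmod(config.n_adaptive, block_size)
            if rem:
                raise ValueError("n_adaptive must be a multiple of block_size")
            scafs = freqs.snps["scaffold"].to_numpy()
            taken: set[int] = set()
            for _ in range(n_blocks):
                for _attempt in range(1000):
                    start = int(rng.integers(0, freqs.n_snps - block_size))
                    block = range(start, start + block_size)
                    if scafs[start] == scafs[start + block_size - 1] and not taken.intersection(block):
                        taken.update(block)
                        break
                else:  # pragma: no cover - pathological configs only
                    raise RuntimeError("could not place adaptive blocks")
            chosen = sorted(taken)

    p = freqs.freq.copy()
    for j in chosen:
        p[j, :] = np.clip(p[j, :] + config.beta * e, FREQ_LO, FREQ_HI)
    out = AlleleFreqMatrix(
        freq=p,
        mask=freqs.mask.copy(),
        pi=p.mean(axis=1),
        snps=freqs.snps.copy(),
        pop_labels=list(freqs.pop_labels),
    )
    truth.adaptive_snp_ids = chosen
    truth.beta_per_snp = {j: config.beta for j in chosen}
    return out, truth


def simulate_pool_reads(
    freqs: AlleleFreqMatrix, depth_mean: float, seed: int = 0
) -> PoolCounts:
    """Binomial read sampling: depth ~ Poisson(depth_mean), alt ~ Bin(depth, p)."""
    if np.any((freqs.freq < 0) | (freqs.freq > 1)):
        raise ValueError("frequencies must lie in [0,1]")
    rng = np.random.default_rng(seed)
    depth = rng.poisson(depth_mean, size=freqs.freq.shape)
    alt = rng.binomial(depth, freqs.freq)
    ref = depth - alt
    snps = freqs.snps.copy()
    bases = np.array(["A", "C", "G", "T"])
    ref_al = rng.integers(0, 4, size=freqs.n_snps)
    alt_al = (ref_al + rng.integers(1, 4, size=freqs.n_snps)) % 4
    snps["ref"] = bases[ref_al]
    snps["alt"] = bases[alt_al]
    return PoolCounts(
        ref_count=ref, alt_count=alt, snps=snps, pop_labels=list(freqs.pop_labels)
    )


def simulate_visitation(
    n_pops: int = 21,
    categories: tuple[str, ...] = POLLINATOR_CATEGORIES,
    rate_matrix: np.ndarray | None = None,
    dispersion: float = 2.0,
    seed: int = 0,
    plants_per_pop: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Over-dispersed visitation counts per (population, category).

    Counts are negative binomial with mean from ``rate_matrix`` and shape
    ``dispersion`` (Poisson recovered as dispersion -> infinity).  With
    ``plants_per_pop`` set, a per-plant decomposition of total visits is
    also returned (population random effect included) for BLUP testing.
    """
    rng = np.random.default_rng(seed)
    n_cat = len(categories)
    if rate_matrix is None:
        # heterogeneous but fixed expected rates: community composition
        # varies across populations around category-level base rates
        base = rng.gamma(2.0, 4.0, size=n_cat)
        pop_effect = rng.lognormal(0.0, 0.5, size=(n_pops, 1))
        tilt = rng.lognormal(0.0, 0.6, size=(n_pops, n_cat))
        rate_matrix = base[None, :] * pop_effect * tilt
    rate_matrix = np.asarray(rate_matrix, dtype=float)
    if rate_matrix.shape != (n_pops, n_cat):
        raise ValueError("rate_matrix must be (n_pops, n_categories)")
    if np.any(rate_matrix < 0):
        raise ValueError("rate_matrix must be nonnegative")

    with np.errstate(divide="ignore", invalid="ignore"):
        p = dispersion / (dispersion + rate_matrix)
    counts = np.where(
        rate_matrix > 0, rng.negative_binomial(dispersion, np.clip(p, 1e-12, 1.0)), 0
    )
    labels = pop_labels(n_pops)
    visits = pd.DataFrame(counts, index=pd.Index(labels, name="population"), columns=list(categories))

    plant_level = None
    if plants_per_pop:
        rows = []
        for i, lab in enumerate(labels):
            total = counts[i].sum()
            # multinomial split of the population total over plants
            share = rng.dirichlet(np.ones(plants_per_pop))
            per_plant = rng.multinomial(total, share)
            for k, v in enumerate(per_plant):
                rows.append({"population": lab, "plant": f"{lab}_p{k + 1}", "visits": int(v)})
        plant_level = pd.DataFrame(rows)
    return visits, plant_level


def write_synthetic_inputs(
    outdir: str | Path,
    config: SimulationConfig | None = None,
    n_genes_per_scaffold: int = 5,
    spike_block_size: int = 1,
) -> dict[str, Path]:
    """Emit a complete synthetic input bundle: pooled VCF, env TSV,
    visitation TSV, a toy GFF3 with genes tiled over the scaffolds, and the
    ground-truth table as JSON.

    Round-trips losslessly through :mod:`poolgea.vcfio`.
    """
    import json

    from . import vcfio  # local import: avoid cycle at module load

    config = config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    freqs, truth = simulate_frequencies(config)
    env = simulate_environment(config.n_pops, seed=config.seed)
    if config.n_adaptive:
        freqs, truth = spike_environment(
            freqs, env.iloc[:, -1].to_numpy(), config, truth,
            block_size=spike_block_size,
        )
        truth.spiked_variable = env.columns[-1]
    counts = simulate_pool_reads(freqs, config.depth_mean, seed=config.seed + 2)

    paths = {
        "vcf": outdir / "pools.vcf",
        "env": outdir / "environment.tsv",
        "visits": outdir / "visitation.tsv",
        "gff": outdir / "annotation.gff3",
        "config": outdir / "config.yaml",
        "truth": outdir / "truth.json",
    }
    vcfio.write_pool_vcf(counts, paths["vcf"])
    env.to_csv(paths["env"], sep="\t")
    visits, _ = simulate_visitation(config.n_pops, seed=config.seed + 3)
    visits.to_csv(paths["visits"], sep="\t")
    _write_toy_gff(freqs.snps, paths["gff"], n_genes_per_scaffold)
    config.to_yaml(paths["config"])
    adaptive = freqs.snps.iloc[truth.adaptive_snp_ids]
    paths["truth"].write_text(
        json.dumps(
            {
                "adaptive_snp_ids": list(map(int, truth.adaptive_snp_ids)),
                "adaptive_sites": [
                    f"{row.scaffold}:{row.pos}" for row in adaptive.itertuples()
                ],
                "beta": config.beta,
                "spiked_variable": truth.spiked_variable,
            },
            indent=2,
        )
        + "\n"
    )
    return paths


def _write_toy_gff(snps: pd.DataFrame, path: Path, n_genes_per_scaffold: int) -> None:
    lines = ["##gff-version 3"]
    gene_id = 0
    for scaf, grp in snps.groupby("scaffold", sort=False):
        length = int(grp["pos"].max()) + 1000
        lines.append(f"##sequence-region {scaf} 1 {length}")
        span = length // n_genes_per_scaffold
        for g in range(n_genes_per_scaffold):
            gene_id += 1
            start = g * span + span // 4 + 1
            end = start + span // 2
            strand = "+" if g % 2 == 0 else "-"
            lines.append(
                f"{scaf}\tsynthetic\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID=gene{gene_id:04d};Name=gene{gene_id:04d}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
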