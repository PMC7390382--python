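"""Synthetic biparental-family RNA-seq counts with planted inheritance modes.

The generator emulates a two-parent / seven-F1 willow family design: 9
genotypes sampled at 4 time points (0, 6, 24, 96 h) with 3 replicates each,
negative-binomial counts with a common dispersion, unequal library sizes
(log-normal around 6.4 million reads), gene positions spread over 19
chromosomes, and an optional causal co-expression module whose genotype-level
activity drives a phenotypic trait.

Every gene carries a planted inheritance class; group mean CPMs are set from
the class (dominant: hybrid mean equals one parent; additive: arithmetic
mid-parent; over/underdominant: a fixed log2 offset beyond the parental
range), giving exact ground truth for parameter-recovery tests.  Class
counts follow the requested proportions deterministically (largest-remainder
allocation), and one seed drives independent substreams for means, classes,
positions, library sizes, counts and traits, so any component can be
regenerated alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CountsMatrix, cpm_normalize
from .association import module_eigengene

__all__ = ["SimulationConfig", "simulate_family", "simulate_traits", "write_dataset"]

TRUE_CLASSES = (
    "P1_dominant",
    "P2_dominant",
    "additive",
    "overdominant",
    "underdominant",
    "conserved",
)

_DEFAULT_PROPORTIONS = {
    "P1_dominant": 0.15,
    "P2_dominant": 0.15,
    "additive": 0.05,
    "overdominant": 0.05,
    "underdominant": 0.05,
    "conserved": 0.55,
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the family simulator.

    Defaults mirror the emulated design: 2 parents + 7 F1 genotypes, time
    points 0/6/24/96 h, 3 replicates, NB dispersion 0.05, baseline expression
    log-normal with median 200 CPM, parental difference of 2 log2 units for
    non-conserved genes, transgressive offset 1 log2 unit beyond the parental
    range, library sizes log-normal around 6.38 million reads, and 19
    chromosomes of 18 Mb.
    """

    n_genes: int = 1200
    class_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    n_f1_genotypes: int = 7
    time_points: tuple = (0, 6, 24, 96)
    replicates: int = 3
    baseline_log2cpm_mean: float = float(np.log2(200.0))
    baseline_log2cpm_sd: float = 1.0
    parental_log2fc: float = 2.0
    transgressive_log2_offset: float = 1.0
    dispersion: float = 0.05
    library_size_mean: float = 6_384_059.0
    library_size_sdlog: float = 0.18
    n_chromosomes: int = 19
    chromosome_length: int = 18_000_000
    causal_module_size: int = 30
    module_genotype_sd: float = 0.5
    trait_effect: float = 1.0
    trait_sd: float = 0.25
    time_varying_classes: bool = False
    seed: int = 0

    def validate(self) -> None:
        props = self.class_proportions
        unknown = set(props) - set(TRUE_CLASSES)
        if unknown:
            raise ValueError(f"class_proportions: unknown classes {sorted(unknown)}")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in props.values()):
            raise ValueError("class_proportions must be nonnegative and sum to 1")
        for name in ("n_genes", "n_f1_genotypes", "replicates", "n_chromosomes",
                     "chromosome_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion must be >= 0 and library sizes positive")
        if self.causal_module_size < 0 or self.trait_sd < 0:
            raise ValueError("causal_module_size and trait_sd must be nonnegative")


def _largest_remainder(n: int, proportions: dict) -> list[str]:
    """Deterministic class allocation: exact counts by largest remainder."""
    labels = [c for c in TRUE_CLASSES if proportions.get(c, 0) > 0]
    quotas = np.array([proportions[c] * n for c in labels])
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:short]] += 1
    out = []
    for lbl, k in zip(labels, base):
        out.extend([lbl] * k)
    return out


def _class_means(cls: str, base_cpm: float, rng, delta: float, offset: float):
    """Ground-truth (mu_P1, mu_P2, mu_H) CPM for one gene."""
    if cls == "conserved":
        return base_cpm, base_cpm, base_cpm
    hi = base_cpm * 2 ** (delta / 2)
    lo = base_cpm * 2 ** (-delta / 2)
    p1_high = bool(rng.integers(2))
    mu_p1, mu_p2 = (hi, lo) if p1_high else (lo, hi)
    if cls == "P1_dominant":
        mu_h = mu_p1
    elif cls == "P2_dominant":
        mu_h = mu_p2
    elif cls == "additive":
        mu_h = (mu_p1 + mu_p2) / 2
    elif cls == "overdominant":
        mu_h = max(mu_p1, mu_p2) * 2**offset
    elif cls == "underdominant":
        mu_h = min(mu_p1, mu_p2) * 2**-offset
    else:  # pragma: no cover
        raise ValueError(cls)
    return mu_p1, mu_p2, mu_h


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_family(config: SimulationConfig):
    """Generate (CountsMatrix, sample table, gene annotation, truth table).

    Deterministic given ``config.seed``; independent named substreams are
    spawned from one root SeedSequence.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("classes", "means", "positions", "libsizes", "counts", "module"),
            root.spawn(6),
        )
    }

    genes = [f"gene{str(i + 1).zfill(5)}" for i in range(config.n_genes)]
    classes = _largest_remainder(config.n_genes, config.class_proportions)
    # interleave classes across the genome deterministically
    perm = streams["classes"].permutation(config.n_genes)
    classes = [classes[j] for j in np.argsort(perm, kind="stable")]

    base = 2 ** streams["means"].normal(
        config.baseline_log2cpm_mean, config.baseline_log2cpm_sd, config.n_genes
    )
    mu = np.empty((config.n_genes, 3))
    for i, (cls, b) in enumerate(zip(classes, base)):
        mu[i] = _class_means(
            cls, b, streams["means"], config.parental_log2fc,
            config.transgressive_log2_offset,
        )

    # gene positions: uniform over chromosomes, BED half-open
    rngp = streams["positions"]
    chroms = rngp.integers(1, config.n_chromosomes + 1, config.n_genes)
    lengths = rngp.integers(300, 5001, config.n_genes)
    starts = rngp.integers(0, config.chromosome_length - 5001, config.n_genes)
    annotation = pd.DataFrame(
        {
            "chromosome": [f"Chr{c:02d}" for c in chroms],
            "start": starts,
            "end": starts + lengths,
        },
        index=pd.Index(genes, name="gene_id"),
    )

    # causal module: conserved genes sharing a genotype-level activity factor
    module_label = np.full(config.n_genes, "", dtype=object)
    conserved_idx = np.flatnonzero(np.array(classes) == "conserved")
    if config.causal_module_size > len(conserved_idx):
        raise ValueError(
            "causal_module_size exceeds the number of conserved genes; "
            "raise the conserved proportion"
        )
    member_idx = conserved_idx[: config.causal_module_size]
    module_label[member_idx] = "causal"

    genotypes = ["P1", "P2"] + [f"F1_{i + 1:02d}" for i in range(config.n_f1_genotypes)]
    roles = {g: ("P1" if g == "P1" else "P2" if g == "P2" else "F1") for g in genotypes}
    geno_factor = dict(
        zip(genotypes, streams["module"].normal(0.0, 1.0, len(genotypes)))
    )

    rows = []
    for g in genotypes:
        for tp in config.time_points:
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{g}_T{tp}_R{rep}",
                        "genotype_id": g,
                        "role": roles[g],
                        "time_point": tp,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(rows)

    lib = np.asarray(
        np.round(
            config.library_size_mean
            * np.exp(
                streams["libsizes"].normal(0.0, config.library_size_sdlog, len(samples))
                - config.library_size_sdlog**2 / 2
            )
        ),
        dtype=np.int64,
    )

    role_col = {"P1": 0, "P2": 1, "F1": 2}
    counts = np.empty((config.n_genes, len(samples)), dtype=np.int64)
    class_by_time = {tp: classes for tp in config.time_points}
    if config.time_varying_classes:
        for tp in config.time_points[1:]:
            perm_t = streams["classes"].permutation(config.n_genes)
            class_by_time[tp] = [classes[j] for j in perm_t]

    mu_by_time = {config.time_points[0]: mu}
    for tp in config.time_points[1:]:
        if config.time_varying_classes:
            m_t = np.empty_like(mu)
            for i, (cls, b) in enumerate(zip(class_by_time[tp], base)):
                m_t[i] = _class_means(
                    cls, b, streams["means"], config.parental_log2fc,
                    config.transgressive_log2_offset,
                )
            mu_by_time[tp] = m_t
        else:
            mu_by_time[tp] = mu

    rngc = streams["counts"]
    for j, row in samples.iterrows():
        m_t = mu_by_time[row["time_point"]]
        cpm_mean = m_t[:, role_col[row["role"]]].copy()
        if config.causal_module_size:
            cpm_mean[member_idx] = cpm_mean[member_idx] * 2 ** (
                config.module_genotype_sd * geno_factor[row["genotype_id"]]
            )
        sample_mean = cpm_mean * lib[j] / 1e6
        counts[:, j] = _nb_draw(rngc, sample_mean, config.dispersion)

    cm = CountsMatrix(
        pd.DataFrame(counts, index=genes, columns=samples["sample_id"]),
        pd.Series(lib, index=samples["sample_id"]),
    )
    truth = pd.DataFrame(
        {
            "true_class": pd.Categorical(classes, categories=list(TRUE_CLASSES)),
            "mu_p1": mu[:, 0],
            "mu_p2": mu[:, 1],
            "mu_h": mu[:, 2],
            "chromosome": annotation["chromosome"].to_numpy(),
            "start": annotation["start"].to_numpy(),
            "module_label": module_label,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    if config.time_varying_classes:
        for tp in config.time_points:
            truth[f"class_T{tp}"] = pd.Categorical(
                class_by_time[tp], categories=list(TRUE_CLASSES)
            )
    return cm, samples, annotation, truth


def simulate_traits(
    truth: pd.DataFrame,
    counts: CountsMatrix,
    samples: pd.DataFrame,
    effect: float = 1.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    trait_name: str = "damage_severity",
) -> pd.DataFrame:
    """Genotype-level trait coupled to the causal module's eigengene.

    trait(genotype) = effect * genotype-mean eigengene + N(0, noise_sd).
    Returns a tidy table (genotype_id, trait_name, value), one row per
    genotype.
    """
    members = truth.index[truth["module_label"] == "causal"].tolist()
    if not members:
        raise ValueError("truth table has no causal module genes")
    norm = cpm_normalize(counts, log_scale=True)
    eig = module_eigengene(norm, members, label="causal")
    geno = samples.set_index("sample_id")["genotype_id"]
    by_geno = eig.values.groupby(geno.loc[eig.values.index]).mean()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    vals = effect * by_geno.to_numpy() + rng.normal(0.0, noise_sd, len(by_geno))
    return pd.DataFrame(
        {
            "genotype_id": by_geno.index,
            "trait_name": trait_name,
            "value": vals,
        }
    ).reset_index(drop=True)


def write_dataset(outdir, config: SimulationConfig, with_traits: bool = True) -> dict:
    """Simulate and write a full dataset directory; returns the manifest."""
    import json
    from pathlib import Path

    from .io import write_counts, write_gene_positions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, samples, annotation, truth = simulate_family(config)
    write_counts(cm, outdir / "counts.tsv")
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_gene_positions(annotation, outdir / "genes.bed")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    files = ["counts.tsv", "samples.tsv", "genes.bed", "truth.tsv"]
    if with_traits and config.causal_module_size:
        traits = simulate_traits(
            truth, cm, samples,
            effect=config.trait_effect, noise_sd=config.trait_sd, seed=config.seed,
        )
        traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
        files.append("traits.tsv")
    manifest = {"config": asdict(config), "files": files}
    manifest["config"]["class_proportions"] = dict(config.class_proportions)
    manifest["config"]["time_points"] = list(config.time_points)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
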