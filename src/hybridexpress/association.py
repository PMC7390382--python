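"""Gene-trait and module-trait association.

Traits are genotype-level means (e.g. percent damage severity), so gene
expression is summarized per genotype as the mean log2-CPM over that
genotype's samples before regression.  The per-gene association statistic is
the Manhattan score R^2 * -log10(p) from a simple linear regression of trait
on expression, with a genome-wide Bonferroni threshold of -log10(alpha / n
genes).  Co-expression modules are summarized by their eigengene (first
principal component of the z-scored member submatrix) and correlated with
traits at the genotype level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountsMatrix, NormalizedMatrix, cpm_normalize, validate_sample_table

__all__ = [
    "ModuleEigengene",
    "gene_trait_score",
    "genomewide_threshold",
    "manhattan_table",
    "module_eigengene",
    "module_trait_correlation",
    "qpcr_relative_expression",
    "genotype_mean_expression",
    "TraitAssociationModel",
    "AssociationResults",
]

_P_FLOOR = 1e-300


def genotype_mean_expression(
    norm: NormalizedMatrix, samples: pd.DataFrame, time_point=None
) -> pd.DataFrame:
    """Mean expression per genotype (genes x genotypes), optionally at one
    time point."""
    samples = validate_sample_table(samples)
    if time_point is not None:
        samples = samples[samples["time_point"] == time_point]
        if samples.empty:
            raise ValueError(f"no samples at time point {time_point!r}")
    cols = {}
    for genotype, gdf in samples.groupby("genotype_id", sort=True):
        cols[genotype] = norm.values[gdf["sample_id"].tolist()].mean(axis=1)
    return pd.DataFrame(cols)


def gene_trait_score(expression, trait) -> dict:
    """Regress a trait on one gene's per-genotype expression.

    Returns r_squared (squared Pearson correlation), the two-sided p-value
    from the t statistic with n - 2 df, and the Manhattan score
    R^2 * -log10(p) (p floored at 1e-300).  Zero variance in either variable
    yields a degenerate record with score 0 rather than an error.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.size != y.size:
        raise ValueError("expression and trait must be paired per genotype")
    if x.size < 3:
        raise ValueError("need at least 3 genotypes for a regression")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r_squared": 0.0, "p_value": 1.0, "score": 0.0, "degenerate": True}
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    p = float(max(fit.pvalue, _P_FLOOR))
    return {
        "r_squared": r2,
        "p_value": p,
        "score": r2 * -np.log10(p),
        "degenerate": False,
    }


def genomewide_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni-style genome-wide score threshold, -log10(alpha / n)."""
    if n_genes < 1 or alpha <= 0:
        raise ValueError("n_genes must be >= 1 and alpha > 0")
    return float(-np.log10(alpha / n_genes))


def manhattan_table(
    records: pd.DataFrame, annotation: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach genomic positions to association records for Manhattan plotting.

    Rows (chromosome, position_mb, gene_id, score, passes_threshold) sorted by
    chromosome then position; the threshold is genomewide_threshold over the
    number of records.
    """
    missing = sorted(set(records["gene_id"]) - set(annotation.index))
    if missing:
        raise ValueError(f"genes missing from annotation: {missing[:10]}")
    thr = genomewide_threshold(len(records), alpha)
    ann = annotation.loc[records["gene_id"]]
    out = records.copy()
    out["chromosome"] = ann["chromosome"].to_numpy()
    out["position_mb"] = (ann["start"].to_numpy() + ann["end"].to_numpy()) / 2 / 1e6
    out["passes_threshold"] = out["score"] >= thr
    out = out.sort_values(["chromosome", "position_mb"], kind="stable")
    out.attrs["threshold"] = thr
    return out.reset_index(drop=True)


@dataclass
class ModuleEigengene:
    """First-PC summary of a co-expression module, one value per sample.

    Values are zero-mean with unit standard deviation, oriented so the mean
    correlation with member genes is nonnegative (ties broken by the first
    member gene).
    """

    module_label: str
    values: pd.Series
    variance_explained: float


def module_eigengene(norm: NormalizedMatrix, member_genes, label: str = "module") -> ModuleEigengene:
    """Eigengene of a gene module: first principal component across samples.

    Member rows are z-scored across samples, then the dominant left pattern
    of the samples x genes matrix is extracted by SVD and scaled to unit SD.
    """
    member_genes = [g for g in member_genes]
    if len(member_genes) < 2:
        raise ValueError("a module needs at least 2 member genes")
    missing = sorted(set(member_genes) - set(norm.gene_ids))
    if missing:
        raise ValueError(f"module genes absent from matrix: {missing[:10]}")
    X = norm.values.loc[member_genes].to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("all module genes are constant across samples")
    keep = sd > 0
    X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    # samples x genes, columns standardized; first left singular vector
    u, s, _ = np.linalg.svd(X.T, full_matrices=False)
    eig = u[:, 0]
    corrs = np.array([np.corrcoef(eig, g)[0, 1] for g in X])
    mean_corr = corrs.mean()
    sign = np.sign(mean_corr) if mean_corr != 0 else np.sign(corrs[0]) or 1.0
    eig = eig * sign
    eig = eig / eig.std()
    return ModuleEigengene(
        module_label=label,
        values=pd.Series(eig, index=norm.sample_ids),
        variance_explained=float(s[0] ** 2 / np.sum(s**2)),
    )


def module_trait_correlation(
    eig: ModuleEigengene, trait: pd.Series, samples: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation of the genotype-mean eigengene with a trait.

    ``trait`` is indexed by genotype_id.  Returns (r, two-sided p).
    """
    samples = validate_sample_table(samples)
    by_geno = (
        pd.DataFrame(
            {
                "genotype_id": samples.set_index("sample_id").loc[
                    eig.values.index, "genotype_id"
                ],
                "eig": eig.values.to_numpy(),
            }
        )
        .groupby("genotype_id")["eig"]
        .mean()
    )
    common = by_geno.index.intersection(trait.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genotypes with both eigengene and trait")
    r, p = stats.pearsonr(by_geno.loc[common], trait.loc[common])
    return float(r), float(p)


def qpcr_relative_expression(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Comparative-Ct relative expression, 2**(-ddCt).

    ddCt = (Ct_target,treated - Ct_ref,treated) - (Ct_target,control -
    Ct_ref,control).
    """
    cts = np.array(
        [ct_target_treated, ct_reference_treated, ct_target_control, ct_reference_control],
        dtype=float,
    )
    if not np.all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))


@dataclass
class TraitAssociationModel:
    """Genome-wide gene-trait association for genotype-level trait means.

    Parameters
    ----------
    counts
        Expression-filtered counts.
    samples
        Sample metadata table.
    traits
        Tidy trait table with columns genotype_id, trait_name, value (one
        row per genotype per trait).
    annotation
        Optional gene positions for the Manhattan table.
    time_point
        Restrict the expression summary to one time point (default: mean
        over all samples of each genotype).
    """

    counts: CountsMatrix
    samples: pd.DataFrame
    traits: pd.DataFrame
    annotation: pd.DataFrame | None = None
    time_point: object = None

    def __post_init__(self) -> None:
        req = {"genotype_id", "trait_name", "value"}
        if not req <= set(self.traits.columns):
            raise ValueError(f"trait table needs columns {sorted(req)}")
        if self.traits.duplicated(["genotype_id", "trait_name"]).any():
            raise ValueError("duplicate (genotype, trait) rows in trait table")
        self.samples = validate_sample_table(self.samples)
        geno_expr = set(self.samples["genotype_id"])
        for trait_name, tdf in self.traits.groupby("trait_name"):
            matched = set(tdf["genotype_id"]) & geno_expr
            if len(matched) < 3:
                unmatched = sorted(set(tdf["genotype_id"]) - geno_expr)
                raise ValueError(
                    f"trait {trait_name!r}: fewer than 3 genotypes with "
                    f"expression data (unmatched: {unmatched})"
                )

    def fit(self, alpha: float = 0.05, log_pseudocount: float = 1.0) -> "AssociationResults":
        """Score every gene against every trait and flag genome-wide hits."""
        norm = cpm_normalize(self.counts, log_scale=True, pseudocount=log_pseudocount)
        expr = genotype_mean_expression(norm, self.samples, self.time_point)
        rows = []
        for trait_name, tdf in self.traits.groupby("trait_name", sort=True):
            tser = tdf.set_index("genotype_id")["value"]
            common = expr.columns.intersection(tser.index)
            e = expr[common].to_numpy()
            y = tser.loc[common].to_numpy(dtype=float)
            for i, gene in enumerate(expr.index):
                rec = gene_trait_score(e[i], y)
                rec.update(gene_id=gene, trait_name=trait_name)
                rows.append(rec)
        records = pd.DataFrame(rows)[
            ["gene_id", "trait_name", "r_squared", "p_value", "score", "degenerate"]
        ]
        thr = genomewide_threshold(expr.shape[0], alpha)
        records["passes_threshold"] = records["score"] >= thr
        return AssociationResults(
            records=records, threshold=thr, alpha=alpha,
            n_genes=expr.shape[0], annotation=self.annotation,
        )


@dataclass
class AssociationResults:
    """Per-gene association records and the genome-wide threshold used."""

    records: pd.DataFrame
    threshold: float
    alpha: float
    n_genes: int
    annotation: pd.DataFrame | None = field(default=None, repr=False)

    def manhattan_table(self, trait_name: str | None = None) -> pd.DataFrame:
        if self.annotation is None:
            raise ValueError("no gene annotation attached to the model")
        rec = self.records
        if trait_name is not None:
            rec = rec[rec["trait_name"] == trait_name]
        return manhattan_table(rec, self.annotation, self.alpha)

    def summary(self) -> str:
        lines = [
            "Gene-trait association (score = R^2 x -log10 p)",
            f"  genes: {self.n_genes}   alpha: {self.alpha}   "
            f"genome-wide threshold: {self.threshold:.4f}",
        ]
        for trait, tdf in self.records.groupby("trait_name"):
            top = tdf.loc[tdf["score"].idxmax()]
            lines.append(
                f"  {trait}: {int(tdf['passes_threshold'].sum())} genes pass; "
                f"top {top['gene_id']} (score {top['score']:.3f}, "
                f"R^2 {top['r_squared']:.3f})"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)
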