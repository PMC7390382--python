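"""Classification of F1 expression inheritance into six modes.

For each gene at a given time point, three pairwise exact-test comparisons
are run at a common FDR level alpha: P1 vs P2, hybrid (H) vs P1, and H vs
P2.  "H is indistinguishable from P1" means the H-vs-P1 comparison is not
significant; "H above P1" means significant with a positive log2 fold
change.  The six classes:

* conserved      — P1 ~ H ~ P2 (nothing significant)
* P1_dominant    — H ~ P1 and H != P2
* P2_dominant    — H ~ P2 and H != P1
* additive       — H between distinguishable parents (H != P1, H != P2 in
                   opposite directions, and P1 != P2)
* overdominant   — H above both parents
* underdominant  — H below both parents

Flag patterns matching none of these (e.g. parents differ but H matches
both) are "ambiguous".  The default "literal" rule applies the definitions
exactly as stated; the "strict" rule additionally requires the parents to
differ for the dominant classes, routing genes with indistinguishable
parents to ambiguous instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountsMatrix, validate_sample_table
from .nbtest import de_compare

__all__ = [
    "CLASSES",
    "classify_gene",
    "classify_all",
    "summarize_by_time",
    "bin_by_chromosome",
    "InheritanceModel",
    "InheritanceResults",
]

CLASSES = (
    "P1_dominant",
    "P2_dominant",
    "additive",
    "overdominant",
    "underdominant",
    "conserved",
    "ambiguous",
)


def classify_gene(
    sig_p1p2: bool,
    sig_hp1: bool,
    sig_hp2: bool,
    dir_hp1: int = 0,
    dir_hp2: int = 0,
    rule: str = "literal",
) -> str:
    """Map the three significance flags and two H-vs-parent signs to a class.

    ``dir_hp1``/``dir_hp2`` are the signs of the H-over-parent log2 fold
    changes and only matter when the corresponding flag is significant.
    Total and single-valued over the whole flag/direction space.
    """
    if rule not in ("literal", "strict"):
        raise ValueError(f"unknown rule {rule!r}")
    if not (sig_p1p2 or sig_hp1 or sig_hp2):
        return "conserved"
    if sig_hp1 and sig_hp2:
        if dir_hp1 > 0 and dir_hp2 > 0:
            return "overdominant"
        if dir_hp1 < 0 and dir_hp2 < 0:
            return "underdominant"
        # H between the parents: requires the parents themselves to differ
        if sig_p1p2 and dir_hp1 * dir_hp2 < 0:
            return "additive"
        return "ambiguous"
    if not sig_hp1 and sig_hp2:  # H ~ P1, H != P2
        if rule == "strict" and not sig_p1p2:
            return "ambiguous"
        return "P1_dominant"
    if not sig_hp2 and sig_hp1:  # H ~ P2, H != P1
        if rule == "strict" and not sig_p1p2:
            return "ambiguous"
        return "P2_dominant"
    return "ambiguous"  # e.g. parents differ but H matches both


def _roles(samples: pd.DataFrame, time_point) -> pd.DataFrame:
    sub = samples[samples["time_point"] == time_point]
    for role in ("P1", "P2", "F1"):
        if not (sub["role"] == role).any():
            raise ValueError(f"no {role} samples at time point {time_point!r}")
    return sub


def classify_all(
    m: CountsMatrix,
    samples: pd.DataFrame,
    time_point,
    alpha: float = 0.01,
    rule: str = "literal",
    f1: str = "pooled",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Classify every gene's inheritance mode at one time point.

    ``f1="pooled"`` pools all F1 samples into one hybrid group (family-level
    call); ``f1="per_f1"`` classifies each F1 genotype separately and returns
    one row per gene per genotype.  The counts matrix is expected to be
    expression-filtered already (CPM > 1 in at least half the samples).
    """
    if f1 not in ("pooled", "per_f1"):
        raise ValueError(f"unknown f1 mode {f1!r}")
    samples = validate_sample_table(samples)
    sub = _roles(samples, time_point)
    p1 = sub.loc[sub["role"] == "P1", "sample_id"].tolist()
    p2 = sub.loc[sub["role"] == "P2", "sample_id"].tolist()
    f1_sub = sub[sub["role"] == "F1"]
    groups = (
        {"F1(pooled)": f1_sub["sample_id"].tolist()}
        if f1 == "pooled"
        else {
            g: gdf["sample_id"].tolist()
            for g, gdf in f1_sub.groupby("genotype_id", sort=True)
        }
    )

    res_p1p2 = de_compare(m, p1, p2, alpha=alpha, min_abs_log2fc=0.0,
                          dispersion=dispersion)
    frames = []
    for genotype, h in groups.items():
        res_hp1 = de_compare(m, h, p1, alpha=alpha, min_abs_log2fc=0.0,
                             dispersion=dispersion)
        res_hp2 = de_compare(m, h, p2, alpha=alpha, min_abs_log2fc=0.0,
                             dispersion=dispersion)
        dir_hp1 = np.sign(res_hp1["log2_fold_change"].to_numpy()).astype(int)
        dir_hp2 = np.sign(res_hp2["log2_fold_change"].to_numpy()).astype(int)
        cls = [
            classify_gene(s0, s1, s2, d1, d2, rule=rule)
            for s0, s1, s2, d1, d2 in zip(
                res_p1p2["significant"].to_numpy(),
                res_hp1["significant"].to_numpy(),
                res_hp2["significant"].to_numpy(),
                dir_hp1,
                dir_hp2,
            )
        ]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": m.gene_ids,
                    "time_point": time_point,
                    "f1_genotype": genotype,
                    "p_p1p2": res_p1p2["p_value"].to_numpy(),
                    "fdr_p1p2": res_p1p2["fdr"].to_numpy(),
                    "p_hp1": res_hp1["p_value"].to_numpy(),
                    "fdr_hp1": res_hp1["fdr"].to_numpy(),
                    "p_hp2": res_hp2["p_value"].to_numpy(),
                    "fdr_hp2": res_hp2["fdr"].to_numpy(),
                    "sig_p1p2": res_p1p2["significant"].to_numpy(),
                    "sig_hp1": res_hp1["significant"].to_numpy(),
                    "sig_hp2": res_hp2["significant"].to_numpy(),
                    "dir_hp1": dir_hp1,
                    "dir_hp2": dir_hp2,
                    "inheritance_class": pd.Categorical(cls, categories=CLASSES),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_by_time(calls: pd.DataFrame, family_average: bool = False) -> pd.DataFrame:
    """Per-class gene counts for each time point.

    With ``family_average`` (per-genotype calls), class counts are first
    computed per F1 genotype and then averaged across genotypes, giving the
    family-average summary.
    """
    if calls.empty:
        raise ValueError("no calls to summarize")
    by = ["time_point", "f1_genotype"] if family_average else ["time_point"]
    tab = (
        calls.groupby(by, observed=False)["inheritance_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CLASSES), fill_value=0)
    )
    if family_average:
        tab = tab.groupby(level="time_point").mean()
    tab.columns.name = None
    return tab.reset_index()


def bin_by_chromosome(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    n_bins: int = 12,
    equal_width: bool = False,
) -> pd.DataFrame:
    """Per-chromosome positional binning of inheritance classes.

    Genes on each chromosome are ordered by start position and split into
    ``n_bins`` contiguous bins of near-equal gene count (sizes differ by at
    most one); ``equal_width`` bins by equal spans of physical position
    instead.  Returns tidy rows (chromosome, bin_index, class, count).
    """
    missing = sorted(set(calls["gene_id"]) - set(annotation.index))
    if missing:
        raise ValueError(f"genes missing from annotation: {missing[:10]}")
    ann = annotation.loc[calls["gene_id"]]
    df = calls.copy()
    df["chromosome"] = ann["chromosome"].to_numpy()
    df["start"] = ann["start"].to_numpy()
    out = []
    for chrom, cdf in df.groupby("chromosome", sort=True):
        cdf = cdf.sort_values(["start", "gene_id"], kind="stable")
        if equal_width:
            lo, hi = cdf["start"].min(), cdf["start"].max()
            edges = np.linspace(lo, hi, n_bins + 1)
            idx = np.clip(np.searchsorted(edges, cdf["start"], "right") - 1, 0, n_bins - 1)
        else:
            parts = np.array_split(np.arange(len(cdf)), n_bins)
            idx = np.empty(len(cdf), dtype=int)
            for b, part in enumerate(parts):
                idx[part] = b
        cdf = cdf.assign(bin_index=idx + 1)
        counts = (
            cdf.groupby("bin_index", observed=False)["inheritance_class"]
            .value_counts()
            .rename("count")
            .reset_index()
        )
        counts.insert(0, "chromosome", chrom)
        out.append(counts)
    res = pd.concat(out, ignore_index=True)
    res = res.rename(columns={"inheritance_class": "inheritance_class"})
    return res


@dataclass
class InheritanceModel:
    """Inheritance-mode analysis of a biparental family expression dataset.

    Parameters
    ----------
    counts
        Expression-filtered counts (see :func:`hybridexpress.io.filter_cpm`).
    samples
        Sample metadata with sample_id, genotype_id, role, time_point,
        replicate.
    annotation
        Optional gene positions (BED-derived frame) for chromosome binning.
    """

    counts: CountsMatrix
    samples: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = validate_sample_table(self.samples)
        unknown = set(self.samples["sample_id"]) - set(self.counts.sample_ids)
        if unknown:
            raise ValueError(f"sample ids not in counts matrix: {sorted(unknown)[:5]}")

    def fit(
        self,
        time_points=None,
        alpha: float = 0.01,
        rule: str = "literal",
        f1: str = "pooled",
        dispersion: float | None = None,
    ) -> "InheritanceResults":
        """Run the three pairwise exact tests and classify every gene.

        ``time_points`` defaults to every time point in the sample table.
        """
        if time_points is None:
            time_points = sorted(self.samples["time_point"].unique())
        calls = pd.concat(
            [
                classify_all(
                    self.counts, self.samples, tp,
                    alpha=alpha, rule=rule, f1=f1, dispersion=dispersion,
                )
                for tp in time_points
            ],
            ignore_index=True,
        )
        return InheritanceResults(
            calls=calls, alpha=alpha, rule=rule, f1=f1,
            annotation=self.annotation,
        )


@dataclass
class InheritanceResults:
    """Per-gene inheritance calls plus the summaries derived from them."""

    calls: pd.DataFrame
    alpha: float
    rule: str
    f1: str
    annotation: pd.DataFrame | None = field(default=None, repr=False)

    def by_time(self) -> pd.DataFrame:
        return summarize_by_time(self.calls, family_average=(self.f1 == "per_f1"))

    def bin_by_chromosome(self, n_bins: int = 12, equal_width: bool = False) -> pd.DataFrame:
        if self.annotation is None:
            raise ValueError("no gene annotation attached to the model")
        return bin_by_chromosome(self.calls, self.annotation, n_bins, equal_width)

    def summary(self) -> str:
        tab = self.by_time()
        lines = [
            "Inheritance-mode classification",
            f"  FDR alpha: {self.alpha}   rule: {self.rule}   F1 handling: {self.f1}",
            f"  genes classified: {self.calls['gene_id'].nunique()}",
            "",
            tab.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)
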