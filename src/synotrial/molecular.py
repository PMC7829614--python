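"""Gene-module classification of bulk expression into B-cell poor/rich.

Counts are normalised with median-of-ratios size factors, transformed
with a shifted-log variance-stabilising surrogate
``log2(count / size_factor + 1)``, and summarised per sample as the mean
transformed value over a predefined B-cell gene set (a FANTOM5-derived
module of 73 genes in the motivating trial). Samples at or below the
cohort median module score are called B-cell poor, above it B-cell rich;
the median cutoff avoids choosing a threshold from outcome data. A
post-hoc sensitivity scan re-runs the poor-stratum primary comparison
while sliding the cutoff percentile around the median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .histology import PathotypeLabel

__all__ = [
    "ExpressionMatrix",
    "ModuleScoreTable",
    "size_factors",
    "vst_surrogate",
    "module_score",
    "classify_molecular",
    "cutoff_scan",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_gmt",
    "write_gmt",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples count matrix with optional transformed view."""

    gene_ids: List[str]
    sample_ids: List[str]
    counts: np.ndarray
    transformed: Optional[np.ndarray] = None
    size_factors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.size_factors is not None and (np.asarray(self.size_factors) <= 0).any():
            raise ValueError("size factors must be positive")

    def ensure_transformed(self) -> np.ndarray:
        """Compute (and cache) the VST-surrogate view if absent."""
        if self.transformed is None:
            if self.size_factors is None:
                self.size_factors = size_factors(self.counts, self.sample_ids)
            self.transformed = vst_surrogate(self.counts, self.size_factors)
        return self.transformed


@dataclass
class ModuleScoreTable:
    sample_ids: List[str]
    score: np.ndarray
    module_name: str
    n_module_genes_found: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.score}
        ).assign(module=self.module_name)


def size_factors(
    counts: np.ndarray, sample_ids: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Median-of-ratios size factors (geometric mean of factors = 1).

    For each sample, the median over genes of count / geometric-mean
    count, restricted to genes whose geometric mean is nonzero (genes
    with a zero in any sample drop out of the reference). Factors are
    rescaled so their geometric mean is one; equal columns get factors
    of one.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D genes x samples matrix")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = int(np.flatnonzero(totals == 0)[0])
        name = sample_ids[bad] if sample_ids is not None else str(bad)
        raise ValueError(f"sample {name!r} has all-zero counts")
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    usable = np.isfinite(log_counts).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    log_geomean = log_counts[usable].mean(axis=1)
    log_ratios = log_counts[usable] - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def vst_surrogate(counts: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """Shifted-log transform: log2(count / size_factor + 1).

    Monotone in counts, zero maps to zero, and invariant when a column's
    counts and its size factor double together.
    """
    counts = np.asarray(counts, dtype=float)
    factors = np.asarray(factors, dtype=float)
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / factors[None, :] + 1.0)


def module_score(
    expr: ExpressionMatrix,
    gene_set: Sequence[str],
    module_name: str = "bcell_module",
    aggregate: Literal["mean", "median"] = "mean",
) -> ModuleScoreTable:
    """Per-sample module score over the transformed expression matrix.

    The per-sample summary over the module genes is the mean of
    transformed values (median available as an option; the summary
    statistic used by the original trial is not published). Warns when
    fewer than 80% of the set's genes are found.
    """
    transformed = expr.ensure_transformed()
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    found = [index[g] for g in gene_set if g in index]
    if not found:
        raise ValueError(f"no gene of module {module_name!r} found in the matrix")
    if len(found) < 0.8 * len(gene_set):
        warnings.warn(
            f"only {len(found)}/{len(gene_set)} genes of {module_name!r} found",
            stacklevel=2,
        )
    sub = transformed[found, :]
    score = sub.mean(axis=0) if aggregate == "mean" else np.median(sub, axis=0)
    return ModuleScoreTable(
        sample_ids=list(expr.sample_ids),
        score=np.asarray(score, dtype=float),
        module_name=module_name,
        n_module_genes_found=len(found),
    )


def classify_molecular(scores: ModuleScoreTable) -> List[PathotypeLabel]:
    """Median-cutoff classification of module scores into poor/rich.

    The cutoff is the median score of the classified cohort; scores at
    or below it are B-cell poor, above it B-cell rich. Rank-based, so
    invariant under any strictly increasing transform of the scores.
    """
    s = np.asarray(scores.score, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 samples for a median split")
    if np.ptp(s) == 0:
        raise ValueError("all module scores identical; no split possible")
    cutoff = float(np.median(s))
    return [
        PathotypeLabel("bcell_poor" if v <= cutoff else "bcell_rich", "molecular")
        for v in s
    ]


def cutoff_scan(
    scores: ModuleScoreTable,
    responses: Sequence[int],
    treatments: Sequence[str],
    center: float = 50.0,
    halfwidth: float = 10.0,
    step: float = 1.0,
    ref_arm: str = "rituximab",
    alt_arm: str = "tocilizumab",
) -> pd.DataFrame:
    """Cutoff sensitivity scan around the median split.

    For each percentile cutoff in ``[center - halfwidth, center +
    halfwidth]`` (step ``step``), samples at or below the percentile
    score are reclassified B-cell poor and the primary-endpoint risk
    difference (alt minus ref arm, percentage points, Wald CI,
    chi-square/Fisher p) is recomputed in the poor stratum. Rows whose
    reclassification empties a treatment cell are flagged, not fatal.
    """
    from .analysis import binary_test, risk_difference

    s = np.asarray(scores.score, dtype=float)
    responses = np.asarray(responses, dtype=float)
    treatments = np.asarray(treatments)
    if not (len(s) == len(responses) == len(treatments)):
        raise ValueError("scores, responses and treatments must align")

    n_steps = int(round(2 * halfwidth / step)) if halfwidth > 0 else 0
    percentiles = center - halfwidth + step * np.arange(n_steps + 1)
    rows = []
    for q in percentiles:
        cutoff = float(np.percentile(s, q))
        poor = s <= cutoff
        keep = poor & ~np.isnan(responses)
        x_ref = int(responses[keep & (treatments == ref_arm)].sum())
        n_ref = int((keep & (treatments == ref_arm)).sum())
        x_alt = int(responses[keep & (treatments == alt_arm)].sum())
        n_alt = int((keep & (treatments == alt_arm)).sum())
        row = {
            "percentile": q,
            "cutoff": cutoff,
            "n_poor": int(poor.sum()),
            "n_ref": n_ref,
            "x_ref": x_ref,
            "n_alt": n_alt,
            "x_alt": x_alt,
            "flagged": n_ref == 0 or n_alt == 0,
        }
        if not row["flagged"]:
            rd = risk_difference(x_ref, n_ref, x_alt, n_alt)
            p, method = binary_test(x_ref, n_ref, x_alt, n_alt)
            row.update(
                effect=rd.effect,
                ci_low=rd.ci_low,
                ci_high=rd.ci_high,
                p_value=p,
                method=method,
            )
        else:
            row.update(
                effect=np.nan, ci_low=np.nan, ci_high=np.nan,
                p_value=np.nan, method="",
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("percentile").reset_index(drop=True)


# ---------------------------------------------------------------------------
# File formats: counts TSV / MatrixMarket, gene sets GMT


def read_counts_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(),
    )


def write_counts_tsv(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(
        expr.counts, index=expr.gene_ids, columns=expr.sample_ids
    ).to_csv(path, sep="\t")


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "synotrial") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
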