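"""Multi-experiment co-expression matrices for a query gene.

For each expression experiment, probe rows are averaged per gene, the
Pearson correlation of every gene with the query gene is computed, and
correlations are variance-stabilized with the Fisher r-to-Z transform
scaled by sqrt(n - 3) so that Z values are comparable across experiments of
different sample counts. The resulting gene x experiment matrix is ordered
so the strongest mean-Z genes and experiments sit in the top-left corner,
with cells highlighted where r exceeds 0.75. A word cloud over experiment
descriptions summarizes the conditions, tissues and disease states.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import tokenize

log = logging.getLogger(__name__)

#: Experiments need n - 3 > 0 samples for the scaled Fisher transform.
MIN_SAMPLES = 4

#: Highlight correlations strictly above this value (and up to 1.0).
HIGHLIGHT_R = 0.75

_R_CLAMP = 0.999999


def _stopwords() -> frozenset[str]:
    text = resources.files("ontoseek").joinpath("data/stopwords.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@dataclass
class ExpressionExperiment:
    """One probe x sample expression matrix with a free-text description."""

    experiment_id: str
    description: str
    values: pd.DataFrame              # probe rows x sample columns
    probe_to_gene: dict[str, str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, values_path, mapping_path, description_path=None,
                 experiment_id: str | None = None) -> "ExpressionExperiment":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        mapping = pd.read_csv(mapping_path, sep="\t", index_col=0)
        probe_to_gene = mapping.iloc[:, 0].to_dict()
        description = ""
        if description_path is not None:
            description = Path(description_path).read_text(encoding="utf-8").strip()
        return cls(experiment_id or Path(values_path).stem, description,
                   values, probe_to_gene)


def average_probes(exp: ExpressionExperiment) -> pd.DataFrame:
    """Per-gene arithmetic mean of its probe rows. Unmapped probes are
    ignored; genes with no probes are absent from the output."""
    gene_of = pd.Series(exp.probe_to_gene)
    mapped = exp.values.loc[exp.values.index.intersection(gene_of.index)]
    if mapped.empty:
        return pd.DataFrame(columns=exp.values.columns)
    return mapped.groupby(gene_of.loc[mapped.index]).mean()


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; a constant vector is degenerate and
    recorded as 0 (see :func:`is_degenerate`)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {x.size}")
    if is_degenerate(x) or is_degenerate(y):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def is_degenerate(v) -> bool:
    v = np.asarray(v, dtype=float)
    return bool(np.all(v == v[0]))


def fisher_z(r: float, n: int) -> float:
    """Fisher r-to-Z: atanh(r) * sqrt(n - 3), with r clamped away from +-1."""
    if n < MIN_SAMPLES:
        raise ValueError(f"Fisher Z needs n >= {MIN_SAMPLES}, got {n}")
    if abs(r) > 1:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    return math.atanh(max(-_R_CLAMP, min(_R_CLAMP, r))) * math.sqrt(n - 3)


@dataclass
class CoexpressionMatrix:
    query_gene: str
    genes: list[str]
    experiments: list[str]
    r: pd.DataFrame          # gene x experiment Pearson r (NaN = absent)
    z: pd.DataFrame          # matching Fisher Z grid
    degenerate: pd.DataFrame = field(default=None)  # mask of constant-input cells

    @property
    def highlight(self) -> pd.DataFrame:
        """Cells with r strictly above the 0.75 threshold."""
        return self.r > HIGHLIGHT_R

    def to_tsv(self, prefix) -> None:
        prefix = Path(prefix)
        self.z.to_csv(prefix.with_suffix(".z.tsv"), sep="\t")
        self.r.to_csv(prefix.with_suffix(".r.tsv"), sep="\t")
        self.highlight.to_csv(prefix.with_suffix(".highlight.tsv"), sep="\t")


def build_coexpression_matrix(query_gene: str,
                              experiments: Sequence[ExpressionExperiment],
                              ) -> CoexpressionMatrix:
    """Correlate every gene with the query gene across experiments.

    Experiments with fewer than four samples are skipped (logged). Cells
    where a gene is absent from an experiment stay empty (NaN). Raises if
    the query gene is present nowhere.
    """
    usable: list[ExpressionExperiment] = []
    for exp in experiments:
        if exp.n_samples < MIN_SAMPLES:
            log.info("experiment %s skipped: %d samples < %d",
                     exp.experiment_id, exp.n_samples, MIN_SAMPLES)
            continue
        usable.append(exp)

    r_cols: dict[str, pd.Series] = {}
    z_cols: dict[str, pd.Series] = {}
    deg_cols: dict[str, pd.Series] = {}
    query_found = False
    for exp in usable:
        genes = average_probes(exp)
        if query_gene not in genes.index:
            continue
        query_found = True
        q = genes.loc[query_gene].to_numpy()
        others = genes.drop(index=query_gene)
        n = exp.n_samples
        r_col, z_col, deg_col = {}, {}, {}
        for gene, row in others.iterrows():
            v = row.to_numpy()
            deg = is_degenerate(q) or is_degenerate(v)
            r = pearson_r(q, v)
            r_col[gene] = r
            z_col[gene] = fisher_z(r, n)
            deg_col[gene] = deg
        r_cols[exp.experiment_id] = pd.Series(r_col)
        z_cols[exp.experiment_id] = pd.Series(z_col)
        deg_cols[exp.experiment_id] = pd.Series(deg_col)
    if not query_found:
        raise ValueError(f"query gene {query_gene!r} absent from every experiment")

    r = pd.DataFrame(r_cols)
    z = pd.DataFrame(z_cols)
    deg = pd.DataFrame(deg_cols).fillna(False).astype(bool)
    return CoexpressionMatrix(
        query_gene=query_gene,
        genes=list(r.index),
        experiments=list(r.columns),
        r=r,
        z=z,
        degenerate=deg.reindex(index=r.index, columns=r.columns, fill_value=False),
    )


def order_matrix(m: CoexpressionMatrix) -> CoexpressionMatrix:
    """Sort genes and experiments by mean Z descending (ties by id), so the
    most co-expressed genes and most related experiments occupy the
    top-left corner. Empty cells are excluded from the means."""
    gene_means = m.z.mean(axis=1, skipna=True)
    exp_means = m.z.mean(axis=0, skipna=True)
    gene_order = sorted(m.z.index, key=lambda g: (-gene_means[g], g))
    exp_order = sorted(m.z.columns, key=lambda e: (-exp_means[e], e))
    return CoexpressionMatrix(
        query_gene=m.query_gene,
        genes=gene_order,
        experiments=exp_order,
        r=m.r.loc[gene_order, exp_order],
        z=m.z.loc[gene_order, exp_order],
        degenerate=m.degenerate.loc[gene_order, exp_order],
    )


def build_word_cloud(experiments: Sequence[ExpressionExperiment],
                     top: int = 50) -> dict[str, int]:
    """Term counts over experiment descriptions: stopwords and numerals
    dropped, the ``top`` most frequent terms kept (count descending, then
    alphabetical)."""
    if not experiments:
        raise ValueError("word cloud needs at least one experiment")
    stop = _stopwords()
    counts: dict[str, int] = {}
    for exp in experiments:
        for tok in tokenize(exp.description):
            w = tok.text
            if w in stop or w.replace(".", "").isdigit():
                continue
            counts[w] = counts.get(w, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return dict(ranked)


def export_word_cloud(cloud: Mapping[str, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tcount\n")
        for term, count in cloud.items():
            fh.write(f"{term}\t{count}\n")
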