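"""Two-condition miR expression analysis.

The experiment contrasts cells in which the transcription factor was depleted
by shRNA ("knockdown") against empty-vector controls.  Probe-level array
intensities are quantile-normalized, log2-transformed, collapsed to genes, and
tested per gene with Welch's unequal-variance t-test at a raw p cutoff
(default 0.05).  Genes and samples can be ordered by correlation-distance
hierarchical clustering for heat-map rendering, and a comparative-Ct helper
converts qPCR cycle numbers into fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "DendrogramOrder",
    "read_expression",
    "quantile_normalize",
    "welch_t",
    "call_de",
    "de_table",
    "cluster_order",
    "qpcr_relative_expression",
]

KNOCKDOWN = "knockdown"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with a probe->gene map and a design.

    ``values`` is indexed by probe id (columns = sample ids), ``gene_ids`` maps
    probe id -> gene id (many probes per gene allowed), and ``condition`` maps
    sample id -> 'knockdown' | 'control'.
    """

    values: pd.DataFrame
    gene_ids: pd.Series
    condition: pd.Series

    def __post_init__(self) -> None:
        self.gene_ids = self.gene_ids.reindex(self.values.index)
        if self.gene_ids.isna().any():
            missing = list(self.gene_ids.index[self.gene_ids.isna()])[:3]
            raise ValueError(f"probes without gene annotation: {missing}")
        self.condition = self.condition.reindex(self.values.columns)
        bad = set(self.condition.dropna()) - {KNOCKDOWN, CONTROL}
        if self.condition.isna().any() or bad:
            raise ValueError(
                f"every sample needs a condition in {{{KNOCKDOWN}, {CONTROL}}}"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")

    def samples(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    mean_kd: float
    mean_ctrl: float
    log2_fc: float
    t_stat: float
    df: float
    p_value: float
    direction: Literal["down_in_kd", "up_in_kd", "ns"]


@dataclass(frozen=True)
class DendrogramOrder:
    leaf_order: tuple[int, ...]
    merge_heights: tuple[float, ...]
    labels: tuple[str, ...]


def read_expression(matrix_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a TSV matrix (probe_id, gene_id, samples...) plus a design file.

    The design file has two tab-separated columns: sample id and condition
    ('knockdown' or 'control'); a header row is permitted in both files.
    """
    mat = pd.read_csv(matrix_path, sep="\t")
    probe_col, gene_col = mat.columns[:2]
    mat = mat.set_index(probe_col)
    gene_ids = mat[gene_col].astype(str)
    values = mat.drop(columns=[gene_col]).astype(float)
    design = pd.read_csv(design_path, sep="\t")
    if design.shape[1] < 2:
        raise ValueError(f"{design_path}: design file needs sample and condition columns")
    condition = pd.Series(
        design.iloc[:, 1].astype(str).values, index=design.iloc[:, 0].astype(str)
    )
    return ExpressionMatrix(values=values, gene_ids=gene_ids, condition=condition)


def _quantile_normalize_values(values: pd.DataFrame) -> pd.DataFrame:
    x = values.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values cannot be quantile-normalized")
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)  # rank means
    out = np.empty_like(x)
    for j in range(m):
        col_order = order[:, j]
        col_sorted = x[col_order, j]
        # ties within a column get the mean of the reference values they span
        assigned = ref.copy()
        start = 0
        for k in range(1, n + 1):
            if k == n or col_sorted[k] != col_sorted[start]:
                if k - start > 1:
                    assigned[start:k] = ref[start:k].mean()
                start = k
        out[col_order, j] = assigned
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of cross-sample rank means."""
    if matrix.values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    return ExpressionMatrix(
        values=_quantile_normalize_values(matrix.values),
        gene_ids=matrix.gene_ids,
        condition=matrix.condition,
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with t = (mean_a - mean_b)/sqrt(s2a/na + s2b/nb),
    df from the Welch-Satterthwaite approximation, and a two-sided p-value.
    When both groups have zero variance and equal means, p = 1 by convention
    (and 0 for unequal means).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / a.size + vb / b.size
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(a.size + b.size - 2), 1.0
        return float(np.sign(diff)) * np.inf, float(a.size + b.size - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _welch_rows(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test for a genes x samples split (a = knockdown)."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    if degenerate.any():
        eq = degenerate & (diff == 0.0)
        ne = degenerate & (diff != 0.0)
        t[eq], p[eq], df[degenerate] = 0.0, 1.0, na + nb - 2
        t[ne] = np.sign(diff[ne]) * np.inf
        p[ne] = 0.0
    return t, df, p


def call_de(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    log_transform: bool = True,
    pseudocount: float = 1.0,
    collapse: Literal["median", "none"] = "median",
    bh_correction: bool = False,
) -> list[DEResult]:
    """Call differentially expressed genes with per-gene Welch tests.

    Intensities are log2(x + pseudocount)-transformed, probes collapsed per
    gene by median (``collapse='none'`` keeps probe-level rows), then each gene
    is tested knockdown vs control.  ``direction`` is 'ns' unless the
    (optionally BH-adjusted) p-value is <= alpha; significant genes are
    labelled by the sign of the knockdown-minus-control log2 fold change.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    kd, ctrl = matrix.samples(KNOCKDOWN), matrix.samples(CONTROL)
    if len(kd) < 2 or len(ctrl) < 2:
        raise ValueError("each condition needs >= 2 samples")
    values = matrix.values
    if log_transform:
        values = np.log2(values + pseudocount)
    if collapse == "median":
        values = values.groupby(matrix.gene_ids).median()
    elif collapse == "none":
        pass
    else:
        raise ValueError(f"unknown collapse rule {collapse!r}")

    a = values[kd].to_numpy()
    b = values[ctrl].to_numpy()
    t, df, p = _welch_rows(a, b)
    p_for_calls = _bh_adjust(p) if bh_correction else p
    mean_kd, mean_ctrl = a.mean(axis=1), b.mean(axis=1)
    fc = mean_kd - mean_ctrl
    results = []
    for i, gene in enumerate(values.index):
        if p_for_calls[i] <= alpha:
            direction = "down_in_kd" if fc[i] < 0 else "up_in_kd"
        else:
            direction = "ns"
        results.append(
            DEResult(
                gene_id=str(gene),
                mean_kd=float(mean_kd[i]),
                mean_ctrl=float(mean_ctrl[i]),
                log2_fc=float(fc[i]),
                t_stat=float(t[i]),
                df=float(df[i]),
                p_value=float(p[i]),
                direction=direction,
            )
        )
    return results


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "mean_kd": [r.mean_kd for r in results],
            "mean_ctrl": [r.mean_ctrl for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "t": [r.t_stat for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    )


def cluster_order(
    matrix: ExpressionMatrix,
    axis: Literal["genes", "samples"] = "genes",
    linkage: Literal["single", "complete", "average"] = "average",
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> DendrogramOrder:
    """Agglomerative ordering under correlation distance d = 1 - Pearson r.

    Items with zero variance have no defined correlation and raise an error
    naming the offending item.  The leaf order is deterministic given the
    input order (scipy's tie-break: earlier-formed clusters first).
    """
    values = matrix.values
    if log_transform:
        values = np.log2(values + pseudocount)
    data = values.to_numpy() if axis == "genes" else values.to_numpy().T
    labels = list(values.index if axis == "genes" else values.columns)
    if data.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    sd = data.std(axis=1)
    if (sd == 0).any():
        bad = labels[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance item cannot be clustered: {bad!r}")
    dist = pdist(data, metric="correlation")
    Z = hierarchy.linkage(dist, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return DendrogramOrder(
        leaf_order=tuple(int(i) for i in leaves),
        merge_heights=tuple(float(h) for h in Z[:, 2]),
        labels=tuple(str(l) for l in labels),
    )


def qpcr_relative_expression(
    ct_target_a: float, ct_ref_a: float, ct_target_b: float, ct_ref_b: float
) -> float:
    """Comparative-Ct (2^-ddCt) fold change of condition A relative to B.

    ddCt = (Ct_target_A - Ct_ref_A) - (Ct_target_B - Ct_ref_B); e.g. ddCt = 3
    means an 8-fold reduction (fold change 0.125) of the target in A.
    """
    cts = (ct_target_a, ct_ref_a, ct_target_b, ct_ref_b)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return float(2.0 ** (-ddct))
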