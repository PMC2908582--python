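"""Per-cell-line fold changes and BH-corrected paired t-test selection.

For each probeset the fold change is the linear ratio hypoxic/normoxic
within each cell line.  The test is a two-sided one-sample t-test of the
per-line log2 ratios against 0 (equivalent to a paired t-test on the
log2 values); log2 ratios stabilize the variance and make the test
symmetric in up-/down-regulation.  Selection keeps probesets whose mean
|log2 fold change| passes the fold threshold, then applies
Benjamini-Hochberg within the kept set and requires adjusted p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PairedDesign
from .signature import Signature

__all__ = [
    "FoldChangeResult",
    "fold_changes",
    "paired_t_test",
    "benjamini_hochberg",
    "de_select",
]


@dataclass
class FoldChangeResult:
    """Per-probeset fold changes across cell lines plus test statistics.

    ``per_line_fc``: probesets x lines linear ratios (hypoxic/normoxic);
    ``mean_log2fc``: mean over lines of log2 FC; ``p_value`` from the
    one-sample t-test of the log2 ratios; ``adj_p`` and ``passes`` are
    filled by :func:`de_select`.
    """

    probeset_ids: list[str]
    line_ids: list[str]
    per_line_fc: np.ndarray
    mean_log2fc: np.ndarray
    p_value: np.ndarray
    adj_p: np.ndarray | None = None
    passes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.per_line_fc <= 0).any():
            raise ValueError("fold changes must be positive")
        if ((self.p_value < 0) | (self.p_value > 1)).any():
            raise ValueError("p-values out of [0, 1]")

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.per_line_fc,
            index=self.probeset_ids,
            columns=[f"FC_{l}" for l in self.line_ids],
        )
        df["mean_log2fc"] = self.mean_log2fc
        df["p"] = self.p_value
        if self.adj_p is not None:
            df["adj_p"] = self.adj_p
        if self.passes is not None:
            df["pass"] = self.passes
        return df


def fold_changes(E: ExpressionMatrix, D: PairedDesign) -> FoldChangeResult:
    """Hypoxic/normoxic ratio per cell line plus t-test p-values."""
    if E.scale != "linear":
        raise ValueError("fold_changes expects a linear-scale matrix")
    D.validate_against(E)
    nox = E.data[D.normoxic_samples].to_numpy(dtype=float)
    hyp = E.data[D.hypoxic_samples].to_numpy(dtype=float)
    if (nox <= 0).any():
        raise ValueError("zero or negative normoxic values")
    fc = hyp / nox
    log2fc = np.log2(fc)
    mean = log2fc.mean(axis=1)
    p = np.array([paired_t_test(row) for row in log2fc])
    return FoldChangeResult(
        probeset_ids=E.probeset_ids,
        line_ids=D.cell_lines,
        per_line_fc=fc,
        mean_log2fc=mean,
        p_value=p,
    )


def paired_t_test(log_ratios: np.ndarray) -> float:
    """Two-sided one-sample t-test of per-line log2 ratios against 0.

    Degenerate (zero-variance) input returns p = 1.
    """
    log_ratios = np.asarray(log_ratios, dtype=float)
    if log_ratios.size < 2:
        raise ValueError("need at least 2 lines")
    if np.ptp(log_ratios) == 0.0:
        return 1.0
    return float(stats.ttest_1samp(log_ratios, 0.0).pvalue)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment: monotone, >= raw, <= 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_select(
    FC: FoldChangeResult,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    fc_rule: str = "mean",
    name: str = "de",
) -> Signature:
    """Fold filter then BH-corrected significance on the kept set.

    ``fc_rule='mean'``: |mean log2 FC| >= log2(fc_threshold);
    ``fc_rule='all-lines'``: every line modulated at least fc_threshold-fold
    in the same direction.  BH is applied to the t-test p-values of the
    probesets passing the fold filter; the final list requires
    adj_p < alpha.  Mutates ``FC`` in place with adj_p and pass flags.
    """
    if fc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be > 0")
    log_thr = np.log2(fc_threshold)
    if fc_rule == "mean":
        kept = np.abs(FC.mean_log2fc) >= log_thr
    elif fc_rule == "all-lines":
        l2 = np.log2(FC.per_line_fc)
        kept = (l2 >= log_thr).all(axis=1) | (l2 <= -log_thr).all(axis=1)
    else:
        raise ValueError("fc_rule must be 'mean' or 'all-lines'")
    adj = np.full(FC.p_value.shape, np.nan)
    if kept.any():
        adj[kept] = benjamini_hochberg(FC.p_value[kept])
    passes = kept & (np.nan_to_num(adj, nan=1.0) < alpha)
    FC.adj_p = adj
    FC.passes = passes
    ids = [pid for pid, ok in zip(FC.probeset_ids, passes) if ok]
    # order by significance, then by probeset id for stability
    ids.sort(key=lambda pid: (adj[FC.probeset_ids.index(pid)], pid))
    return Signature(name, ids)
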