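"""Per-contrast differential phosphosite calling: fold change + t-test.

For each site the log2 fold change is the numerator-group mean minus the
denominator-group mean on the log2 scale, and significance comes from a
two-sided two-sample t-test (Welch by default; Student available).  A site
is called *up* when log2FC ≥ the fold-change threshold and the p-criterion
is met, *down* symmetrically, otherwise *ns*.  Sites with fewer than two
observed values in either group are reported with p = NA and call = ns
rather than dropped.

The t statistics are computed vectorized over all sites; the per-site
formulas match ``scipy.stats.ttest_ind`` (checked in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import (
    Contrast,
    DataError,
    DifferentialTable,
    SiteTable,
    StudyDesign,
)

__all__ = ["DifferentialParams", "compute_contrast", "volcano_table",
           "summarize_contrasts"]

KEY_META = ["protein_id", "gene_name", "position", "residue", "multiplicity"]


@dataclass
class DifferentialParams:
    min_abs_log2fc: float = math.log2(1.5)
    max_p: float = 0.05
    test: str = "welch"        # welch | student
    p_adjust: str = "none"     # none | BH

    def __post_init__(self) -> None:
        if not 0.0 < self.max_p < 1.0:
            raise DataError("max_p must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise DataError("min_abs_log2fc must be >= 0")
        if self.test not in ("welch", "student"):
            raise DataError(f"test must be 'welch' or 'student', got {self.test!r}")
        if self.p_adjust not in ("none", "BH"):
            raise DataError(f"p_adjust must be 'none' or 'BH', got {self.p_adjust!r}")


def _nan_moments(x: np.ndarray):
    mask = ~np.isnan(x)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        m = np.where(mask, x, 0.0).sum(axis=1) / n
        centered = np.where(mask, x - m[:, None], 0.0)
        # unbiased variance; undefined (NaN) when n < 2
        v = np.where(n > 1, (centered ** 2).sum(axis=1) / np.maximum(n - 1, 1), np.nan)
    m = np.where(n > 0, m, np.nan)
    return n, m, v


def _t_test(x: np.ndarray, y: np.ndarray, kind: str):
    """Vectorized two-sided two-sample t-test over rows; NaN-aware."""
    n1, m1, v1 = _nan_moments(x)
    n2, m2, v2 = _nan_moments(y)
    diff = m1 - m2
    testable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "welch":
            se2 = v1 / n1 + v2 / n2
            t = diff / np.sqrt(se2)
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df = (n1 + n2 - 2).astype(float)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(testable, t, np.nan)
    p = np.where(testable, p, np.nan)
    return diff, t, p


def compute_contrast(table: SiteTable, design: StudyDesign,
                     contrast: Contrast | str,
                     params: DifferentialParams | None = None) -> DifferentialTable:
    """Fold change and t-test for one contrast over a log2-scale table."""
    p = params or DifferentialParams()
    if isinstance(contrast, str):
        contrast = design.contrast(contrast)
    if table.scale != "log2":
        raise DataError(
            f"compute_contrast requires a log2-scale table; provenance says {table.scale!r}"
        )
    design.check_samples(table.sample_ids)
    for g in (contrast.numerator, contrast.denominator):
        if g not in design.groups:
            raise DataError(f"contrast {contrast.name!r} references unknown group {g!r}")
    x = table.data[design.groups[contrast.numerator]].to_numpy(float)
    y = table.data[design.groups[contrast.denominator]].to_numpy(float)
    log2fc, t, pval = _t_test(x, y, p.test)

    out = table.data[KEY_META].copy()
    out["contrast"] = contrast.name
    out["log2fc"] = log2fc
    out["t_stat"] = t
    out["p_value"] = pval
    if p.p_adjust == "BH":
        adj = np.full(len(out), np.nan)
        mask = ~np.isnan(pval)
        if mask.any():
            adj[mask] = multipletests(pval[mask], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        crit = adj
    else:
        crit = pval
    with np.errstate(invalid="ignore"):
        sig = (crit < p.max_p) & ~np.isnan(crit)
        up = sig & (log2fc >= p.min_abs_log2fc)
        down = sig & (log2fc <= -p.min_abs_log2fc)
    out["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    return DifferentialTable(contrast=contrast, data=out,
                             source_hash=table.provenance_hash(), params=p)


def volcano_table(dt: DifferentialTable) -> pd.DataFrame:
    """Per-site (log2fc, −log10 p, call) rows for volcano plotting.

    Rows with NA p-values (untestable sites) are excluded; call counts are
    attached as ``df.attrs["counts"]``.
    """
    d = dt.data.dropna(subset=["p_value"]).copy()
    with np.errstate(divide="ignore"):
        d["neg_log10_p"] = -np.log10(d["p_value"])
    cols = KEY_META + ["log2fc", "neg_log10_p", "call"]
    out = d[cols].reset_index(drop=True)
    out.attrs["counts"] = dt.counts()
    return out


def summarize_contrasts(tables: list[DifferentialTable]) -> pd.DataFrame:
    """Per-contrast significant/up/down counts; n_up + n_down = n_significant."""
    rows = []
    for dt in tables:
        rows.append({"contrast": dt.contrast.name, **dt.counts()})
    return pd.DataFrame(rows, columns=["contrast", "n_significant", "n_up", "n_down"])
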