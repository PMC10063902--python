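"""Filtering, imputation and normalization of the phosphosite table.

The default chain mirrors standard class-I phosphoproteomics practice:

1. confidence ("class-I") filter — localization probability ≥ 0.75 and
   delta score ≥ 8, both inclusive;
2. valid-value filter — keep a site when at least one group quantifies it
   in ≥ 50% of that group's samples;
3. log2 transform;
4. median normalization — every sample shifted to the common median (the
   grand median of the pre-normalization sample medians, so location is
   preserved);
5. group-mean imputation — a missing cell is filled with its own group's
   observed mean when that group has ≥ 50% observed values.

Imputation runs last, on the normalized log2 scale, where the arithmetic
group mean is not dominated by high raw intensities; ``stage_order`` allows
any permutation, including imputing on the raw scale first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tables import (
    DataError,
    DesignError,
    MULTIPLICITY_CLASSES,
    RESIDUES,
    SiteTable,
    StudyDesign,
)

__all__ = [
    "ProcessingParams",
    "SummaryStats",
    "ProcessingResult",
    "filter_class_one",
    "filter_valid_values",
    "impute_group_mean",
    "log2_transform",
    "median_normalize",
    "run_processing",
    "summarize",
    "residue_fraction_percentages",
    "total_peptides",
]

DEFAULT_STAGE_ORDER = ("class_one", "valid_values", "log2", "median_normalize", "impute")


@dataclass
class ProcessingParams:
    min_loc_prob: float = 0.75
    min_delta_score: float = 8.0
    #: a site is kept when some group quantifies it in >= this fraction of samples
    min_valid_fraction_any_group: float = 0.5
    impute: str = "group_mean"      # group_mean | none
    normalize: str = "median"       # median | none
    log2: bool = True
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_valid_fraction_any_group <= 1.0:
            raise DataError("min_valid_fraction_any_group must be in [0, 1]")
        if not 0.0 <= self.min_loc_prob <= 1.0:
            raise DataError("min_loc_prob must be in [0, 1]")
        if self.min_delta_score < 0:
            raise DataError("min_delta_score must be >= 0")
        unknown = set(self.stage_order) - set(DEFAULT_STAGE_ORDER)
        if unknown:
            raise DataError(f"unknown stage name(s): {sorted(unknown)}")
        missing = set(self._wanted_stages()) - set(self.stage_order)
        if missing:
            raise DataError(f"stage_order omits enabled stage(s): {sorted(missing)}")

    def _wanted_stages(self) -> list[str]:
        stages = ["class_one", "valid_values"]
        if self.log2:
            stages.append("log2")
        if self.normalize == "median":
            stages.append("median_normalize")
        if self.impute == "group_mean":
            stages.append("impute")
        return stages

    def enabled_stages(self) -> list[str]:
        wanted = self._wanted_stages()
        return [s for s in self.stage_order if s in wanted]


def filter_class_one(table: SiteTable, params: ProcessingParams | None = None) -> SiteTable:
    """Keep confidently localized sites: loc prob ≥ threshold AND delta ≥ threshold."""
    p = params or ProcessingParams()
    keep = (table.data["localization_prob"] >= p.min_loc_prob) & \
           (table.data["delta_score"] >= p.min_delta_score)
    kept = table.data[keep].reset_index(drop=True)
    return table.with_stage(
        f"class_one(loc>={p.min_loc_prob}, delta>={p.min_delta_score}): "
        f"kept {len(kept)}, dropped {len(table) - len(kept)}",
        data=kept,
    )


def _group_columns(table: SiteTable, design: StudyDesign) -> dict[str, list[str]]:
    design.check_samples(table.sample_ids)
    cols = {}
    for g, samples in design.groups.items():
        if not samples:
            raise DesignError(f"group {g!r} has zero samples")
        cols[g] = list(samples)
    return cols


def filter_valid_values(table: SiteTable, design: StudyDesign,
                        params: ProcessingParams | None = None) -> SiteTable:
    """Keep sites quantified in ≥ the valid fraction of samples in some group."""
    p = params or ProcessingParams()
    groups = _group_columns(table, design)
    keep = np.zeros(len(table), dtype=bool)
    for g, cols in groups.items():
        frac = table.data[cols].notna().sum(axis=1).to_numpy() / len(cols)
        keep |= frac >= p.min_valid_fraction_any_group
    kept = table.data[keep].reset_index(drop=True)
    return table.with_stage(
        f"valid_values(>={p.min_valid_fraction_any_group} in any group): "
        f"kept {len(kept)}, dropped {len(table) - len(kept)}",
        data=kept,
    )


def impute_group_mean(table: SiteTable, design: StudyDesign,
                      params: ProcessingParams | None = None) -> SiteTable:
    """Fill missing cells with their group's observed mean.

    A cell is filled only when its group observes ≥ the valid fraction of
    samples for that site (missingness ≤ 50% at defaults); observed cells
    are untouched.
    """
    p = params or ProcessingParams()
    groups = _group_columns(table, design)
    data = table.data.copy()
    n_filled = 0
    for g, cols in groups.items():
        block = data[cols]
        observed = block.notna()
        eligible = observed.sum(axis=1) / len(cols) >= p.min_valid_fraction_any_group
        means = block.mean(axis=1)
        for c in cols:
            fill = eligible & block[c].isna()
            n_filled += int(fill.sum())
            data.loc[fill, c] = means[fill]
    return table.with_stage(f"impute_group_mean: filled {n_filled} cells", data=data)


def log2_transform(table: SiteTable) -> SiteTable:
    """log2 the observed intensities (missing preserved)."""
    if table.scale == "log2":
        raise DataError("table is already on the log2 scale")
    data = table.data.copy()
    block = data[table.sample_ids].to_numpy(float)
    if np.nanmin(block, initial=np.inf) <= 0:
        raise DataError("log2 transform requires strictly positive intensities")
    data[table.sample_ids] = np.log2(block)
    return table.with_stage("log2_transform", data=data, scale="log2")


def median_normalize(table: SiteTable) -> SiteTable:
    """Shift every sample to the common median.

    Each sample's median over observed values is subtracted and the grand
    median of the pre-normalization sample medians added back, preserving
    overall location.  After one pass all sample medians coincide, and a
    second pass is the identity.
    """
    data = table.data.copy()
    medians = {}
    for s in table.sample_ids:
        vals = data[s].dropna()
        if vals.empty:
            raise DataError(f"sample {s!r} has no observed values; cannot normalize")
        medians[s] = float(vals.median())
    grand = float(np.median(list(medians.values())))
    for s in table.sample_ids:
        data[s] = data[s] - medians[s] + grand
    return table.with_stage(f"median_normalize(grand_median={grand:.6g})", data=data)


# -- summary statistics ---------------------------------------------------


@dataclass
class SummaryStats:
    """Identification statistics of a site table.

    Peptide counts per multiplicity class are record counts per class; one
    record is one site × multiplicity state.
    """

    n_records: int
    n_sites: int
    n_proteins: int
    multiplicity_counts: dict[str, int]
    residue_counts: dict[str, int]
    residue_fractions: dict[str, float]
    n_high_confidence: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_records", self.n_records), ("n_sites", self.n_sites),
                ("n_proteins", self.n_proteins),
                ("n_high_confidence", self.n_high_confidence)]
        rows += [(f"n_multiplicity_{m}", self.multiplicity_counts.get(m, 0))
                 for m in MULTIPLICITY_CLASSES]
        rows += [(f"n_residue_{r}", self.residue_counts.get(r, 0)) for r in RESIDUES]
        rows += [(f"frac_residue_{r}", self.residue_fractions.get(r, 0.0))
                 for r in RESIDUES]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def residue_fraction_percentages(counts: dict[str, int] | tuple[int, int, int],
                                 ndigits: int | None = 2) -> dict[str, float]:
    """S/T/Y percentages from residue counts (e.g. 17,577/3,424/238 → 82.76/16.12/1.12)."""
    if not isinstance(counts, dict):
        counts = dict(zip(RESIDUES, counts))
    total = sum(counts.get(r, 0) for r in RESIDUES)
    if total == 0:
        raise DataError("no residues counted")
    out = {r: 100.0 * counts.get(r, 0) / total for r in RESIDUES}
    if ndigits is not None:
        out = {r: round(v, ndigits) for r, v in out.items()}
    return out


def total_peptides(multiplicity_counts: dict[str, int] | tuple[int, ...]) -> int:
    """Total peptides as the sum over multiplicity classes (e.g. 17,003+2,824+571+95)."""
    values = multiplicity_counts.values() if isinstance(multiplicity_counts, dict) \
        else multiplicity_counts
    return int(sum(values))


def summarize(table: SiteTable, params: ProcessingParams | None = None) -> SummaryStats:
    p = params or ProcessingParams()
    df = table.data
    residue_counts = {r: int((df["residue"] == r).sum()) for r in RESIDUES}
    n = len(df)
    fractions = {r: residue_counts[r] / n if n else 0.0 for r in RESIDUES}
    mult_counts = {m: int((df["multiplicity"].astype(str) == m).sum())
                   for m in MULTIPLICITY_CLASSES}
    high_conf = int(((df["localization_prob"] >= p.min_loc_prob) &
                     (df["delta_score"] >= p.min_delta_score)).sum())
    return SummaryStats(
        n_records=n,
        n_sites=n,
        n_proteins=int(df["protein_id"].nunique()),
        multiplicity_counts=mult_counts,
        residue_counts=residue_counts,
        residue_fractions=fractions,
        n_high_confidence=high_conf,
    )


@dataclass
class ProcessingResult:
    table: SiteTable
    summary_before: SummaryStats
    summary_after: SummaryStats


def run_processing(table: SiteTable, design: StudyDesign,
                   params: ProcessingParams | None = None) -> ProcessingResult:
    """Apply the processing stages in ``params.stage_order``."""
    p = params or ProcessingParams()
    before = summarize(table, p)
    current = table
    for stage in p.enabled_stages():
        if stage == "class_one":
            current = filter_class_one(current, p)
        elif stage == "valid_values":
            current = filter_valid_values(current, design, p)
        elif stage == "log2":
            current = log2_transform(current)
        elif stage == "median_normalize":
            current = median_normalize(current)
        elif stage == "impute":
            current = impute_group_mean(current, design, p)
        else:  # pragma: no cover - guarded by ProcessingParams validation
            raise DataError(f"unknown stage {stage!r}")
    return ProcessingResult(current, before, summarize(current, p))
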