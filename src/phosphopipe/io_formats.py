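"""Readers and writers for every file the pipeline touches.

Formats: a MaxQuant "Phospho (STY)Sites"-style tab-delimited site table
(column names configurable through :class:`TableDialect`), a YAML study
design, Broad GMT gene sets, a STRING-style 3-column interaction TSV, and
plain TSV outputs with a provenance header comment.

The site-table reader accepts two layouts:

* **wide** (MaxQuant export): intensity columns ``<prefix><sample>___<m>``
  with multiplicity suffixes ___1/___2/___3; each input row is expanded to
  one record per multiplicity state, dropping states whose intensities are
  all missing (MaxQuant leaves zeros in unused multiplicity columns).
* **long** (this package's own output): an explicit ``Multiplicity`` column
  and one intensity column per sample.

Intensity cells that are ``0`` or empty are read as missing — MaxQuant's
convention for unquantified cells, and a prerequisite for meaningful
valid-value filtering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import (
    META_COLUMNS,
    ConfigError,
    Contrast,
    DataError,
    EdgeList,
    GeneSetCollection,
    SiteTable,
    StudyDesign,
    normalize_multiplicity,
)

__all__ = [
    "TableDialect",
    "ParseReport",
    "read_phosphosite_table",
    "write_site_table",
    "read_design",
    "write_design",
    "read_gene_sets",
    "write_gene_sets",
    "read_ppi_edges",
    "write_edges",
    "write_table",
    "read_table",
]

MULT_SEP = "___"


@dataclass
class TableDialect:
    """Column mapping for the phosphosite table, MaxQuant defaults."""

    protein: str = "Protein"
    gene: str = "Gene names"
    position: str = "Position"
    residue: str = "Amino acid"
    localization_prob: str = "Localization prob"
    delta_score: str = "Delta score"
    intensity_prefix: str = "Intensity "
    multiplicity: str = "Multiplicity"  # present only in long-format tables

    @property
    def mandatory(self) -> list[str]:
        return [self.protein, self.gene, self.position, self.residue,
                self.localization_prob, self.delta_score]


@dataclass
class ParseReport:
    """Row accounting for a site-table parse: rows_in = rows_kept + rows_rejected."""

    n_rows: int = 0
    n_rows_rejected: int = 0
    n_records: int = 0
    n_empty_states_dropped: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)

    @property
    def n_rows_kept(self) -> int:
        return self.n_rows - self.n_rows_rejected


def _validate_row(row: pd.Series, dialect: TableDialect) -> str | None:
    """Return a rejection reason for a raw input row, or None if valid."""
    try:
        pos = int(float(row[dialect.position]))
    except (ValueError, TypeError):
        return f"unparsable position {row[dialect.position]!r}"
    if pos < 1:
        return f"position {pos} < 1"
    res = str(row[dialect.residue]).strip()
    if res not in ("S", "T", "Y"):
        return f"residue {res!r} not in {{S, T, Y}}"
    try:
        lp = float(row[dialect.localization_prob])
    except (ValueError, TypeError):
        return f"unparsable localization prob {row[dialect.localization_prob]!r}"
    if not 0.0 <= lp <= 1.0:
        return f"localization prob {lp} outside [0, 1]"
    try:
        ds = float(row[dialect.delta_score])
    except (ValueError, TypeError):
        return f"unparsable delta score {row[dialect.delta_score]!r}"
    if ds < 0:
        return f"delta score {ds} < 0"
    return None


def _parse_intensity(value) -> float:
    """0, empty, NaN → missing; otherwise a finite non-negative float."""
    if value is None:
        return math.nan
    s = str(value).strip()
    if s in ("", "NaN", "nan", "NA"):
        return math.nan
    x = float(s)
    if x == 0.0:
        return math.nan
    if x < 0 or not math.isfinite(x):
        raise DataError(f"invalid intensity {value!r}")
    return x


def read_phosphosite_table(
    path,
    dialect: TableDialect | None = None,
    on_bad_rows: str = "raise",
    return_report: bool = False,
):
    """Parse a phosphosite quantification TSV into a :class:`SiteTable`.

    Parameters
    ----------
    on_bad_rows:
        ``"raise"`` (default) raises :class:`DataError` listing offending
        line numbers; ``"drop"`` rejects invalid rows and records them in
        the :class:`ParseReport`.
    return_report:
        When true, return ``(table, report)``.
    """
    dialect = dialect or TableDialect()
    if on_bad_rows not in ("raise", "drop"):
        raise ConfigError(f"on_bad_rows must be 'raise' or 'drop', got {on_bad_rows!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in dialect.mandatory:
        if col not in raw.columns:
            raise ConfigError(f"mandatory column {col!r} missing from {path}")

    long_format = dialect.multiplicity in raw.columns
    prefix = dialect.intensity_prefix
    intensity_cols = [c for c in raw.columns if c.startswith(prefix)]
    if not intensity_cols:
        raise ConfigError(f"no intensity columns with prefix {prefix!r} in {path}")

    if long_format:
        sample_ids = [c[len(prefix):] for c in intensity_cols]
        col_of = {s: prefix + s for s in sample_ids}
    else:
        sample_ids, mults = [], []
        for c in intensity_cols:
            stem = c[len(prefix):]
            if MULT_SEP not in stem:
                raise ConfigError(
                    f"intensity column {c!r} lacks a {MULT_SEP}<m> multiplicity suffix"
                )
            sample, m = stem.rsplit(MULT_SEP, 1)
            if sample not in sample_ids:
                sample_ids.append(sample)
            if m not in mults:
                mults.append(m)
        mults = sorted(mults, key=int)

    report = ParseReport(n_rows=len(raw))
    records: list[dict] = []
    for idx, row in raw.iterrows():
        lineno = idx + 2  # 1-based, counting the header line
        reason = _validate_row(row, dialect)
        if reason is None:
            try:
                if long_format:
                    states = [(normalize_multiplicity(row[dialect.multiplicity]),
                               {s: _parse_intensity(row[col_of[s]]) for s in sample_ids})]
                else:
                    states = []
                    for m in mults:
                        vals = {
                            s: _parse_intensity(row.get(f"{prefix}{s}{MULT_SEP}{m}", ""))
                            for s in sample_ids
                        }
                        if all(math.isnan(v) for v in vals.values()):
                            report.n_empty_states_dropped += 1
                            continue
                        states.append((normalize_multiplicity(m), vals))
            except (DataError, ValueError) as exc:
                reason = str(exc)
        if reason is not None:
            report.n_rows_rejected += 1
            report.rejections.append((lineno, reason))
            continue
        base = {
            "protein_id": str(row[dialect.protein]).strip(),
            "gene_name": str(row[dialect.gene]).strip().upper(),
            "position": int(float(row[dialect.position])),
            "residue": str(row[dialect.residue]).strip(),
            "localization_prob": float(row[dialect.localization_prob]),
            "delta_score": float(row[dialect.delta_score]),
        }
        for m, vals in states:
            records.append({**base, "multiplicity": m, **vals})

    if report.rejections and on_bad_rows == "raise":
        lines = "; ".join(f"line {n}: {r}" for n, r in report.rejections[:10])
        raise DataError(f"{report.n_rows_rejected} invalid row(s) in {path}: {lines}")

    data = pd.DataFrame(records, columns=META_COLUMNS + sample_ids)
    if data.empty:
        data = data.astype({s: float for s in sample_ids} | {"position": int})
    report.n_records = len(data)
    table = SiteTable(data, sample_ids, provenance=[f"read_phosphosite_table({Path(path).name})"])
    return (table, report) if return_report else table


def write_site_table(table: SiteTable, path, dialect: TableDialect | None = None,
                     header_meta: dict | None = None) -> None:
    """Write a SiteTable in the long layout (explicit Multiplicity column).

    Missing intensities are written as 0 per the MaxQuant convention; a
    re-read maps them back to missing.
    """
    dialect = dialect or TableDialect()
    out = pd.DataFrame({
        dialect.protein: table.data["protein_id"],
        dialect.gene: table.data["gene_name"],
        dialect.position: table.data["position"],
        dialect.residue: table.data["residue"],
        dialect.localization_prob: table.data["localization_prob"],
        dialect.delta_score: table.data["delta_score"],
        dialect.multiplicity: table.data["multiplicity"],
    })
    for s in table.sample_ids:
        out[dialect.intensity_prefix + s] = table.data[s].fillna(0.0)
    meta = dict(header_meta or {})
    meta.setdefault("scale", table.scale)
    meta.setdefault("provenance", " | ".join(table.provenance))
    write_table(out, path, meta=meta)


# -- study design ---------------------------------------------------------


def read_design(path) -> StudyDesign:
    """Read a YAML study design: groups plus optional ordered contrasts.

    Contrasts may be given as ``"H/C"`` strings (numerator/denominator) or
    as mappings with ``name``/``numerator``/``denominator`` keys.  When
    omitted, the default contrast set H/C, S/H, E/H is used.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "groups" not in cfg or not isinstance(cfg["groups"], dict):
        raise ConfigError(f"design {path} must declare a 'groups' mapping")
    groups = {str(g): [str(s) for s in samples] for g, samples in cfg["groups"].items()}
    contrasts = []
    for entry in cfg.get("contrasts") or []:
        if isinstance(entry, str):
            if "/" not in entry:
                raise ConfigError(f"contrast {entry!r} must look like 'NUM/DEN'")
            num, den = entry.split("/", 1)
            contrasts.append(Contrast(entry, num.strip(), den.strip()))
        elif isinstance(entry, dict):
            try:
                num, den = str(entry["numerator"]), str(entry["denominator"])
            except KeyError as exc:
                raise ConfigError(f"contrast entry {entry!r} missing {exc}") from exc
            contrasts.append(Contrast(str(entry.get("name", f"{num}/{den}")), num, den))
        else:
            raise ConfigError(f"unrecognized contrast entry {entry!r}")
    return StudyDesign(groups=groups, contrasts=contrasts)


def write_design(design: StudyDesign, path) -> None:
    cfg = {
        "groups": {g: list(s) for g, s in design.groups.items()},
        "contrasts": [
            {"name": c.name, "numerator": c.numerator, "denominator": c.denominator}
            for c in design.contrasts
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# -- gene sets (GMT) ------------------------------------------------------


def read_gene_sets(path, category: str) -> GeneSetCollection:
    """Read a Broad-format GMT file, tagging every set with ``category``."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}: line {lineno}: GMT line needs id and description")
            set_id, desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                warnings.warn(f"{path}: line {lineno}: set {set_id!r} has no members; dropped")
                continue
            coll.add(set_id, desc, category, members)
    if not coll.sets:
        warnings.warn(f"{path}: no gene sets read")
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.set_id, gs.name, *gs.members]) + "\n")


# -- PPI edges ------------------------------------------------------------


def read_ppi_edges(path, score_scale: str = "milli") -> EdgeList:
    """Read a STRING-style 3-column TSV (protein_a, protein_b, score).

    ``score_scale="milli"`` divides scores by 1000 (the STRING flat-file
    convention of storing the combined score × 1000); ``"unit"`` takes
    scores as-is.  Confidences must land in [0, 1] after scaling.
    """
    if score_scale not in ("milli", "unit"):
        raise ConfigError(f"score_scale must be 'milli' or 'unit', got {score_scale!r}")
    df = pd.read_csv(path, sep=r"[\t ]+", engine="python", dtype=str,
                     comment="#", header=None)
    if df.shape[1] < 3:
        raise DataError(f"{path}: expected 3 columns, found {df.shape[1]}")
    df = df.iloc[:, :3]
    # tolerate a header line
    try:
        float(df.iloc[0, 2])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    scores = df.iloc[:, 2].astype(float)
    if score_scale == "milli":
        scores = scores / 1000.0
    return EdgeList.from_records(zip(df.iloc[:, 0], df.iloc[:, 1], scores))


def write_edges(edges: EdgeList, path, score_scale: str = "unit",
                meta: dict | None = None) -> None:
    out = edges.edges.copy()
    if score_scale == "milli":
        out["confidence"] = (out["confidence"] * 1000).round().astype(int)
    write_table(out, path, meta=meta, header=False)


# -- generic TSV output ---------------------------------------------------


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                header: bool = True) -> None:
    """Write a DataFrame as TSV with '#'-prefixed provenance header lines.

    Floats are rendered with 12 significant digits so a re-read round-trips
    values to that precision.
    """
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, header=header, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping header comments."""
    return pd.read_csv(path, sep="\t", comment="#")
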