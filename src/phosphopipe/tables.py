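"""Core containers for the phosphoproteomics pipeline.

The central object is :class:`SiteTable`: one row per phosphosite ×
multiplicity state, carrying site metadata plus per-sample intensities
(``NaN`` marks an unquantified cell).  :class:`StudyDesign` maps samples to
experimental groups and declares the ordered group-vs-group contrasts;
:class:`GeneSetCollection` and :class:`EdgeList` hold flat annotation sets
and a confidence-scored protein interaction edge list.

All containers validate their invariants on construction so downstream
stages can assume well-formed input.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "META_COLUMNS",
    "RESIDUES",
    "MULTIPLICITY_CLASSES",
    "DataError",
    "ConfigError",
    "DesignError",
    "SiteTable",
    "Contrast",
    "StudyDesign",
    "GeneSet",
    "GeneSetCollection",
    "EdgeList",
    "DifferentialTable",
]

#: Metadata columns every SiteTable carries, in canonical order.
META_COLUMNS = [
    "protein_id",
    "gene_name",
    "position",
    "residue",
    "localization_prob",
    "delta_score",
    "multiplicity",
]

RESIDUES = ("S", "T", "Y")

#: Multiplicity classes: number of phosphate groups on the quantified
#: peptide form; ">3" states are binned as "3+".
MULTIPLICITY_CLASSES = ("1", "2", "3", "3+")

KEY_COLUMNS = ["protein_id", "position", "multiplicity"]


class DataError(ValueError):
    """Raised when file contents violate a data invariant."""


class ConfigError(ValueError):
    """Raised for malformed configuration (columns, groups, contrasts)."""


class DesignError(ValueError):
    """Raised when a study design is inconsistent with the data."""


def normalize_multiplicity(value) -> str:
    """Map a raw multiplicity value onto the class labels 1/2/3/3+."""
    s = str(value).strip()
    if s in MULTIPLICITY_CLASSES:
        return s
    try:
        m = int(float(s))
    except ValueError as exc:
        raise DataError(f"unparsable multiplicity {value!r}") from exc
    if m < 1:
        raise DataError(f"multiplicity must be >= 1, got {m}")
    return str(m) if m <= 3 else "3+"


@dataclass
class SiteTable:
    """Phosphosite quantification table.

    Parameters
    ----------
    data:
        DataFrame with the :data:`META_COLUMNS` plus one float column per
        sample.  Missing intensities are ``NaN``; observed intensities are
        finite and non-negative (raw scale) or finite (log2 scale).
    sample_ids:
        Ordered sample column names.
    provenance:
        Human-readable descriptors appended by each processing stage.
    scale:
        ``"raw"`` or ``"log2"``; guards scale-sensitive stages.
    """

    data: pd.DataFrame
    sample_ids: list[str]
    provenance: list[str] = field(default_factory=list)
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        missing_cols = [c for c in META_COLUMNS + self.sample_ids if c not in self.data.columns]
        if missing_cols:
            raise DataError(f"SiteTable missing columns: {missing_cols}")
        if self.scale not in ("raw", "log2"):
            raise DataError(f"unknown scale {self.scale!r}")
        df = self.data
        bad_res = set(df["residue"].unique()) - set(RESIDUES)
        if bad_res:
            raise DataError(f"residues outside S/T/Y: {sorted(bad_res)}")
        if (df["position"] < 1).any():
            raise DataError("positions must be >= 1")
        lp = df["localization_prob"].to_numpy(float)
        if ((lp < 0) | (lp > 1)).any():
            raise DataError("localization_prob outside [0, 1]")
        if (df["delta_score"].to_numpy(float) < 0).any():
            raise DataError("delta_score must be >= 0")
        bad_mult = set(df["multiplicity"].astype(str).unique()) - set(MULTIPLICITY_CLASSES)
        if bad_mult:
            raise DataError(f"multiplicity classes outside {MULTIPLICITY_CLASSES}: {sorted(bad_mult)}")
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            offenders = df.loc[dup, KEY_COLUMNS].drop_duplicates().head(10)
            raise DataError(
                "duplicate (protein_id, position, multiplicity) keys:\n"
                + offenders.to_string(index=False)
            )
        inten = df[self.sample_ids].to_numpy(float)
        if np.isinf(inten).any():
            raise DataError("intensities must be finite or missing")
        if self.scale == "raw" and np.nanmin(inten, initial=0.0) < 0:
            raise DataError("raw intensities must be >= 0")

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def intensities(self) -> pd.DataFrame:
        """View of the per-sample intensity block."""
        return self.data[self.sample_ids]

    @property
    def meta(self) -> pd.DataFrame:
        return self.data[META_COLUMNS]

    def copy(self) -> "SiteTable":
        return replace(self, data=self.data.copy(), provenance=list(self.provenance))

    def with_stage(self, description: str, data: pd.DataFrame | None = None,
                   scale: str | None = None) -> "SiteTable":
        """Return a new table with ``description`` appended to provenance."""
        return SiteTable(
            data=self.data if data is None else data,
            sample_ids=self.sample_ids,
            provenance=list(self.provenance) + [description],
            scale=self.scale if scale is None else scale,
        )

    def provenance_hash(self) -> str:
        """Digest binding results to one processing run of one table.

        Covers provenance history, scale, samples and the data content, so
        contrasts computed from different runs are detectably incompatible.
        """
        h = hashlib.sha1()
        for line in self.provenance:
            h.update(line.encode())
        h.update(self.scale.encode())
        h.update("\t".join(self.sample_ids).encode())
        content = pd.util.hash_pandas_object(
            self.data[KEY_COLUMNS + self.sample_ids], index=False
        ).to_numpy()
        h.update(content.tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class Contrast:
    """A named group-vs-group comparison; log2 FC = numerator − denominator."""

    name: str
    numerator: str
    denominator: str


#: Default contrasts of the 4-group design: disease vs control and each
#: treatment vs disease.
DEFAULT_CONTRASTS = (
    Contrast("H/C", "H", "C"),
    Contrast("S/H", "S", "H"),
    Contrast("E/H", "E", "H"),
)


@dataclass
class StudyDesign:
    """Sample→group mapping with an ordered list of contrasts."""

    groups: dict[str, list[str]]
    contrasts: list[Contrast] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for g, samples in self.groups.items():
            if len(samples) < 2:
                raise DesignError(f"group {g!r} has fewer than 2 samples")
            for s in samples:
                if s in seen:
                    raise DesignError(f"sample {s!r} appears in groups {seen[s]!r} and {g!r}")
                seen[s] = g
        if not self.contrasts:
            self.contrasts = [c for c in DEFAULT_CONTRASTS if
                              c.numerator in self.groups and c.denominator in self.groups]
        for c in self.contrasts:
            for g in (c.numerator, c.denominator):
                if g not in self.groups:
                    raise DesignError(f"contrast {c.name!r} references unknown group {g!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for samples in self.groups.values() for s in samples]

    def contrast(self, name: str) -> Contrast:
        for c in self.contrasts:
            if c.name == name:
                return c
        raise DesignError(f"unknown contrast {name!r}; have {[c.name for c in self.contrasts]}")

    def check_samples(self, sample_ids: list[str]) -> None:
        missing = set(self.sample_ids) - set(sample_ids)
        if missing:
            raise DesignError(f"design samples absent from table: {sorted(missing)}")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str
    members: tuple[str, ...]  # deduplicated, uppercased gene symbols


CATEGORIES = ("KEGG", "GO_BP", "GO_CC", "GO_MF", "SUBCELL")


@dataclass
class GeneSetCollection:
    """Flat gene-set annotations (KEGG pathways, GO terms, compartments)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gs in self.sets.values():
            if not gs.members:
                raise DataError(f"gene set {gs.set_id!r} has no members")

    def add(self, set_id: str, name: str, category: str, members) -> None:
        dedup = tuple(dict.fromkeys(str(m).upper() for m in members if str(m).strip()))
        if not dedup:
            warnings.warn(f"gene set {set_id!r} has no members; dropped")
            return
        self.sets[set_id] = GeneSet(set_id, name, category, dedup)

    def by_category(self, category: str) -> "GeneSetCollection":
        return GeneSetCollection(
            {k: v for k, v in self.sets.items() if v.category == category}
        )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


@dataclass
class EdgeList:
    """Canonical undirected protein-interaction edges with confidences.

    Edges are stored with ``protein_a < protein_b`` (uppercased symbols),
    self-loops dropped and duplicate pairs collapsed keeping the maximum
    confidence.
    """

    edges: pd.DataFrame  # columns protein_a, protein_b, confidence

    COLUMNS = ["protein_a", "protein_b", "confidence"]

    @classmethod
    def from_records(cls, records) -> "EdgeList":
        rows = []
        n_loops = 0
        for a, b, conf in records:
            a, b = str(a).upper(), str(b).upper()
            conf = float(conf)
            if not 0.0 <= conf <= 1.0:
                raise DataError(f"confidence {conf} outside [0, 1] for edge ({a}, {b})")
            if a == b:
                n_loops += 1
                continue
            if b < a:
                a, b = b, a
            rows.append((a, b, conf))
        if n_loops:
            warnings.warn(f"dropped {n_loops} self-loop edge(s)")
        df = pd.DataFrame(rows, columns=cls.COLUMNS)
        if len(df):
            df = (
                df.groupby(["protein_a", "protein_b"], as_index=False)["confidence"]
                .max()
                .sort_values(["protein_a", "protein_b"], ignore_index=True)
            )
        return cls(df)

    def __len__(self) -> int:
        return len(self.edges)

    def filter(self, min_confidence: float) -> "EdgeList":
        kept = self.edges[self.edges["confidence"] >= min_confidence]
        return EdgeList(kept.reset_index(drop=True))


@dataclass
class DifferentialTable:
    """Per-site differential result for one contrast.

    ``data`` has the site key columns, ``log2fc`` (numerator − denominator
    group mean on the log2 scale), ``t_stat``, ``p_value``, optionally
    ``p_adjusted``, and ``call`` ∈ {up, down, ns}.  ``source_hash`` ties the
    table to the processed SiteTable it was computed from.
    """

    contrast: Contrast
    data: pd.DataFrame
    source_hash: str
    params: object = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def significant(self) -> pd.DataFrame:
        return self.data[self.data["call"] != "ns"]

    def counts(self) -> dict[str, int]:
        n_up = int((self.data["call"] == "up").sum())
        n_down = int((self.data["call"] == "down").sum())
        return {"n_significant": n_up + n_down, "n_up": n_up, "n_down": n_down}
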