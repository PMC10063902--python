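"""Loaders for the published direction-call fixtures shipped with the package.

``data/reversal_directions_*.tsv`` encode, per protein, the published
disease (H/C) and treatment (S/H or E/H) phosphorylation direction calls of
the two drug-reversal result tables (44 proteins for semaglutide, 60 for
empagliflozin).  :func:`build_differential_fixture` expands them into a
pair of minimal :class:`~phosphopipe.tables.DifferentialTable` objects with
synthetic supporting values (positions, fold changes and p-values are
placeholders; only the direction calls are real), which is what the
reversal screen consumes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tables import Contrast, DataError, DifferentialTable

__all__ = ["load_direction_fixture", "build_differential_fixture",
           "load_dopaminergic_sites"]

TREATMENT_CONTRAST = {"semaglutide": "S/H", "empagliflozin": "E/H"}

_FIXTURE_P = 1e-4
_FIXTURE_FC = 1.0


def _data_path(name: str):
    return resources.files("phosphopipe.data").joinpath(name)


def load_direction_fixture(treatment: str) -> pd.DataFrame:
    """Direction columns of the published reversal table for one treatment."""
    if treatment not in TREATMENT_CONTRAST:
        raise DataError(f"treatment must be one of {sorted(TREATMENT_CONTRAST)}")
    with resources.as_file(_data_path(f"reversal_directions_{treatment}.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_dopaminergic_sites() -> pd.DataFrame:
    """Published site-level calls for CACNA1D in the dopaminergic synapse pathway."""
    with resources.as_file(_data_path("dopaminergic_synapse_sites.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def _site(gene: str, position: int, call: str, contrast: str) -> dict:
    return {
        "protein_id": gene.upper(), "gene_name": gene.upper(),
        "position": position, "residue": "S", "multiplicity": "1",
        "contrast": contrast,
        "log2fc": _FIXTURE_FC if call == "up" else -_FIXTURE_FC,
        "t_stat": 10.0 if call == "up" else -10.0,
        "p_value": _FIXTURE_P, "call": call,
    }


def build_differential_fixture(treatment: str):
    """Expand a direction fixture into (disease, treatment) differential tables.

    Single-direction proteins get one significant site per contrast with
    the published calls; mixed ("Up/down" / "Down/up") proteins get two
    discordant site pairs, so protein-level classification reproduces the
    published class.  Supporting positions/p-values/fold changes are
    synthetic placeholders.
    """
    directions = load_direction_fixture(treatment)
    t_name = TREATMENT_CONTRAST[treatment]
    d_rows, t_rows = [], []
    for row in directions.itertuples(index=False):
        gene = row.gene_name
        if row.disease_direction in ("Down", "Up"):
            d_call = row.disease_direction.lower()
            t_call = row.treatment_direction.lower()
            d_rows.append(_site(gene, 10, d_call, "H/C"))
            t_rows.append(_site(gene, 20, t_call, t_name))
        elif row.disease_direction == "Up/down":
            d_rows.append(_site(gene, 10, "up", "H/C"))
            d_rows.append(_site(gene, 30, "down", "H/C"))
            t_rows.append(_site(gene, 20, "down", t_name))
            t_rows.append(_site(gene, 40, "up", t_name))
        else:
            raise DataError(f"unrecognized direction {row.disease_direction!r}")
    columns = ["protein_id", "gene_name", "position", "residue", "multiplicity",
               "contrast", "log2fc", "t_stat", "p_value", "call"]
    disease = DifferentialTable(
        contrast=Contrast("H/C", "H", "C"),
        data=pd.DataFrame(d_rows, columns=columns),
        source_hash=f"fixture:{treatment}",
    )
    treat = DifferentialTable(
        contrast=Contrast(t_name, t_name.split("/")[0], "H"),
        data=pd.DataFrame(t_rows, columns=columns),
        source_hash=f"fixture:{treatment}",
    )
    return disease, treat
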