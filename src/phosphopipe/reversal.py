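"""Cross-contrast drug-reversal screen.

Finds proteins whose significant phosphorylation change in the disease
contrast (H/C) is opposed by a significant change in a treatment contrast
(S/H or E/H), then restricts the hits to proteins belonging to the top-20
enriched KEGG pathways.

Two matching modes:

* ``"protein"`` (default): any significant Down site of a protein in the
  disease contrast paired with any significant Up site of the *same
  protein* in the treatment contrast (and vice versa) — the sites need not
  coincide, reflecting that a kinase cascade can be rerouted through a
  different residue of the same protein.
* ``"site"``: the stricter variant requiring the identical
  (protein, position, multiplicity) site with opposite calls.

Protein classes: ``down_up`` (only Down→Up evidence), ``up_down`` (only
Up→Down), ``mixed`` (both discordant patterns on distinct site pairs).
"""

from __future__ import annotations

import pandas as pd

from .tables import DataError, DifferentialTable, GeneSetCollection

__all__ = ["find_reversed_sites", "classify_proteins", "restrict_to_pathways",
           "reversal_screen"]

PAIR_COLUMNS = [
    "gene_name", "protein_id",
    "disease_position", "disease_residue", "disease_multiplicity",
    "disease_call", "disease_p",
    "treatment_position", "treatment_residue", "treatment_multiplicity",
    "treatment_call", "treatment_p",
    "pattern",
]

CLASS_ORDER = {"down_up": 0, "up_down": 1, "mixed": 2}


def find_reversed_sites(disease: DifferentialTable, treatment: DifferentialTable,
                        mode: str = "protein",
                        check_provenance: bool = True) -> pd.DataFrame:
    """All (disease site, treatment site) pairs with opposite significant calls.

    Both tables must come from the same processed site table; mismatched
    provenance hashes raise :class:`DataError` unless ``check_provenance``
    is disabled (fixture inputs).
    """
    if mode not in ("protein", "site"):
        raise DataError(f"mode must be 'protein' or 'site', got {mode!r}")
    if check_provenance and disease.source_hash != treatment.source_hash:
        raise DataError(
            "differential tables come from different processing runs "
            f"({disease.source_hash[:12]} vs {treatment.source_hash[:12]})"
        )
    cols = ["gene_name", "protein_id", "position", "residue", "multiplicity",
            "call", "p_value"]
    d = disease.significant[cols].rename(columns={
        "position": "disease_position", "residue": "disease_residue",
        "multiplicity": "disease_multiplicity", "call": "disease_call",
        "p_value": "disease_p"})
    t = treatment.significant[cols].rename(columns={
        "position": "treatment_position", "residue": "treatment_residue",
        "multiplicity": "treatment_multiplicity", "call": "treatment_call",
        "p_value": "treatment_p"})
    merged = d.merge(t, on=["gene_name", "protein_id"], how="inner")
    if mode == "site":
        merged = merged[
            (merged["disease_position"] == merged["treatment_position"])
            & (merged["disease_multiplicity"] == merged["treatment_multiplicity"])
        ]
    opposite = merged["disease_call"] != merged["treatment_call"]
    merged = merged[opposite].copy()
    merged["pattern"] = merged["disease_call"].map(
        {"down": "down_up", "up": "up_down"})
    merged = merged[PAIR_COLUMNS].sort_values(
        ["gene_name", "disease_position", "treatment_position"],
        ignore_index=True)
    return merged


def classify_proteins(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse site-level reversal pairs to per-protein hits.

    A protein with only Down→Up pairs is ``down_up``, only Up→Down pairs
    ``up_down``, both patterns ``mixed`` (a single pair can never be mixed).
    """
    rows = []
    for (gene, protein), grp in pairs.groupby(["gene_name", "protein_id"], sort=True):
        has_du = (grp["pattern"] == "down_up").any()
        has_ud = (grp["pattern"] == "up_down").any()
        if has_du and has_ud:
            cls, d_dir, t_dir = "mixed", "Up/down", "Down/up"
        elif has_du:
            cls, d_dir, t_dir = "down_up", "Down", "Up"
        else:
            cls, d_dir, t_dir = "up_down", "Up", "Down"
        rows.append({
            "gene_name": gene, "protein_id": protein,
            "disease_direction": d_dir, "treatment_direction": t_dir,
            "class": cls,
            "n_down_up_pairs": int((grp["pattern"] == "down_up").sum()),
            "n_up_down_pairs": int((grp["pattern"] == "up_down").sum()),
        })
    return pd.DataFrame(rows, columns=[
        "gene_name", "protein_id", "disease_direction", "treatment_direction",
        "class", "n_down_up_pairs", "n_up_down_pairs"])


def restrict_to_pathways(hits: pd.DataFrame, top_sets) -> pd.DataFrame:
    """Keep hits whose protein belongs to ≥1 of the given pathways.

    ``top_sets`` is either a :class:`GeneSetCollection` or an enrichment
    result DataFrame paired with the collection via ``(results, collection)``.
    Retained hits carry a semicolon-joined ``pathways`` column; output is
    sorted by class (down_up, up_down, mixed) then gene.
    """
    if isinstance(top_sets, tuple):
        results, coll = top_sets
        sets = [coll.sets[sid] for sid in results["set_id"] if sid in coll.sets]
    elif isinstance(top_sets, GeneSetCollection):
        sets = list(top_sets)
    else:
        raise DataError("top_sets must be a GeneSetCollection or (results, collection)")
    member_of: dict[str, list[str]] = {}
    for gs in sets:
        for m in gs.members:
            member_of.setdefault(m, []).append(gs.set_id)
    if hits.empty:
        out = hits.copy()
        out["pathways"] = pd.Series(dtype=str)
        return out
    pathways = hits["gene_name"].str.upper().map(
        lambda g: ";".join(member_of.get(g, [])))
    out = hits[pathways != ""].copy()
    out["pathways"] = pathways[pathways != ""]
    out = out.sort_values(
        ["class", "gene_name"],
        key=lambda c: c.map(CLASS_ORDER) if c.name == "class" else c,
        ignore_index=True)
    return out


def reversal_screen(disease: DifferentialTable, treatment: DifferentialTable,
                    top_sets, mode: str = "protein",
                    check_provenance: bool = True) -> pd.DataFrame:
    """find → classify → restrict, in one call."""
    pairs = find_reversed_sites(disease, treatment, mode=mode,
                                check_provenance=check_provenance)
    return restrict_to_pathways(classify_proteins(pairs), top_sets)
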