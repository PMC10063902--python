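"""Synthetic phosphoproteomics study generator with known ground truth.

Emulates a label-free quantitative (LFQ) phosphosite experiment over a
4-group design (control C, disease H, two treatments S and E) with three
replicates per group: ~21k sites on ~4.3k proteins, the observed S/T/Y
residue composition and peptide multiplicity distribution, log-normal
intensities, intensity-dependent (MNAR-biased) missingness, and spiked-in
"reversed" proteins whose disease-direction phosphorylation change flips
sign under treatment.  Matching gene-set annotations (with designated
enriched target sets) and a confidence-scored interaction edge list are
generated alongside, plus a ground-truth ledger enabling parameter-recovery
tests of every downstream stage.

The generative model, on the log2 scale::

    x[site, sample] = base + protein_effect + site_offset
                      + group_effect[site, group(sample)] + noise

with ``group_effect = 0`` in C, ``±effect_size_log2`` in H for differential
sites, and the H effect either persisting (non-reversed) or cancelled
(reversed) in S/E.  Intensities are ``2**x`` with cells masked missing with
probability increasing as intensity decreases (MNAR weight) on top of a
uniform floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    DataError,
    EdgeList,
    GeneSetCollection,
    SiteTable,
    StudyDesign,
)

__all__ = ["SimulationParams", "GroundTruth", "SimulatedStudy", "generate_study",
           "truth_report", "RecoveryMetrics"]

GROUPS = ("C", "H", "S", "E")


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults emulate the 4-group hippocampal study."""

    n_proteins: int = 4290
    n_sites: int = 21239
    #: S/T/Y residue probabilities.
    residue_probs: tuple[float, float, float] = (0.8276, 0.1612, 0.0112)
    #: peptide multiplicity class probabilities for 1/2/3/3+,
    #: from counts 17,003 : 2,824 : 571 : 95.
    multiplicity_probs: tuple[float, ...] = (
        17003 / 20493, 2824 / 20493, 571 / 20493, 95 / 20493)
    n_replicates: int = 3
    base_log2_mean: float = 23.0
    protein_sd: float = 2.0
    site_sd: float = 1.0
    noise_sd: float = 0.3
    effect_size_log2: float = 1.5
    #: fraction of sites made differential in H vs C (assigned protein-wise).
    fraction_hc_differential: float = 0.05
    #: fractions of differential proteins whose effect is reversed by each treatment.
    fraction_reversed_by_S: float = 0.3
    fraction_reversed_by_E: float = 0.3
    #: fraction of reversed proteins given discordant site directions ("mixed").
    mixed_fraction: float = 0.1
    missing_rate: float = 0.2
    #: >0 biases missingness toward low intensities (missing-not-at-random).
    mnar_weight: float = 1.0
    locprob_alpha: float = 6.0
    locprob_beta: float = 1.0
    delta_shape: float = 2.0
    delta_scale: float = 15.0
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (10, 80)
    n_target_sets: int = 3
    #: fraction of each target set's members drawn from reversed proteins.
    enrichment_spike: float = 0.5
    ppi_density: float = 0.001
    #: edge probability among members of a target set (on top of background).
    ppi_within_target_density: float = 0.2
    conf_alpha: float = 6.0
    conf_beta: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.residue_probs) - 1.0) > 1e-9:
            raise DataError("residue_probs must sum to 1")
        if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
            raise DataError("multiplicity_probs must sum to 1")
        if self.n_proteins < 1 or self.n_sites < self.n_proteins:
            raise DataError("need n_sites >= n_proteins >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DataError("missing_rate must be in [0, 1)")
        for name in ("fraction_hc_differential", "fraction_reversed_by_S",
                     "fraction_reversed_by_E", "mixed_fraction", "enrichment_spike"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 2:
            raise DataError("need at least 2 replicates per group")
        if self.effect_size_log2 < 0:
            raise DataError("effect_size_log2 must be >= 0")
        if (self.fraction_reversed_by_S > 0 or self.fraction_reversed_by_E > 0) \
                and self.fraction_hc_differential == 0:
            raise DataError("cannot reverse sites when no sites are differential")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery scoring.

    ``sites`` holds per-record true group effects and per-contrast
    differential flags/directions; ``proteins`` holds per-protein reversal
    classes per treatment (none / down_up / up_down / mixed);
    ``target_sets`` lists the gene sets spiked with reversed proteins.
    """

    sites: pd.DataFrame
    proteins: pd.DataFrame
    target_sets: list[str] = field(default_factory=list)


@dataclass
class SimulatedStudy:
    site_table: SiteTable
    design: StudyDesign
    gene_sets: GeneSetCollection
    edges: EdgeList
    truth: GroundTruth
    params: SimulationParams


def _positions_per_protein(counts: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    """Strictly increasing residue positions for each protein's sites."""
    out = []
    for c in counts:
        gaps = rng.integers(1, 60, size=c)
        out.append(np.cumsum(gaps))
    return out


def generate_study(params: SimulationParams | None = None) -> SimulatedStudy:
    """Generate the full study: site table, design, gene sets, edges, truth.

    Deterministic for a fixed ``params.seed``.
    """
    p = params or SimulationParams()
    p.validate()
    rng = np.random.default_rng(p.seed)

    # -- identifiers ------------------------------------------------------
    proteins = np.array([f"P{i:05d}" for i in range(p.n_proteins)])
    genes = np.array([f"GN{i:04d}" for i in range(p.n_proteins)])

    # every protein gets >= 1 site; the rest are assigned at random
    protein_idx = np.concatenate([
        np.arange(p.n_proteins),
        rng.integers(0, p.n_proteins, size=p.n_sites - p.n_proteins),
    ])
    protein_idx = protein_idx[rng.permutation(p.n_sites)]
    order = np.argsort(protein_idx, kind="stable")
    protein_idx = protein_idx[order]
    counts = np.bincount(protein_idx, minlength=p.n_proteins)
    positions = np.concatenate(_positions_per_protein(counts, rng))

    residues = rng.choice(list("STY"), size=p.n_sites, p=list(p.residue_probs))
    mult = rng.choice(["1", "2", "3", "3+"], size=p.n_sites,
                      p=list(p.multiplicity_probs))
    locprob = rng.beta(p.locprob_alpha, p.locprob_beta, size=p.n_sites)
    delta = rng.gamma(p.delta_shape, p.delta_scale, size=p.n_sites)

    # -- design -----------------------------------------------------------
    samples = {g: [f"{g}{r + 1}" for r in range(p.n_replicates)] for g in GROUPS}
    design = StudyDesign(groups={g: list(s) for g, s in samples.items()})
    sample_ids = design.sample_ids
    sample_group = np.array([g for g in GROUPS for _ in range(p.n_replicates)])

    # -- plant effects protein-wise --------------------------------------
    n_diff_target = int(round(p.fraction_hc_differential * p.n_sites))
    shuffled = rng.permutation(p.n_proteins)
    diff_proteins: list[int] = []
    acc = 0
    for pi in shuffled:
        if acc >= n_diff_target:
            break
        diff_proteins.append(int(pi))
        acc += int(counts[pi])
    diff_proteins = np.array(sorted(diff_proteins), dtype=int)

    site_dir = np.zeros(p.n_sites, dtype=int)  # H-vs-C sign per site
    protein_pattern = {}  # protein idx -> 'up' | 'down' | 'mixed'
    for pi in diff_proteins:
        mask = protein_idx == pi
        n_p = int(mask.sum())
        if n_p >= 2 and rng.random() < p.mixed_fraction:
            dirs = np.where(np.arange(n_p) % 2 == 0, 1, -1)
            protein_pattern[pi] = "mixed"
        else:
            d = 1 if rng.random() < 0.5 else -1
            dirs = np.full(n_p, d)
            protein_pattern[pi] = "up" if d > 0 else "down"
        site_dir[mask] = dirs

    def _pick_reversed(fraction: float) -> np.ndarray:
        n_rev = int(round(fraction * len(diff_proteins)))
        return np.sort(rng.choice(diff_proteins, size=n_rev, replace=False)) \
            if n_rev else np.array([], dtype=int)

    reversed_S = _pick_reversed(p.fraction_reversed_by_S)
    reversed_E = _pick_reversed(p.fraction_reversed_by_E)
    rev_S_mask = np.isin(protein_idx, reversed_S)
    rev_E_mask = np.isin(protein_idx, reversed_E)

    delta_fx = p.effect_size_log2
    effect_H = site_dir * delta_fx
    # reversed sites: treatment cancels the disease effect (opposite sign vs H);
    # non-reversed differential sites persist under treatment.
    effect_S = np.where(rev_S_mask, 0.0, effect_H)
    effect_E = np.where(rev_E_mask, 0.0, effect_H)

    # -- intensities ------------------------------------------------------
    protein_base = rng.normal(0.0, p.protein_sd, size=p.n_proteins)
    site_mu = (p.base_log2_mean + protein_base[protein_idx]
               + rng.normal(0.0, p.site_sd, size=p.n_sites))
    group_fx = np.zeros((p.n_sites, len(sample_ids)))
    fx_of = {"C": np.zeros(p.n_sites), "H": effect_H, "S": effect_S, "E": effect_E}
    for j, g in enumerate(sample_group):
        group_fx[:, j] = fx_of[g]
    log2_x = (site_mu[:, None] + group_fx
              + rng.normal(0.0, p.noise_sd, size=(p.n_sites, len(sample_ids))))

    intensities = np.power(2.0, log2_x)
    if p.missing_rate > 0:
        z = (log2_x - log2_x.mean()) / max(log2_x.std(), 1e-12)
        w = np.exp(-p.mnar_weight * z)
        prob = np.clip(p.missing_rate * w / w.mean(), 0.0, 0.95)
        mask = rng.random(size=log2_x.shape) < prob
        intensities = np.where(mask, np.nan, intensities)

    data = pd.DataFrame({
        "protein_id": proteins[protein_idx],
        "gene_name": genes[protein_idx],
        "position": positions,
        "residue": residues,
        "localization_prob": locprob,
        "delta_score": delta,
        "multiplicity": mult,
    })
    for j, s in enumerate(sample_ids):
        data[s] = intensities[:, j]
    table = SiteTable(data, sample_ids,
                      provenance=[f"simulated(seed={p.seed}, n_sites={p.n_sites})"])

    # -- ground truth -----------------------------------------------------
    def _dir_label(e):
        return np.where(e > 0, "up", np.where(e < 0, "down", "ns"))

    truth_sites = pd.DataFrame({
        "protein_id": data["protein_id"],
        "gene_name": data["gene_name"],
        "position": data["position"],
        "multiplicity": data["multiplicity"],
        "effect_H": effect_H,
        "effect_S": effect_S,
        "effect_E": effect_E,
        "diff_HC": effect_H != 0,
        "dir_HC": _dir_label(effect_H),
        "diff_SH": (effect_S - effect_H) != 0,
        "dir_SH": _dir_label(effect_S - effect_H),
        "diff_EH": (effect_E - effect_H) != 0,
        "dir_EH": _dir_label(effect_E - effect_H),
    })

    def _class_of(pi: int) -> str:
        pat = protein_pattern[pi]
        # treatment flips the disease direction, so a 'down' disease pattern
        # yields a down→up reversal and vice versa
        return {"down": "down_up", "up": "up_down", "mixed": "mixed"}[pat]

    truth_proteins = pd.DataFrame({
        "protein_id": proteins,
        "gene_name": genes,
        "reversal_class_S": ["none"] * p.n_proteins,
        "reversal_class_E": ["none"] * p.n_proteins,
    })
    for pi in reversed_S:
        truth_proteins.loc[pi, "reversal_class_S"] = _class_of(pi)
    for pi in reversed_E:
        truth_proteins.loc[pi, "reversal_class_E"] = _class_of(pi)

    # -- gene sets --------------------------------------------------------
    reversed_genes = np.unique(genes[np.sort(np.union1d(reversed_S, reversed_E))]) \
        if len(reversed_S) or len(reversed_E) else np.array([], dtype=object)
    coll = GeneSetCollection()
    target_ids = []
    lo, hi = p.set_size_range
    for i in range(p.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < p.n_target_sets and len(reversed_genes):
            n_spike = min(int(round(p.enrichment_spike * size)), len(reversed_genes))
            spiked = rng.choice(reversed_genes, size=n_spike, replace=False)
            rest = rng.choice(genes, size=size - n_spike, replace=False)
            members = np.unique(np.concatenate([spiked, rest]))
            set_id = f"TARGET{i + 1:02d}"
            target_ids.append(set_id)
        else:
            members = rng.choice(genes, size=size, replace=False)
            set_id = f"SET{i + 1:03d}"
        coll.add(set_id, f"simulated pathway {set_id}", "KEGG", members.tolist())

    # -- PPI edges --------------------------------------------------------
    n_possible = p.n_proteins * (p.n_proteins - 1) // 2
    n_bg = int(round(p.ppi_density * n_possible))
    a = rng.integers(0, p.n_proteins, size=2 * n_bg)
    b = rng.integers(0, p.n_proteins, size=2 * n_bg)
    keep = a != b
    pairs = {(min(x, y), max(x, y)) for x, y in zip(a[keep][:n_bg], b[keep][:n_bg])}
    gene_to_idx = {g: i for i, g in enumerate(genes)}
    for set_id in target_ids:
        members = [gene_to_idx[m] for m in coll.sets[set_id].members if m in gene_to_idx]
        for i, x in enumerate(members):
            for y in members[i + 1:]:
                if rng.random() < p.ppi_within_target_density:
                    pairs.add((min(x, y), max(x, y)))
    pairs = sorted(pairs)
    conf = rng.beta(p.conf_alpha, p.conf_beta, size=len(pairs))
    edges = EdgeList.from_records(
        (genes[x], genes[y], c) for (x, y), c in zip(pairs, conf))

    truth = GroundTruth(sites=truth_sites, proteins=truth_proteins,
                        target_sets=target_ids)
    return SimulatedStudy(table, design, coll, edges, truth, p)


# -- recovery scoring -----------------------------------------------------


@dataclass
class RecoveryMetrics:
    """Sensitivity/FDR of differential calls, reversal recovery, set ranks."""

    differential: pd.DataFrame  # contrast, sensitivity, fdr, n_true, n_called
    reversal: pd.DataFrame      # treatment, sensitivity, n_true, n_recovered
    set_ranks: pd.DataFrame     # set_id, rank (NaN if absent from results)


_TRUTH_COLS = {"H/C": ("diff_HC", "dir_HC"), "S/H": ("diff_SH", "dir_SH"),
               "E/H": ("diff_EH", "dir_EH")}


def truth_report(truth: GroundTruth,
                 differential_tables: dict | None = None,
                 reversal_hits: dict | None = None,
                 enrichment: pd.DataFrame | None = None) -> RecoveryMetrics:
    """Score pipeline outputs against the planted ground truth.

    Parameters
    ----------
    differential_tables:
        contrast name → :class:`~phosphopipe.tables.DifferentialTable`.
    reversal_hits:
        treatment label (``"S"`` or ``"E"``) → classified-protein DataFrame
        (pre-pathway-restriction) with a ``gene_name`` column.
    enrichment:
        enrichment result DataFrame with ``set_id`` and ``rank`` columns.
    """
    key = ["protein_id", "position", "multiplicity"]
    diff_rows = []
    for name, dt in (differential_tables or {}).items():
        if name not in _TRUTH_COLS:
            raise DataError(f"no ground truth for contrast {name!r}")
        flag_col, dir_col = _TRUTH_COLS[name]
        merged = truth.sites[key + [flag_col, dir_col]].merge(
            dt.data[key + ["call"]], on=key, how="inner")
        if merged.empty:
            raise DataError(f"no identifiers shared between truth and results for {name}")
        called = merged["call"] != "ns"
        true_pos = called & (merged["call"] == merged[dir_col])
        n_true = int(merged[flag_col].sum())
        n_called = int(called.sum())
        diff_rows.append({
            "contrast": name,
            "sensitivity": float(true_pos.sum() / n_true) if n_true else np.nan,
            "fdr": float((called & ~merged[flag_col]).sum() / n_called) if n_called else 0.0,
            "n_true": n_true,
            "n_called": n_called,
        })

    rev_rows = []
    for treatment, hits in (reversal_hits or {}).items():
        col = f"reversal_class_{treatment}"
        if col not in truth.proteins.columns:
            raise DataError(f"no ground truth for treatment {treatment!r}")
        true_genes = set(truth.proteins.loc[truth.proteins[col] != "none", "gene_name"])
        found = set(hits["gene_name"].astype(str))
        rev_rows.append({
            "treatment": treatment,
            "sensitivity": float(len(true_genes & found) / len(true_genes))
            if true_genes else np.nan,
            "n_true": len(true_genes),
            "n_recovered": len(true_genes & found),
        })

    rank_rows = []
    if enrichment is not None:
        ranks = dict(zip(enrichment["set_id"], enrichment["rank"]))
        for sid in truth.target_sets:
            rank_rows.append({"set_id": sid, "rank": ranks.get(sid, np.nan)})

    return RecoveryMetrics(
        differential=pd.DataFrame(diff_rows),
        reversal=pd.DataFrame(rev_rows),
        set_ranks=pd.DataFrame(rank_rows),
    )
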