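import numpy as np
import pandas as pd
import pytest

from phosphopipe.synthetic import SimulationParams, generate_study
from phosphopipe.tables import SiteTable, StudyDesign


SMALL_PARAMS = dict(
    n_proteins=120,
    n_sites=600,
    n_gene_sets=15,
    set_size_range=(5, 25),
    ppi_density=0.002,
    seed=1,
)


@pytest.fixture(scope="session")
def small_study():
    """Small simulated study shared across tests (read-only)."""
    return generate_study(SimulationParams(**SMALL_PARAMS))


def make_site_table(intensity_rows, sample_ids, *, locprob=0.9, delta=20.0,
                    residue="S", scale="raw"):
    """Build a minimal SiteTable from per-site intensity rows (NaN = missing)."""
    rows = []
    for i, vals in enumerate(intensity_rows):
        rows.append({
            "protein_id": f"P{i:03d}", "gene_name": f"G{i:03d}",
            "position": 10 + i, "residue": residue,
            "localization_prob": locprob, "delta_score": delta,
            "multiplicity": "1",
            **dict(zip(sample_ids, [float(v) for v in vals])),
        })
    return SiteTable(pd.DataFrame(rows), list(sample_ids), scale=scale)


@pytest.fixture
def two_group_design():
    return StudyDesign(groups={"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]},
                       contrasts=[])


def random_table(rng, n_sites, sample_ids, missing_rate=0.0, scale="raw"):
    vals = rng.lognormal(mean=15, sigma=1.0, size=(n_sites, len(sample_ids)))
    if scale == "log2":
        vals = np.log2(vals)
    if missing_rate:
        vals = np.where(rng.random(vals.shape) < missing_rate, np.nan, vals)
    rows = vals.tolist()
    return make_site_table(rows, sample_ids, scale=scale)
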