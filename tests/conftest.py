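import pandas as pd
import pytest

from skinmwas.functional import KoMap
from skinmwas.simulate import (default_config, simulate_cohort,
                               simulate_gene_tables, simulate_taxon_profiles)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-design cohort (180 samples) simulated once per run."""
    cfg = default_config(seed=11)
    meta, truth = simulate_cohort(cfg)
    taxa = simulate_taxon_profiles(meta, truth, cfg)
    genes, pathways = simulate_gene_tables(taxa, cfg)
    komap = KoMap(genes.attrs["family_to_ko"], cfg.catalog())
    return {"config": cfg, "meta": meta, "truth": truth, "taxa": taxa,
            "genes": genes, "pathways": pathways, "komap": komap}


@pytest.fixture()
def toy_meta():
    """Minimal 8-sample metadata: 2 subjects per group, one site, 2 timepoints."""
    rows = []
    for subj, grp in (("C01", "children"), ("C02", "children"),
                      ("T01", "teens"), ("T02", "teens")):
        for tp in ("1h", "8h"):
            rows.append((f"{subj}_underarm_{tp}", subj, grp, "F", "underarm",
                         tp, 40.0, "none"))
    return pd.DataFrame(rows, columns=[
        "sample_id", "subject_id", "age_group", "sex", "site", "timepoint",
        "odor_intensity", "odor_characters"])
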