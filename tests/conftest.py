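import numpy as np
import pandas as pd
import pytest

from silscreen import screenstats, simdata
from silscreen.pipeline import FunnelConfig, run_funnel
from silscreen.simdata import DASATINIB, VEHICLE


@pytest.fixture(scope="session")
def default_report():
    """One full funnel run on the packaged default fixture."""
    return run_funnel(FunnelConfig())


@pytest.fixture(scope="session")
def primary_v_table():
    """Normalized viability table of the default fixture's primary screen."""
    fx = simdata.funnel_fixture("funnel_default")
    library = simdata.build_library(fx.library_spec, fx.gene_names)
    meas = simdata.simulate_screen(library, fx.truth, [VEHICLE, DASATINIB],
                                   replicates_per_arm=2, noise=fx.noise)
    return screenstats.normalize_viability(meas, library)


@pytest.fixture()
def small_spec():
    return simdata.LibrarySpec(n_genes=12)


def make_null_vtable(n_genes: int, n_rep: int, sd: float,
                     rng: np.random.Generator,
                     effect: dict | None = None) -> pd.DataFrame:
    """Synthetic log2-V replicate table for direct moderated-test input."""
    effect = effect or {}
    rows = []
    for g in range(n_genes):
        gene = f"g{g:03d}"
        for arm in (DASATINIB, VEHICLE):
            mu = effect.get(gene, 0.0) if arm == DASATINIB else 0.0
            for rep in range(n_rep):
                rows.append({"gene_id": gene, "arm": arm, "replicate": rep,
                             "logV": rng.normal(mu, sd)})
    return pd.DataFrame(rows)
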