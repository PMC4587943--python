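import numpy as np
import pandas as pd
import pytest

import fireweek as fw


@pytest.fixture(scope="session")
def tiny_fit_data():
    """3×3 lattice, 2 years, cropland-only: the bundled end-to-end fixture."""
    return fw.make_fixture("tiny-fit")


@pytest.fixture(scope="session")
def small_dataset():
    """5×5 cropland-only lattice with rest-day deficits, 3 years."""
    config = fw.SimulationConfig(
        rows=5, cols=5, n_years=3, anthrome_weights={"Cropland": 1.0}, seed=11
    )
    records, graph, labels, panel, truth = fw.simulate_dataset(config)
    return {
        "config": config,
        "records": records,
        "graph": graph,
        "labels": labels,
        "panel": panel,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A converged interaction-model fit on the small dataset (shared)."""
    d = small_dataset
    spec = fw.ModelSpec.from_string("R + W + R:W + ICAR")
    samples = fw.fit_mcmc(
        d["panel"], d["labels"], d["truth"].log_areas, d["graph"], spec,
        config=fw.MCMCConfig(n_chains=2, n_iter=3000, n_burn=1000, thin=2, seed=5),
    )
    return {"samples": samples, "spec": spec, **d}


def make_single_region_panel(counts_by_weekday, years=(2003,), region_id="r0"):
    """Dense one-region panel from a length-7 weekday count vector per year."""
    arr = np.asarray(counts_by_weekday)
    if arr.ndim == 1:
        arr = np.repeat(arr[:, None], len(years), axis=1)
    return fw.FireCountPanel(arr[None, :, :], [region_id], list(years))


def labels_frame(region_ids, religion="Christian", anthrome="Cropland"):
    n = len(region_ids)
    rel = [religion] * n if isinstance(religion, str) else list(religion)
    ant = [anthrome] * n if isinstance(anthrome, str) else list(anthrome)
    return pd.DataFrame(
        {"region_id": region_ids, "religion_label": rel, "anthrome_label": ant}
    )
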