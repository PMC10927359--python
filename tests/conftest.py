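import warnings

import numpy as np
import pandas as pd
import pytest

import treking as tk

warnings.filterwarnings("ignore", message=".*fallback.*")


@pytest.fixture
def small_plate() -> tk.TimeSeriesPlate:
    """3 wells (2 inhibitors + DMSO), 5 timepoints, one pre-thrombin."""
    times = np.array([-2.0, 0.0, 5.0, 10.0, 15.0])
    wells = pd.DataFrame(
        {
            "inhibitor": ["inhA", "inhB", "DMSO"],
            "condition": ["thrombin"] * 3,
            "replicate": [1, 1, 1],
        },
        index=pd.Index(["w1", "w2", "w3"], name="well"),
    )
    values = pd.DataFrame(
        [
            [1.0, 0.9, 0.7, 0.8, 0.9],
            [1.1, 1.0, 0.5, 0.6, 0.8],
            [1.0, 0.95, 0.8, 0.9, 1.0],
        ],
        index=wells.index,
        columns=times,
    )
    return tk.TimeSeriesPlate(times=times, wells=wells, values=values,
                              thrombin_time_min=-1.0)


@pytest.fixture
def toy_panel() -> tk.KinaseActivityPanel:
    rng = np.random.default_rng(42)
    return tk.KinaseActivityPanel(pd.DataFrame(
        rng.uniform(0.0, 100.0, size=(28, 10)),
        index=[f"inh{i:02d}" for i in range(28)],
        columns=[f"K{j}" for j in range(10)],
    ))


@pytest.fixture(scope="session")
def default_screen():
    """The default synthetic screen (28 inhibitors, 60 kinases, 6 planted
    signed windowed effects, 3 replicates, fixed seed) run through the full
    kinetics + regression pipeline. Session-scoped: the elastic-net stage
    dominates suite runtime."""
    cfg = tk.SimConfig(seed=1)
    panel = tk.simulate_panel(cfg)
    plate, truth = tk.simulate_screen(cfg, None, panel)
    plate_n = tk.normalize_baseline(plate)
    grid = tk.enumerate_windows(360)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auc = tk.compute_auc_matrix(plate_n, grid)
        matrix = tk.build_functionality_matrix(auc, panel)
    return {
        "config": cfg, "panel": panel, "plate": plate, "truth": truth,
        "grid": grid, "auc": auc, "matrix": matrix,
    }


@pytest.fixture
def chain_background() -> tk.BackgroundNetwork:
    import networkx as nx
    G = nx.DiGraph()
    G.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("X", "X")])
    return tk.BackgroundNetwork(graph=G, organism="synthetic")
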