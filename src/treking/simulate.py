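"""Synthetic impedance screens, specificity panels, and background graphs
with known ground truth.

The generator embodies the linear model the kinase regression assumes: the
control well follows a disruption/recovery cell-index curve c(t) (acute
drop peaking ~25 min after thrombin, then recovery), and each planted
kinase effect perturbs inhibitor wells additively, scaled by how strongly
that inhibitor hits the kinase, only inside the effect's active time
window. A barrier-strengthening (+1) kinase lowers the cell index when
inhibited, so the per-window AUC regressed on residual activity has a
positive slope — the sign convention of the functionality calls. Replicate
wells share the signal and carry independent Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import CONTROL_ID, TimeSeriesPlate, WindowGrid
from .netgen import BackgroundNetwork
from .tkir import FunctionalityMatrix, KinaseActivityPanel

import networkx as nx


@dataclass
class PlantedEffect:
    """One signed, time-windowed kinase effect on the cell index."""

    kinase: str
    sign: int                    # +1 strengthening, -1 weakening
    t_on: float                  # minutes after inhibitor addition
    t_off: float
    magnitude: float             # cell-index units per unit inhibition

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")
        if not self.t_on < self.t_off:
            raise ValueError("t_on must precede t_off")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")


@dataclass
class SimConfig:
    """Study conditions of the synthetic screen.

    Defaults mirror the real screen's geometry: 28 inhibitors in triplicate,
    cell index sampled every minute for 2 h then every 5 min for 4 h, with
    a short pre-treatment baseline; the control curve drops by ~0.4 index
    units, bottoming out 25 min after thrombin.
    """

    n_inhibitors: int = 28
    n_kinases: int = 60
    n_replicates: int = 3
    drop_depth: float = 0.4        # D, cell-index units
    t_min: float = 25.0            # minutes to the disruption minimum
    baseline_index: float = 1.0
    noise_sd: float = 0.01
    span_min: float = 360.0
    fine_rate_min: float = 1.0     # sampling every minute ...
    fine_span_min: float = 120.0   # ... for the first 2 h
    coarse_rate_min: float = 5.0   # then every 5 min
    pre_min: float = 7.0           # pre-treatment samples, 1/min
    thrombin_time_min: float = -6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inhibitors < 3:
            raise ValueError("need at least 3 inhibitors")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.t_min < self.span_min:
            raise ValueError("time of minimum must lie within the span")

    def sample_times(self) -> np.ndarray:
        pre = np.arange(-self.pre_min, 0.0, 1.0)
        fine = np.arange(0.0, self.fine_span_min + 1e-9, self.fine_rate_min)
        coarse = np.arange(self.fine_span_min + self.coarse_rate_min,
                           self.span_min + 1e-9, self.coarse_rate_min)
        return np.concatenate([pre, fine, coarse])


def default_planted_effects(panel: KinaseActivityPanel) -> list[PlantedEffect]:
    """Six planted kinases, one of them a switch kinase (both signs).

    The switch kinase weakens the barrier early (5-35 min, the fine-sampled
    window indices 5-30) and strengthens it late (100-245 min, coarse
    window indices 100-140 on the default grid).
    """
    k = panel.kinases
    return [
        PlantedEffect(k[0], -1, 5.0, 35.0, 0.25),
        PlantedEffect(k[0], +1, 100.0, 245.0, 0.25),   # switch kinase
        PlantedEffect(k[1], +1, 10.0, 70.0, 0.30),
        PlantedEffect(k[2], -1, 30.0, 110.0, 0.25),
        PlantedEffect(k[3], +1, 150.0, 300.0, 0.30),
        PlantedEffect(k[4], -1, 200.0, 340.0, 0.25),
        PlantedEffect(k[5], +1, 60.0, 180.0, 0.20),
    ]


@dataclass
class GroundTruth:
    effects: list[PlantedEffect]
    panel: KinaseActivityPanel
    config: SimConfig

    @property
    def kinases(self) -> set[str]:
        return {e.kinase for e in self.effects}

    def true_matrix(self, grid: WindowGrid) -> FunctionalityMatrix:
        """Per-window true functionality: sign of the effect whose active
        interval contains the window midpoint."""
        mids = grid.midpoints
        calls = pd.DataFrame(0, index=self.panel.kinases, columns=mids,
                             dtype=int)
        for e in self.effects:
            active = (mids >= e.t_on) & (mids <= e.t_off)
            calls.loc[e.kinase, mids[active]] = e.sign
        return FunctionalityMatrix(calls=calls, condition="truth", grid=grid)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "effects": [vars(e) for e in self.effects],
                    "kinases": sorted(self.kinases),
                    "seed": self.config.seed,
                },
                fh, indent=2,
            )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_panel(config: SimConfig, min_hits: int = 2,
                   mean_hits: float = 4.0) -> KinaseActivityPanel:
    """Inhibitor x kinase residual-activity panel with realistic selectivity.

    Kinase inhibitors are selective: most kinases retain near-full activity
    under most inhibitors, and each kinase is strongly inhibited by a small
    subset. Residual activity is drawn near 100 (clipped normal, mean 92)
    except for each kinase's strong inhibitors (2 + Poisson, mean
    ``mean_hits`` total) which draw uniform [0, 50). This gives the
    identifiability guarantee the regression needs: every kinase is
    inhibited below 50% by at least ``min_hits`` inhibitors.
    """
    if min_hits > config.n_inhibitors:
        raise ValueError("overlap guarantee infeasible: min_hits > n_inhibitors")
    rng = np.random.default_rng(config.seed)
    m = np.clip(
        rng.normal(92.0, 6.0, size=(config.n_inhibitors, config.n_kinases)),
        55.0, 100.0,
    )
    for j in range(config.n_kinases):
        n_hits = min(
            config.n_inhibitors,
            min_hits + int(rng.poisson(max(mean_hits - min_hits, 0.0))),
        )
        hit = rng.choice(config.n_inhibitors, size=n_hits, replace=False)
        m[hit, j] = rng.uniform(0.0, 50.0, size=n_hits)
    inhibitors = [f"inh{i:02d}" for i in range(config.n_inhibitors)]
    kinases = [f"KIN{j:03d}" for j in range(config.n_kinases)]
    return KinaseActivityPanel(pd.DataFrame(m, index=inhibitors, columns=kinases))


def control_curve(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Disruption/recovery cell index: baseline before thrombin, then a
    gamma-like drop c(t) = b0 − D·(s/t_min)·e^(1−s/t_min), s = minutes
    since thrombin."""
    t = np.asarray(t, dtype=float)
    s = t - config.thrombin_time_min
    drop = np.where(
        s > 0,
        config.drop_depth * (s / config.t_min) * np.exp(1.0 - s / config.t_min),
        0.0,
    )
    return config.baseline_index - drop


def simulate_screen(
    config: SimConfig,
    planted: list[PlantedEffect] | None,
    panel: KinaseActivityPanel,
) -> tuple[TimeSeriesPlate, GroundTruth]:
    """Generate one plate: control wells follow c(t); inhibitor i's well is
    c(t) − Σ_k sign_k·mag_k·(1 − a_ik/100)·1[t ∈ active_k] + noise."""
    planted = default_planted_effects(panel) if planted is None else planted
    for e in planted:
        if e.kinase not in panel.matrix.columns:
            raise ValueError(f"planted kinase {e.kinase!r} absent from panel")
    rng = np.random.default_rng(config.seed)
    times = config.sample_times()
    base = control_curve(times, config)

    frac = panel.fractions()
    rows: dict[str, np.ndarray] = {}
    meta: list[tuple[str, str, str, int]] = []
    condition = "thrombin"
    for inhib in list(panel.inhibitors) + [CONTROL_ID]:
        signal = base.copy()
        if inhib != CONTROL_ID:
            for e in planted:
                inhibition = 1.0 - float(frac.loc[inhib, e.kinase])
                active = (times >= e.t_on) & (times <= e.t_off)
                signal = signal - e.sign * e.magnitude * inhibition * active
        for rep in range(1, config.n_replicates + 1):
            well = f"{inhib}_r{rep}"
            noise = rng.normal(0.0, config.noise_sd, size=times.shape) \
                if config.noise_sd > 0 else 0.0
            rows[well] = signal + noise
            meta.append((well, inhib, condition, rep))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=times)
    wells = pd.DataFrame(
        meta, columns=["well", "inhibitor", "condition", "replicate"]
    ).set_index("well")
    plate = TimeSeriesPlate(
        times=times, wells=wells, values=values,
        thrombin_time_min=config.thrombin_time_min,
        inhibitor_time_min=0.0,
    )
    return plate, GroundTruth(effects=planted, panel=panel, config=config)


def simulate_background(
    n_nodes: int,
    planted_paths: list[list[str]],
    p: float = 0.1,
    seed: int = 0,
    extra_nodes_prefix: str = "BG",
) -> BackgroundNetwork:
    """Random directed graph (edge probability p) with every planted chain's
    edges guaranteed present."""
    if any(len(chain) == 0 for chain in planted_paths):
        raise ValueError("planted chains must be nonempty")
    rng = np.random.default_rng(seed)
    nodes: list[str] = []
    for chain in planted_paths:
        for n in chain:
            if n not in nodes:
                nodes.append(n)
    i = 0
    while len(nodes) < n_nodes:
        cand = f"{extra_nodes_prefix}{i:03d}"
        i += 1
        if cand not in nodes:
            nodes.append(cand)
    G = nx.DiGraph()
    G.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                G.add_edge(u, v)
    for chain in planted_paths:
        G.add_edges_from(zip(chain, chain[1:]))
    return BackgroundNetwork(
        graph=G, organism="synthetic",
        provenance={"planted_paths": planted_paths, "p": p, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _dilate(idx: set[int], slack: int, n: int) -> set[int]:
    out: set[int] = set()
    for i in idx:
        out.update(range(max(0, i - slack), min(n, i + slack + 1)))
    return out


def score_recovery(
    predicted: FunctionalityMatrix,
    truth: GroundTruth,
    grid: WindowGrid,
    slack_windows: int = 2,
) -> dict[str, float]:
    """Kinase-level detection metrics with window slack.

    precision / recall on the detected-kinase sets (precision 1 by
    convention when nothing is predicted); sign accuracy = fraction of
    nonzero predicted entries of true-positive kinases whose sign matches a
    true call within ±slack windows; Jaccard = symmetric slack-tolerant
    window overlap, averaged over true positives.
    """
    true_m = truth.true_matrix(grid)
    if list(predicted.calls.columns) != list(true_m.calls.columns):
        raise ValueError("predicted and truth use different window grids")
    pred_k = set(predicted.calls.index[(predicted.calls != 0).any(axis=1)])
    true_k = truth.kinases
    tp = pred_k & true_k
    precision = len(tp) / len(pred_k) if pred_k else 1.0
    recall = len(tp) / len(true_k) if true_k else 1.0

    n = predicted.calls.shape[1]
    sign_ok = sign_total = 0
    jaccards: list[float] = []
    for k in tp:
        prow = predicted.calls.loc[k].to_numpy()
        trow = true_m.calls.loc[k].to_numpy()
        # sign accuracy: among predicted calls inside the (slack-dilated)
        # true support, is the direction right?
        sup_dil = _dilate(set(np.nonzero(trow != 0)[0].tolist()), slack_windows, n)
        for s in (-1, 1):
            p_idx = set(np.nonzero(prow == s)[0].tolist()) & sup_dil
            t_dil = _dilate(set(np.nonzero(trow == s)[0].tolist()),
                            slack_windows, n)
            sign_total += len(p_idx)
            sign_ok += len(p_idx & t_dil)
        p_any = set(np.nonzero(prow != 0)[0].tolist())
        t_any = set(np.nonzero(trow != 0)[0].tolist())
        p_dil = _dilate(p_any, slack_windows, n)
        t_dil = _dilate(t_any, slack_windows, n)
        matched = len(p_any & t_dil) + len(t_any & p_dil)
        denom = len(p_any) + len(t_any)
        jaccards.append(matched / denom if denom else 1.0)
    return {
        "precision": precision,
        "recall": recall,
        "sign_accuracy": (sign_ok / sign_total) if sign_total else 1.0,
        "window_jaccard": float(np.mean(jaccards)) if jaccards else 0.0,
        "n_predicted": float(len(pred_k)),
        "n_true": float(len(true_k)),
    }
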