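"""Validation-side quantification: densitometry fold changes, the
activation decision rule, and relative qPCR expression.

Western-blot band intensities are first normalized to the loading control
(e.g. GAPDH), then to the untreated reference timepoint, giving per-replicate
fold changes of phosphorylation from the basal level. A kinase is called
"different from basal" when a t test gives p < 0.05 OR every biological
replicate moves at least 20% in the same direction. qPCR transcript
abundance uses the 2^-ddCT method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DensitometryTable:
    """Replicate x timepoint band intensities for target + loading control.

    ``data`` columns: replicate, timepoint, target_intensity,
    loading_intensity; ``reference`` is the basal (e.g. media-only "0-M")
    timepoint present in every replicate.
    """

    data: pd.DataFrame
    reference: str = "0-M"

    def __post_init__(self) -> None:
        need = {"replicate", "timepoint", "target_intensity", "loading_intensity"}
        if not need <= set(self.data.columns):
            raise ValueError(f"densitometry table needs columns {sorted(need)}")
        if (self.data[["target_intensity", "loading_intensity"]] <= 0).any().any():
            raise ValueError("band intensities must be > 0")
        by_rep = self.data.groupby("replicate")["timepoint"].apply(set)
        if not all(self.reference in s for s in by_rep):
            raise ValueError(f"reference timepoint {self.reference!r} missing "
                             "from some replicate")

    @classmethod
    def from_csv(cls, path, reference: str = "0-M") -> "DensitometryTable":
        return cls(pd.read_csv(path, dtype={"timepoint": str}), reference)


def fold_change(table: DensitometryTable) -> pd.DataFrame:
    """Replicate x timepoint fold changes.

    fc = (target/loading) / (target_ref/loading_ref) per replicate; the
    reference timepoint maps to exactly 1, and rescaling all of one
    replicate's intensities by a constant leaves fc unchanged.
    """
    df = table.data.copy()
    df["norm"] = df["target_intensity"] / df["loading_intensity"]
    ref = (
        df[df["timepoint"] == table.reference]
        .set_index("replicate")["norm"]
    )
    df["fc"] = df["norm"] / df["replicate"].map(ref).to_numpy()
    return df.pivot(index="replicate", columns="timepoint", values="fc")


def activation_call(
    fcs: np.ndarray | pd.Series,
    alpha: float = 0.05,
    min_change: float = 0.20,
    mode: str = "one_sample_log",
    raw_treated: np.ndarray | None = None,
    raw_control: np.ndarray | None = None,
) -> tuple[bool, str]:
    """Is activity at this timepoint different from basal?

    True iff the t test gives p < alpha, OR every replicate's fold change
    is >= 1 + min_change, OR every replicate's is <= 1 - min_change. The
    evidence tag records which clause fired ("ttest", "all_up", "all_down",
    or "none"). Default test: two-sided one-sample t on log2 fold changes
    vs 0; mode="two_sample" runs an independent t test on the raw
    normalized intensities instead.
    """
    fcs = np.asarray(fcs, dtype=float)
    if fcs.size < 2:
        raise ValueError("need at least 2 replicates")
    if np.all(fcs >= 1.0 + min_change):
        return True, "all_up"
    if np.all(fcs <= 1.0 - min_change):
        return True, "all_down"
    if mode == "one_sample_log":
        if np.ptp(np.log2(fcs)) == 0 and fcs[0] == 1.0:
            p = 1.0
        else:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # identical replicates
                p = float(stats.ttest_1samp(np.log2(fcs), 0.0).pvalue)
    elif mode == "two_sample":
        if raw_treated is None or raw_control is None:
            raise ValueError("two_sample mode needs raw intensity arrays")
        p = float(stats.ttest_ind(raw_treated, raw_control).pvalue)
    else:
        raise ValueError(f"unknown t-test mode {mode!r}")
    if np.isfinite(p) and p < alpha:
        return True, "ttest"
    return False, "none"


@dataclass
class QpcrRecord:
    """CT values for target and housekeeping gene in test and reference."""

    ct_target_test: float
    ct_hk_test: float
    ct_target_ref: float
    ct_hk_ref: float

    def __post_init__(self) -> None:
        for v in vars(self).values():
            if not (np.isfinite(v) and v > 0):
                raise ValueError("CT values must be finite and positive")


def relative_expression(q: QpcrRecord) -> float:
    """2^-ddCT with ddCT = (CT_target - CT_hk)_test - (CT_target - CT_hk)_ref."""
    ddct = (q.ct_target_test - q.ct_hk_test) - (q.ct_target_ref - q.ct_hk_ref)
    return float(2.0 ** (-ddct))
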