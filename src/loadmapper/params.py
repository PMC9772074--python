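"""Load (alpha) and anxiety (beta) contrast parameters on network BOLD.

For each subject and network, the BOLD signal strength SS is estimated in
each of the four load x anxiety conditions, and two contrasts summarise the
network's response:

    alpha = [(SS_3b_safe - SS_1b_safe) + (SS_3b_threat - SS_1b_threat)] / 2
    beta  = [(SS_3b_threat - SS_3b_safe) + (SS_1b_threat - SS_1b_safe)] / 2

alpha is the average load effect (3-back > 1-back), beta the average induced
anxiety effect (threat > safe).  Scenario classification: a network driven
only by load (alpha > 0, beta = 0) is "A", only by anxiety "B", by both "C",
neither "null"; negative estimates fall outside the modelled scenarios and
are flagged "other".
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import CleanSeries
from .synthetic import CONDITIONS


def shift_labels(labels: pd.DataFrame, lag: int, run_boundaries) -> pd.DataFrame:
    """Delay condition labels by ``lag`` frames within each run.

    The BOLD response lags the stimulus; with a lag of ``lag`` frames, frame t
    is attributed to the condition shown at frame t - lag.  The first ``lag``
    frames of a run keep their own labels (there is nothing earlier to
    attribute them to).
    """
    if lag == 0:
        return labels
    if lag < 0:
        raise ValueError("lag must be non-negative")
    out = labels.copy()
    rb = list(run_boundaries)
    cols = ["block", "load", "anxiety", "phase"]
    for start, stop in zip(rb[:-1], rb[1:]):
        chunk = labels.iloc[start:stop][cols].to_numpy()
        shifted = np.vstack([chunk[:lag], chunk[:-lag]]) if lag < len(chunk) else chunk
        out.iloc[start:stop, [labels.columns.get_loc(c) for c in cols]] = shifted
    return out


def block_signal_strength(
    network_series: pd.DataFrame,
    clean: CleanSeries,
    lag: int = 2,
    estimator: str = "mean",
    hrf_kernel: np.ndarray | None = None,
) -> pd.DataFrame:
    """Condition signal strength SS per network.

    ``network_series`` holds one row per retained frame (output of
    :func:`loadmapper.preprocess.aggregate_networks`).  With the default
    ``"mean"`` estimator, SS of a condition is the mean of the cleaned
    network signal over that condition's letter-phase frames after shifting
    labels by ``lag`` frames (hemodynamic delay).  The ``"glm"`` estimator
    instead regresses the series on the four condition indicators (optionally
    HRF-convolved) plus an intercept and reports intercept + beta per cell.

    Returns a DataFrame indexed by network with one column per
    ``(load, anxiety)`` condition.
    """
    if estimator not in ("mean", "glm"):
        raise ValueError(f"unknown estimator {estimator!r}")
    labels = shift_labels(clean.labels, lag, clean.run_boundaries)
    retained = labels.iloc[clean.retained_indices].reset_index(drop=True)
    if len(network_series) != len(retained):
        raise ValueError("network series is not aligned with retained frames")
    letters = (retained["phase"] == "letters").to_numpy()

    cells: dict[tuple[str, str], np.ndarray] = {}
    for load, anx in CONDITIONS:
        sel = letters & (retained["load"] == load).to_numpy() & (
            retained["anxiety"] == anx
        ).to_numpy()
        if not sel.any():
            raise ValueError(f"condition {(load, anx)} has zero retained letter frames")
        cells[(load, anx)] = sel

    X = network_series.to_numpy()
    if estimator == "mean":
        ss = {cond: X[sel].mean(axis=0) for cond, sel in cells.items()}
    else:
        regs = []
        for cond in CONDITIONS:
            x = cells[cond].astype(float)
            if hrf_kernel is not None:
                conv = np.empty_like(x)
                # retained frames are not contiguous; convolve on the full
                # timeline then subset, so the kernel sees true spacing
                full = np.zeros(int(clean.run_boundaries[-1]))
                full[clean.retained_indices] = x
                rb = list(clean.run_boundaries)
                for start, stop in zip(rb[:-1], rb[1:]):
                    full[start:stop] = np.convolve(full[start:stop], hrf_kernel)[: stop - start]
                conv = full[clean.retained_indices]
                regs.append(conv)
            else:
                regs.append(x)
        design = np.column_stack([np.ones(len(X))] + regs)
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        ss = {cond: beta[0] + beta[1 + i] for i, cond in enumerate(CONDITIONS)}

    out = pd.DataFrame(
        {cond: pd.Series(vals, index=network_series.columns) for cond, vals in ss.items()}
    )
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["load", "anxiety"])
    return out


def alpha_beta(ss: Mapping[tuple[str, str], float]) -> tuple[float, float]:
    """alpha/beta contrasts from one network's four condition signals."""
    for cond in CONDITIONS:
        if cond not in ss:
            raise ValueError(f"missing condition cell {cond}")
    s3s, s3t = ss[("3-back", "safe")], ss[("3-back", "threat")]
    s1s, s1t = ss[("1-back", "safe")], ss[("1-back", "threat")]
    alpha = ((s3s - s1s) + (s3t - s1t)) / 2.0
    beta = ((s3t - s3s) + (s1t - s1s)) / 2.0
    return float(alpha), float(beta)


def compute_alpha_beta(ss: pd.DataFrame) -> pd.DataFrame:
    """Per-network alpha and beta from a condition-signal table.

    ``ss`` is indexed by network with ``(load, anxiety)`` columns (the output
    of :func:`block_signal_strength`).
    """
    rows = {}
    for net in ss.index:
        cells = {cond: float(ss.loc[net, cond]) for cond in CONDITIONS}
        rows[net] = alpha_beta(cells)
    return pd.DataFrame(rows, index=["alpha", "beta"]).T


def classify_scenario(alpha: float, beta: float, epsilon: float = 0.0) -> str:
    """Map (alpha, beta) to the qualitative response scenario.

    "A" load-only, "B" anxiety-only, "C" both, "null" neither (within the
    tolerance band ``epsilon``); estimates that are reliably negative on
    either axis do not fit the modelled scenarios and return "other".
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    a_pos = alpha > epsilon
    b_pos = beta > epsilon
    a_null = abs(alpha) <= epsilon
    b_null = abs(beta) <= epsilon
    if a_pos and b_null:
        return "A"
    if a_null and b_pos:
        return "B"
    if a_pos and b_pos:
        return "C"
    if a_null and b_null:
        return "null"
    return "other"


def subject_params_table(
    subject_id: str,
    group: str,
    ss: pd.DataFrame,
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Tidy per-network parameter table for one subject."""
    ab = compute_alpha_beta(ss)
    ab.insert(0, "network", ab.index)
    ab.insert(0, "group", group)
    ab.insert(0, "subject", subject_id)
    ab["scenario"] = [
        classify_scenario(a, b, epsilon) for a, b in zip(ab["alpha"], ab["beta"])
    ]
    return ab.reset_index(drop=True)
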