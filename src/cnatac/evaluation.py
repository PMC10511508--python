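"""Concordance machinery: pseudo-bulk profiles and per-state accuracy.

A population of single-cell calls is summarized by its pseudo-bulk copy
number per bin,

    cnv[i] = (1 * N_loss + 2 * N_normal + 3 * N_gain) / N_cells,

on the {1,2,3} scale (loss=1, normal=2, gain=3).  Two profiles are compared
by Pearson correlation and mean squared error, or converted to a 3-state
classification with two thresholds (below ``c_low`` -> loss, above ``c_high``
-> gain) and scored with per-state precision / recall / F1.  For
depth-robustness studies, two karyotype matrices restricted to their common
cells and bins are compared bin-by-bin and the fraction of bins retaining
each reference state is reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import GAIN, LOSS, NORMAL, Karyotype

__all__ = [
    "pseudobulk",
    "standardize",
    "profile_mse",
    "classify_profile",
    "prf1",
    "concordance_vs_reference",
]

_STATE_NAMES = {LOSS: "loss", NORMAL: "normal", GAIN: "gain"}


def pseudobulk(karyotype: Karyotype) -> np.ndarray:
    """Per-bin mean copy number across cells on the {1,2,3} scale."""
    if karyotype.states.shape[0] == 0:
        raise ValueError("pseudobulk of zero cells is undefined")
    return (karyotype.states + 1.0).mean(axis=0)


def standardize(profile: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to unit (population) standard deviation."""
    v = np.asarray(profile, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant profile")
    return (v - v.mean()) / sd


def profile_mse(a: np.ndarray, b: np.ndarray, paper_form: bool = False) -> float:
    """Mean squared error between two per-bin profiles.

    Default is the conventional ``sum((a-b)^2) / N``; with ``paper_form`` the
    sum is divided by ``N^2`` instead (an alternative normalization in the
    literature, available for literal reproduction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    n = a.size
    sse = float(np.sum((a - b) ** 2))
    return sse / (n * n) if paper_form else sse / n


def classify_profile(
    profile: np.ndarray, c_low: float, c_high: float
) -> np.ndarray:
    """Threshold a mean-copy-number profile into {loss, normal, gain} states."""
    if c_low > c_high:
        raise ValueError("c_low must be <= c_high")
    v = np.asarray(profile, dtype=float)
    return np.where(v > c_high, GAIN, np.where(v < c_low, LOSS, NORMAL)).astype(
        np.int8
    )


def prf1(pred: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Per-state precision, recall and F1 of a state vector against truth.

    For each state s: tp = #(pred==s and truth==s), fp = #(pred==s, truth!=s),
    fn = #(pred!=s, truth==s); precision = tp/(tp+fp), recall = tp/(tp+fn),
    F1 = 2PR/(P+R).  Undefined ratios (0/0) are reported as 0 with
    ``defined = False``.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth differ in length")
    rows = []
    for state, name in _STATE_NAMES.items():
        tp = int(np.sum((pred == state) & (truth == state)))
        fp = int(np.sum((pred == state) & (truth != state)))
        fn = int(np.sum((pred != state) & (truth == state)))
        defined = (tp + fp) > 0 and (tp + fn) > 0
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        rows.append((name, tp, fp, fn, precision, recall, f1, defined))
    return pd.DataFrame(
        rows,
        columns=["state", "tp", "fp", "fn", "precision", "recall", "f1", "defined"],
    ).set_index("state")


def concordance_vs_reference(
    k_test: Karyotype, k_ref: Karyotype
) -> dict[str, float]:
    """State retention of a test karyotype against a reference.

    The matrices are first restricted to their common cells and common bins;
    the overall fraction of unchanged bins and, per reference state, the
    fraction of bins retaining that state are returned.  Per-state fractions
    are NaN when the reference carries no bin in that state.
    """
    common_cells = [c for c in k_ref.cell_ids if c in set(k_test.cell_ids)]
    common_bins = [b for b in k_ref.bin_ids if b in set(k_test.bin_ids)]
    if not common_cells or not common_bins:
        raise ValueError("no common cells/bins between the two matrices")
    t_ci = {c: i for i, c in enumerate(k_test.cell_ids)}
    t_bi = {b: i for i, b in enumerate(k_test.bin_ids)}
    r_ci = {c: i for i, c in enumerate(k_ref.cell_ids)}
    r_bi = {b: i for i, b in enumerate(k_ref.bin_ids)}
    test = k_test.states[
        np.ix_([t_ci[c] for c in common_cells], [t_bi[b] for b in common_bins])
    ]
    ref = k_ref.states[
        np.ix_([r_ci[c] for c in common_cells], [r_bi[b] for b in common_bins])
    ]
    same = test == ref
    out = {"overall": float(same.mean())}
    for state, name in _STATE_NAMES.items():
        mask = ref == state
        out[name] = float(same[mask].mean()) if mask.any() else float("nan")
    return out
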