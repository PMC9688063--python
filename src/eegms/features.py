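"""Per-epoch microstate features.

Five families x four states = 20 features per 5-s epoch:

* ``Occurrence_X`` — appearances of state X per second (Hz);
* ``Duration_X`` — mean dwell time of X (ms);
* ``Coverage_X`` — percent of samples labeled X;
* ``MeanGFP_X`` — mean global field power over X-labeled samples (uV);
* ``MsMC_X`` — microstate map correlation: the mean absolute spatial
  correlation between X-labeled GFP-peak maps and the X template.

For partition labelings the identities ``sum(Coverage) = 100`` and
``Occurrence * Duration / 10 = Coverage`` hold exactly. A state absent
from an epoch yields 0 for its features plus an entry in the flag sidecar
(never a silent NaN), keeping the table dense for classifiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .microstates import (
    GFPSeries,
    Segmentation,
    TemplateSet,
    backfit_labels,
    compute_gfp,
)
from .recording import EpochSet

__all__ = [
    "FEATURE_FAMILIES",
    "feature_columns",
    "run_lengths",
    "occurrence",
    "duration",
    "coverage",
    "mean_gfp",
    "msmc",
    "epoch_features",
    "extract_feature_table",
    "subject_means",
]

FEATURE_FAMILIES = ("Occurrence", "Duration", "Coverage", "MeanGFP", "MsMC")


def feature_columns(labels: tuple[str, ...] = ("A", "B", "C", "D")) -> list[str]:
    """The canonical 20 feature column names, family-major."""
    return [f"{fam}_{lab}" for fam in FEATURE_FAMILIES for lab in labels]


def run_lengths(labels: np.ndarray, state: int) -> np.ndarray:
    """Lengths (in samples) of maximal contiguous runs of ``state``."""
    mask = np.asarray(labels) == state
    if not mask.any():
        return np.array([], dtype=int)
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ends - starts


def occurrence(seg: Segmentation, state: int, epoch_len_s: float) -> float:
    """Number of runs of ``state`` per second (Hz)."""
    return len(run_lengths(seg.sample_labels, state)) / epoch_len_s


def duration(seg: Segmentation, state: int, fs: float) -> float:
    """Mean run length of ``state`` in milliseconds (0 if absent)."""
    rl = run_lengths(seg.sample_labels, state)
    if rl.size == 0:
        return 0.0
    return float(rl.mean() * 1000.0 / fs)


def coverage(seg: Segmentation, state: int) -> float:
    """Percent of samples labeled ``state``."""
    labels = seg.sample_labels
    return 100.0 * float(np.count_nonzero(labels == state)) / labels.size


def mean_gfp(seg: Segmentation, gfp: GFPSeries | np.ndarray, state: int) -> float:
    """Mean GFP over samples labeled ``state`` (0 if absent)."""
    g = gfp.values if isinstance(gfp, GFPSeries) else np.asarray(gfp)
    mask = seg.sample_labels == state
    if not mask.any():
        return 0.0
    return float(g[mask].mean())


def msmc(seg: Segmentation, state: int) -> float:
    """Mean absolute peak-to-template correlation for ``state`` peaks."""
    mask = seg.peak_labels == state
    if not mask.any():
        return 0.0
    return float(seg.peak_correlations[mask].mean())


def epoch_features(
    epoch: np.ndarray,
    templates: TemplateSet,
    fs: float,
    seg: Segmentation | None = None,
) -> tuple[dict[str, float], list[str]]:
    """All 20 features of one epoch, plus absent-state flags."""
    if seg is None:
        seg = backfit_labels(epoch, templates)
    g = compute_gfp(epoch)
    epoch_len_s = epoch.shape[1] / fs
    feats: dict[str, float] = {}
    flags: list[str] = []
    for s, lab in enumerate(templates.labels):
        present = np.any(seg.sample_labels == s)
        feats[f"Occurrence_{lab}"] = occurrence(seg, s, epoch_len_s)
        feats[f"Duration_{lab}"] = duration(seg, s, fs)
        feats[f"Coverage_{lab}"] = coverage(seg, s)
        feats[f"MeanGFP_{lab}"] = mean_gfp(seg, g, s)
        feats[f"MsMC_{lab}"] = msmc(seg, s)
        if not present:
            flags.append(f"absent_state_{lab}")
    # family-major column order
    feats = {c: feats[c] for c in feature_columns(templates.labels)}
    return feats, flags


def extract_feature_table(
    epoch_sets: list[EpochSet],
    templates: TemplateSet,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One row of 20 features per retained epoch, across subjects.

    Returns the table (columns: ``subject_id``, ``group``, ``epoch``, then
    the 20 features) and a sidecar mapping ``"subject:epoch"`` keys to any
    absent-state flags raised for that epoch.
    """
    rows = []
    flag_sidecar: dict[str, list[str]] = {}
    for es in epoch_sets:
        for i in np.flatnonzero(es.retained):
            feats, flags = epoch_features(es.epochs[i], templates, es.fs)
            row = {"subject_id": es.subject_id, "group": es.group, "epoch": int(i)}
            row.update(feats)
            rows.append(row)
            if flags:
                flag_sidecar[f"{es.subject_id}:{int(i)}"] = flags
    table = pd.DataFrame(rows)
    return table, flag_sidecar


def subject_means(table: pd.DataFrame) -> pd.DataFrame:
    """Subject-level feature means (for group-table style reporting)."""
    cols = [c for c in table.columns if c not in ("subject_id", "group", "epoch")]
    return (
        table.groupby(["subject_id", "group"], as_index=False)[cols].mean()
    )
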