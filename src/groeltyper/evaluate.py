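"""Scoring inferred community profiles against a known composition.

Given a ground-truth table (taxon, relative protein share), the detection
outcome at a Top Rank Count threshold is summarized by true/false positives
and false negatives, sensitivity = |TP| / |truth|, and precision =
|TP| / (|TP| + |FP|).  Abundance accuracy is summarized by the signed x-fold
deviation, measured/expected - 1 (0 = exact, 1 = two-fold overestimate,
-0.5 = two-fold underestimate), with quartiles and 10th/90th percentiles
computed by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import ProfileResult, profile_community
from .reference_db import GroELRecord, PeptideIndex


@dataclass(frozen=True)
class DetectionOutcome:
    """Detection performance at one Top Rank Count threshold."""

    threshold: int
    true_positives: tuple[str, ...]
    false_positives: tuple[str, ...]
    false_negatives: tuple[str, ...]
    sensitivity: float
    precision: float
    zero_detection: bool = False


def load_ground_truth(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth TSV with columns ``taxon`` and ``share``."""
    truth = pd.read_csv(path, sep="\t")
    if not {"taxon", "share"} <= set(truth.columns):
        raise ValueError("ground truth must have columns 'taxon' and 'share'")
    return truth


def score_detection(
    detected_taxa: set[str], truth_taxa: set[str], threshold: int
) -> DetectionOutcome:
    """Compare a detected taxon set with the expected one.

    With nothing detected, precision is reported as 1.0 with the
    ``zero_detection`` flag set (rather than NaN) so threshold sweeps remain
    plottable.
    """
    tp = detected_taxa & truth_taxa
    fp = detected_taxa - truth_taxa
    fn = truth_taxa - detected_taxa
    zero = not detected_taxa
    precision = 1.0 if zero else len(tp) / (len(tp) + len(fp))
    return DetectionOutcome(
        threshold=threshold,
        true_positives=tuple(sorted(tp)),
        false_positives=tuple(sorted(fp)),
        false_negatives=tuple(sorted(fn)),
        sensitivity=len(tp) / len(truth_taxa) if truth_taxa else 1.0,
        precision=precision,
        zero_detection=zero,
    )


def sweep_thresholds(
    detected: pd.DataFrame,
    records: list[GroELRecord],
    index: PeptideIndex,
    truth: pd.DataFrame,
    rank: str,
    thresholds: list[int],
) -> list[DetectionOutcome]:
    """Re-run the full pipeline at each Top Rank Count threshold and score
    the detected taxon set against the ground truth."""
    if not thresholds or any(t < 1 for t in thresholds):
        raise ValueError("thresholds must be a non-empty list of positive integers")
    truth_taxa = set(truth["taxon"])
    outcomes = []
    for t in thresholds:
        result: ProfileResult = profile_community(
            detected, records, index, rank=rank, trc_threshold=t,
            schemes=("peptide_count",),
        )
        outcomes.append(score_detection(result.detected_taxa(), truth_taxa, t))
    return outcomes


def xfold_deviation(measured: float, expected: float) -> float:
    """Signed x-fold deviation of a measured relative abundance:
    measured / expected - 1.  Undefined for expected <= 0."""
    if expected <= 0:
        raise ValueError("expected abundance must be > 0")
    return measured / expected - 1.0


def deviation_summary(
    profile: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-taxon x-fold deviations of a profile from the ground truth.

    Taxa in the truth that were not detected (and detected taxa absent from
    the truth) are excluded, matching a not-detected-removed comparison.
    Returns the per-taxon table and summary statistics (median, quartiles,
    10th/90th percentile; linear interpolation).
    """
    merged = profile.merge(truth, on="taxon", how="inner")
    merged = merged[merged["share"] > 0]
    deviations = merged.apply(
        lambda row: xfold_deviation(row["relative_abundance"], row["share"]), axis=1
    )
    table = pd.DataFrame(
        {"taxon": merged["taxon"], "xfold_deviation": deviations}
    ).reset_index(drop=True)
    if len(table):
        q10, q25, q50, q75, q90 = np.percentile(
            table["xfold_deviation"], [10, 25, 50, 75, 90]
        )
    else:
        q10 = q25 = q50 = q75 = q90 = float("nan")
    summary = {
        "n": float(len(table)),
        "p10": float(q10),
        "q1": float(q25),
        "median": float(q50),
        "q3": float(q75),
        "p90": float(q90),
    }
    return table, summary


def outcomes_table(outcomes: list[DetectionOutcome]) -> pd.DataFrame:
    """Flatten DetectionOutcomes into a DataFrame for export/plotting."""
    return pd.DataFrame(
        {
            "threshold": [o.threshold for o in outcomes],
            "n_true_positives": [len(o.true_positives) for o in outcomes],
            "n_false_positives": [len(o.false_positives) for o in outcomes],
            "n_false_negatives": [len(o.false_negatives) for o in outcomes],
            "sensitivity": [o.sensitivity for o in outcomes],
            "precision": [o.precision for o in outcomes],
            "zero_detection": [o.zero_detection for o in outcomes],
        }
    )
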