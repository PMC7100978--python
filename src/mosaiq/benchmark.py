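"""Synthetic benchmarking of annotation performance.

Performance is scored by the mean absolute error (MAE) over the ordered
dosage labels {0, 1, 2} — a metric that penalizes a 0<->2 confusion twice
as hard as an off-by-one — and by plain accuracy.  The benchmark grid
crosses clone size (controlled through the recombination window and
reported as realized mean cells per clone) with fluorescence ambiguity
sigma_alpha, running replicate simulations per condition and scoring both
the full spatially-informed annotator and the marginal classifier that
ignores spatial context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationConfig, annotate_detailed
from .data import MeasurementTable
from .errors import AlignmentError, DimensionError, PairingError
from .simulate import (
    FluorescenceParams,
    GrowthParams,
    grow_culture,
    mean_clone_size,
    synthesize_measurements,
)

# desk-scale default grid: recombination-window levels (start size, duration),
# ordered from large clones (early onset) to small (late onset)
DEFAULT_CLONE_SIZE_LEVELS = ((8, 4), (32, 4), (128, 4), (512, 4))
DEFAULT_SIGMA_LEVELS = (0.1, 0.3, 0.5, 0.8)


def mae(true_dosages, predicted_dosages) -> float:
    """Mean absolute error between ordered dosage labels."""
    t = np.asarray(true_dosages, dtype=float)
    p = np.asarray(predicted_dosages, dtype=float)
    if t.shape != p.shape:
        raise DimensionError(f"length mismatch: {t.shape} vs {p.shape}")
    return float(np.mean(np.abs(t - p)))


@dataclass
class BenchmarkResult:
    """Score of one classifier on one replicate of one grid condition."""

    start_size: int
    duration: int
    sigma_alpha: float
    replicate: int
    seed: int
    classifier: str            # "full" or "marginal"
    mae: float
    accuracy: float
    mean_clone_size: float
    n_cells: int
    error: str | None = None


def run_replicate(
    start_size: int,
    duration: int,
    sigma_alpha: float,
    seed: int,
    final_size: int = 2048,
    config: AnnotationConfig | None = None,
) -> list[BenchmarkResult]:
    """Grow one culture, annotate it with a freshly trained model, score both
    classifiers.  Border cells are not excluded, so the scores are a lower
    bound on curated performance."""
    params = GrowthParams(
        recombination_start_size=start_size,
        recombination_duration=duration,
        final_size=final_size,
    )
    rng = np.random.default_rng(seed)
    culture = grow_culture(params, seed=int(rng.integers(2**31)))
    table = synthesize_measurements(
        culture, FluorescenceParams(sigma_alpha=sigma_alpha),
        seed=int(rng.integers(2**31)),
    )
    if config is None:
        config = AnnotationConfig(marker_channel=1, seed=int(rng.integers(2**31)))
    truth = table.data["true_dosage"].to_numpy()
    common = dict(
        start_size=start_size,
        duration=duration,
        sigma_alpha=sigma_alpha,
        seed=seed,
        mean_clone_size=mean_clone_size(culture),
        n_cells=len(table),
    )
    try:
        _, result = annotate_detailed(table, config)
    except Exception as exc:  # recorded, not fatal (spec: per-replicate failures)
        return [
            BenchmarkResult(
                replicate=-1, classifier=c, mae=np.nan, accuracy=np.nan,
                error=f"{type(exc).__name__}: {exc}", **common,
            )
            for c in ("full", "marginal")
        ]
    out = []
    for name, pred in (("full", result.dosages), ("marginal", result.marginal_dosages)):
        out.append(
            BenchmarkResult(
                replicate=-1,
                classifier=name,
                mae=mae(truth, pred),
                accuracy=float(np.mean(truth == pred)),
                **common,
            )
        )
    return out


def run_grid(
    clone_size_levels=DEFAULT_CLONE_SIZE_LEVELS,
    sigma_levels=DEFAULT_SIGMA_LEVELS,
    n_replicates: int = 10,
    seed: int = 0,
    final_size: int = 2048,
) -> pd.DataFrame:
    """Full benchmark: conditions x replicates, both classifiers.

    Replicate seeds are spawned deterministically from the master seed, so
    the whole grid is bit-reproducible.  Returns one row per replicate per
    condition per classifier.
    """
    if not clone_size_levels or not sigma_levels:
        raise ValueError("grid levels must be non-empty")
    rows = []
    master = np.random.default_rng(seed)
    for start_size, duration in clone_size_levels:
        for sigma in sigma_levels:
            for rep in range(n_replicates):
                rep_seed = int(master.integers(2**31))
                for res in run_replicate(
                    start_size, duration, sigma, rep_seed, final_size=final_size
                ):
                    res.replicate = rep
                    rows.append(res)
    return pd.DataFrame([vars(r) for r in rows])


def compare_to_marginal(results: pd.DataFrame) -> pd.DataFrame:
    """log2 fold-change in MAE when spatial context is neglected.

    Positive values mean the marginal classifier is worse, i.e. spatial
    context helps.  MAEs are floored at one-cell resolution (1 / n_cells)
    before the ratio so perfect runs do not divide by zero.
    """
    keys = ["start_size", "duration", "sigma_alpha"]
    mean_mae = (
        results.dropna(subset=["mae"])
        .groupby(keys + ["classifier"])[["mae", "n_cells"]]
        .mean()
        .reset_index()
    )
    pivot = mean_mae.pivot_table(index=keys, columns="classifier", values="mae")
    if "full" not in pivot.columns or "marginal" not in pivot.columns:
        raise PairingError("results lack one of the classifiers")
    if pivot[["full", "marginal"]].isna().any().any():
        raise PairingError("unpaired condition in benchmark results")
    ncells = mean_mae.groupby(keys)["n_cells"].mean()
    floor = 1.0 / ncells
    out = pivot.copy()
    out["log2_fold_change"] = np.log2(
        np.maximum(pivot["marginal"], floor) / np.maximum(pivot["full"], floor)
    )
    return out.reset_index()


def agreement(
    labels_a: pd.Series,
    labels_b: pd.Series,
    border: pd.Series | None = None,
    n_labels: int = 3,
) -> tuple[float, pd.DataFrame]:
    """Percent agreement and column-normalized confusion matrix.

    Both inputs are label Series indexed by cell id over the same cell set
    (``labels_a`` indexes the confusion-matrix columns, e.g. the reference
    labels).  ``border`` optionally excludes flagged cells before scoring.
    """
    labels_a, labels_b = pd.Series(labels_a), pd.Series(labels_b)
    if not labels_a.index.equals(labels_b.index):
        if sorted(labels_a.index) != sorted(labels_b.index):
            raise AlignmentError("label vectors refer to different cell sets")
        labels_b = labels_b.reindex(labels_a.index)
    if border is not None:
        keep = ~pd.Series(border).reindex(labels_a.index).fillna(False).astype(bool)
        labels_a, labels_b = labels_a[keep], labels_b[keep]
    pct = float(np.mean(labels_a.to_numpy() == labels_b.to_numpy()) * 100)
    counts = np.zeros((n_labels, n_labels))
    for a, b in zip(labels_a, labels_b):
        counts[int(b), int(a)] += 1
    colsum = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(colsum > 0, counts / colsum, np.nan)
    cm = pd.DataFrame(
        confusion,
        index=pd.Index(range(n_labels), name="predicted"),
        columns=pd.Index(range(n_labels), name="true"),
    )
    return pct, cm


def score_labels(table: MeasurementTable, truth_column: str = "true_dosage") -> dict:
    """Convenience: MAE + accuracy of an annotated table against ground truth."""
    truth = table.data[truth_column].to_numpy(dtype=float)
    pred = table.dosages
    return {
        "mae": mae(truth, pred),
        "accuracy": float(np.mean(truth == pred)),
        "n": len(table),
    }
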