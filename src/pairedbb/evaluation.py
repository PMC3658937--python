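"""ROC evaluation of ranked tuple lists, with the paired-design exclusion rule.

Detection performance is assessed by ranking tuples by a per-tuple score
(for this package, the posterior probability of the relevant model) and
sweeping a threshold.  When a dataset contains both within-pair and
between-group differential expression, tuples simulated with
between-group changes are neither true nor false positives for the
within-pair task — the within-pair model correctly assigns them low
posteriors, while regression-style competitors flag them — so they are
excluded from both rates to keep comparisons fair.

External per-tuple score lists (e.g. from GLM-based methods) can be
evaluated through the same functions, so competitors need not be
re-implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data_model import ModelSpec, ReplicateStructure
from .estimation import build_theta_many
from .inference import compute_posteriors
from .simulator import (
    BETWEEN_DE,
    WITHIN_DE,
    SimulationConfig,
    simulate_dataset,
)

__all__ = [
    "RocCurve",
    "roc_points",
    "mean_roc",
    "read_scores_tsv",
    "default_models",
    "analyse_dataset",
    "simulation_study",
]

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_points(tuple_ids, scores, positives, excluded=()) -> RocCurve:
    """ROC curve of a ranked tuple list.

    Parameters
    ----------
    tuple_ids, scores : aligned sequences
        Per-tuple real scores, higher meaning stronger evidence.  NaN
        scores are ranked last (below every finite score) and logged.
    positives : set of tuple ids
        The true positives for the task being evaluated.
    excluded : set of tuple ids
        Tuples removed before computing either rate; exclusion wins over
        positive status.

    Thresholds are swept over unique score values in descending order;
    the AUC is the trapezoidal area under the curve.
    """
    ids = np.asarray(list(tuple_ids))
    scores = np.asarray(scores, dtype=float)
    if ids.shape != scores.shape:
        raise ValueError("tuple_ids and scores must be aligned")
    excluded = set(excluded)
    keep = np.array([t not in excluded for t in ids])
    ids, scores = ids[keep], scores[keep]
    n_missing = int(np.isnan(scores).sum())
    if n_missing:
        logger.info("%d missing scores ranked last", n_missing)
        finite = scores[~np.isnan(scores)]
        fill = (finite.min() if finite.size else 0.0) - 1.0
        scores = np.where(np.isnan(scores), fill, scores)
    y = np.array([t in positives for t in ids], dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need both positives and negatives after exclusion")
    fpr, tpr, _ = _sk_roc_curve(y, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def mean_roc(runs, grid) -> np.ndarray:
    """Vertical average of several ROC curves at fixed FPR grid points.

    Each run's curve is treated as a step function (the TPR attained at
    the largest observed FPR not exceeding the grid point), mirroring the
    averaging of repeated-simulation ROC curves.
    """
    if not runs:
        raise ValueError("at least one ROC run required")
    grid = np.asarray(grid, dtype=float)
    tprs = np.empty((len(runs), grid.size))
    for k, run in enumerate(runs):
        fpr, tpr = (run.fpr, run.tpr) if isinstance(run, RocCurve) else run
        idx = np.searchsorted(fpr, grid, side="right") - 1
        tprs[k] = np.where(idx >= 0, np.asarray(tpr)[np.maximum(idx, 0)], 0.0)
    return tprs.mean(axis=0)


def read_scores_tsv(path) -> tuple:
    """Read an external (tuple id, score) table; returns (ids, scores)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return list(frame.index), frame.iloc[:, 0].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# model templates and the repeated-simulation study harness


def default_models(n_pairs: int, n_groups: int = 1,
                   group_of_pair=None) -> list:
    """The standard model trio for paired designs.

    * ``no_de``: one set with the proportion fixed at 0.5, the
      one-to-one-ratio null;
    * ``consistent_de``: one free set — a ratio deviating from 1:1 but
      shared by every sample pair (within-pair differential expression);
    * ``group_de`` (two-group designs only): one free set per
      experimental condition — the ratio differs between conditions.
    """
    all_pairs = list(range(n_pairs))
    models = [
        ModelSpec("no_de", [all_pairs], [0.5]),
        ModelSpec("consistent_de", [all_pairs], [None]),
    ]
    if n_groups == 2:
        if group_of_pair is None:
            half = n_pairs // 2
            group_of_pair = np.array([0] * half + [1] * (n_pairs - half))
        sets = [list(np.flatnonzero(np.asarray(group_of_pair) == g))
                for g in range(2)]
        models.append(ModelSpec("group_de", sets, [None, None]))
    return models


def analyse_dataset(counts, scaling, *, n_groups=1, group_of_pair=None,
                    theta_size=None, seed=0, models=None, replicates=None,
                    per_group_dispersion=False):
    """Full inference on one dataset: Theta, likelihoods, priors, posteriors.

    Replicate groups default to the experimental conditions.  Returns a
    :class:`PosteriorTable`.
    """
    n = counts.n_pairs
    if replicates is None:
        if n_groups == 2:
            gop = (np.asarray(group_of_pair) if group_of_pair is not None
                   else np.array([0] * (n // 2) + [1] * (n - n // 2)))
            groups = [list(np.flatnonzero(gop == g)) for g in range(2)]
            replicates = ReplicateStructure(groups, n)
        else:
            replicates = ReplicateStructure.single_group(n)
    if models is None:
        models = default_models(n, n_groups, group_of_pair)
    theta = build_theta_many(counts, models, replicates, scaling,
                             sample_size=theta_size, seed=seed,
                             per_group_dispersion=per_group_dispersion)
    return compute_posteriors(counts, models, theta, scaling)


def simulation_study(config: SimulationConfig, seeds, theta_size=None) -> pd.DataFrame:
    """Repeated simulation + inference, one row of AUCs per seed.

    For each seed the dataset is regenerated, the posterior analysis run
    with the simulator's true library scaling factors, and ROC AUCs
    computed: ``within_auc`` scores within-pair differential expression
    by the posterior of the consistent-ratio model (between-group tuples
    excluded, as they are neither clean positives nor clean negatives for
    that task); ``between_auc`` scores between-group differential
    expression by the posterior of the group-difference model.
    """
    rows = []
    for seed in seeds:
        cfg = SimulationConfig(**{**config.__dict__, "seed": int(seed)})
        counts, scaling, truth = simulate_dataset(cfg)
        table = analyse_dataset(counts, scaling, n_groups=cfg.n_groups,
                                group_of_pair=cfg.group_of_pair,
                                theta_size=theta_size, seed=int(seed))
        ids = table.tuple_ids
        row = {"seed": int(seed)}
        j = table.model_names.index("consistent_de")
        row["within_auc"] = roc_points(
            ids, table.posteriors[:, j],
            positives=truth.ids_with_label(WITHIN_DE),
            excluded=truth.ids_with_label(BETWEEN_DE),
        ).auc
        between_ids = truth.ids_with_label(BETWEEN_DE)
        if "group_de" in table.model_names and between_ids:
            jg = table.model_names.index("group_de")
            row["between_auc"] = roc_points(
                ids, table.posteriors[:, jg], positives=between_ids,
            ).auc
        rows.append(row)
    return pd.DataFrame(rows)
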