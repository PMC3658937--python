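"""Core validated containers for paired count data.

A *tuple pair* is the set of paired counts for one genomic object (gene,
tag, methylation locus, ...) across ``n`` sample pairs.  For tuple ``c``
the data are ``D_c = {(u_1c, ..., u_nc), (u'_1c, ..., u'_nc)}`` where
``u_ic`` is the count in the first member of sample pair ``i`` (e.g. the
tumour library of patient ``i``) and ``u'_ic`` the count in its matched
partner (the normal library).

The containers here validate shape and domain invariants once, so that
downstream likelihood code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedCountMatrix",
    "ScalingFactors",
    "ReplicateStructure",
    "ModelSpec",
    "EffectiveParams",
    "DesignBundle",
    "validate_design",
    "FREE",
]

#: Sentinel marking a model set whose expected proportion is estimated
#: from the data rather than held fixed.
FREE = None


def _as_count_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
            raise ValueError(f"{name} must contain integral values")
    if arr.size and arr.min() < 0:
        raise ValueError(f"negative count in {name}")
    return arr.astype(np.int64)


@dataclass
class PairedCountMatrix:
    """Counts for the two members of each sample pair, tuples x pairs.

    ``counts_first[c, i]`` is ``u_ic`` and ``counts_second[c, i]`` is
    ``u'_ic``.  Tuples whose counts are zero everywhere are retained but
    flagged via :attr:`all_zero_mask`; downstream modules decide their
    treatment.
    """

    tuple_ids: list
    counts_first: np.ndarray
    counts_second: np.ndarray
    pair_labels: list

    def __post_init__(self):
        self.counts_first = _as_count_matrix(self.counts_first, "counts_first")
        self.counts_second = _as_count_matrix(self.counts_second, "counts_second")
        self.tuple_ids = list(self.tuple_ids)
        self.pair_labels = list(self.pair_labels)
        if self.counts_first.shape != self.counts_second.shape:
            raise ValueError("counts_first and counts_second have different shapes")
        if len(self.tuple_ids) != self.counts_first.shape[0]:
            raise ValueError("tuple_ids length does not match count matrix rows")
        if len(self.pair_labels) != self.counts_first.shape[1]:
            raise ValueError("pair_labels length does not match count matrix columns")
        if len(set(self.tuple_ids)) != len(self.tuple_ids):
            raise ValueError("tuple_ids must be unique")
        if len(set(self.pair_labels)) != len(self.pair_labels):
            raise ValueError("pair_labels must be unique")

    @property
    def n_tuples(self) -> int:
        return self.counts_first.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.counts_first.shape[1]

    @property
    def pair_totals(self) -> np.ndarray:
        """``u_ic + u'_ic``, the per-pair totals conditioned on in the model."""
        return self.counts_first + self.counts_second

    @property
    def all_zero_mask(self) -> np.ndarray:
        """Boolean mask of tuples with zero counts in every library."""
        return self.pair_totals.sum(axis=1) == 0

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        """One row per tuple; columns ``<pair>_a`` / ``<pair>_b``."""
        data = {}
        for i, lab in enumerate(self.pair_labels):
            data[f"{lab}_a"] = self.counts_first[:, i]
            data[f"{lab}_b"] = self.counts_second[:, i]
        return pd.DataFrame(data, index=pd.Index(self.tuple_ids, name="tuple_id"))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PairedCountMatrix":
        a_cols = [c for c in frame.columns if c.endswith("_a")]
        labels = [c[:-2] for c in a_cols]
        missing = [lab for lab in labels if f"{lab}_b" not in frame.columns]
        if missing:
            raise ValueError(f"missing _b columns for pairs: {missing}")
        first = frame[[f"{lab}_a" for lab in labels]].to_numpy()
        second = frame[[f"{lab}_b" for lab in labels]].to_numpy()
        return cls(list(frame.index), first, second, labels)

    @classmethod
    def from_tsv(cls, path) -> "PairedCountMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0, comment="#"))

    @classmethod
    def from_two_tsv(cls, path_first, path_second) -> "PairedCountMatrix":
        """Two files with matching tuple ids and pair headers."""
        fa = pd.read_csv(path_first, sep="\t", index_col=0, comment="#")
        fb = pd.read_csv(path_second, sep="\t", index_col=0, comment="#")
        if list(fa.index) != list(fb.index) or list(fa.columns) != list(fb.columns):
            raise ValueError("the two count files must share tuple ids and pair headers")
        return cls(list(fa.index), fa.to_numpy(), fb.to_numpy(), list(fa.columns))


@dataclass
class ScalingFactors:
    """Per-library normalisation constants proportional to sequencing depth."""

    L: np.ndarray
    L_prime: np.ndarray

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.L_prime = np.asarray(self.L_prime, dtype=float)
        if self.L.shape != self.L_prime.shape or self.L.ndim != 1:
            raise ValueError("L and L_prime must be 1-D and of equal length")
        if np.any(self.L <= 0) or np.any(self.L_prime <= 0):
            raise ValueError("scaling factors must be strictly positive")

    def __len__(self) -> int:
        return self.L.shape[0]

    @classmethod
    def unit(cls, n: int) -> "ScalingFactors":
        return cls(np.ones(n), np.ones(n))


def _check_partition(sets: Sequence[Sequence[int]], n: int, what: str) -> list:
    out = [sorted(int(i) for i in s) for s in sets]
    if not out:
        raise ValueError(f"{what}: at least one set required")
    flat = [i for s in out for i in s]
    if any(len(s) == 0 for s in out):
        raise ValueError(f"{what}: empty set")
    if len(set(flat)) != len(flat):
        raise ValueError(f"{what}: sets overlap")
    if set(flat) != set(range(n)):
        raise ValueError(f"{what}: sets do not cover all {n} sample pairs")
    return out


@dataclass
class ReplicateStructure:
    """Partition {F_1, ..., F_s} of sample pairs into replicate groups.

    ``i, j`` belong to the same group iff sample pair ``j`` is a biological
    replicate of sample pair ``i``; dispersion is estimated under this
    structure so that genuine differential expression between groups is not
    mistaken for dispersion.
    """

    groups: list
    n_pairs: int

    def __post_init__(self):
        self.groups = _check_partition(self.groups, self.n_pairs, "replicate structure")

    @classmethod
    def single_group(cls, n: int) -> "ReplicateStructure":
        return cls([list(range(n))], n)


@dataclass
class ModelSpec:
    """A model M: a partition {E_1, ..., E_m} of sample pairs.

    Each set either has a FIXED expected proportion (e.g. 0.5, the
    no-differential-expression one-to-one ratio) or a FREE proportion
    estimated per tuple.  Sample pairs within one set share distribution
    parameters under the model.
    """

    name: str
    sets: list
    proportions: list = field(default_factory=list)
    n_pairs: int = 0

    def __post_init__(self):
        if not self.proportions:
            self.proportions = [FREE] * len(self.sets)
        if len(self.proportions) != len(self.sets):
            raise ValueError("one proportion mode per model set required")
        if self.n_pairs == 0:
            self.n_pairs = sum(len(s) for s in self.sets)
        self.sets = _check_partition(self.sets, self.n_pairs, f"model {self.name!r}")
        for p in self.proportions:
            if p is not FREE:
                p = float(p)
                if not 0.0 < p < 1.0:
                    raise ValueError(
                        f"model {self.name!r}: fixed proportion must lie in (0, 1)"
                    )

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_free_sets(self) -> int:
        """Number of freely estimated proportions; the BIC parameter count."""
        return sum(1 for p in self.proportions if p is FREE)


@dataclass
class EffectiveParams:
    """Beta shapes implied by a proportion and dispersion.

    ``alpha = p (1 - phi) / phi`` and ``beta = (1 - p)(1 - phi) / phi``,
    defined for ``phi > 0``; ``p = alpha / (alpha + beta)`` always holds.
    """

    p: float
    alpha: float
    beta: float

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @classmethod
    def from_pi_phi(cls, pi: float, phi: float, L: float = 1.0,
                    L_prime: float = 1.0) -> "EffectiveParams":
        from .betabinom import effective_proportion

        if not 0.0 < phi < 1.0:
            raise ValueError("EffectiveParams requires 0 < phi < 1")
        p = float(effective_proportion(pi, L, L_prime))
        return cls(p=p, alpha=p * (1 - phi) / phi, beta=(1 - p) * (1 - phi) / phi)


@dataclass
class DesignBundle:
    counts: PairedCountMatrix
    scaling: ScalingFactors
    replicates: ReplicateStructure
    models: list


def validate_design(counts: PairedCountMatrix, scaling: ScalingFactors,
                    reps: ReplicateStructure, models: Sequence[ModelSpec]) -> DesignBundle:
    """Check that all design components refer to the same n sample pairs.

    Returns the bundle unchanged if consistent; idempotent.
    """
    n = counts.n_pairs
    if len(scaling) != n:
        raise ValueError(f"scaling factors for {len(scaling)} pairs, counts have {n}")
    if reps.n_pairs != n:
        raise ValueError(f"replicate structure over {reps.n_pairs} pairs, counts have {n}")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("model names must be unique")
    for m in models:
        if m.n_pairs != n:
            raise ValueError(f"model {m.name!r} partitions {m.n_pairs} pairs, counts have {n}")
    return DesignBundle(counts, scaling, reps, list(models))
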