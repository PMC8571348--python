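"""Fixed-size feature vectors, gene-grouped folds, and rank-based AUROC.

Each peptide is summarized, per property scale, as a 40-dimensional vector:

* 20 relative amino-acid frequencies (scale-independent),
* sequence length,
* the scale values of the first six and last six residues (12),
* the whole-sequence mean of the scale (1),
* the scale mean over six equal-length regions (6), with region boundaries
  at ``round(i * L / 6)`` so shorter sequences simply have shorter regions.

Cross-validation folds are grouped by gene — every fragment of a gene lands
in the same fold, so sequence similarity between overlapping fragments can
never leak between training and test — while a greedy assignment keeps fold
sizes and class ratios balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .biophys import STANDARD_AA, AAScale

MIN_PEPTIDE_LENGTH = 50  # dataset filter: shorter fragments are unlikely to fold
_TERMINUS = 6
N_FEATURES = 40

__all__ = [
    "MIN_PEPTIDE_LENGTH",
    "N_FEATURES",
    "SecretabilityDataset",
    "FoldAssignment",
    "extract_features",
    "feature_matrix",
    "feature_names",
    "build_dataset",
    "make_folds",
    "auroc",
]

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def feature_names(scale_name: str) -> list[str]:
    """Column names of the 40-feature vector, in extraction order."""
    names = [f"freq_{aa}" for aa in STANDARD_AA]
    names.append("length")
    names += [f"{scale_name}_nterm_{i + 1}" for i in range(_TERMINUS)]
    names += [f"{scale_name}_cterm_{i + 1}" for i in range(_TERMINUS)]
    names.append(f"{scale_name}_mean")
    names += [f"{scale_name}_region_{i + 1}" for i in range(6)]
    return names


def extract_features(peptide: str, scale: AAScale) -> np.ndarray:
    """40-feature vector for one peptide under one property scale.

    Requires a peptide of length >= 12 over the 20-letter alphabet (both
    six-residue terminus windows must fit).
    """
    length = len(peptide)
    if length < 2 * _TERMINUS:
        raise ValueError(
            f"peptide length {length} < {2 * _TERMINUS}: cannot fill terminus features"
        )
    vec = np.empty(N_FEATURES)
    counts = np.zeros(20)
    track = np.empty(length)
    for i, aa in enumerate(peptide):
        try:
            j = _AA_INDEX[aa]
        except KeyError:
            raise ValueError(f"non-standard residue {aa!r} in peptide") from None
        counts[j] += 1
        track[i] = scale.values[aa]
    vec[0:20] = counts / length
    vec[20] = length
    vec[21:27] = track[:_TERMINUS]
    vec[27:33] = track[-_TERMINUS:]
    vec[33] = track.mean()
    bounds = [int(np.floor(i * length / 6 + 0.5)) for i in range(7)]
    for i in range(6):
        vec[34 + i] = track[bounds[i] : bounds[i + 1]].mean()
    return vec


def feature_matrix(peptides: list[str], scale: AAScale) -> np.ndarray:
    return np.stack([extract_features(p, scale) for p in peptides])


@dataclass
class SecretabilityDataset:
    """Labelled peptides with gene ids for grouped cross-validation."""

    keys: list[str]
    peptides: list[str]
    labels: np.ndarray  # 1 = secretable (enriched), 0 = depleted
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.keys)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.peptides) == len(self.labels) == len(self.gene_ids) == n):
            raise ValueError("misaligned dataset columns")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        short = [p for p in self.peptides if len(p) < MIN_PEPTIDE_LENGTH]
        if short:
            raise ValueError(
                f"{len(short)} peptides shorter than {MIN_PEPTIDE_LENGTH} aa"
            )

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def build_dataset(
    records: pd.DataFrame,
    peptides: dict[str, str],
    gene_ids: dict[str, str],
    min_length: int = MIN_PEPTIDE_LENGTH,
) -> SecretabilityDataset:
    """Dataset of consistently classified fragments with peptides >= 50 aa.

    ``records`` is an enrichment table (needs a ``class`` column); enriched
    fragments become positives, depleted ones negatives, everything else is
    dropped, as are fragments without a peptide or shorter than
    ``min_length``.
    """
    keys, peps, labels, genes = [], [], [], []
    for key, cls in records["class"].items():
        if cls == "enriched":
            lab = 1
        elif cls == "depleted":
            lab = 0
        else:
            continue
        pep = peptides.get(key)
        if pep is None or len(pep) < min_length:
            continue
        keys.append(key)
        peps.append(pep)
        labels.append(lab)
        genes.append(gene_ids[key])
    return SecretabilityDataset(keys, peps, np.array(labels), genes)


@dataclass
class FoldAssignment:
    """Gene-to-fold map plus the induced per-record fold index."""

    n_folds: int
    gene_fold: dict[str, int]
    record_fold: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.record_fold == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.record_fold != fold)


def make_folds(
    dataset: SecretabilityDataset, k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Greedy gene-grouped folds balancing size and class ratio.

    Genes are visited by decreasing fragment count (ties shuffled by the
    seed) and each is assigned to the fold minimizing a size-plus-imbalance
    objective, keeping per-fold positive rates close to the global rate.
    """
    genes: dict[str, list[int]] = {}
    for i, g in enumerate(dataset.gene_ids):
        genes.setdefault(g, []).append(i)
    if len(genes) < k:
        raise ValueError(f"only {len(genes)} genes for {k} folds")
    rng = np.random.default_rng(seed)
    order = list(genes)
    rng.shuffle(order)
    order.sort(key=lambda g: -len(genes[g]))

    global_rate = dataset.labels.mean()
    target = len(dataset) / k
    fold_n = np.zeros(k)
    fold_pos = np.zeros(k)
    gene_fold: dict[str, int] = {}
    for g in order:
        idx = genes[g]
        g_n = len(idx)
        g_pos = int(dataset.labels[idx].sum())
        new_n = fold_n + g_n
        new_rate = (fold_pos + g_pos) / new_n
        cost = (new_n / target) ** 2 + np.abs(new_rate - global_rate)
        f = int(np.argmin(cost))
        gene_fold[g] = f
        fold_n[f] += g_n
        fold_pos[f] += g_pos
    record_fold = np.array([gene_fold[g] for g in dataset.gene_ids], dtype=int)
    return FoldAssignment(k, gene_fold, record_fold)


def auroc(labels, scores) -> float:
    """Area under the ROC curve via mid-ranks (ties count one half).

    Equals the probability that a random positive outscores a random
    negative, with ties contributing 0.5.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
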