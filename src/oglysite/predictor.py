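"""RBF-kernel SVM prediction of glycosylation sites.

One classifier is trained per site type (clustered or isolated) on
balanced data: all positive sites of that type plus an equal number of
negatives sampled uniformly without replacement.  Evaluation is
protein-grouped 10-fold cross-validation — every site of a protein
stays in that protein's fold, so no sequence neighborhood leaks between
training and validation — with the kernel parameters chosen by grid
search over C and γ and performance reported as the fold-averaged
accuracy at the best grid point.  On a balanced set the chance level is
0.5 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .exceptions import ConfigError, ValidationError
from .features import ENCODINGS, build_design_matrix
from .io import GlycoProteinRecord
from .sites import SITE_TYPES, negative_sites, typed_positive_sites

# Logarithmic grids spanning the conventional C in [0.1, 100] and
# gamma in [1e-4, 1] search ranges.
DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class SvmConfig:
    c: float
    gamma: float
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ConfigError(f"C and gamma must be positive, got C={self.c}, gamma={self.gamma}")


@dataclass
class CvResult:
    ws: int
    encoding: str
    site_type: str
    fold_accuracies: list[float]
    mean_accuracy: float
    best_c: float
    best_gamma: float
    #: mean accuracy of every grid point, keyed by (C, gamma)
    grid_means: dict[tuple[float, float], float] = field(default_factory=dict)


@dataclass
class TrainedModel:
    """A fitted SVM together with everything needed to re-encode inputs."""

    svc: SVC
    site_type: str
    encoding: str
    ws: int
    config: SvmConfig

    def predict(self, labeled_sites, ignore_labels: bool = True) -> np.ndarray:
        X, _ = build_design_matrix(labeled_sites, self.ws, self.encoding)
        return self.svc.predict(X)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        return joblib.load(path)


def sample_balanced_negatives(
    positives: Sequence, negatives: Sequence, seed: int
) -> list:
    """Uniform sample of negatives, without replacement, matching the
    positive count; reproducible from ``seed``."""
    if len(negatives) < len(positives):
        raise ValidationError(
            f"cannot balance: {len(positives)} positives but only "
            f"{len(negatives)} negatives"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=len(positives), replace=False)
    return [negatives[i] for i in sorted(idx)]


def make_protein_folds(
    records: Sequence[GlycoProteinRecord], k: int = 10, seed: int = 0
) -> dict[str, int]:
    """Assign each protein to one of ``k`` folds, sizes differing by ≤ 1."""
    if len(records) < k:
        raise ValidationError(f"need at least {k} proteins for {k} folds, got {len(records)}")
    ids = [r.protein_id for r in records]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[j]: i % k for i, j in enumerate(order)}


def _balanced_fold_sets(
    records: Sequence[GlycoProteinRecord],
    site_type: str,
    folds: dict[str, int],
    k: int,
    seed: int,
    require_both_sides: bool = False,
) -> list[list[tuple[GlycoProteinRecord, int, int]]]:
    """Per fold: all typed positives of the fold's proteins plus an equal
    number of negatives sampled from the same proteins.  Negatives are
    drawn once per fold, so train and validation negatives always come
    from disjoint proteins."""
    positives = typed_positive_sites(records, site_type, require_both_sides)
    negatives = negative_sites(records)
    fold_sets: list[list[tuple[GlycoProteinRecord, int, int]]] = []
    for f in range(k):
        pos_f = [(r, p) for r, p in positives if folds[r.protein_id] == f]
        neg_pool = [(r, p) for r, p in negatives if folds[r.protein_id] == f]
        if not pos_f:
            warnings.warn(
                f"fold {f} has no {site_type} positives and is skipped", stacklevel=2
            )
            fold_sets.append([])
            continue
        fold_seed = np.random.SeedSequence([seed, f]).generate_state(1)[0] % (2**31)
        neg_f = sample_balanced_negatives(pos_f, neg_pool, int(fold_seed))
        fold_sets.append(
            [(r, p, 1) for r, p in pos_f] + [(r, p, -1) for r, p in neg_f]
        )
    if all(not fs for fs in fold_sets):
        raise ValidationError(f"no fold contains any {site_type} positive site")
    return fold_sets


def cross_validate(
    records: Sequence[GlycoProteinRecord],
    site_type: str,
    encoding: str,
    ws: int,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 10,
    seed: int = 0,
    require_both_sides: bool = False,
) -> CvResult:
    """Protein-grouped k-fold CV with (C, γ) grid search.

    For every grid point the SVM is trained on the union of nine folds'
    balanced sets and scored on the held-out fold's balanced set; the
    grid point with the best fold-averaged accuracy is reported.
    """
    if site_type not in SITE_TYPES:
        raise ValidationError(f"unknown site type {site_type!r}")
    if encoding not in ENCODINGS:
        raise ValidationError(f"unknown encoding {encoding!r}")
    folds = make_protein_folds(records, k=k, seed=seed)
    fold_sets = _balanced_fold_sets(records, site_type, folds, k, seed, require_both_sides)
    usable = [f for f in range(k) if fold_sets[f]]
    encoded = {
        f: build_design_matrix(fold_sets[f], ws, encoding) for f in usable
    }

    grid_means: dict[tuple[float, float], float] = {}
    grid_folds: dict[tuple[float, float], list[float]] = {}
    for c in c_grid:
        for gamma in gamma_grid:
            accs = []
            for f in usable:
                X_test, y_test = encoded[f]
                X_train = np.vstack([encoded[g][0] for g in usable if g != f])
                y_train = np.concatenate([encoded[g][1] for g in usable if g != f])
                clf = SVC(kernel="rbf", C=c, gamma=gamma)
                clf.fit(X_train, y_train)
                accs.append(float(np.mean(clf.predict(X_test) == y_test)))
            grid_folds[(c, gamma)] = accs
            grid_means[(c, gamma)] = float(np.mean(accs))

    best = max(grid_means, key=lambda key: grid_means[key])
    return CvResult(
        ws=ws,
        encoding=encoding,
        site_type=site_type,
        fold_accuracies=grid_folds[best],
        mean_accuracy=grid_means[best],
        best_c=best[0],
        best_gamma=best[1],
        grid_means=grid_means,
    )


def train_model(
    records: Sequence[GlycoProteinRecord],
    site_type: str,
    encoding: str,
    ws: int,
    c: float,
    gamma: float,
    seed: int = 0,
    require_both_sides: bool = False,
) -> TrainedModel:
    """Fit one SVM on the full balanced set of one site type."""
    positives = typed_positive_sites(records, site_type, require_both_sides)
    if not positives:
        raise ValidationError(f"no {site_type} positive sites to train on")
    negs = sample_balanced_negatives(positives, negative_sites(records), seed)
    labeled = [(r, p, 1) for r, p in positives] + [(r, p, -1) for r, p in negs]
    X, y = build_design_matrix(labeled, ws, encoding)
    cfg = SvmConfig(c, gamma)
    clf = SVC(kernel="rbf", C=c, gamma=gamma)
    clf.fit(X, y)
    return TrainedModel(clf, site_type, encoding, ws, cfg)


def cross_type_evaluate(
    model: TrainedModel,
    records: Sequence[GlycoProteinRecord],
    site_type: str,
    seed: int = 0,
    require_both_sides: bool = False,
) -> float:
    """Accuracy of a trained model on a balanced set of another site type."""
    positives = typed_positive_sites(records, site_type, require_both_sides)
    if not positives:
        raise ValidationError(f"no {site_type} positive sites to evaluate on")
    negs = sample_balanced_negatives(positives, negative_sites(records), seed)
    labeled = [(r, p, 1) for r, p in positives] + [(r, p, -1) for r, p in negs]
    X, y = build_design_matrix(labeled, model.ws, model.encoding)
    return float(np.mean(model.svc.predict(X) == y))


def ws_sweep(
    records: Sequence[GlycoProteinRecord],
    site_type: str,
    encoding: str,
    ws_list: Sequence[int],
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 10,
    seed: int = 0,
) -> "pd.DataFrame":
    """Mean CV accuracy as a function of window size (odd Ws in [3, 55])."""
    import pandas as pd

    for ws in ws_list:
        if ws % 2 == 0 or not 3 <= ws <= 55:
            raise ValidationError(f"window sizes must be odd and in [3, 55], got {ws}")
    rows = []
    for ws in ws_list:
        res = cross_validate(
            records, site_type, encoding, ws,
            c_grid=c_grid, gamma_grid=gamma_grid, k=k, seed=seed,
        )
        rows.append(
            {
                "ws": ws,
                "site_type": site_type,
                "encoding": encoding,
                "mean_accuracy": res.mean_accuracy,
                "best_C": res.best_c,
                "best_gamma": res.best_gamma,
            }
        )
    return pd.DataFrame(rows)
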