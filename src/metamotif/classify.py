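"""Motif-family classification from metamotif density features.

A dictionary of family-tagged metamotifs is learned from labelled motif
sets (clustering each family, then nested-sampling metamotifs per cluster).
Each motif is then summarised by scanning it with every dictionary
metamotif -- the maximum and average window log densities -- plus a handful
of column-statistics features, and a random-forest learner maps the feature
vectors to family labels.  Out-of-bag (OOB) accuracy provides an unbiased
error estimate as part of training, and the number of candidate features
per split is tuned on a multiplier grid around sqrt(p).

The learner sits behind a minimal train/predict/out-of-bag contract so a
different backend can be substituted; the default wraps
scikit-learn's RandomForestClassifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PWM, Metamotif, from_mean_precision, floor_weights
from .estimate import fit_mle_dirichlet, fit_symmetric_dirichlet
from .infer import InferenceConfig, nested_sample
from .prior import FLOOR_LOG_DENSITY, pwm_to_metamotif, window_log_densities
from .similarity import cluster_motifs

#: Names of the fixed (non-dictionary) features, in order.
FEATURE_NAMES_FIXED = (
    "mean_column_entropy",
    "mle_alpha_A",
    "mle_alpha_C",
    "mle_alpha_G",
    "mle_alpha_T",
    "symmetric_alpha",
)

#: Protocol defaults for dictionary construction.
DEFAULT_CLUSTER_CUTOFF = 6.0
DEFAULT_METAMOTIFS_PER_CLUSTER = 3
DEFAULT_DICT_MIN_LENGTH = 6
DEFAULT_DICT_MAX_LENGTH = 15
DEFAULT_DICT_FRACTION = 0.5
DEFAULT_MEAN_PSEUDOCOUNT = 0.01

#: Classifier training defaults.
DEFAULT_TREES = 5000
DEFAULT_MTRY_GRID = tuple(round(0.1 * i, 1) for i in range(1, 21))


def _regularise_mean(mm: Metamotif, pseudocount: float) -> Metamotif:
    """Add a pseudocount to the mean weights, keeping precisions."""
    means = (mm.means + pseudocount) / (1.0 + 4 * pseudocount)
    return Metamotif(
        mm.name, from_mean_precision(means, mm.precisions).alpha, family=mm.family
    )


def build_dictionary(
    labelled_motifs: dict[str, list[PWM]],
    per_family_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    metamotifs_per_cluster: int = DEFAULT_METAMOTIFS_PER_CLUSTER,
    l_min: int = DEFAULT_DICT_MIN_LENGTH,
    l_max: int = DEFAULT_DICT_MAX_LENGTH,
    expected_fraction: float = DEFAULT_DICT_FRACTION,
    mean_pseudocount: float = DEFAULT_MEAN_PSEUDOCOUNT,
    sampler: InferenceConfig | None = None,
    seed: int = 0,
) -> list[Metamotif]:
    """Build a family-tagged metamotif dictionary from labelled motifs.

    Per family: motifs are clustered by SSD distance at
    ``per_family_cutoff``; ``metamotifs_per_cluster`` metamotifs are then
    nested-sampled from each cluster with lengths in [l_min, l_max] and
    expected usage fraction ``expected_fraction``.  A cluster of size one
    falls back to a direct PWM-to-metamotif conversion.  All dictionary
    metamotifs receive a small pseudocount on their mean weights.

    ``sampler`` overrides the nested-sampling budget (ensemble size,
    iterations, ...); length/count/fraction settings always follow the
    protocol arguments above.
    """
    if not labelled_motifs:
        raise ValueError("no families given")
    base = sampler or InferenceConfig()
    dictionary: list[Metamotif] = []
    for fam_i, (family, motifs) in enumerate(sorted(labelled_motifs.items())):
        motifs = list(motifs)
        if len(motifs) < 2:
            raise ValueError(f"family {family!r} needs at least 2 motifs")
        labels = cluster_motifs(motifs, cutoff=per_family_cutoff)
        for cl in range(labels.max() + 1):
            members = [m for m, lab in zip(motifs, labels) if lab == cl]
            if len(members) == 1:
                mm = pwm_to_metamotif(members[0], name=f"{family}_c{cl}_m0")
                dictionary.append(
                    _regularise_mean(
                        Metamotif(mm.name, mm.alpha, family=family), mean_pseudocount
                    )
                )
                continue
            cfg = InferenceConfig(
                num_metamotifs=metamotifs_per_cluster,
                min_length=min(l_min, min(len(m) for m in members)),
                max_length=min(l_max, min(len(m) for m in members)),
                expected_fraction=expected_fraction,
                revcomp=base.revcomp,
                ensemble_size=base.ensemble_size,
                iterations=base.iterations,
                moves_per_decorrelation=base.moves_per_decorrelation,
                mixing_flip_prob=base.mixing_flip_prob,
                step_sigma=base.step_sigma,
                prior_draw_prob=base.prior_draw_prob,
                seed=seed + 1000 * fam_i + cl,
            )
            result = nested_sample(members, cfg)
            for k, mm in enumerate(result.metamotifs):
                tagged = Metamotif(
                    f"{family}_c{cl}_m{k}", mm.alpha, family=family
                )
                dictionary.append(_regularise_mean(tagged, mean_pseudocount))
    return dictionary


def extract_features(
    pwm: PWM, dictionary: list[Metamotif], two_stranded: bool = True
) -> np.ndarray:
    """Feature vector of a motif against a metamotif dictionary.

    Per dictionary metamotif: the maximum and the average window log
    density when scanning the motif (both strands when ``two_stranded``).
    Fixed features: mean column Shannon entropy (bits), the four MLE
    Dirichlet parameters of the motif's columns, and the symmetric
    Dirichlet MLE parameter.  Length is ``2 * len(dictionary) + 6``.
    """
    feats = []
    for mm in dictionary:
        vals = window_log_densities(pwm, mm)
        if two_stranded:
            vals_rc = window_log_densities(pwm, mm.reverse_complement())
            vals = np.concatenate([vals, vals_rc])
        if vals.size == 0:
            feats.extend([FLOOR_LOG_DENSITY, FLOOR_LOG_DENSITY])
        else:
            feats.extend([float(vals.max()), float(vals.mean())])
    w = floor_weights(pwm.weights)
    entropy = float(-(w * np.log2(w)).sum(axis=1).mean())
    if len(pwm) >= 2:
        mle = fit_mle_dirichlet(pwm.weights).alpha
    else:
        mle = fit_mle_dirichlet(np.vstack([pwm.weights, pwm.weights])).alpha
    sym = fit_symmetric_dirichlet(pwm.weights)
    feats.append(entropy)
    feats.extend(mle.tolist())
    feats.append(sym)
    return np.asarray(feats)


def feature_names(dictionary: list[Metamotif]) -> list[str]:
    names = []
    for mm in dictionary:
        names += [f"max_density_{mm.name}", f"avg_density_{mm.name}"]
    return names + list(FEATURE_NAMES_FIXED)


def feature_table(
    motifs, dictionary: list[Metamotif], two_stranded: bool = True
) -> pd.DataFrame:
    """Feature matrix for a motif list, one row per motif."""
    motifs = list(motifs)
    rows = [extract_features(m, dictionary, two_stranded) for m in motifs]
    return pd.DataFrame(
        rows, index=[m.name for m in motifs], columns=feature_names(dictionary)
    )


class RandomForestBackend:
    """Default learner backend: scikit-learn random forest with OOB scoring."""

    def __init__(self, trees: int, max_features, seed: int):
        from sklearn.ensemble import RandomForestClassifier

        self._rf = RandomForestClassifier(
            n_estimators=trees,
            max_features=max_features,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )

    def fit(self, X, y):
        with warnings.catch_warnings():
            # small classes can leave some points out of every bag
            warnings.simplefilter("ignore")
            self._rf.fit(X, y)
        return self

    @property
    def oob_accuracy(self) -> float:
        return float(self._rf.oob_score_)

    @property
    def oob_votes(self) -> np.ndarray:
        return self._rf.oob_decision_function_

    @property
    def classes(self) -> np.ndarray:
        return self._rf.classes_

    def predict_votes(self, X) -> np.ndarray:
        return self._rf.predict_proba(X)


@dataclass
class MotifFamilyClassifier:
    """A trained family classifier bound to its metamotif dictionary."""

    dictionary: list[Metamotif]
    backend: RandomForestBackend
    classes: np.ndarray
    oob_accuracy: float
    per_class_error: pd.Series
    confusion: pd.DataFrame
    mtry: int
    two_stranded: bool = True

    def predict(self, pwm: PWM) -> tuple[str, pd.Series]:
        """Predict the family of a motif; returns (label, vote fractions)."""
        x = extract_features(pwm, self.dictionary, self.two_stranded)
        if x.shape[0] != 2 * len(self.dictionary) + len(FEATURE_NAMES_FIXED):
            raise ValueError("feature vector does not match the dictionary")
        votes = self.backend.predict_votes(x[None])[0]
        series = pd.Series(votes, index=self.classes)
        return str(series.idxmax()), series


def _confusion_from_votes(y, votes, classes) -> tuple[pd.DataFrame, pd.Series]:
    pred = classes[np.argmax(votes, axis=1)]
    classes = list(classes)
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, pred):
        cm.loc[t, p] += 1
    err = 1.0 - pd.Series(np.diag(cm), index=classes) / cm.sum(axis=1).replace(0, 1)
    return cm, err


def train_classifier(
    features,
    labels,
    trees: int = DEFAULT_TREES,
    mtry_grid=DEFAULT_MTRY_GRID,
    seed: int = 0,
    dictionary: list[Metamotif] | None = None,
    two_stranded: bool = True,
) -> MotifFamilyClassifier:
    """Train the family classifier on a feature matrix.

    Sweeps the candidate-feature-count (mtry) over multiples
    ``mtry_grid`` of sqrt(p), selecting the value with the best out-of-bag
    accuracy, then reports OOB per-class errors and the OOB confusion
    matrix (rows = truth, columns = predicted).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")

    base = np.sqrt(X.shape[1])
    tried: dict[int, RandomForestBackend] = {}
    best_m, best_backend = None, None
    for mult in mtry_grid:
        m = int(np.clip(round(mult * base), 1, X.shape[1]))
        if m in tried:
            continue
        backend = RandomForestBackend(trees, m, seed).fit(X, y)
        tried[m] = backend
        if best_backend is None or backend.oob_accuracy > best_backend.oob_accuracy:
            best_m, best_backend = m, backend

    cm, err = _confusion_from_votes(y, best_backend.oob_votes, best_backend.classes)
    return MotifFamilyClassifier(
        dictionary=dictionary or [],
        backend=best_backend,
        classes=best_backend.classes,
        oob_accuracy=best_backend.oob_accuracy,
        per_class_error=err,
        confusion=cm,
        mtry=best_m,
        two_stranded=two_stranded,
    )
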