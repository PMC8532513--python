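"""Sequence and evolution features for essential-gene prediction.

Sequence features are overlapping dinucleotide composition (DNC; counts over
N-1) and trinucleotide frequencies (Kmer with k=3; counts over the sequence
length N, so the 64 entries sum to (N-2)/N).  Evolution-based features are
the ortholog-group mean conservation score, gene-level dN/dS, occurrence
count across species, and average paralog number (sequences per unique
species in the group).  Class imbalance is handled by oversampling the
minority class; performance is reported as ROC/AUC plus the standard
confusion-derived metrics; feature contributions are ranked by chi-square.

Classifier backends (SVM, random forest) are consumed through their
scikit-learn interface; the bespoke content here is the features and the
evaluation, not the learners.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

NUCLEOTIDES = "ACGT"
DINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)]
TRINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]

__all__ = [
    "dnc",
    "kmer3",
    "evolution_features",
    "oversample_minority",
    "roc_auc",
    "feature_importance_chi2",
    "find_ambiguous",
    "feature_table",
    "DINUCLEOTIDES",
    "TRINUCLEOTIDES",
]


def find_ambiguous(sequence: str) -> List[int]:
    """0-based positions of characters outside {A, C, G, T}."""
    return [i for i, c in enumerate(sequence) if c not in NUCLEOTIDES]


def _check_sequence(sequence: str, min_length: int) -> None:
    if len(sequence) < min_length:
        raise ValueError(f"sequence shorter than {min_length}")
    bad = find_ambiguous(sequence)
    if bad:
        raise ValueError(f"ambiguous bases at positions {bad[:10]}")


def dnc(sequence: str) -> np.ndarray:
    """Overlapping dinucleotide composition: counts over N-1, in fixed
    order AA, AC, ..., TT.  Sums to 1."""
    _check_sequence(sequence, 2)
    n = len(sequence)
    counts = {d: 0 for d in DINUCLEOTIDES}
    for i in range(n - 1):
        counts[sequence[i : i + 2]] += 1
    return np.array([counts[d] / (n - 1) for d in DINUCLEOTIDES])


def kmer3(sequence: str, frame: bool = False) -> np.ndarray:
    """Trinucleotide frequencies in fixed lexicographic order.

    Overlapping counts are divided by the sequence length N, so the vector
    sums to (N-2)/N.  ``frame=True`` switches to non-overlapping codon-frame
    counting (counts over N//3).
    """
    _check_sequence(sequence, 3)
    n = len(sequence)
    counts = {t: 0 for t in TRINUCLEOTIDES}
    if frame:
        for i in range(0, n - n % 3, 3):
            counts[sequence[i : i + 3]] += 1
        denom = n // 3
    else:
        for i in range(n - 2):
            counts[sequence[i : i + 3]] += 1
        denom = n
    return np.array([counts[t] / denom for t in TRINUCLEOTIDES])


@dataclass(frozen=True)
class EvolutionFeatures:
    conservation_score: float  # mean residue conservation, in [0, 1]
    dn_ds: float  # gene-level dN/dS, >= 0
    occurrence_count: int  # species carrying the gene
    avg_paralog_number: float  # sequences per unique species, >= 1


def evolution_features(
    mean_conservation: float,
    dn_ds: float,
    n_species_with_gene: int,
    n_sequences: int,
    n_unique_species: int,
) -> EvolutionFeatures:
    """Assemble the evolution-based feature tuple for one ortholog group."""
    if n_unique_species < 1:
        raise ValueError("need at least one unique species")
    if n_sequences < n_unique_species:
        raise ValueError("n_sequences must be >= n_unique_species")
    if not 0.0 <= mean_conservation <= 1.0:
        raise ValueError("conservation score must lie in [0, 1]")
    if dn_ds < 0:
        raise ValueError("dN/dS must be non-negative")
    if n_species_with_gene < 0:
        raise ValueError("occurrence count must be non-negative")
    return EvolutionFeatures(
        conservation_score=float(mean_conservation),
        dn_ds=float(dn_ds),
        occurrence_count=int(n_species_with_gene),
        avg_paralog_number=n_sequences / n_unique_species,
    )


def feature_table(
    sequences: Dict[str, str],
    evo: Optional[Dict[str, EvolutionFeatures]] = None,
) -> pd.DataFrame:
    """Gene x feature frame: 16 DNC + 64 Kmer columns, plus the 4 evolution
    features when provided."""
    rows = {}
    for gene, seq in sequences.items():
        values = np.concatenate([dnc(seq), kmer3(seq)])
        rows[gene] = values
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=[f"dnc_{d}" for d in DINUCLEOTIDES]
        + [f"kmer_{t}" for t in TRINUCLEOTIDES],
    )
    if evo is not None:
        evo_df = pd.DataFrame.from_dict(
            {
                gene: {
                    "conservation_score": e.conservation_score,
                    "dn_ds": e.dn_ds,
                    "occurrence_count": e.occurrence_count,
                    "avg_paralog_number": e.avg_paralog_number,
                }
                for gene, e in evo.items()
            },
            orient="index",
        )
        df = df.join(evo_df)
    return df.sort_index()


# ---------------------------------------------------------------------------
# class balancing and evaluation
# ---------------------------------------------------------------------------

def oversample_minority(labels: Sequence[int], seed: int = 0) -> np.ndarray:
    """Index multiset balancing the classes by resampling the minority with
    replacement; majority indices untouched; deterministic under seed."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    idx_all = np.arange(len(labels))
    if n_needed == 0:
        return idx_all
    rng = np.random.default_rng(seed)
    minority_idx = idx_all[labels == minority]
    extra = rng.choice(minority_idx, size=n_needed, replace=True)
    return np.concatenate([idx_all, extra])


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[pd.DataFrame, float]:
    """ROC curve by threshold sweep and AUC via the rank (Mann-Whitney)
    formulation; tied scores contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # threshold sweep over unique scores, descending
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep the last index of each tied block
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    points = pd.DataFrame(
        {
            "threshold": np.r_[np.inf, sorted_scores[distinct]],
            "fpr": np.r_[0.0, fps[distinct] / n_neg],
            "tpr": np.r_[0.0, tps[distinct] / n_pos],
        }
    )
    # Mann-Whitney with midranks
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return points, float(auc)


def make_classifier(kind: str = "rf", seed: int = 0):
    """A scikit-learn classifier behind a two-method (fit/score) surface.

    ``rf`` = random forest, ``svm`` = RBF support-vector machine with
    feature standardization.  The learners themselves are stock
    scikit-learn; only the features and evaluation are bespoke.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if kind == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if kind == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    raise ValueError(f"unknown classifier kind {kind!r}")


def _scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def train_and_evaluate(
    features: pd.DataFrame,
    labels: Sequence[int],
    kind: str = "rf",
    test_fraction: float = 0.2,
    seed: int = 0,
    oversample: bool = True,
) -> Dict[str, float]:
    """Random train/test split, minority oversampling on the training set,
    fit, and held-out evaluation (confusion metrics + AUC)."""
    from sklearn.model_selection import train_test_split

    y = np.asarray(labels, dtype=int)
    x = features.to_numpy(dtype=float)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    if oversample:
        idx = oversample_minority(y_tr, seed=seed)
        x_tr, y_tr = x_tr[idx], y_tr[idx]
    model = make_classifier(kind, seed)
    model.fit(x_tr, y_tr)
    scores = _scores(model, x_te)
    pred = model.predict(x_te)
    from .fba import ConfusionCounts, confusion_metrics

    counts = ConfusionCounts(
        TP=int(((pred == 1) & (y_te == 1)).sum()),
        TN=int(((pred == 0) & (y_te == 0)).sum()),
        FP=int(((pred == 1) & (y_te == 0)).sum()),
        FN=int(((pred == 0) & (y_te == 1)).sum()),
    )
    m = confusion_metrics(counts)
    _, auc = roc_auc(scores, y_te)
    return {
        "accuracy": m.accuracy,
        "recall": m.sensitivity,
        "specificity": m.specificity,
        "precision": m.precision,
        "f1": m.f1,
        "fpr": m.fpr,
        "auc": auc,
    }


def cross_validated_auc(
    features: pd.DataFrame,
    labels: Sequence[int],
    kind: str = "rf",
    n_splits: int = 5,
    seed: int = 0,
) -> float:
    """Mean held-out AUC over stratified folds (the ROC evaluation
    protocol)."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    x = features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(x, y):
        idx = oversample_minority(y[tr], seed=seed)
        model = make_classifier(kind, seed)
        model.fit(x[tr][idx], y[tr][idx])
        _, auc = roc_auc(_scores(model, x[te]), y[te])
        aucs.append(auc)
    return float(np.mean(aucs))


def feature_importance_chi2(
    features: pd.DataFrame, labels: Sequence[int], dn_ds_max: float = 10.0
) -> pd.DataFrame:
    """Rank features by the chi-square statistic between class-aggregated
    feature mass and labels (descending).  Features must be non-negative;
    dN/dS is clipped at ``dn_ds_max`` before testing."""
    from sklearn.feature_selection import chi2

    x = features.copy()
    if "dn_ds" in x.columns:
        x["dn_ds"] = x["dn_ds"].clip(upper=dn_ds_max)
    if (x.to_numpy() < 0).any():
        raise ValueError("features must be non-negative for the chi-square test")
    stats, pvalues = chi2(x.to_numpy(), np.asarray(labels, dtype=int))
    out = pd.DataFrame(
        {"feature": x.columns, "chi2": stats, "p_value": pvalues}
    ).sort_values(["chi2", "feature"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)
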