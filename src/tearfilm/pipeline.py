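"""End-to-end orchestration: images → descriptors → CV accuracies → stats.

For the histogram-based methods (Butterworth, Gabor) the nonequidistant
binnings are calibration state: inside cross-validation they are fitted
on the training fold's filter responses only and then applied to the test
fold, so no information leaks across folds.  Filter responses themselves
are image-local and are computed once per image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .classify import CLASSIFIER_IDS, CVResult, LabelledDataset, crossval_accuracy, make_classifier
from .colour import SPACES, channels_in_space, descriptor_in_space
from .image import ChannelImage, RGBImage
from .stats import compare_classifiers
from .synth import SyntheticDataset
from .tables import accuracy_table_from_results
from .texture import fit_nonequidistant_bins, histogram_descriptor
from .texture.butterworth import butterworth_band_image
from .texture.gabor import gabor_magnitude_responses

log = logging.getLogger(__name__)

#: Experimental conditions evaluated per method, mirroring the reference design.
METHOD_CONDITIONS = {
    "butterworth": [("band", b) for b in range(1, 10)],
    "wavelet": [("", None)],
    "cooccurrence": [("d", d) for d in range(1, 8)],
    "gmrf": [("d", d) for d in range(1, 11)],
    "gabor": [("n_bins", nb) for nb in (3, 5, 7, 9)],
}

CALIBRATED_METHODS = ("butterworth", "gabor")


def featurize(
    images, method: str, space: str, **params
) -> np.ndarray:
    """Stack per-image descriptors into an n×p matrix (uncalibrated path)."""
    return np.stack([descriptor_in_space(img, method, space, **params) for img in images])


def _responses(img: RGBImage, method: str, space: str, **params) -> list[np.ndarray]:
    """Flat list of filter-response images across the space's channels."""
    out: list[np.ndarray] = []
    for ch in channels_in_space(img, space):
        if method == "butterworth":
            out.append(butterworth_band_image(ch, params["band"]).pixels)
        elif method == "gabor":
            out.extend(gabor_magnitude_responses(ch))
        else:
            raise ValueError(f"{method!r} needs no response calibration")
    return out


def crossval_accuracy_calibrated(
    images,
    labels,
    method: str,
    space: str,
    classifier_id: str,
    n_bins: int,
    k: int = 10,
    seed: int = 0,
    **params,
) -> CVResult:
    """CV for histogram methods with per-fold binning calibration.

    Responses are computed once per image; inside each fold, one binning
    per filter is fitted on the pooled training responses and applied to
    both partitions before training/evaluating the classifier.
    """
    y = np.asarray(labels)
    resp = [_responses(img, method, space, **params) for img in images]
    n_filters = len(resp[0])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    model = make_classifier(classifier_id, seed=seed)
    fold_acc: list[float] = []
    fold_sizes: list[int] = []
    for train, test in skf.split(np.zeros((y.size, 1)), y):
        binnings = [
            fit_nonequidistant_bins(
                np.concatenate([resp[i][f].ravel() for i in train]), n_bins
            )
            for f in range(n_filters)
        ]
        def desc(i: int) -> np.ndarray:
            return np.concatenate(
                [histogram_descriptor(resp[i][f], binnings[f]) for f in range(n_filters)]
            )
        Xtr = np.stack([desc(i) for i in train])
        Xte = np.stack([desc(i) for i in test])
        m = clone(model)
        m.fit(Xtr, y[train])
        fold_acc.append(float(np.mean(m.predict(Xte) == y[test]) * 100.0))
        fold_sizes.append(test.size)
    total = sum(fold_sizes)
    overall = float(sum(a * s for a, s in zip(fold_acc, fold_sizes)) / total)
    return CVResult(classifier_id.upper(), overall, tuple(fold_acc), tuple(fold_sizes), seed)


@dataclass(frozen=True)
class ExperimentResult:
    tables: dict            # space → AccuracyTable
    comparisons: dict       # space → ComparisonReport


def run_experiment(
    dataset: SyntheticDataset,
    method: str,
    spaces=SPACES,
    classifiers=CLASSIFIER_IDS,
    conditions=None,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> ExperimentResult:
    """Evaluate every condition × classifier × colour space, then compare.

    ``conditions`` defaults to the method's reference design (bands 1-9,
    distances 1-7, neighbourhoods 1-10 or bin counts {3,5,7,9}).
    """
    if method not in METHOD_CONDITIONS:
        raise ValueError(f"unknown method {method!r}")
    conditions = conditions if conditions is not None else METHOD_CONDITIONS[method]
    y = np.asarray(dataset.labels)
    tables: dict = {}
    comparisons: dict = {}
    for space in spaces:
        log.info("experiment: method=%s space=%s (%d conditions)", method, space, len(conditions))
        results: dict[str, dict[str, float]] = {cid: {} for cid in classifiers}
        for pname, pval in conditions:
            cond_label = f"{pname}={pval}" if pname else method
            params = {pname: pval} if pname else {}
            if method in CALIBRATED_METHODS:
                n_bins = params.pop("n_bins", 16 if method == "butterworth" else None)
                for cid in classifiers:
                    cv = crossval_accuracy_calibrated(
                        dataset.images, y, method, space, cid,
                        n_bins=n_bins, k=k, seed=seed, **params,
                    )
                    results[cid][cond_label] = cv.accuracy
            else:
                X = featurize(dataset.images, method, space, **params)
                data = LabelledDataset(X, y)
                for cid in classifiers:
                    cv = crossval_accuracy(data, cid, k=k, seed=seed)
                    results[cid][cond_label] = cv.accuracy
        table = accuracy_table_from_results(results, space, method)
        tables[space] = table
        if len(conditions) >= 4 and len(classifiers) >= 2:
            comparisons[space] = compare_classifiers(table.rows(), alpha=alpha, seed=seed)
        else:
            comparisons[space] = None  # too few conditions for the normality gate
    return ExperimentResult(tables, comparisons)
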