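"""Chemometric baselines on a single optimal-offset spectrum.

The conventional SORS workflow first chooses one offset distance whose
spectrum best reflects the subsurface layer, then regresses the storage day
on that single 200-band spectrum with PLSR, SVR (RBF kernel) or extremely
randomized trees.  Two selection criteria are provided:

``cv_r2``
    For each offset column, cross-validate a PLSR fit on that column's
    spectra and pick the offset with the highest mean CV R-squared.
``contrast_ratio``
    Pick the offset maximizing the mean ratio of the 1269 cm-1 protein-peak
    amplitude (above its local background) to the fluorescence background —
    a model-free subsurface-contrast heuristic.

Ties break toward the smaller offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.model_selection import GridSearchCV, KFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import InputError

BASELINE_KINDS = ("plsr", "svr", "et")

# documented, fixed SVR search grid (the RBF kernel width and penalty are
# not dictated by the protocol; the grid is deliberately small and seeded)
SVR_GRID = {"svr__C": [1.0, 10.0, 100.0, 1000.0],
            "svr__gamma": ["scale", 1e-3, 1e-2, 1e-1]}
ET_N_ESTIMATORS = 200
PLS_MAX_COMPONENTS = 20


@dataclass(frozen=True)
class OffsetSelection:
    offset_index: int
    criterion_values: tuple[float, ...]
    method: str


def _pls_cv_r2(spectra: np.ndarray, labels: np.ndarray, k_folds: int,
               seed: int) -> float:
    n_comp = _pick_pls_components(spectra, labels, k_folds, seed)
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(PLSRegression(n_components=n_comp), spectra,
                             labels, cv=cv, scoring="r2")
    return float(scores.mean())


def _pick_pls_components(spectra: np.ndarray, labels: np.ndarray,
                         k_folds: int, seed: int) -> int:
    max_comp = min(PLS_MAX_COMPONENTS, spectra.shape[1],
                   len(labels) - len(labels) // k_folds - 1)
    max_comp = max(1, max_comp)
    cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    best, best_score = 1, -np.inf
    for n in range(1, max_comp + 1):
        score = cross_val_score(PLSRegression(n_components=n), spectra,
                                labels, cv=cv, scoring="r2").mean()
        if score > best_score:
            best, best_score = n, float(score)
    return best


def peak_contrast(spectrum: np.ndarray, band_centers: np.ndarray,
                  peak_cm1: float = 1269.0, shoulder_cm1: float = 40.0
                  ) -> float:
    """Amplitude of the peak above its shoulder baseline, over background."""
    at = np.argmin(np.abs(band_centers - peak_cm1))
    sh_lo = np.argmin(np.abs(band_centers - (peak_cm1 - shoulder_cm1)))
    sh_hi = np.argmin(np.abs(band_centers - (peak_cm1 + shoulder_cm1)))
    background = 0.5 * (spectrum[sh_lo] + spectrum[sh_hi])
    if background <= 0:
        return 0.0
    return float((spectrum[at] - background) / background)


def select_optimal_offset(samples: np.ndarray, labels: np.ndarray,
                          method: str = "cv_r2",
                          band_centers: np.ndarray | None = None,
                          k_folds: int = 5, seed: int = 0) -> OffsetSelection:
    """Choose the offset column whose spectrum best predicts the label.

    ``samples`` is (n, bands, offsets).
    """
    samples = np.asarray(samples, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    if samples.ndim != 3 or samples.shape[2] < 1:
        raise InputError("samples must be (n, bands, offsets)")
    if np.unique(labels).size < 2:
        raise InputError("offset selection needs at least two label values")
    n_offsets = samples.shape[2]
    if n_offsets == 1:
        return OffsetSelection(0, (np.nan,), method)

    values = []
    for j in range(n_offsets):
        spectra = samples[:, :, j]
        if method == "cv_r2":
            values.append(_pls_cv_r2(spectra, labels, k_folds, seed))
        elif method == "contrast_ratio":
            if band_centers is None:
                raise InputError("contrast_ratio needs band_centers")
            values.append(float(np.mean(
                [peak_contrast(s, band_centers) for s in spectra])))
        else:
            raise InputError(f"unknown selection method {method!r}")
    values = np.asarray(values)
    # argmax with ties broken toward the smaller offset
    best = int(np.flatnonzero(values == values.max())[0])
    return OffsetSelection(best, tuple(float(v) for v in values), method)


def fit_baseline(kind: str, spectra: np.ndarray, labels: np.ndarray,
                 k_folds: int = 5, seed: int = 0):
    """Fit one baseline on (n, bands) single-offset spectra.

    Returns a fitted estimator with scikit-learn's predict contract.
    PLSR components are chosen by k-fold CV; SVR hyperparameters by a
    seeded grid search; ET is a seeded 200-tree ensemble.
    """
    spectra = np.asarray(spectra, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    if len(spectra) < 10:
        raise InputError("baselines need at least 10 training samples")
    if kind == "plsr":
        n_comp = _pick_pls_components(spectra, labels, k_folds, seed)
        return PLSRegression(n_components=n_comp).fit(spectra, labels)
    if kind == "svr":
        pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
        cv = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(pipe, SVR_GRID, cv=cv, scoring="r2")
        return search.fit(spectra, labels).best_estimator_
    if kind == "et":
        est = ExtraTreesRegressor(n_estimators=ET_N_ESTIMATORS,
                                  random_state=seed)
        return est.fit(spectra, labels)
    raise InputError(f"unknown baseline kind {kind!r}; expected one of "
                     f"{BASELINE_KINDS}")


def predict_baseline(estimator, spectra: np.ndarray) -> np.ndarray:
    return np.asarray(estimator.predict(spectra)).ravel()
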