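"""Whole-slide aggregation of patch-level class probabilities.

Patch predictions are assembled into three aligned probability maps (ND,
LUAD, LUSC) over the slide's patch grid.  Two slide-level classifiers are
provided: **max voting** (the class with more argmax-positive patches wins)
and a **random-forest regression** over 50 statistical and morphological
features of the LUAD and LUSC maps, of which the top 25 by Fisher-score
class separability are used.  The forest is an ensemble of 10 bagged
regression trees with one third of the variables considered per split and a
minimum leaf size of 5; its [0, 1] output is binarized at a threshold
(default 0.5, LUSC inclusive).

Feature manifest (names are stable so the selection step is auditable): per
map m in {LUAD, LUSC}: mean, median, variance; positive-cell count and
fraction at tau = 0.5; top-5 8-connected component sizes (cells, descending,
zero-padded) at tau in {0.5, 0.7, 0.9}.  Plus LUAD:LUSC ratio features
(epsilon-guarded, eps = 1e-6): mean, median, variance and total-mass ratios;
positive-count ratios and largest-component ratios at the three thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestRegressor

from .fixtures import CLASS_NAMES

__all__ = [
    "FEATURE_NAMES",
    "THRESHOLDS",
    "assemble_probability_maps",
    "extract_features",
    "select_features",
    "max_vote",
    "SlideForest",
    "train_rf",
    "rf_classify",
]

THRESHOLDS = (0.5, 0.7, 0.9)
_EPS = 1e-6
_EIGHT = np.ones((3, 3), dtype=bool)


def _build_feature_names():
    names = []
    for m in ("LUAD", "LUSC"):
        names += [f"{m}_mean", f"{m}_median", f"{m}_variance"]
        names += [f"{m}_positive_count_t50", f"{m}_positive_fraction_t50"]
        for tau in THRESHOLDS:
            tag = f"t{int(tau * 100)}"
            names += [f"{m}_component{i}_{tag}" for i in range(1, 6)]
    names += ["ratio_mean", "ratio_median", "ratio_variance",
              "ratio_total_mass"]
    for tau in THRESHOLDS:
        names.append(f"ratio_positive_count_t{int(tau * 100)}")
    for tau in THRESHOLDS:
        names.append(f"ratio_largest_component_t{int(tau * 100)}")
    return tuple(names)


FEATURE_NAMES = _build_feature_names()
assert len(FEATURE_NAMES) == 50


def assemble_probability_maps(predictions) -> dict[str, np.ndarray]:
    """Lay per-patch class probabilities onto the slide's patch grid.

    ``predictions`` is an iterable of ``(row, col, probs)`` with ``probs``
    ordered (ND, LUAD, LUSC).  Grid extents come from the maximum indices;
    cells without a prediction are filled as pure ND (1, 0, 0).  Duplicate
    coordinates raise.
    """
    entries = [(int(r), int(c), np.asarray(p, dtype=np.float64))
               for r, c, p in predictions]
    if not entries:
        raise ValueError("no predictions to assemble")
    seen = set()
    for r, c, _ in entries:
        if (r, c) in seen:
            raise ValueError(f"duplicate patch coordinate ({r}, {c})")
        seen.add((r, c))
    h = max(r for r, _, _ in entries) + 1
    w = max(c for _, c, _ in entries) + 1
    grid = np.zeros((h, w, 3))
    grid[:, :, 0] = 1.0  # missing cells are non-diagnostic
    for r, c, p in entries:
        grid[r, c] = p
    return {name: grid[:, :, k].copy() for k, name in enumerate(CLASS_NAMES)}


def _top5_components(mask: np.ndarray) -> list[float]:
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return [0.0] * 5
    sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1]
    out = sizes[:5].astype(float).tolist()
    return out + [0.0] * (5 - len(out))


def _ratio(a: float, b: float) -> float:
    return (a + _EPS) / (b + _EPS)


def extract_features(maps: dict[str, np.ndarray]) -> dict[str, float]:
    """The 50-feature summary of a slide's LUAD and LUSC probability maps."""
    luad, lusc = np.asarray(maps["LUAD"]), np.asarray(maps["LUSC"])
    if luad.size == 0 or luad.shape != lusc.shape:
        raise ValueError("maps must be nonempty and congruent")
    feats: dict[str, float] = {}
    tops: dict[tuple[str, float], list[float]] = {}
    for name, m in (("LUAD", luad), ("LUSC", lusc)):
        feats[f"{name}_mean"] = float(m.mean())
        feats[f"{name}_median"] = float(np.median(m))
        feats[f"{name}_variance"] = float(m.var())
        pos = m >= 0.5
        feats[f"{name}_positive_count_t50"] = float(pos.sum())
        feats[f"{name}_positive_fraction_t50"] = float(pos.mean())
        for tau in THRESHOLDS:
            top = _top5_components(m >= tau)
            tops[(name, tau)] = top
            tag = f"t{int(tau * 100)}"
            for i, size in enumerate(top, start=1):
                feats[f"{name}_component{i}_{tag}"] = size
    feats["ratio_mean"] = _ratio(feats["LUAD_mean"], feats["LUSC_mean"])
    feats["ratio_median"] = _ratio(feats["LUAD_median"], feats["LUSC_median"])
    feats["ratio_variance"] = _ratio(feats["LUAD_variance"],
                                     feats["LUSC_variance"])
    feats["ratio_total_mass"] = _ratio(float(luad.sum()), float(lusc.sum()))
    for tau in THRESHOLDS:
        tag = f"t{int(tau * 100)}"
        feats[f"ratio_positive_count_{tag}"] = _ratio(
            float((luad >= tau).sum()), float((lusc >= tau).sum()))
        feats[f"ratio_largest_component_{tag}"] = _ratio(
            tops[("LUAD", tau)][0], tops[("LUSC", tau)][0])
    assert set(feats) == set(FEATURE_NAMES)
    return feats


def select_features(feature_rows: list[dict[str, float]], labels,
                    k: int = 25) -> list[str]:
    """Top-k features by Fisher score (mu1-mu2)^2 / (s1^2 + s2^2 + eps).

    Ties resolve to the fixed manifest order, so selection is deterministic.
    """
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("feature selection needs exactly two classes")
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"need at least 2 slides of class {c!r}")
    x = np.array([[row[name] for name in FEATURE_NAMES]
                  for row in feature_rows])
    y = np.array([classes.index(l) for l in labels])
    a, b = x[y == 0], x[y == 1]
    score = (a.mean(0) - b.mean(0)) ** 2 / (a.var(0) + b.var(0) + _EPS)
    order = sorted(range(len(FEATURE_NAMES)), key=lambda i: (-score[i], i))
    return [FEATURE_NAMES[i] for i in order[:k]]


def max_vote(maps: dict[str, np.ndarray]) -> str:
    """Slide label by positive-patch count.

    A cell is positive for the class holding its argmax; the LUAD and LUSC
    positive counts are compared.  Ties fall through to the larger summed
    probability mass, then to LUAD.
    """
    stack = np.stack([maps[name] for name in CLASS_NAMES])
    if stack.size == 0:
        raise ValueError("empty probability maps")
    arg = stack.argmax(axis=0)
    n_luad = int((arg == CLASS_NAMES.index("LUAD")).sum())
    n_lusc = int((arg == CLASS_NAMES.index("LUSC")).sum())
    if n_luad != n_lusc:
        return "LUAD" if n_luad > n_lusc else "LUSC"
    mass_luad = float(maps["LUAD"].sum())
    mass_lusc = float(maps["LUSC"].sum())
    if mass_luad != mass_lusc:
        return "LUAD" if mass_luad > mass_lusc else "LUSC"
    return "LUAD"


@dataclass
class SlideForest:
    """Trained random-forest regression with its feature schema."""

    forest: RandomForestRegressor
    feature_names: list[str]

    def predict(self, features: dict[str, float]) -> float:
        x = np.array([[features[name] for name in self.feature_names]])
        return float(self.forest.predict(x)[0])


#: Label encoding of the regression target.
LABEL_CODE = {"LUAD": 0.0, "LUSC": 1.0}


def train_rf(feature_rows: list[dict[str, float]], labels,
             feature_names: list[str], seed: int = 0) -> SlideForest:
    """Fit the bagged random-forest regression on selected features.

    10 bootstrap-bagged trees, ceil(p/3) candidate variables per split,
    minimum leaf size 5; the prediction is the mean of the tree outputs.
    """
    labels = list(labels)
    if len(labels) < 6:
        raise ValueError("random forest needs at least 6 slides")
    if len(set(labels)) < 2:
        raise ValueError("labels are degenerate (single class)")
    y = np.array([LABEL_CODE[l] for l in labels])
    x = np.array([[row[name] for name in feature_names]
                  for row in feature_rows])
    p = len(feature_names)
    forest = RandomForestRegressor(
        n_estimators=10,
        max_features=int(np.ceil(p / 3)),
        min_samples_leaf=5,
        bootstrap=True,
        random_state=int(seed) % (2 ** 31),
    )
    forest.fit(x, y)
    return SlideForest(forest, list(feature_names))


def rf_classify(model: SlideForest, features: dict[str, float],
                threshold: float = 0.5) -> str:
    """LUSC iff the regression output is >= threshold (inclusive)."""
    return "LUSC" if model.predict(features) >= threshold else "LUAD"
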