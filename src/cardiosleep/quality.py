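"""Binary sleep-quality evaluation from hypnogram structure.

A night's predicted (or annotated) hypnogram is reduced to a small set
of architecture features — efficiency, durations, fragmentation and
early-awakening measures — and a degree-3 polynomial-kernel SVM
classifies the night as *good* or *poor* sleep against the questionnaire
threshold (score <= 6 is good, on the 0–22 scale).

Fragmentation is summarised by the *transition intensity*: stages are
mapped W -> 1, R -> 0, L -> 1, D -> 1 and the absolute differences of
neighbouring codes are summed.  (The printed mapping makes W <-> L/D
transitions invisible; the alternative 1/0/−1 coding is available via
``labeling="signed"``.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import Hypnogram

#: The nine hypnogram features retained for the default quality model.
DEFAULT_QUALITY_FEATURES = (
    "sleep_efficiency",
    "total_sleep_time",
    "n_W_bouts",
    "transition_intensity",
    "freq_WR_after_6h",
    "NREM_duration",
    "W_duration",
    "R_proportion",
    "D_proportion",
)

#: All computed hypnogram features (the nine above plus auxiliaries).
ALL_QUALITY_FEATURES = DEFAULT_QUALITY_FEATURES + (
    "sleep_incubation",
    "REM_incubation",
    "wakefulness_times",
    "R_duration",
    "L_duration",
    "D_duration",
    "L_proportion",
    "W_proportion",
)

GOOD_SCORE_MAX = 6


@dataclass
class QualityLabel:
    """Questionnaire outcome: integer score 0–22 and its binary label."""

    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 22:
            raise ValueError(f"score must be in [0, 22], got {self.score}")

    @property
    def label(self) -> str:
        return "good" if self.score <= GOOD_SCORE_MAX else "poor"


_LABELING = {
    "printed": {"W": 1, "R": 0, "L": 1, "D": 1},
    "signed": {"W": 1, "R": 0, "L": -1, "D": -1},
}


def transition_intensity(hyp: Hypnogram, labeling: str = "printed") -> int:
    """Sum of absolute differences of the per-epoch stage codes."""
    codes = np.array([_LABELING[labeling][s] for s in hyp.labels])
    return int(np.sum(np.abs(np.diff(codes))))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) half-open index pairs."""
    out = []
    i, n = 0, mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return out


def hypnogram_features(
    hyp: Hypnogram,
    labeling: str = "printed",
    min_hours: float = 2.0,
) -> dict[str, float]:
    """Sleep-architecture features of one night.

    Definitions: sleep onset is the first non-W epoch; sleep efficiency is
    the fraction of non-W epochs over all epochs; ``n_W_bouts`` (and
    ``wakefulness_times``) count maximal W runs after onset;
    ``freq_WR_after_6h`` is the number of W or R epochs beyond the 6-h
    mark per hour of record beyond it (missing for shorter nights).
    Durations are in minutes.
    """
    labels = hyp.labels
    n = labels.size
    if n * hyp.epoch_len < min_hours * 3600.0:
        raise ValueError("night shorter than the minimum for quality features")
    ep_min = hyp.epoch_len / 60.0

    is_w = labels == "W"
    non_w = np.flatnonzero(~is_w)
    onset = int(non_w[0]) if non_w.size else n

    counts = {s: int(np.sum(labels == s)) for s in "WRLD"}
    w_bouts = len(_runs(is_w[onset:])) if onset < n else 0

    six_h = int(round(6 * 3600.0 / hyp.epoch_len))
    if n > six_h:
        tail = labels[six_h:]
        hours_beyond = tail.size * hyp.epoch_len / 3600.0
        freq_wr = float(np.sum((tail == "W") | (tail == "R")) / hours_beyond)
    else:
        freq_wr = np.nan

    first_r = np.flatnonzero(labels == "R")
    rem_incubation = (
        (int(first_r[0]) - onset) * ep_min if first_r.size and onset < n else np.nan
    )

    return {
        "sleep_efficiency": float(np.mean(~is_w)),
        "total_sleep_time": (n - counts["W"]) * ep_min,
        "n_W_bouts": float(w_bouts),
        "transition_intensity": float(transition_intensity(hyp, labeling)),
        "freq_WR_after_6h": freq_wr,
        "NREM_duration": (counts["L"] + counts["D"]) * ep_min,
        "W_duration": counts["W"] * ep_min,
        "R_proportion": counts["R"] / n,
        "D_proportion": counts["D"] / n,
        "sleep_incubation": onset * ep_min,
        "REM_incubation": rem_incubation,
        "wakefulness_times": float(w_bouts),
        "R_duration": counts["R"] * ep_min,
        "L_duration": counts["L"] * ep_min,
        "D_duration": counts["D"] * ep_min,
        "L_proportion": counts["L"] / n,
        "W_proportion": counts["W"] / n,
    }


def quality_feature_table(
    hyps: dict[str, Hypnogram] | list[Hypnogram],
    labeling: str = "printed",
) -> pd.DataFrame:
    """Feature table over a cohort of nights, indexed by record id."""
    if isinstance(hyps, dict):
        items = list(hyps.items())
    else:
        items = [(f"night{i:03d}", h) for i, h in enumerate(hyps)]
    rows = {rid: hypnogram_features(h, labeling) for rid, h in items}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# SVM-RFE


def svm_rfe(
    X: pd.DataFrame,
    y: np.ndarray,
    C: float = 1.0,
) -> list[str]:
    """Rank features by recursive elimination with a linear-kernel SVM.

    Repeatedly trains a standardized linear SVC and drops the feature
    with the smallest squared weight; the return value lists feature
    names from most to least important (last eliminated first).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if X.shape[1] < 2:
        raise ValueError("need at least two features to rank")
    cols = list(X.columns)
    M = X.to_numpy(dtype=float).copy()
    med = np.array([
        np.nanmedian(col) if np.isfinite(col).any() else 0.0 for col in M.T
    ])
    for j in range(M.shape[1]):
        bad = ~np.isfinite(M[:, j])
        M[bad, j] = med[j]
    remaining = list(range(len(cols)))
    eliminated: list[int] = []
    while len(remaining) > 1:
        Z = M[:, remaining]
        mu, sd = Z.mean(axis=0), Z.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Z - mu) / sd
        svc = SVC(kernel="linear", C=C).fit(Z, y)
        w2 = (svc.coef_.ravel()) ** 2
        drop = int(np.argmin(w2))
        eliminated.append(remaining.pop(drop))
    ranking = remaining + eliminated[::-1]
    return [cols[i] for i in ranking]


# ---------------------------------------------------------------------------
# Model / Results interface


class SleepQualityModel:
    """Good/poor sleep classifier over hypnogram architecture features.

    Parameters
    ----------
    features : DataFrame
        One row per night; columns at least ``feature_names``.
    labels : sequence of str or QualityLabel or int scores
        Planted or questionnaire-derived outcomes per night.
    feature_names : tuple, optional
        Defaults to the nine retained architecture features.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels,
        feature_names: tuple[str, ...] = DEFAULT_QUALITY_FEATURES,
        C_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
        random_state: int = 0,
    ) -> None:
        self.features = features
        self.labels = np.asarray([self._coerce_label(v) for v in labels])
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both quality classes must be present")
        if len(self.labels) != len(features):
            raise ValueError("features and labels must align")
        self.feature_names = tuple(feature_names)
        self.C_grid = C_grid
        self.random_state = random_state

    @staticmethod
    def _coerce_label(v) -> str:
        if isinstance(v, QualityLabel):
            return v.label
        if isinstance(v, (int, np.integer)):
            return QualityLabel(int(v)).label
        if v in ("good", "poor"):
            return str(v)
        raise ValueError(f"cannot interpret quality label {v!r}")

    @classmethod
    def from_hypnograms(
        cls, hyps: dict[str, Hypnogram], scores: dict[str, int], **kwargs
    ) -> "SleepQualityModel":
        common = [rid for rid in hyps if rid in scores]
        feats = quality_feature_table({rid: hyps[rid] for rid in common})
        labels = [scores[rid] for rid in common]
        return cls(feats, labels, **kwargs)

    def _design(self) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in self.features.columns]
        if missing:
            raise KeyError(f"features absent from table: {missing}")
        M = self.features.loc[:, list(self.feature_names)].to_numpy(dtype=float).copy()
        med = np.array([
            np.nanmedian(col) if np.isfinite(col).any() else 0.0 for col in M.T
        ])
        for j in range(M.shape[1]):
            bad = ~np.isfinite(M[:, j])
            M[bad, j] = med[j]
        self._impute_values = med
        return M

    def _pipeline(self) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="poly", degree=3, gamma="scale")),
            ]
        )

    def fit(self, cv_folds: int = 5) -> "SleepQualityResults":
        """Grid-search C, report k-fold CV metrics, refit on all nights."""
        M = self._design()
        y = self.labels
        n_per_class = min(np.sum(y == c) for c in np.unique(y))
        folds = int(min(cv_folds, n_per_class))
        cv = StratifiedKFold(folds, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            self._pipeline(), {"svc__C": list(self.C_grid)}, cv=cv, n_jobs=1
        )
        search.fit(M, y)
        best_c = search.best_params_["svc__C"]

        # per-fold report with the selected C
        fold_rows = []
        for i, (tr, te) in enumerate(cv.split(M, y)):
            pipe = self._pipeline().set_params(svc__C=best_c).fit(M[tr], y[tr])
            pred = pipe.predict(M[te])
            row = {"fold": i}
            for cls_name in ("good", "poor"):
                m = y[te] == cls_name
                row[f"{cls_name}_accuracy"] = (
                    float(np.mean(pred[m] == cls_name)) if m.any() else np.nan
                )
            row["accuracy"] = float(np.mean(pred == y[te]))
            from sklearn.metrics import f1_score

            row["macro_f1"] = float(
                f1_score(y[te], pred, labels=["good", "poor"], average="macro")
            )
            fold_rows.append(row)
        cv_report = pd.DataFrame(fold_rows).set_index("fold")

        final = self._pipeline().set_params(svc__C=best_c).fit(M, y)
        return SleepQualityResults(self, final, best_c, cv_report)


class SleepQualityResults:
    """Fitted quality model with its cross-validation report."""

    def __init__(
        self,
        model: SleepQualityModel,
        pipeline: Pipeline,
        C: float,
        cv_report: pd.DataFrame,
    ) -> None:
        self.model = model
        self.pipeline = pipeline
        self.C = C
        self.cv_report = cv_report

    @property
    def cv_accuracy(self) -> float:
        return float(self.cv_report["accuracy"].mean())

    @property
    def cv_macro_f1(self) -> float:
        return float(self.cv_report["macro_f1"].mean())

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        names = self.model.feature_names
        missing = [f for f in names if f not in features.columns]
        if missing:
            raise KeyError(f"features absent from table: {missing}")
        M = features.loc[:, list(names)].to_numpy(dtype=float).copy()
        impute = getattr(self.model, "_impute_values", np.zeros(M.shape[1]))
        for j in range(M.shape[1]):
            bad = ~np.isfinite(M[:, j])
            M[bad, j] = impute[j]
        return M

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Labels and decision values for a cohort feature table."""
        M = self._design(features)
        return pd.DataFrame(
            {
                "label": self.pipeline.predict(M),
                "decision_value": self.pipeline.decision_function(M),
            },
            index=features.index,
        )

    def to_bundle(self) -> dict:
        """All fitted parameters as a plain (JSON-serialisable) mapping.

        The polynomial decision function is reconstructed at load time as
        f(x) = sum_i alpha_i (gamma <x, sv_i> + coef0)^degree + b on the
        standardized features, so bundles stay language-neutral text.
        """
        scaler = self.pipeline.named_steps["scale"]
        svc = self.pipeline.named_steps["svc"]
        return {
            "kind": "sleep_quality_model",
            "feature_names": list(self.model.feature_names),
            "impute_values": getattr(
                self.model, "_impute_values", np.zeros(len(self.model.feature_names))
            ),
            "scaler_mean": scaler.mean_,
            "scaler_scale": scaler.scale_,
            "support_vectors": svc.support_vectors_,
            "dual_coef": svc.dual_coef_.ravel(),
            "intercept": float(svc.intercept_[0]),
            "gamma": float(svc._gamma),
            "coef0": float(svc.coef0),
            "degree": int(svc.degree),
            "classes": [str(c) for c in svc.classes_],
            "C": self.C,
            "cv_report": self.cv_report.reset_index().to_dict(orient="list"),
        }

    def summary(self) -> str:
        mean = self.cv_report.mean(numeric_only=True)
        lines = [
            "Sleep quality model (degree-3 polynomial SVM)",
            "=" * 46,
            f"features: {', '.join(self.model.feature_names)}",
            f"C = {self.C}",
            f"CV good-class accuracy: {mean.get('good_accuracy', float('nan')):.3f}",
            f"CV poor-class accuracy: {mean.get('poor_accuracy', float('nan')):.3f}",
            f"CV average accuracy:    {mean['accuracy']:.3f}",
            f"CV average macro F1:    {mean['macro_f1']:.3f}",
        ]
        return "\n".join(lines)


def predict_quality(bundle: dict, features: pd.DataFrame) -> pd.DataFrame:
    """Deterministic label + margin from a serialised quality bundle.

    Evaluates the polynomial-kernel decision function directly from the
    stored support vectors; a missing required feature column raises.
    """
    names = list(bundle["feature_names"])
    missing = [f for f in names if f not in features.columns]
    if missing:
        raise KeyError(f"features absent from table: {missing}")
    M = features.loc[:, names].to_numpy(dtype=float).copy()
    impute = np.asarray(bundle["impute_values"], dtype=float)
    for j in range(M.shape[1]):
        bad = ~np.isfinite(M[:, j])
        M[bad, j] = impute[j]
    Z = (M - np.asarray(bundle["scaler_mean"])) / np.asarray(bundle["scaler_scale"])
    sv = np.asarray(bundle["support_vectors"], dtype=float)
    K = (bundle["gamma"] * (Z @ sv.T) + bundle["coef0"]) ** bundle["degree"]
    f = K @ np.asarray(bundle["dual_coef"], dtype=float) + bundle["intercept"]
    classes = bundle["classes"]
    labels = np.where(f > 0, classes[1], classes[0])
    return pd.DataFrame(
        {"label": labels, "decision_value": f}, index=features.index
    )
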