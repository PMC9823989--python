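"""Four-stage sleep staging from nightly HRV feature tables.

The staging method works on the *shape* of the night rather than on
isolated epochs.  For each stage a *recognizer* projects a small set of
HRV features onto their first principal component F1, smooths it at a
small and a large frame length (SF1 tracks the epochs, BF1 tracks the
~90-min sleep-cycle scale), and tags the epochs where SF1 sits on the
stage's side of the shifted trend BF1 + k:

* wakefulness / REM:  SF1 > BF1 + k
* light sleep:        BF1 + k1 < SF1 < BF1 + k2
* deep sleep:         SF1 < BF1 + k

Near threshold crossings the tags are corrected by a local, variable
threshold adjustment whose height and width are proportional to the
height and slope of the excursion.  Epochs tagged by zero or several
recognizers are resolved by three Platt-calibrated binary SVM
classifiers (wake+REM vs NREM, W vs R, L vs D) combined through joint
probabilities.  Finally two physiological corrections are applied: REM
within the first 80 min after sleep onset becomes wakefulness, and deep
sleep in the half hour before the final awakening becomes light sleep.

``SleepStagingModel`` / ``SleepStagingResults`` wrap the individual
operations into a fit/predict interface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .datatypes import Hypnogram, STAGES

#: Features whose direction of variation opposes the rest and is negated
#: before PCA.
DEFAULT_FLIP_SET = ("SE", "alpha2")

#: Stage-specific feature combinations used by default.
DEFAULT_RECOGNIZER_FEATURES: dict[str, tuple[str, ...]] = {
    "W": ("coRR", "HR", "resf", "alpha2"),
    "R": ("coRR", "HR", "resf", "alpha1", "alpha2", "G1"),
    "L": ("HR", "resf", "SE", "alpha2", "P1"),
    "D": ("resf", "LF", "alpha1", "corr2"),
}

DIRECTIONS = {"W": "above", "R": "above", "L": "band", "D": "below"}


@dataclass
class Recognizer:
    """A per-stage detector on the dually smoothed principal component."""

    stage: str
    feature_names: tuple[str, ...]
    flip_set: tuple[str, ...] = DEFAULT_FLIP_SET
    small_frame: int = 11
    large_frame: int = 121
    sg_order: int = 2
    direction: str = ""
    k: float = 0.0
    k2: float | None = None  # band recognizers use (k, k2) with k < k2
    c_h: float = 0.25
    c_w: float = 0.5
    pca_loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.direction:
            self.direction = DIRECTIONS.get(self.stage, "above")
        if self.direction not in ("above", "below", "band"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.small_frame >= self.large_frame:
            raise ValueError("small_frame must be below large_frame")
        if self.direction == "band" and self.k2 is not None and not self.k < self.k2:
            raise ValueError("band recognizer needs k < k2")

    def to_dict(self) -> dict:
        d = {
            "stage": self.stage,
            "feature_names": list(self.feature_names),
            "flip_set": list(self.flip_set),
            "small_frame": self.small_frame,
            "large_frame": self.large_frame,
            "sg_order": self.sg_order,
            "direction": self.direction,
            "k": self.k,
            "k2": self.k2,
            "c_h": self.c_h,
            "c_w": self.c_w,
        }
        if self.pca_loadings is not None:
            d["pca_loadings"] = np.asarray(self.pca_loadings).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Recognizer":
        d = dict(d)
        d["feature_names"] = tuple(d["feature_names"])
        d["flip_set"] = tuple(d.get("flip_set", DEFAULT_FLIP_SET))
        if d.get("pca_loadings") is not None:
            d["pca_loadings"] = np.asarray(d["pca_loadings"], dtype=float)
        return cls(**d)


def default_recognizers() -> dict[str, Recognizer]:
    return {
        s: Recognizer(stage=s, feature_names=DEFAULT_RECOGNIZER_FEATURES[s])
        for s in STAGES
    }


# ---------------------------------------------------------------------------
# Principal-component curves


def _odd_clip(frame: int, n: int) -> int:
    frame = min(frame, n if n % 2 == 1 else n - 1)
    if frame % 2 == 0:
        frame -= 1
    return max(frame, 1)


def _sg_smooth(y: np.ndarray, frame: int, order: int) -> np.ndarray:
    frame = _odd_clip(frame, y.size)
    if frame <= order:
        return y.copy()
    return savgol_filter(y, frame, order)


def principal_curves(
    night_features: pd.DataFrame, rec: Recognizer
) -> dict[str, np.ndarray]:
    """F1 and its two smoothings for one night.

    Columns are median-imputed (a column with > 50 % missing raises),
    flip-set features negated, z-scored within the night; F1 is the
    projection on the first principal component, itself z-scored, and
    SF1/BF1 its Savitzky–Golay smoothings at the two frame lengths.
    The PC sign is oriented so that HR's loading (or the first listed
    feature's) is positive.
    """
    missing = [f for f in rec.feature_names if f not in night_features.columns]
    if missing:
        raise KeyError(f"features absent from table: {missing}")
    X = night_features.loc[:, list(rec.feature_names)].to_numpy(dtype=float).copy()
    n, p = X.shape
    for j in range(p):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.mean() > 0.5:
            raise ValueError(
                f"feature {rec.feature_names[j]!r} is >50% missing in this night"
            )
        if bad.any():
            col[bad] = np.nanmedian(col)
    for j, name in enumerate(rec.feature_names):
        if name in rec.flip_set:
            X[:, j] = -X[:, j]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    if rec.pca_loadings is not None:
        w = np.asarray(rec.pca_loadings, dtype=float)
    else:
        if p == 1:
            w = np.array([1.0])
        else:
            _, _, vt = np.linalg.svd(Z, full_matrices=False)
            w = vt[0]
        anchor = (
            rec.feature_names.index("HR") if "HR" in rec.feature_names else 0
        )
        if w[anchor] < 0:
            w = -w
    f1 = Z @ w
    sdf = f1.std()
    f1 = (f1 - f1.mean()) / (sdf if sdf > 0 else 1.0)
    sf1 = _sg_smooth(f1, rec.small_frame, rec.sg_order)
    bf1 = _sg_smooth(f1, rec.large_frame, rec.sg_order)
    return {"F1": f1, "SF1": sf1, "BF1": bf1, "loadings": w}


def apply_recognizer(curves: dict[str, np.ndarray], rec: Recognizer) -> np.ndarray:
    """Boolean tag per epoch from the stage's comparison rule (strict)."""
    delta = curves["SF1"] - curves["BF1"]
    if rec.direction == "above":
        return delta > rec.k
    if rec.direction == "below":
        return delta < rec.k
    k2 = rec.k2 if rec.k2 is not None else -rec.k
    return (delta > rec.k) & (delta < k2)


# ---------------------------------------------------------------------------
# Boundary-value processing


def _ramp_adjustment(
    delta: np.ndarray, k: float, c_h: float, c_w: float
) -> np.ndarray:
    """Local threshold raise near the crossings of ``delta`` with ``k``.

    For each excursion of ``delta − k`` above zero (minimum, up-crossing,
    maximum, down-crossing), a linear ramp is added to the threshold on
    the medial side of each crossing.  Its height is ``c_h·(H − L)`` and
    its width ``c_w·(H − L)/|slope|`` epochs, where H is the excursion
    maximum, L the adjacent minimum outside it, and the slope is the
    one-epoch difference of SF1 at the crossing.
    """
    g = delta - k
    n = g.size
    adj = np.zeros(n)
    if n < 3 or c_h == 0:
        return adj
    sign = g > 0
    # excursion runs of consecutive positive epochs
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if sign[i]:
            j = i
            while j + 1 < n and sign[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    for i0, j0 in runs:
        h = float(np.max(g[i0 : j0 + 1]))
        # preceding minimum (left side) and following minimum (right side)
        left = g[:i0]
        right = g[j0 + 1 :]
        sides = []
        if i0 > 0 and left.size:
            lmin = float(np.min(left[max(left.size - 40, 0):]))
            slope = abs(g[i0] - g[i0 - 1])
            sides.append(("L", i0, h - lmin, slope))
        if j0 < n - 1 and right.size:
            rmin = float(np.min(right[:40]))
            slope = abs(g[j0 + 1] - g[j0])
            sides.append(("R", j0, h - rmin, slope))
        for where, cidx, height, slope in sides:
            if height <= 0 or slope <= 0:
                continue
            amp = c_h * height
            width = c_w * height / slope
            if width <= 0:
                continue
            span = int(np.ceil(width))
            if where == "L":
                idx = np.arange(cidx, min(cidx + span + 1, j0 + 1))
                off = idx - cidx
            else:
                idx = np.arange(max(cidx - span, i0), cidx + 1)
                off = cidx - idx
            ramp = amp * np.maximum(0.0, 1.0 - off / width)
            np.maximum.at(adj, idx, ramp)
    return adj


def adjust_boundaries(
    curves: dict[str, np.ndarray], rec: Recognizer, tags: np.ndarray
) -> np.ndarray:
    """Re-evaluate tags against the locally adjusted threshold.

    The threshold is raised on the medial side of each crossing for the
    W and R recognizers and lowered for the D recognizer; the band (L)
    recognizer is returned unchanged.  ``c_h = 0`` is a no-op.
    """
    if rec.direction == "band" or rec.c_h == 0:
        return tags.copy()
    delta = curves["SF1"] - curves["BF1"]
    if rec.direction == "above":
        adj = _ramp_adjustment(delta, rec.k, rec.c_h, rec.c_w)
        return delta > rec.k + adj
    adj = _ramp_adjustment(-delta, -rec.k, rec.c_h, rec.c_w)
    return delta < rec.k - adj


# ---------------------------------------------------------------------------
# Platt-calibrated SVM and the fusion model


@dataclass
class PlattSVC:
    """A binary margin model with an explicit Platt sigmoid.

    Holds everything needed to evaluate the decision function without
    sklearn state: standardisation constants, support vectors, dual
    coefficients, intercept, RBF gamma and the sigmoid coefficients
    ``(A, B)`` such that P(positive | x) = 1 / (1 + exp(A·f(x) + B)).
    """

    feature_names: tuple[str, ...]
    positive_label: str
    negative_label: str
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    impute_values: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    platt_a: float
    platt_b: float

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"features absent from table: {missing}")
        M = X.loc[:, list(self.feature_names)].to_numpy(dtype=float).copy()
        for j in range(M.shape[1]):
            bad = ~np.isfinite(M[:, j])
            M[bad, j] = self.impute_values[j]
        return (M - self.scaler_mean) / self.scaler_scale

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._prepare(X)
        d2 = (
            np.sum(Z**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(positive class) per row, in [0, 1]."""
        f = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(np.clip(self.platt_a * f + self.platt_b, -500, 500)))

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "scaler_mean": self.scaler_mean,
            "scaler_scale": self.scaler_scale,
            "impute_values": self.impute_values,
            "support_vectors": self.support_vectors,
            "dual_coef": self.dual_coef,
            "intercept": self.intercept,
            "gamma": self.gamma,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlattSVC":
        d = dict(d)
        d["feature_names"] = tuple(d["feature_names"])
        for key in ("scaler_mean", "scaler_scale", "impute_values",
                    "support_vectors", "dual_coef"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def fit_platt_svc(
    X: pd.DataFrame,
    y: np.ndarray,
    positive_label: str,
    negative_label: str,
    feature_names: tuple[str, ...],
    c_grid: tuple[float, ...] = (1.0, 10.0),
    max_samples: int = 4000,
    random_state: int = 0,
) -> PlattSVC:
    """Train one calibrated binary classifier.

    An RBF SVC (C selected by a small inner grid search) provides the
    margin; a logistic fit on the training margins provides the Platt
    sigmoid.  Rows are median-imputed and standardised; large problems
    are subsampled for tractability.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    M = X.loc[:, list(feature_names)].to_numpy(dtype=float).copy()
    impute = np.array([
        np.nanmedian(M[:, j]) if np.isfinite(M[:, j]).any() else 0.0
        for j in range(M.shape[1])
    ])
    impute[~np.isfinite(impute)] = 0.0
    for j in range(M.shape[1]):
        bad = ~np.isfinite(M[:, j])
        M[bad, j] = impute[j]
    mean, scale = M.mean(axis=0), M.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (M - mean) / scale
    yy = (y == positive_label).astype(int)

    if Z.shape[0] > max_samples:
        rng = np.random.default_rng(random_state)
        idx = rng.choice(Z.shape[0], max_samples, replace=False)
        if len(np.unique(yy[idx])) < 2:  # keep both classes represented
            idx = np.concatenate([idx, np.flatnonzero(yy != yy[idx[0]])[:10]])
        Z, yy = Z[idx], yy[idx]

    if len(c_grid) > 1:
        search = GridSearchCV(
            SVC(kernel="rbf", gamma="scale"),
            {"C": list(c_grid)},
            cv=3,
            n_jobs=1,
        )
        search.fit(Z, yy)
        svc = search.best_estimator_
    else:
        svc = SVC(kernel="rbf", gamma="scale", C=c_grid[0]).fit(Z, yy)

    f = svc.decision_function(Z)
    lr = LogisticRegression(C=1e6).fit(f[:, None], yy)
    platt_a = -float(lr.coef_[0, 0])
    platt_b = -float(lr.intercept_[0])
    return PlattSVC(
        feature_names=tuple(feature_names),
        positive_label=positive_label,
        negative_label=negative_label,
        scaler_mean=mean,
        scaler_scale=scale,
        impute_values=impute,
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_.ravel(),
        intercept=float(svc.intercept_[0]),
        gamma=float(svc._gamma),
        platt_a=platt_a,
        platt_b=platt_b,
    )


@dataclass
class FusionModel:
    """The three calibrated binary classifiers plus tag-routing logic."""

    wrn: PlattSVC  # positive: epoch is W or R
    wr: PlattSVC  # positive: W (vs R)
    ld: PlattSVC  # positive: L (vs D)

    def probabilities(self, X: pd.DataFrame) -> pd.DataFrame:
        """P(WR), P(N), P(W|WR), P(R|WR), P(L|N), P(D|N) per epoch."""
        p_wr = self.wrn.predict_proba(X)
        p_w = self.wr.predict_proba(X)
        p_l = self.ld.predict_proba(X)
        return pd.DataFrame(
            {
                "P_WR": p_wr,
                "P_N": 1.0 - p_wr,
                "P_W_given_WR": p_w,
                "P_R_given_WR": 1.0 - p_w,
                "P_L_given_N": p_l,
                "P_D_given_N": 1.0 - p_l,
            },
            index=X.index,
        )

    def to_dict(self) -> dict:
        return {"wrn": self.wrn.to_dict(), "wr": self.wr.to_dict(), "ld": self.ld.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "FusionModel":
        return cls(
            wrn=PlattSVC.from_dict(d["wrn"]),
            wr=PlattSVC.from_dict(d["wr"]),
            ld=PlattSVC.from_dict(d["ld"]),
        )


def train_fusion(
    features: pd.DataFrame,
    labels: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    context_names: tuple[str, ...] | None = None,
    n_context: int = 8,
    random_state: int = 0,
    **svc_kwargs,
) -> FusionModel:
    """Train the WR/N, W/R and L/D classifiers on labelled epochs.

    ``feature_names`` are always used; ``context_names`` are ranked by
    SVM-RFE against the WR/N split and the top ``n_context`` join the
    feature set of all three classifiers.
    """
    from .quality import svm_rfe  # shared ranking machinery

    labels = np.asarray(labels, dtype="<U1")
    if feature_names is None:
        feature_names = tuple(
            c for c in features.columns
            if c in DEFAULT_RECOGNIZER_FEATURES_UNION
        )
    selected = list(feature_names)
    if context_names:
        ctx = features.loc[:, list(context_names)].copy()
        ctx = ctx.fillna(ctx.median(numeric_only=True)).fillna(0.0)
        y_wrn = np.isin(labels, ["W", "R"]).astype(int)
        if len(np.unique(y_wrn)) == 2:
            ranked = svm_rfe(ctx, y_wrn)
            selected += list(ranked[:n_context])

    is_wr = np.isin(labels, ["W", "R"])
    wrn_y = np.where(is_wr, "A", "N")
    wrn = fit_platt_svc(
        features, wrn_y, "A", "N", tuple(selected),
        random_state=random_state, **svc_kwargs,
    )
    m_wr = is_wr
    wr = fit_platt_svc(
        features.loc[m_wr], labels[m_wr], "W", "R", tuple(selected),
        random_state=random_state, **svc_kwargs,
    )
    m_ld = np.isin(labels, ["L", "D"])
    ld = fit_platt_svc(
        features.loc[m_ld], labels[m_ld], "L", "D", tuple(selected),
        random_state=random_state, **svc_kwargs,
    )
    return FusionModel(wrn=wrn, wr=wr, ld=ld)


DEFAULT_RECOGNIZER_FEATURES_UNION = tuple(
    dict.fromkeys(itertools.chain(*DEFAULT_RECOGNIZER_FEATURES.values()))
)


@dataclass
class StagingResult:
    """Per-night staging output."""

    hypnogram: Hypnogram
    tag_sets: list[frozenset]
    probabilities: pd.DataFrame


def fuse(
    tag_sets: list[frozenset],
    fusion: FusionModel,
    features: pd.DataFrame,
) -> StagingResult:
    """Resolve per-epoch tag sets into a single stage label each.

    Routing: a single tag stands; ``{W,R}`` and ``{L,D}`` are resolved by
    their conditional classifier alone; one tag from each group is
    resolved by the WR/N classifier choosing the group; zero, three or
    four tags fall back to the argmax of the four joint probabilities
    P(WR)·P(W|WR), P(WR)·P(R|WR), P(N)·P(L|N), P(N)·P(D|N).
    """
    probs = fusion.probabilities(features)
    joint = np.column_stack(
        [
            probs["P_WR"] * probs["P_W_given_WR"],
            probs["P_WR"] * probs["P_R_given_WR"],
            probs["P_N"] * probs["P_L_given_N"],
            probs["P_N"] * probs["P_D_given_N"],
        ]
    )
    order = np.array(STAGES)
    out = []
    for i, tags in enumerate(tag_sets):
        tags = frozenset(tags)
        if len(tags) == 1:
            out.append(next(iter(tags)))
        elif tags == frozenset({"W", "R"}):
            out.append("W" if probs["P_W_given_WR"].iloc[i] >= 0.5 else "R")
        elif tags == frozenset({"L", "D"}):
            out.append("L" if probs["P_L_given_N"].iloc[i] >= 0.5 else "D")
        elif len(tags) == 2:  # one tag from each group
            group_wr = probs["P_WR"].iloc[i] >= 0.5
            kept = tags & ({"W", "R"} if group_wr else {"L", "D"})
            out.append(next(iter(kept)))
        else:  # 0, 3 or 4 tags
            out.append(order[int(np.argmax(joint[i]))])
    hyp = Hypnogram(np.asarray(out), source="predicted")
    return StagingResult(hypnogram=hyp, tag_sets=[frozenset(t) for t in tag_sets], probabilities=probs)


# ---------------------------------------------------------------------------
# Physiological post-corrections


def _postprocess_once(labels: np.ndarray, epoch_len: float) -> np.ndarray:
    labels = labels.copy()
    non_w = np.flatnonzero(labels != "W")
    if non_w.size == 0:
        return labels
    onset = int(non_w[0])
    lim = onset + int(round(80 * 60 / epoch_len))
    seg = labels[onset:lim]
    seg[seg == "R"] = "W"
    labels[onset:lim] = seg
    # final awakening: start of the trailing contiguous W run, if any
    if labels[-1] == "W":
        fw = len(labels)
        while fw > 0 and labels[fw - 1] == "W":
            fw -= 1
        lo = max(fw - int(round(30 * 60 / epoch_len)), 0)
        seg = labels[lo:fw]
        seg[seg == "D"] = "L"
        labels[lo:fw] = seg
    return labels


def postprocess(hyp: Hypnogram) -> Hypnogram:
    """Apply the physiological corrections, iterated to a fixed point.

    REM within the first 80 min after sleep onset (first non-W epoch)
    becomes W; deep sleep within 30 min before the final awakening (the
    trailing contiguous W run) becomes L.  A single pass can move the
    landmarks it is defined against, so the pass is repeated until the
    hypnogram is stable, which makes the operation idempotent.
    """
    labels = hyp.labels.copy()
    for _ in range(20):
        new = _postprocess_once(labels, hyp.epoch_len)
        if np.array_equal(new, labels):
            break
        labels = new
    return Hypnogram(labels, hyp.epoch_len, source="predicted")


# ---------------------------------------------------------------------------
# Evaluation


def binary_metrics(tags: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and Youden's index of a detector."""
    tags = np.asarray(tags, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = float(np.sum(tags & truth))
    tn = float(np.sum(~tags & ~truth))
    fp = float(np.sum(tags & ~truth))
    fn = float(np.sum(~tags & truth))
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    spec = tn / (tn + fp) if tn + fp > 0 else 0.0
    return {
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
        "sensitivity": sens,
        "specificity": spec,
        "youden": sens + spec - 1.0,
    }


def evaluate_staging(pred: Hypnogram, truth: Hypnogram) -> dict:
    """Four-class staging metrics against an annotated hypnogram.

    Returns overall accuracy, macro F1 (unweighted mean of per-class F1),
    per-stage sensitivity/specificity/Youden, and the confusion matrix
    (rows: truth, columns: prediction).
    """
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    p, t = pred.labels, truth.labels
    acc = float(np.mean(p == t))
    macro = float(f1_score(t, p, labels=list(STAGES), average="macro", zero_division=0))
    per_stage = {
        s: binary_metrics(p == s, t == s) for s in STAGES
    }
    cm = pd.DataFrame(
        [[int(np.sum((t == a) & (p == b))) for b in STAGES] for a in STAGES],
        index=list(STAGES),
        columns=list(STAGES),
    )
    return {
        "accuracy": acc,
        "macro_f1": macro,
        "per_stage": per_stage,
        "confusion_matrix": cm,
    }


# ---------------------------------------------------------------------------
# Feature-combination search and useless-feature elimination


def _eval_threshold_grid(
    delta: np.ndarray, target: np.ndarray, direction: str, k_grid: np.ndarray
) -> tuple[float, float, float, float]:
    """Best (score, k, accuracy, youden) over a threshold grid; for band
    recognizers the grid is over symmetric half-widths."""
    n = delta.size
    pos = target.sum()
    neg = n - pos
    best = (-np.inf, 0.0, 0.0, 0.0)
    for k in k_grid:
        if direction == "above":
            tags = delta > k
        elif direction == "below":
            tags = delta < k
        else:
            half = abs(k)
            tags = (delta > -half) & (delta < half)
        tp = np.sum(tags & target)
        tn = np.sum(~tags & ~target)
        sens = tp / pos if pos else 0.0
        spec = tn / neg if neg else 0.0
        acc = (tp + tn) / n
        youden = sens + spec - 1.0
        score = (acc + youden) / 2.0
        # tie-break toward the smaller |k|
        if score > best[0] + 1e-12 or (
            abs(score - best[0]) <= 1e-12 and abs(k) < abs(best[1])
        ):
            best = (score, float(k), float(acc), float(youden))
    return best


def search_feature_combinations(
    nights: list[tuple[pd.DataFrame, Hypnogram]],
    stage: str,
    candidates: tuple[str, ...],
    max_size: int = 3,
    min_size: int = 1,
    k_grid: np.ndarray | None = None,
    small_frame: int = 11,
    large_frame: int = 121,
) -> pd.DataFrame:
    """Exhaustively score feature combinations for one stage recognizer.

    Every combination of ``min_size``..``max_size`` candidate features is
    turned into a provisional recognizer (PCA, dual smoothing, best
    offset on a grid) and scored by the mean of binary accuracy and
    Youden's index over the pooled training epochs.  Returns a ranked
    DataFrame (best first).
    """
    if k_grid is None:
        k_grid = np.linspace(-2.0, 2.0, 41)
    direction = DIRECTIONS[stage]
    if direction == "band":
        k_grid = np.abs(k_grid[k_grid != 0])
    rows = []
    combos: list[tuple[str, ...]] = []
    for size in range(min_size, max_size + 1):
        combos.extend(itertools.combinations(candidates, size))
    for combo in combos:
        deltas, targets = [], []
        for feats, hyp in nights:
            rec = Recognizer(
                stage=stage,
                feature_names=combo,
                small_frame=small_frame,
                large_frame=large_frame,
                direction=direction,
            )
            curves = principal_curves(feats, rec)
            deltas.append(curves["SF1"] - curves["BF1"])
            targets.append(hyp.labels == stage)
        delta = np.concatenate(deltas)
        target = np.concatenate(targets)
        score, k, acc, youden = _eval_threshold_grid(delta, target, direction, k_grid)
        rows.append(
            {
                "combination": combo,
                "k": k,
                "accuracy": acc,
                "youden": youden,
                "score": score,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["score", "accuracy"], ascending=False, kind="mergesort"
    )
    return df.reset_index(drop=True)


def eliminate_useless_features(
    ranked: dict[str, pd.DataFrame],
    quantile: float = 0.25,
) -> tuple[list[str], dict[str, set]]:
    """Remove features that are useless for every stage.

    Per stage, a feature is *useless* when it appears in the bottom
    ``quantile`` of ranked combinations but never in the top ``quantile``.
    The intersection of the four per-stage useless sets is removed from
    the global feature pool.  Returns (retained features, per-stage
    useless sets).
    """
    all_feats: set[str] = set()
    useless_per_stage: dict[str, set] = {}
    for stage, df in ranked.items():
        n = len(df)
        cut = max(int(np.ceil(n * quantile)), 1)
        top = set(itertools.chain(*df["combination"].iloc[:cut]))
        bottom = set(itertools.chain(*df["combination"].iloc[n - cut :]))
        stage_feats = set(itertools.chain(*df["combination"]))
        all_feats |= stage_feats
        useless_per_stage[stage] = bottom - top
    if useless_per_stage:
        removed = set.intersection(*useless_per_stage.values())
    else:
        removed = set()
    retained = sorted(all_feats - removed)
    return retained, useless_per_stage


# ---------------------------------------------------------------------------
# Model / Results interface


class SleepStagingModel:
    """Four-class sleep stager over nightly HRV feature tables.

    Parameters
    ----------
    nights : list of (DataFrame, Hypnogram)
        Training nights: a feature table (one row per epoch; columns from
        :mod:`cardiosleep.features`) and the annotated hypnogram.
    recognizers : dict, optional
        Stage recognizers to start from; defaults to the stage-specific
        feature combinations above with unfitted offsets.
    context_names : tuple, optional
        Contextual feature columns offered to the fusion classifiers.
    """

    def __init__(
        self,
        nights: list[tuple[pd.DataFrame, Hypnogram]],
        recognizers: dict[str, Recognizer] | None = None,
        context_names: tuple[str, ...] | None = None,
        k_grid: np.ndarray | None = None,
        random_state: int = 0,
        svc_kwargs: dict | None = None,
    ) -> None:
        if not nights:
            raise ValueError("need at least one training night")
        self.nights = nights
        self.recognizers = recognizers or default_recognizers()
        self.context_names = context_names
        self.k_grid = np.linspace(-2.0, 2.0, 41) if k_grid is None else np.asarray(k_grid)
        self.random_state = random_state
        self.svc_kwargs = svc_kwargs or {}

    def _fit_offsets(self) -> dict[str, Recognizer]:
        fitted = {}
        for stage, rec in self.recognizers.items():
            deltas, targets = [], []
            for feats, hyp in self.nights:
                curves = principal_curves(feats, rec)
                deltas.append(curves["SF1"] - curves["BF1"])
                targets.append(hyp.labels == stage)
            delta = np.concatenate(deltas)
            target = np.concatenate(targets)
            if rec.direction == "band":
                grid = np.abs(self.k_grid[self.k_grid != 0])
                _, k, _, _ = _eval_threshold_grid(delta, target, "band", grid)
                fitted[stage] = replace(rec, k=-abs(k), k2=abs(k))
            else:
                _, k, _, _ = _eval_threshold_grid(
                    delta, target, rec.direction, self.k_grid
                )
                fitted[stage] = replace(rec, k=k)
        return fitted

    def fit(self) -> "SleepStagingResults":
        """Fit recognizer offsets and the fusion classifiers."""
        fitted = self._fit_offsets()
        pooled = pd.concat([f for f, _ in self.nights])
        labels = np.concatenate([h.labels for _, h in self.nights])
        usable = (
            pooled["usable"].to_numpy(dtype=bool)
            if "usable" in pooled.columns
            else np.ones(len(pooled), dtype=bool)
        )
        fusion = train_fusion(
            pooled.loc[usable],
            labels[usable],
            context_names=self.context_names,
            random_state=self.random_state,
            **self.svc_kwargs,
        )
        return SleepStagingResults(self, fitted, fusion)


class SleepStagingResults:
    """Fitted stager: recognizers with offsets, fusion model, metrics."""

    def __init__(
        self,
        model: SleepStagingModel,
        recognizers: dict[str, Recognizer],
        fusion: FusionModel,
    ) -> None:
        self.model = model
        self.recognizers = recognizers
        self.fusion = fusion

    def tag(self, features: pd.DataFrame, boundary: bool = True) -> dict[str, np.ndarray]:
        """Per-stage boolean tags for one night."""
        tags = {}
        for stage, rec in self.recognizers.items():
            curves = principal_curves(features, rec)
            t = apply_recognizer(curves, rec)
            if boundary:
                t = adjust_boundaries(curves, rec, t)
            tags[stage] = t
        return tags

    def predict(
        self,
        features: pd.DataFrame,
        boundary: bool = True,
        post: bool = True,
    ) -> StagingResult:
        """Stage one night of features into a predicted hypnogram."""
        tags = self.tag(features, boundary=boundary)
        n = len(features)
        tag_sets = [
            frozenset(s for s in STAGES if tags[s][i]) for i in range(n)
        ]
        result = fuse(tag_sets, self.fusion, features)
        if post:
            result.hypnogram = postprocess(result.hypnogram)
        return result

    def evaluate(
        self, nights: list[tuple[pd.DataFrame, Hypnogram]], **kwargs
    ) -> dict:
        """Pooled four-class metrics over a list of nights."""
        preds, truths = [], []
        for feats, hyp in nights:
            preds.append(self.predict(feats, **kwargs).hypnogram.labels)
            truths.append(hyp.labels)
        return evaluate_staging(
            Hypnogram(np.concatenate(preds), source="predicted"),
            Hypnogram(np.concatenate(truths)),
        )

    def summary(self) -> str:
        lines = ["Sleep staging model", "=" * 40]
        for stage, rec in self.recognizers.items():
            if rec.direction == "band":
                thresh = f"{rec.k:+.3f} < SF1-BF1 < {rec.k2:+.3f}"
            else:
                cmp_ = ">" if rec.direction == "above" else "<"
                thresh = f"SF1-BF1 {cmp_} {rec.k:+.3f}"
            lines.append(
                f"{stage} recognizer: features={', '.join(rec.feature_names)}; {thresh}"
            )
        for name, clf in (("WR/N", self.fusion.wrn), ("W/R", self.fusion.wr),
                          ("L/D", self.fusion.ld)):
            lines.append(
                f"{name} classifier: {len(clf.feature_names)} features, "
                f"{clf.support_vectors.shape[0]} support vectors, "
                f"Platt(A={clf.platt_a:.3f}, B={clf.platt_b:.3f})"
            )
        return "\n".join(lines)

    def to_bundle(self) -> dict:
        return {
            "kind": "sleep_staging_model",
            "recognizers": {s: r.to_dict() for s, r in self.recognizers.items()},
            "fusion": self.fusion.to_dict(),
        }

    @classmethod
    def from_bundle(cls, bundle: dict) -> "SleepStagingResults":
        recs = {s: Recognizer.from_dict(d) for s, d in bundle["recognizers"].items()}
        fusion = FusionModel.from_dict(bundle["fusion"])
        obj = cls.__new__(cls)
        obj.model = None
        obj.recognizers = recs
        obj.fusion = fusion
        return obj
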