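"""Untargeted volatile-fingerprint chemometrics.

Consumes an already-aligned GC-MS peak table (samples x volatile peak areas,
with treatment class labels) and provides:

* linear temperature-programmed retention indices against an n-alkane ladder,
* internal-standard normalisation and total-peak-area comparison,
* PLS-DA (partial least squares regression on one-vs-rest class dummies,
  NIPALS extraction via scikit-learn) on autoscaled areas,
* variable identification (VID) coefficients — the Pearson correlation
  between each autoscaled variable and the model-reconstructed membership of
  each class — and discriminant selection at |VID| above a threshold,
* correlation-scaled bi-plot coordinates with the 70%/100% correlation
  circles.

A positive VID marks a compound more abundant in that treatment class than
in the others, a negative VID one that is depleted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .models import InvalidInputError
from .quality import GroupComparison, group_compare

__all__ = [
    "PeakTable",
    "AlkaneLadder",
    "PlsdaModel",
    "retention_index",
    "normalize_peaks",
    "total_peak_area",
    "plsda_fit",
    "loo_class_accuracy",
    "select_n_lv",
    "vid_coefficients",
    "select_discriminants",
    "biplot_coordinates",
]


@dataclass
class PeakTable:
    """Aligned peak-area table: samples x variables, positive areas.

    ``classes`` maps each sample to its treatment label;
    ``retention_times`` optionally maps variable id -> RT (min);
    ``internal_standard`` names the internal-standard column, if present.
    """

    areas: pd.DataFrame
    classes: pd.Series
    retention_times: Optional[dict] = None
    internal_standard: Optional[str] = None

    def __post_init__(self):
        self.areas = self.areas.astype(float)
        self.classes = pd.Series(self.classes)
        if not self.areas.index.equals(self.classes.index):
            self.classes = self.classes.reindex(self.areas.index)
            if self.classes.isna().any():
                raise InvalidInputError("class labels do not cover every sample")
        if (self.areas.values < 0).any():
            raise InvalidInputError("negative peak areas")
        if self.internal_standard is not None and self.internal_standard not in self.areas.columns:
            raise InvalidInputError(
                f"internal standard {self.internal_standard!r} not in table"
            )

    @property
    def n_classes(self) -> int:
        return self.classes.nunique()

    def class_labels(self) -> list:
        return sorted(self.classes.unique())


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times of the n-alkane standards (e.g. C8-C22)."""

    carbon_numbers: Tuple[int, ...]
    retention_times: Tuple[float, ...]

    def __post_init__(self):
        if len(self.carbon_numbers) != len(self.retention_times):
            raise InvalidInputError("ladder lengths differ")
        if len(self.carbon_numbers) < 2:
            raise InvalidInputError("ladder needs >= 2 alkanes")
        if any(b <= a for a, b in zip(self.carbon_numbers, self.carbon_numbers[1:])):
            raise InvalidInputError("carbon numbers must increase")
        if any(b <= a for a, b in zip(self.retention_times, self.retention_times[1:])):
            raise InvalidInputError("retention times must strictly increase")


def retention_index(rt: float, ladder: AlkaneLadder, extrapolate: bool = False) -> float:
    """Linear (temperature-programmed) retention index.

    RI = 100 * (n + (rt - t_n) / (t_{n+1} - t_n)) for the bracketing alkanes
    C_n and C_{n+1}.  Outside the ladder span an error is raised unless
    ``extrapolate=True``, which extends the first/last segment.
    """
    cs = ladder.carbon_numbers
    ts = ladder.retention_times
    if not extrapolate and not (ts[0] <= rt <= ts[-1]):
        raise InvalidInputError(
            f"rt {rt} min outside alkane ladder span [{ts[0]}, {ts[-1]}]; "
            "pass extrapolate=True to extend"
        )
    if rt <= ts[0]:
        j = 0
    elif rt >= ts[-1]:
        j = len(ts) - 2
    else:
        j = int(np.searchsorted(ts, rt, side="right")) - 1
        j = min(j, len(ts) - 2)
    frac = (rt - ts[j]) / (ts[j + 1] - ts[j])
    span = cs[j + 1] - cs[j]
    return 100.0 * (cs[j] + frac * span)


def normalize_peaks(table: PeakTable, internal_standard: Optional[str] = None) -> PeakTable:
    """Divide each sample's areas by its internal-standard area and drop the
    internal-standard column."""
    is_id = internal_standard or table.internal_standard
    if is_id is None:
        raise InvalidInputError("no internal standard specified")
    if is_id not in table.areas.columns:
        raise InvalidInputError(f"internal standard {is_id!r} not in table")
    is_areas = table.areas[is_id]
    if (is_areas <= 0).any():
        raise InvalidInputError("internal-standard area must be > 0 in every sample")
    areas = table.areas.drop(columns=[is_id]).div(is_areas, axis=0)
    rts = None
    if table.retention_times is not None:
        rts = {k: v for k, v in table.retention_times.items() if k != is_id}
    return PeakTable(areas=areas, classes=table.classes.copy(), retention_times=rts)


def total_peak_area(table: PeakTable, compare: bool = True):
    """Per-sample totals of all peak areas, optionally with a group
    comparison of the totals across classes (ANOVA + t-test letters)."""
    if table.areas.shape[1] < 1:
        raise InvalidInputError("empty peak table")
    totals = table.areas.sum(axis=1)
    comparison: Optional[GroupComparison] = None
    if compare and table.n_classes >= 2:
        groups = {
            label: totals[table.classes == label].to_numpy()
            for label in table.class_labels()
        }
        comparison = group_compare(groups)
    return totals, comparison


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PlsdaModel:
    """Fitted PLS-DA model on autoscaled X against one-vs-rest class dummies."""

    n_lv: int
    class_labels: list
    feature_names: list
    log_transform: bool
    x_mean: np.ndarray
    x_std: np.ndarray
    x_scores: np.ndarray  # T, n_samples x n_lv (orthogonal columns)
    x_weights: np.ndarray  # W
    x_loadings: np.ndarray  # P
    y_loadings: np.ndarray  # Q
    coef: np.ndarray  # regression coefficients on preprocessed X
    y_mean: np.ndarray
    explained_x: np.ndarray  # fraction of X variance per LV
    explained_y: np.ndarray  # fraction of Y (dummy) variance per LV
    dropped_variables: list = field(default_factory=list)

    def preprocess(self, areas: pd.DataFrame) -> np.ndarray:
        x = areas[self.feature_names].to_numpy(dtype=float)
        if self.log_transform:
            if np.any(x <= 0):
                raise InvalidInputError("log preprocessing requires strictly positive areas")
            x = np.log(x)
        return (x - self.x_mean) / self.x_std

    def predict_membership(self, areas: pd.DataFrame) -> pd.DataFrame:
        """Model-reconstructed class membership (continuous dummy scores)."""
        xc = self.preprocess(areas)
        yhat = xc @ self.coef + self.y_mean
        return pd.DataFrame(yhat, index=areas.index, columns=self.class_labels)

    def predict_classes(self, areas: pd.DataFrame) -> pd.Series:
        yhat = self.predict_membership(areas)
        return yhat.idxmax(axis=1)

    def scores_frame(self, index) -> pd.DataFrame:
        cols = [f"LV{i + 1}" for i in range(self.n_lv)]
        return pd.DataFrame(self.x_scores, index=index, columns=cols)


def _dummy_matrix(classes: pd.Series, labels: Sequence[str]) -> np.ndarray:
    return np.column_stack([(classes == lab).to_numpy(float) for lab in labels])


def plsda_fit(
    table: PeakTable,
    n_lv: Optional[int] = None,
    max_lv: int = 10,
    log_transform: bool = True,
) -> PlsdaModel:
    """Fit PLS-DA on the preprocessed peak table.

    Preprocessing is a log transform (areas are positive and right-skewed,
    with roughly multiplicative noise) followed by column autoscaling;
    ``log_transform=False`` autoscales the raw areas instead.  Classes are
    one-vs-rest dummy coded.  When ``n_lv`` is None, the model complexity is
    the smallest number of latent variables whose leave-one-out class
    assignment is perfect, falling back to the accuracy maximum (see
    :func:`select_n_lv`).  Constant variables (zero variance after
    preprocessing) are dropped with a warning.
    """
    if table.n_classes < 2:
        raise InvalidInputError("PLS-DA needs >= 2 classes")
    labels = table.class_labels()
    areas = table.areas
    if log_transform and (areas.values <= 0).any():
        raise InvalidInputError("log preprocessing requires strictly positive areas")
    work = np.log(areas) if log_transform else areas
    std = work.std(ddof=1)
    dropped = list(areas.columns[std == 0.0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant variable(s): {dropped[:5]}...")
        areas = areas.drop(columns=dropped)
        work = work.drop(columns=dropped)
        std = std.drop(dropped)
    n, p = areas.shape
    if n_lv is None:
        n_lv = select_n_lv(PeakTable(areas, table.classes), max_lv=max_lv,
                           log_transform=log_transform)
    if not (1 <= n_lv <= min(n - 1, p)):
        raise InvalidInputError(f"n_lv must lie in [1, {min(n - 1, p)}], got {n_lv}")

    x_mean = work.mean().to_numpy()
    x_std = std.to_numpy()
    xc = (work.to_numpy(dtype=float) - x_mean) / x_std
    y = _dummy_matrix(table.classes, labels)
    y_mean = y.mean(axis=0)
    yc = y - y_mean

    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(xc, y)

    t_scores = pls.x_scores_
    p_load = pls.x_loadings_
    q_load = pls.y_loadings_
    ssx = float(np.sum(xc**2))
    ssy = float(np.sum(yc**2))
    t_ss = np.sum(t_scores**2, axis=0)
    explained_x = t_ss * np.sum(p_load**2, axis=0) / ssx
    explained_y = t_ss * np.sum(q_load**2, axis=0) / ssy

    return PlsdaModel(
        n_lv=n_lv,
        class_labels=labels,
        feature_names=list(areas.columns),
        log_transform=log_transform,
        x_mean=x_mean,
        x_std=x_std,
        x_scores=t_scores,
        x_weights=pls.x_weights_,
        x_loadings=p_load,
        y_loadings=q_load,
        coef=pls.coef_.T,
        y_mean=y_mean,
        explained_x=explained_x,
        explained_y=explained_y,
        dropped_variables=dropped,
    )


def loo_class_accuracy(table: PeakTable, n_lv: int, log_transform: bool = True) -> float:
    """Leave-one-out class-assignment accuracy of a PLS-DA model with ``n_lv``."""
    n = table.areas.shape[0]
    correct = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train = PeakTable(table.areas.iloc[keep], table.classes.iloc[keep])
        if train.n_classes < table.n_classes:
            continue  # the left-out sample's class must stay represented
        model = plsda_fit(train, n_lv=n_lv, log_transform=log_transform)
        pred = model.predict_classes(table.areas.iloc[[i]]).iloc[0]
        correct += pred == table.classes.iloc[i]
    return correct / n


def select_n_lv(table: PeakTable, max_lv: int = 10, log_transform: bool = True) -> int:
    """Smallest number of LVs achieving perfect leave-one-out class
    separation; if none does, the accuracy-maximising (then smallest) count."""
    n, p = table.areas.shape
    cap = min(max_lv, n - 2, p)
    if cap < 1:
        raise InvalidInputError("too few samples/variables to select LVs")
    best_lv, best_acc = 1, -1.0
    for k in range(1, cap + 1):
        acc = loo_class_accuracy(table, k, log_transform=log_transform)
        if acc == 1.0:
            return k
        if acc > best_acc:
            best_lv, best_acc = k, acc
    return best_lv


# ---------------------------------------------------------------------------
# VID coefficients and discriminant selection
# ---------------------------------------------------------------------------


def vid_coefficients(model: PlsdaModel, table: PeakTable) -> pd.DataFrame:
    """VID(variable, class): Pearson correlation between each autoscaled
    variable and the model-reconstructed membership column of each class.

    Values lie in [-1, 1]; the sign follows the direction of the class mean
    difference (positive = enriched in that class).
    """
    xc = model.preprocess(table.areas)
    if np.any(xc.std(axis=0) == 0):
        raise InvalidInputError("zero-variance column in the table being scored")
    yhat = model.predict_membership(table.areas).to_numpy()
    xs = (xc - xc.mean(axis=0)) / xc.std(axis=0)
    ys = yhat - yhat.mean(axis=0)
    ysd = ys.std(axis=0)
    if np.any(ysd == 0):
        raise InvalidInputError("degenerate membership reconstruction (constant column)")
    ys = ys / ysd
    vid = xs.T @ ys / xc.shape[0]
    out = pd.DataFrame(vid, index=model.feature_names, columns=model.class_labels)
    return out.clip(-1.0, 1.0)


def select_discriminants(
    vid: pd.DataFrame,
    threshold: float = 0.8,
    retention_times: Optional[dict] = None,
    ladder: Optional[AlkaneLadder] = None,
) -> pd.DataFrame:
    """Per class, the variables with |VID| > ``threshold``, sorted by
    decreasing VID (negative VIDs — depleted compounds — are retained and
    sort last).  Retention indices are attached when RTs and an alkane
    ladder are supplied."""
    if not 0 < threshold <= 1.0:
        raise InvalidInputError("threshold must lie in (0, 1]")
    rows = []
    for label in vid.columns:
        col = vid[label]
        hits = col[col.abs() > threshold].sort_values(ascending=False)
        for var, value in hits.items():
            row = {"class": label, "variable": var, "vid": float(value)}
            if retention_times is not None and var in retention_times:
                row["rt_min"] = retention_times[var]
                if ladder is not None:
                    row["retention_index"] = retention_index(
                        retention_times[var], ladder, extrapolate=True
                    )
            rows.append(row)
    cols = ["class", "variable", "vid"]
    if retention_times is not None:
        cols += ["rt_min"] + (["retention_index"] if ladder is not None else [])
    return pd.DataFrame(rows, columns=cols)


def biplot_coordinates(model: PlsdaModel, table: PeakTable, lv_pair=(1, 2)) -> dict:
    """Coordinates for a correlation-scaled bi-plot on a pair of LVs.

    Returns sample scores, variable correlation loadings (corr of each
    autoscaled variable with the two score vectors — discriminants lie near
    the unit circle), class correlation vectors (corr of each class dummy
    with the scores), and the 70%/100% correlation circle radii.
    """
    i, j = lv_pair
    if not (1 <= i <= model.n_lv and 1 <= j <= model.n_lv and i != j):
        raise InvalidInputError(f"LV pair {lv_pair} outside fitted model with {model.n_lv} LVs")
    t = model.x_scores[:, [i - 1, j - 1]]
    xc = model.preprocess(table.areas)
    y = _dummy_matrix(table.classes, model.class_labels)

    def _corr_with_scores(mat):
        mc = mat - mat.mean(axis=0)
        sd = mc.std(axis=0)
        sd[sd == 0] = np.nan
        tc = t - t.mean(axis=0)
        tsd = tc.std(axis=0)
        return (mc / sd).T @ (tc / tsd) / mat.shape[0]

    cols = [f"LV{i}", f"LV{j}"]
    scores = pd.DataFrame(t, index=table.areas.index, columns=cols)
    var_corr = pd.DataFrame(_corr_with_scores(xc), index=model.feature_names, columns=cols)
    class_corr = pd.DataFrame(_corr_with_scores(y), index=model.class_labels, columns=cols)
    return {
        "scores": scores,
        "variable_correlations": var_corr,
        "class_correlations": class_corr,
        "explained_x": (model.explained_x[i - 1], model.explained_x[j - 1]),
        "explained_y": (model.explained_y[i - 1], model.explained_y[j - 1]),
        "circle_radii": (0.7, 1.0),
    }
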