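"""Open-curve eigenshape morphometrics of floral outlines.

An outline (an ordered open curve between two anchor landmarks, e.g. the two
ends of an orchid labellum margin) is resampled into equally spaced
semi-landmarks, converted to a phi shape function — the sequence of tangent
angles at equal arc-length steps, with the chord angle subtracted so the
representation is invariant to translation, rotation and uniform scale — and
the covariance matrix of phi functions across specimens is decomposed by SVD
into orthogonal eigenshape axes. Downstream analyses operate on specimen
scores on the axes describing a set fraction (default 90%) of shape
variation: nearest-model distances with group t-tests, and two-group
canonical variates analysis (Fisher discriminant) with a classification rate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from floralsignals.community_stats import GroupContrastResult


class GeometryError(ValueError):
    """Degenerate outline (zero length, repeated points...)."""


@dataclass(frozen=True)
class Outline:
    """An open floral outline: ordered 2-D points with anchors at both ends."""

    points: np.ndarray  # (n, 2)
    species: str = ""
    group: str = ""  # e.g. "yellow" / "non-yellow"
    family: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise GeometryError("an outline needs >= 3 (x, y) points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0):
            raise GeometryError("repeated consecutive points")
        if np.allclose(pts[0], pts[-1]):
            raise GeometryError("outline must be open (start != end)")
        object.__setattr__(self, "points", pts)


def interpolate_semilandmarks(o: Outline, m: int = 100) -> Outline:
    """Resample an outline to ``m`` points equally spaced by arc length.

    The two anchor landmarks (first and last points) are preserved exactly.
    Idempotent on outlines already equally spaced with ``m`` points.
    """
    if m < 3:
        raise ValueError("need m >= 3 semi-landmarks")
    pts = o.points
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("zero-length outline")
    target = np.linspace(0.0, total, m)
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    new = np.column_stack([x, y])
    new[0], new[-1] = pts[0], pts[-1]
    return replace(o, points=new)


def to_phi(o: Outline, variant: str = "phi") -> np.ndarray:
    """Tangent-angle shape function of an equally spaced outline.

    phi_j is the angle of segment j, unwrapped to remove 2-pi jumps, minus the
    angle of the chord from start to end anchor (rotation standardisation).
    Equal step lengths make the representation size-free. ``variant="phi-star"``
    subtracts the mean angle instead of the chord angle (net-deviation form).
    """
    pts = o.points
    d = np.diff(pts, axis=0)
    if np.any(np.linalg.norm(d, axis=1) == 0):
        raise GeometryError("coincident consecutive points")
    ang = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    if variant == "phi":
        chord = pts[-1] - pts[0]
        ref = np.arctan2(chord[1], chord[0])
    elif variant == "phi-star":
        ref = ang.mean()
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ang - ref


def outlines_to_phi_matrix(
    outlines, m: int = 100, variant: str = "phi"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Interpolate + convert a collection of outlines; returns (phi matrix, metadata)."""
    phis, meta = [], []
    for o in outlines:
        phis.append(to_phi(interpolate_semilandmarks(o, m), variant=variant))
        meta.append(
            {
                "specimen_id": o.specimen_id,
                "species": o.species,
                "group": o.group,
                "family": o.family,
            }
        )
    return np.vstack(phis), pd.DataFrame(meta)


class EigenshapeDecomposition(TransformerMixin, BaseEstimator):
    """SVD of the covariance matrix of phi shape functions.

    Parameters
    ----------
    retain_fraction : float in (0, 1]
        Keep the smallest number of axes whose cumulative variance fraction
        reaches this value (default 0.90). ``retain_fraction=1`` keeps all
        axes with nonzero variance.

    Fitted attributes follow PCA conventions: ``mean_``, ``components_``
    (orthonormal axes, rows), ``explained_variance_`` (eigenvalues of the
    covariance matrix, ddof=1), ``explained_variance_ratio_``,
    ``n_components_``. ``transform`` projects centred phi rows onto the
    retained axes.
    """

    def __init__(self, retain_fraction: float = 0.90):
        self.retain_fraction = retain_fraction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D phi matrix with >= 2 specimens")
        if not 0 < self.retain_fraction <= 1:
            raise ValueError("retain_fraction must be in (0, 1]")
        n = X.shape[0]
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        ev = s**2 / (n - 1)
        total = ev.sum()
        ratio = ev / total if total > 0 else np.zeros_like(ev)
        nonzero = int(np.sum(ev > ev[0] * 1e-12)) if total > 0 else 0
        if self.retain_fraction >= 1.0:
            k = nonzero
        else:
            k = int(np.searchsorted(np.cumsum(ratio), self.retain_fraction) + 1)
            k = min(k, nonzero) if nonzero else 1
        self.singular_values_ = s
        self.full_explained_variance_ = ev
        self.components_ = Vt[:k]
        self.explained_variance_ = ev[:k]
        self.explained_variance_ratio_ = ratio[:k]
        self.n_components_ = k
        self.total_variance_ = float(total)
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


@dataclass
class EigenshapeResult:
    """Axes, eigenvalues and per-specimen scores of an eigenshape analysis."""

    mean_phi: np.ndarray
    axes: np.ndarray  # (k, m-1), orthonormal rows
    eigenvalues: np.ndarray  # (k,), non-increasing
    scores: np.ndarray  # (n_specimens, k)
    variance_fraction: np.ndarray  # per retained axis, of the total variance
    total_variance: float
    metadata: pd.DataFrame | None = None

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]


def eigenshape_decompose(phis, metadata: pd.DataFrame | None = None) -> EigenshapeResult:
    """Full (all nonzero axes) eigenshape decomposition of a phi matrix."""
    est = EigenshapeDecomposition(retain_fraction=1.0).fit(np.asarray(phis, dtype=float))
    scores = est.transform(np.asarray(phis, dtype=float))
    return EigenshapeResult(
        mean_phi=est.mean_,
        axes=est.components_,
        eigenvalues=est.explained_variance_,
        scores=scores,
        variance_fraction=est.explained_variance_ratio_,
        total_variance=est.total_variance_,
        metadata=metadata,
    )


def retain_axes(r: EigenshapeResult, fraction: float = 0.90) -> EigenshapeResult:
    """Truncate to the smallest k axes reaching the cumulative variance fraction."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction >= 1.0:
        k = r.n_axes
    else:
        k = int(np.searchsorted(np.cumsum(r.variance_fraction), fraction) + 1)
        k = min(k, r.n_axes)
    return EigenshapeResult(
        mean_phi=r.mean_phi,
        axes=r.axes[:k],
        eigenvalues=r.eigenvalues[:k],
        scores=r.scores[:, :k],
        variance_fraction=r.variance_fraction[:k],
        total_variance=r.total_variance,
        metadata=r.metadata,
    )


def nearest_group_distance(
    scores: np.ndarray, families, target_family: str = "Malpighiaceae"
) -> np.ndarray:
    """Per-specimen Euclidean distance in score space to the nearest target-family specimen.

    Specimens of the target family get the distance to their nearest *other*
    target-family specimen excluded — they are reported as NaN, since the
    statistic is only defined for non-target specimens.
    """
    scores = np.asarray(scores, dtype=float)
    fam = np.asarray(list(families))
    mask = fam == target_family
    if not mask.any():
        raise ValueError(f"no specimens of target family {target_family!r}")
    targets = scores[mask]
    out = np.full(len(fam), np.nan)
    non = ~mask
    if non.any():
        diffs = scores[non, None, :] - targets[None, :, :]
        out[non] = np.sqrt((diffs**2).sum(axis=2)).min(axis=1)
    return out


def group_distance_test(
    distances,
    groups,
    mimic_group: str = "yellow-Oncidiinae",
    other_group: str = "other-angiosperms",
    exclude: list | None = None,
    labels=None,
) -> GroupContrastResult:
    """Welch one-sided test: putative mimics sit closer to the model family.

    ``distances`` are nearest-model distances per specimen, ``groups`` the
    specimen group labels; the alternative is that the mimic group's mean is
    smaller. ``exclude`` drops named specimens (``labels``) before testing —
    exclusion is always an explicit caller decision, never automatic.
    """
    d = np.asarray(distances, dtype=float)
    g = np.asarray(list(groups))
    keep = ~np.isnan(d)
    if exclude:
        if labels is None:
            raise ValueError("labels required when exclude is given")
        keep &= ~np.isin(np.asarray(list(labels)), list(exclude))
    d, g = d[keep], g[keep]
    a = d[g == mimic_group]
    b = d[g == other_group]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 specimens per group (got {len(a)} / {len(b)})")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return GroupContrastResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue), n_a=len(a), n_b=len(b)
    )


class CanonicalVariates(ClassifierMixin, BaseEstimator):
    """Two-group canonical variates analysis (Fisher linear discriminant).

    The single canonical axis is w = S_w^{-1} (m_1 - m_0) with S_w the pooled
    within-group covariance; assignment is by the discriminant score against
    the threshold at the pooled midpoint w . (m_0 + m_1)/2. When S_w is
    singular or ill-conditioned (retained axes >= specimens), ridge shrinkage
    ``S_w + ridge * tr(S_w)/p * I`` is applied and flagged in ``regularized_``.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("exactly two groups required")
        for c in classes:
            if (y == c).sum() < 2:
                raise ValueError("need >= 2 specimens per group")
        self.classes_ = classes
        X0, X1 = X[y == classes[0]], X[y == classes[1]]
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        n0, n1 = len(X0), len(X1)
        Sw = (np.cov(X0, rowvar=False, ddof=1) * (n0 - 1) +
              np.cov(X1, rowvar=False, ddof=1) * (n1 - 1)) / (n0 + n1 - 2)
        Sw = np.atleast_2d(Sw)
        p = Sw.shape[0]
        self.regularized_ = False
        lam = 0.0
        cond = np.linalg.cond(Sw) if np.isfinite(Sw).all() else np.inf
        if not np.isfinite(cond) or cond > 1e10:
            lam = self.ridge * max(np.trace(Sw) / p, 1e-300)
            self.regularized_ = True
        try:
            w = np.linalg.solve(Sw + lam * np.eye(p), m1 - m0)
        except np.linalg.LinAlgError:
            lam = self.ridge * max(np.trace(Sw) / p, 1e-300)
            self.regularized_ = True
            w = np.linalg.solve(Sw + lam * np.eye(p), m1 - m0)
        self.ridge_used_ = lam
        self.coef_ = w
        self.threshold_ = float(w @ (m0 + m1) / 2.0)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ - self.threshold_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])


@dataclass(frozen=True)
class CVAResult:
    """Classification summary of a two-group CVA."""

    classification_rate: float
    confusion: np.ndarray  # (2, 2), rows true, cols predicted, class order
    classes: tuple
    validation: str
    regularized: bool

    @property
    def n(self) -> int:
        return int(self.confusion.sum())


def cva_two_group(scores, labels, validation: str = "resubstitution", ridge: float = 1e-8) -> CVAResult:
    """Two-group CVA classification rate under the chosen validation scheme.

    ``validation`` is "resubstitution" (fit and classify the same specimens)
    or "leave-one-out" (refit without each specimen in turn).
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if validation == "resubstitution":
        est = CanonicalVariates(ridge=ridge).fit(X, y)
        pred = est.predict(X)
        reg = est.regularized_
    elif validation == "leave-one-out":
        pred = np.empty_like(y)
        reg = False
        idx = np.arange(len(y))
        for i in idx:
            est = CanonicalVariates(ridge=ridge).fit(X[idx != i], y[idx != i])
            pred[i] = est.predict(X[i : i + 1])[0]
            reg |= est.regularized_
    else:
        raise ValueError(f"unknown validation {validation!r}")
    conf = np.zeros((2, 2), dtype=int)
    for ti, tc in enumerate(classes):
        for pi, pc in enumerate(classes):
            conf[ti, pi] = int(np.sum((y == tc) & (pred == pc)))
    rate = float(np.trace(conf) / conf.sum())
    return CVAResult(
        classification_rate=rate,
        confusion=conf,
        classes=tuple(classes),
        validation=validation,
        regularized=bool(reg),
    )


# ---------------------------------------------------------------------------
# outline I/O

def read_outlines_csv(coords_path, metadata_path=None) -> list[Outline]:
    """Read outlines from a long CSV (specimen_id, point_index, x, y).

    ``metadata_path`` optionally maps specimen_id -> species, group, family.
    """
    df = pd.read_csv(coords_path)
    meta = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path).set_index("specimen_id")
        meta = mdf.to_dict("index")
    outlines = []
    for sid, sub in df.groupby("specimen_id", sort=True):
        sub = sub.sort_values("point_index")
        info = meta.get(sid, {})
        outlines.append(
            Outline(
                points=sub[["x", "y"]].to_numpy(float),
                specimen_id=str(sid),
                species=str(info.get("species", "")),
                group=str(info.get("group", "")),
                family=str(info.get("family", "")),
            )
        )
    return outlines


def read_outlines_tps(path, metadata_path=None) -> list[Outline]:
    """Read open-curve outlines from a TPS file (LM= blocks with ID= labels)."""
    meta = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path).set_index("specimen_id")
        meta = mdf.to_dict("index")
    outlines = []
    pts: list[list[float]] = []
    expected = 0
    sid = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            m = re.match(r"^LM\s*=\s*(\d+)", line, flags=re.I)
            if m:
                if pts:
                    outlines.append(_tps_outline(pts, sid, meta))
                expected = int(m.group(1))
                pts, sid = [], ""
                continue
            m = re.match(r"^ID\s*=\s*(.+)", line, flags=re.I)
            if m:
                sid = m.group(1).strip()
                continue
            if re.match(r"^[-+0-9.eE]+\s+[-+0-9.eE]+$", line):
                pts.append([float(v) for v in line.split()])
    if pts:
        if expected and len(pts) != expected:
            raise GeometryError(f"TPS block declares {expected} landmarks, found {len(pts)}")
        outlines.append(_tps_outline(pts, sid, meta))
    return outlines


def _tps_outline(pts, sid, meta) -> Outline:
    info = meta.get(sid, {})
    return Outline(
        points=np.asarray(pts, dtype=float),
        specimen_id=str(sid),
        species=str(info.get("species", "")),
        group=str(info.get("group", "")),
        family=str(info.get("family", "")),
    )
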