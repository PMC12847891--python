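"""Component decomposition of coupling histograms.

Per channel, condition and histogram kind, subjects' 2-D coupling maps are
vectorized (row-major frequency x coupling order), column-standardized, and
decomposed with PCA (10 components retained) and ICA (5 components for
SO-power maps; 4 for SO-phase maps, falling back to 3 when FastICA does not
converge). Component signs are arbitrary, so loadings and scores are
oriented so that higher scores correspond to higher TF-peak density in
patient groups relative to controls. Components recurring across channels
and conditions are grouped into a pattern catalogue by greedy centroid
clustering on the absolute Pearson correlation of their loading maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .socoupling import CoupledHistogram

__all__ = [
    "FeatureMatrix",
    "ComponentSet",
    "PatternCatalogue",
    "build_matrix",
    "fit_pca",
    "fit_ica",
    "orient_components",
    "group_patterns",
    "project",
]


@dataclass
class FeatureMatrix:
    """Subjects x vectorized-histogram-cells matrix with stored column stats."""

    data: np.ndarray                 # standardized, subjects x cells
    subjects: list[str]
    col_means: np.ndarray
    col_sds: np.ndarray              # 1.0 recorded for constant columns
    constant_cols: np.ndarray        # boolean flags
    channel: str = ""
    condition: str = ""
    kind: str = ""
    grid_shape: tuple[int, int] = (0, 0)


@dataclass
class ComponentSet:
    """Loadings + per-subject projection scores from one decomposition."""

    method: str                      # 'PCA' or 'ICA'
    loadings: np.ndarray             # components x cells
    scores: np.ndarray               # subjects x components
    subjects: list[str]
    explained_var_ratio: np.ndarray | None = None
    orientation_signs: np.ndarray | None = None
    converged: bool = True
    channel: str = ""
    condition: str = ""
    kind: str = ""

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


@dataclass
class PatternCatalogue:
    """Named clusters of similar component loading maps across channels/conditions.

    Patterns are ordered by descending member count and named with the given
    prefix (Pow1, Pow2, ... for power maps; Pha1, ... for phase maps).
    """

    names: list[str]
    members: dict                    # name -> list of (channel, condition, method, index)
    centroids: dict                  # name -> loading vector
    threshold: float


def build_matrix(histograms: list[CoupledHistogram]) -> FeatureMatrix:
    """Vectorize and column-standardize one channel/condition/kind's maps.

    Cell order is row-major frequency x coupling. Columns with zero variance
    (no peaks anywhere in that cell) standardize to 0 and are flagged rather
    than dropped, so grids stay aligned across subjects and splits.
    """
    if len(histograms) < 3:
        raise ValueError("need >= 3 subjects to build a feature matrix")
    h0 = histograms[0]
    for h in histograms[1:]:
        if not h.same_grid(h0):
            raise ValueError("histogram grids differ across subjects")
    X = np.stack([h.values.ravel(order="C") for h in histograms])
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    const = sds < 1e-12
    safe = np.where(const, 1.0, sds)
    Z = (X - means) / safe
    Z[:, const] = 0.0
    return FeatureMatrix(
        data=Z, subjects=[h.subject for h in histograms],
        col_means=means, col_sds=safe, constant_cols=const,
        channel=h0.channel, condition=h0.condition, kind=h0.kind,
        grid_shape=h0.values.shape)


def fit_pca(fm: FeatureMatrix, n_components: int = 10) -> ComponentSet:
    """PCA of the standardized matrix; components ordered by explained variance.

    If fewer than ``n_components`` directions exist (n_subjects - 1), the
    available number is retained with a warning.
    """
    n_sub = fm.data.shape[0]
    if n_sub < 2:
        raise ValueError("PCA needs >= 2 subjects")
    avail = min(n_components, n_sub - 1, fm.data.shape[1])
    if avail < n_components:
        warnings.warn(f"only {avail} PCA components available; requested {n_components}")
    model = PCA(n_components=avail, svd_solver="full")
    scores = model.fit_transform(fm.data)
    return ComponentSet(
        method="PCA", loadings=model.components_.copy(), scores=scores,
        subjects=list(fm.subjects),
        explained_var_ratio=model.explained_variance_ratio_.copy(),
        channel=fm.channel, condition=fm.condition, kind=fm.kind)


def fit_ica(fm: FeatureMatrix, n_components: int = 5, seed: int = 0,
            max_iter: int = 500, tol: float = 1e-4) -> ComponentSet:
    """FastICA on PCA-whitened data (deflation), seeded for reproducibility.

    Non-convergence is not silent: the returned set carries
    ``converged=False`` so callers can fall back to fewer components.
    """
    if n_components > min(fm.data.shape):
        raise ValueError("n_components exceeds matrix rank bounds")
    rank = int(np.linalg.matrix_rank(fm.data))
    n_use = min(n_components, rank)
    if n_use < 1:
        warnings.warn("feature matrix has no variance; ICA skipped (flagged)")
        return ComponentSet(
            method="ICA", loadings=np.zeros((n_components, fm.data.shape[1])),
            scores=np.zeros((fm.data.shape[0], n_components)),
            subjects=list(fm.subjects), converged=False,
            channel=fm.channel, condition=fm.condition, kind=fm.kind)
    if n_use < n_components:
        warnings.warn(f"matrix rank {rank} < {n_components} requested ICA "
                      "components; fitting the available number (flagged)")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = FastICA(n_components=n_use, algorithm="deflation",
                        whiten="unit-variance", max_iter=max_iter, tol=tol,
                        random_state=seed)
        try:
            scores = model.fit_transform(fm.data)
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"ICA failed numerically ({err}); flagged zero result")
            return ComponentSet(
                method="ICA",
                loadings=np.zeros((n_components, fm.data.shape[1])),
                scores=np.zeros((fm.data.shape[0], n_components)),
                subjects=list(fm.subjects), converged=False,
                channel=fm.channel, condition=fm.condition, kind=fm.kind)
    converged = n_use == n_components and not any(
        "did not converge" in str(w.message).lower() for w in caught)
    return ComponentSet(
        method="ICA", loadings=model.components_.copy(), scores=scores,
        subjects=list(fm.subjects), converged=converged,
        channel=fm.channel, condition=fm.condition, kind=fm.kind)


def fit_ica_with_fallback(fm: FeatureMatrix, n_candidates=(4, 3), seed: int = 0,
                          max_iter: int = 500, tol: float = 1e-4) -> ComponentSet:
    """Try ICA model orders in turn, keeping the first that converges.

    Used for SO-phase maps where the appropriate order is 3 or 4 depending on
    convergence; if none converges the last (flagged) fit is returned.
    """
    cs = None
    for n in n_candidates:
        cs = fit_ica(fm, n, seed=seed, max_iter=max_iter, tol=tol)
        if cs.converged:
            return cs
    return cs


def orient_components(cs: ComponentSet, group_labels: list[str],
                      control: str = "control") -> ComponentSet:
    """Flip component signs so patient groups tend to score above controls.

    For each component, if the majority of patient groups have median score
    below the control median the sign of that component's loading row and
    score column is flipped; the score-loading reconstruction is unchanged.
    """
    labels = np.asarray(group_labels)
    if control not in labels:
        raise ValueError(f"control group {control!r} not present")
    if len(labels) != len(cs.subjects):
        raise ValueError("one group label per subject required")
    signs = np.ones(cs.n_components)
    ctrl = labels == control
    patients = [g for g in dict.fromkeys(group_labels) if g != control]
    for k in range(cs.n_components):
        med_c = np.median(cs.scores[ctrl, k])
        above = sum(np.median(cs.scores[labels == g, k]) >= med_c for g in patients)
        below = len(patients) - above
        if below > above:
            signs[k] = -1.0
    out = ComponentSet(
        method=cs.method, loadings=cs.loadings * signs[:, None],
        scores=cs.scores * signs[None, :], subjects=list(cs.subjects),
        explained_var_ratio=None if cs.explained_var_ratio is None
        else cs.explained_var_ratio.copy(),
        orientation_signs=signs, converged=cs.converged,
        channel=cs.channel, condition=cs.condition, kind=cs.kind)
    return out


def group_patterns(component_sets: list[ComponentSet], threshold: float = 0.7,
                   prefix: str = "P") -> PatternCatalogue:
    """Greedy centroid clustering of loading maps on absolute Pearson r.

    All components from all sets are pooled; repeatedly, the unassigned
    component with the most unassigned neighbours at |r| >= threshold seeds a
    pattern, absorbs those neighbours, and its centroid is their (sign-
    aligned) mean loading. Patterns are named by descending member count;
    singletons are allowed. Every member correlates with its centroid at
    |r| >= threshold.
    """
    if len(component_sets) < 2:
        raise ValueError("need >= 2 component sets to group patterns")
    items = []
    for cs in component_sets:
        for k in range(cs.n_components):
            items.append(((cs.channel, cs.condition, cs.method, k),
                          cs.loadings[k]))
    n = len(items)
    vecs = np.stack([v for _, v in items])
    sd = vecs.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zn = (vecs - vecs.mean(axis=1, keepdims=True)) / sd
    R = np.abs(zn @ zn.T / vecs.shape[1])
    np.fill_diagonal(R, 1.0)

    def _zcorr(v: np.ndarray) -> np.ndarray:
        zc = (v - v.mean()) / (v.std() or 1.0)
        return zn @ zc / v.shape[0]

    unassigned = set(range(n))
    clusters: list[tuple[list[int], np.ndarray]] = []
    while unassigned:
        idx = sorted(unassigned)
        sub = R[np.ix_(idx, idx)] >= threshold
        seed_pos = int(np.argmax(sub.sum(axis=1)))
        seed = idx[seed_pos]
        members = [idx[j] for j in range(len(idx)) if sub[seed_pos, j]]
        # refine against the sign-aligned centroid so every member keeps
        # |r| >= threshold with it (the guarantee the catalogue advertises)
        centroid = vecs[seed]
        for _ in range(3):
            signs = np.sign(_zcorr(centroid)[members])
            signs[signs == 0] = 1.0
            centroid = np.mean(vecs[members] * signs[:, None], axis=0)
            r = np.abs(_zcorr(centroid)[members])
            ok = [m for m, ri in zip(members, r) if ri >= threshold]
            if seed not in ok:
                members, centroid = [seed], vecs[seed]
                break
            if len(ok) == len(members):
                break
            members = ok
        clusters.append((members, centroid))
        unassigned -= set(members)

    clusters.sort(key=lambda c: len(c[0]), reverse=True)
    names, member_map, centroids = [], {}, {}
    for i, (cl, centroid) in enumerate(clusters, start=1):
        name = f"{prefix}{i}"
        names.append(name)
        member_map[name] = [items[j][0] for j in cl]
        centroids[name] = centroid
    return PatternCatalogue(names, member_map, centroids, threshold)


def project(hist: CoupledHistogram, cs: ComponentSet, fm: FeatureMatrix) -> np.ndarray:
    """Score a (possibly new) histogram against a fitted component set.

    Standardizes with the training column stats, then multiplies by the
    loadings; training subjects reproduce their stored scores. Only valid for
    PCA sets, whose loadings are the orthonormal projection basis.
    """
    if hist.values.shape != fm.grid_shape:
        raise ValueError("histogram grid does not match the training grid")
    x = hist.values.ravel(order="C")
    z = (x - fm.col_means) / fm.col_sds
    z[fm.constant_cols] = 0.0
    return cs.loadings @ z
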