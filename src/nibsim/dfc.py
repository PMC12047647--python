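"""Dynamic functional connectivity: sliding-window FC, states, fluidity.

Functional connectivity (Pearson correlation between node signals) is
computed over sliding windows, giving a time series of network-state
representations.  Recurring states are identified by k-means clustering of
the vectorized FC matrices, visualized by PCA projection (component
loadings reshape back to symmetric matrices), and summarized by occupancy
fractions, dwell times and the state-transition rate — the latter serving
as the fluidity proxy, complemented by the variance of pairwise window-FC
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["DFCSeries", "StateModel", "sliding_fc", "cluster_states",
           "pca_project", "state_statistics", "fc_variance_fluidity"]


@dataclass
class DFCSeries:
    """Windowed FC matrices and their vectorized upper triangles."""

    window_centers: np.ndarray    # (n_windows,) seconds
    window_s: float
    overlap: float
    fc: np.ndarray                # (n_windows, n, n)
    vectors: np.ndarray           # (n_windows, n(n-1)/2) upper triangles

    @property
    def n_windows(self) -> int:
        return len(self.fc)

    @property
    def step_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)


@dataclass
class StateModel:
    """Clustered + PCA-projected representation of a DFC series."""

    k: int
    centers: np.ndarray            # (k, n_pairs) in FC-vector space
    labels: np.ndarray             # (n_windows,)
    inertia: float = np.nan
    components: np.ndarray | None = None        # (n_pc, n_pairs)
    explained_variance_ratio: np.ndarray | None = None
    projected: np.ndarray | None = None         # (n_windows, n_pc)
    occupancy: np.ndarray | None = None
    mean_dwell_s: np.ndarray | None = None
    transition_rate_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def center_matrix(self, j: int) -> np.ndarray:
        return _unvectorize(self.centers[j])

    def component_matrix(self, j: int) -> np.ndarray:
        """PCA component reshaped to a symmetric FC-space matrix (zero diag)."""
        if self.components is None:
            raise ValueError("run pca_project first")
        return _unvectorize(self.components[j])


def _unvectorize(vec: np.ndarray) -> np.ndarray:
    m = len(vec)
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    return out + out.T


def sliding_fc(signals: np.ndarray, fs: float, window_s: float = 10.0,
               overlap: float = 0.5) -> DFCSeries:
    """Pearson-correlation FC over sliding windows.

    ``signals`` is (n_nodes, n_samples).  The number of windows is
    ``floor((T - L) / (L (1 - overlap))) + 1`` for T samples of data and
    window length L; a zero-variance node in any window is an error (a
    constant signal carries no correlation structure).
    """
    x = np.asarray(signals, float)
    if x.ndim != 2:
        raise ValueError("signals must be (n_nodes, n_samples)")
    L = int(round(window_s * fs))
    if L < 2:
        raise ValueError("window must contain at least 2 samples")
    step = int(round(L * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too close to 1 for this window")
    T = x.shape[1]
    if T < L:
        raise ValueError("signal shorter than one window")
    n_win = (T - L) // step + 1
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    fc = np.empty((n_win, n, n))
    vecs = np.empty((n_win, len(iu[0])))
    centers = np.empty(n_win)
    for w in range(n_win):
        seg = x[:, w * step: w * step + L]
        sd = seg.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if len(dead):
            raise ValueError(
                f"zero-variance node(s) {dead.tolist()} in window {w}")
        c = np.corrcoef(seg)
        fc[w] = c
        vecs[w] = c[iu]
        centers[w] = (w * step + L / 2) / fs
    return DFCSeries(window_centers=centers, window_s=window_s, overlap=overlap,
                     fc=fc, vectors=vecs)


def cluster_states(dfc: DFCSeries, k: int, seed: int = 0,
                   n_init: int = 10) -> StateModel:
    """K-means network states on the FC upper-triangle vectors."""
    if not 1 <= k <= dfc.n_windows:
        raise ValueError("k must be between 1 and the number of windows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(dfc.vectors)
    return StateModel(k=k, centers=km.cluster_centers_,
                      labels=km.labels_.astype(int), inertia=float(km.inertia_))


def pca_project(dfc: DFCSeries, n_components: int = 2,
                model: StateModel | None = None) -> StateModel:
    """Mean-centered PCA of the FC vectors; fills the projection fields.

    Without an existing :class:`StateModel` a trivial single-state model is
    created to carry the projection.
    """
    n_components = min(n_components, dfc.n_windows, dfc.vectors.shape[1])
    pca = PCA(n_components=n_components).fit(dfc.vectors)
    if model is None:
        model = StateModel(k=1, centers=dfc.vectors.mean(0, keepdims=True),
                           labels=np.zeros(dfc.n_windows, int))
    model.components = pca.components_
    model.explained_variance_ratio = pca.explained_variance_ratio_
    model.projected = pca.transform(dfc.vectors)
    return model


def state_statistics(model: StateModel, dfc: DFCSeries) -> StateModel:
    """Occupancy, mean dwell time and transition rate of the label sequence.

    The transition rate (state changes per second of window-center time) is
    the fluidity proxy.
    """
    lab = model.labels
    occ = np.bincount(lab, minlength=model.k) / len(lab)
    step = dfc.step_s
    dwell = np.full(model.k, np.nan)
    runs = {j: [] for j in range(model.k)}
    start = 0
    for i in range(1, len(lab) + 1):
        if i == len(lab) or lab[i] != lab[start]:
            runs[lab[start]].append((i - start) * step)
            start = i
    for j in range(model.k):
        if runs[j]:
            dwell[j] = float(np.mean(runs[j]))
    n_trans = int(np.sum(lab[1:] != lab[:-1]))
    span = (len(lab) - 1) * step
    model.occupancy = occ
    model.mean_dwell_s = dwell
    model.transition_rate_hz = n_trans / span if span > 0 else 0.0
    return model


def block_loading_pvalue(component_matrix: np.ndarray, hemisphere: np.ndarray,
                         n_perm: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Permutation test: does a PC load on inter-hemispheric blocks?

    The statistic is the mean absolute loading over cross-hemisphere node
    pairs minus the within-hemisphere mean; the null permutes the
    hemisphere assignment of the nodes.  Returns (statistic, p_value).
    A small p with a positive statistic means the component predominantly
    reflects inter-hemispheric coupling.
    """
    m = np.abs(np.asarray(component_matrix, float))
    hemi = np.asarray(hemisphere)
    n = len(hemi)
    iu = np.triu_indices(n, k=1)
    vals = m[iu]

    def stat(h):
        cross = h[iu[0]] != h[iu[1]]
        return vals[cross].mean() - vals[~cross].mean()

    obs = stat(hemi)
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.permutation(hemi)) for _ in range(n_perm)])
    p = (1 + np.sum(null >= obs)) / (1 + n_perm)
    return float(obs), float(p)


def fc_variance_fluidity(dfc: DFCSeries) -> float:
    """Secondary fluidity measure: variance of pairwise window-FC correlations.

    High variance means windows alternate between similar and dissimilar
    connectivity patterns, i.e. richer state dynamics.
    """
    v = dfc.vectors - dfc.vectors.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(v, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    sim = (v / nrm) @ (v / nrm).T
    iu = np.triu_indices(dfc.n_windows, k=1)
    return float(np.var(sim[iu]))
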