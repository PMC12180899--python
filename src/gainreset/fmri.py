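"""Parcel-level BOLD analysis: low-dimensional trajectories and topology.

The pipeline mirrors the macroscale test of the gain-reset hypothesis:

1. group PCA of standardised parcel time series pools subjects into a
   shared low-dimensional space;
2. each principal-component time series is modelled with an ordinary
   least-squares GLM whose nine regressors are switch-locked event
   trains (first two images; the seven images centred on the perceptual
   switch, Delta = -3..+3; last two images) convolved with a canonical
   double-gamma haemodynamic response function;
3. a block-resampling permutation null (switch labels shuffled across
   picture sets, design rebuilt per permutation) calibrates the evoked
   beta values;
4. the main BOLD displacement (MBD = |beta|) and its surprisal per unit
   displacement ("landscape depth") quantify the flattening of the
   egocentric energy landscape around the switch;
5. signed-modularity Louvain consensus clustering of functional
   connectivity plus cartographic profiling (participation coefficient,
   module-degree z-score) relate switch-evoked engagement to network
   integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParcelDataset",
    "EventDesign",
    "GroupPCAResult",
    "GLMResult",
    "CartographicProfile",
    "group_pca",
    "canonical_hrf",
    "build_event_design",
    "pc_glm",
    "beta_gradient",
    "block_resample_null",
    "mbd_energy",
    "group_mbd",
    "signed_modularity",
    "louvain_signed",
    "consensus_louvain",
    "cartography",
    "cartographic_correlation",
]

N_EVENT_TYPES = 9  # first-two, Delta -3..+3, last-two
SWITCH_REGRESSOR = 4  # index of the Delta = 0 regressor


@dataclass
class ParcelDataset:
    """Per-subject region x time matrices with event annotations.

    ``events`` has one row per presented image with columns
    (subject, set_id, image_index, onset_s, is_switch); ``image_index``
    runs 1..15 within each picture set and ``is_switch`` marks the image
    on which the perceptual switch was reported.
    """

    data: list[np.ndarray]  # each (n_regions, T)
    events: pd.DataFrame
    tr_s: float = 2.0
    subject_ids: Optional[list] = None

    def __post_init__(self) -> None:
        if self.subject_ids is None:
            self.subject_ids = list(range(len(self.data)))
        required = {"subject", "set_id", "image_index", "onset_s", "is_switch"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")

    @property
    def n_regions(self) -> int:
        return self.data[0].shape[0]


@dataclass
class EventDesign:
    """HRF-convolved design matrix for the nine switch-locked event types."""

    matrix: np.ndarray  # (T, 9)
    names: list[str]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


@dataclass
class GroupPCAResult:
    loadings: np.ndarray  # (n_regions, k)
    variance_explained: np.ndarray  # (k,), percent
    subject_scores: list[np.ndarray]  # per subject (T, k)


@dataclass
class GLMResult:
    betas: np.ndarray  # (9,)
    pvalues: np.ndarray  # (9,), two-sided parameter p-values
    intercept: float
    residuals: np.ndarray
    r_squared: float


def group_pca(
    dataset: ParcelDataset, k: int = 10, standardise: bool = True
) -> GroupPCAResult:
    """PCA over subjects' concatenated parcel time series.

    With ``standardise`` (default) each region's time series is z-scored
    within subject before concatenation so regions with different signal
    scales contribute comparably.  Loadings are spatial maps over
    regions; per-subject PC time courses are obtained by projecting each
    subject's (standardised) data onto the group loadings.
    """
    from sklearn.decomposition import PCA

    n_regions = dataset.n_regions
    standardised = []
    for idx, mat in enumerate(dataset.data):
        if mat.shape[0] != n_regions:
            raise ValueError(
                f"subject {dataset.subject_ids[idx]} has {mat.shape[0]} regions, "
                f"expected {n_regions}"
            )
        centred = mat - mat.mean(axis=1, keepdims=True)
        if standardise:
            sd = mat.std(axis=1, keepdims=True)
            if np.any(sd == 0):
                bad = np.where(sd[:, 0] == 0)[0]
                raise ValueError(f"constant region time series: regions {bad.tolist()}")
            centred = centred / sd
        standardised.append(centred)
    stacked = np.hstack(standardised).T  # (T_total, n_regions)
    k = min(k, *stacked.shape)
    pca = PCA(n_components=k)
    pca.fit(stacked)
    loadings = pca.components_.T
    scores = [(s.T - pca.mean_) @ loadings for s in standardised]
    return GroupPCAResult(loadings, 100.0 * pca.explained_variance_ratio_, scores)


def canonical_hrf(
    tr_s: float,
    duration_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    ratio: float = 6.0,
    dispersion_s: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, unit-peak normalised.

    h(t) = pdf_gamma(t; peak_delay) - pdf_gamma(t; undershoot_delay) / ratio
    with unit dispersion; the kernel starts at 0, peaks near 5 s and has
    a late undershoot.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, duration_s + 1e-9, tr_s)
    h = stats.gamma.pdf(t, peak_delay_s / dispersion_s, scale=dispersion_s) - (
        stats.gamma.pdf(t, undershoot_delay_s / dispersion_s, scale=dispersion_s) / ratio
    )
    return h / h.max()


def _event_type(image_index: int, switch_index: Optional[int], n_images: int = 15):
    """Regressor indices an image contributes to (possibly several)."""
    out = []
    if image_index <= 2:
        out.append(0)
    if image_index >= n_images - 1:
        out.append(8)
    if switch_index is not None:
        delta = image_index - switch_index
        if -3 <= delta <= 3:
            out.append(1 + delta + 3)
    return out


def build_event_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr_s: float = 2.0,
    hrf: Optional[np.ndarray] = None,
    switch_override: Optional[dict] = None,
) -> EventDesign:
    """Nine HRF-convolved event regressors for one subject's run.

    ``switch_override`` maps set_id to a replacement switch image index
    (used by the block-resampling null to move switch labels across
    sets without touching the recorded events).
    """
    hrf = canonical_hrf(tr_s) if hrf is None else hrf
    trains = np.zeros((n_volumes, N_EVENT_TYPES))
    for set_id, grp in events.groupby("set_id"):
        n_images = int(grp["image_index"].max())
        sw = grp.loc[grp["is_switch"].astype(bool), "image_index"]
        switch_index = int(sw.iloc[0]) if len(sw) else None
        if switch_override is not None:
            switch_index = switch_override.get(set_id, switch_index)
        for _, row in grp.iterrows():
            vol = int(round(row["onset_s"] / tr_s))
            if not 0 <= vol < n_volumes:
                raise ValueError(
                    f"event onset {row['onset_s']} s outside run (set {set_id})"
                )
            for reg in _event_type(int(row["image_index"]), switch_index, n_images):
                trains[vol, reg] += 1.0
    mat = np.empty_like(trains)
    for j in range(N_EVENT_TYPES):
        mat[:, j] = np.convolve(trains[:, j], hrf)[:n_volumes]
    names = ["first_two"] + [f"delta_{d:+d}" for d in range(-3, 4)] + ["last_two"]
    return EventDesign(mat, names)


def pc_glm(pc_ts: np.ndarray, design: EventDesign, cond_max: float = 1e8) -> GLMResult:
    """OLS fit of one PC time series on the event design (with intercept)."""
    import statsmodels.api as sm

    y = np.asarray(pc_ts, dtype=float)
    if len(y) != design.matrix.shape[0]:
        raise ValueError("time series and design lengths differ")
    X = sm.add_constant(design.matrix, has_constant="add")
    if np.linalg.cond(X) > cond_max:
        raise ValueError("design matrix is (near-)collinear")
    fit = sm.OLS(y, X).fit()
    return GLMResult(
        betas=fit.params[1:],
        pvalues=fit.pvalues[1:],
        intercept=float(fit.params[0]),
        residuals=fit.resid,
        r_squared=float(fit.rsquared),
    )


def beta_gradient(betas: np.ndarray) -> np.ndarray:
    """Successive differences of the nine ordered beta values."""
    betas = np.asarray(betas, dtype=float)
    return np.diff(betas)


def block_resample_null(
    pc_ts: np.ndarray,
    events: pd.DataFrame,
    n_perm: int = 5000,
    seed: Optional[int] = None,
    tr_s: float = 2.0,
    hrf: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-resampling null for the evoked betas.

    The resampling unit is the picture set: each permutation reassigns
    the sets' switch image indices by a random permutation across sets,
    rebuilds the design, and refits the GLM.  Returns the null |beta|
    array (n_perm, 9) and the per-regressor 95th percentiles.
    """
    rng = np.random.default_rng(seed)
    hrf = canonical_hrf(tr_s) if hrf is None else hrf
    n_vol = len(pc_ts)
    set_ids = []
    switches = []
    for set_id, grp in events.groupby("set_id"):
        sw = grp.loc[grp["is_switch"].astype(bool), "image_index"]
        if len(sw):
            set_ids.append(set_id)
            switches.append(int(sw.iloc[0]))
    switches = np.asarray(switches)
    n_sets = len(set_ids)
    if n_sets < 2:
        raise ValueError("need at least two sets with switches to resample")

    # The first-two/last-two regressors do not depend on the switch
    # assignment; only the seven switch-locked trains move.  Precompute
    # each set's image-onset volumes so a permutation is a cheap
    # re-binning plus seven convolutions.
    base_design = build_event_design(
        events, n_vol, tr_s, hrf, switch_override={s: None for s in set_ids}
    ).matrix  # switch regressors all zero here
    onset_by_set = {
        set_id: dict(
            zip(
                grp["image_index"].astype(int),
                (grp["onset_s"] / tr_s).round().astype(int),
            )
        )
        for set_id, grp in events.groupby("set_id")
    }
    X = np.empty((n_vol, N_EVENT_TYPES + 1))
    X[:, 0] = 1.0
    X[:, 1:] = base_design
    y = np.asarray(pc_ts, dtype=float)
    null = np.empty((n_perm, N_EVENT_TYPES))
    switch_cols = 1 + 1 + np.arange(7)  # intercept + first_two, then delta -3..+3
    for p in range(n_perm):
        perm = rng.permutation(n_sets)
        trains = np.zeros((n_vol, 7))
        for i, set_id in enumerate(set_ids):
            v = switches[perm[i]]
            onsets = onset_by_set[set_id]
            for d in range(-3, 4):
                vol = onsets.get(v + d)
                if vol is not None:
                    trains[vol, d + 3] += 1.0
        for j in range(7):
            X[:, switch_cols[j]] = np.convolve(trains[:, j], hrf)[:n_vol]
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        null[p] = np.abs(beta[1:])
    return null, np.percentile(null, 95, axis=0)


def mbd_energy(
    betas: np.ndarray,
    p_nonzero: np.ndarray,
    p_min: float = 1e-12,
) -> pd.DataFrame:
    """Main BOLD displacement, its surprisal, and the landscape depth.

    ``p_nonzero`` is the probability, per regressor, that the evoked
    value differs from zero (the complement of the GLM parameter
    p-value).  The energy of a displacement is its surprisal
    E = ln(1/p); the depth is energy per unit displacement, E / |beta|,
    which bottoms out where large displacements are unsurprising — at
    the perceptual switch.
    """
    betas = np.asarray(betas, dtype=float)
    p = np.clip(np.asarray(p_nonzero, dtype=float), p_min, 1.0)
    mbd = np.abs(betas)
    energy = np.log(1.0 / p)
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = np.where(mbd > 0, energy / mbd, np.inf)
    return pd.DataFrame({"MBD": mbd, "energy": energy, "depth": depth})


def group_mbd(betas_per_subject: np.ndarray, p_min: float = 1e-12) -> pd.DataFrame:
    """Group-level MBD table from per-subject evoked betas.

    The displacement per regressor is the absolute group-mean beta; the
    probability that the evoked value differs from zero comes from a
    one-sample t-test across subjects (its complement p-value), which
    keeps the surprisal on a comparable scale across regressors.
    """
    b = np.asarray(betas_per_subject, dtype=float)
    t, pval = stats.ttest_1samp(b, 0.0, axis=0)
    return mbd_energy(b.mean(axis=0), 1.0 - pval, p_min=p_min)


# --------------------------------------------------------------------------
# signed modularity, Louvain consensus, cartography
# --------------------------------------------------------------------------


def _split_signs(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    return np.clip(W, 0, None), np.clip(-W, 0, None)


def signed_modularity(
    W: np.ndarray, partition: np.ndarray, struct_gamma: float = 1.0
) -> float:
    """Signed modularity Q_T of a partition.

    Positive weights reward within-module concentration normalised by
    the total positive weight; negative weights penalise it, weighted by
    v- / (v+ + v-) relative to their own null model.  ``struct_gamma``
    scales the degree-based null expectations (the resolution
    parameter).
    """
    Wp, Wn = _split_signs(W)
    labels = np.asarray(partition)
    if Wp.sum() == 0 and Wn.sum() == 0:
        raise ValueError("all-zero matrix: modularity undefined")
    same = labels[:, None] == labels[None, :]
    q = 0.0
    vp = Wp.sum()
    if vp > 0:
        kp = Wp.sum(axis=1)
        ep = struct_gamma * np.outer(kp, kp) / vp
        q += ((Wp - ep) * same).sum() / vp
    vn = Wn.sum()
    if vn > 0:
        kn = Wn.sum(axis=1)
        en = struct_gamma * np.outer(kn, kn) / vn
        q -= ((Wn - en) * same).sum() / (vp + vn)
    return float(q)


def _louvain_one_level(
    Wp: np.ndarray, Wn: np.ndarray, struct_gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Greedy node-moving phase of Louvain on a signed graph."""
    n = Wp.shape[0]
    labels = np.arange(n)
    kp = Wp.sum(axis=1)
    kn = Wn.sum(axis=1)
    vp = Wp.sum()
    vn = Wn.sum()
    Sp = kp.copy()  # community positive strengths (labels start singleton)
    Sn = kn.copy()
    wp_scale = 1.0 / vp if vp > 0 else 0.0
    wn_scale = 1.0 / (vp + vn) if (vp + vn) > 0 else 0.0
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            li = labels[i]
            Sp[li] -= kp[i]
            Sn[li] -= kn[i]
            labels[i] = -1
            # links from i to each community
            neigh = np.unique(labels[(Wp[i] > 0) | (Wn[i] > 0)])
            neigh = neigh[neigh >= 0]
            candidates = np.unique(np.append(neigh, li))
            best_gain, best_c = -np.inf, li
            for c in candidates:
                in_c = labels == c
                gain = 0.0
                if vp > 0:
                    gain += wp_scale * (
                        Wp[i, in_c].sum() - struct_gamma * kp[i] * Sp[c] / vp
                    )
                if vn > 0:
                    gain -= wn_scale * (
                        Wn[i, in_c].sum() - struct_gamma * kn[i] * Sn[c] / vn
                    )
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            labels[i] = best_c
            Sp[best_c] += kp[i]
            Sn[best_c] += kn[i]
            if best_c != li:
                improved = True
    # relabel 0..K-1
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _aggregate(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    K = labels.max() + 1
    M = np.zeros((len(labels), K))
    M[np.arange(len(labels)), labels] = 1.0
    return M.T @ W @ M


def louvain_signed(
    W: np.ndarray,
    struct_gamma: float = 1.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """One randomised Louvain run maximising signed modularity."""
    rng = np.random.default_rng(seed)
    Wp, Wn = _split_signs(W)
    n = W.shape[0]
    labels = np.arange(n)
    cur_p, cur_n = Wp, Wn
    node_labels = labels.copy()
    while True:
        lv = _louvain_one_level(cur_p, cur_n, struct_gamma, rng)
        node_labels = lv[node_labels]
        if lv.max() + 1 == cur_p.shape[0]:
            break  # no merge happened
        cur_p = _aggregate(cur_p, lv)
        cur_n = _aggregate(cur_n, lv)
    _, node_labels = np.unique(node_labels, return_inverse=True)
    return node_labels


def _agreement_consensus(
    partitions: np.ndarray,
    tau: float = 0.5,
    seed: Optional[int] = None,
    max_iter: int = 50,
    n_recluster: int = 16,
) -> np.ndarray:
    """Consensus partition by iterative clustering of the agreement matrix.

    The agreement probability D (fraction of partitions placing two
    nodes together) is re-clustered as the signed matrix D - tau —
    co-assignment above chance attracts, below repels — until all runs
    agree.  Raises with diagnostics if the consensus cycles.
    """
    rng = np.random.default_rng(seed)
    parts = np.asarray(partitions)
    D = None
    for _ in range(max_iter):
        if all(_same_partition(parts[0], parts[r]) for r in range(1, len(parts))):
            return _canonical_labels(parts[0])
        D = np.zeros((parts.shape[1], parts.shape[1]))
        for r in range(len(parts)):
            D += parts[r][:, None] == parts[r][None, :]
        D /= len(parts)
        np.fill_diagonal(D, 0.0)
        A = D - tau
        np.fill_diagonal(A, 0.0)
        if not (A > 0).any():
            # no agreement above threshold: everything is its own module
            return np.arange(parts.shape[1])
        parts = np.stack(
            [
                louvain_signed(A, 1.0, seed=int(rng.integers(2**31)))
                for _ in range(n_recluster)
            ]
        )
    raise RuntimeError(
        f"consensus did not converge in {max_iter} iterations "
        f"(last agreement range {D.min():.2f}-{D.max():.2f})"
    )


def _canonical_labels(a: np.ndarray) -> np.ndarray:
    """Relabel communities in order of first appearance (0, 1, 2, ...)."""
    mapping: dict = {}
    out = np.empty(len(a), dtype=int)
    for i, v in enumerate(a):
        out[i] = mapping.setdefault(v, len(mapping))
    return out


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    return np.array_equal(_canonical_labels(a), _canonical_labels(b))


def consensus_louvain(
    W: np.ndarray,
    gamma_range: Sequence[float] = tuple(np.arange(0.5, 2.01, 0.1)),
    reps: int = 500,
    seed: Optional[int] = None,
    hierarchical: bool = True,
    min_module_size: int = 4,
    tau: float = 0.5,
) -> np.ndarray:
    """Hierarchical consensus partition over repeated Louvain runs.

    Louvain is run ``reps`` times spread across the resolution range;
    the runs are collapsed with an agreement-matrix consensus.  With
    ``hierarchical`` the procedure is repeated once inside each
    first-level module (on the submatrix); a sub-split is accepted only
    if it does not lower the global signed modularity at resolution 1,
    so flat structure stays flat.
    """
    rng = np.random.default_rng(seed)
    gammas = np.asarray(list(gamma_range), dtype=float)
    parts = []
    for r in range(reps):
        g = gammas[r % len(gammas)]
        parts.append(louvain_signed(W, g, seed=int(rng.integers(2**31))))
    labels = _agreement_consensus(
        np.stack(parts), tau=tau, seed=int(rng.integers(2**31))
    )
    if not hierarchical:
        return labels
    out = labels.copy()
    next_label = labels.max() + 1
    for m in np.unique(labels):
        idx = np.where(labels == m)[0]
        if len(idx) < min_module_size:
            continue
        sub = W[np.ix_(idx, idx)]
        if np.abs(sub).sum() == 0:
            continue
        sub_parts = [
            louvain_signed(sub, gammas[r % len(gammas)], seed=int(rng.integers(2**31)))
            for r in range(max(8, reps // max(1, len(np.unique(labels)))))
        ]
        try:
            sub_labels = _agreement_consensus(
                np.stack(sub_parts), tau=tau, seed=int(rng.integers(2**31))
            )
        except RuntimeError:
            continue  # unstable sub-structure: keep the first-level module
        if sub_labels.max() > 0:
            candidate = out.copy()
            base = next_label
            for sm in np.unique(sub_labels)[1:]:
                candidate[idx[sub_labels == sm]] = base
                base += 1
            if signed_modularity(W, candidate, 1.0) >= signed_modularity(W, out, 1.0):
                out = candidate
                next_label = base
    _, out = np.unique(out, return_inverse=True)
    return out


@dataclass
class CartographicProfile:
    """Participation coefficient and module-degree z-score per region."""

    participation: np.ndarray
    module_z: np.ndarray


def cartography(W: np.ndarray, partition: np.ndarray) -> CartographicProfile:
    """Integration/segregation profile on the positive weights.

    P_i = 1 - sum_m (kappa_im / k_i)^2 measures how evenly node i's
    positive strength spreads over modules; the module-degree z-score
    standardises its within-module strength against its module's
    distribution.  Isolated nodes get P = 0 (flagged via a warning).
    """
    Wp, _ = _split_signs(W)
    labels = np.asarray(partition)
    n = Wp.shape[0]
    k = Wp.sum(axis=1)
    modules = np.unique(labels)
    kappa = np.stack([Wp[:, labels == m].sum(axis=1) for m in modules], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, kappa / k[:, None], 0.0)
    P = 1.0 - (frac**2).sum(axis=1)
    P[k == 0] = 0.0
    if np.any(k == 0):
        warnings.warn(
            f"{int((k == 0).sum())} isolated node(s): participation set to 0",
            stacklevel=2,
        )
    within = kappa[np.arange(n), np.searchsorted(modules, labels)]
    z = np.zeros(n)
    for mi, m in enumerate(modules):
        grp = labels == m
        mu = within[grp].mean()
        sd = within[grp].std()
        z[grp] = (within[grp] - mu) / sd if sd > 0 else 0.0
    return CartographicProfile(P, z)


def cartographic_correlation(
    profiles: Sequence[CartographicProfile],
    beta_sums: Sequence[float],
    n_perm: int = 5000,
    seed: Optional[int] = None,
    n_bins: int = 101,
    p_range: tuple[float, float] = (0.0, 1.0),
    z_range: tuple[float, float] = (-1.0, 1.0),
    min_subjects: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Correlate joint-histogram occupancy with switch-evoked engagement.

    Each subject's regions are binned into an ``n_bins x n_bins`` joint
    histogram over (participation, module-degree z); the count in each
    bin is correlated across subjects with the subject's combined
    regression weight (sum of the switch betas for the second and third
    components).  Significance is assessed by permuting the subject
    labels of the beta sums.  Bins occupied by fewer than
    ``min_subjects`` subjects are excluded.
    """
    beta_sums = np.asarray(list(beta_sums), dtype=float)
    n_subj = len(beta_sums)
    if n_subj < 5:
        raise ValueError("need at least 5 subjects")
    if np.std(beta_sums) == 0:
        warnings.warn("constant beta sums: correlation undefined", stacklevel=2)
        shape = (n_bins, n_bins)
        return {
            "r": np.full(shape, np.nan),
            "p": np.full(shape, np.nan),
            "significant": np.zeros(shape, dtype=bool),
            "occupancy": np.zeros(shape, dtype=int),
        }
    p_edges = np.linspace(*p_range, n_bins + 1)
    z_edges = np.linspace(*z_range, n_bins + 1)
    hists = np.stack(
        [
            np.histogram2d(
                np.clip(prof.participation, *p_range),
                np.clip(prof.module_z, *z_range),
                bins=[p_edges, z_edges],
            )[0]
            for prof in profiles
        ]
    )  # (n_subj, n_bins, n_bins)
    occupancy = (hists > 0).sum(axis=0)
    usable = occupancy >= min_subjects
    flat = hists.reshape(n_subj, -1)
    mask = usable.ravel()
    # vectorised Pearson r across subjects per usable bin
    def _corr(bs: np.ndarray) -> np.ndarray:
        x = flat[:, mask]
        xc = x - x.mean(axis=0)
        yc = bs - bs.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, np.nan)

    r_obs = _corr(beta_sums)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(r_obs.shape)
    valid = np.isfinite(r_obs)
    for _ in range(n_perm):
        r_null = _corr(rng.permutation(beta_sums))
        exceed += np.abs(np.nan_to_num(r_null)) >= np.abs(np.nan_to_num(r_obs))
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    pvals[~valid] = np.nan

    r_map = np.full(n_bins * n_bins, np.nan)
    p_map = np.full(n_bins * n_bins, np.nan)
    r_map[mask] = r_obs
    p_map[mask] = pvals
    r_map = r_map.reshape(n_bins, n_bins)
    p_map = p_map.reshape(n_bins, n_bins)
    return {
        "r": r_map,
        "p": p_map,
        "significant": np.nan_to_num(p_map, nan=1.0) < alpha,
        "occupancy": occupancy.astype(int),
    }
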