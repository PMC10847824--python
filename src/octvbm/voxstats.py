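"""Voxel-wise statistics: GLM, FDR and cluster-extent correction.

At every unmasked voxel an ordinary least-squares GLM

    thickness ~ intercept + group + age + sex + retina_thickness(voxel)

is fitted across subjects (the total retinal thickness at that voxel
enters as a per-voxel covariate).  Group effects are tested with a
contrast t (two groups) or an omnibus F (several groups).  Multiplicity
is handled in two steps: Benjamini-Hochberg FDR over all valid voxels of
one layer's map, then removal of significant-voxel connected components
smaller than a minimum extent (default 9 voxels, 8-connectivity).

All fits are solved in one batched normal-equations pass across voxels;
per-voxel missing data is handled with 0/1 weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, DesignError, StackError
from .mapping import FoveaMask, GroupStack

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_CLUSTER_VOXELS = 9
DEFAULT_CONNECTIVITY = 8


@dataclass
class GLMSpec:
    """Design of one voxel-wise comparison."""

    covariates: Tuple[str, ...] = ("age", "sex", "retina")
    contrast: str = "two-group-t"          # or "omnibus-F"
    reference_group: str = "HC"
    alpha: float = DEFAULT_ALPHA
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS
    connectivity: int = DEFAULT_CONNECTIVITY

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise DesignError("alpha must be in (0, 1)")
        if self.min_cluster_voxels < 1:
            raise DesignError("min_cluster_voxels must be >= 1")
        if self.connectivity not in (4, 8):
            raise DesignError("connectivity must be 4 or 8")
        unknown = set(self.covariates) - {"age", "sex", "retina"}
        if unknown:
            raise DesignError(f"unknown covariates {sorted(unknown)}")


@dataclass
class StatMapSet:
    """Per-voxel results of one voxel-wise comparison."""

    stat: np.ndarray                       # t or F grid
    p: np.ndarray                          # raw p grid
    sig: np.ndarray                        # after FDR + cluster filter
    clusters: np.ndarray                   # integer label grid (0 = none)
    q_threshold: float                     # realized BH p cutoff
    diff: Optional[np.ndarray]             # adjusted mean difference (um)
    n_effective: np.ndarray                # per-voxel subjects used
    beta: Dict[str, np.ndarray] = field(default_factory=dict)
    stat_kind: str = "t"
    alpha: float = DEFAULT_ALPHA
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS
    connectivity: int = DEFAULT_CONNECTIVITY

    @property
    def n_significant(self) -> int:
        return int(self.sig.sum())


# ---------------------------------------------------------------------------
# batched least squares
# ---------------------------------------------------------------------------

def _batched_ols(Y: np.ndarray, X: np.ndarray, W: np.ndarray):
    """Weighted OLS at every voxel.

    Y : (n, V) responses (invalid entries arbitrary), X : (V, n, p)
    per-voxel designs, W : (n, V) 0/1 weights.  Returns
    (beta (V, p), xtx_inv (V, p, p), rss (V,), n_valid (V,)).
    Voxels whose normal equations are singular come back NaN.
    """
    n, V = Y.shape
    p = X.shape[2]
    Wv = W.T  # (V, n)
    Yv = np.where(W, Y, 0.0).T  # (V, n)
    Xw = X * Wv[:, :, None]
    xtx = np.einsum("vnp,vnq->vpq", Xw, X)
    xty = np.einsum("vnp,vn->vp", Xw, Yv)
    yty = np.einsum("vn,vn->v", Yv, Yv)
    n_valid = Wv.sum(axis=1)

    beta = np.full((V, p), np.nan)
    xtx_inv = np.full((V, p, p), np.nan)
    ok = n_valid >= p + 1
    if ok.any():
        sub = xtx[ok]
        # guard singular designs voxel-by-voxel via determinant sign of
        # the Cholesky attempt; fall back to pinv where needed
        try:
            inv = np.linalg.inv(sub)
            solvable = np.all(np.isfinite(inv), axis=(1, 2))
        except np.linalg.LinAlgError:
            inv = np.empty_like(sub)
            solvable = np.zeros(sub.shape[0], dtype=bool)
            for i in range(sub.shape[0]):
                try:
                    inv[i] = np.linalg.inv(sub[i])
                    solvable[i] = True
                except np.linalg.LinAlgError:
                    inv[i] = np.nan
        xtx_inv[ok] = inv
        b = np.einsum("vpq,vq->vp", inv, xty[ok])
        b[~solvable] = np.nan
        beta[ok] = b
    rss = yty - np.einsum("vp,vp->v", np.nan_to_num(beta), xty)
    rss = np.where(np.isfinite(beta).all(axis=1), rss, np.nan)
    # numerically exact fits can give tiny negative residuals
    rss = np.where(rss < 0, 0.0, rss)
    return beta, xtx_inv, rss, n_valid


def _build_base_design(cov: pd.DataFrame, groups: Sequence[str],
                       reference_group: str,
                       covariates: Tuple[str, ...]):
    """Base (voxel-independent) design columns and their names."""
    n = len(cov)
    cols = [np.ones(n)]
    names = ["intercept"]
    others = [g for g in groups if g != reference_group]
    for g in others:
        cols.append((cov["group"].values == g).astype(float))
        names.append(f"group[{g}]")
    if "age" in covariates:
        cols.append(pd.to_numeric(cov["age"], errors="coerce").values)
        names.append("age")
    if "sex" in covariates:
        cols.append((cov["sex"].values == "M").astype(float))
        names.append("sex")
    return np.column_stack(cols), names, others


def voxelwise_glm(layer_stack: GroupStack,
                  retina_stack: Optional[GroupStack] = None,
                  spec: Optional[GLMSpec] = None,
                  fovea_mask: Optional[FoveaMask] = None) -> StatMapSet:
    """Fit the voxel-wise GLM for one layer and test the group effect.

    ``retina_stack`` supplies the per-voxel total retinal thickness
    covariate when ``"retina"`` is in ``spec.covariates``.  The central
    fovea is excluded through ``fovea_mask``.  Voxels with fewer valid
    subjects than design parameters + 1 are excluded and reported in
    ``n_effective``.
    """
    spec = spec or GLMSpec()
    cov = layer_stack.covariates
    shape = layer_stack.grid_shape
    groups = list(pd.unique(cov["group"]))
    if len(groups) < 2:
        raise DesignError("voxel-wise comparison needs >= 2 groups")
    reference = (spec.reference_group if spec.reference_group in groups
                 else groups[0])
    if spec.contrast == "two-group-t" and len(groups) != 2:
        raise DesignError(
            f"two-group-t contrast needs exactly 2 groups, got {groups}")

    use_retina = "retina" in spec.covariates
    if use_retina:
        if retina_stack is None:
            raise DesignError("retina covariate requested without a "
                              "Retina stack")
        if retina_stack.grid_shape != shape or \
                retina_stack.n_subjects != layer_stack.n_subjects:
            raise StackError("retina stack misaligned with layer stack")

    Xbase, names, test_groups = _build_base_design(
        cov, groups, reference, spec.covariates)
    # subjects with missing base covariates are dropped from every voxel
    subj_ok = np.isfinite(Xbase).all(axis=1)
    n, V = layer_stack.n_subjects, int(np.prod(shape))
    Y = layer_stack.data.reshape(n, V)
    W = np.isfinite(Y) & subj_ok[:, None]
    if use_retina:
        R = retina_stack.data.reshape(n, V)
        W &= np.isfinite(R)

    p_base = Xbase.shape[1]
    p_full = p_base + (1 if use_retina else 0)
    X = np.broadcast_to(Xbase[None, :, :], (V, n, p_base)).copy()
    if use_retina:
        Rcol = np.where(W.T[:, :, None], R.T[:, :, None], 0.0)
        X = np.concatenate([X, Rcol], axis=2)
        names = names + ["retina"]

    if fovea_mask is not None:
        excluded = fovea_mask.mask.reshape(V)
        W = W & ~excluded[None, :]

    beta, xtx_inv, rss, n_valid = _batched_ols(Y, X, W)
    df = n_valid - p_full
    fitted = np.isfinite(beta).all(axis=1) & (df > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = rss / df
    betas = {name: beta[:, j].reshape(shape) for j, name in enumerate(names)}

    stat = np.full(V, np.nan)
    pval = np.full(V, np.nan)
    diff = None
    if spec.contrast == "two-group-t":
        j = names.index(f"group[{test_groups[0]}]")
        se = np.sqrt(sigma2 * xtx_inv[:, j, j])
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta[:, j] / se
        t[~fitted] = np.nan
        stat = t
        pval = np.where(np.isfinite(t),
                        2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)),
                        np.nan)
        # raw (unadjusted) group mean difference: this is what overlays
        # display; the covariate-adjusted effect stays in beta[group[...]]
        in_test = (cov["group"].values == test_groups[0])
        in_ref = (cov["group"].values == reference)
        W_t = W & in_test[:, None]
        W_r = W & in_ref[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_t = np.where(W_t, Y, 0.0).sum(axis=0) / W_t.sum(axis=0)
            mean_r = np.where(W_r, Y, 0.0).sum(axis=0) / W_r.sum(axis=0)
        diff = (mean_t - mean_r).reshape(shape)
        diff[~fitted.reshape(shape)] = np.nan
        kind = "t"
    elif spec.contrast == "omnibus-F":
        gidx = [names.index(f"group[{g}]") for g in test_groups]
        q = len(gidx)
        keep = [j for j in range(p_full) if j not in gidx]
        Xr = X[:, :, keep]
        _, _, rss_r, _ = _batched_ols(Y, Xr, W)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = ((rss_r - rss) / q) / sigma2
        F[~fitted] = np.nan
        F = np.where(np.isfinite(F) & (F < 0), 0.0, F)
        stat = F
        pval = np.where(np.isfinite(F),
                        stats.f.sf(F, q, np.maximum(df, 1)), np.nan)
        kind = "F"
    else:
        raise DesignError(f"unknown contrast {spec.contrast!r}")

    if not fitted.any():
        raise DesignError("design is rank deficient / under-powered at "
                          "every voxel")

    p_grid = pval.reshape(shape)
    valid_family = np.isfinite(p_grid)
    reject, cutoff = fdr_correct(p_grid, spec.alpha, mask=valid_family)
    sig, labels = cluster_filter(reject, spec.min_cluster_voxels,
                                 spec.connectivity)
    return StatMapSet(stat=stat.reshape(shape), p=p_grid, sig=sig,
                      clusters=labels, q_threshold=cutoff, diff=diff,
                      n_effective=(n_valid.reshape(shape) *
                                   fitted.reshape(shape)).astype(int),
                      beta=betas, stat_kind=kind, alpha=spec.alpha,
                      min_cluster_voxels=spec.min_cluster_voxels,
                      connectivity=spec.connectivity)


# ---------------------------------------------------------------------------
# multiplicity control
# ---------------------------------------------------------------------------

def fdr_correct(p_map: np.ndarray, alpha: float = DEFAULT_ALPHA,
                mask: Optional[np.ndarray] = None,
                ) -> Tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over all valid voxels of one map.

    Returns the rejection grid and the realized p cutoff (largest raw p
    among rejected voxels; 0 when nothing is rejected).
    """
    p_map = np.asarray(p_map, dtype=float)
    family = np.isfinite(p_map)
    if mask is not None:
        family &= np.asarray(mask, dtype=bool)
    reject = np.zeros(p_map.shape, dtype=bool)
    if not family.any():
        import warnings

        warnings.warn("empty FDR family: no valid p-values", stacklevel=2)
        return reject, 0.0
    pv = p_map[family]
    if np.any((pv < 0) | (pv > 1)):
        raise DegenerateInputError("p-values outside [0, 1]")
    rej, *_ = multipletests(pv, alpha=alpha, method="fdr_bh")
    reject[family] = rej
    cutoff = float(pv[rej].max()) if rej.any() else 0.0
    return reject, cutoff


def cluster_filter(sig: np.ndarray,
                   min_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
                   connectivity: int = DEFAULT_CONNECTIVITY,
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Remove significant-voxel components smaller than ``min_voxels``.

    Surviving components are labelled 1..K in decreasing size, ties
    broken by the top-left-most member voxel.  Returns (filtered boolean
    grid, label grid).
    """
    if min_voxels < 1:
        raise DegenerateInputError("min_voxels must be >= 1")
    sig = np.asarray(sig, dtype=bool)
    structure = (np.ones((3, 3), dtype=int) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    raw_labels, n_comp = ndimage.label(sig, structure=structure)
    filtered = np.zeros_like(sig)
    labels = np.zeros(sig.shape, dtype=int)
    if n_comp == 0:
        return filtered, labels
    sizes = np.bincount(raw_labels.ravel())[1:]
    flat = raw_labels.ravel()
    first_idx = np.full(n_comp + 1, flat.size, dtype=int)
    nz = np.flatnonzero(flat)
    # first (row-major) occurrence of each component = top-left-most voxel
    np.minimum.at(first_idx, flat[nz], nz)
    keep = [k for k in range(1, n_comp + 1) if sizes[k - 1] >= min_voxels]
    keep.sort(key=lambda k: (-sizes[k - 1], first_idx[k]))
    for new, k in enumerate(keep, start=1):
        comp = raw_labels == k
        filtered |= comp
        labels[comp] = new
    return filtered, labels


def cluster_table(sms: StatMapSet) -> pd.DataFrame:
    """Tabulate surviving clusters: label, size, centroid, peak statistic
    and mean difference."""
    rows = []
    for label in range(1, int(sms.clusters.max()) + 1):
        comp = sms.clusters == label
        idx = np.argwhere(comp)
        stat_vals = sms.stat[comp]
        peak = float(np.nanmax(np.abs(stat_vals)))
        rows.append({
            "label": label,
            "size_voxels": int(comp.sum()),
            "centroid_row": float(idx[:, 0].mean()),
            "centroid_col": float(idx[:, 1].mean()),
            "peak_stat": peak,
            "mean_diff_um": (float(np.nanmean(sms.diff[comp]))
                             if sms.diff is not None else np.nan),
        })
    return pd.DataFrame(rows, columns=["label", "size_voxels", "centroid_row",
                                       "centroid_col", "peak_stat",
                                       "mean_diff_um"])


# ---------------------------------------------------------------------------
# voxel-wise covariate regression
# ---------------------------------------------------------------------------

def voxelwise_regression(layer_stack: GroupStack, covariate: str,
                         adjusters: Tuple[str, ...] = (),
                         retina_stack: Optional[GroupStack] = None,
                         alpha: float = DEFAULT_ALPHA,
                         min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS,
                         connectivity: int = DEFAULT_CONNECTIVITY,
                         ) -> StatMapSet:
    """Voxel-wise regression of thickness on a clinical covariate.

    Reports the standardized regression coefficient (SRC): the slope of
    z-scored thickness on the z-scored predictor, adjusted for
    ``adjusters`` (subset of age/sex/retina).  With no adjusters the SRC
    equals the per-voxel Pearson correlation.  Significance uses the
    same FDR + cluster-extent procedure as the group comparison.
    """
    cov = layer_stack.covariates
    if covariate not in cov.columns:
        raise DesignError(f"covariate {covariate!r} not in table")
    x = pd.to_numeric(cov[covariate], errors="coerce").values.astype(float)
    if np.unique(x[np.isfinite(x)]).size < 3:
        raise DegenerateInputError(
            f"covariate {covariate!r} has < 3 distinct values")

    shape = layer_stack.grid_shape
    n, V = layer_stack.n_subjects, int(np.prod(shape))
    Y = layer_stack.data.reshape(n, V)

    adj_cols, adj_names = [], []
    if "age" in adjusters and covariate != "age":
        adj_cols.append(pd.to_numeric(cov["age"], errors="coerce").values)
        adj_names.append("age")
    if "sex" in adjusters:
        adj_cols.append((cov["sex"].values == "M").astype(float))
        adj_names.append("sex")
    use_retina = "retina" in adjusters
    if use_retina and retina_stack is None:
        raise DesignError("retina adjuster requested without a Retina stack")

    subj_ok = np.isfinite(x)
    for c in adj_cols:
        subj_ok &= np.isfinite(c)
    W = np.isfinite(Y) & subj_ok[:, None]
    if use_retina:
        R = retina_stack.data.reshape(n, V)
        W &= np.isfinite(R)

    # per-voxel z-scoring of predictor and response over valid subjects
    Wv = W.T.astype(float)                                 # (V, n)
    nv = Wv.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_mean = (Wv * x[None, :]).sum(axis=1) / nv
        x_sd = np.sqrt((Wv * (x[None, :] - x_mean[:, None]) ** 2
                        ).sum(axis=1) / nv)
        y0 = np.where(W, Y, 0.0).T
        y_mean = y0.sum(axis=1) / nv
        y_sd = np.sqrt((Wv * (y0 - y_mean[:, None]) ** 2).sum(axis=1) / nv)
        zx = (x[None, :] - x_mean[:, None]) / x_sd[:, None]
        zy = (y0 - y_mean[:, None]) / y_sd[:, None]
    zx = np.where(W.T, zx, 0.0)
    zy = np.where(W.T, zy, 0.0)

    p_extra = len(adj_cols) + (1 if use_retina else 0)
    p_full = 2 + p_extra                                   # intercept + zx
    X = np.empty((V, n, p_full))
    X[:, :, 0] = 1.0
    col = 1
    for c in adj_cols:
        X[:, :, col] = c[None, :]
        col += 1
    if use_retina:
        X[:, :, col] = np.where(W, R, 0.0).T
        col += 1
    X[:, :, col] = zx
    j_src = col

    beta, xtx_inv, rss, n_valid = _batched_ols(zy.T, X, W)
    df = n_valid - p_full
    fitted = np.isfinite(beta).all(axis=1) & (df > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 * xtx_inv[:, j_src, j_src])
        t = beta[:, j_src] / se
    # perfect fits (rss == 0) have infinite t; p -> 0
    t[~fitted] = np.nan
    pval = np.where(np.isfinite(t),
                    2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan)
    pval[fitted & ~np.isfinite(t) & np.isfinite(beta[:, j_src])] = 0.0

    src = beta[:, j_src].reshape(shape)
    p_grid = pval.reshape(shape)
    reject, cutoff = fdr_correct(p_grid, alpha, mask=np.isfinite(p_grid))
    sig, labels = cluster_filter(reject, min_cluster_voxels, connectivity)
    return StatMapSet(stat=np.where(np.isfinite(t), t, np.nan).reshape(shape),
                      p=p_grid, sig=sig, clusters=labels, q_threshold=cutoff,
                      diff=None,
                      n_effective=(n_valid.reshape(shape) *
                                   fitted.reshape(shape)).astype(int),
                      beta={"SRC": src}, stat_kind="t", alpha=alpha,
                      min_cluster_voxels=min_cluster_voxels,
                      connectivity=connectivity)


# ---------------------------------------------------------------------------
# overlay rendering
# ---------------------------------------------------------------------------

def render_overlay(sms: StatMapSet, diff_or_pct: np.ndarray,
                   fundus: Optional[np.ndarray] = None,
                   color_range: float = 5.0,
                   units: str = "um",
                   title: Optional[str] = None,
                   path=None) -> np.ndarray:
    """Render significant voxels over a fundus image.

    Only significant voxels are coloured, with a diverging colormap
    clipped at ``+/- color_range`` (e.g. 5 um for difference maps or 15
    for percentage maps).  Without a fundus image a blank background
    with grid ticks is used.  Returns the rendered RGBA array; saves a
    PNG when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    grid = np.asarray(diff_or_pct, dtype=float)
    if grid.shape != sms.sig.shape:
        raise StackError("overlay grid does not match stat maps")
    fig, ax = plt.subplots(figsize=(7, 4), dpi=100)
    extent = (0, grid.shape[1], grid.shape[0], 0)
    if fundus is not None:
        ax.imshow(np.asarray(fundus), cmap="gray", extent=extent,
                  aspect="auto")
    else:
        ax.set_facecolor("0.15")
    overlay = np.ma.masked_where(~sms.sig, np.clip(grid, -color_range,
                                                   color_range))
    im = ax.imshow(overlay, cmap="RdBu_r", vmin=-color_range,
                   vmax=color_range, extent=extent, aspect="auto")
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label(f"difference ({units})")
    ax.set_xlabel("A-scan")
    ax.set_ylabel("B-scan")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.canvas.draw()
    rgba = np.asarray(fig.canvas.buffer_rgba()).copy()
    if path is not None:
        fig.savefig(path)
    plt.close(fig)
    return rgba
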