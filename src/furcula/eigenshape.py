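"""Eigenshape analysis of open outline curves.

Each resampled outline is converted to a turning-angle (phi) function — the
sequence of signed angular deviations between successive segments — which is
invariant to translation, rotation and uniform scaling of the source points.
The specimen-by-angle matrix is mean-centred (optionally standardized to unit
variance per angle variable, the "correlation matrix" option) and decomposed
by SVD.  Columns of ``axes`` are the eigenshapes; ``scores`` places each
specimen in shape space; ``variance_fraction`` comes from the squared
singular values.

The extended variant computes phi per landmark-bounded segment and
concatenates, so homologous segments stay aligned across specimens.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .shapes_io import PseudolandmarkSet


@dataclass(frozen=True)
class PhiVector:
    """Turning-angle representation of one resampled outline."""

    specimen_id: str
    phi: np.ndarray  # length n_points - 2 (minus one extra per landmark for extended)
    segment_lengths: tuple[int, ...] = ()  # phi lengths per segment (extended form)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))


@dataclass(frozen=True)
class EigenshapeModel:
    mean_phi: np.ndarray
    axes: np.ndarray  # (n_vars, n_axes), orthonormal columns
    variance_fraction: np.ndarray
    scores: np.ndarray  # (n_specimens, n_axes)
    standardization: np.ndarray  # per-variable scale divisors (1s when covariance)
    specimen_ids: tuple[str, ...]
    n_points: int
    open_curve: bool = True
    segment_lengths: tuple[int, ...] = ()
    dropped_variables: tuple[int, ...] = ()


def phi_transform(points: PseudolandmarkSet | np.ndarray, specimen_id: str | None = None) -> PhiVector:
    """Signed turning angles between successive segments, wrapped to (-pi, pi].

    A counter-clockwise (left) turn is positive under the y-up convention.
    """
    if isinstance(points, PseudolandmarkSet):
        pts = points.points
        sid = points.specimen_id
    else:
        pts = np.asarray(points, dtype=float)
        sid = specimen_id or ""
    if len(pts) < 3:
        raise ValueError("need >= 3 points")
    seg = np.diff(pts, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise ValueError(f"zero-length segment at index {int(bad[0])}")
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    dphi = np.diff(ang)
    dphi = np.mod(dphi + np.pi, 2 * np.pi) - np.pi
    dphi[dphi == -np.pi] = np.pi  # wrap to (-pi, pi]
    return PhiVector(sid, dphi)


def phi_transform_segmented(pls: PseudolandmarkSet) -> PhiVector:
    """Per-segment turning angles for a landmarked curve, concatenated.

    Angles are never taken across a landmark, so each segment's shape is
    recorded independently of its neighbours' orientation.
    """
    if not pls.landmark_indices:
        return phi_transform(pls)
    bounds = [0, *pls.landmark_indices, pls.n_points - 1]
    phis = []
    seg_lens = []
    for a, b in zip(bounds, bounds[1:]):
        v = phi_transform(pls.points[a : b + 1], pls.specimen_id)
        phis.append(v.phi)
        seg_lens.append(len(v.phi))
    return PhiVector(pls.specimen_id, np.concatenate(phis), tuple(seg_lens))


def _fix_axis_signs(axes: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-magnitude loading of each axis positive (reproducible signs)."""
    flips = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(axes.shape[1])])
    flips[flips == 0] = 1.0
    return axes * flips, scores * flips


def eigenshape_fit(
    phis: Sequence[PhiVector],
    use_correlation: bool = True,
    open_curve: bool = True,
    n_points: int | None = None,
) -> EigenshapeModel:
    """Fit an eigenshape model to a set of phi vectors by SVD.

    With ``use_correlation`` each phi variable is scaled to unit variance
    across specimens after mean-centring; variables with zero variance are
    dropped (with a warning) and recorded on the model.
    """
    if len(phis) < 2:
        raise ValueError("need >= 2 specimens")
    lengths = {len(p.phi) for p in phis}
    if len(lengths) != 1:
        raise ValueError(f"phi vectors differ in length: {sorted(lengths)}")
    X = np.vstack([p.phi for p in phis])
    ids = tuple(p.specimen_id for p in phis)
    seg_lens = phis[0].segment_lengths
    mean_phi = X.mean(axis=0)
    Xc = X - mean_phi
    scale = np.ones(X.shape[1])
    dropped: tuple[int, ...] = ()
    if use_correlation:
        sd = Xc.std(axis=0, ddof=1)
        zero = sd <= 1e-15
        if np.all(zero):
            raise ValueError("degenerate model: all specimens identical")
        if np.any(zero):
            dropped = tuple(int(i) for i in np.flatnonzero(zero))
            warnings.warn(f"dropping {len(dropped)} zero-variance phi variables")
        scale = np.where(zero, 1.0, sd)
        Xc = Xc[:, ~zero] / scale[~zero]
        kept_scale = scale[~zero]
    else:
        if np.allclose(Xc, 0.0):
            raise ValueError("degenerate model: all specimens identical")
        kept_scale = scale
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    nz = s > s[0] * 1e-12 if s[0] > 0 else s > 0
    U, s, Vt = U[:, nz], s[nz], Vt[nz]
    axes = Vt.T
    scores = U * s
    var_frac = s**2 / np.sum(s**2)
    axes, scores = _fix_axis_signs(axes, scores)
    if use_correlation and dropped:
        # re-embed axes over the full variable set with zeros at dropped slots
        full = np.zeros((X.shape[1], axes.shape[1]))
        full[~np.isin(np.arange(X.shape[1]), dropped)] = axes
        axes = full
        full_scale = scale
    else:
        full_scale = kept_scale
    npts = n_points if n_points is not None else len(mean_phi) + 2 + len(seg_lens)
    return EigenshapeModel(
        mean_phi=mean_phi,
        axes=axes,
        variance_fraction=var_frac,
        scores=scores,
        standardization=full_scale,
        specimen_ids=ids,
        n_points=npts,
        open_curve=open_curve,
        segment_lengths=seg_lens,
        dropped_variables=dropped,
    )


def extended_eigenshape_fit(
    curves: Sequence[PseudolandmarkSet],
    use_correlation: bool = True,
) -> EigenshapeModel:
    """Eigenshape fit for landmarked curves (per-segment phi, concatenated).

    All specimens must share the landmark count; with zero landmarks this
    reduces exactly to the standard fit.
    """
    counts = {len(c.landmark_indices) for c in curves}
    if len(counts) != 1:
        raise ValueError(f"specimens differ in landmark count: {sorted(counts)}")
    phis = [phi_transform_segmented(c) for c in curves]
    return eigenshape_fit(phis, use_correlation=use_correlation, n_points=curves[0].n_points)


def reconstruct_phi(model: EigenshapeModel, scores: dict[int, float] | Sequence[float]) -> np.ndarray:
    """Mean phi plus the scored combination of axes, back on the raw angle scale."""
    if isinstance(scores, dict):
        vec = np.zeros(model.axes.shape[1])
        for k, v in scores.items():
            if not 0 <= int(k) < model.axes.shape[1]:
                raise IndexError(f"score index {k} beyond axis count {model.axes.shape[1]}")
            vec[int(k)] = v
    else:
        vec = np.asarray(scores, dtype=float)
        if len(vec) > model.axes.shape[1]:
            raise IndexError("score vector longer than axis count")
        vec = np.pad(vec, (0, model.axes.shape[1] - len(vec)))
    dev = model.axes @ vec
    return model.mean_phi + dev * model.standardization


def integrate_phi(phi: np.ndarray, segment_length: float = 1.0, start_angle: float = 0.0) -> np.ndarray:
    """Rebuild coordinates from turning angles: fixed-step walk from the origin heading +x."""
    angles = start_angle + np.concatenate([[0.0], np.cumsum(phi)])
    steps = segment_length * np.column_stack([np.cos(angles), np.sin(angles)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def reconstruct_outline(
    model: EigenshapeModel,
    scores: dict[int, float] | Sequence[float],
    segment_length: float = 1.0,
) -> PseudolandmarkSet:
    """Model-based outline for a (possibly partial) score vector.

    Unspecified axes are treated as zero, so an empty score set returns the
    mean shape.  Extended models integrate each segment from a fresh +x
    heading, matching how their phi was measured.
    """
    phi = reconstruct_phi(model, scores)
    if model.segment_lengths:
        pieces = []
        off = 0
        lms = []
        pos = 0
        for j, L in enumerate(model.segment_lengths):
            seg = integrate_phi(phi[off : off + L], segment_length)
            off += L
            if j == 0:
                pieces.append(seg)
                pos = len(seg)
            else:
                lms.append(pos - 1)
                seg = seg - seg[0] + pieces[-1][-1]
                pieces.append(seg[1:])
                pos += len(seg) - 1
        pts = np.vstack(pieces)
        return PseudolandmarkSet("reconstruction", "profile", pts, len(pts), tuple(lms))
    pts = integrate_phi(phi, segment_length)
    return PseudolandmarkSet("reconstruction", "profile", pts, len(pts))


def combine_views(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse two views' score matrices by SVD of their standardized concatenation.

    Returns (fused scores, variance fractions).  Rows must correspond to the
    same specimens in the same order.
    """
    A = np.asarray(scores_a, dtype=float)
    B = np.asarray(scores_b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"row mismatch: {A.shape[0]} vs {B.shape[0]}")
    X = np.hstack([A, B])
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd <= 1e-15] = 1.0
    Xs = Xc / sd
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    nz = s > (s[0] * 1e-12 if s[0] > 0 else 0)
    U, s = U[:, nz], s[nz]
    fused = U * s
    axes = Vt[nz].T
    _, fused = _fix_axis_signs(axes, fused)
    return fused, s**2 / np.sum(s**2)


def curve_sensitivity(
    datasets: dict[str, Sequence[PseudolandmarkSet]],
    groups: Sequence[str],
    tree,
    n_axes: int = 3,
    n_sim: int = 199,
    seed: int = 0,
    use_correlation: bool = True,
) -> pd.DataFrame:
    """Rank curve definitions by between-group separation of their eigenshapes.

    For each definition the first ``n_axes`` eigenshape scores enter a
    phylogenetic MANOVA; definitions are ranked by the MANOVA statistic
    (larger Wilks-based F = better separation), ties broken by name.
    """
    from .phylo_tests import phyl_anova

    if not datasets:
        raise ValueError("no curve definitions supplied")
    ids0 = None
    for name, curves in datasets.items():
        ids = sorted(c.specimen_id for c in curves)
        if ids0 is None:
            ids0 = ids
        elif ids != ids0:
            missing = sorted(set(ids0) ^ set(ids))
            raise ValueError(f"definition {name!r}: specimen mismatch {missing}")
    rows = []
    for name in sorted(datasets):
        curves = datasets[name]
        model = extended_eigenshape_fit(curves, use_correlation=use_correlation)
        k = min(n_axes, model.scores.shape[1])
        scores = model.scores[:, :k]
        labels = pd.Series(list(groups), index=list(model.specimen_ids))
        res = phyl_anova(
            pd.DataFrame(scores, index=list(model.specimen_ids)),
            labels,
            tree,
            n_sim=n_sim,
            seed=seed,
        )
        # separation on the F scale (Wilks' lambda itself shrinks with separation)
        sep = res.extras.get("F", res.statistic)
        rows.append((name, sep, res.p_phylogenetic))
    df = pd.DataFrame(rows, columns=["curve_definition", "separation_F", "p_phylogenetic"])
    return df.sort_values(
        ["separation_F", "curve_definition"], ascending=[False, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Serialization


def scores_table(model: EigenshapeModel, n_axes: int | None = None) -> pd.DataFrame:
    k = model.scores.shape[1] if n_axes is None else min(n_axes, model.scores.shape[1])
    cols = [f"es{i + 1}" for i in range(k)]
    df = pd.DataFrame(model.scores[:, :k], columns=cols)
    df.insert(0, "specimen_id", list(model.specimen_ids))
    return df


def variance_table(model: EigenshapeModel) -> pd.DataFrame:
    vf = model.variance_fraction
    return pd.DataFrame(
        {
            "axis": np.arange(1, len(vf) + 1),
            "variance_fraction": vf,
            "cumulative": np.cumsum(vf),
        }
    )


def save_model(model: EigenshapeModel, path) -> None:
    payload = {
        "mean_phi": model.mean_phi.tolist(),
        "axes": model.axes.tolist(),
        "variance_fraction": model.variance_fraction.tolist(),
        "scores": model.scores.tolist(),
        "standardization": model.standardization.tolist(),
        "specimen_ids": list(model.specimen_ids),
        "n_points": model.n_points,
        "open_curve": model.open_curve,
        "segment_lengths": list(model.segment_lengths),
        "dropped_variables": list(model.dropped_variables),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> EigenshapeModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return EigenshapeModel(
        mean_phi=np.array(d["mean_phi"]),
        axes=np.array(d["axes"]),
        variance_fraction=np.array(d["variance_fraction"]),
        scores=np.array(d["scores"]),
        standardization=np.array(d["standardization"]),
        specimen_ids=tuple(d["specimen_ids"]),
        n_points=int(d["n_points"]),
        open_curve=bool(d["open_curve"]),
        segment_lengths=tuple(d["segment_lengths"]),
        dropped_variables=tuple(d["dropped_variables"]),
    )
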