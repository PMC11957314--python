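"""SMOGN oversampling for imbalanced regression, implemented from scratch.

Cytotoxic (low-viability) profiles are rare in a screen where most
treatments do nothing, which starves a regressor of exactly the examples it
must learn.  SMOGN synthesizes new rare cases: a boxplot-based *relevance
function* marks which target values are rare and important, the data are
split into contiguous rare/normal bins along the sorted target, and each
rare bin is grown by either SMOTE-style interpolation between a seed case
and one of its k nearest rare neighbours (when the neighbour is close) or
by Gaussian perturbation of the seed (when it is distant).  Under
``samp_method='balance'`` every bin is resized to the mean original bin
size, undersampling over-represented normal bins by random removal.

The construction rules implemented here are documented and authoritative
for this package; results are deterministic given ``(data, config)``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

XTRM_TYPES = ("low", "high", "both")
SAMP_METHODS = ("balance", "extreme")


@dataclass(frozen=True)
class SmognConfig:
    """Knobs of the augmentation; defaults target rare *low* values."""

    rel_xtrm_type: str = "low"
    samp_method: str = "balance"
    rel_coef: float = 5.0
    rel_thres: float = 0.8
    k_neighbors: int = 5
    noise_sd_frac: float = 0.02
    seed: int = 0
    undersample: bool = True

    def validate(self) -> None:
        if self.rel_xtrm_type not in XTRM_TYPES:
            raise ValueError(f"rel_xtrm_type must be one of {XTRM_TYPES}")
        if self.samp_method not in SAMP_METHODS:
            raise ValueError(f"samp_method must be one of {SAMP_METHODS}")
        if not 0 < self.rel_thres < 1:
            raise ValueError("rel_thres must lie in (0, 1)")
        if self.rel_coef <= 0:
            raise ValueError("rel_coef must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.noise_sd_frac <= 0:
            raise ValueError("noise_sd_frac must be positive")


class RelevanceFunction:
    """Piecewise-monotone map from target value to relevance in [0, 1].

    Built from boxplot control points: with ``rel_xtrm_type='low'``
    relevance is 1 at the low adjacent value ``Q1 - rel_coef * IQR``
    (clamped up to ``min(y)``), 0 at the median and beyond; interpolation
    between control points is shape-preserving cubic (PCHIP), clamped to
    [0, 1] and extended flat outside the control range.
    """

    def __init__(self, control_points: list[tuple[float, float]]):
        pts = sorted(control_points)
        xs = np.array([p[0] for p in pts], dtype=float)
        vs = np.array([p[1] for p in pts], dtype=float)
        keep = np.concatenate([[True], np.diff(xs) > 0])
        xs, vs = xs[keep], vs[keep]
        if len(xs) < 2:
            raise ValueError("relevance needs >= 2 distinct control points")
        self.control_points = list(zip(xs.tolist(), vs.tolist()))
        self._lo, self._hi = xs[0], xs[-1]
        self._interp = PchipInterpolator(xs, vs, extrapolate=False)

    def __call__(self, y):
        y = np.asarray(y, dtype=float)
        out = self._interp(np.clip(y, self._lo, self._hi))
        lo_val = self.control_points[0][1]
        hi_val = self.control_points[-1][1]
        out = np.where(y <= self._lo, lo_val, out)
        out = np.where(y >= self._hi, hi_val, out)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


def build_relevance(y, cfg: SmognConfig) -> RelevanceFunction:
    """Boxplot-based relevance over the observed target distribution."""
    cfg.validate()
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 target values")
    if np.ptp(y) == 0:
        raise ValueError("constant target: relevance undefined")
    q1, med, q3 = np.percentile(y, [25, 50, 75])
    iqr = q3 - q1
    ymin, ymax = float(y.min()), float(y.max())
    adj_low = max(q1 - cfg.rel_coef * iqr, ymin)
    adj_high = min(q3 + cfg.rel_coef * iqr, ymax)
    if cfg.rel_xtrm_type == "low":
        points = [(adj_low, 1.0), (med, 0.0), (ymax, 0.0)]
    elif cfg.rel_xtrm_type == "high":
        points = [(ymin, 0.0), (med, 0.0), (adj_high, 1.0)]
    else:
        points = [(adj_low, 1.0), (med, 0.0), (adj_high, 1.0)]
    return RelevanceFunction(points)


@dataclass
class Bin:
    """A contiguous run of rare or normal cases along the sorted target."""

    indices: np.ndarray  # positions into the original arrays
    rare: bool

    @property
    def size(self) -> int:
        return len(self.indices)


def partition_bins(
    y, rel: RelevanceFunction, rel_thres: float
) -> tuple[np.ndarray, np.ndarray, list[Bin]]:
    """Split cases into rare/normal sets and contiguous bins along sorted y.

    Rare cases are those with ``relevance(y) >= rel_thres``.  The two sets
    partition the data; an empty rare set is an explicit error (augmentation
    has nothing to synthesize from).
    """
    y = np.asarray(y, dtype=float)
    relevance = np.asarray(rel(y), dtype=float)
    rare_mask = relevance >= rel_thres
    rare_idx = np.flatnonzero(rare_mask)
    normal_idx = np.flatnonzero(~rare_mask)
    if rare_idx.size == 0:
        raise ValueError(
            "no rare cases at rel_thres="
            f"{rel_thres}: relevance never reaches the threshold, "
            "augmentation refused"
        )
    order = np.argsort(y, kind="stable")
    bins: list[Bin] = []
    start = 0
    sorted_mask = rare_mask[order]
    for i in range(1, len(order) + 1):
        if i == len(order) or sorted_mask[i] != sorted_mask[start]:
            bins.append(Bin(indices=order[start:i], rare=bool(sorted_mask[start])))
            start = i
    return rare_idx, normal_idx, bins


def _interpolate(x_seed, y_seed, x_nb, y_nb, u: float):
    """SMOTE-style convex step from seed toward neighbour at fraction ``u``.

    The synthetic target is the distance-weighted mean of the two parents
    (closer parent weighs more); at ``u = 0`` the sample is a copy of the
    seed.
    """
    x_new = x_seed + u * (x_nb - x_seed)
    d1 = float(np.linalg.norm(x_new - x_seed))
    d2 = float(np.linalg.norm(x_new - x_nb))
    if d1 + d2 == 0:
        y_new = 0.5 * (y_seed + y_nb)
    else:
        y_new = (d2 * y_seed + d1 * y_nb) / (d1 + d2)
    return x_new, float(y_new)


def _gauss_perturb(x_seed, y_seed, feature_sd, y_sd, frac, y_range, rng):
    """Gaussian-noise generation around a seed case, target clipped to range."""
    x_new = x_seed + rng.normal(0.0, frac * feature_sd)
    y_new = float(np.clip(y_seed + rng.normal(0.0, frac * y_sd), *y_range))
    return x_new, y_new


def synth_sample(
    seed_x,
    seed_y,
    nb_X,
    nb_y,
    nb_dists,
    cfg: SmognConfig,
    rng: np.random.Generator,
    feature_sd,
    y_sd,
    y_range,
):
    """One synthetic case from a seed and its rare-bin neighbours.

    If the randomly chosen neighbour lies closer than half the median
    distance of the seed to its k neighbours, interpolate (safe region);
    otherwise perturb the seed with Gaussian noise scaled per feature.
    """
    if len(nb_y) == 0:
        raise ValueError("synth_sample needs at least one neighbour")
    j = int(rng.integers(len(nb_y)))
    half_median = 0.5 * float(np.median(nb_dists))
    if nb_dists[j] < half_median:
        u = float(rng.uniform())
        x_new, y_new = _interpolate(seed_x, seed_y, nb_X[j], nb_y[j], u)
        mode = "interpolation"
    else:
        x_new, y_new = _gauss_perturb(
            seed_x, seed_y, feature_sd, y_sd, cfg.noise_sd_frac, y_range, rng
        )
        mode = "noise"
    return x_new, y_new, mode


def _bin_targets(bins: list[Bin], cfg: SmognConfig) -> list[int]:
    sizes = np.array([b.size for b in bins], dtype=float)
    mean_size = sizes.mean()
    if cfg.samp_method == "balance":
        return [int(round(mean_size))] * len(bins)
    # 'extreme': invert bin frequencies, then rescale to preserve the total
    inverted = mean_size**2 / sizes
    scaled = inverted * sizes.sum() / inverted.sum()
    return [max(1, int(round(t))) for t in scaled]


def augment(X, y, cfg: SmognConfig):
    """Resample (X, y) so rare target regions are properly represented.

    Returns ``(X_aug, y_aug, synthetic)`` where ``synthetic`` flags the
    generated rows.  Original test-set isolation is the caller's contract:
    augment only ever sees training rows.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    rng = np.random.default_rng(cfg.seed)
    rel = build_relevance(y, cfg)
    _rare, _normal, bins = partition_bins(y, rel, cfg.rel_thres)
    targets = _bin_targets(bins, cfg)
    feature_sd = X.std(axis=0, ddof=0)
    y_sd = float(y.std(ddof=0))
    y_range = (float(y.min()), float(y.max()))

    keep_parts: list[np.ndarray] = []
    synth_X: list[np.ndarray] = []
    synth_y: list[float] = []

    for b, target in zip(bins, targets):
        idx = b.indices
        if b.size > target and (cfg.undersample or b.rare):
            chosen = np.sort(rng.choice(b.size, size=target, replace=False))
            keep_parts.append(idx[chosen])
            continue
        keep_parts.append(idx)
        need = target - b.size
        if need <= 0 or not b.rare:
            continue
        bin_X, bin_y = X[idx], y[idx]
        if b.size == 1:
            for _ in range(need):
                x_new, y_new = _gauss_perturb(
                    bin_X[0], bin_y[0], feature_sd, y_sd,
                    cfg.noise_sd_frac, y_range, rng,
                )
                synth_X.append(x_new)
                synth_y.append(y_new)
            continue
        k = min(cfg.k_neighbors, b.size - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(bin_X)
        dists, nbrs = nn.kneighbors(bin_X)
        dists, nbrs = dists[:, 1:], nbrs[:, 1:]  # drop self
        order = rng.permutation(b.size)
        for t in range(need):
            s = int(order[t % b.size])
            x_new, y_new, _mode = synth_sample(
                bin_X[s],
                bin_y[s],
                bin_X[nbrs[s]],
                bin_y[nbrs[s]],
                dists[s],
                cfg,
                rng,
                feature_sd,
                y_sd,
                y_range,
            )
            synth_X.append(x_new)
            synth_y.append(y_new)

    kept = np.concatenate(keep_parts) if keep_parts else np.array([], dtype=int)
    X_parts = [X[kept]]
    y_parts = [y[kept]]
    if synth_X:
        X_parts.append(np.vstack(synth_X))
        y_parts.append(np.asarray(synth_y))
    X_aug = np.vstack(X_parts)
    y_aug = np.concatenate(y_parts)
    synthetic = np.zeros(len(y_aug), dtype=bool)
    synthetic[len(kept):] = True
    log.info(
        "SMOGN: %d originals kept, %d synthesized (%d bins)",
        len(kept),
        int(synthetic.sum()),
        len(bins),
    )
    return X_aug, y_aug, synthetic


def make_augmenter(cfg: SmognConfig):
    """Closure suitable for :func:`myoscreen.models.global_model`."""

    def _augment(X_train, y_train):
        return augment(X_train, y_train, cfg)

    return _augment
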