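"""Prior-weighted Gaussian-mixture tissue segmentation (one or two channels).

Each tissue class k (GM, WM, CSF, background, optionally WML) is modelled
as a mixture of J_k Gaussians over the channel intensities; a voxel-wise
class prior pi_k(v) — flat, or a population tissue probability map —
multiplies the class likelihood, raised to a mixing exponent alpha in
[0, 1] (alpha = 1 is the full Bayesian prior, alpha = 0 ignores the
prior).  Expectation-maximisation maximises

    sum_v log sum_k pi_k(v)^alpha sum_j w_kj N(y_v; mu_kj, Sigma_kj)

which is a valid EM objective for fixed priors, so the data
log-likelihood is monotone non-decreasing across iterations; the trace
is recorded and assertable.  Posterior responsibilities summed over a
class's components form its tissue probability map.

There is no Markov-random-field term and no bias-field model; spatial
regularity enters only through the priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from wmlquant.image import SubjectImage, TPMSet

LOG2PI = np.log(2.0 * np.pi)

#: default Gaussians per class (common practice for T1W brain segmentation)
DEFAULT_COMPONENTS = {"gm": 2, "wm": 2, "csf": 2, "wml": 1, "background": 3}


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class FitConfig:
    n_components: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    alpha: float = 1.0          # prior mixing exponent in [0, 1]
    tol: float = 1e-6           # relative log-likelihood change
    max_iter: int = 200
    seed: int = 0
    ridge: float = 1e-6         # x channel variance, added on singularity
    init_means: dict = None     # class -> per-channel mean vector (optional)

    def components_for(self, cls: str) -> int:
        return int(self.n_components.get(cls, 1))


@dataclass
class MixtureModel:
    """Fitted mixture parameters plus the EM convergence log.

    ``class_weights`` are the learned global tissue proportions tau_k
    (they multiply the voxel-wise spatial prior, which modulates rather
    than replaces them); ``weights`` are the within-class component
    mixing weights and sum to one per class.
    """

    classes: tuple
    channels: tuple
    weights: dict               # class -> (J,), sums to 1 within class
    class_weights: dict         # class -> scalar tau_k, sums to 1 over classes
    means: dict                 # class -> (J, C)
    covariances: dict           # class -> (J, C, C)
    alpha: float
    loglik_trace: list
    converged: bool

    def class_mean(self, cls: str) -> np.ndarray:
        """Mixing-weight average of the class's component means."""
        w = self.weights[cls]
        return (w[:, None] * self.means[cls]).sum(axis=0)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "channels": list(self.channels),
            "alpha": self.alpha,
            "converged": self.converged,
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "weights": {c: self.weights[c].tolist() for c in self.classes},
            "class_weights": {c: float(self.class_weights[c]) for c in self.classes},
            "means": {c: self.means[c].tolist() for c in self.classes},
            "covariances": {c: self.covariances[c].tolist() for c in self.classes},
        }


def _log_gauss(Y, mu, cov, ridge_base):
    """Log N(y; mu, cov) for all rows of Y; regularises a singular cov."""
    C = Y.shape[1]
    cov = np.asarray(cov, float)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance ridge-regularised", ConvergenceWarning)
        cov = cov + np.eye(C) * ridge_base
        L = np.linalg.cholesky(cov)
    diff = Y - mu
    sol = np.linalg.solve(L, diff.T)
    maha = (sol ** 2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (C * LOG2PI + logdet + maha), cov


def _initial_params(Y, channels, classes, config):
    """Initial component means/covariances.

    Class means are seeded from the data by k-means clusters mapped to
    classes through the canonical T1W/FLAIR contrast rules (see
    :func:`_kmeans_init`) whether or not spatial priors are supplied —
    priors enter EM as voxel-wise class priors, not as intensity seeds,
    which keeps rare classes (WML) from being seeded off a blend of
    lesion and normal-tissue intensities.  Pass ``config.init_means`` to
    seed explicitly for non-standard channel sets.
    """
    rng = np.random.default_rng(config.seed)
    C = Y.shape[1]
    glob_var = Y.var(axis=0) + 1e-12

    class_means = {}
    if config.init_means:
        for cls in classes:
            class_means[cls] = np.asarray(config.init_means[cls], float)
    else:
        class_means.update(_kmeans_init(Y, channels, classes, config.seed))

    # hard-assign voxels to nearest class mean (whitened), then split each
    # class into components by quantiles of the first channel
    M = np.stack([class_means[c] for c in classes])
    d2 = (((Y[:, None, :] - M[None, :, :]) / np.sqrt(glob_var)) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)

    weights, class_weights, means, covs = {}, {}, {}, {}
    for ci, cls in enumerate(classes):
        J = config.components_for(cls)
        sub = Y[assign == ci]
        class_weights[cls] = max(sub.shape[0], 1) / Y.shape[0]
        if sub.shape[0] < 2 * J:
            sub = Y[rng.choice(Y.shape[0], size=max(2 * J, 8), replace=False)]
        order = np.argsort(sub[:, 0], kind="stable")
        chunks = np.array_split(order, J)
        means[cls] = np.stack([sub[ch].mean(axis=0) for ch in chunks])
        base_cov = np.cov(sub.T).reshape(C, C) + np.eye(C) * config.ridge * glob_var.mean()
        covs[cls] = np.stack([base_cov.copy() for _ in range(J)])
        weights[cls] = np.full(J, 1.0 / J)
    total = sum(class_weights.values())
    class_weights = {c: w / total for c, w in class_weights.items()}
    return weights, class_weights, means, covs


def _kmeans_init(Y, channels, classes, seed):
    """Data-driven class seeding for flat-prior fits.

    The normal-tissue classes are seeded by k-means clusters assigned to
    classes through the canonical contrast rules: background is the
    darkest cluster overall, CSF the FLAIR-darkest (CSF signal is
    suppressed on FLAIR) or T1W-darkest remaining cluster, WM the
    T1W-brightest, GM what is left (T1W-ascending for several leftovers).
    A WML class (FLAIR present) is seeded afterwards from voxels whose
    FLAIR intensity clearly exceeds the brightest normal-tissue cluster —
    lesions are FLAIR-hyperintense outliers however small their volume
    fraction, so a fixed quantile would miss them.
    """
    from sklearn.cluster import KMeans

    channels = list(channels)
    rng = np.random.default_rng(seed)
    t1_idx = channels.index("t1w") if "t1w" in channels else 0
    fl_idx = channels.index("flair") if "flair" in channels else None

    means = {}
    remaining = list(classes)
    if "wml" in remaining and fl_idx is not None:
        remaining.remove("wml")

    sample = Y
    if sample.shape[0] > 20000:
        sample = sample[rng.choice(sample.shape[0], 20000, replace=False)]
    km = KMeans(n_clusters=len(remaining), n_init=3, random_state=int(seed) & 0x7FFFFFFF)
    km.fit(sample)
    centres = km.cluster_centers_

    if "wml" in classes and fl_idx is not None:
        fl = Y[:, fl_idx]
        bright_normal = centres[:, fl_idx].max()
        robust_max = np.quantile(fl, 0.9999)
        cut = bright_normal + 0.5 * max(robust_max - bright_normal, 0.0)
        top = fl > cut
        if top.sum() < 8:        # no clear hyperintense tail: take extremes
            top = fl >= np.partition(fl, -8)[-8]
        means["wml"] = Y[top].mean(axis=0)

    free = list(range(len(remaining)))

    def _take(idx):
        free.remove(idx)
        return centres[idx]

    if "background" in remaining:
        means["background"] = _take(min(free, key=lambda i: np.linalg.norm(centres[i])))
        remaining.remove("background")
    if "csf" in remaining:
        key_idx = fl_idx if fl_idx is not None else t1_idx
        means["csf"] = _take(min(free, key=lambda i: centres[i][key_idx]))
        remaining.remove("csf")
    if "wm" in remaining:
        means["wm"] = _take(max(free, key=lambda i: centres[i][t1_idx]))
        remaining.remove("wm")
    for cls, i in zip(remaining, sorted(free, key=lambda i: centres[i][t1_idx])):
        means[cls] = centres[i]
        free.remove(i)
    return means


def fit_mixture(image: SubjectImage, priors=None, channels=("t1w",),
                classes=("gm", "wm", "csf", "background"),
                config: FitConfig | None = None) -> tuple[MixtureModel, TPMSet]:
    """Fit the prior-weighted Gaussian mixture and return posterior TPMs.

    ``priors`` is a :class:`TPMSet` (or anything with matching ``probs``)
    giving voxel-wise class priors; ``None`` means flat priors.  The
    returned TPMs are the per-voxel posterior class responsibilities and
    sum to one by construction.

    Channels are canonicalised to sorted name order internally, so a
    consistent relabelling of the input channels leaves the posteriors
    bit-identical.
    """
    config = config or FitConfig()
    channels = tuple(sorted(channels))
    classes = tuple(classes)
    Y = image.stacked(channels)
    V, C = Y.shape
    K = len(classes)

    if priors is not None:
        missing = [c for c in classes if c not in priors.probs]
        if missing:
            raise ValueError(f"priors lack classes {missing}")
        if priors.probs[classes[0]].shape != image.shape:
            raise ValueError("prior geometry does not match the image")
        P = np.stack([priors.probs[c].reshape(-1) for c in classes], axis=1)
        P = np.clip(P, 1e-12, None)
        log_prior = config.alpha * np.log(P)
    else:
        log_prior = np.zeros((V, K))

    weights, class_weights, means, covs = _initial_params(Y, channels, classes, config)
    comp_index = [(cls, j) for cls in classes for j in range(config.components_for(cls))]
    n_comp = len(comp_index)
    ridge_base = config.ridge * float(Y.var(axis=0).mean() + 1e-12)

    loglik_trace = []
    converged = False
    log_r = np.empty((V, n_comp))
    for it in range(config.max_iter):
        # E-step
        for m, (cls, j) in enumerate(comp_index):
            lg, covs[cls][j] = _log_gauss(Y, means[cls][j], covs[cls][j], ridge_base)
            ci = classes.index(cls)
            log_r[:, m] = (log_prior[:, ci]
                           + np.log(class_weights[cls] * weights[cls][j] + 1e-300) + lg)
        norm = logsumexp(log_r, axis=1)
        ll = float(norm.sum())
        loglik_trace.append(ll)
        R = np.exp(log_r - norm[:, None])

        # M-step
        for m, (cls, j) in enumerate(comp_index):
            r = R[:, m]
            tot = r.sum()
            if tot < 1e-10:
                continue  # dead component: keep previous parameters
            mu = (r @ Y) / tot
            diff = Y - mu
            cov = (diff * r[:, None]).T @ diff / tot
            cov += np.eye(C) * ridge_base * 1e-3
            means[cls][j] = mu
            covs[cls][j] = cov
        for cls in classes:
            idx = [m for m, (c, _) in enumerate(comp_index) if c == cls]
            totals = R[:, idx].sum(axis=0)
            s = totals.sum()
            if s > 0:
                weights[cls] = totals / s
            class_weights[cls] = s / V

        if it > 0:
            prev = loglik_trace[-2]
            if abs(ll - prev) <= config.tol * (abs(prev) + 1e-12):
                converged = True
                break

    if not converged:
        warnings.warn("EM did not converge within max_iter", ConvergenceWarning)

    # final E-step with the last parameters so TPMs match the model exactly
    for m, (cls, j) in enumerate(comp_index):
        lg, _ = _log_gauss(Y, means[cls][j], covs[cls][j], ridge_base)
        ci = classes.index(cls)
        log_r[:, m] = (log_prior[:, ci]
                       + np.log(class_weights[cls] * weights[cls][j] + 1e-300) + lg)
    R = np.exp(log_r - logsumexp(log_r, axis=1)[:, None])

    probs = {}
    for ci, cls in enumerate(classes):
        idx = [m for m, (c, _) in enumerate(comp_index) if c == cls]
        probs[cls] = R[:, idx].sum(axis=1).reshape(image.shape)

    model = MixtureModel(classes=classes, channels=tuple(channels),
                         weights=weights, class_weights=class_weights,
                         means=means, covariances=covs,
                         alpha=config.alpha, loglik_trace=loglik_trace,
                         converged=converged)
    tpms = TPMSet(probs=probs, voxel_size=image.voxel_size, affine=image.affine,
                  meta={"converged": converged, "alpha": config.alpha,
                        "channels": list(channels)})
    return model, tpms


def build_population_tpm(tpm_list, smoothing_fwhm_mm: float = 4.0) -> TPMSet:
    """Population priors: voxel-wise mean of subject TPMs, Gaussian
    smoothed, renormalised to sum to one per voxel.

    All subjects must share the common-space geometry.  Smoothing uses
    zero-padded borders; the per-voxel renormalisation divides by the
    smoothed all-ones field, so interior values equal the plain blurred
    mean.
    """
    if len(tpm_list) < 2:
        raise ValueError("population priors need at least 2 subjects")
    ref = tpm_list[0]
    for t in tpm_list[1:]:
        if not ref.same_geometry(t):
            raise ValueError("subject TPMs disagree on geometry")
    from scipy import ndimage

    classes = ref.classes
    mean_maps = {c: np.mean([t.probs[c] for t in tpm_list], axis=0) for c in classes}
    if smoothing_fwhm_mm > 0:
        sigma_vox = (smoothing_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
                     / np.asarray(ref.voxel_size))
        mean_maps = {c: ndimage.gaussian_filter(v, sigma=sigma_vox, mode="constant")
                     for c, v in mean_maps.items()}
    total = np.zeros(ref.shape)
    for v in mean_maps.values():
        total += v
    total = np.where(total > 0, total, 1.0)
    probs = {c: v / total for c, v in mean_maps.items()}
    return TPMSet(probs=probs, voxel_size=ref.voxel_size, affine=ref.affine,
                  meta={"n_subjects": len(tpm_list),
                        "smoothing_fwhm_mm": smoothing_fwhm_mm})


def resegment_with_priors(image: SubjectImage, priors: TPMSet,
                          config: FitConfig | None = None,
                          channels=None) -> TPMSet:
    """Re-segment a native image using population priors.

    When a ``flair`` channel is supplied the priors must include a WML
    class (the two-channel model is what separates lesions from GM).
    """
    channels = tuple(channels or image.channels)
    if "flair" in channels and "wml" not in priors.probs:
        raise ValueError("priors must include a wml class for FLAIR re-segmentation")
    classes = tuple(priors.classes)
    _, tpms = fit_mixture(image, priors=priors, channels=channels,
                          classes=classes, config=config)
    return tpms


def skull_strip(tpms: TPMSet, threshold: float = 0.1) -> np.ndarray:
    """Brain mask: combined non-background tissue probability > threshold."""
    total = np.zeros(tpms.shape)
    for cls, vol in tpms.probs.items():
        if cls != "background":
            total += vol
    mask = total > threshold
    if not mask.any():
        raise ValueError("skull stripping produced an empty brain mask")
    return mask
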