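"""Mass-univariate mixed-design ANOVA with cluster-mass permutation control.

For one spatial IC cluster, the data are a stack of per-IC ERSP pairs
(NoSupp and the collapsed suppression condition Supp_Ave).  At every
time-frequency pixel a 2 (Group, between) x 2 (Suppression, within)
split-plot ANOVA yields F statistics for the Group and Suppression main
effects and their Interaction; the observation unit is the IC, as the ERSP
tensor's third dimension.  Suprathreshold pixels (parametric p < 0.05) are
grouped into connected components, each component's *mass* is the sum of
|F| over its pixels, and significance is declared by comparing each true
mass against the 95th percentile of the permutation distribution of the
maximum mass — weak control of the family-wise error rate (wFWER).

Because both factors have two levels, every F map reduces to closed-form
expressions in the per-IC condition means ``M`` and differences ``D``; the
permutation loop exploits this to recompute thousands of F maps with a few
matrix products.

Label shuffling respects the dependence structure: the Suppression effect
flips the sign of ``D`` within ICs; the Group effect and the Interaction
permute group labels across *subjects*, moving all of a subject's ICs
together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "EFFECTS",
    "FStatMap",
    "PixelCluster",
    "NullDistribution",
    "SignificanceMask",
    "mixed_anova_fmaps",
    "extract_clusters",
    "wfwer_permutation_test",
]

EFFECTS = ("Group", "Suppression", "Interaction")

#: minimum number of exchangeable units for a permutation test
_MIN_UNITS = 5


@dataclass(frozen=True)
class FStatMap:
    effect: str
    F: np.ndarray  # (n_freqs, n_times)
    p: np.ndarray
    df: tuple[int, int]


@dataclass(frozen=True)
class PixelCluster:
    """A connected set of suprathreshold pixels and its mass (sum of |F|)."""

    pixels: tuple[np.ndarray, np.ndarray]  # (freq indices, time indices)
    mass: float

    @property
    def size(self) -> int:
        return int(self.pixels[0].size)


@dataclass(frozen=True)
class NullDistribution:
    effect: str
    max_masses: np.ndarray  # (n_perm,)
    threshold: float  # 95th percentile (linear interpolation)


@dataclass(frozen=True)
class SignificanceMask:
    effect: str
    mask: np.ndarray  # bool (n_freqs, n_times): union of significant clusters
    clusters: list[PixelCluster]  # all suprathreshold clusters of the true map
    significant: np.ndarray  # bool per cluster
    threshold: float
    direction: float  # mean effect contrast within the mask (dB); 0 if empty


def _prepare(data, groups):
    data = np.asarray(data, dtype=float)
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError("data must have shape (n_ics, 2, n_freqs, n_times)")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contain non-finite values")
    groups = np.asarray(groups)
    if groups.shape != (data.shape[0],):
        raise ValueError("groups must have one label per IC")
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels.size}")
    g = groups == levels[1]
    if min((~g).sum(), g.sum()) < 2:
        raise ValueError("need at least 2 ICs in each group")
    n, _, nf, nt = data.shape
    M = data.mean(axis=1).reshape(n, nf * nt)
    D = (data[:, 1] - data[:, 0]).reshape(n, nf * nt)
    return M, D, g, (nf, nt)


def _safe_f(num_ss, num_df, den_ss, den_df):
    """F ratio with 0/0 -> 0 (no variance at all means no evidence)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (num_ss / num_df) / (den_ss / den_df)
    f = np.where(num_ss <= 0, 0.0, f)
    return np.where(np.isfinite(f), f, np.inf)


def mixed_anova_fmaps(data, groups) -> dict[str, FStatMap]:
    """Pixel-wise split-plot F maps for Group, Suppression and Interaction.

    Parameters
    ----------
    data
        ``(n_ics, 2, n_freqs, n_times)``; condition axis ordered
        ``(NoSupp, Supp_Ave)``.
    groups
        per-IC group label (two levels; the between factor).
    """
    M, D, g, shape = _prepare(data, groups)
    n = M.shape[0]
    n1, n2 = int((~g).sum()), int(g.sum())
    df_err = n - 2

    m1, m2 = M[~g].mean(axis=0), M[g].mean(axis=0)
    gm = (n1 * m1 + n2 * m2) / n
    ss_group = 2.0 * (n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2)
    ss_subj = 2.0 * (
        ((M[~g] - m1) ** 2).sum(axis=0) + ((M[g] - m2) ** 2).sum(axis=0)
    )

    d1, d2 = D[~g].mean(axis=0), D[g].mean(axis=0)
    dbar = (n1 * d1 + n2 * d2) / n
    ss_supp = n * dbar**2 / 2.0
    ss_inter = (n1 * (d1 - dbar) ** 2 + n2 * (d2 - dbar) ** 2) / 2.0
    ss_err = (((D[~g] - d1) ** 2).sum(axis=0) + ((D[g] - d2) ** 2).sum(axis=0)) / 2.0

    out = {}
    for effect, num, den in (
        ("Group", ss_group, ss_subj),
        ("Suppression", ss_supp, ss_err),
        ("Interaction", ss_inter, ss_err),
    ):
        f = _safe_f(num, 1, den, df_err)
        p = stats.f.sf(f, 1, df_err)
        out[effect] = FStatMap(
            effect=effect,
            F=f.reshape(shape),
            p=p.reshape(shape),
            df=(1, df_err),
        )
    return out


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def extract_clusters(
    fmap: FStatMap, alpha_pixel: float = 0.05, connectivity: int = 4
) -> list[PixelCluster]:
    """Connected suprathreshold components of an F map and their masses."""
    structure = _connectivity_structure(connectivity)
    supra = fmap.p < alpha_pixel
    labeled, n_clusters = ndimage.label(supra, structure=structure)
    clusters = []
    for idx in range(1, n_clusters + 1):
        pix = np.nonzero(labeled == idx)
        mass = float(np.abs(fmap.F[pix]).sum())
        clusters.append(PixelCluster(pixels=pix, mass=mass))
    return clusters


def _max_masses(f_stack, f_crit, shape, structure) -> np.ndarray:
    """Largest cluster mass of each permuted F map (0 when nothing survives)."""
    out = np.empty(f_stack.shape[0])
    for i, f_flat in enumerate(f_stack):
        f_map = f_flat.reshape(shape)
        labeled, n_clusters = ndimage.label(f_map > f_crit, structure=structure)
        if n_clusters == 0:
            out[i] = 0.0
        else:
            masses = ndimage.sum_labels(f_map, labeled, index=np.arange(1, n_clusters + 1))
            out[i] = masses.max()
    return out


def _suppression_f_from_signs(D, g, signs) -> np.ndarray:
    """Suppression-effect F maps after flipping each IC's condition order."""
    n = D.shape[0]
    n1, n2 = int((~g).sum()), int(g.sum())
    d_sq = (D**2).sum(axis=0)
    d1 = (signs[:, ~g] @ D[~g]) / n1
    d2 = (signs[:, g] @ D[g]) / n2
    dbar = (n1 * d1 + n2 * d2) / n
    ss_supp = n * dbar**2 / 2.0
    ss_err = (d_sq[None, :] - n1 * d1**2 - n2 * d2**2) / 2.0
    return _safe_f(ss_supp, 1, ss_err, n - 2)


def _between_f_from_indicator(X, indicator, effect) -> np.ndarray:
    """Group / Interaction F maps for permuted group memberships.

    ``X`` is ``M`` for the Group effect and ``D`` for the Interaction;
    ``indicator`` is a boolean (n_perm, n_ics) membership matrix of the
    second group.
    """
    n = X.shape[0]
    n2 = indicator.sum(axis=1, keepdims=True).astype(float)
    n1 = n - n2
    ind = indicator.astype(float)
    s2 = ind @ X
    total = X.sum(axis=0, keepdims=True)
    x1 = (total - s2) / n1
    x2 = s2 / n2
    x_sq = (X**2).sum(axis=0)
    if effect == "Group":
        gm = total / n
        ss_num = 2.0 * (n1 * (x1 - gm) ** 2 + n2 * (x2 - gm) ** 2)
        ss_den = 2.0 * (x_sq[None, :] - n1 * x1**2 - n2 * x2**2)
    else:  # Interaction
        xbar = total / n
        ss_num = (n1 * (x1 - xbar) ** 2 + n2 * (x2 - xbar) ** 2) / 2.0
        ss_den = (x_sq[None, :] - n1 * x1**2 - n2 * x2**2) / 2.0
    return _safe_f(ss_num, 1, ss_den, n - 2)


def wfwer_permutation_test(
    data,
    groups,
    subject_ids,
    effect: str,
    n_perm: int = 1000,
    seed: int = 0,
    alpha_pixel: float = 0.05,
    alpha_cluster: float = 0.05,
    connectivity: int = 4,
    chunk: int = 200,
) -> tuple[NullDistribution, SignificanceMask]:
    """Cluster-mass permutation test with weak FWER control for one effect.

    True clusters whose mass exceeds the ``1 - alpha_cluster`` empirical
    quantile of the permutation maximum-mass distribution are flagged
    significant; the returned mask is their union.  Deterministic for a
    fixed seed.
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    M, D, g, shape = _prepare(data, groups)
    subject_ids = np.asarray(subject_ids)
    if subject_ids.shape != (M.shape[0],):
        raise ValueError("subject_ids must have one entry per IC")
    structure = _connectivity_structure(connectivity)
    rng = np.random.default_rng(seed)
    n = M.shape[0]
    df_err = n - 2
    f_crit = stats.f.isf(alpha_pixel, 1, df_err)

    fmaps = mixed_anova_fmaps(data, groups)
    true_map = fmaps[effect]
    true_clusters = extract_clusters(true_map, alpha_pixel, connectivity)

    if effect == "Suppression":
        if n < _MIN_UNITS:
            raise ValueError(
                f"need at least {_MIN_UNITS} ICs to permute condition order; got {n}"
            )
        max_masses = np.empty(n_perm)
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            signs = rng.choice([-1.0, 1.0], size=(m, n))
            f_stack = _suppression_f_from_signs(D, g, signs)
            max_masses[done : done + m] = _max_masses(f_stack, f_crit, shape, structure)
            done += m
    else:
        uniq, subj_idx = np.unique(subject_ids, return_inverse=True)
        n_subj = uniq.size
        if n_subj < _MIN_UNITS:
            raise ValueError(
                f"need at least {_MIN_UNITS} subjects to permute group labels; got {n_subj}"
            )
        # group label per subject; must be constant within subject
        subj_group = np.zeros(n_subj, dtype=bool)
        for j in range(n_subj):
            labels = np.unique(g[subj_idx == j])
            if labels.size != 1:
                raise ValueError("group label varies within a subject")
            subj_group[j] = labels[0]
        X = M if effect == "Group" else D
        max_masses = np.empty(n_perm)
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perm_subj = np.stack([rng.permutation(subj_group) for _ in range(m)])
            indicator = perm_subj[:, subj_idx]
            f_stack = _between_f_from_indicator(X, indicator, effect)
            max_masses[done : done + m] = _max_masses(f_stack, f_crit, shape, structure)
            done += m

    threshold = float(np.percentile(max_masses, 100.0 * (1.0 - alpha_cluster)))
    significant = np.array([c.mass > threshold for c in true_clusters], dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    for c, sig in zip(true_clusters, significant):
        if sig:
            mask[c.pixels] = True

    if mask.any():
        if effect == "Group":
            contrast = M[g][:, mask.ravel()].mean() - M[~g][:, mask.ravel()].mean()
        elif effect == "Suppression":
            direction_vals = D[:, mask.ravel()]
            contrast = direction_vals.mean()
        else:
            contrast = D[g][:, mask.ravel()].mean() - D[~g][:, mask.ravel()].mean()
        direction = float(contrast)
    else:
        direction = 0.0

    null = NullDistribution(effect=effect, max_masses=max_masses, threshold=threshold)
    sig_mask = SignificanceMask(
        effect=effect,
        mask=mask,
        clusters=true_clusters,
        significant=significant,
        threshold=threshold,
        direction=direction,
    )
    return null, sig_mask
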